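"""Per-taxon genomic-feature summaries and ANI-based UPGMA dendrograms.

Feature summaries (genome size, G+C content, CDS counts and lengths,
16S copy number) are compiled at every rank from species up to phylum, each
genome contributing once per ancestor taxon. Dendrograms are built from an
ANI matrix by UPGMA on the distance d = 100 - ANI with merge heights d/2,
so the tree is ultrametric and branch lengths are in percent-identity
half-distance units.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .orthoani import ANIMatrix

RANKS = ("phylum", "class", "order", "family", "genus", "species", "subspecies")

FEATURES = (
    "genome_size",
    "gc",
    "n_cds",
    "mean_cds_len",
    "mean_intergenic_len",
    "n_16s_copies",
)

_STATS = ("min", "q1", "median", "q3", "max", "mean", "sd")


def _feature_stats(x: pd.Series) -> dict[str, float]:
    v = x.dropna().to_numpy(dtype=float)
    if v.size == 0:
        return {}
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    return {
        "min": float(v.min()),
        "q1": float(q1),
        "median": float(med),
        "q3": float(q3),
        "max": float(v.max()),
        "mean": float(v.mean()),
        "sd": float(v.std(ddof=1)) if v.size > 1 else 0.0,
    }


@dataclass(frozen=True)
class TaxonFeatureSummary:
    taxon: str
    rank: str
    n_genomes: int
    features: dict[str, dict[str, float]]  # feature -> stat -> value; absent features omitted


def summarize_taxon(
    features: pd.DataFrame, taxonomy: pd.DataFrame
) -> list[TaxonFeatureSummary]:
    """Summarise per-genome features at every taxonomic rank.

    ``features`` has one row per genome_id with any subset of FEATURES
    columns (missing columns or NaNs are reported as absent, not zero);
    16S copy number is summarised only over genomes whose ``complete``
    column is true, since copy number is unreliable in draft assemblies.
    ``taxonomy`` maps genome_id to the rank columns.
    """
    merged = features.merge(taxonomy, on="genome_id", how="left", validate="one_to_one")
    missing = merged["species"].isna()
    if missing.any():
        import logging

        logging.getLogger(__name__).warning(
            "%d genomes lack taxonomy and are excluded", int(missing.sum())
        )
        merged = merged[~missing]

    summaries: list[TaxonFeatureSummary] = []
    for rank in RANKS:
        if rank not in merged.columns:
            continue
        sub = merged[merged[rank].notna() & (merged[rank] != "")]
        for taxon, grp in sub.groupby(rank, sort=True):
            feats: dict[str, dict[str, float]] = {}
            for feat in FEATURES:
                if feat not in grp.columns:
                    continue
                col = grp[feat]
                if feat == "n_16s_copies" and "complete" in grp.columns:
                    col = col[grp["complete"].astype(bool)]
                st = _feature_stats(col)
                if st:
                    feats[feat] = st
            summaries.append(
                TaxonFeatureSummary(
                    taxon=str(taxon), rank=rank, n_genomes=len(grp), features=feats
                )
            )
    return summaries


def summaries_to_frame(summaries: list[TaxonFeatureSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        row: dict[str, object] = {"taxon": s.taxon, "rank": s.rank, "n_genomes": s.n_genomes}
        for feat, st in s.features.items():
            for name in _STATS:
                row[f"{feat}_{name}"] = st[name]
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# UPGMA


@dataclass
class DendroNode:
    """Node of a rooted ultrametric dendrogram (leaf iff name is set)."""

    height: float
    name: str | None = None
    children: tuple["DendroNode", "DendroNode"] | None = None

    @property
    def is_leaf(self) -> bool:
        return self.children is None

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.name]  # type: ignore[list-item]
        out: list[str] = []
        for c in self.children:  # type: ignore[union-attr]
            out.extend(c.leaves())
        return out


@dataclass(frozen=True)
class Dendrogram:
    root: DendroNode

    def leaf_names(self) -> list[str]:
        return self.root.leaves()


def upgma(m: ANIMatrix) -> Dendrogram:
    """UPGMA tree from an ANI matrix (d = 100 - ANI, merge height d/2).

    Agglomeration uses arithmetic-mean (size-weighted) cluster distances;
    among pairs at the minimal distance the one whose sorted leading leaf
    names are lexicographically smallest is merged, making the topology
    deterministic.
    """
    n = len(m.ids)
    if n < 2:
        raise ValueError("UPGMA needs at least two leaves")
    dist = 100.0 - m.values
    clusters: dict[int, DendroNode] = {
        i: DendroNode(height=0.0, name=m.ids[i]) for i in range(n)
    }
    sizes = {i: 1 for i in range(n)}
    lead = {i: m.ids[i] for i in range(n)}  # smallest leaf name per cluster
    d = {(i, j): dist[i, j] for i in range(n) for j in range(i + 1, n)}
    next_id = n
    while len(clusters) > 1:
        best_key = None
        best_pair = None
        for (i, j), dij in d.items():
            key = (dij, *sorted((lead[i], lead[j])))
            if best_key is None or key < best_key:
                best_key, best_pair = key, (i, j)
        i, j = best_pair  # type: ignore[misc]
        h = d[(i, j)] / 2.0
        merged = DendroNode(height=h, children=(clusters[i], clusters[j]))
        new = next_id
        next_id += 1
        for k in list(clusters):
            if k in (i, j):
                continue
            dik = d[tuple(sorted((i, k)))]
            djk = d[tuple(sorted((j, k)))]
            d[(k, new)] = (sizes[i] * dik + sizes[j] * djk) / (sizes[i] + sizes[j])
        for key in [key for key in d if i in key or j in key]:
            del d[key]
        sizes[new] = sizes.pop(i) + sizes.pop(j)
        lead[new] = min(lead.pop(i), lead.pop(j))
        clusters[new] = merged
        del clusters[i], clusters[j]
    return Dendrogram(root=next(iter(clusters.values())))


def _newick(node: DendroNode, parent_height: float | None) -> str:
    if node.is_leaf:
        label = node.name
    else:
        a, b = node.children  # type: ignore[misc]
        label = f"({_newick(a, node.height)},{_newick(b, node.height)})"
    if parent_height is None:
        return label  # root carries no branch length
    return f"{label}:{parent_height - node.height:.17g}"


def write_newick(t: Dendrogram, path: str | Path | None = None) -> str:
    """Serialise a dendrogram to Newick with branch lengths."""
    text = _newick(t.root, None) + ";"
    if path is not None:
        Path(path).write_text(text + "\n")
    return text
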