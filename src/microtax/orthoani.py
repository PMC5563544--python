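"""Fragment-based reciprocal-best-hit average nucleotide identity.

Both genomes are cut into consecutive, non-overlapping 1020 bp fragments
(trailing remainders discarded). Every fragment of one genome is searched
against the fragments of the other, strand-aware: candidate partner
fragments are nominated by shared canonical k-mer seeds and scored by an
edit-distance alignment of the query fragment as an infix of the candidate
fragment plus flanking sequence (robust to indels shifting the fragment
grid), in the better orientation. Orthologous
fragment pairs are reciprocal best hits, and the ANI is the mean percent
identity over those pairs, averaging the two search directions.

A comparison that yields zero orthologous pairs is reported as a distinct
"no ANI" outcome, never as ANI = 0 — unrelated genomes must not produce a
spurious low identity that could drive a taxonomic call.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import edlib
import numpy as np

from .genomeio import GenomeAssembly, reverse_complement

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Fragment:
    contig: str
    start: int  # 0-based offset of the fragment on its contig
    seq: str


@dataclass(frozen=True)
class OrthoANIConfig:
    frag_len: int = 1020
    seed_k: int = 15            # canonical seed k-mer size
    min_seed_kmers: int = 5     # shared seeds required to nominate a pair
    max_candidates: int = 2     # candidate partners aligned per fragment
    min_identity: float = 0.35  # floor on fragment alignment identity
    min_coverage: float = 0.35  # floor on aligned fraction of the fragment


@dataclass(frozen=True)
class ANIResult:
    query_id: str
    ref_id: str
    ani: float | None           # percent; None encodes the "no ANI" outcome
    n_ortho_pairs: int
    coverage: float             # fraction of query fragments in ortho pairs

    @property
    def has_ani(self) -> bool:
        return self.ani is not None


def fragment_genome(asm: GenomeAssembly, frag_len: int = 1020) -> list[Fragment]:
    """Cut each contig into consecutive frag_len pieces; drop remainders."""
    if frag_len <= 0:
        raise ValueError("fragment length must be positive")
    frags: list[Fragment] = []
    for name, seq in asm.contigs:
        for start in range(0, len(seq) - frag_len + 1, frag_len):
            frags.append(Fragment(contig=name, start=start, seq=seq[start : start + frag_len]))
    return frags


def _seed_sets(frags: list[Fragment], k: int) -> list[np.ndarray]:
    """Sorted unique canonical k-mer seeds per fragment, integer-encoded."""
    code = np.full(256, -1, dtype=np.int64)
    for i, b in enumerate("ACGT"):
        code[ord(b)] = i
    comp = 3 - np.arange(4)
    out: list[np.ndarray] = []
    for frag in frags:
        codes = code[np.frombuffer(frag.seq.encode(), dtype=np.uint8)]
        n = codes.size
        fwd = np.zeros(n - k + 1, dtype=np.int64)
        rev = np.zeros(n - k + 1, dtype=np.int64)
        valid = np.ones(n - k + 1, dtype=bool)
        for j in range(k):
            c = codes[j : n - k + 1 + j]
            fwd = fwd * 4 + np.where(c < 0, 0, c)
            rc = codes[k - 1 - j : n - j]
            rev = rev * 4 + np.where(rc < 0, 0, comp[np.clip(rc, 0, 3)])
            valid &= c >= 0
        canon = np.minimum(fwd, rev)[valid]
        out.append(np.unique(canon))
    return out


def _extended_window(frag: Fragment, contigs: dict[str, str], frag_len: int) -> str:
    """The candidate fragment padded with one fragment length of flanking
    contig sequence on each side; alignment as an infix of this window keeps
    identity robust when indels have shifted the fragment grid."""
    seq = contigs[frag.contig]
    return seq[max(0, frag.start - frag_len) : frag.start + 2 * frag_len]


def _best_hits(
    frags_q: list[Fragment],
    seeds_q: list[np.ndarray],
    frags_r: list[Fragment],
    seeds_r: list[np.ndarray],
    contigs_r: dict[str, str],
    cfg: OrthoANIConfig,
) -> dict[int, tuple[int, float]]:
    """Best partner fragment in the reference for each query fragment.

    Returns {query index: (ref index, identity percent)} for fragments with
    an acceptable hit.
    """
    if not seeds_r:
        return {}
    ref_kmers = np.concatenate(seeds_r)
    ref_ids = np.repeat(
        np.arange(len(seeds_r)), [s.size for s in seeds_r]
    )
    order = np.argsort(ref_kmers, kind="stable")
    ref_kmers = ref_kmers[order]
    ref_ids = ref_ids[order]

    hits: dict[int, tuple[int, float]] = {}
    for i, qk in enumerate(seeds_q):
        lo = np.searchsorted(ref_kmers, qk, side="left")
        hi = np.searchsorted(ref_kmers, qk, side="right")
        sel = hi > lo
        if not sel.any():
            continue
        matched = np.concatenate(
            [ref_ids[a:b] for a, b in zip(lo[sel], hi[sel])]
        )
        counts = np.bincount(matched, minlength=len(seeds_r))
        cands = np.nonzero(counts >= cfg.min_seed_kmers)[0]
        if cands.size == 0:
            continue
        cands = sorted(cands.tolist(), key=lambda j: (-int(counts[j]), j))
        best: tuple[float, int] | None = None
        q = frags_q[i].seq
        for j in cands[: cfg.max_candidates]:
            t = _extended_window(frags_r[j], contigs_r, cfg.frag_len)
            d_f = edlib.align(q, t, mode="HW", task="distance")["editDistance"]
            d_r = edlib.align(q, reverse_complement(t), mode="HW", task="distance")["editDistance"]
            d = min(d_f, d_r)
            ident = 1.0 - d / cfg.frag_len
            # candidates arrive in decreasing shared-seed order; on identity
            # ties keep the earlier (higher-seed) one — seed counts are
            # symmetric, which keeps best hits reciprocal
            if best is None or ident > best[0]:
                best = (ident, j)
        ident, j = best
        if ident < cfg.min_identity:
            continue
        # the infix alignment consumes the whole query fragment, so aligned
        # coverage is complete up to indel slack; the floor guards
        # degenerate configs
        if 1.0 < cfg.min_coverage:
            continue
        hits[i] = (j, 100.0 * ident)
    return hits


def orthoani(
    a: GenomeAssembly, b: GenomeAssembly, cfg: OrthoANIConfig | None = None
) -> ANIResult:
    """OrthoANI between two assemblies (symmetric by construction)."""
    cfg = cfg or OrthoANIConfig()
    frags_a = fragment_genome(a, cfg.frag_len)
    frags_b = fragment_genome(b, cfg.frag_len)
    if not frags_a or not frags_b:
        raise ValueError(
            f"orthoani needs at least one full {cfg.frag_len} bp fragment per "
            f"genome ({a.id}: {len(frags_a)}, {b.id}: {len(frags_b)})"
        )
    seeds_a = _seed_sets(frags_a, cfg.seed_k)
    seeds_b = _seed_sets(frags_b, cfg.seed_k)
    contigs_a = dict(a.contigs)
    contigs_b = dict(b.contigs)
    ab = _best_hits(frags_a, seeds_a, frags_b, seeds_b, contigs_b, cfg)
    ba = _best_hits(frags_b, seeds_b, frags_a, seeds_a, contigs_a, cfg)

    identities: list[float] = []
    n_pairs = 0
    for i, (j, ident_ab) in ab.items():
        back = ba.get(j)
        if back is not None and back[0] == i:
            identities.append(0.5 * (ident_ab + back[1]))
            n_pairs += 1
    if n_pairs == 0:
        logger.info("%s vs %s: no orthologous fragment pairs", a.id, b.id)
        return ANIResult(query_id=a.id, ref_id=b.id, ani=None, n_ortho_pairs=0, coverage=0.0)
    return ANIResult(
        query_id=a.id,
        ref_id=b.id,
        ani=float(np.mean(identities)),
        n_ortho_pairs=n_pairs,
        coverage=n_pairs / len(frags_a),
    )


@dataclass(frozen=True)
class ANIMatrix:
    ids: tuple[str, ...]
    values: np.ndarray            # percent, symmetric, diagonal 100
    no_ani: np.ndarray            # bool mask of pairs without orthologous pairs

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape must match id count")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("ANI matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 100.0):
            raise ValueError("ANI matrix diagonal must be 100")


def ani_matrix(
    genomes: list[GenomeAssembly],
    cfg: OrthoANIConfig | None = None,
    no_ani_floor: float = 60.0,
) -> ANIMatrix:
    """All-vs-all ANI; pairs without orthologous fragments get a floor value.

    The floor keeps the matrix usable for dendrograms; the ``no_ani`` mask
    flags which cells it filled.
    """
    if len(genomes) < 2:
        raise ValueError("ANI matrix needs at least two genomes")
    ids = tuple(g.id for g in genomes)
    n = len(ids)
    vals = np.full((n, n), 100.0)
    mask = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            res = orthoani(genomes[i], genomes[j], cfg)
            if res.has_ani:
                vals[i, j] = vals[j, i] = res.ani
            else:
                vals[i, j] = vals[j, i] = no_ani_floor
                mask[i, j] = mask[j, i] = True
    return ANIMatrix(ids=ids, values=vals, no_ani=mask)


def write_ani_matrix_tsv(m: ANIMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("id\t" + "\t".join(m.ids) + "\n")
        for i, gid in enumerate(m.ids):
            fh.write(gid + "\t" + "\t".join(f"{x:.4f}" for x in m.values[i]) + "\n")


def read_ani_matrix_tsv(path: str | Path) -> ANIMatrix:
    with open(path) as fh:
        ids = tuple(fh.readline().rstrip("\n").split("\t")[1:])
        rows = []
        for line in fh:
            rows.append([float(x) for x in line.rstrip("\n").split("\t")[1:]])
    vals = np.asarray(rows)
    return ANIMatrix(ids=ids, values=vals, no_ani=np.zeros_like(vals, dtype=bool))
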