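"""Marker genes: extraction from assemblies and two-step similarity search.

Three phylogenetic markers are handled: the 16S rRNA gene (SSU16S) and the
protein-coding genes gyrB and recA. Markers are located in an assembly by
semi-global alignment of bait sequences (known copies of the gene) against
every contig and strand; the best location above configurable identity and
coverage thresholds is extracted with coordinates.

Searches of a marker against a reference collection use a two-step scheme:
a fast canonical k-mer prefilter shortlists candidate references, then a
global alignment with free terminal gaps scores each survivor. Similarity
is the "taxonomically meaningful" convention: matches over all alignment
columns between the first and last aligned base pair — internal gap columns
count against similarity, terminal overhangs (e.g. a partial amplicon
against a full-length gene) do not.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from functools import lru_cache

import edlib
from Bio.Align import PairwiseAligner

from .genomeio import GenomeAssembly, reverse_complement

logger = logging.getLogger(__name__)


class MarkerType(str, Enum):
    SSU16S = "SSU16S"
    gyrB = "gyrB"
    recA = "recA"


@dataclass(frozen=True)
class MarkerGene:
    """A typed marker-gene sequence located on an assembly contig.

    Coordinates are 0-based half-open on the plus strand of the contig;
    ``seq`` is the plus-strand extract, reverse-complemented when strand
    is '-'.
    """

    marker_type: MarkerType
    genome_id: str
    contig: str
    start: int
    end: int
    strand: str
    seq: str

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("marker end must exceed start")
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        if len(self.seq) != self.end - self.start:
            raise ValueError("marker seq length must equal end - start")


@dataclass(frozen=True)
class SimilarityHit:
    ref_id: str
    similarity: float  # percent
    aligned_columns: int

    def __post_init__(self) -> None:
        if self.similarity > 100.0:
            raise ValueError("similarity cannot exceed 100")


@dataclass(frozen=True)
class ExtractionConfig:
    min_identity: float = 0.70   # fraction of bait length matched
    min_coverage: float = 0.50   # aligned span / bait length


def _best_bait_placement(bait: str, contig: str):
    """Best infix placement of *bait* in *contig*, either strand.

    Returns (identity, start, end, strand) with plus-strand coordinates,
    or None if edlib finds no alignment. Identity is 1 - d/len(bait), the
    edit-distance identity relative to the bait.
    """
    best = None
    L = len(contig)
    for strand, target in (("+", contig), ("-", reverse_complement(contig))):
        res = edlib.align(bait, target, mode="HW", task="locations")
        d = res["editDistance"]
        if d < 0 or not res["locations"]:
            continue
        s, e = res["locations"][0]
        e += 1  # edlib end is inclusive
        if strand == "-":
            s, e = L - e, L - s
        ident = 1.0 - d / len(bait)
        key = (ident, -(s), strand)
        if best is None or key > best[0]:
            best = (key, ident, s, e, strand)
    if best is None:
        return None
    return best[1], best[2], best[3], best[4]


def extract_markers(
    asm: GenomeAssembly,
    bait_set: list[MarkerGene],
    cfg: ExtractionConfig | None = None,
) -> list[MarkerGene]:
    """Locate marker genes in *asm* using bait sequences.

    For each marker type present in ``bait_set`` the best-scoring placement
    across all baits, contigs and strands is kept if it clears the identity
    and coverage thresholds; marker types without an acceptable hit are
    simply absent from the result (a legal outcome consumed downstream).
    """
    cfg = cfg or ExtractionConfig()
    by_type: dict[MarkerType, list[MarkerGene]] = {}
    for bait in bait_set:
        by_type.setdefault(MarkerType(bait.marker_type), []).append(bait)

    found: list[MarkerGene] = []
    for mtype in sorted(by_type, key=lambda m: m.value):
        best = None  # (identity, contig, start, end, strand)
        for bait in by_type[mtype]:
            for contig_name, contig_seq in asm.contigs:
                if len(contig_seq) < len(bait.seq) * cfg.min_coverage:
                    continue
                placed = _best_bait_placement(bait.seq, contig_seq)
                if placed is None:
                    continue
                ident, s, e, strand = placed
                if ident < cfg.min_identity:
                    continue
                if (e - s) < cfg.min_coverage * len(bait.seq):
                    continue
                key = (ident, -s, contig_name)
                if best is None or key > best[0]:
                    best = (key, contig_name, s, e, strand)
        if best is not None:
            _, contig_name, s, e, strand = best
            contig_seq = dict(asm.contigs)[contig_name]
            sub = contig_seq[s:e]
            if strand == "-":
                sub = reverse_complement(sub)
            found.append(
                MarkerGene(
                    marker_type=mtype,
                    genome_id=asm.id,
                    contig=contig_name,
                    start=s,
                    end=e,
                    strand=strand,
                    seq=sub,
                )
            )
    return found


# ---------------------------------------------------------------------------
# Two-step similarity search


def _canonical_kmers(seq: str, k: int) -> set[str]:
    rc = reverse_complement(seq)
    n = len(seq)
    out = set()
    for i in range(n - k + 1):
        fwd = seq[i : i + k]
        if "N" in fwd:
            continue
        rev = rc[n - k - i : n - i]
        out.add(fwd if fwd <= rev else rev)
    return out


def kmer_prefilter(
    q: str,
    refs: dict[str, str],
    k: int = 8,
    top_n: int = 20,
) -> list[str]:
    """Rank references by shared canonical k-mer count with the query.

    References sharing no k-mers are dropped, so the result can be empty.
    Ties break deterministically on reference id.
    """
    if not 6 <= k <= 15:
        raise ValueError("prefilter word size must be in [6, 15]")
    qk = _canonical_kmers(q, k)
    scored = []
    for ref_id in sorted(refs):
        shared = len(qk & _canonical_kmers(refs[ref_id], k))
        if shared > 0:
            scored.append((-shared, ref_id))
    scored.sort()
    return [ref_id for _, ref_id in scored[:top_n]]


@lru_cache(maxsize=1)
def _aligner() -> PairwiseAligner:
    al = PairwiseAligner(
        mode="global",
        match_score=2,
        mismatch_score=-1,
        open_gap_score=-4,
        extend_gap_score=-1,
    )
    # free terminal gaps: overhangs are neither rewarded nor penalised
    al.end_insertion_score = 0.0
    al.end_deletion_score = 0.0
    return al


def pairwise_similarity(a: str, b: str, ref_id: str = "") -> SimilarityHit:
    """Similarity of two sequences under a free-end-gap global alignment.

    similarity = 100 * matches / columns, where columns run from the first
    to the last aligned base pair (internal gap columns included, terminal
    overhangs excluded).
    """
    if not a or not b:
        raise ValueError("cannot align empty sequences")
    # canonical argument order: among tied-score alignments the aligner picks
    # one deterministically, so aligning in a fixed order makes the
    # similarity exactly symmetric
    if b < a:
        a, b = b, a
    aln = _aligner().align(a, b)[0]
    seg_a, seg_b = aln.aligned
    if len(seg_a) == 0:
        logger.warning("no positive-score alignment path; similarity set to 0")
        return SimilarityHit(ref_id=ref_id, similarity=0.0, aligned_columns=1)
    matches = 0
    paired_cols = 0
    for (as_, ae), (bs, be) in zip(seg_a, seg_b):
        paired_cols += ae - as_
        for i in range(ae - as_):
            if a[as_ + i] == b[bs + i]:
                matches += 1
    internal_gaps = 0
    for j in range(1, len(seg_a)):
        internal_gaps += seg_a[j][0] - seg_a[j - 1][1]
        internal_gaps += seg_b[j][0] - seg_b[j - 1][1]
    cols = paired_cols + internal_gaps
    return SimilarityHit(
        ref_id=ref_id, similarity=100.0 * matches / cols, aligned_columns=cols
    )


def identify_marker(
    q: str,
    refs: dict[str, str],
    top_n: int = 5,
    prefilter_k: int = 8,
    prefilter_top_n: int = 20,
) -> list[SimilarityHit]:
    """Two-step search: k-mer prefilter, then alignment on the survivors.

    Returns hits in descending similarity (tie-break on ref id). On small
    reference sets the result matches an exhaustive alignment ranking.
    """
    if not refs:
        raise ValueError("reference collection is empty")
    candidates = kmer_prefilter(
        q, refs, k=prefilter_k, top_n=max(prefilter_top_n, 2 * top_n)
    )
    hits = [pairwise_similarity(q, refs[rid], ref_id=rid) for rid in candidates]
    hits.sort(key=lambda h: (-h.similarity, h.ref_id))
    return hits[:top_n]


# backwards-friendly alias for the most common marker search
identify_16s = identify_marker


# ---------------------------------------------------------------------------
# Phylotype clustering


@dataclass(frozen=True)
class PhylotypeCluster:
    representative: str
    members: tuple[str, ...]


def cluster_phylotypes(
    seqs: dict[str, str], cutoff: float = 97.0
) -> list[PhylotypeCluster]:
    """Greedy centroid clustering of 16S sequences at a similarity cutoff.

    Sequences are processed longest-first (ties by id); each joins the
    first existing representative it matches at >= cutoff, otherwise founds
    a new cluster. Deterministic given the input set.
    """
    order = sorted(seqs, key=lambda sid: (-len(seqs[sid]), sid))
    reps: list[str] = []
    members: dict[str, list[str]] = {}
    for sid in order:
        placed = False
        for rep in reps:
            if pairwise_similarity(seqs[sid], seqs[rep]).similarity >= cutoff:
                members[rep].append(sid)
                placed = True
                break
        if not placed:
            reps.append(sid)
            members[sid] = [sid]
    return [
        PhylotypeCluster(representative=rep, members=tuple(members[rep]))
        for rep in reps
    ]


def write_hits_tsv(query_id: str, hits: list[SimilarityHit], path) -> None:
    """Similarity hit table as TSV (query, ref, similarity, aligned_columns)."""
    with open(path, "w") as fh:
        fh.write("query\tref\tsimilarity\taligned_columns\n")
        for h in hits:
            fh.write(f"{query_id}\t{h.ref_id}\t{h.similarity:.4f}\t{h.aligned_columns}\n")


def write_clusters_tsv(clusters: list[PhylotypeCluster], path) -> None:
    """Phylotype membership as TSV (sequence id, representative)."""
    with open(path, "w") as fh:
        fh.write("seq_id\trepresentative\n")
        for c in clusters:
            for m in c.members:
                fh.write(f"{m}\t{c.representative}\n")
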