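"""Tetranucleotide z-score genome signatures.

A genome's signature is the vector of 256 z-scores, one per tetranucleotide
in lexicographic order (AAAA..TTTT), measuring the deviation of the
observed 4-mer count from its maximal-order Markov expectation

    E[n(w1w2w3w4)] = n(w1w2w3) * n(w2w3w4) / n(w2w3)

with the approximate variance

    Var = E * (1 - n(w1w2w3)/n(w2w3)) * (1 - n(w2w3w4)/n(w2w3)).

Counts are pooled over all contigs and both strands, so the signature is
orientation-invariant; windows containing N are skipped. Two signatures are
compared by Pearson correlation over the 256 components, which is the
statistic used to shortlist compositionally similar reference genomes.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .genomeio import GenomeAssembly, reverse_complement

logger = logging.getLogger(__name__)

TETRAMERS: tuple[str, ...] = tuple(
    "".join(p) for p in itertools.product("ACGT", repeat=4)
)

_BASE_CODE = np.full(256, 4, dtype=np.int64)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i

MIN_SIGNATURE_LENGTH = 2_000


class SignatureLengthError(ValueError):
    """Raised when an assembly is too short for a stable signature."""


@dataclass(frozen=True)
class ZScoreVector:
    genome_id: str
    z: np.ndarray  # shape (256,), float64
    n_undefined: int = 0  # components zeroed because of zero-count denominators

    def __post_init__(self) -> None:
        if self.z.shape != (256,):
            raise ValueError("z-score vector must have exactly 256 components")
        if not np.all(np.isfinite(self.z)):
            raise ValueError("z-score vector must be finite")


@dataclass(frozen=True)
class TetraHit:
    ref_id: str
    r: float


def _kmer_counts(codes: np.ndarray, k: int) -> np.ndarray:
    """Counts of all 4^k words in one encoded strand; N windows skipped."""
    n = codes.size
    if n < k:
        return np.zeros(4**k, dtype=np.int64)
    word = np.zeros(n - k + 1, dtype=np.int64)
    valid = np.ones(n - k + 1, dtype=bool)
    for j in range(k):
        c = codes[j : n - k + 1 + j]
        word = word * 4 + np.where(c == 4, 0, c)
        valid &= c != 4
    return np.bincount(word[valid], minlength=4**k)


def _pooled_counts(seqs: list[str], k: int) -> np.ndarray:
    total = np.zeros(4**k, dtype=np.int64)
    for seq in seqs:
        for s in (seq, reverse_complement(seq)):
            codes = _BASE_CODE[np.frombuffer(s.encode(), dtype=np.uint8)]
            total += _kmer_counts(codes, k)
    return total


def tetra_zscores(asm: GenomeAssembly) -> ZScoreVector:
    """Compute the 256-component tetranucleotide z-score signature of *asm*."""
    seqs = asm.sequences()
    unambiguous = sum(len(s) - s.count("N") for s in seqs)
    if unambiguous < MIN_SIGNATURE_LENGTH:
        raise SignatureLengthError(
            f"{asm.id}: {unambiguous} unambiguous bp < required "
            f"{MIN_SIGNATURE_LENGTH} for a tetranucleotide signature"
        )
    n4 = _pooled_counts(seqs, 4).astype(float)
    n3 = _pooled_counts(seqs, 3).astype(float)
    n2 = _pooled_counts(seqs, 2).astype(float)

    idx = np.arange(256)
    left3 = idx // 4          # w1w2w3
    right3 = idx % 64         # w2w3w4
    mid2 = (idx // 4) % 16    # w2w3

    with np.errstate(divide="ignore", invalid="ignore"):
        exp = n3[left3] * n3[right3] / n2[mid2]
        var = exp * (1.0 - n3[left3] / n2[mid2]) * (1.0 - n3[right3] / n2[mid2])
        z = (n4 - exp) / np.sqrt(var)
    bad = ~np.isfinite(z)
    n_undef = int(bad.sum())
    if n_undef:
        logger.debug("%s: %d z components undefined, set to 0", asm.id, n_undef)
        z = np.where(bad, 0.0, z)
    return ZScoreVector(genome_id=asm.id, z=z, n_undefined=n_undef)


def tetra_correlation(a: ZScoreVector, b: ZScoreVector) -> float:
    """Pearson correlation between two z-score signatures."""
    za, zb = a.z, b.z
    if np.std(za) == 0.0 or np.std(zb) == 0.0:
        raise ValueError(
            f"correlation undefined: zero-variance z-vector "
            f"({a.genome_id!r} vs {b.genome_id!r})"
        )
    return float(np.corrcoef(za, zb)[0, 1])


def tetra_search(
    q: ZScoreVector, refs: list[ZScoreVector], top_n: int = 5
) -> list[TetraHit]:
    """Rank reference signatures by correlation with the query.

    Descending by r with a deterministic tie-break on reference id; at most
    ``min(top_n, len(refs))`` hits are returned.
    """
    if not refs:
        raise ValueError("reference signature collection is empty")
    hits = [TetraHit(ref_id=r.genome_id, r=tetra_correlation(q, r)) for r in refs]
    hits.sort(key=lambda h: (-h.r, h.ref_id))
    return hits[:top_n]


def write_zscores_tsv(vectors: list[ZScoreVector], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("genome_id\t" + "\t".join(TETRAMERS) + "\n")
        for v in vectors:
            fh.write(v.genome_id + "\t" + "\t".join(f"{x:.10g}" for x in v.z) + "\n")


def read_zscores_tsv(path: str | Path) -> list[ZScoreVector]:
    vectors = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header[1:]) != TETRAMERS:
            raise ValueError(f"{path}: unexpected z-score TSV header")
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            vectors.append(
                ZScoreVector(genome_id=parts[0], z=np.array(parts[1:], dtype=float))
            )
    return vectors
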