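"""Assembly I/O, statistics and quality screening.

Genome assemblies are held as plain multi-FASTA contig sets. All sequences
are normalised to uppercase {A,C,G,T,N}: IUPAC ambiguity codes (and any
other letter) collapse to N so that GC content and tetranucleotide counts
are defined over unambiguous bases only. Coordinates everywhere in this
package are 0-based, half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

_VALID = set("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class FastaFormatError(ValueError):
    """Raised for malformed or empty FASTA input."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class AssemblyStats:
    """Summary statistics of one assembly.

    ``gc_percent`` is computed over unambiguous (A/C/G/T) positions only and
    is None, with ``gc_undefined`` set, for an all-N assembly. ``n50`` uses
    the standard cumulative-half rule.
    """

    total_length: int
    n_contigs: int
    gc_percent: float | None
    n50: int
    ambiguous_fraction: float

    @property
    def gc_undefined(self) -> bool:
        return self.gc_percent is None


@dataclass
class GenomeAssembly:
    """One whole-genome assembly: an id plus ordered, named contigs."""

    id: str
    contigs: list[tuple[str, str]]
    depositor_name: str | None = None
    stats: AssemblyStats | None = None

    def __post_init__(self) -> None:
        for name, seq in self.contigs:
            if not seq:
                raise ValueError(f"{self.id}: contig {name!r} is empty")
            if set(seq) - _VALID:
                raise ValueError(
                    f"{self.id}: contig {name!r} contains characters outside "
                    "A/C/G/T/N; normalise with read_fasta/normalize_sequence"
                )

    @property
    def total_length(self) -> int:
        return sum(len(s) for _, s in self.contigs)

    def sequences(self) -> list[str]:
        return [s for _, s in self.contigs]

    def compute_stats(self) -> AssemblyStats:
        if self.stats is None:
            self.stats = assembly_stats(self)
        return self.stats


def normalize_sequence(seq: str) -> tuple[str, int]:
    """Uppercase *seq* and map every non-ACGT character to N.

    Returns the normalised sequence and the number of characters changed to
    N that were not already N/n.
    """
    up = seq.upper()
    out = []
    mapped = 0
    for ch in up:
        if ch in "ACGTN":
            out.append(ch)
        else:
            out.append("N")
            mapped += 1
    return "".join(out), mapped


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a (possibly wrapped) multi-FASTA file into (name, seq) records.

    Sequences are normalised; a single warning is logged per file if any
    ambiguity characters were mapped to N. Record order is preserved.
    """
    path = Path(path)
    records: list[tuple[str, str]] = []
    name: str | None = None
    chunks: list[str] = []
    n_mapped = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                header = line[1:].strip()
                if not header:
                    raise FastaFormatError(f"{path}:{lineno}: empty FASTA header")
                if name is not None:
                    seq, m = normalize_sequence("".join(chunks))
                    if not seq:
                        raise FastaFormatError(
                            f"{path}: record {name!r} has no sequence"
                        )
                    n_mapped += m
                    records.append((name, seq))
                name = header.split()[0]
                chunks = []
            else:
                if name is None:
                    raise FastaFormatError(
                        f"{path}:{lineno}: sequence data before first header"
                    )
                chunks.append(line)
    if name is None:
        raise FastaFormatError(f"{path}: empty file or no FASTA records")
    seq, m = normalize_sequence("".join(chunks))
    if not seq:
        raise FastaFormatError(f"{path}: record {name!r} has no sequence")
    n_mapped += m
    records.append((name, seq))
    if n_mapped:
        logger.warning(
            "%s: %d ambiguous/invalid characters mapped to N", path, n_mapped
        )
    return records


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def load_assembly(path: str | Path, asm_id: str | None = None,
                  depositor_name: str | None = None) -> GenomeAssembly:
    """Load one assembly from FASTA.

    When no depositor name is given, the description of the first header
    (text after the contig id) is used — the conventional place a
    submitter's organism name travels with an assembly.
    """
    records = read_fasta(path)
    if asm_id is None:
        asm_id = Path(path).stem
    if depositor_name is None:
        with open(path) as fh:
            for line in fh:
                if line.startswith(">"):
                    parts = line[1:].strip().split(maxsplit=1)
                    if len(parts) == 2:
                        depositor_name = parts[1]
                    break
    return GenomeAssembly(id=asm_id, contigs=records, depositor_name=depositor_name)


def _n50(lengths: Sequence[int]) -> int:
    arr = np.sort(np.asarray(lengths))[::-1]
    half = arr.sum() / 2.0
    csum = np.cumsum(arr)
    return int(arr[np.searchsorted(csum, half)])


def assembly_stats(asm: GenomeAssembly) -> AssemblyStats:
    """Compute total length, contig count, GC%, N50 and ambiguous fraction."""
    if not asm.contigs:
        raise ValueError(f"{asm.id}: assembly has no contigs")
    lengths = [len(s) for _, s in asm.contigs]
    total = sum(lengths)
    gc = at = n_amb = 0
    for _, seq in asm.contigs:
        gc += seq.count("G") + seq.count("C")
        at += seq.count("A") + seq.count("T")
        n_amb += seq.count("N")
    unambiguous = gc + at
    gc_percent = 100.0 * gc / unambiguous if unambiguous else None
    if gc_percent is None:
        logger.warning("%s: all-N assembly, GC content undefined", asm.id)
    return AssemblyStats(
        total_length=total,
        n_contigs=len(lengths),
        gc_percent=gc_percent,
        n50=_n50(lengths),
        ambiguous_fraction=n_amb / total,
    )


@dataclass(frozen=True)
class QCConfig:
    """Quality-screen thresholds (heuristic defaults, all overridable)."""

    min_total_length: int = 100_000
    max_contigs: int = 2_000
    max_ambiguous_fraction: float = 0.10


@dataclass(frozen=True)
class QCVerdict:
    passed: bool
    reasons: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.passed != (len(self.reasons) == 0):
            raise ValueError("passed must be true iff reasons is empty")


def qc_config_from_file(path: str | Path) -> QCConfig:
    """Read QC thresholds from a flat ``key = value`` (or ``key<TAB>value``)
    file; unknown keys are rejected, missing keys keep their defaults."""
    values: dict[str, float] = {}
    fields = {f.name: f.type for f in QCConfig.__dataclass_fields__.values()}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, val = (
                line.partition("=") if "=" in line else line.partition("\t")
            )
            key, val = key.strip(), val.strip()
            if key not in fields:
                raise ValueError(f"{path}:{lineno}: unknown QC option {key!r}")
            values[key] = float(val)
    kwargs = {
        k: int(v) if k in ("min_total_length", "max_contigs") else v
        for k, v in values.items()
    }
    return QCConfig(**kwargs)


def qc_screen(asm: GenomeAssembly, cfg: QCConfig | None = None) -> QCVerdict:
    """Screen an assembly against length / contig-count / ambiguity rules.

    Every violated rule is listed; degenerate assemblies fail rather than
    raising.
    """
    cfg = cfg or QCConfig()
    stats = asm.compute_stats()
    reasons: list[str] = []
    if stats.total_length < cfg.min_total_length:
        reasons.append("min_length")
    if stats.n_contigs > cfg.max_contigs:
        reasons.append("max_contigs")
    if stats.ambiguous_fraction > cfg.max_ambiguous_fraction:
        reasons.append("max_ambiguous")
    return QCVerdict(passed=not reasons, reasons=tuple(reasons))


def qc_report(verdicts: dict[str, QCVerdict], path: str | Path) -> None:
    """Write a per-assembly QC report TSV (id, passed, reasons)."""
    with open(path, "w") as fh:
        fh.write("assembly_id\tpassed\treasons\n")
        for asm_id, v in verdicts.items():
            fh.write(f"{asm_id}\t{str(v.passed).lower()}\t{','.join(v.reasons)}\n")
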