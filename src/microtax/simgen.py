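"""Seeded synthetic fixtures: random genomes, evolution, reference databases.

The generator emulates the objects the identification pipeline consumes —
a taxonomy-annotated reference genome database with marker genes and
tetranucleotide signatures — entirely from seeded random sequence, so the
whole pipeline is testable offline. A hierarchy of genera/species/strains
is produced by recursively evolving a root genome:

* inter-genus divergence  ~20% (two genera each 10% from the common root)
* inter-species divergence ~8-10% within a genus
* intra-species divergence ~0.5-2% between strains

Marker genes (16S ~1500 bp, gyrB ~1900 bp, recA ~1050 bp) are random
template sequences evolved along the same hierarchy at reduced rates —
slowest for 16S, intermediate for gyrB/recA — mirroring the relative
phylogenetic resolution of these genes, and planted into each genome at a
recorded position and strand. Every generated genome carries a ground-truth
record (parent, realised mutation counts, planted coordinates).

Templates are synthetic sequences of realistic lengths, not real genes; the
pipeline only relies on similarity structure, not biological content.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .genomeio import GenomeAssembly, reverse_complement
from .marker import MarkerGene, MarkerType

_BASES = np.array(list("ACGT"))

MARKER_LENGTHS = {MarkerType.SSU16S: 1500, MarkerType.gyrB: 1900, MarkerType.recA: 1050}
# marker substitution rate relative to the genome rate along the same branch
MARKER_RATE_FACTOR = {MarkerType.SSU16S: 0.25, MarkerType.gyrB: 0.6, MarkerType.recA: 0.6}

# branch rates from parent to child at each level of the hierarchy; pairwise
# divergence between two leaves is roughly the sum of the branch rates on
# the path between them
GENUS_BRANCH_RATE = 0.05     # pairwise inter-genus divergence ~ 20%
SPECIES_BRANCH_RATE = 0.04   # pairwise inter-species divergence ~ 9%
STRAIN_BRANCH_RATE = 0.005   # pairwise intra-species divergence ~ 1%


@dataclass
class GenomeTruth:
    genome_id: str
    taxon: tuple[str, ...]            # (phylum..species[, subspecies])
    parent: str | None
    sub_rate: float
    indel_rate: float
    n_substitutions: int
    n_indels: int
    markers: dict[str, tuple[str, int, int, str]] = field(default_factory=dict)
    # marker type -> (contig, start, end, strand)


@dataclass
class FixtureTruth:
    seed: int
    genomes: dict[str, GenomeTruth] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "genomes": {gid: asdict(t) for gid, t in self.genomes.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def random_genome(length: int, gc: float, seed: int, asm_id: str = "sim") -> GenomeAssembly:
    """i.i.d. random genome with P(G) + P(C) = gc/100, reproducible per seed."""
    if length <= 0:
        raise ValueError("genome length must be positive")
    if not 0.0 < gc < 100.0:
        raise ValueError("GC percent must lie strictly between 0 and 100")
    rng = np.random.default_rng(seed)
    g = gc / 100.0
    p = [(1 - g) / 2, g / 2, g / 2, (1 - g) / 2]
    seq = "".join(_BASES[rng.choice(4, size=length, p=p)])
    return GenomeAssembly(id=asm_id, contigs=[(f"{asm_id}_c1", seq)])


def _mutate(
    seq: str, sub_rate: float, indel_rate: float, rng: np.random.Generator
) -> tuple[str, int, int]:
    """Apply substitutions and geometric-length (mean 3) indels to *seq*."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    code = np.zeros(256, dtype=np.int64)
    for i, b in enumerate("ACGT"):
        code[ord(b)] = i
    codes = code[arr]
    sub_mask = rng.random(codes.size) < sub_rate
    n_sub = int(sub_mask.sum())
    if n_sub:
        shift = rng.integers(1, 4, size=n_sub)
        codes[sub_mask] = (codes[sub_mask] + shift) % 4
    out = "".join(_BASES[codes])

    n_indel_events = rng.binomial(codes.size, indel_rate) if indel_rate > 0 else 0
    if n_indel_events:
        positions = np.sort(rng.integers(0, len(out), size=n_indel_events))[::-1]
        chars = list(out)
        for pos in positions:
            length = int(rng.geometric(1.0 / 3.0))
            if rng.random() < 0.5:
                ins = "".join(_BASES[rng.integers(0, 4, size=length)])
                chars[pos:pos] = list(ins)
            else:
                del chars[pos : pos + length]
        out = "".join(chars)
    return out, n_sub, int(n_indel_events)


def evolve(
    g: GenomeAssembly,
    sub_rate: float,
    indel_rate: float,
    seed: int,
    new_id: str | None = None,
) -> tuple[GenomeAssembly, GenomeTruth]:
    """Evolve an assembly at per-site substitution and indel rates."""
    if not 0.0 <= sub_rate <= 0.3 or not 0.0 <= indel_rate <= 0.3:
        raise ValueError("mutation rates must lie in [0, 0.3]")
    rng = np.random.default_rng(seed)
    new_id = new_id or f"{g.id}_ev"
    contigs = []
    tot_sub = tot_indel = 0
    for name, seq in g.contigs:
        mseq, n_sub, n_indel = _mutate(seq, sub_rate, indel_rate, rng)
        tot_sub += n_sub
        tot_indel += n_indel
        contigs.append((name.replace(g.id, new_id, 1) if g.id in name else name, mseq))
    child = GenomeAssembly(id=new_id, contigs=contigs, depositor_name=g.depositor_name)
    truth = GenomeTruth(
        genome_id=new_id,
        taxon=(),
        parent=g.id,
        sub_rate=sub_rate,
        indel_rate=indel_rate,
        n_substitutions=tot_sub,
        n_indels=tot_indel,
    )
    return child, truth


@dataclass
class ReferenceFixture:
    """In-memory reference database fixture plus its ground truth."""

    assemblies: list[GenomeAssembly]
    markers: list[MarkerGene]
    taxonomy: list[dict[str, object]]   # rows: genome_id, rank columns, is_type, depositor
    truth: FixtureTruth
    marker_templates: dict[MarkerType, str]


def _evolve_seq(seq: str, rate: float, rng: np.random.Generator) -> str:
    out, _, _ = _mutate(seq, rate, 0.0, rng)
    return out


def make_refdb(
    n_genera: int = 2,
    species_per_genus: int = 2,
    strains_per_species: int = 2,
    genome_len: int = 200_000,
    seed: int = 0,
    gc: float = 50.0,
) -> ReferenceFixture:
    """Generate a hierarchical reference fixture with planted markers.

    The first strain of each species is flagged as the type strain. Genome
    ids are like ``G01_S01_T1``; taxon names like genus ``Genus01`` and
    species ``Genus01 species01``.
    """
    if min(n_genera, species_per_genus, strains_per_species) < 1:
        raise ValueError("all hierarchy counts must be >= 1")
    rng = np.random.default_rng(seed)
    root = random_genome(genome_len, gc, int(rng.integers(2**31)), asm_id="root")
    root_seq = root.contigs[0][1]
    templates = {
        mt: "".join(_BASES[rng.integers(0, 4, size=MARKER_LENGTHS[mt])])
        for mt in MarkerType
    }

    truth = FixtureTruth(seed=seed)
    assemblies: list[GenomeAssembly] = []
    markers: list[MarkerGene] = []
    taxonomy: list[dict[str, object]] = []

    for gi in range(n_genera):
        genus = f"Genus{gi + 1:02d}"
        genus_seq = _evolve_seq(root_seq, GENUS_BRANCH_RATE, rng)
        genus_markers = {
            mt: _evolve_seq(templates[mt], GENUS_BRANCH_RATE * MARKER_RATE_FACTOR[mt], rng)
            for mt in MarkerType
        }
        for si in range(species_per_genus):
            species = f"{genus} species{si + 1:02d}"
            species_seq = _evolve_seq(genus_seq, SPECIES_BRANCH_RATE, rng)
            species_markers = {
                mt: _evolve_seq(
                    genus_markers[mt], SPECIES_BRANCH_RATE * MARKER_RATE_FACTOR[mt], rng
                )
                for mt in MarkerType
            }
            for ti in range(strains_per_species):
                gid = f"G{gi + 1:02d}_S{si + 1:02d}_T{ti + 1}"
                strain_seq = _evolve_seq(species_seq, STRAIN_BRANCH_RATE, rng)
                strain_markers = {
                    mt: _evolve_seq(
                        species_markers[mt],
                        STRAIN_BRANCH_RATE * MARKER_RATE_FACTOR[mt],
                        rng,
                    )
                    for mt in MarkerType
                }
                contig_name = f"{gid}_c1"
                # distinct insertion points chosen up front so no marker can
                # be planted inside another
                points = np.sort(rng.choice(len(strain_seq), size=len(MarkerType), replace=False))
                strands = ["+" if rng.random() < 0.5 else "-" for _ in MarkerType]
                pieces: list[str] = []
                planted: dict[str, tuple[str, int, int, str]] = {}
                cursor = 0
                offset = 0
                for mt, pos, strand in zip(MarkerType, points, strands):
                    mseq = strain_markers[mt]
                    insert = mseq if strand == "+" else reverse_complement(mseq)
                    pieces.append(strain_seq[cursor:pos])
                    pieces.append(insert)
                    start = int(pos) + offset
                    planted[mt.value] = (contig_name, start, start + len(insert), strand)
                    offset += len(insert)
                    cursor = int(pos)
                pieces.append(strain_seq[cursor:])
                seq = "".join(pieces)
                asm = GenomeAssembly(id=gid, contigs=[(contig_name, seq)])
                assemblies.append(asm)
                for mt in MarkerType:
                    c, s, e, strand = planted[mt.value]
                    markers.append(
                        MarkerGene(
                            marker_type=mt,
                            genome_id=gid,
                            contig=c,
                            start=s,
                            end=e,
                            strand=strand,
                            seq=strain_markers[mt],
                        )
                    )
                taxonomy.append(
                    {
                        "genome_id": gid,
                        "phylum": "Phylum01",
                        "class": "Class01",
                        "order": "Order01",
                        "family": "Family01",
                        "genus": genus,
                        "species": species,
                        "subspecies": "",
                        "is_type": ti == 0,
                        "depositor_name": species,
                    }
                )
                truth.genomes[gid] = GenomeTruth(
                    genome_id=gid,
                    taxon=("Phylum01", "Class01", "Order01", "Family01", genus, species),
                    parent=species,
                    sub_rate=STRAIN_BRANCH_RATE,
                    indel_rate=0.0,
                    n_substitutions=-1,
                    n_indels=0,
                    markers=planted,
                )
    return ReferenceFixture(
        assemblies=assemblies,
        markers=markers,
        taxonomy=taxonomy,
        truth=truth,
        marker_templates=templates,
    )


def make_query(
    fixture: ReferenceFixture,
    source_genome_id: str,
    divergence: float,
    seed: int,
    query_id: str | None = None,
    drop_markers: bool = False,
) -> GenomeAssembly:
    """Derive a query assembly by evolving a fixture genome.

    Marker regions are evolved at their reduced rates (so 16S similarity
    stays informative at genome divergences where raw sequence has drifted);
    with ``drop_markers`` the planted marker regions are excised, yielding a
    query that must fall through to tetranucleotide evidence or Unidentified.
    """
    src = next(a for a in fixture.assemblies if a.id == source_genome_id)
    t = fixture.truth.genomes[source_genome_id]
    rng = np.random.default_rng(seed)
    name, seq = src.contigs[0]
    qid = query_id or f"{source_genome_id}_q{seed}"

    spans = sorted(t.markers.items(), key=lambda kv: kv[1][1])
    out = []
    cursor = 0
    for mt_name, (_, s, e, strand) in spans:
        out.append(_evolve_seq(seq[cursor:s], divergence, rng))
        if not drop_markers:
            mseq = seq[s:e]
            factor = MARKER_RATE_FACTOR[MarkerType(mt_name)]
            out.append(_evolve_seq(mseq, divergence * factor, rng))
        cursor = e
    out.append(_evolve_seq(seq[cursor:], divergence, rng))
    return GenomeAssembly(id=qid, contigs=[(f"{qid}_c1", "".join(out))])
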