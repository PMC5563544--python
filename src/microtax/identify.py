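"""Composite taxonomic identification of genome assemblies.

The decision engine mirrors how modern prokaryotic taxonomy assigns a
genome: phylogenetically plausible neighbour taxa are shortlisted from
cheap evidence — 16S rRNA / gyrB / recA marker similarity searches and
tetranucleotide-signature correlation — and the final call is made by
average nucleotide identity (OrthoANI) against the shortlisted reference
genomes, with 95% ANI as the species boundary.

Outcomes, in order of precedence:

1. best ANI >= species cutoff  -> species call (subspecies when the best
   reference carries a subspecies label); ties broken toward type strains,
   then by genome id;
2. else, marker evidence places the query in a genus (16S similarity above
   the genus cutoff, or gyrB/recA when no 16S could be extracted) ->
   genus-level call flagged as a candidate novel species;
3. else -> Unidentified.

Tetranucleotide correlation only nominates ANI candidates; it is a
compositional, not phylogenetic, signal and never supports a genus call on
its own. When the depositor supplied a name, the assignment is compared
against it and disagreements are flagged as mislabels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import tetra as tetra_mod
from .genomeio import GenomeAssembly, QCConfig, load_assembly, write_fasta
from .marker import (
    ExtractionConfig,
    MarkerGene,
    MarkerType,
    SimilarityHit,
    extract_markers,
    identify_marker,
)
from .orthoani import ANIResult, OrthoANIConfig, orthoani
from .tetra import SignatureLengthError, ZScoreVector, tetra_search, tetra_zscores

logger = logging.getLogger(__name__)

LEVELS = ("species", "subspecies", "genus", "unidentified")


@dataclass(frozen=True)
class Taxonomy:
    phylum: str
    class_: str
    order: str
    family: str
    genus: str
    species: str
    subspecies: str | None = None


@dataclass
class RefEntry:
    genome_id: str
    taxonomy: Taxonomy
    is_type: bool
    markers: dict[MarkerType, str]      # marker type -> sequence
    zvec: ZScoreVector
    assembly: GenomeAssembly | None = None
    assembly_path: Path | None = None

    def get_assembly(self) -> GenomeAssembly:
        if self.assembly is None:
            if self.assembly_path is None:
                raise ValueError(f"{self.genome_id}: no assembly available")
            self.assembly = load_assembly(self.assembly_path, asm_id=self.genome_id)
        return self.assembly


class ReferenceDB:
    """Taxonomy-annotated reference genomes with markers and signatures."""

    def __init__(self, entries: list[RefEntry]):
        ids = [e.genome_id for e in entries]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate genome ids in reference database")
        type_keys = [
            (e.taxonomy.species, e.taxonomy.subspecies) for e in entries if e.is_type
        ]
        if len(set(type_keys)) != len(type_keys):
            raise ValueError("more than one type genome flagged for a species")
        self.entries: dict[str, RefEntry] = {e.genome_id: e for e in entries}

    def __len__(self) -> int:
        return len(self.entries)

    def marker_seqs(self, mtype: MarkerType) -> dict[str, str]:
        return {
            gid: e.markers[mtype]
            for gid, e in sorted(self.entries.items())
            if mtype in e.markers
        }

    def bait_set(self, max_per_type: int = 10) -> list[MarkerGene]:
        """A deterministic subset of reference markers usable as baits."""
        baits: list[MarkerGene] = []
        for mtype in MarkerType:
            for gid in sorted(self.marker_seqs(mtype))[:max_per_type]:
                seq = self.entries[gid].markers[mtype]
                baits.append(
                    MarkerGene(
                        marker_type=mtype,
                        genome_id=gid,
                        contig="db",
                        start=0,
                        end=len(seq),
                        strand="+",
                        seq=seq,
                    )
                )
        return baits

    def zvectors(self) -> list[ZScoreVector]:
        return [e.zvec for _, e in sorted(self.entries.items())]

    # -- persistence --------------------------------------------------------

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        (directory / "assemblies").mkdir(parents=True, exist_ok=True)
        marker_records = []
        with open(directory / "taxonomy.tsv", "w") as fh:
            fh.write(
                "genome_id\tphylum\tclass\torder\tfamily\tgenus\tspecies\t"
                "subspecies\tis_type\n"
            )
            for gid, e in sorted(self.entries.items()):
                t = e.taxonomy
                fh.write(
                    "\t".join(
                        [
                            gid, t.phylum, t.class_, t.order, t.family, t.genus,
                            t.species, t.subspecies or "",
                            "1" if e.is_type else "0",
                        ]
                    )
                    + "\n"
                )
                write_fasta(e.get_assembly().contigs, directory / "assemblies" / f"{gid}.fasta")
                for mtype, seq in sorted(e.markers.items(), key=lambda kv: kv[0].value):
                    marker_records.append((f"{gid}|{mtype.value}", seq))
        write_fasta(marker_records, directory / "markers.fasta")
        tetra_mod.write_zscores_tsv(self.zvectors(), directory / "zvectors.tsv")

    @classmethod
    def load(cls, directory: str | Path) -> "ReferenceDB":
        directory = Path(directory)
        expected = ["taxonomy.tsv", "markers.fasta", "zvectors.tsv", "assemblies"]
        missing = [f for f in expected if not (directory / f).exists()]
        if missing:
            raise FileNotFoundError(
                f"reference database at {directory} is missing: {', '.join(missing)}"
            )
        from .genomeio import read_fasta

        markers: dict[str, dict[MarkerType, str]] = {}
        for header, seq in read_fasta(directory / "markers.fasta"):
            gid, mtype = header.rsplit("|", 1)
            markers.setdefault(gid, {})[MarkerType(mtype)] = seq
        zvecs = {v.genome_id: v for v in tetra_mod.read_zscores_tsv(directory / "zvectors.tsv")}
        entries: list[RefEntry] = []
        with open(directory / "taxonomy.tsv") as fh:
            fh.readline()
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                gid = parts[0]
                entries.append(
                    RefEntry(
                        genome_id=gid,
                        taxonomy=Taxonomy(
                            phylum=parts[1], class_=parts[2], order=parts[3],
                            family=parts[4], genus=parts[5], species=parts[6],
                            subspecies=parts[7] or None,
                        ),
                        is_type=parts[8] == "1",
                        markers=markers.get(gid, {}),
                        zvec=zvecs[gid],
                        assembly_path=directory / "assemblies" / f"{gid}.fasta",
                    )
                )
        return cls(entries)


def build_refdb(
    assemblies: list[GenomeAssembly],
    taxonomy_rows: list[dict[str, object]],
    markers: list[MarkerGene] | None = None,
    bait_set: list[MarkerGene] | None = None,
    extraction: ExtractionConfig | None = None,
) -> ReferenceDB:
    """Compile a ReferenceDB from assemblies and a taxonomy table.

    Markers may be supplied directly (e.g. from fixture ground truth) or
    extracted with a bait set; tetranucleotide signatures are computed here.
    """
    by_id = {a.id: a for a in assemblies}
    marker_map: dict[str, dict[MarkerType, str]] = {gid: {} for gid in by_id}
    if markers:
        for m in markers:
            marker_map.setdefault(m.genome_id, {})[MarkerType(m.marker_type)] = m.seq
    elif bait_set:
        for gid, asm in by_id.items():
            for m in extract_markers(asm, bait_set, extraction):
                marker_map[gid][MarkerType(m.marker_type)] = m.seq
    entries = []
    for row in taxonomy_rows:
        gid = str(row["genome_id"])
        asm = by_id[gid]
        entries.append(
            RefEntry(
                genome_id=gid,
                taxonomy=Taxonomy(
                    phylum=str(row["phylum"]), class_=str(row["class"]),
                    order=str(row["order"]), family=str(row["family"]),
                    genus=str(row["genus"]), species=str(row["species"]),
                    subspecies=str(row.get("subspecies") or "") or None,
                ),
                is_type=bool(row.get("is_type", False)),
                markers=marker_map.get(gid, {}),
                zvec=tetra_zscores(asm),
                assembly=asm,
            )
        )
    return ReferenceDB(entries)


# ---------------------------------------------------------------------------
# Configuration and result types


@dataclass(frozen=True)
class IdentifyConfig:
    species_ani_cutoff: float = 95.0
    genus_16s_cutoff: float = 94.5
    genus_protein_cutoff: float = 85.0   # gyrB/recA fallback when 16S absent
    top_hits_per_marker: int = 5
    top_tetra_hits: int = 5
    use_tetra: bool = True
    phylotype_cutoff: float = 97.0
    qc: QCConfig = field(default_factory=QCConfig)
    extraction: ExtractionConfig = field(default_factory=ExtractionConfig)
    ani: OrthoANIConfig = field(default_factory=OrthoANIConfig)

    def __post_init__(self) -> None:
        for name in ("species_ani_cutoff", "genus_16s_cutoff", "phylotype_cutoff"):
            v = getattr(self, name)
            if not 0.0 < v <= 100.0:
                raise ValueError(f"{name} must lie in (0, 100], got {v}")


@dataclass(frozen=True)
class CandidateItem:
    genome_id: str
    evidence: frozenset[str]  # subset of {"16S", "gyrB", "recA", "tetra"}

    def __post_init__(self) -> None:
        if not self.evidence:
            raise ValueError("candidate must carry at least one evidence tag")


@dataclass(frozen=True)
class CandidateList:
    items: tuple[CandidateItem, ...]

    def __post_init__(self) -> None:
        ids = [c.genome_id for c in self.items]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate genome ids in candidate list")

    def ids(self) -> list[str]:
        return [c.genome_id for c in self.items]


@dataclass(frozen=True)
class MislabelRecord:
    flag: bool | None          # None means "unknown" (unparseable depositor name)
    depositor_name: str | None
    assigned_name: str | None
    note: str = ""


@dataclass
class IdentificationResult:
    query_id: str
    level: str
    taxon: str | None
    best_ani: float | None
    best_ref: str | None
    novel_species_candidate: bool
    mislabel: MislabelRecord
    candidates: CandidateList
    ani_results: dict[str, ANIResult]
    marker_hits: dict[str, list[SimilarityHit]] = field(default_factory=dict)
    error: str | None = None

    def __post_init__(self) -> None:
        if self.level not in LEVELS:
            raise ValueError(f"unknown level {self.level!r}")
        if self.novel_species_candidate and self.level != "genus":
            raise ValueError("novel-species candidates are genus-level by definition")


# ---------------------------------------------------------------------------
# Engine


def _query_markers(
    q: GenomeAssembly, db: ReferenceDB, cfg: IdentifyConfig
) -> dict[MarkerType, str]:
    found = extract_markers(q, db.bait_set(), cfg.extraction)
    return {MarkerType(m.marker_type): m.seq for m in found}


def build_candidates(
    q: GenomeAssembly,
    db: ReferenceDB,
    cfg: IdentifyConfig | None = None,
    query_markers: dict[MarkerType, str] | None = None,
    marker_hits_out: dict[str, list[SimilarityHit]] | None = None,
) -> CandidateList:
    """Shortlist reference genomes by marker and tetra evidence.

    The union of the top marker-similarity hits (per available marker type)
    and the top tetranucleotide-correlation hits, each item tagged with the
    evidence that nominated it; ordering is deterministic (by genome id).
    """
    cfg = cfg or IdentifyConfig()
    if len(db) == 0:
        return CandidateList(items=())
    if query_markers is None:
        query_markers = _query_markers(q, db, cfg)

    evidence: dict[str, set[str]] = {}
    tag_of = {MarkerType.SSU16S: "16S", MarkerType.gyrB: "gyrB", MarkerType.recA: "recA"}
    for mtype, qseq in sorted(query_markers.items(), key=lambda kv: kv[0].value):
        refs = db.marker_seqs(mtype)
        if not refs:
            continue
        hits = identify_marker(qseq, refs, top_n=cfg.top_hits_per_marker)
        if marker_hits_out is not None:
            marker_hits_out[tag_of[mtype]] = hits
        for h in hits:
            evidence.setdefault(h.ref_id, set()).add(tag_of[mtype])
    if cfg.use_tetra:
        try:
            qz = tetra_zscores(q)
            for hit in tetra_search(qz, db.zvectors(), top_n=cfg.top_tetra_hits):
                evidence.setdefault(hit.ref_id, set()).add("tetra")
        except SignatureLengthError as exc:
            logger.warning("%s: tetra evidence unavailable (%s)", q.id, exc)
    items = tuple(
        CandidateItem(genome_id=gid, evidence=frozenset(tags))
        for gid, tags in sorted(evidence.items())
    )
    return CandidateList(items=items)


def _genus_from_markers(
    db: ReferenceDB,
    marker_hits: dict[str, list[SimilarityHit]],
    cfg: IdentifyConfig,
) -> str | None:
    """Genus attribution from marker evidence; 16S wins over gyrB/recA."""
    hits_16s = marker_hits.get("16S")
    if hits_16s:
        best = hits_16s[0]
        if best.similarity >= cfg.genus_16s_cutoff:
            return db.entries[best.ref_id].taxonomy.genus
        return None  # 16S present but too distant: no genus support
    genera = []
    for tag in ("gyrB", "recA"):
        hits = marker_hits.get(tag)
        if hits and hits[0].similarity >= cfg.genus_protein_cutoff:
            genera.append(db.entries[hits[0].ref_id].taxonomy.genus)
    if not genera:
        return None
    if len(set(genera)) > 1:
        logger.warning("conflicting genus evidence %s; using gyrB", genera)
    return genera[0]


def classify(
    q: GenomeAssembly,
    db: ReferenceDB,
    cfg: IdentifyConfig | None = None,
    candidates: CandidateList | None = None,
) -> IdentificationResult:
    """Assign a query assembly to species/subspecies/genus or Unidentified.

    ``candidates`` may be forced (e.g. to the full database) to bypass the
    shortlisting heuristics; evidence tags then still reflect the searches.
    """
    cfg = cfg or IdentifyConfig()
    marker_hits: dict[str, list[SimilarityHit]] = {}
    query_markers = _query_markers(q, db, cfg) if len(db) else {}
    auto = build_candidates(
        q, db, cfg, query_markers=query_markers, marker_hits_out=marker_hits
    )
    if candidates is None:
        candidates = auto

    ani_results: dict[str, ANIResult] = {}
    for gid in candidates.ids():
        try:
            ani_results[gid] = orthoani(q, db.entries[gid].get_assembly(), cfg.ani)
        except ValueError as exc:
            logger.warning("%s vs %s: ANI unavailable (%s)", q.id, gid, exc)

    scored = [
        (res.ani, gid)
        for gid, res in ani_results.items()
        if res.has_ani
    ]
    best_ref = best_ani = None
    if scored:
        scored.sort(key=lambda t: (-t[0], not db.entries[t[1]].is_type, t[1]))
        best_ani, best_ref = scored[0]

    level = "unidentified"
    taxon = None
    novel = False
    if best_ani is not None and best_ani >= cfg.species_ani_cutoff:
        entry = db.entries[best_ref]
        if entry.taxonomy.subspecies:
            level = "subspecies"
            taxon = f"{entry.taxonomy.species} subsp. {entry.taxonomy.subspecies}"
        else:
            level = "species"
            taxon = entry.taxonomy.species
    else:
        genus = _genus_from_markers(db, marker_hits, cfg)
        if genus is not None:
            level = "genus"
            taxon = genus
            novel = True

    result = IdentificationResult(
        query_id=q.id,
        level=level,
        taxon=taxon,
        best_ani=best_ani,
        best_ref=best_ref,
        novel_species_candidate=novel,
        mislabel=MislabelRecord(flag=None, depositor_name=q.depositor_name,
                                assigned_name=taxon, note="not evaluated"),
        candidates=candidates,
        ani_results=ani_results,
        marker_hits=marker_hits,
    )
    result.mislabel = detect_mislabel(result)
    return result


# ---------------------------------------------------------------------------
# Mislabel detection

_GENUS_ONLY_EPITHETS = {"sp.", "sp", "bacterium", "archaeon"}


def parse_binomial(name: str) -> tuple[str, str | None] | None:
    """Parse a depositor-asserted name into (genus, epithet-or-None).

    Returns None when no capitalised genus token can be found (e.g.
    "bacterium sp."). "Candidatus" prefixes are skipped; "sp."-style
    epithets yield a genus-only parse.
    """
    tokens = name.strip().split()
    if tokens and tokens[0].lower() == "candidatus":
        tokens = tokens[1:]
    if not tokens or not tokens[0][:1].isupper() or not tokens[0].isalnum():
        return None
    genus = tokens[0]
    if len(tokens) == 1 or tokens[1].lower() in _GENUS_ONLY_EPITHETS:
        return genus, None
    epithet = tokens[1]
    if not epithet[:1].islower() or not epithet.isalnum():
        return genus, None
    return genus, epithet


def detect_mislabel(res: IdentificationResult) -> MislabelRecord:
    """Compare the depositor-asserted name against the assigned taxon.

    Species/subspecies assignments are compared as binomials; genus-only
    depositor labels (and genus-level assignments) are compared at genus
    rank. Unparseable names flag as unknown, never silently as false.
    """
    dep = res.mislabel.depositor_name
    if dep is None or res.level == "unidentified" or res.taxon is None:
        return MislabelRecord(flag=None, depositor_name=dep,
                              assigned_name=res.taxon, note="not applicable")
    parsed = parse_binomial(dep)
    if parsed is None:
        return MislabelRecord(flag=None, depositor_name=dep,
                              assigned_name=res.taxon, note="unparseable depositor name")
    dep_genus, dep_epithet = parsed
    assigned_tokens = res.taxon.split()
    asg_genus = assigned_tokens[0]
    if res.level == "genus" or dep_epithet is None:
        flag = dep_genus != asg_genus
        note = "compared at genus rank"
    else:
        asg_epithet = assigned_tokens[1] if len(assigned_tokens) > 1 else ""
        flag = (dep_genus, dep_epithet) != (asg_genus, asg_epithet)
        note = "compared as species binomial"
    return MislabelRecord(flag=flag, depositor_name=dep,
                          assigned_name=res.taxon, note=note)


# ---------------------------------------------------------------------------
# Batch driver


def batch_identify(
    queries: list[GenomeAssembly],
    db: ReferenceDB,
    cfg: IdentifyConfig | None = None,
) -> tuple[list[IdentificationResult], dict[str, int]]:
    """Identify a batch of queries; failures are isolated per query.

    Returns the per-query results (input order) and summary counts by level
    plus the number of flagged mislabels.
    """
    ids = [q.id for q in queries]
    seen: set[str] = set()
    for qid in ids:
        if qid in seen:
            raise ValueError(f"duplicate query id: {qid!r}")
        seen.add(qid)
    results: list[IdentificationResult] = []
    for q in queries:
        try:
            results.append(classify(q, db, cfg))
        except Exception as exc:  # noqa: BLE001 - per-query isolation is the contract
            logger.error("%s: identification failed: %s", q.id, exc)
            results.append(
                IdentificationResult(
                    query_id=q.id, level="unidentified", taxon=None,
                    best_ani=None, best_ref=None, novel_species_candidate=False,
                    mislabel=MislabelRecord(flag=None, depositor_name=q.depositor_name,
                                            assigned_name=None, note="error"),
                    candidates=CandidateList(items=()), ani_results={},
                    error=str(exc),
                )
            )
    summary = {level: 0 for level in LEVELS}
    summary["mislabels"] = 0
    summary["errors"] = 0
    for r in results:
        summary[r.level] += 1
        if r.mislabel.flag:
            summary["mislabels"] += 1
        if r.error:
            summary["errors"] += 1
    return results, summary


def results_to_rows(results: list[IdentificationResult]) -> list[dict[str, object]]:
    rows = []
    for r in results:
        rows.append(
            {
                "query_id": r.query_id,
                "level": r.level,
                "taxon": r.taxon or "",
                "best_ani": f"{r.best_ani:.2f}" if r.best_ani is not None else "",
                "best_ref": r.best_ref or "",
                "novel_species_candidate": str(r.novel_species_candidate).lower(),
                "mislabel": {True: "true", False: "false", None: "unknown"}[r.mislabel.flag],
                "depositor_name": r.mislabel.depositor_name or "",
                "n_candidates": len(r.candidates.items),
                "error": r.error or "",
            }
        )
    return rows
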