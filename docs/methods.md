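# Methods

## Problem and overall design

`microtax` assigns prokaryotic whole-genome assemblies (WGAs) to taxa
against a curated reference database. The species definition in modern
prokaryotic taxonomy is genomic: two strains are conspecific when their
average nucleotide identity (ANI) over orthologous regions reaches about
95–96%. Computing ANI against every reference genome is infeasible, so the
pipeline first shortlists phylogenetically plausible neighbours with cheap
evidence and only then computes ANI:

1. **Marker-gene searches.** The 16S rRNA gene plus two faster-evolving
   protein-coding markers, gyrB and recA (useful both for extra resolution
   and for the ~7% of assemblies that carry no usable 16S copy). The top
   similarity hits of each available marker nominate candidate references.
2. **Tetranucleotide signature correlation.** A compositional, alignment-free
   screen that works even for marker-free assemblies. Tetra evidence only
   nominates ANI candidates; because genome composition is not a
   phylogenetic signal (it can be distorted by large-scale lateral
   transfer), it never supports a taxon call by itself.
3. **OrthoANI decision.** Fragment-based reciprocal-best-hit ANI against
   every candidate. Best ANI ≥ 95% → species-level call (subspecies when
   the best reference carries a subspecies label). Otherwise, if marker
   evidence places the query in a genus, the query is a genus-level call
   flagged as a *candidate novel species*. Otherwise it is *Unidentified*.

When the submitter supplied an organism name, the assignment is compared
against it and disagreements are flagged as mislabels.

## Assembly statistics and QC

GC content is computed over unambiguous bases only; every IUPAC ambiguity
code is collapsed to N on input so downstream counting is well defined.
N50 uses the standard cumulative-half rule. The quality screen is a set of
configurable heuristics — minimum total length 100 kb, maximum 2,000
contigs, maximum ambiguous fraction 0.10 — chosen as permissive defaults
that reject fragments and heavily-gapped assemblies; they are not claimed
to reproduce any particular curated corpus. Degenerate assemblies fail QC
with reasons rather than raising.

## Tetranucleotide z-scores

For each 4-mer `w1w2w3w4` the observed count (pooled over all contigs and
both strands, windows containing N skipped) is compared with its
maximal-order Markov expectation

    E = n(w1w2w3) · n(w2w3w4) / n(w2w3)

with variance approximated as

    Var = E · (1 − n(w1w2w3)/n(w2w3)) · (1 − n(w2w3w4)/n(w2w3)),

giving z = (obs − E)/√Var. Strand pooling makes signatures orientation
invariant, which matters for draft assemblies whose contigs have arbitrary
orientation. Components with zero-count denominators are set to 0 (and
counted) instead of NaN so correlations stay defined on skewed inputs.
Signatures require ≥ 2 kb of unambiguous sequence. Two signatures are
compared by Pearson correlation over the 256 components.

## Marker extraction and the two-step search

Markers are *extracted by similarity*, not predicted ab initio: bait copies
of each gene are aligned semi-globally (edlib infix mode, both strands)
against every contig, and the best placement above 70% identity and 50%
bait coverage is taken. This is adequate for well-conserved markers and
lets synthetic fixtures carry exact ground-truth coordinates. For an exact
planted copy the reported coordinates are exact; for diverged copies the
boundaries can wobble a few base pairs where terminal bases mutated.

Marker searches use a two-step scheme: a canonical k-mer prefilter
(k = 8, top 20 candidates by shared-k-mer count, deterministic tie-break
on id) followed by a global alignment with free terminal gaps on the
survivors. Similarity is the taxonomically meaningful convention:
matches / columns between the first and last aligned base pair, internal
gap columns counting against similarity and terminal overhangs (e.g. a
partial amplicon against a full-length gene) excluded. Alignment scoring
is match +2, mismatch −1, gap open −5, gap extend −1 with free end gaps;
among tied-score alignments the aligner's deterministic first choice is
used, and arguments are aligned in a fixed canonical order so similarity
is exactly symmetric. On reference sets of ≤ 50 sequences the two-step
ranking is checked against the exhaustive alignment ranking.

Phylotype clustering (the species-like units recognised at 97% 16S
similarity) is greedy centroid clustering: sequences processed
longest-first (ties by id) join the first representative at ≥ cutoff or
found a new cluster, which makes representatives deterministic.

## OrthoANI

Both genomes are cut into consecutive non-overlapping 1020 bp fragments;
trailing remainders are discarded. For each fragment of one genome,
candidate partner fragments in the other are nominated by shared canonical
15-mers (at least 5 shared seeds required) and scored by edlib edit
distance, aligning the query fragment as an infix of the candidate
fragment padded with one fragment length of flanking contig sequence on
each side, in the better orientation. Identity is 1 − d/1020. The infix
window makes the score robust to insertions elsewhere in the genome having
shifted the fragment grid; for identical genomes the distance is 0, so
self-ANI is exactly 100. Orthologous pairs are reciprocal best hits (on
identity ties the candidate with more shared seeds wins — seed counts are
symmetric, which keeps best hits reciprocal); ANI is the mean identity
over orthologous pairs, averaging the two search directions.

The minimum-seed requirement is what terminates the null case: unrelated
random genomes essentially never share 5 seeds within one fragment pair,
so they produce the distinct "no ANI" outcome rather than a spurious
alignment-noise identity (random 1 kb DNA aligns at ~47–55% under edit
distance, far above any usable identity floor). The 35% identity/coverage
floors on candidate hits are retained as configurable guards. In all-vs-all
matrices, "no ANI" pairs are recorded at a floor value (default 60) with a
flag so dendrograms stay computable.

Identity is derived from edit distance relative to the fragment length;
under substitution-only divergence this equals the match fraction exactly,
and under the small indel rates the fixtures use it is a slight
underestimate (a conservative bias).

## Decision engine details

* Candidates: top 5 hits per available marker plus top 5 tetra hits
  (config-exposed); the union is deduplicated with evidence tags.
* Genus attribution: best 16S hit ≥ 94.5% similarity (a common working
  genus threshold, config-exposed); when no 16S could be extracted, gyrB
  or recA best hits ≥ 85% stand in. If 16S is present but below the
  cutoff, the protein markers do not override it — 16S wins on conflict,
  with a logged warning when gyrB/recA disagree.
* ANI ties break toward type strains, then lexicographic genome id.
* Subspecies calls are a labelling convention: the best ≥ 95% reference's
  subspecies label is passed through; no separate subspecies cutoff
  exists.
* Depositor names are parsed as binomials from the first two whitespace
  tokens, with "Candidatus" skipped and "sp."-style epithets treated as
  genus-only; unparseable names yield an *unknown* mislabel flag, never a
  silent *false*.
* Raising the species cutoff can only demote species calls to genus or
  unidentified, never promote them (monotonicity, tested).

## Taxon summaries and dendrograms

Per-genome features (genome size, GC, CDS counts/lengths, intergenic
lengths, 16S copy number) are summarised at every rank from species to
phylum with min/quartiles/median/max/mean/sd; a genome contributes once
per ancestor rank. Features not supplied are reported absent, not zero.
16S copy number is summarised only over genomes flagged complete, since
copy number cannot be trusted in draft assemblies.

UPGMA dendrograms use d = 100 − ANI with merge height d/2, size-weighted
average linkage, and a deterministic tie-break (merge the pair whose
smallest leaf names sort first). The result is ultrametric by
construction; on an exactly ultrametric input matrix the generating
heights are reconstructed exactly. Newick output carries branch lengths at
full float precision and round-trips through standard readers to 1e-9.

## Synthetic fixtures

The generator emulates the reference-database setting with seeded random
sequence only (no biological data is shipped). A root genome is evolved
down a genus → species → strain hierarchy with branch substitution rates
0.05 / 0.04 / 0.005, giving pairwise divergences of roughly 20% between
genera, 9% between congeneric species and 1% between conspecific strains —
the regimes in which the 95% ANI boundary separates ranks. Marker genes
are random templates of realistic lengths (16S ≈ 1500 bp, gyrB ≈ 1900 bp,
recA ≈ 1050 bp) evolved along the same hierarchy at reduced rates (×0.25
for 16S, ×0.6 for gyrB/recA), mirroring the markers' slower evolution and
relative resolution, then planted at recorded positions and strands.
Substitutions are uniform over alternative bases; indels have geometric
lengths (mean 3). Everything is reproducible from (seed, parameters), and
every genome carries a ground-truth record.

What the fixtures do **not** model: rearrangements, recombination, lateral
transfer, mobile elements, repeat families, GC skew, multiple rRNA operon
copies, and real oligonucleotide composition structure. Passing tests
therefore demonstrate the machinery (search, alignment, reciprocal-best-hit
logic, thresholds, determinism) under controlled divergence, not
performance on the full messiness of public assemblies. In particular the
tetra correlation is far cleaner on i.i.d. random genomes than on real
ones.

## Problem sizes used in tests and the acceptance script

Unit and end-to-end tests run on 100 kb genomes (reference hierarchies of
8–20 genomes), divergence-recovery checks on 1 Mb genome pairs over 10
seeds per rate, and search-oracle checks on databases of 50 sequences of
350–400 bp over 20 seeds. These sizes were chosen so the complete suite
and the acceptance script each finish in minutes on a single CPU while
keeping every fragment/search code path and statistical regime exercised;
ANI behaviour is fragment-local, so accuracy does not depend on genome
length beyond having enough fragments to average.

## Known limitations

* Marker extraction assumes the bait set contains a relative within ~30%
  identity of the true gene; wholly novel lineages can lose marker
  evidence and fall through to tetra nomination.
* ANI identity from edit distance slightly penalises indel-rich divergence
  relative to match-counting over alignment columns.
* The fragment grid, not a local aligner, defines orthology resolution;
  small syntenic blocks below 1020 bp are invisible.
* Published worked examples against NCBI assemblies require network access
  (`scripts/ncbi_examples.py`) and are not part of the offline suite.
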