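# microtax

Taxonomic identification of prokaryotic whole-genome assemblies against a
reference database, for microbiologists who need reproducible, genome-based
species calls: clinical and environmental isolate typing, curation of
public assembly metadata, and novel-species discovery.

## What it computes

Modern prokaryotic taxonomy defines species genomically: two strains are
conspecific when their **average nucleotide identity (ANI)** over
orthologous regions is ≥ 95%. `microtax` implements the composite pipeline
built around that boundary:

* **Marker-gene search** — 16S rRNA, *gyrB* and *recA* genes are extracted
  from the assembly by bait-sequence alignment and searched against the
  reference markers with a two-step scheme (canonical *k*-mer prefilter,
  then global alignment with free terminal gaps). Similarity is
  `100 × matches / columns` between the first and last aligned pair,
  internal gaps counting as mismatches.
* **Tetranucleotide z-score signatures** — for each 4-mer
  `w₁w₂w₃w₄`, `z = (obs − E)/√Var` with the maximal-order Markov
  expectation `E = n(w₁w₂w₃)·n(w₂w₃w₄)/n(w₂w₃)`; 256-component signatures
  are compared by Pearson correlation to nominate candidates even for
  marker-free assemblies.
* **OrthoANI** — genomes are cut into 1020 bp fragments; orthologous
  fragment pairs are reciprocal best hits under a seeded, strand-aware
  edit-distance alignment, and ANI is the mean identity over those pairs.
  Unrelated genomes yield a distinct "no ANI" outcome, never a spurious
  low value.
* **Decision engine** — best ANI ≥ 95% → species (or subspecies) call;
  otherwise marker evidence ≥ genus thresholds → genus-level call flagged
  as a *candidate novel species*; otherwise *Unidentified*. Depositor
  names that disagree with the assignment are flagged as mislabels.
* Plus: 97% phylotype clustering of 16S sequences, per-taxon genomic
  feature summaries, ANI-based UPGMA dendrograms (Newick), and a seeded
  synthetic-fixture generator so the whole pipeline runs offline.

## Worked example

Simulate a small reference database (2 genera × 2 species × 2 strains of
150 kb each), then identify a query isolate derived from one of the
species at ~1% divergence, deliberately labelled with its sister species'
name:

```sh
microtax simulate --n-genera 2 --species-per-genus 2 --strains-per-species 2 \
    --genome-len 150000 --seed 4 --out refdb
microtax identify isolate_X.fasta --db refdb --out results
cat results/results.tsv
```

Here `isolate_X.fasta` was made with the package's `make_query` helper — a
seeded 1.2% mutant of reference genome `G01_S02_T1` whose FASTA header
description carries the (wrong) asserted name `Genus01 species01`.

Output (real run):

```
query_id   level    taxon              best_ani  best_ref    novel_species_candidate  mislabel  depositor_name     n_candidates
isolate_X  species  Genus01 species02  98.84     G01_S02_T1  false                    true      Genus01 species01  7
```

The query was assigned to *Genus01 species02* because its best OrthoANI,
98.84% against reference genome `G01_S02_T1`, clears the 95% species
boundary; seven candidate references were nominated by marker and tetra
evidence. The depositor called it *Genus01 species01* — a different
species — so the mislabel flag is raised. `results/evidence.jsonl` holds
the full evidence trail (per-candidate ANI values and marker hits), and
`microtax ani a.fasta b.fasta` prints a single pairwise ANI line:

```
isolate_X   G01_S02_T1   98.84   151   1.000
```

(ANI %, number of orthologous fragment pairs, fragment coverage.)

Other subcommands: `build-db` (compile a reference database from FASTAs +
taxonomy TSV), `taxstats` (per-taxon feature summaries), `dendro` (UPGMA
Newick tree from an ANI matrix).

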