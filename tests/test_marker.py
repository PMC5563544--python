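"""Marker extraction, two-step similarity search and phylotype clustering."""

import numpy as np
import pytest

from microtax.genomeio import GenomeAssembly, reverse_complement
from microtax.marker import (
    MarkerGene,
    MarkerType,
    cluster_phylotypes,
    extract_markers,
    identify_marker,
    kmer_prefilter,
    pairwise_similarity,
)

from conftest import random_dna


def bait(seq: str, mtype: MarkerType = MarkerType.SSU16S, bid: str = "b") -> MarkerGene:
    return MarkerGene(marker_type=mtype, genome_id=bid, contig="bait",
                      start=0, end=len(seq), strand="+", seq=seq)


def mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    out = list(seq)
    for i in np.nonzero(rng.random(len(seq)) < rate)[0]:
        out[i] = "ACGT"[("ACGT".index(out[i]) + int(rng.integers(1, 4))) % 4]
    return "".join(out)


# ---------------------------------------------------------------------------
# Needleman-Wunsch oracle with free terminal gaps (independent of the package
# aligner; same scoring scheme, quadratic DP with explicit traceback)

MATCH, MISMATCH, GAP_OPEN, GAP_EXT = 2, -1, -4, -1


def nw_similarity_oracle(a: str, b: str) -> float:
    n, m = len(a), len(b)
    NEG = float("-inf")
    # affine-gap DP: M = match state, X = gap in b (consume a), Y = gap in a
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = 0.0  # free terminal gap
    for j in range(1, m + 1):
        Y[0][j] = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = MATCH if a[i - 1] == b[j - 1] else MISMATCH
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] + GAP_OPEN + GAP_EXT, X[i - 1][j] + GAP_EXT)
            Y[i][j] = max(M[i][j - 1] + GAP_OPEN + GAP_EXT, Y[i][j - 1] + GAP_EXT)
    # free terminal gaps at the end: best cell on last row/column in any state
    best, bi, bj = NEG, n, m
    for i in range(n + 1):
        for state in (M, X, Y):
            if state[i][m] > best:
                best, bi, bj = state[i][m], i, m
    for j in range(m + 1):
        for state in (M, X, Y):
            if state[n][j] > best:
                best, bi, bj = state[n][j], n, j
    # traceback counting matches and internal gap columns between the first
    # and last aligned pair
    i, j = bi, bj
    cols = []  # list of ("pair", match?) / ("gap",)
    state = max(("M", M[i][j]), ("X", X[i][j]), ("Y", Y[i][j]), key=lambda t: t[1])[0]
    while i > 0 or j > 0:
        if state == "M":
            if i == 0 or j == 0:
                break
            cols.append(("pair", a[i - 1] == b[j - 1]))
            prev = max(
                ("M", M[i - 1][j - 1]), ("X", X[i - 1][j - 1]), ("Y", Y[i - 1][j - 1]),
                key=lambda t: t[1],
            )[0]
            i, j = i - 1, j - 1
            state = prev
        elif state == "X":
            if X[i][j] == 0.0 and i > 0 and j == 0:
                break
            prev = "M" if M[i - 1][j] + GAP_OPEN + GAP_EXT >= X[i - 1][j] + GAP_EXT else "X"
            cols.append(("gap",))
            i -= 1
            state = prev
        else:
            if Y[i][j] == 0.0 and j > 0 and i == 0:
                break
            prev = "M" if M[i][j - 1] + GAP_OPEN + GAP_EXT >= Y[i][j - 1] + GAP_EXT else "Y"
            cols.append(("gap",))
            j -= 1
            state = prev
    cols.reverse()
    # trim terminal gap runs
    while cols and cols[0][0] == "gap":
        cols.pop(0)
    while cols and cols[-1][0] == "gap":
        cols.pop()
    matches = sum(1 for c in cols if c[0] == "pair" and c[1])
    return 100.0 * matches / len(cols)


class TestPairwiseSimilarity:
    def test_identical_sequences_100(self, rng):
        s = random_dna(rng, 100)
        hit = pairwise_similarity(s, s)
        assert hit.similarity == 100.0
        assert hit.aligned_columns == 100

    def test_single_substitution_99(self, rng):
        s = random_dna(rng, 100)
        mut = "G" + s[1:] if s[0] != "G" else "C" + s[1:]
        assert pairwise_similarity(s, mut).similarity == pytest.approx(99.0)

    def test_terminal_overhang_excluded(self, rng):
        core = random_dna(rng, 80)
        assert pairwise_similarity(core, "GG" + core + "TT").similarity == 100.0

    def test_internal_deletion_counts_as_mismatch(self):
        a = "ACGTACGTAC"
        b = "ACGTCGTAC"  # one internal base deleted
        hit = pairwise_similarity(a, b)
        assert hit.similarity == pytest.approx(90.0)
        assert hit.aligned_columns == 10

    def test_symmetry(self, rng):
        a, b = random_dna(rng, 120), random_dna(rng, 110)
        assert pairwise_similarity(a, b).similarity == pytest.approx(
            pairwise_similarity(b, a).similarity
        )

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_matches_quadratic_nw_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = random_dna(rng, 40)
        b = mutate(a, 0.15, rng)
        b = b[3:]  # add an overhang
        assert pairwise_similarity(a, b).similarity == pytest.approx(
            nw_similarity_oracle(a, b)
        )

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            pairwise_similarity("", "ACGT")


class TestKmerPrefilter:
    def test_identical_ref_ranks_first(self, rng):
        q = random_dna(rng, 300)
        refs = {"match": q, "other": random_dna(rng, 300), "other2": random_dna(rng, 300)}
        assert kmer_prefilter(q, refs)[0] == "match"

    def test_disjoint_query_yields_empty_list(self):
        assert kmer_prefilter("A" * 50, {"r1": "C" * 50}) == []

    def test_bad_word_size_rejected(self):
        with pytest.raises(ValueError):
            kmer_prefilter("ACGTACGT", {"r": "ACGTACGT"}, k=3)

    def test_top10_contains_true_nearest_in_95pct_of_trials(self):
        """Graded-divergence screen: the prefilter shortlist almost always
        contains the reference an exhaustive alignment ranks first."""
        rng = np.random.default_rng(42)
        template = random_dna(rng, 400)
        refs = {
            f"r{i:02d}": mutate(template, rate, rng)
            for i, rate in enumerate(np.linspace(0.01, 0.25, 50))
        }
        successes = 0
        for _ in range(100):
            q = mutate(template, 0.05, rng)
            truth = max(
                ((pairwise_similarity(q, s).similarity, rid) for rid, s in refs.items()),
                key=lambda t: (t[0], t[1]),
            )[1]
            if truth in kmer_prefilter(q, refs, top_n=10):
                successes += 1
        assert successes >= 95


class TestIdentifyMarker:
    def test_identical_query_found(self, rng):
        refs = {f"r{i}": random_dna(rng, 400) for i in range(5)}
        hits = identify_marker(refs["r3"], refs, top_n=3)
        assert hits[0].ref_id == "r3" and hits[0].similarity == 100.0

    def test_disjoint_query_returns_no_hits(self):
        assert identify_marker("A" * 200, {"r": "C" * 200}) == []

    def test_empty_db_rejected(self):
        with pytest.raises(ValueError):
            identify_marker("ACGT" * 100, {})

    @pytest.mark.parametrize("seed", range(5))
    def test_two_step_equals_exhaustive_ranking(self, seed):
        rng = np.random.default_rng(seed)
        template = random_dna(rng, 400)
        refs = {
            f"r{i:02d}": mutate(template, rate, rng)
            for i, rate in enumerate(np.linspace(0.005, 0.3, 30))
        }
        q = mutate(template, 0.04, rng)
        hits = identify_marker(q, refs, top_n=5)
        oracle = sorted(
            (pairwise_similarity(q, s, ref_id=rid) for rid, s in refs.items()),
            key=lambda h: (-h.similarity, h.ref_id),
        )[:5]
        assert [(h.ref_id, round(h.similarity, 9)) for h in hits] == [
            (h.ref_id, round(h.similarity, 9)) for h in oracle
        ]


class TestExtractMarkers:
    def test_planted_marker_recovered_at_exact_coordinates(self, rng):
        gene = random_dna(rng, 1500)
        backbone = random_dna(rng, 50_000)
        seq = backbone[:20_000] + gene + backbone[20_000:]
        a = GenomeAssembly(id="g", contigs=[("c1", seq)])
        found = extract_markers(a, [bait(gene)])
        assert len(found) == 1
        m = found[0]
        assert (m.start, m.end, m.strand) == (20_000, 21_500, "+")
        assert m.seq == gene

    def test_minus_strand_marker_returned_in_gene_orientation(self, rng):
        gene = random_dna(rng, 1000)
        backbone = random_dna(rng, 30_000)
        seq = backbone[:10_000] + reverse_complement(gene) + backbone[10_000:]
        a = GenomeAssembly(id="g", contigs=[("c1", seq)])
        found = extract_markers(a, [bait(gene)])
        assert len(found) == 1
        assert found[0].strand == "-"
        assert found[0].seq == gene

    def test_diverged_copy_still_found(self, rng):
        gene = random_dna(rng, 1500)
        copy = mutate(gene, 0.10, rng)
        backbone = random_dna(rng, 30_000)
        a = GenomeAssembly(id="g", contigs=[("c1", backbone[:5000] + copy + backbone[5000:])])
        found = extract_markers(a, [bait(gene)])
        assert len(found) == 1
        assert abs(found[0].start - 5000) < 20

    def test_absent_markers_yield_empty_list(self, rng):
        a = GenomeAssembly(id="g", contigs=[("c1", random_dna(rng, 30_000))])
        assert extract_markers(a, [bait(random_dna(rng, 1500))]) == []

    def test_one_hit_per_marker_type(self, rng):
        g16, grec = random_dna(rng, 1500), random_dna(rng, 1050)
        backbone = random_dna(rng, 40_000)
        seq = backbone[:10_000] + g16 + backbone[10_000:30_000] + grec + backbone[30_000:]
        a = GenomeAssembly(id="g", contigs=[("c1", seq)])
        found = extract_markers(
            a, [bait(g16, MarkerType.SSU16S), bait(grec, MarkerType.recA)]
        )
        assert sorted(m.marker_type.value for m in found) == ["SSU16S", "recA"]


class TestClusterPhylotypes:
    def test_identical_sequences_one_cluster(self, rng):
        s = random_dna(rng, 500)
        clusters = cluster_phylotypes({"a": s, "b": s})
        assert len(clusters) == 1
        assert sorted(clusters[0].members) == ["a", "b"]

    def test_divergent_pair_two_clusters(self, rng):
        s = random_dna(rng, 500)
        far = mutate(s, 0.10, rng)
        assert pairwise_similarity(s, far).similarity < 97.0  # generated divergence check
        assert len(cluster_phylotypes({"a": s, "b": far})) == 2

    def test_empty_input_empty_clustering(self):
        assert cluster_phylotypes({}) == []

    def test_partition_and_representative_similarity(self, rng):
        base1, base2 = random_dna(rng, 600), random_dna(rng, 600)
        seqs = {"a1": base1, "a2": mutate(base1, 0.01, rng),
                "b1": base2, "b2": mutate(base2, 0.015, rng)}
        clusters = cluster_phylotypes(seqs, cutoff=97.0)
        members = [m for c in clusters for m in c.members]
        assert sorted(members) == sorted(seqs)  # every sequence in exactly one cluster
        for c in clusters:
            for m in c.members:
                assert pairwise_similarity(seqs[m], seqs[c.representative]).similarity >= 97.0


class TestTsvOutputs:
    def test_hit_table_roundtrips_fields(self, tmp_path, rng):
        from microtax.marker import write_hits_tsv

        refs = {f"r{i}": random_dna(rng, 200) for i in range(3)}
        hits = identify_marker(refs["r1"], refs, top_n=3)
        p = tmp_path / "hits.tsv"
        write_hits_tsv("q", hits, p)
        lines = p.read_text().splitlines()
        assert lines[0].split("\t") == ["query", "ref", "similarity", "aligned_columns"]
        assert lines[1].split("\t")[1] == "r1"

    def test_cluster_membership_table(self, tmp_path, rng):
        from microtax.marker import write_clusters_tsv

        s = random_dna(rng, 400)
        clusters = cluster_phylotypes({"a": s, "b": s, "c": mutate(s, 0.2, rng)})
        p = tmp_path / "clusters.tsv"
        write_clusters_tsv(clusters, p)
        body = p.read_text().splitlines()[1:]
        assert len(body) == 3
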