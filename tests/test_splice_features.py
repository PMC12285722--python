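"""MaxEnt scorers, GC, percentile ranks, branch-point distances, profiling."""

import math
import os

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from retentia import (
    IntronRecord,
    branchpoint_distance,
    derive_introns,
    feature_profile,
    gc_fraction,
    load_maxent_models,
    percentile_rank,
    score_3ss,
    score_5ss,
)
from retentia.splice_features import (
    ModelLoadError,
    ScoringError,
    _seq_index,
    ag_exclusion_zone,
    at_fraction,
    compute_intron_features,
)

def rand_kmers(n, k, seed):
    rng = np.random.default_rng(seed)
    return ["".join(rng.choice(list("ACGT"), size=k)) for _ in range(n)]


class TestModelLoading:
    def test_fixture_loads_and_validates(self, uniform_maxent):
        donor, acceptor = load_maxent_models(uniform_maxent)
        assert donor.kind == "donor5" and acceptor.kind == "acceptor3"
        assert len(donor.tables[0]) == 4**7
        assert [len(t) for t in acceptor.tables] == [4**7] * 5 + [64, 256, 64, 256]

    def test_missing_file_names_it(self, uniform_maxent, tmp_path):
        import shutil

        broken = tmp_path / "broken"
        shutil.copytree(uniform_maxent, broken)
        os.remove(broken / "me2x3acc4")
        with pytest.raises(ModelLoadError, match="me2x3acc4"):
            load_maxent_models(str(broken))

    def test_truncated_table_rejected(self, uniform_maxent, tmp_path):
        import shutil

        broken = tmp_path / "trunc"
        shutil.copytree(uniform_maxent, broken)
        (broken / "me2x5").write_text("1\n" * 100)
        with pytest.raises(ModelLoadError, match="me2x5"):
            load_maxent_models(str(broken))


class TestScorers:
    def test_uniform_model_scores_zero_everywhere(self, uniform_maxent):
        donor, acceptor = load_maxent_models(uniform_maxent)
        for seq in rand_kmers(50, 9, seed=1):
            assert score_5ss(seq, donor) == 0.0
        for seq in rand_kmers(50, 23, seed=2):
            assert score_3ss(seq, acceptor) == 0.0

    def test_u_normalization(self, uniform_maxent):
        donor, _ = load_maxent_models(uniform_maxent)
        assert score_5ss("GGGUAAGUA", donor) == score_5ss("GGGTAAGTA", donor)

    @pytest.mark.parametrize("bad", ["GGGTAAGT", "GGGTAAGTAA", "GGGTANGTA"])
    def test_bad_donor_input_rejected(self, uniform_maxent, bad):
        donor, _ = load_maxent_models(uniform_maxent)
        with pytest.raises(ScoringError):
            score_5ss(bad, donor)

    def test_donor_decomposition(self, uniform_maxent, tmp_path):
        """Score = consensus log-odds + log2 of the 7-mer table entry."""
        import shutil

        d = tmp_path / "donor"
        shutil.copytree(uniform_maxent, d)
        # non-trivial table: entry value 2**i on a few chosen indices
        table = np.ones(4**7)
        seq = "CAGGTACGT"
        rest = seq[:3] + seq[5:]
        idx = _seq_index(rest)
        table[idx] = 8.0
        np.savetxt(d / "me2x5", table, fmt="%.6f")
        donor, _ = load_maxent_models(str(d))
        # uniform consensus & background leave only the table term
        assert score_5ss(seq, donor) == pytest.approx(3.0)
        assert score_5ss("CAGGTACGA", donor) == pytest.approx(0.0)

    def test_acceptor_component_structure(self, uniform_maxent, tmp_path):
        """Five component models add; four overlap models subtract."""
        import shutil

        d = tmp_path / "acc"
        shutil.copytree(uniform_maxent, d)
        seq = "TTTTTTTTTTTTTTTTTTAGTTT"
        rest = seq[:18] + seq[20:]  # 21-mer
        windows = [(0, 7), (7, 14), (14, 21), (4, 11), (11, 18), (4, 7), (7, 11), (11, 14), (14, 18)]
        for i, (lo, hi) in enumerate(windows, start=1):
            n = 4 ** (hi - lo)
            table = np.ones(n)
            table[_seq_index(rest[lo:hi])] = 2.0
            np.savetxt(d / f"me2x3acc{i}", table, fmt="%.6f")
        _, acceptor = load_maxent_models(str(d))
        # +1 bit from each of 5 components, -1 bit from each of 4 overlaps
        assert score_3ss(seq, acceptor) == pytest.approx(5.0 - 4.0)

    def test_consensus_term_uses_published_constants(self, uniform_maxent, tmp_path):
        import json
        import shutil

        d = tmp_path / "cons"
        shutil.copytree(uniform_maxent, d)
        os.remove(d / "consensus.json")  # fall back to the published constants
        donor, acceptor = load_maxent_models(str(d))
        # all-ones tables isolate the consensus log-odds
        expect_gt = math.log2((0.9896 / 0.23) * (0.9884 / 0.27))
        assert score_5ss("AAAGTAAAA", donor) == pytest.approx(expect_gt)
        expect_ag = math.log2((0.9903 / 0.27) * (0.9905 / 0.23))
        assert score_3ss("A" * 18 + "AG" + "AAA", acceptor) == pytest.approx(expect_ag)


class TestSequenceStats:
    @pytest.mark.parametrize(
        "seq,expected", [("ATGC", 0.5), ("GGCC", 1.0), ("ANT", 0.0), ("gcgc", 1.0)]
    )
    def test_gc_fraction(self, seq, expected):
        assert gc_fraction(seq) == pytest.approx(expected)

    def test_all_n_rejected(self):
        with pytest.raises(ValueError):
            gc_fraction("NNN")

    @given(st.text(alphabet="ACGT", min_size=1, max_size=100))
    @settings(max_examples=50, deadline=None)
    def test_gc_plus_at_is_one(self, seq):
        assert gc_fraction(seq) + at_fraction(seq) == pytest.approx(1.0)


class TestPercentileRank:
    def test_unique_minimum_of_hundred(self):
        pop = list(range(100))
        assert percentile_rank(0, pop) == pytest.approx(0.5)

    def test_median_of_odd_population(self):
        assert percentile_rank(3, [1, 2, 3, 4, 5]) == pytest.approx(50.0)

    def test_all_ties_give_fifty(self):
        assert percentile_rank(7.0, [7.0] * 25) == pytest.approx(50.0)

    def test_matches_midrank_formula(self):
        rng = np.random.default_rng(3)
        pop = rng.integers(0, 20, size=200).astype(float)
        for x in [-1.0, 0.0, 7.0, 19.0, 25.0]:
            expected = 100 * (np.sum(pop < x) + 0.5 * np.sum(pop == x)) / pop.size
            assert percentile_rank(x, pop) == pytest.approx(expected)

    @given(st.lists(st.integers(-50, 50), min_size=1, max_size=80), st.integers(-60, 60))
    @settings(max_examples=60, deadline=None)
    def test_bounded_and_monotone(self, pop, x):
        lo = percentile_rank(x, pop)
        hi = percentile_rank(x + 1, pop)
        assert 0.0 <= lo <= hi <= 100.0

    def test_empty_population_rejected(self):
        with pytest.raises(ValueError):
            percentile_rank(1.0, [])


class TestBranchPoint:
    def test_plus_strand_distance(self):
        intron = IntronRecord("t", 1, "chr1", "+", 100, 200, False)
        bp = {("chr1", 100, 200, "+"): 174}
        assert branchpoint_distance(intron, bp) == 24

    def test_minus_strand_mirror_distance(self):
        intron = IntronRecord("t", 1, "chr1", "-", 300, 400, False)
        bp = {("chr1", 300, 400, "-"): 325}
        assert branchpoint_distance(intron, bp) == 24

    def test_absent_intron_is_missing(self):
        intron = IntronRecord("t", 1, "chr1", "+", 100, 200, False)
        assert branchpoint_distance(intron, {}) is None

    def test_branch_point_outside_intron_rejected(self):
        intron = IntronRecord("t", 1, "chr1", "+", 100, 200, False)
        with pytest.raises(ValueError, match="outside"):
            branchpoint_distance(intron, {("chr1", 100, 200, "+"): 250})

    def test_ag_exclusion_zone(self):
        #         bp at 3, next AG starts at 8 -> 4 nt strictly between
        assert ag_exclusion_zone("CCCACCCCAGCC", 3) == 4
        assert ag_exclusion_zone("CCCACCCC", 3) is None


class TestFeatureProfile:
    def test_percentiles_within_gene_match_brute_force(self, default_gene, uniform_maxent):
        models = load_maxent_models(uniform_maxent)
        introns = derive_introns(default_gene.transcript)
        population = compute_intron_features(introns, default_gene.genome, models)
        ranked, within = feature_profile(
            default_gene.transcript, default_gene.genome, models, population
        )
        assert len(ranked) == default_gene.transcript.n_introns
        lengths = [f.length_nt for f in population]
        gcs = [f.gc for f in population]
        for f in ranked:
            assert 0 <= min(f.percentiles.values()) <= max(f.percentiles.values()) <= 100
            # brute-force mid-rank oracle
            bf = 100 * (
                sum(v < f.length_nt for v in lengths)
                + 0.5 * sum(v == f.length_nt for v in lengths)
            ) / len(lengths)
            assert f.percentiles["length_nt"] == pytest.approx(bf)
            bf_gc = 100 * (
                sum(v < f.gc for v in gcs) + 0.5 * sum(v == f.gc for v in gcs)
            ) / len(gcs)
            assert f.percentiles["gc"] == pytest.approx(bf_gc)

    def test_within_gene_table_has_all_scores(self, default_gene, uniform_maxent):
        models = load_maxent_models(uniform_maxent)
        introns = derive_introns(default_gene.transcript)
        population = compute_intron_features(introns, default_gene.genome, models)
        _, within = feature_profile(
            default_gene.transcript, default_gene.genome, models, population
        )
        assert list(within["ordinal"]) == [1, 2, 3, 4]
        assert (within["score5"] == 0.0).all() and (within["score3"] == 0.0).all()

    def test_n_in_window_excluded_from_score_population(self, uniform_maxent):
        models = load_maxent_models(uniform_maxent)
        genome = {"chr1": "A" * 100 + "N" + "A" * 300}
        intron = IntronRecord("t", 1, "chr1", "+", 103, 203, False)  # N in donor window
        feats = compute_intron_features([intron], genome, models)
        assert feats[0].score5 is None
        assert feats[0].score3 is not None
        assert feats[0].gc == 0.0  # N dropped from the GC denominator
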