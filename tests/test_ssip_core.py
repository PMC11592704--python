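import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kruskal as scipy_kruskal
from scipy.stats import rankdata

import ssipscore as ss
from ssipscore.ssip_core import RankedMatrix, kruskal_wallis
from ssipscore.tables_io import ScoreMatrix


def make_matrix(data, direction=None, is_rankscore=None):
    df = pd.DataFrame(data)
    df.index = [f"V{i+1}" for i in range(len(df))]
    df.index.name = "variant"
    direction = direction or {c: 1 for c in df.columns}
    is_rankscore = is_rankscore or {c: False for c in df.columns}
    return ScoreMatrix(scores=df.astype(float), direction=direction,
                       is_rankscore=is_rankscore)


def brute_force_permutation_p(groups):
    """Oracle: exact permutation p over all distinct group relabelings."""
    data = np.concatenate(groups)
    sizes = [len(g) for g in groups]
    labels = tuple(np.repeat(range(len(sizes)), sizes))
    h_obs = scipy_kruskal(*groups)[0]
    hits = total = 0
    for perm in set(itertools.permutations(labels)):
        perm = np.asarray(perm)
        gs = [data[perm == i] for i in range(len(sizes))]
        h = scipy_kruskal(*gs)[0]
        total += 1
        hits += h >= h_obs - 1e-12
    return hits / total


class TestRankScores:
    def test_normalized_ranks(self):
        m = make_matrix({"A": [0.1, 0.5, 0.9]})
        r = ss.rank_scores(m)
        assert list(r.ranks["A"]) == pytest.approx([1 / 3, 2 / 3, 1.0])

    def test_ties_averaged(self):
        m = make_matrix({"A": [0.2, 0.2, 0.7]})
        r = ss.rank_scores(m)
        assert list(r.ranks["A"]) == pytest.approx([0.5, 0.5, 1.0])

    def test_direction_flip(self):
        m = make_matrix({"S": [0.01, 0.5]}, direction={"S": -1})
        r = ss.rank_scores(m)
        assert list(r.ranks["S"]) == pytest.approx([1.0, 0.5])

    def test_rankscore_passthrough_and_missing(self):
        m = make_matrix({"R": [0.9, np.nan, 0.2], "A": [1.0, 2.0, np.nan]},
                        is_rankscore={"R": True, "A": False})
        r = ss.rank_scores(m)
        assert list(r.ranks["R"].dropna()) == [0.9, 0.2]
        assert np.isnan(r.ranks.loc["V3", "A"])

    def test_sparse_column_left_missing(self):
        m = make_matrix({"A": [0.5, np.nan, np.nan], "B": [1, 2, 3]})
        with pytest.warns(UserWarning, match="non-missing"):
            r = ss.rank_scores(m)
        assert r.ranks["A"].isna().all()


class TestKruskalWallis:
    def test_asymptotic_closed_form_df2(self):
        res = kruskal_wallis([[1, 2], [3, 4], [5, 6]], method="asymptotic")
        assert res.H == pytest.approx(32 / 7)
        assert res.df == 2
        # chi-square upper tail with 2 df is exp(-H/2)
        assert res.p == pytest.approx(math.exp(-res.H / 2), rel=1e-12)

    def test_identical_groups(self):
        res = kruskal_wallis([[1, 2, 3]] * 3)
        assert res.H == 0.0 and res.p == 1.0

    def test_all_tied_is_degenerate(self):
        res = kruskal_wallis([[2.0, 2.0], [2.0, 2.0]])
        assert res.degenerate and res.p == 1.0

    def test_untestable_marker(self):
        res = kruskal_wallis([[1, 2, 3], []])
        assert res.method == "untestable" and np.isnan(res.p)

    @pytest.mark.parametrize("sizes", [(2, 2, 2), (2, 3, 3), (3, 3, 3)])
    def test_exact_mode_matches_bruteforce(self, sizes):
        rng = np.random.default_rng(11)
        for _ in range(3):
            groups = [rng.normal(size=s) for s in sizes]
            res = kruskal_wallis(groups)  # auto -> exact at this N
            assert res.method == "exact"
            assert res.p == pytest.approx(brute_force_permutation_p(groups), abs=1e-12)

    def test_exact_mode_handles_ties(self):
        groups = [[1.0, 1.0], [1.0, 2.0], [2.0, 2.0]]
        res = kruskal_wallis(groups)
        assert res.p == pytest.approx(brute_force_permutation_p(groups), abs=1e-12)


class TestSelectSsips:
    def test_constant_predictor_never_selected(self, small_synth):
        matrix, labels = small_synth
        matrix.scores["flat"] = 0.7
        matrix.direction["flat"] = 1
        matrix.is_rankscore["flat"] = False
        tests = ss.select_ssips(ss.rank_scores(matrix), labels).set_index("predictor")
        assert tests.loc["flat", "raw_p"] == 1.0
        assert not tests.loc["flat", "is_ssip"]

    def test_informative_recovered_noise_rejected(self, small_synth):
        matrix, labels = small_synth
        tests = ss.select_ssips(ss.rank_scores(matrix), labels)
        sel = set(tests.loc[tests["is_ssip"], "predictor"])
        assert sel == {p for p in matrix.predictors if p.startswith("inf")}

    def test_min_group_n_blocks_testing(self, small_synth):
        matrix, labels = small_synth
        sparse = labels.groups[labels.groups != "Benign"]
        tests = ss.select_ssips(
            ss.rank_scores(matrix),
            type(labels)(groups=sparse, provenance=labels.provenance.loc[sparse.index]))
        assert not tests["tested"].any()


class TestMetaScores:
    def _ranked(self, data):
        df = pd.DataFrame(data, index=[f"V{i+1}" for i in range(len(next(iter(data.values()))))])
        return RankedMatrix(ranks=df.astype(float),
                            direction={c: 1 for c in df.columns},
                            is_rankscore={c: False for c in df.columns})

    def test_combined_mean_and_top_rank(self):
        r = self._ranked({"A": [0.5, 1.0], "B": [1.0, 0.5]})
        out = ss.combined_score(r, ["A", "B"]).set_index("variant")
        assert out.loc["V1", "combined"] == pytest.approx(0.75)
        r1 = self._ranked({"A": [0.5, 1.0]})
        top = ss.combined_score(r1, ["A"]).set_index("variant")
        assert top.loc["V2", "combined"] == 1.0

    def test_min_fraction_rule(self):
        # variant V1 missing 3 of 5 SSIP values -> below the 0.5 coverage floor
        r = self._ranked({f"P{i}": [np.nan if i < 3 else 0.8, 0.5] for i in range(5)})
        out = ss.combined_score(r, list(r.ranks.columns), min_fraction=0.5).set_index("variant")
        assert np.isnan(out.loc["V1", "combined"])
        assert out.loc["V2", "combined"] == pytest.approx(0.5)

    def test_weighted_mean_before_rescale(self):
        r = self._ranked({"A": [1.0, 0.0, 0.5], "B": [0.0, 1.0, 0.5]})
        tests = pd.DataFrame({"predictor": ["A", "B"], "tested": [True, True],
                              "adj_p": [0.1, 0.9]})  # weights 0.9 / 0.1
        out = ss.weighted_score(r, tests).set_index("variant")
        # pre-rescale scores: V1 0.9, V2 0.1, V3 0.5 -> min-max {1, 0, 0.5}
        assert out.loc["V1", "weighted"] == pytest.approx(1.0)
        assert out.loc["V2", "weighted"] == pytest.approx(0.0)
        assert out.loc["V3", "weighted"] == pytest.approx(0.5)

    def test_uniform_weights_reduce_to_rescaled_mean(self):
        rng = np.random.default_rng(3)
        r = self._ranked({c: rng.random(6) for c in "ABCD"})
        tests = pd.DataFrame({"predictor": list("ABCD"), "tested": True, "adj_p": 0.4})
        w = ss.weighted_score(r, tests)["weighted"].to_numpy()
        mean = r.ranks.mean(axis=1).to_numpy()
        rescaled = (mean - mean.min()) / (mean.max() - mean.min())
        assert w == pytest.approx(rescaled)

    def test_all_zero_weights_warn(self):
        r = self._ranked({"A": [0.5, 1.0]})
        tests = pd.DataFrame({"predictor": ["A"], "tested": [True], "adj_p": [1.0]})
        with pytest.warns(UserWarning, match="zero"):
            out = ss.weighted_score(r, tests)
        assert out["weighted"].isna().all()


class TestScoreAllVariants:
    def test_monotone_transform_invariance(self, small_synth):
        """A strictly increasing transform of one predictor's raw scores
        must leave every rank-based output identical."""
        matrix, labels = small_synth
        base = ss.score_all_variants(matrix, labels)
        warped = ScoreMatrix(scores=matrix.scores.copy(),
                             direction=dict(matrix.direction),
                             is_rankscore=dict(matrix.is_rankscore))
        col = warped.scores.columns[0]
        warped.scores[col] = np.exp(3.0 * warped.scores[col])
        out = ss.score_all_variants(warped, labels)
        pd.testing.assert_frame_equal(base.tests, out.tests)
        pd.testing.assert_frame_equal(base.scores, out.scores)

    def test_deterministic_composition(self, small_synth):
        matrix, labels = small_synth
        a = ss.score_all_variants(matrix, labels)
        b = ss.score_all_variants(matrix, labels)
        pd.testing.assert_frame_equal(a.tests, b.tests)
        pd.testing.assert_frame_equal(a.scores, b.scores)
        assert a.summary == b.summary

    def test_scores_bounded_and_top_variant_is_max(self, small_synth):
        matrix, labels = small_synth
        res = ss.score_all_variants(matrix, labels)
        sc = res.scores["combined"].dropna()
        assert ((sc >= 0) & (sc <= 1)).all()
        wt = res.scores["weighted"].dropna()
        assert ((wt >= 0) & (wt <= 1)).all()

    def test_zero_informative_predictors_yield_no_ssips(self):
        cfg = ss.SynthConfig(n_pathogenic=6, n_benign=6, n_vus=40,
                             n_informative=0, n_noise=6, seed=5)
        matrix, labels = ss.generate_score_matrix(cfg)
        res = ss.score_all_variants(matrix, labels)
        assert res.summary["n_ssips"] == 0
        assert res.scores["combined"].isna().all()
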