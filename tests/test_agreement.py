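import numpy as np
import pandas as pd
import pytest

from pairelo import (
    SimConfig,
    icc_consistency_avg,
    mean_likert,
    pearson,
    rater_subset,
    simulate_panel,
    summarize,
    williams_t,
)

def ratings_frame(arr, stimuli=None, raters=None):
    arr = np.asarray(arr, dtype=float)
    return pd.DataFrame(
        arr,
        index=stimuli or [f"S{i}" for i in range(arr.shape[0])],
        columns=raters or [f"R{j}" for j in range(arr.shape[1])],
    )


class TestMeanLikert:
    def test_constant_ratings(self):
        means = mean_likert(ratings_frame(np.full((3, 5), 4)))
        assert (means == 4).all()

    def test_mean_over_available_raters(self):
        m = ratings_frame([[3, 6], [2, np.nan]])
        means = mean_likert(m)
        assert means.iloc[0] == 4.5
        assert means.iloc[1] == 2.0

    def test_unrated_stimulus_is_an_error(self):
        m = ratings_frame([[3, 4], [np.nan, np.nan]], stimuli=["ok", "empty"])
        with pytest.raises(ValueError, match="empty"):
            mean_likert(m)

    def test_tracks_latent_strengths_on_synthetic_panel(self):
        panel = simulate_panel(SimConfig(n_stimuli=30, n_raters=25, seed=3))
        means = mean_likert(panel.ratings)
        assert pearson(means.to_numpy(), panel.latent.reindex(means.index)) > 0.8


class TestICC:
    def test_additive_rater_offsets_are_ignored(self):
        truth = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        offsets = np.array([0.0, -1.5, 2.0])
        res = icc_consistency_avg(ratings_frame(truth[:, None] + offsets[None, :]))
        assert res.icc == pytest.approx(1.0, abs=1e-12)

    def test_no_stimulus_variance_is_an_explicit_error(self):
        with pytest.raises(ValueError, match="undefined"):
            icc_consistency_avg(ratings_frame(np.full((4, 3), 5)))

    def test_missing_entries_rejected(self):
        m = ratings_frame([[1, 2], [3, np.nan], [5, 6]])
        with pytest.raises(ValueError, match="missing"):
            icc_consistency_avg(m)

    def test_independent_ratings_give_near_zero_icc(self):
        rng = np.random.default_rng(8)
        m = ratings_frame(rng.integers(1, 8, size=(82, 56)))
        res = icc_consistency_avg(m)
        assert res.ci_lower < 0.15
        assert abs(res.icc) < 0.35

    def test_matches_pingouin_icc3k(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(12)
        m = ratings_frame(
            rng.normal(size=(10, 1)) + rng.normal(scale=0.7, size=(10, 6))
        )
        res = icc_consistency_avg(m)
        long = m.rename_axis("stimulus").reset_index().melt(
            id_vars="stimulus", var_name="rater", value_name="score"
        )
        table = pingouin.intraclass_corr(
            data=long, targets="stimulus", raters="rater", ratings="score"
        )
        mask = table["Type"].isin(["ICC3k", "ICC(C,k)"])
        ref = table[mask].iloc[0]
        ci_col = "CI95%" if "CI95%" in table.columns else "CI95"
        assert res.icc == pytest.approx(ref["ICC"], abs=1e-6)
        # pingouin rounds the CI to two decimals
        assert res.ci_lower == pytest.approx(ref[ci_col][0], abs=0.011)
        assert res.ci_upper == pytest.approx(ref[ci_col][1], abs=0.011)

    def test_icc_decreases_with_added_noise(self):
        rng = np.random.default_rng(4)
        truth = rng.normal(size=(40, 1))
        iccs = []
        for noise_sd in (0.2, 1.0, 3.0):
            vals = [
                icc_consistency_avg(
                    ratings_frame(truth + rng.normal(scale=noise_sd, size=(40, 8)))
                ).icc
                for _ in range(5)
            ]
            iccs.append(np.mean(vals))
        assert iccs[0] > iccs[1] > iccs[2]


class TestPearson:
    def test_textbook_values(self):
        x = np.array([1.0, 2, 3, 4, 5])
        assert pearson(x, x) == pytest.approx(1.0)
        assert pearson(x, -x) == pytest.approx(-1.0)
        y = np.array([2.0, 1, 4, 3, 7])
        # direct product-moment formula
        r = ((x - 3) * (y - y.mean())).sum() / np.sqrt(
            ((x - 3) ** 2).sum() * ((y - y.mean()) ** 2).sum()
        )
        assert pearson(x, y) == pytest.approx(r, abs=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            pearson([1, 1, 1, 1], [1, 2, 3, 4])


class TestWilliamsT:
    def test_equal_correlations_give_zero_statistic(self):
        res = williams_t(0.5, 0.5, 0.3, 50)
        assert res.t == 0.0
        assert res.p == pytest.approx(1.0)

    def test_degrees_of_freedom_are_n_minus_3(self):
        assert williams_t(0.44, 0.40, 0.9, 82).df == 79

    def test_sign_and_symmetry(self):
        a = williams_t(0.6, 0.4, 0.5, 40)
        b = williams_t(0.4, 0.6, 0.5, 40)
        assert a.t > 0 > b.t
        assert a.t == pytest.approx(-b.t)
        assert a.p == pytest.approx(b.p)

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            williams_t(0.5, 0.4, 0.3, 3)

    def test_perfect_correlation_rejected(self):
        with pytest.raises(ValueError):
            williams_t(1.0, 0.4, 0.3, 30)


class TestRaterSubset:
    def test_full_fraction_is_identity(self, small_panel):
        sub = rater_subset(small_panel.trials, 1)
        assert sub.trials == small_panel.trials.trials

    @pytest.mark.parametrize("fraction, expected", [(0.5, 28), (0.25, 14)])
    def test_half_and_quarter_of_56_raters(self, fraction, expected):
        panel = simulate_panel(SimConfig(n_stimuli=10, n_raters=56, seed=2))
        sub = rater_subset(panel.trials, fraction)
        assert len(sub.raters) == expected
        assert sub.raters == panel.trials.raters[:expected]
        ratings_sub = rater_subset(panel.ratings, fraction)
        assert ratings_sub.shape[1] == expected

    def test_invalid_fraction_rejected(self, small_panel):
        with pytest.raises(ValueError):
            rater_subset(small_panel.trials, 0)


class TestSummarize:
    def test_constant_vector(self):
        s = summarize([7.0, 7.0, 7.0])
        assert (s.mean, s.sd, s.median, s.minimum, s.maximum) == (7, 0, 7, 7, 7)

    def test_five_point_vector(self):
        s = summarize([1, 2, 3, 4, 5])
        assert s.mean == 3
        assert s.median == 3
        assert (s.minimum, s.maximum) == (1, 5)
        assert s.sd == pytest.approx(np.std([1, 2, 3, 4, 5], ddof=1))

    def test_empty_vector_rejected(self):
        with pytest.raises(ValueError):
            summarize([])
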