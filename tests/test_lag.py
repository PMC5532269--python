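"""Best-lag correlation, TF delay analysis, null envelope, lncRNA targets."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from teb.expression import cpm_normalize, filter_expressed
from teb.lag import (
    best_lag_correlation,
    delay_null_envelope,
    lag_correlation_matrix,
    lncrna_target_inference,
    select_candidate_lncrnas,
    tf_activity_profile,
    tf_target_delays,
)
from teb.scenarios import lag_scenario
from teb.simulate import simulate_study
from tests.conftest import make_experiment, profile_experiment


def brute_force_best_lag(x, y, max_lag, mode="positive"):
    """Exhaustive enumeration oracle with the documented tie-break."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = x.size
    cands = []
    for l in range(-max_lag, max_lag + 1):
        a, b = (x[: n - l], y[l:]) if l >= 0 else (x[-l:], y[: n + l])
        if a.std() == 0 or b.std() == 0:
            continue
        cands.append((l, stats.pearsonr(a, b).statistic))
    if not cands:
        return None, None
    key = (max if mode == "positive" else min)(c[1] for c in cands)
    ties = [c for c in cands if c[1] == key]
    ties.sort(key=lambda c: (abs(c[0]), c[0] < 0))
    return ties[0]


class TestBestLagCorrelation:
    def test_identical_series_lag_zero_r_one(self):
        x = np.sin(np.linspace(0, 3, 21)) + np.linspace(0, 1, 21)
        res = best_lag_correlation(x, x, 3)
        assert res.best_lag == 0 and res.max_r == pytest.approx(1.0)

    def test_pure_shift_recovered_exactly(self):
        t = np.arange(30)
        f = lambda t: np.sin(2 * np.pi * t / 17.0) + 0.05 * t
        x, y = f(t), f(t - 2)  # y lags x by 2 samples
        res = best_lag_correlation(x, y, 4)
        assert res.best_lag == 2
        assert res.max_r >= 0.999

    @pytest.mark.parametrize("mode", ["positive", "negative"])
    def test_matches_exhaustive_enumeration(self, mode):
        rng = np.random.default_rng(5)
        for _ in range(50):
            x = rng.normal(size=21)
            y = rng.normal(size=21)
            res = best_lag_correlation(x, y, 3, mode=mode)
            lag_bf, r_bf = brute_force_best_lag(x, y, 3, mode)
            assert res.best_lag == lag_bf
            assert res.max_r == pytest.approx(r_bf, abs=1e-12)

    def test_symmetry_under_argument_swap(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            x, y = rng.normal(size=21), rng.normal(size=21)
            r1 = best_lag_correlation(x, y, 3)
            r2 = best_lag_correlation(y, x, 3)
            assert r1.best_lag == -r2.best_lag
            assert r1.max_r == pytest.approx(r2.max_r, abs=1e-12)

    def test_constant_series_gives_undefined_sentinel(self):
        res = best_lag_correlation(np.ones(21), np.random.default_rng(0).normal(size=21), 3)
        assert not res.defined

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            best_lag_correlation(np.arange(6.0), np.arange(6.0), 3)

    def test_matrix_path_agrees_with_scalar(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=21)
        Y = rng.normal(size=(10, 21))
        lags = list(range(-3, 4))
        R = lag_correlation_matrix(x, Y, lags)
        for j in range(10):
            for i, l in enumerate(lags):
                res = best_lag_correlation(x, Y[j], 3, min_lag_samples=l)
                # cross-check one entry per (lag, series) via pearson
                n = 21
                a, b = (x[: n - l], Y[j, l:]) if l >= 0 else (x[-l:], Y[j, : n + l])
                assert R[i, j] == pytest.approx(stats.pearsonr(a, b).statistic, abs=1e-12)


class TestTfTargetDelays:
    def test_planted_six_hour_shift_concentrates_histogram(self):
        expt, genes, truth = simulate_study(lag_scenario(3, n_genes=300, n_targets=15))
        expt = filter_expressed(cpm_normalize(expt))
        targets = [t for _, t, _, _ in truth.lagged_pairs()]
        hist, results = tf_target_delays("TF0000", targets, expt, 0.8, 3)
        assert hist.sum() == sum(1 for r in results if r.passed)
        assert hist.idxmax() == 6.0
        assert hist[6.0] >= 0.9 * len(targets)

    def test_uncorrelated_noise_rarely_passes(self):
        rng = np.random.default_rng(8)
        prof = rng.normal(5, 0.5, size=(200, 21))
        expt = cpm_normalize(profile_experiment(prof, np.arange(21) * 6.0, scale=2000))
        hist, results = tf_target_delays("g0", [f"g{i}" for i in range(1, 200)], expt, 0.8, 3)
        assert sum(r.passed for r in results) <= 10  # ~5% of 199 at r>0.8

    def test_tf_as_its_own_target(self):
        rng = np.random.default_rng(9)
        prof = rng.normal(5, 0.5, size=(20, 21))
        expt = cpm_normalize(profile_experiment(prof, np.arange(21) * 6.0, scale=2000))
        _, results = tf_target_delays("g0", ["g0"], expt, 0.8, 3)
        assert results[0].best_lag == 0
        assert results[0].max_r == pytest.approx(1.0)

    def test_empty_target_set_rejected(self, norm_small):
        with pytest.raises(ValueError):
            tf_target_delays("g0", [], norm_small, 0.8, 0)


class TestDelayNullEnvelope:
    def _expt(self, seed=10, n=320):
        rng = np.random.default_rng(seed)
        prof = rng.normal(5, 0.5, size=(n, 21))
        return cpm_normalize(profile_experiment(prof, np.arange(21) * 6.0, scale=2000))

    def test_envelope_deterministic_under_seed(self):
        expt = self._expt()
        e1 = delay_null_envelope(expt, "g0", 20, n_draws=40, seed=5)
        e2 = delay_null_envelope(expt, "g0", 20, n_draws=40, seed=5)
        assert e1.quantiles.equals(e2.quantiles)

    def test_envelope_counts_bounded_by_set_size(self):
        expt = self._expt()
        env = delay_null_envelope(expt, "g0", 20, n_draws=40, seed=5)
        assert (env.quantiles >= 0).all() and (env.quantiles <= 20).all()

    def test_planted_set_exceeds_envelope_at_planted_lag(self):
        expt, genes, truth = simulate_study(lag_scenario(4, n_genes=300, n_targets=15))
        expt = filter_expressed(cpm_normalize(expt))
        targets = [t for _, t, _, _ in truth.lagged_pairs()]
        hist, _ = tf_target_delays("TF0000", targets, expt, 0.8, 3)
        env = delay_null_envelope(expt, "TF0000", len(targets), n_draws=100, seed=0)
        assert hist[6.0] > env.quantiles[6.0]

    def test_small_universe_rejected(self):
        expt = self._expt(n=50)
        with pytest.raises(ValueError):
            delay_null_envelope(expt, "g0", 20, n_draws=10, seed=0)


class TestNullCalibration:
    def test_random_set_passing_rate_matches_direct_monte_carlo(self):
        # P(max-over-lags r > 0.8) for i.i.d. noise, length 21: the passing
        # rate of random gene sets should match an independent simulation
        rng = np.random.default_rng(30)
        n_mc = 4000
        exceed = 0
        for _ in range(n_mc):
            x, y = rng.normal(size=21), rng.normal(size=21)
            best = max(
                stats.pearsonr(x[: 21 - l], y[l:]).statistic if l >= 0
                else stats.pearsonr(x[-l:], y[: 21 + l]).statistic
                for l in range(-3, 4)
            )
            exceed += best > 0.8
        p_direct = exceed / n_mc

        prof = rng.normal(5, 0.5, size=(400, 21))
        expt = cpm_normalize(profile_experiment(prof, np.arange(21) * 6.0, scale=2000))
        _, results = tf_target_delays("g0", [f"g{i}" for i in range(1, 400)], expt, 0.8, 3)
        p_sets = np.mean([r.passed for r in results])
        se = np.sqrt(p_direct * (1 - p_direct) * (1 / n_mc + 1 / 399))
        assert abs(p_sets - p_direct) < max(4 * se, 0.02)


class TestTfActivityProfile:
    def test_constant_targets_give_zero_profile(self):
        prof = np.full((5, 21), 4.0)
        expt = cpm_normalize(profile_experiment(prof, np.arange(21) * 6.0, scale=2000))
        act = tf_activity_profile(["g0", "g1", "g2"], expt)
        assert np.allclose(act, 0.0, atol=1e-9)

    def test_hand_computed_medians(self):
        # three targets with known log2 fold changes relative to t=0
        t = [0.0, 6.0, 12.0]
        prof = np.array(
            [
                [3.0, 4.0, 5.0],  # +1, +2
                [3.0, 3.0, 3.0],  # 0, 0
                [3.0, 5.0, 2.0],  # +2, -1
            ]
        )
        counts = np.round(1000 * np.power(2.0, np.repeat(prof, 2, axis=1)))
        filler = counts.sum(axis=0).max() * 2 - counts.sum(axis=0)  # equal libraries
        expt = cpm_normalize(make_experiment(np.vstack([counts, filler]), t))
        act = tf_activity_profile(["g0", "g1", "g2"], expt)
        assert act[0.0] == pytest.approx(0.0)
        assert act[6.0] == pytest.approx(1.0, abs=0.01)
        assert act[12.0] == pytest.approx(0.0, abs=0.01)


class TestLncrnaTargets:
    def _planted(self, seed=0):
        t = np.arange(21) * 6.0
        base = np.sin(2 * np.pi * t / 48.0) * 1.5 + 5
        shift = np.sin(2 * np.pi * (t - 6.0) / 48.0) * 1.5 + 5
        lead = np.sin(2 * np.pi * (t + 6.0) / 48.0) * 1.5 + 5
        neg = 10 - base
        rng = np.random.default_rng(seed)
        filler = rng.normal(5, 0.3, size=(6, 21))
        prof = np.vstack([base, shift, lead, neg, filler])
        return cpm_normalize(profile_experiment(prof, t, scale=5000))

    def test_shifted_candidate_is_positive_target_with_6h_delay(self):
        expt = self._planted()
        out = lncrna_target_inference(["g0"], [f"g{i}" for i in range(1, 10)], expt,
                                      r_threshold=0.9)
        hit = out[(out["target"] == "g1") & (out["association"] == "positive")]
        assert len(hit) == 1
        assert abs(hit["delay_hours"].iloc[0] - 6.0) <= 1.3  # one dense-grid step

    def test_negated_profile_is_negative_target_at_lag_zero(self):
        expt = self._planted()
        out = lncrna_target_inference(["g0"], ["g3"], expt, r_threshold=0.9)
        hit = out[(out["target"] == "g3") & (out["association"] == "negative")]
        assert len(hit) == 1
        assert hit["delay_hours"].iloc[0] == pytest.approx(0.0)

    def test_candidate_leading_the_lncrna_is_excluded(self):
        # g2 leads g0 by 6 h; only lags >= 0 (lncRNA leading) are searched
        expt = self._planted()
        out = lncrna_target_inference(["g0"], ["g2"], expt, r_threshold=0.97)
        assert out[(out["target"] == "g2") & (out["association"] == "positive")].empty

    def test_excessive_delay_window_rejected(self):
        expt = self._planted()
        with pytest.raises(ValueError):
            lncrna_target_inference(["g0"], ["g1"], expt, max_delay_hours=100.0)


class TestSelectCandidateLncrnas:
    def _setup(self, n_lnc=30, seed=11):
        rng = np.random.default_rng(seed)
        prof = rng.normal(5, 1.0, size=(n_lnc + 20, 21))
        expt = cpm_normalize(profile_experiment(prof, np.arange(21) * 6.0, scale=2000))
        import pandas as pd

        biotype = ["lincRNA"] * n_lnc + ["protein_coding"] * 20
        ann = pd.DataFrame(
            {"gene_id": list(expt.gene_ids), "biotype": biotype}
        ).set_index("gene_id", drop=False)
        return expt, ann

    def test_combined_rank_equals_independent_recomputation(self):
        expt, ann = self._setup()
        sel = select_candidate_lncrnas(expt, ann, n=10)
        lnc = [g for g in expt.gene_ids if ann.loc[g, "biotype"] == "lincRNA"]
        le = expt.logexpr.loc[lnc]
        med_rank = le.median(axis=1).rank(ascending=False, method="first")
        var_rank = le.var(axis=1).rank(ascending=False, method="first")
        pool = set(med_rank.index[med_rank <= 10]) | set(var_rank.index[var_rank <= 10])
        expected = (med_rank + var_rank).loc[sorted(pool)].sort_values(kind="stable").index[:10]
        assert sel == list(expected)
        assert all(ann.loc[g, "biotype"] == "lincRNA" for g in sel)

    def test_n_larger_than_pool_returns_everything(self):
        expt, ann = self._setup(n_lnc=5)
        sel = select_candidate_lncrnas(expt, ann, n=50)
        assert len(sel) == 5
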