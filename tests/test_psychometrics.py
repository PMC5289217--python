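"""Probit psychometric fitting against independent oracles, plus group stats."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from headgain.observers import LinearObserver, p_with
from headgain.psychometrics import (
    TrialRecord,
    aggregate,
    apply_outlier_rule,
    bootstrap_ci,
    fit_probit,
    fit_trials,
    group_stats,
)


def make_table(gains, n_with, n_total):
    return pd.DataFrame({"gain": gains, "n_with": n_with, "n_total": n_total})


def grid_search_ml(table, pse_range=(-1.0, 1.0), sd_range=(0.02, 1.5)):
    """Brute-force ML oracle: exhaustive coarse grid, then a fine local grid.

    Independent of the package's Fisher-scoring path: evaluates the binomial
    log-likelihood of Phi((g - pse)/sd) on an explicit parameter grid.
    """
    g = table["gain"].to_numpy(float)
    k = table["n_with"].to_numpy(float)
    n = table["n_total"].to_numpy(float)

    def loglik(pse, sd):
        p = np.clip(norm.cdf((g[None, None, :] - pse[:, None, None]) / sd[None, :, None]),
                    1e-12, 1 - 1e-12)
        return np.sum(k * np.log(p) + (n - k) * np.log1p(-p), axis=-1)

    pses = np.linspace(*pse_range, 401)
    sds = np.linspace(*sd_range, 371)
    for _ in range(3):
        ll = loglik(pses, sds)
        i, j = np.unravel_index(np.argmax(ll), ll.shape)
        dp, ds = pses[1] - pses[0], sds[1] - sds[0]
        pses = np.linspace(pses[i] - 2 * dp, pses[i] + 2 * dp, 81)
        sds = np.linspace(max(sds[j] - 2 * ds, 1e-3), sds[j] + 2 * ds, 81)
    ll = loglik(pses, sds)
    i, j = np.unravel_index(np.argmax(ll), ll.shape)
    return pses[i], sds[j]


def simulate_trials(obs, gains, reps, rng, condition="c", listener="L01"):
    recs = []
    for g in gains:
        p = p_with(obs, g)
        for _ in range(reps):
            recs.append(TrialRecord(listener, condition, float(g),
                                    "with" if rng.random() < p else "against", 60.0))
    return recs


class TestAggregate:
    def test_constant_stimuli_counts(self, rng):
        gains = np.round(np.arange(-0.5, 0.751, 0.25), 10)
        obs = LinearObserver(e=0.85, r=1.0)
        recs = simulate_trials(obs, gains, 20, rng)
        table = aggregate(recs)
        assert len(table) == 6
        assert (table["n_total"] == 20).all()
        assert table["n_total"].sum() == 120

    def test_single_trial(self):
        t = aggregate([TrialRecord("L", "c", 0.1, "with", 50.0)])
        assert t.shape == (1, 3)
        assert t.loc[0, "n_with"] == 1 and t.loc[0, "n_total"] == 1

    def test_order_invariance(self, rng):
        gains = [-0.2, 0.0, 0.2]
        recs = simulate_trials(LinearObserver(e=0.9, r=1.0), gains, 10, rng)
        shuffled = list(recs)
        rng.shuffle(shuffled)
        pd.testing.assert_frame_equal(aggregate(recs), aggregate(shuffled))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            aggregate([])


TOY_TABLES = [
    # (gains, n_with out of n_total) — small method-of-constant-stimuli tables
    ([-0.25, 0.0, 0.25], [2, 10, 18], [20, 20, 20]),
    ([-0.5, -0.25, 0.0, 0.25, 0.5, 0.75], [1, 3, 8, 14, 19, 20], [20] * 6),
    ([-0.4, -0.3, -0.2, -0.1, 0.0, 0.1, 0.2, 0.3, 0.4],
     [0, 1, 2, 5, 9, 13, 17, 19, 20], [20] * 9),
    ([-0.2, 0.0, 0.2, 0.4], [3, 7, 15, 19], [20, 20, 20, 20]),
]


class TestFitProbit:
    def test_consistency_at_asymptotic_n(self):
        # counts generated exactly from Phi((g-0.1)/0.2), n = 1e6 per gain
        gains = np.round(np.arange(-0.5, 0.751, 0.25), 10)
        n = 1_000_000
        k = np.round(norm.cdf((gains - 0.1) / 0.2) * n).astype(int)
        fit = fit_probit(make_table(gains, k, [n] * 6))
        assert fit.converged
        assert fit.pse == pytest.approx(0.100, abs=0.001)
        assert fit.sd == pytest.approx(0.200, abs=0.002)

    @pytest.mark.parametrize("gains,k,n", TOY_TABLES)
    def test_matches_grid_search_oracle(self, gains, k, n):
        table = make_table(gains, k, n)
        fit = fit_probit(table)
        pse_o, sd_o = grid_search_ml(table)
        assert fit.converged
        assert fit.pse == pytest.approx(pse_o, abs=1e-3)
        assert fit.sd == pytest.approx(sd_o, abs=1e-3)

    @pytest.mark.parametrize("gains,k,n", TOY_TABLES[:2])
    def test_matches_statsmodels_probit_glm(self, gains, k, n):
        # second independent route: IRLS probit GLM on (intercept, slope)
        sm = pytest.importorskip("statsmodels.api")
        table = make_table(gains, k, n)
        endog = np.column_stack([table["n_with"], table["n_total"] - table["n_with"]])
        exog = sm.add_constant(table["gain"].to_numpy())
        res = sm.GLM(endog, exog, family=sm.families.Binomial(sm.families.links.Probit())).fit()
        a, b = res.params
        fit = fit_probit(table)
        assert fit.pse == pytest.approx(-a / b, abs=1e-6)
        assert fit.sd == pytest.approx(1 / abs(b), abs=1e-6)

    def test_flipped_responses_keep_pse(self):
        gains, k, n = TOY_TABLES[1]
        fit = fit_probit(make_table(gains, k, n))
        flipped = fit_probit(make_table(gains, np.array(n) - np.array(k), n))
        assert flipped.pse == pytest.approx(fit.pse, abs=1e-9)
        assert flipped.sd == pytest.approx(fit.sd, abs=1e-9)

    def test_gain_shift_equivariance(self):
        gains, k, n = TOY_TABLES[2]
        fit = fit_probit(make_table(gains, k, n))
        c = 0.37
        shifted = fit_probit(make_table(np.asarray(gains) + c, k, n))
        assert shifted.pse == pytest.approx(fit.pse + c, abs=1e-8)
        assert shifted.sd == pytest.approx(fit.sd, abs=1e-8)

    def test_all_identical_responses_flagged_not_raised(self):
        fit = fit_probit(make_table([-0.2, 0.0, 0.2], [0, 0, 0], [20, 20, 20]))
        assert not fit.converged
        fit = fit_probit(make_table([-0.2, 0.0, 0.2], [20, 20, 20], [20, 20, 20]))
        assert not fit.converged

    def test_perfect_separation_flagged(self):
        fit = fit_probit(make_table([-0.2, -0.1, 0.1, 0.2], [0, 0, 20, 20], [20] * 4))
        assert not fit.converged

    def test_single_gain_flagged(self):
        assert not fit_probit(make_table([0.0], [10], [20])).converged

    def test_estimator_bias_small_at_design_n(self):
        # Monte-Carlo at the standard design: 6 gains x 20 trials,
        # true pse 0.15, sd 0.25 — mean recovered PSE within 0.01
        gains = np.round(np.arange(-0.5, 0.751, 0.25), 10)
        p = norm.cdf((gains - 0.15) / 0.25)
        rng = np.random.default_rng(77)
        pses = []
        for _ in range(1000):
            k = rng.binomial(20, p)
            fit = fit_probit(make_table(gains, k, [20] * 6))
            if fit.converged:
                pses.append(fit.pse)
        assert len(pses) > 950
        assert abs(np.mean(pses) - 0.15) < 0.01


class TestBootstrap:
    def test_deterministic_given_seed(self, rng):
        recs = simulate_trials(LinearObserver(e=0.85, r=1.0),
                               np.arange(-0.5, 0.751, 0.25), 20, rng)
        a = bootstrap_ci(recs, n_boot=200, seed=42)
        b = bootstrap_ci(recs, n_boot=200, seed=42)
        assert a == b

    def test_interval_narrow_at_large_n(self):
        gains = np.round(np.arange(-0.5, 0.751, 0.25), 10)
        n = 20_000
        k = np.round(norm.cdf((gains - 0.15) / 0.25) * n).astype(int)
        frames = []
        for g, kk in zip(gains, k):
            frames.append(pd.DataFrame({
                "listener_id": "L", "condition": "c", "gain": g,
                "response": ["with"] * kk + ["against"] * (n - kk),
                "rms_speed": 60.0,
            }))
        ci = bootstrap_ci(pd.concat(frames, ignore_index=True), n_boot=150, seed=0)
        lo, hi = ci["pse_ci"]
        assert hi - lo < 0.01
        assert ci["skip_rate"] == 0.0

    def test_coverage_near_nominal(self):
        # 200 synthetic repeats of the 120-trial design: the 95% interval
        # should cover the true PSE about 95% of the time (+/-5 points)
        gains = np.round(np.arange(-0.5, 0.751, 0.25), 10)
        true_pse, true_sd = 0.15, 0.25
        p = norm.cdf((gains - true_pse) / true_sd)
        rng = np.random.default_rng(2024)
        covered = trials = 0
        for _ in range(200):
            k = rng.binomial(20, p)
            recs = []
            for g, kk in zip(gains, k):
                recs.extend([TrialRecord("L", "c", float(g), "with", 60.0)] * kk)
                recs.extend([TrialRecord("L", "c", float(g), "against", 60.0)] * (20 - kk))
            ci = bootstrap_ci(recs, n_boot=200, seed=rng.integers(2**31))
            lo, hi = ci["pse_ci"]
            if np.isfinite(lo):
                trials += 1
                covered += lo <= true_pse <= hi
        assert trials > 190
        assert abs(covered / trials - 0.95) < 0.05

    def test_small_n_boot_rejected(self, rng):
        recs = simulate_trials(LinearObserver(e=0.85, r=1.0), [-0.2, 0.0, 0.2], 10, rng)
        with pytest.raises(ValueError):
            bootstrap_ci(recs, n_boot=50)


class TestGroupStats:
    def test_identical_pses_degenerate_flag(self):
        fits = pd.DataFrame({"listener_id": list("abc"), "condition": ["c"] * 3,
                             "pse": [0.15, 0.15, 0.15]})
        out = group_stats(fits)
        assert out.loc[0, "degenerate"]
        assert out.loc[0, "se"] == 0.0
        assert np.isinf(out.loc[0, "t"])

    def test_symmetric_values_give_t_zero(self):
        fits = pd.DataFrame({"listener_id": list("abcd"), "condition": ["c"] * 4,
                             "pse": [-0.2, -0.1, 0.1, 0.2]})
        out = group_stats(fits)
        assert out.loc[0, "t"] == pytest.approx(0.0, abs=1e-12)
        assert out.loc[0, "p"] == pytest.approx(1.0)

    def test_t_matches_textbook_formula(self):
        rng = np.random.default_rng(11)
        x = rng.normal(0.15, 0.09, 12)
        fits = pd.DataFrame({"listener_id": [f"L{i}" for i in range(12)],
                             "condition": ["c"] * 12, "pse": x})
        out = group_stats(fits)
        t_oracle = np.mean(x) / (np.std(x, ddof=1) / np.sqrt(12))
        assert out.loc[0, "t"] == pytest.approx(t_oracle, rel=0.10)

    def test_single_listener_rejected(self):
        fits = pd.DataFrame({"listener_id": ["a"], "condition": ["c"], "pse": [0.1]})
        with pytest.raises(ValueError):
            group_stats(fits)


class TestOutlierRule:
    def test_far_listener_dropped_whole(self):
        pse = [0.15] * 11 + [50.0]
        fits = pd.DataFrame({"listener_id": [f"L{i}" for i in range(12)],
                             "condition": ["c"] * 12, "pse": pse})
        kept, excluded = apply_outlier_rule(fits, n_sd=3.0)
        assert excluded == ["L11"]
        assert len(kept) == 11

    def test_no_outliers_untouched(self):
        fits = pd.DataFrame({"listener_id": list("abc"), "condition": ["c"] * 3,
                             "pse": [0.1, 0.15, 0.2]})
        kept, excluded = apply_outlier_rule(fits, n_sd=10.0)
        assert excluded == []
        assert len(kept) == 3


def test_fit_trials_end_to_end(rng):
    obs = LinearObserver(e=0.85, r=1.0, sigma_m=0.25, lapse=0.0)
    gains = np.round(np.arange(-0.5, 0.751, 0.25), 10)
    recs = simulate_trials(obs, gains, 200, rng)
    fit = fit_trials(recs)
    assert fit.converged
    assert fit.pse == pytest.approx(0.15, abs=0.04)
    assert fit.sd == pytest.approx(0.25, abs=0.05)
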