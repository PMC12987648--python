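"""Design-matrix construction, logistic/linear fitting, the quadratic RT
vertex, sliding RT windows, collinearity pruning and the behavioural
battery."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from c1readout import choice_models as cm
from c1readout import onsets, synth


def _toy_trials(n=200, seed=0, n_cov=0):
    rng = np.random.default_rng(seed)
    t = pd.DataFrame({
        "rt_ms": rng.uniform(150, 550, n),
        "choice": rng.integers(0, 2, n),
        "target": rng.integers(0, 2, n),
        "prev_choice": rng.integers(0, 2, n),
        "correct": rng.integers(0, 2, n),
        "participant": rng.integers(0, 4, n),
        "excluded": np.zeros(n, dtype=bool),
    })
    cov = pd.DataFrame({f"s{i}": rng.normal(size=n) for i in range(n_cov)})
    return t, cov


class TestBuildDesign:
    def test_sixteen_predictors_give_48_regressors(self):
        """C1 + target + previous choice + 7 time-domain + 6 TF signals,
        each with main, linear-RT and quadratic-RT terms: 48 columns."""
        t, cov = _toy_trials(n=300, n_cov=13)
        cov["c1"] = np.random.default_rng(1).normal(size=300)
        predictors = ["c1", "target", "prev_choice"] + \
            [f"s{i}" for i in range(13)]
        spec = cm.DesignSpec(predictors=predictors,
                             rt_interactions="quadratic")
        assert spec.n_regressors() == 48
        design, y, groups = cm.build_design(t, cov, spec)
        assert design.shape[1] == 48

    def test_no_interactions_gives_16_columns(self):
        t, cov = _toy_trials(n=300, n_cov=13)
        cov["c1"] = np.random.default_rng(1).normal(size=300)
        predictors = ["c1", "target", "prev_choice"] + \
            [f"s{i}" for i in range(13)]
        design, _, _ = cm.build_design(
            t, cov, cm.DesignSpec(predictors=predictors,
                                  rt_interactions="none"))
        assert design.shape[1] == 16

    def test_zscoring_and_binary_coding(self):
        t, cov = _toy_trials(n=500, n_cov=1)
        design, _, _ = cm.build_design(
            t, cov, cm.DesignSpec(predictors=["s0", "target"],
                                  rt_interactions="none"))
        assert design["s0"].mean() == pytest.approx(0.0, abs=1e-10)
        assert design["s0"].std(ddof=0) == pytest.approx(1.0, abs=1e-10)
        assert set(np.unique(design["target"])) <= {0.0, 1.0}

    def test_rt_exclusions_applied(self):
        t, cov = _toy_trials(n=100)
        t.loc[:9, "rt_ms"] = 700.0      # over the 600 ms analysis cut
        t.loc[10, "excluded"] = True
        design, y, _ = cm.build_design(
            t, None, cm.DesignSpec(predictors=["target"],
                                   rt_interactions="none"))
        assert len(y) == 89

    def test_constant_predictor_dropped_with_warning(self):
        t, cov = _toy_trials(n=100, n_cov=1)
        cov["s0"] = 1.0
        with pytest.warns(UserWarning, match="constant"):
            design, _, _ = cm.build_design(
                t, cov, cm.DesignSpec(predictors=["s0", "target"],
                                      rt_interactions="none"))
        assert list(design.columns) == ["target"]


class TestQuadraticVertex:
    def test_published_style_triplet(self):
        """beta (0.56, -3.68, 5.32): the quadratic in RT is extremal at
        -(-3.68)/(2*5.32) s = 346 ms."""
        ms, kind = cm.quadratic_vertex(0.56, -3.68, 5.32)
        assert round(ms) == 346
        assert kind == "min"

    def test_zero_linear_term_vertex_at_zero(self):
        assert cm.quadratic_vertex(1.0, 0.0, 2.0)[0] == 0.0

    def test_constructed_vertex(self):
        v, a = 0.25, 1.0
        ms, _ = cm.quadratic_vertex(0.0, -2 * a * v, a)
        assert ms == pytest.approx(250.0)

    def test_invariant_to_common_rescaling(self):
        m1, _ = cm.quadratic_vertex(0.56, -3.68, 5.32)
        m2, _ = cm.quadratic_vertex(5.6, -36.8, 53.2)
        assert m1 == pytest.approx(m2)

    def test_zero_quadratic_rejected(self):
        with pytest.raises(ValueError):
            cm.quadratic_vertex(1.0, 1.0, 0.0)


class TestFitLogistic:
    def test_parameter_recovery_within_3_se(self):
        rng = np.random.default_rng(2)
        n = 20_000
        X = pd.DataFrame({"a": rng.normal(size=n), "b": rng.normal(size=n)})
        eta = 1.0 * X["a"] - 0.5 * X["b"]
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).to_numpy(float)
        fit = cm.fit_logistic(X, y)
        assert abs(fit["a"]["beta"] - 1.0) < 3 * fit["a"]["se"]
        assert abs(fit["b"]["beta"] + 0.5) < 3 * fit["b"]["se"]

    def test_agrees_with_statsmodels_oracle(self):
        """The in-package IRLS matches an independent maximum-likelihood
        fit to 1e-6 in coefficients and standard errors."""
        rng = np.random.default_rng(3)
        for n in (60, 200):
            X = pd.DataFrame({"a": rng.normal(size=n),
                              "b": rng.normal(size=n)})
            y = (rng.random(n) < 0.3 + 0.4 * (X["a"] > 0)).to_numpy(float)
            fit = cm.fit_logistic(X, y)
            ref = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
            assert np.allclose(fit.params, ref.params.to_numpy(), atol=1e-6)
            assert np.allclose(fit.se, ref.bse.to_numpy(), atol=1e-6)

    def test_type_one_error_calibrated(self):
        """A predictor independent of the response exceeds |t| = 2 in at
        most ~6% of seeded replicates."""
        rng = np.random.default_rng(4)
        hits = 0
        n_rep = 500
        for _ in range(n_rep):
            n = 300
            X = pd.DataFrame({"a": rng.normal(size=n)})
            y = rng.integers(0, 2, n).astype(float)
            fit = cm.fit_logistic(X, y)
            hits += abs(fit["a"]["t"]) < 2
        assert hits / n_rep >= 0.94

    def test_perfect_separation_flagged(self):
        X = pd.DataFrame({"a": np.linspace(-1, 1, 40)})
        y = (X["a"] > 0).to_numpy(float)
        with pytest.warns(cm.PerfectSeparationWarning):
            fit = cm.fit_logistic(X, y)
        assert not fit.converged

    def test_constant_response_rejected(self):
        X = pd.DataFrame({"a": np.arange(10.0)})
        with pytest.raises(ValueError):
            cm.fit_logistic(X, np.ones(10))

    def test_random_intercepts_recover_group_structure(self):
        rng = np.random.default_rng(5)
        n, q = 6000, 10
        g = rng.integers(0, q, n)
        u = rng.normal(0, 1.0, q)
        X = pd.DataFrame({"a": rng.normal(size=n)})
        eta = 0.8 * X["a"].to_numpy() + u[g]
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        fit = cm.fit_logistic(X, y, random_intercepts=True, groups=g)
        assert abs(fit["a"]["beta"] - 0.8) < 3 * fit["a"]["se"]


class TestSlidingWindows:
    def test_grid_is_81_windows(self):
        trials = synth.simulate_c1_dataset(4, 300, coupling=0.0,
                                           band_ms=None, seed=0)
        series = cm.sliding_rt_models(trials, None, ["c1", "target"])
        assert len(series.centers_pct) == 81
        assert series.centers_pct[0] == 10 and series.centers_pct[-1] == 90
        assert np.all(np.diff(series.centers_ms) >= 0)

    def test_recovers_injected_rt_band(self):
        """C1-choice coupling confined to RTs 250-380 ms: the significant-
        window run covers that band within one window width at each
        edge."""
        trials = synth.simulate_c1_dataset(10, 1000, coupling=0.6,
                                           band_ms=(250.0, 380.0), seed=7)
        series = cm.sliding_rt_models(trials, None,
                                      ["c1", "target", "prev_choice"])
        run = onsets.fit_significance_run(series.significance("c1"))
        assert run is not None
        on_ms, off_ms = onsets.run_to_latencies(run, series, "c1")
        rt = trials.loc[trials["rt_ms"] <= 600, "rt_ms"]

        def width(center_pct):
            lo, hi = cm.rt_window_bounds(rt, center_pct)
            return hi - lo

        assert abs(on_ms - 250.0) <= width(series.centers_pct[run[0]])
        assert abs(off_ms - 380.0) <= width(series.centers_pct[run[1]])
        # the reporting sign flip makes in-band coefficients positive
        inside = slice(run[0], run[1] + 1)
        assert series.coefficients("c1", flip=True)[inside].mean() > 0

    def test_null_coupling_calibrated(self):
        """Without any injected coupling the significant-window fraction
        stays near the nominal 5% level (averaged over seeded
        replicates)."""
        fracs = []
        for seed in range(8):
            trials = synth.simulate_c1_dataset(6, 400, coupling=0.0,
                                               band_ms=None, seed=seed)
            series = cm.sliding_rt_models(trials, None, ["c1", "target"])
            fracs.append(series.significance("c1").mean())
        assert np.mean(fracs) < 0.12

    def test_windows_span_20_percentile_points(self):
        trials = synth.simulate_c1_dataset(2, 500, coupling=0.0,
                                           band_ms=None, seed=1)
        rt = trials.loc[trials["rt_ms"] <= 600, "rt_ms"].to_numpy()
        lo, hi = cm.rt_window_bounds(rt, 50.0)
        inside = ((rt >= lo) & (rt <= hi)).mean()
        assert inside == pytest.approx(0.20, abs=0.02)


class TestCollinearityPrune:
    def test_duplicate_column_removed(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=100)
        d = pd.DataFrame({"c1": rng.normal(size=100), "x": a, "y": a})
        pruned, dropped = cm.collinearity_prune(d, 0.5)
        assert len(dropped) == 1 and dropped[0] in {"x", "y"}

    def test_matches_bruteforce_minimum(self):
        """Greedy pruning removes exactly as many columns as the
        brute-force minimal subset on an engineered 8-column design."""
        from itertools import combinations

        rng = np.random.default_rng(1)
        n = 400
        base = rng.normal(size=(n, 6))
        d = pd.DataFrame(base, columns=[f"v{i}" for i in range(6)])
        d["w0"] = d["v0"] * 0.95 + 0.1 * rng.normal(size=n)
        d["w1"] = d["v1"] * 0.95 + 0.1 * rng.normal(size=n)

        def ok(cols):
            R = np.corrcoef(d[list(cols)].to_numpy(), rowvar=False)
            np.fill_diagonal(R, 0)
            return np.abs(R).max() <= 0.5

        cols = list(d.columns)
        brute = None
        for k in range(len(cols) + 1):
            if any(ok(set(cols) - set(drop))
                   for drop in combinations(cols, k)):
                brute = k
                break
        _, dropped = cm.collinearity_prune(d, 0.5, protected=())
        assert len(dropped) == brute == 2

    def test_already_satisfying_untouched(self):
        rng = np.random.default_rng(2)
        d = pd.DataFrame(rng.normal(size=(200, 4)),
                         columns=list("abcd"))
        _, dropped = cm.collinearity_prune(d, 0.5)
        assert dropped == []

    def test_protected_pair_raises(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=100)
        d = pd.DataFrame({"c1": a, "c1:rt": a + 1e-6 * rng.normal(size=100)})
        with pytest.raises(ValueError, match="protected"):
            cm.collinearity_prune(d, 0.5)


class TestC1DvModel:
    def _history_dataset(self, gain, seed=0):
        trials = synth.simulate_c1_dataset(8, 800, coupling=0.0,
                                           band_ms=None, seed=seed)
        band = trials["rt_ms"].between(250, 400)
        trials.loc[band, "c1"] -= gain * (
            2 * trials.loc[band, "prev_choice"] - 1)
        return trials

    def test_detects_banded_history_modulation(self):
        """A previous-choice C1 modulation confined to an interior RT band
        appears as a significant quadratic RT interaction."""
        trials = self._history_dataset(gain=0.8, seed=11)
        fit = cm.fit_c1_dv_model(trials, None)
        assert fit["prev_choice:rt2"]["p"] < 0.05

    def test_null_modulation_calibrated(self):
        hits = 0
        for seed in range(10):
            fit = cm.fit_c1_dv_model(self._history_dataset(0.0, seed), None)
            hits += fit["prev_choice:rt2"]["p"] < 0.05
        assert hits <= 2

    def test_history_effect_stable_without_current_choice(self):
        trials = self._history_dataset(gain=0.8, seed=11)
        with_choice = cm.fit_c1_dv_model(trials, None)
        without = cm.fit_c1_dv_model(trials, None,
                                     include_current_choice=False)
        a = with_choice["prev_choice"]
        b = without["prev_choice"]
        assert abs(a["beta"] - b["beta"]) < a["se"]


class TestBehaviouralModels:
    def test_quadratic_accuracy_and_history_signs(self, big_trials):
        t = big_trials.copy()
        t["participant"] = 0
        out = cm.fit_behavioural_models(t)
        acc = out["accuracy_rt"]
        assert acc["rt_s2"]["beta"] < 0 and acc["rt_s2"]["p"] < 1e-3
        hist = out["choice_history"]
        assert hist["prev_choice"]["beta"] < 0    # switching tendency

    def test_deadline_contrasts(self, both_deadline_trials):
        out = cm.fit_behavioural_models(both_deadline_trials)
        assert out["rt_deadline"]["deadline"]["beta"] > 0   # 600 ms slower
        assert out["accuracy_rt"]["deadline"]["beta"] > 0   # and better
        sd = out["rt_variability"]
        assert (sd["sd_600"] > sd["sd_400"]).all()
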