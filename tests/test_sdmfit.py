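"""Mixed-model fitting, AIC selection, discrimination metrics and CV."""

import itertools

import numpy as np
import pandas as pd
import pytest

from conftest import simulate_mixed_logistic
from seasonsdm.errors import SingleClassError
from seasonsdm.sdmfit import (
    auc,
    cross_validate,
    fit_sdm,
    run_design,
    stepwise_aic,
    threshold_metrics,
)


def brute_force_auc(scores, labels):
    """O(n^2) pairwise-counting oracle, ties counted one half."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestAUC:
    def test_perfect_and_random(self):
        assert auc([0.9, 0.1], [1, 0]) == 1.0
        assert auc([0.5, 0.5, 0.5, 0.5], [1, 0, 1, 0]) == 0.5

    def test_matches_pairwise_counting_on_random_sets(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = rng.integers(4, 30)
            scores = rng.choice(np.round(rng.uniform(size=8), 2), size=n)  # force ties
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            assert auc(scores, labels) == pytest.approx(brute_force_auc(scores, labels))

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(1)
        scores = rng.uniform(size=40)
        labels = rng.integers(0, 2, 40)
        labels[:2] = [0, 1]
        a = auc(scores, labels)
        assert auc(np.exp(3 * scores), labels) == pytest.approx(a)
        assert auc(np.log(scores + 1), labels) == pytest.approx(a)

    def test_single_class_rejected(self):
        with pytest.raises(SingleClassError):
            auc([0.2, 0.8], [1, 1])


class TestThresholds:
    def test_perfect_separation_fixed_half(self):
        scores = [0.9, 0.8, 0.2, 0.1]
        labels = [1, 1, 0, 0]
        t, sens, spec = threshold_metrics(scores, labels, "fixed_0.5")
        assert (t, sens, spec) == (0.5, 1.0, 1.0)

    def test_sens95_keeps_19_of_20_positives(self):
        rng = np.random.default_rng(2)
        scores = np.concatenate([rng.uniform(0.3, 1.0, 20), rng.uniform(0.0, 0.7, 20)])
        labels = np.array([1] * 20 + [0] * 20)
        t, sens, _ = threshold_metrics(scores, labels, "sens_0.95")
        assert (scores[labels == 1] >= t).sum() >= 19
        # exhaustive scan oracle: t is the largest observed score with sens >= 0.95
        feasible = [c for c in np.unique(scores) if np.mean(scores[labels == 1] >= c) >= 0.95]
        assert t == max(feasible)

    def test_sens_eq_spec_minimises_gap(self):
        rng = np.random.default_rng(3)
        scores = rng.uniform(size=50)
        labels = rng.integers(0, 2, 50)
        labels[:2] = [0, 1]
        t, sens, spec = threshold_metrics(scores, labels, "sens_eq_spec")
        gap = abs(sens - spec)
        for c in np.unique(scores):  # exhaustive scan oracle
            s = np.mean(scores[labels == 1] >= c)
            p = np.mean(scores[labels == 0] < c)
            assert gap <= abs(s - p) + 1e-12

    def test_unknown_rule_rejected(self):
        with pytest.raises(ValueError):
            threshold_metrics([0.1, 0.9], [0, 1], "youden")


def brute_force_logistic(z, y):
    """Nested grid-search ML oracle for a one-covariate logistic model."""
    from scipy.special import expit

    def nll(b0, b1):
        eta = b0 + b1 * z
        return -(y * eta - np.logaddexp(0, eta)).sum()

    center, width = np.zeros(2), 4.0
    for _ in range(12):
        g0 = np.linspace(center[0] - width, center[0] + width, 21)
        g1 = np.linspace(center[1] - width, center[1] + width, 21)
        vals = [[nll(a, b) for b in g1] for a in g0]
        i, j = np.unravel_index(np.argmin(vals), (21, 21))
        center = np.array([g0[i], g1[j]])
        width *= 0.2
    return center


class TestFitSDM:
    def test_null_data_gives_null_coefficients(self):
        rng = np.random.default_rng(4)
        n = 600
        df = pd.DataFrame(
            {
                "x1": rng.normal(size=n),
                "x2": rng.normal(size=n),
                "year": rng.choice([2014, 2015, 2016], n),
                "label": rng.integers(0, 2, n),
            }
        )
        m = fit_sdm(df, {"x1": "linear", "x2": "linear"}, compute_se=True)
        for v in ("x1", "x2"):
            assert abs(m.coef[v]) <= 2 * m.se[v]

    def test_single_covariate_matches_grid_search_oracle(self):
        rng = np.random.default_rng(5)
        n = 300
        x = rng.normal(size=n)
        y = (rng.uniform(size=n) < 1 / (1 + np.exp(-(0.4 + 1.1 * x)))).astype(int)
        df = pd.DataFrame({"x": x, "year": 2014, "label": y})  # single year -> plain logistic
        m = fit_sdm(df, {"x": "linear"})
        assert m.fallback
        z = (x - x.mean()) / x.std()
        b0, b1 = brute_force_logistic(z, y)
        assert m.coef["Intercept"] == pytest.approx(b0, abs=1e-3)
        assert m.coef["x"] == pytest.approx(b1, abs=1e-3)

    def test_agrees_with_lme4_adaptive_quadrature(self):
        """Independent oracle: the same dataset fitted in R with
        lme4::glmer(..., family=binomial, nAGQ=25) gives fixed effects
        (-0.0501, 1.1034, -0.5459), variance 0.3225 and AIC 807.6614
        (on covariates standardised before the fit)."""
        df = simulate_mixed_logistic(
            120, {"x1": 1.0, "x2": -0.6}, intercept=0.3, sigma=0.8,
            years=(2011, 2012, 2013, 2014, 2015, 2016), seed=42,
        )
        m = fit_sdm(df, {"x1": "linear", "x2": "linear"})
        assert not m.fallback
        assert m.coef["Intercept"] == pytest.approx(-0.0501, abs=0.01)
        assert m.coef["x1"] == pytest.approx(1.1034, abs=0.01)
        assert m.coef["x2"] == pytest.approx(-0.5459, abs=0.01)
        assert m.sigma2 == pytest.approx(0.3225, abs=0.01)
        assert m.aic == pytest.approx(807.6614, abs=0.05)

    def test_parameter_recovery_within_two_se(self):
        """Estimates fall within 2 SE of truth in >= 90% of 50 seeds (n=2000)."""
        betas = {"x1": 1.0, "x2": -0.6}
        hits = 0
        for seed in range(50):
            df = simulate_mixed_logistic(500, betas, intercept=0.2, sigma=0.6, seed=seed)
            m = fit_sdm(df, {v: "linear" for v in betas}, compute_se=True)
            # truth on the standardised scale: beta * sd(x)
            ok = all(
                abs(m.coef[v] - b * df[v].std()) <= 2 * m.se[v] for v, b in betas.items()
            )
            hits += ok
        assert hits >= 45

    def test_single_year_falls_back_to_plain_logistic(self):
        df = simulate_mixed_logistic(200, {"x1": 1.0}, 0.0, 0.5, years=(2014,), seed=1)
        m = fit_sdm(df, {"x1": "linear"})
        assert m.fallback and m.sigma2 == 0.0
        assert m.n_params == 2  # no variance parameter counted

    def test_single_class_rejected(self):
        df = pd.DataFrame({"x1": [0.1, 0.2], "year": 2014, "label": [1, 1]})
        with pytest.raises(SingleClassError):
            fit_sdm(df, {"x1": "linear"})

    def test_raw_coefficients_reproduce_predictions(self):
        df = simulate_mixed_logistic(150, {"x1": 0.8, "x2": -0.5}, 0.3, 0.5, seed=3)
        m = fit_sdm(df, {"x1": "quadratic", "x2": "linear"})
        raw = m.raw_coefficients
        eta_raw = (
            raw["Intercept"]
            + raw["x1"] * df["x1"]
            + raw["x1^2"] * df["x1"] ** 2
            + raw["x2"] * df["x2"]
        )
        assert np.allclose(eta_raw, m.linear_predictor({v: df[v].to_numpy() for v in ("x1", "x2")}))


def _quadratic_logistic_data(seed, n=400, noise_var=True):
    """One informative quadratic covariate, optionally plus a pure-noise one."""
    rng = np.random.default_rng(seed)
    x1 = rng.normal(size=n)
    eta = 1.0 + 1.5 * x1 - 1.2 * x1**2
    df = pd.DataFrame(
        {
            "x1": x1,
            "year": 2014,
            "label": (rng.uniform(size=n) < 1 / (1 + np.exp(-eta))).astype(int),
        }
    )
    if noise_var:
        df["x2"] = rng.normal(size=n)
    return df


class TestStepwise:
    def test_noise_covariate_usually_removed(self):
        removed = sum(
            "x2"
            not in stepwise_aic(
                _quadratic_logistic_data(seed), {"x1": "quadratic", "x2": "linear"}
            ).terms
            for seed in range(20)
        )
        assert removed >= 16  # >= 80% of seeds

    def test_final_aic_never_above_full_model(self):
        df = _quadratic_logistic_data(0)
        full = fit_sdm(df)
        best = stepwise_aic(df)
        assert best.aic <= full.aic

    def test_matches_exhaustive_enumeration_on_two_variables(self):
        """Greedy backward selection finds the global AIC minimum over all
        hierarchical term subsets of a clearly structured 2-variable problem."""
        df = _quadratic_logistic_data(7)
        best = stepwise_aic(df)
        candidates = []
        for k1, k2 in itertools.product(("none", "linear", "quadratic"), repeat=2):
            terms = {}
            if k1 != "none":
                terms["x1"] = k1
            if k2 != "none":
                terms["x2"] = k2
            if not terms:
                continue  # intercept-only handled separately below
            candidates.append(fit_sdm(df, terms))
        global_best = min(candidates, key=lambda m: m.aic)
        assert best.terms == global_best.terms
        assert best.aic == pytest.approx(global_best.aic)

    def test_marginality_quadratic_never_without_linear(self):
        for seed in range(5):
            best = stepwise_aic(_quadratic_logistic_data(seed))
            assert set(best.terms.values()) <= {"linear", "quadratic"}


class TestCrossValidation:
    def test_report_shape_and_ranges(self):
        df = _quadratic_logistic_data(1)
        rep = cross_validate(df, terms={"x1": "quadratic"}, k=5, seed=0)
        assert sorted(rep.records["fold"].unique()) == [0, 1, 2, 3, 4]
        assert set(rep.records["rule"]) == {"fixed_0.5", "sens_eq_spec", "sens_0.95"}
        assert rep.records[["auc", "sens", "spec"]].stack().between(0, 1).all()
        # AUC is threshold-free: identical across rules within a fold
        per_fold = rep.records.groupby("fold")["auc"].nunique()
        assert (per_fold == 1).all()

    def test_shuffled_labels_give_chance_auc(self):
        """Mean validation AUC is 0.5 +/- 0.1 over 20 label permutations."""
        rng = np.random.default_rng(8)
        df = _quadratic_logistic_data(2, n=200)
        aucs = []
        for seed in range(20):
            shuffled = df.copy()
            shuffled["label"] = rng.permutation(df["label"].to_numpy())
            rep = cross_validate(shuffled, terms={"x1": "quadratic", "x2": "linear"},
                                 k=5, seed=seed)
            aucs.append(rep.mean_auc)
        assert abs(np.mean(aucs) - 0.5) <= 0.1

    def test_separable_data_gives_high_auc(self):
        rng = np.random.default_rng(9)
        n = 200
        x = np.concatenate([rng.normal(-2, 0.5, n // 2), rng.normal(2, 0.5, n // 2)])
        df = pd.DataFrame({"x1": x, "year": 2014,
                           "label": np.r_[np.zeros(n // 2), np.ones(n // 2)].astype(int)})
        rep = cross_validate(df, terms={"x1": "linear"}, k=5, seed=0)
        assert rep.mean_auc > 0.9

    def test_too_few_class_members_rejected(self):
        df = pd.DataFrame({"x1": np.arange(8.0), "year": 2014,
                           "label": [1, 1, 1, 0, 0, 0, 0, 0]})
        with pytest.raises(ValueError, match="at least"):
            cross_validate(df, terms={"x1": "linear"}, k=5, seed=0)


class TestDesign:
    def test_reduced_design_cardinality_and_frequencies(self, small_presences, small_stack):
        from seasonsdm.pabs import SamplerConfig

        res = run_design(
            small_presences,
            small_stack,
            ["MINTEMP", "NDVI", "RFD"],
            sampler_config=SamplerConfig(seed=4, n_sets=1),
            seed=4,
        )
        assert res.n_models == 2 * 1 * 8  # methods x sets x season bins
        assert res.variable_frequency["frequency"].between(0, 1).all()
        for (method, subset), common in res.common_variables.items():
            for v in common:
                row = res.variable_frequency.query(
                    "method == @method and subset == @subset and variable == @v"
                )
                assert int(row["frequency"].iloc[0]) == 1
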