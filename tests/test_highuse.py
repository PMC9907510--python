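"""Top-quintile labelling and the IRLS logistic regression."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from pedabx import highuse, synth
from pedabx.codemap import BODY_SYSTEMS
from pedabx.config import GeneratorConfig, default_config


class TestLabelTopQuantile:
    def test_decile_counts(self):
        labels = highuse.label_top_quantile(np.arange(10), q=0.2)
        assert set(np.arange(10)[labels == 1]) == {8, 9}

    def test_all_equal_labels_none(self):
        assert highuse.label_top_quantile(np.full(7, 4.0), q=0.2).sum() == 0

    def test_tie_at_boundary(self):
        labels = highuse.label_top_quantile(np.array([1, 2, 2, 3]), q=0.25)
        assert labels.tolist() == [0, 0, 0, 1]

    def test_labelled_fraction_never_exceeds_q(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            counts = rng.poisson(3, size=rng.integers(5, 200))
            labels = highuse.label_top_quantile(counts, q=0.2)
            assert labels.mean() <= 0.2 + 1e-12


def _nll(beta, X, y):
    eta = X @ beta
    return -(y @ eta - np.logaddexp(0, eta).sum())


class TestIRLS:
    def test_intercept_only_is_logit_of_prevalence(self):
        y = np.r_[np.ones(200), np.zeros(800)]
        fit = highuse.fit_logistic_irls(np.ones((1000, 1)), y)
        assert fit.converged
        assert fit.coef[0] == pytest.approx(np.log(0.25), abs=1e-8)

    def test_two_by_two_closed_form(self):
        # exposed: 30/100 labelled; unexposed: 10/100 -> log OR = ln(30*90/(70*10))
        x = np.r_[np.ones(100), np.zeros(100)]
        y = np.r_[np.ones(30), np.zeros(70), np.ones(10), np.zeros(90)]
        X = np.column_stack([np.ones(200), x])
        fit = highuse.fit_logistic_irls(X, y)
        assert fit.coef[1] == pytest.approx(np.log(27 / 7), abs=1e-6)
        assert fit.coef[0] == pytest.approx(np.log(10 / 90), abs=1e-6)
        # gradient at the reported optimum is numerically zero
        mu = 1 / (1 + np.exp(-(X @ fit.coef)))
        assert np.linalg.norm(X.T @ (y - mu)) < 1e-6

    def test_matches_direct_likelihood_optimisation(self):
        rng = np.random.default_rng(11)
        x = rng.integers(0, 2, 300).astype(float)
        eta = -1.0 + 1.5 * x
        y = (rng.random(300) < 1 / (1 + np.exp(-eta))).astype(float)
        X = np.column_stack([np.ones(300), x])
        fit = highuse.fit_logistic_irls(X, y)
        res = optimize.minimize(
            _nll, np.zeros(2), args=(X, y), method="BFGS",
            options={"gtol": 1e-10},
        )
        np.testing.assert_allclose(fit.coef, res.x, atol=1e-6)
        assert fit.loglik == pytest.approx(-res.fun, abs=1e-8)

    def test_matches_statsmodels(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(13)
        X = np.column_stack([np.ones(500), rng.integers(0, 2, (500, 3))]).astype(float)
        eta = X @ np.array([-1.2, 0.8, 0.0, -0.5])
        y = (rng.random(500) < 1 / (1 + np.exp(-eta))).astype(float)
        fit = highuse.fit_logistic_irls(X, y)
        ref = sm.Logit(y, X).fit(disp=0)
        np.testing.assert_allclose(fit.coef, ref.params, atol=1e-6)
        np.testing.assert_allclose(fit.se, ref.bse, rtol=1e-4)

    def test_separation_is_detected_and_named(self):
        y = np.r_[np.ones(50), np.zeros(50)]
        X = np.column_stack([np.ones(100), y])  # covariate == label
        with pytest.raises(highuse.SeparationError, match="x1"):
            highuse.fit_logistic_irls(X, y)

    def test_rank_deficient_design_errors(self):
        X = np.column_stack([np.ones(50), np.ones(50)])
        y = np.r_[np.ones(10), np.zeros(40)]
        with pytest.raises(ValueError, match="rank"):
            highuse.fit_logistic_irls(X, y)

    def test_covariance_symmetric_psd(self):
        rng = np.random.default_rng(17)
        X = np.column_stack([np.ones(400), rng.integers(0, 2, (400, 2))]).astype(float)
        y = (rng.random(400) < 0.3).astype(float)
        fit = highuse.fit_logistic_irls(X, y)
        np.testing.assert_allclose(fit.cov, fit.cov.T, atol=1e-14)
        assert (np.linalg.eigvalsh(fit.cov) > 0).all()


class TestOddsRatios:
    def _fit(self):
        rng = np.random.default_rng(19)
        X = np.column_stack([np.ones(400), rng.integers(0, 2, 400).astype(float)])
        y = (rng.random(400) < 0.3).astype(float)
        return highuse.fit_logistic_irls(X, y, names=["intercept", "flag"])

    def test_null_beta_gives_unit_or(self):
        fit = self._fit()
        fit.coef = np.array([0.0, 0.0])
        table = highuse.odds_ratios(fit)
        assert table["odds_ratio"].tolist() == [1.0, 1.0]
        assert (table["p"] > 0.99).all()

    def test_two_by_two_or(self):
        x = np.r_[np.ones(100), np.zeros(100)]
        y = np.r_[np.ones(30), np.zeros(70), np.ones(10), np.zeros(90)]
        fit = highuse.fit_logistic_irls(np.column_stack([np.ones(200), x]), y)
        table = highuse.odds_ratios(fit)
        assert table.loc[1, "odds_ratio"] == pytest.approx(27 / 7, rel=1e-6)

    def test_ci_monotone_in_se(self):
        fit = self._fit()
        narrow = highuse.odds_ratios(fit)
        fit.se = fit.se * 2
        wide = highuse.odds_ratios(fit)
        assert (wide["ci_hi"] > narrow["ci_hi"]).all()
        assert (wide["ci_lo"] < narrow["ci_lo"]).all()

    def test_unconverged_fit_rejected(self):
        fit = self._fit()
        fit.converged = False
        with pytest.raises(ValueError, match="converge"):
            highuse.odds_ratios(fit)


# -- recovery experiments ----------------------------------------------------

_RECOVERY_SYSTEMS = ("pulmonary_respiratory", "otologic", "gastrointestinal",
                     "dermatological", "ophthalmological")
_RECOVERY_MULTS = (2.0, 1.5, 1.0, 3.0, 1.0)
_RECOVERY_PREVS = (0.20, 0.10, 0.15, 0.05, 0.10)


def _recovery_cfg(n, seed):
    d = default_config(n_children=n, seed=seed).to_dict()
    d["condition_prevalences"] = {
        s: dict(zip(_RECOVERY_SYSTEMS, _RECOVERY_PREVS)).get(s, 0.0) for s in BODY_SYSTEMS
    }
    d["condition_multipliers"] = {
        s: dict(zip(_RECOVERY_SYSTEMS, _RECOVERY_MULTS)).get(s, 1.0) for s in BODY_SYSTEMS
    }
    return GeneratorConfig.from_dict(d)


def _fit_cohort(cfg, seed):
    children = synth.sample_children(cfg, seed)
    events = synth.sample_course_events(children, cfg, seed)
    counts = (
        events.groupby("child_id").size().reindex(children["child_id"], fill_value=0)
    )
    labels = highuse.label_top_quantile(counts.to_numpy(), q=0.2)
    flags = children[[f"cond_{s}" for s in _RECOVERY_SYSTEMS]].to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(children)), flags])
    return highuse.fit_logistic_irls(X, labels, names=["intercept", *_RECOVERY_SYSTEMS])


def test_parameter_recovery_against_large_cohort_oracle():
    """Coefficients from small cohorts cover the large-cohort oracle values in
    >= 90% of replicates at nominal 95% Wald level."""
    oracle = _fit_cohort(_recovery_cfg(1_000_000, 100), 100)
    hits = total = 0
    for rep in range(100):
        fit = _fit_cohort(_recovery_cfg(4_000, 101), 200 + rep)
        lo = fit.coef - 1.959964 * fit.se
        hi = fit.coef + 1.959964 * fit.se
        hits += int(((lo <= oracle.coef) & (oracle.coef <= hi)).sum())
        total += len(fit.coef)
    assert hits / total >= 0.90


def test_null_model_false_positive_rate():
    """With all multipliers 1 the per-covariate Wald test rejects at ~5%."""
    d = default_config(n_children=1_500).to_dict()
    d["condition_prevalences"] = {s: 0.10 for s in BODY_SYSTEMS}
    d["condition_multipliers"] = {s: 1.0 for s in BODY_SYSTEMS}
    base = GeneratorConfig.from_dict(d)
    rejections = total = 0
    for rep in range(200):
        children = synth.sample_children(base, 1000 + rep)
        events = synth.sample_course_events(children, base, 1000 + rep)
        counts = (
            events.groupby("child_id").size().reindex(children["child_id"], fill_value=0)
        )
        flags = children[[f"cond_{s}" for s in BODY_SYSTEMS]].to_numpy(dtype=float)
        X = np.column_stack([np.ones(len(children)), flags])
        fit = highuse.fit_logistic_irls(
            X, highuse.label_top_quantile(counts.to_numpy(), q=0.2)
        )
        p = highuse.odds_ratios(fit)["p"].to_numpy()[1:]
        rejections += int((p < 0.05).sum())
        total += len(p)
    rate = rejections / total
    se = np.sqrt(0.05 * 0.95 / total)
    assert rate == pytest.approx(0.05, abs=4 * se)


def test_highuse_regression_end_to_end_recovers_strong_effect(codes):
    cfg = _recovery_cfg(8_000, 55)
    children = synth.sample_children(cfg, 55)
    events = synth.sample_course_events(children, cfg, 55)
    counts = events.groupby("child_id").size().reindex(children["child_id"], fill_value=0)
    counts.index = pd.Index(children["child_id"], name="child_id")
    flags = children.set_index("child_id")[[f"cond_{s}" for s in BODY_SYSTEMS]]
    flags.columns = BODY_SYSTEMS
    fit, table = highuse.highuse_regression(counts, flags)
    assert fit.converged
    row = table.set_index("term").loc["dermatological"]  # the x3 multiplier
    assert row["odds_ratio"] > 2.0 and row["p"] < 1e-6
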