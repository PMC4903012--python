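"""Screening, IRLS logistic regression, stepwise elimination, calibration."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.special import expit

import edchest as e
from edchest.derivation import (
    backward_eliminate,
    build_design,
    default_candidates,
    hosmer_lemeshow_from_probs,
)
from edchest.scoring import PUBLISHED_COEFFICIENTS
from oracles import exhaustive_backward_sets, hosmer_lemeshow_oracle


# ---------------------------------------------------------------------------
# normality


def test_ks_normality_null_and_alternative(rng):
    assert e.ks_normality(rng.normal(size=5000)) > 0.05
    assert e.ks_normality(rng.exponential(size=5000)) <= 0.0015


def test_ks_normality_degenerate():
    with pytest.raises(ValueError, match="constant"):
        e.ks_normality(np.full(100, 2.0))
    with pytest.raises(ValueError, match="at least 8"):
        e.ks_normality([1.0, 2.0, 3.0])


# ---------------------------------------------------------------------------
# univariate screening


def test_screen_published_st_elevation_counts():
    """2x2 association rebuilt from the published group counts."""
    y = np.repeat([1, 0], [254, 509])
    x = np.concatenate([np.repeat([1, 0], [52, 254 - 52]),
                        np.repeat([1, 0], [13, 509 - 13])])
    df = pd.DataFrame({"ecg_ste": x, "mace30": y})
    res = e.univariate_screen(df, candidates=[e.Candidate("ecg_ste", "binary")])
    row = res.iloc[0]
    assert row.test == "chi-square"
    assert row.p_value < 0.001
    assert row.selected


def test_screen_constant_variable_not_selected(sim_cohort):
    df = sim_cohort.assign(flat=1.0)
    res = e.univariate_screen(
        df, candidates=[e.Candidate("flat", "continuous")])
    assert res.iloc[0].p_value == 1.0
    assert not res.iloc[0].selected


def test_screen_fisher_fallback_for_sparse_cells():
    rng = np.random.default_rng(5)
    y = rng.integers(0, 2, 200)
    x = np.zeros(200, dtype=int)
    x[:3] = 1  # expected cell counts < 5
    res = e.univariate_screen(pd.DataFrame({"v": x, "mace30": y}),
                              candidates=[e.Candidate("v", "binary")])
    assert res.iloc[0].test == "fisher"


def test_screen_full_candidate_set(sim_cohort):
    res = e.univariate_screen(sim_cohort)
    assert len(res) == 19
    # the strong flags must be picked up at study size
    sel = dict(zip(res.variable, res.selected))
    assert sel["ecg_ste"] and sel["ecg_std"]


def test_screen_requires_both_classes(sim_cohort):
    df = sim_cohort.assign(mace30=0)
    with pytest.raises(ValueError, match="both classes"):
        e.univariate_screen(df)


# ---------------------------------------------------------------------------
# logistic fit


def _true_design(n, seed):
    cohort = e.simulate_cohort(e.CohortSimSpec(n=n, seed=seed))
    cands = [c for c in default_candidates() if c.indicators]
    X, blocks, _, _ = build_design(cohort, cands)
    return cohort, X, blocks


def test_fit_logistic_matches_statsmodels():
    cohort, X, _ = _true_design(3000, seed=2)
    y = cohort.mace30.to_numpy()
    ours = e.fit_logistic(X, y)
    ref = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
    np.testing.assert_allclose(ours.params["intercept"], ref.params["const"],
                               atol=1e-6)
    for t in ours.terms:
        assert ours.params[t] == pytest.approx(ref.params[t], abs=1e-6)
        assert ours.bse[t] == pytest.approx(ref.bse[t], rel=1e-4)
    assert ours.llf == pytest.approx(ref.llf, abs=1e-6)
    assert ours.converged


def test_fit_logistic_null_covariate(rng):
    x = rng.normal(size=2000)
    y = rng.integers(0, 2, 2000)
    fit = e.fit_logistic(x[:, None], y)
    assert abs(fit.params.iloc[1]) < 3 * fit.bse.iloc[1]


def test_fit_logistic_detects_separation():
    x = np.linspace(-2, 2, 40)
    y = (x > 0).astype(int)
    with pytest.raises(e.SeparationError):
        e.fit_logistic(x[:, None], y)


def test_fit_logistic_recovers_true_betas():
    cohort, X, _ = _true_design(20000, seed=6)
    fit = e.fit_logistic(X, cohort.mace30.to_numpy())
    for name, beta in PUBLISHED_COEFFICIENTS.items():
        assert abs(fit.params[name] - beta) < 3 * fit.bse[name], name


def test_fit_logistic_rank_deficient():
    x = np.ones((100, 2))
    y = np.tile([0, 1], 50)
    with pytest.raises(ValueError, match="rank"):
        e.fit_logistic(x, y)


# ---------------------------------------------------------------------------
# backward stepwise


def _sim_xy(n, betas, seed, intercept=-0.5):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame({f"x{i}": rng.integers(0, 2, n).astype(float)
                      for i in range(len(betas))})
    p = expit(intercept + X.to_numpy() @ np.asarray(betas))
    return X, (rng.random(n) < p).astype(int)


def test_stepwise_keeps_signal_drops_noise():
    X, y = _sim_xy(2000, [1.2, 0.0], seed=3)
    fit, trace = backward_eliminate(X, y)
    assert trace.final_terms == ["x0"]
    assert [ev.variable for ev in trace.removals] == ["x1"]
    assert trace.removals[0].p_value >= 0.10


@pytest.mark.parametrize("k,min_empty", [(1, 0.85), (3, 0.60)])
def test_stepwise_all_noise_usually_empties(k, min_empty):
    """Pure-noise candidates are eliminated down to the intercept.

    The last surviving candidate is the minimum of k null p-values, so it
    escapes removal with probability about 1 - 0.9^k; the expected empty
    fraction is ~0.90 for one candidate and ~0.71 for three.
    """
    empty = 0
    for seed in range(200):
        X, y = _sim_xy(400, [0.0] * k, seed=1000 + seed)
        _, trace = backward_eliminate(X, y)
        empty += not trace.final_terms
    assert empty >= min_empty * 200


def test_stepwise_matches_exhaustive_search():
    for seed in range(5):
        X, y = _sim_xy(300, [0.9, 0.25, 0.0], seed=seed)
        _, trace = backward_eliminate(X, y)

        def block_p(state, X=X, y=y):
            cols = sorted(state)
            full = e.fit_logistic(X[cols], y)
            out = {}
            for v in cols:
                red = e.fit_logistic(X[[c for c in cols if c != v]], y)
                from scipy.stats import chi2
                out[v] = float(chi2.sf(2 * (full.llf - red.llf), 1))
            return out

        finals = exhaustive_backward_sets(block_p, list(X.columns))
        assert finals == {frozenset(trace.final_terms)}


def test_stepwise_lr_statistics_nonnegative():
    X, y = _sim_xy(1000, [0.8, 0.1, 0.0, 0.0], seed=9)
    _, trace = backward_eliminate(X, y)
    assert all(ev.lr_stat >= 0 for ev in trace.removals)


def test_stepwise_blocks_removed_jointly():
    cohort, X, blocks = _true_design(4000, seed=8)
    # add a two-indicator pure-noise block
    rng = np.random.default_rng(1)
    cat = rng.integers(0, 3, len(X))
    X = X.assign(noise_a=(cat == 1).astype(float),
                 noise_b=(cat == 2).astype(float))
    blocks = dict(blocks, noise=["noise_a", "noise_b"])
    _, trace = backward_eliminate(X, cohort.mace30.to_numpy(), blocks)
    removed = {ev.variable for ev in trace.removals}
    assert "noise" in removed
    assert not {"noise_a", "noise_b"} & set(trace.final_terms)
    ev = next(ev for ev in trace.removals if ev.variable == "noise")
    assert ev.df == 2


# ---------------------------------------------------------------------------
# Hosmer-Lemeshow


def test_hl_matches_bruteforce_oracle(rng):
    probs = rng.uniform(0.05, 0.95, 100)  # distinct values, clean deciles
    y = (rng.random(100) < probs).astype(int)
    res = hosmer_lemeshow_from_probs(probs, y, groups=10)
    assert res.statistic == pytest.approx(
        hosmer_lemeshow_oracle(probs, y, 10), rel=1e-9)
    assert res.df == 8
    assert res.table.expected.sum() == pytest.approx(probs.sum(), abs=1e-6)


def test_hl_well_specified_rejection_rate():
    rejections = 0
    reps = 500
    for seed in range(reps):
        rng = np.random.default_rng(20_000 + seed)
        x = rng.normal(size=300)
        y = (rng.random(300) < expit(-0.5 + 0.8 * x)).astype(int)
        fit = e.fit_logistic(x[:, None], y)
        res = hosmer_lemeshow_from_probs(fit.predict(x[:, None]), y)
        rejections += res.p_value < 0.05
    assert rejections / reps == pytest.approx(0.05, abs=0.02)


def test_hl_detects_misspecification(rng):
    x = rng.normal(size=5000)
    y = (rng.random(5000) < expit(-1.0 + 1.5 * x * x)).astype(int)
    fit = e.fit_logistic(x[:, None], y)  # linear fit of a quadratic truth
    res = hosmer_lemeshow_from_probs(fit.predict(x[:, None]), y)
    assert res.p_value < 0.01


def test_hl_needs_enough_observations():
    with pytest.raises(ValueError):
        hosmer_lemeshow_from_probs(np.linspace(0.1, 0.9, 50),
                                   np.zeros(50), groups=10)


# ---------------------------------------------------------------------------
# Model / Results facade


def test_risk_score_model_facade(sim_cohort):
    res = e.RiskScoreModel.from_dataframe(sim_cohort).fit()
    assert set(res.fit.terms) <= set(res.design.columns)
    txt = res.summary()
    assert "backward elimination" in txt and "Hosmer-Lemeshow" in txt
    hl = res.hosmer_lemeshow()
    assert 0 <= hl.p_value <= 1
    scores = res.score_cohort()
    assert scores.min() >= 0
    assert scores.max() <= res.score_table.max_score


def test_risk_score_model_validates_input(sim_cohort):
    with pytest.raises(ValueError, match="outcome"):
        e.RiskScoreModel(sim_cohort.drop(columns=["mace30"]))
    with pytest.raises(ValueError, match="too small"):
        e.RiskScoreModel(sim_cohort.head(30))


def test_stepwise_deterministic(sim_cohort):
    r1 = e.RiskScoreModel.from_dataframe(sim_cohort).fit()
    r2 = e.RiskScoreModel.from_dataframe(sim_cohort.copy()).fit()
    assert [ev.variable for ev in r1.trace.removals] == \
        [ev.variable for ev in r2.trace.removals]
    pd.testing.assert_series_equal(r1.fit.params, r2.fit.params)
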