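"""Score derivation: screening, stepwise logistic regression, calibration.

The derivation pipeline reproduces how an additive clinical score is built
from a cohort with a binary 30-day outcome:

1. univariate screening of every candidate variable (Welch t when both
   outcome groups pass a Lilliefors/Kolmogorov-Smirnov normality check,
   Mann-Whitney otherwise; chi-square or Fisher for binaries) at p < 0.05;
2. categorization of the selected variables into risk indicators;
3. likelihood-ratio backward stepwise logistic regression, removing the
   variable block with the largest LR p-value until every remaining block
   has p below the removal threshold (default 0.10);
4. a Hosmer-Lemeshow decile calibration check;
5. conversion of the final coefficients into integer points
   (:func:`edchest.scoring.build_score_table`).

The user-facing entry point is :class:`RiskScoreModel`, whose ``fit`` returns
a :class:`RiskScoreResults` carrying the univariate table, the stepwise
trace, the final logistic fit, and the derived score table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit
from statsmodels.stats.diagnostic import lilliefors

from .scoring import (
    CategoryRule,
    ScoreModel,
    SEDRSM_RULES,
    SEDRSM_VARIABLES,
    build_score_table,
)

__all__ = [
    "Candidate",
    "LogisticFit",
    "StepwiseTrace",
    "HLResult",
    "SeparationError",
    "ks_normality",
    "univariate_screen",
    "fit_logistic",
    "backward_eliminate",
    "hosmer_lemeshow",
    "hosmer_lemeshow_from_probs",
    "default_candidates",
    "build_design",
    "RiskScoreModel",
    "RiskScoreResults",
]


class SeparationError(RuntimeError):
    """Perfect (quasi-)separation: a coefficient is unbounded."""


# ---------------------------------------------------------------------------
# Candidates and design construction


@dataclass(frozen=True)
class Candidate:
    """A screened candidate predictor.

    ``kind`` is ``"binary"`` (0/1 flag or the ``sex`` column) or
    ``"continuous"``. ``indicators`` names the prebuilt categorization
    (keys of :data:`edchest.scoring.SEDRSM_RULES`); continuous candidates
    without one are median-split when they enter the model.
    """

    name: str
    kind: str
    indicators: tuple[str, ...] = ()


def default_candidates() -> list[Candidate]:
    """The 19-candidate screening set for the standard cohort layout."""
    return [
        Candidate("sex", "binary", ("male",)),
        Candidate("age_years", "continuous", ("age_ge60",)),
        Candidate("hr_bpm", "continuous", ("hr_le55", "hr_56_114")),
        Candidate("ecg_ste", "binary", ("st_elevation",)),
        Candidate("ecg_std", "binary", ("st_depression",)),
        Candidate("ecg_qwave", "binary", ("q_wave",)),
        Candidate("ecg_qtprolong", "binary", ("qt_prolongation",)),
        Candidate("avrr_s", "continuous", ("avrr_lt_0.77",)),
        Candidate("tinn_s", "continuous", ("tinn_lt_0.11", "tinn_gt_0.17")),
        Candidate("hf_power", "continuous", ("hf_lt_0.07",)),
        # candidates with no prespecified categorization
        Candidate("dbp_mmhg", "continuous"),
        Candidate("ecg_tinv", "binary"),
        Candidate("ecg_ivcd", "binary"),
        Candidate("sdrr_s", "continuous"),
        Candidate("avg_hr_bpm", "continuous"),
        Candidate("rmssd_s", "continuous"),
        Candidate("nn50_count", "continuous"),
        Candidate("pnn50_pct", "continuous"),
        Candidate("vlf_power", "continuous"),
    ]


def _binary_indicator(col: pd.Series) -> np.ndarray:
    if col.dtype == object:
        return (col == "male").to_numpy(dtype=float)
    return col.to_numpy(dtype=float)


def build_design(
    data: pd.DataFrame, candidates: list[Candidate]
) -> tuple[pd.DataFrame, dict[str, list[str]], dict[str, CategoryRule],
           dict[str, str]]:
    """Indicator design matrix for the given candidates.

    Returns ``(X, blocks, rules, variables)``: the 0/1 design, the mapping
    of variable name to its indicator columns (multi-category variables are
    tested and removed as blocks), and the rule/variable metadata needed to
    turn fitted coefficients back into a score table. Continuous candidates
    without a prespecified categorization are split at their cohort median.
    """
    cols: dict[str, np.ndarray] = {}
    blocks: dict[str, list[str]] = {}
    rules: dict[str, CategoryRule] = {}
    varmap: dict[str, str] = {}
    for cand in candidates:
        if cand.indicators:
            names = list(cand.indicators)
            var = SEDRSM_VARIABLES[names[0]]
            for nm in names:
                rule = SEDRSM_RULES[nm]
                cols[nm] = rule.applies_vector(data[rule.feature]).astype(float)
                rules[nm] = rule
                varmap[nm] = var
            blocks[var] = names
        elif cand.kind == "binary":
            nm = cand.name
            cols[nm] = _binary_indicator(data[nm])
            rules[nm] = CategoryRule(nm, "flag")
            varmap[nm] = nm
            blocks[nm] = [nm]
        else:
            med = float(data[cand.name].median())
            nm = f"{cand.name}_gt_{med:.4g}"
            rule = CategoryRule(cand.name, "gt", med)
            cols[nm] = rule.applies_vector(data[cand.name]).astype(float)
            rules[nm] = rule
            varmap[nm] = cand.name
            blocks[cand.name] = [nm]
    X = pd.DataFrame(cols, index=data.index)
    return X, blocks, rules, varmap


# ---------------------------------------------------------------------------
# Univariate screening


def ks_normality(values) -> float:
    """Kolmogorov-Smirnov normality p-value with estimated mean/SD
    (Lilliefors correction)."""
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 8:
        raise ValueError("need at least 8 observations for the normality test")
    if np.std(x) == 0:
        raise ValueError("degenerate (constant) sample")
    return float(lilliefors(x, dist="norm")[1])


@dataclass(frozen=True)
class UnivariateResult:
    variable: str
    test: str
    p_value: float
    selected: bool


def _screen_one(col: pd.Series, y: np.ndarray, kind: str,
                alpha: float, normality_alpha: float) -> tuple[str, float]:
    if kind == "binary":
        x = _binary_indicator(col)
        tab = np.array([
            [np.sum((x == 0) & (y == 0)), np.sum((x == 0) & (y == 1))],
            [np.sum((x == 1) & (y == 0)), np.sum((x == 1) & (y == 1))],
        ])
        if tab.sum(axis=0).min() == 0 or tab.sum(axis=1).min() == 0:
            return "chi-square", 1.0  # variable or outcome degenerate
        expected = stats.contingency.expected_freq(tab)
        if (expected < 5).any():
            return "fisher", float(stats.fisher_exact(tab)[1])
        return "chi-square", float(stats.chi2_contingency(tab)[1])
    x = col.to_numpy(dtype=float)
    g0, g1 = x[y == 0], x[y == 1]
    if np.std(g0) == 0 and np.std(g1) == 0:
        return "welch-t", 1.0
    try:
        normal = (ks_normality(g0) > normality_alpha
                  and ks_normality(g1) > normality_alpha)
    except ValueError:
        normal = False
    if normal:
        return "welch-t", float(stats.ttest_ind(g0, g1, equal_var=False)[1])
    return "mann-whitney", float(
        stats.mannwhitneyu(g0, g1, alternative="two-sided")[1])


def univariate_screen(
    data: pd.DataFrame,
    outcome: str = "mace30",
    candidates: list[Candidate] | None = None,
    alpha: float = 0.05,
    normality_alpha: float = 0.05,
) -> pd.DataFrame:
    """Screen candidates against the outcome; selected means p < ``alpha``.

    Continuous variables use Welch's t when both outcome groups pass the
    normality check, otherwise Mann-Whitney; binary variables use the
    chi-square test, or Fisher's exact test when any expected cell count is
    below 5.
    """
    candidates = candidates if candidates is not None else default_candidates()
    y = data[outcome].to_numpy(dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("outcome must have both classes")
    rows = []
    for cand in candidates:
        test, p = _screen_one(data[cand.name], y, cand.kind,
                              alpha, normality_alpha)
        rows.append(UnivariateResult(cand.name, test, p, bool(p < alpha)))
    return pd.DataFrame([r.__dict__ for r in rows])


# ---------------------------------------------------------------------------
# Logistic regression by IRLS


@dataclass
class LogisticFit:
    """Maximum-likelihood logistic fit (intercept named ``intercept``)."""

    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    llf: float
    converged: bool
    n_obs: int
    n_iter: int

    @property
    def terms(self) -> list[str]:
        return [t for t in self.params.index if t != "intercept"]

    @property
    def intercept(self) -> float:
        return float(self.params["intercept"])

    def predict(self, X) -> np.ndarray:
        Xm = np.asarray(X[self.terms] if isinstance(X, pd.DataFrame) else X,
                        dtype=float)
        return expit(self.intercept + Xm @ self.params[self.terms].to_numpy())

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        z = stats.norm.ppf(1 - alpha / 2)
        return pd.DataFrame(
            {"low": self.params - z * self.bse,
             "high": self.params + z * self.bse})


def _loglik(y: np.ndarray, p: np.ndarray) -> float:
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return float(np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))


def fit_logistic(X, y, *, tol: float = 1e-8, maxiter: int = 100,
                 start: np.ndarray | None = None,
                 max_abs_coef: float = 50.0) -> LogisticFit:
    """Logistic regression by iteratively reweighted least squares.

    An intercept is always included. Convergence is declared when the
    log-likelihood changes by less than ``tol``; a coefficient exceeding
    ``max_abs_coef`` in magnitude signals separation and raises
    :class:`SeparationError` rather than returning a silent divergence.
    """
    if isinstance(X, pd.DataFrame):
        names = ["intercept"] + list(X.columns)
        Xm = X.to_numpy(dtype=float)
    else:
        Xm = np.asarray(X, dtype=float)
        if Xm.ndim == 1:
            Xm = Xm[:, None]
        names = ["intercept"] + [f"x{i}" for i in range(Xm.shape[1])]
    y = np.asarray(y, dtype=float)
    n = y.size
    if len(np.unique(y)) < 2:
        raise ValueError("outcome must have both classes")
    A = np.column_stack([np.ones(n), Xm])
    k = A.shape[1]
    if np.linalg.matrix_rank(A) < k:
        raise ValueError("design matrix is rank deficient")
    beta = np.zeros(k) if start is None else np.asarray(start, dtype=float)
    ll_prev = -np.inf
    converged = False
    H = np.eye(k)
    for it in range(1, maxiter + 1):
        eta = A @ beta
        p = expit(eta)
        w = np.clip(p * (1 - p), 1e-10, None)
        grad = A.T @ (y - p)
        H = (A * w[:, None]).T @ A
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError as exc:
            raise SeparationError("singular information matrix") from exc
        beta = beta + step
        if np.max(np.abs(beta)) > max_abs_coef:
            raise SeparationError(
                "separation detected: coefficient diverging")
        ll = _loglik(y, expit(A @ beta))
        if abs(ll - ll_prev) < tol:
            converged = True
            ll_prev = ll
            break
        ll_prev = ll
    cov = np.linalg.inv(H)
    bse = np.sqrt(np.diag(cov))
    z = beta / bse
    pvals = 2 * stats.norm.sf(np.abs(z))
    return LogisticFit(
        params=pd.Series(beta, index=names),
        bse=pd.Series(bse, index=names),
        pvalues=pd.Series(pvals, index=names),
        llf=ll_prev, converged=converged, n_obs=n, n_iter=it,
    )


# ---------------------------------------------------------------------------
# Backward stepwise elimination


@dataclass(frozen=True)
class RemovalEvent:
    variable: str
    lr_stat: float
    df: int
    p_value: float


@dataclass
class StepwiseTrace:
    """Ordered removal events and the surviving variable blocks."""

    removals: list[RemovalEvent] = field(default_factory=list)
    final_terms: list[str] = field(default_factory=list)
    final_block_p: dict[str, float] = field(default_factory=dict)


def _lr_pvalue(X: pd.DataFrame, y, full: LogisticFit, cols: list[str]
               ) -> tuple[float, int, float]:
    keep = [c for c in X.columns if c not in cols]
    start = np.concatenate([
        [full.params["intercept"]],
        full.params[keep].to_numpy() if keep else np.empty(0),
    ])
    reduced = fit_logistic(X[keep], y, start=start) if keep else \
        fit_logistic(np.empty((len(X), 0)), y)
    lr = max(0.0, 2.0 * (full.llf - reduced.llf))
    df = len(cols)
    return lr, df, float(stats.chi2.sf(lr, df))


def backward_eliminate(
    X: pd.DataFrame, y, blocks: dict[str, list[str]] | None = None,
    p_remove: float = 0.10,
) -> tuple[LogisticFit, StepwiseTrace]:
    """Likelihood-ratio backward elimination of variable blocks.

    At each step every remaining variable (all its category indicators
    jointly) is tested by the LR test against the current model; the block
    with the largest p >= ``p_remove`` is dropped. Elimination stops when
    every remaining block has LR p < ``p_remove``. Deterministic given the
    column order; no randomness is involved.
    """
    y = np.asarray(y, dtype=float)
    if blocks is None:
        blocks = {c: [c] for c in X.columns}
    blocks = {v: list(cols) for v, cols in blocks.items()}
    trace = StepwiseTrace()
    while True:
        cols = [c for cols_ in blocks.values() for c in cols_]
        full = fit_logistic(X[cols], y)
        if not blocks:
            break
        pvals = {v: _lr_pvalue(X[cols], y, full, bc)
                 for v, bc in blocks.items()}
        worst = max(pvals, key=lambda v: pvals[v][2])
        lr, df, p = pvals[worst]
        if p < p_remove:
            trace.final_block_p = {v: pv[2] for v, pv in pvals.items()}
            break
        trace.removals.append(RemovalEvent(worst, lr, df, p))
        del blocks[worst]
        if not blocks:
            full = fit_logistic(np.empty((len(X), 0)), y)
            break
    trace.final_terms = [c for cols_ in blocks.values() for c in cols_]
    return full, trace


# ---------------------------------------------------------------------------
# Hosmer-Lemeshow calibration


@dataclass
class HLResult:
    statistic: float
    df: int
    p_value: float
    table: pd.DataFrame
    n_groups: int
    merged: bool


def hosmer_lemeshow_from_probs(probs, y, groups: int = 10) -> HLResult:
    """Hosmer-Lemeshow chi-square over risk deciles of predicted probability.

    Groups are deciles of predicted risk; tied predictions that empty a
    decile cause adjacent groups to merge (recorded in ``merged``).
    statistic = sum (O - E)^2 / (E (1 - E/n_g)), df = groups - 2.
    """
    probs = np.asarray(probs, dtype=float)
    y = np.asarray(y, dtype=float)
    if y.size < 10 * groups:
        raise ValueError(f"need at least {10 * groups} observations")
    labels = pd.qcut(probs, groups, labels=False, duplicates="drop")
    g = int(labels.max()) + 1
    rows = []
    stat = 0.0
    for j in range(g):
        m = labels == j
        n_g = int(m.sum())
        obs = float(y[m].sum())
        exp = float(probs[m].sum())
        denom = exp * (1 - exp / n_g)
        if denom > 0:
            stat += (obs - exp) ** 2 / denom
        rows.append({"group": j, "n": n_g, "observed": obs, "expected": exp,
                     "mean_risk": float(probs[m].mean())})
    df = max(1, g - 2)
    return HLResult(
        statistic=stat, df=df, p_value=float(stats.chi2.sf(stat, df)),
        table=pd.DataFrame(rows), n_groups=g, merged=g < groups,
    )


def hosmer_lemeshow(fit: LogisticFit, X, y, groups: int = 10) -> HLResult:
    return hosmer_lemeshow_from_probs(fit.predict(X), y, groups)


# ---------------------------------------------------------------------------
# Model / Results facade


class RiskScoreModel:
    """Derive an additive integer risk score from a cohort table.

    Parameters
    ----------
    data : DataFrame
        One row per patient; must contain the candidate columns and the
        binary ``outcome`` column.
    outcome : str
        Name of the 0/1 outcome column (default ``mace30``).
    candidates : list of Candidate, optional
        Screening set; defaults to the standard 19-candidate layout.

    Examples
    --------
    >>> res = RiskScoreModel.from_dataframe(cohort).fit()   # doctest: +SKIP
    >>> res.score_table.max_score                           # doctest: +SKIP
    37
    """

    def __init__(self, data: pd.DataFrame, outcome: str = "mace30",
                 candidates: list[Candidate] | None = None):
        if outcome not in data.columns:
            raise ValueError(f"outcome column {outcome!r} not in data")
        if len(data) < 50:
            raise ValueError("cohort too small for derivation (n < 50)")
        self.data = data
        self.outcome = outcome
        self.candidates = (candidates if candidates is not None
                           else default_candidates())

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, **kwargs) -> "RiskScoreModel":
        return cls(data, **kwargs)

    def fit(self, p_remove: float = 0.10, screen_alpha: float = 0.05
            ) -> "RiskScoreResults":
        univ = univariate_screen(self.data, self.outcome, self.candidates,
                                 alpha=screen_alpha)
        selected = [c for c in self.candidates
                    if bool(univ.loc[univ.variable == c.name, "selected"].iloc[0])]
        if not selected:
            raise ValueError("no candidate passed univariate screening")
        X, blocks, rules, varmap = build_design(self.data, selected)
        y = self.data[self.outcome].to_numpy(dtype=int)
        fit, trace = backward_eliminate(X, y, blocks, p_remove=p_remove)
        return RiskScoreResults(self, univ, X, y, fit, trace, rules, varmap,
                                p_remove)


class RiskScoreResults:
    """Results of a score derivation: fit, trace, diagnostics, score table."""

    def __init__(self, model, univariate, X, y, fit, trace, rules, varmap,
                 p_remove):
        self.model = model
        self.univariate = univariate
        self.design = X
        self.y = y
        self.fit = fit
        self.trace = trace
        self._rules = rules
        self._varmap = varmap
        self.p_remove = p_remove

    @property
    def coefficients(self) -> pd.Series:
        """Final predictor coefficients (intercept excluded)."""
        return self.fit.params.drop("intercept")

    @property
    def score_table(self) -> ScoreModel:
        """Integer score table from the final coefficients.

        Raises if any final coefficient is non-positive (the category coding
        would need to be flipped before points can be assigned).
        """
        coefs = {t: float(self.fit.params[t]) for t in self.fit.terms}
        return build_score_table(coefs, self._rules, self._varmap)

    def predicted(self) -> np.ndarray:
        return self.fit.predict(self.design)

    def hosmer_lemeshow(self, groups: int = 10) -> HLResult:
        return hosmer_lemeshow_from_probs(self.predicted(), self.y, groups)

    def score_cohort(self, data: pd.DataFrame | None = None) -> np.ndarray:
        """Integer scores for a cohort under the derived table."""
        data = self.model.data if data is None else data
        table = self.score_table
        total = np.zeros(len(data), dtype=int)
        for c in table.criteria:
            total += c.points * c.rule.applies_vector(
                data[c.rule.feature]).astype(int)
        return total

    def summary(self) -> str:
        lines = ["Risk score derivation", "=" * 52]
        n_sel = int(self.univariate.selected.sum())
        lines.append(f"n = {len(self.model.data)}, outcome = "
                     f"{self.model.outcome!r}")
        lines.append(f"screened {len(self.univariate)} candidates, "
                     f"{n_sel} selected (p < 0.05)")
        lines.append(f"backward elimination (LR, p_remove = {self.p_remove}):")
        for ev in self.trace.removals:
            lines.append(f"  removed {ev.variable:<14s} LR={ev.lr_stat:6.3f} "
                         f"df={ev.df} p={ev.p_value:.3f}")
        hl = self.hosmer_lemeshow()
        lines.append(f"Hosmer-Lemeshow: chi2={hl.statistic:.3f} df={hl.df} "
                     f"p={hl.p_value:.3f}")
        lines.append("-" * 52)
        lines.append(f"{'term':<18s}{'beta':>8s}{'SE':>8s}{'p':>8s}"
                     f"{'OR':>7s}{'points':>7s}")
        try:
            pts = {c.name: c.points for c in self.score_table.criteria}
        except ValueError:
            pts = {}
        for t in self.fit.terms:
            b = self.fit.params[t]
            lines.append(
                f"{t:<18s}{b:8.3f}{self.fit.bse[t]:8.3f}"
                f"{self.fit.pvalues[t]:8.3f}{np.exp(b):7.2f}"
                f"{pts.get(t, float('nan')):7.0f}")
        if pts:
            lines.append(f"score range 0-{self.score_table.max_score} "
                         f"(divisor {self.score_table.divisor:.3f})")
        return "\n".join(lines)
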