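"""Score evaluation: ROC analysis, AUROC comparison, discriminatory values.

AUROC is the tie-corrected Mann-Whitney concordance (a random positive
outranking a random negative, half credit for ties), with DeLong variance
for its confidence interval and the paired DeLong test for comparing two
scores on the same patients. Discriminatory values (sensitivity,
specificity, PPV, NPV) call a patient positive when score >= cutoff and
carry Wald 95 % confidence intervals on their own denominators.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AUROCResult",
    "DiscrimValues",
    "ScoreBinSummary",
    "auroc",
    "delong_compare",
    "discrim",
    "rate_by_bin",
    "roc_points",
    "plot_roc",
    "SEDRSM_BINS",
]

#: Default SEDRSM score bins (inclusive low, inclusive high); extreme scores
#: pooled because few patients reach them.
SEDRSM_BINS: list[tuple[int, int]] = [
    (0, 6), (7, 8), (9, 10), (11, 12), (13, 14), (15, 16), (17, 37),
]


def _split(scores, outcomes) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(scores, dtype=float)
    y = np.asarray(outcomes, dtype=int)
    if s.shape != y.shape:
        raise ValueError("scores and outcomes must have the same length")
    pos, neg = s[y == 1], s[y == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both outcome classes must be present")
    return pos, neg


def _delong_placements(pos: np.ndarray, neg: np.ndarray
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Per-observation placement values (V10 for positives, V01 for
    negatives) of the Mann-Whitney kernel with half credit for ties."""
    diff = pos[:, None] - neg[None, :]
    psi = (diff > 0).astype(float) + 0.5 * (diff == 0)
    return psi.mean(axis=1), 1.0 - psi.mean(axis=0)


@dataclass(frozen=True)
class AUROCResult:
    auc: float
    ci_low: float
    ci_high: float
    se: float
    n_pos: int
    n_neg: int


def auroc(scores, outcomes, alpha: float = 0.05) -> AUROCResult:
    """AUROC with a DeLong confidence interval."""
    pos, neg = _split(scores, outcomes)
    v10, v01 = _delong_placements(pos, neg)
    auc = float(v10.mean())
    var = 0.0
    if pos.size > 1:
        var += np.var(v10, ddof=1) / pos.size
    if neg.size > 1:
        var += np.var(1.0 - v01, ddof=1) / neg.size
    se = float(np.sqrt(var))
    z = stats.norm.ppf(1 - alpha / 2)
    return AUROCResult(
        auc=auc,
        ci_low=float(max(0.0, auc - z * se)),
        ci_high=float(min(1.0, auc + z * se)),
        se=se, n_pos=pos.size, n_neg=neg.size,
    )


def delong_compare(scores_a, scores_b, outcomes) -> float:
    """Two-sided paired DeLong p-value for the AUC difference of two scores
    measured on the same patients."""
    pos_a, neg_a = _split(scores_a, outcomes)
    pos_b, neg_b = _split(scores_b, outcomes)
    va10, va01 = _delong_placements(pos_a, neg_a)
    vb10, vb01 = _delong_placements(pos_b, neg_b)
    auc_a, auc_b = va10.mean(), vb10.mean()
    m, n = pos_a.size, neg_a.size
    d10 = va10 - vb10
    d01 = (1 - va01) - (1 - vb01)
    var = 0.0
    if m > 1:
        var += np.var(d10, ddof=1) / m
    if n > 1:
        var += np.var(d01, ddof=1) / n
    if var <= 0:
        return 1.0
    z = (auc_a - auc_b) / np.sqrt(var)
    return float(2 * stats.norm.sf(abs(z)))


def _wald_ci(p: float, n: int, z: float = 1.959963984540054
             ) -> tuple[float, float]:
    half = z * np.sqrt(p * (1 - p) / n)
    return (max(0.0, p - half), min(1.0, p + half))


@dataclass(frozen=True)
class DiscrimValues:
    """Confusion-matrix summary at a cutoff (positive call: score >= cutoff).

    Each proportion carries a Wald 95 % CI on its own denominator; PPV/NPV
    are NaN (and flagged undefined) when no patient is called positive
    (negative)."""

    cutoff: float
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    sensitivity_ci: tuple[float, float]
    specificity_ci: tuple[float, float]
    ppv_ci: tuple[float, float]
    npv_ci: tuple[float, float]
    ppv_defined: bool = True
    npv_defined: bool = True


def discrim(scores, outcomes, cutoff: float) -> DiscrimValues:
    """Sensitivity, specificity, PPV, NPV (with Wald CIs) at a cutoff."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(outcomes, dtype=int)
    _split(scores, outcomes)  # class check
    call = s >= cutoff
    tp = int(np.sum(call & (y == 1)))
    fp = int(np.sum(call & (y == 0)))
    fn = int(np.sum(~call & (y == 1)))
    tn = int(np.sum(~call & (y == 0)))
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    ppv_def, npv_def = (tp + fp) > 0, (tn + fn) > 0
    ppv = tp / (tp + fp) if ppv_def else float("nan")
    npv = tn / (tn + fn) if npv_def else float("nan")
    return DiscrimValues(
        cutoff=cutoff, tp=tp, fp=fp, tn=tn, fn=fn,
        sensitivity=sens, specificity=spec, ppv=ppv, npv=npv,
        sensitivity_ci=_wald_ci(sens, tp + fn),
        specificity_ci=_wald_ci(spec, tn + fp),
        ppv_ci=_wald_ci(ppv, tp + fp) if ppv_def else (float("nan"),) * 2,
        npv_ci=_wald_ci(npv, tn + fn) if npv_def else (float("nan"),) * 2,
        ppv_defined=ppv_def, npv_defined=npv_def,
    )


@dataclass(frozen=True)
class ScoreBinSummary:
    """Outcome composition of one score bin."""

    label: str
    low: float
    high: float
    n_event: int
    n_no_event: int
    event_rate: float          # NaN for an empty bin
    pct_of_events: float       # % of all events falling in this bin
    pct_of_no_events: float


def rate_by_bin(scores, outcomes, bins: list[tuple[float, float]] | None = None
                ) -> list[ScoreBinSummary]:
    """Event rate and per-outcome-group percentages across score bins.

    ``bins`` is a list of (low, high) pairs, both ends inclusive; the
    default is the pooled SEDRSM binning. Bins must cover the observed
    score range. Per-group percentages sum to 100 across bins.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(outcomes, dtype=int)
    bins = bins if bins is not None else SEDRSM_BINS
    covered = np.zeros(s.size, dtype=bool)
    out = []
    n_ev, n_no = int(np.sum(y == 1)), int(np.sum(y == 0))
    for lo, hi in bins:
        m = (s >= lo) & (s <= hi)
        covered |= m
        ne = int(np.sum(m & (y == 1)))
        nn = int(np.sum(m & (y == 0)))
        tot = ne + nn
        out.append(ScoreBinSummary(
            label=f"{lo:g}-{hi:g}", low=lo, high=hi,
            n_event=ne, n_no_event=nn,
            event_rate=ne / tot if tot else float("nan"),
            pct_of_events=100.0 * ne / n_ev if n_ev else float("nan"),
            pct_of_no_events=100.0 * nn / n_no if n_no else float("nan"),
        ))
    if not covered.all():
        raise ValueError("bins do not cover the observed score range")
    return out


def roc_points(scores, outcomes) -> pd.DataFrame:
    """ROC coordinates (positive rule: score >= threshold), endpoints
    (0,0) and (1,1) included. Invariant under strictly increasing
    transformations of the scores."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(outcomes, dtype=int)
    pos, neg = _split(scores, outcomes)
    thresholds = np.concatenate([[np.inf], np.unique(s)[::-1]])
    rows = []
    for thr in thresholds:
        call = s >= thr
        rows.append({
            "threshold": thr,
            "sensitivity": np.sum(call & (y == 1)) / pos.size,
            "fpr": np.sum(call & (y == 0)) / neg.size,
        })
    return pd.DataFrame(rows)


def plot_roc(scores, outcomes, label: str | None = None, ax=None):
    """Plot the ROC curve; returns the matplotlib axes."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    pts = roc_points(scores, outcomes)
    res = auroc(scores, outcomes)
    lab = f"{label or 'score'} (AUC {res.auc:.3f})"
    ax.plot(pts.fpr, pts.sensitivity, drawstyle="steps-post", label=lab)
    ax.plot([0, 1], [0, 1], ls=":", color="grey", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend(loc="lower right")
    return ax
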