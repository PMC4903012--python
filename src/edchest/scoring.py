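"""Additive integer risk scores: SEDRSM and TIMI (UA/NSTEMI).

An integer clinical score is built from the unstandardized coefficients of a
logistic model: each coefficient is divided by the smallest one and rounded
to the nearest integer, and a patient's score is the arithmetic sum of the
points of the categories they satisfy. The default SEDRSM instance encodes
the published ten-criterion model (range 0-37); the TIMI UA/NSTEMI score is
the standard seven one-point items (range 0-7).

Cohort tables use fixed column names: ``sex`` ("male"/"female"),
``age_years``, ``hr_bpm``, ``ecg_ste``, ``ecg_std``, ``ecg_qwave``,
``ecg_qtprolong``, ``avrr_s``, ``tinn_s``, ``hf_power``, the ``timi_*``
items, and the outcome ``mace30``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "CategoryRule",
    "Criterion",
    "ScoreModel",
    "ScoreBreakdown",
    "IncompleteFeaturesError",
    "build_score_table",
    "default_sedrsm",
    "sedrsm_score",
    "timi_score",
    "categorize_features",
    "add_scores",
    "PUBLISHED_COEFFICIENTS",
    "TIMI_ITEMS",
]


class IncompleteFeaturesError(ValueError):
    """A required patient feature is missing; scores are never imputed."""


@dataclass(frozen=True)
class CategoryRule:
    """A categorization rule on one patient feature.

    ``op`` is one of ``flag`` (boolean feature is true), ``eq``, ``lt``,
    ``le``, ``gt``, ``ge``, or ``between`` (closed on both ends, ``value``
    a (lo, hi) pair). ``floor_first`` truncates the feature to an integer
    before comparing, used for heart rate in whole beats/min.
    """

    feature: str
    op: str
    value: object = None
    floor_first: bool = False

    def applies(self, x) -> bool:
        if self.floor_first:
            x = math.floor(x)
        if self.op == "flag":
            return bool(x)
        if self.op == "eq":
            return x == self.value
        if self.op == "lt":
            return x < self.value
        if self.op == "le":
            return x <= self.value
        if self.op == "gt":
            return x > self.value
        if self.op == "ge":
            return x >= self.value
        if self.op == "between":
            lo, hi = self.value  # type: ignore[misc]
            return lo <= x <= hi
        raise ValueError(f"unknown op {self.op!r}")

    def applies_vector(self, col: pd.Series) -> np.ndarray:
        x = col.to_numpy()
        if self.floor_first:
            x = np.floor(x.astype(float))
        if self.op == "flag":
            return x.astype(bool)
        if self.op == "eq":
            return x == self.value
        if self.op == "lt":
            return x < self.value
        if self.op == "le":
            return x <= self.value
        if self.op == "gt":
            return x > self.value
        if self.op == "ge":
            return x >= self.value
        if self.op == "between":
            lo, hi = self.value  # type: ignore[misc]
            return (x >= lo) & (x <= hi)
        raise ValueError(f"unknown op {self.op!r}")


@dataclass(frozen=True)
class Criterion:
    """One scored (non-reference) category of a score table."""

    name: str          # unique category name, e.g. "hr_le55"
    variable: str      # grouping variable, e.g. "heart_rate"
    rule: CategoryRule
    coefficient: float
    points: int


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass(frozen=True)
class ScoreModel:
    """An additive integer score: criteria, normalizing divisor, range."""

    criteria: tuple[Criterion, ...]
    divisor: float

    @property
    def variables(self) -> list[str]:
        seen: list[str] = []
        for c in self.criteria:
            if c.variable not in seen:
                seen.append(c.variable)
        return seen

    @property
    def max_score(self) -> int:
        """Sum over variables of each variable's maximum points."""
        best: dict[str, int] = {}
        for c in self.criteria:
            best[c.variable] = max(best.get(c.variable, 0), c.points)
        return sum(best.values())

    @property
    def score_range(self) -> tuple[int, int]:
        return (0, self.max_score)

    @property
    def required_features(self) -> set[str]:
        return {c.rule.feature for c in self.criteria}

    def to_json(self, path=None) -> str:
        payload = {
            "divisor": self.divisor,
            "criteria": [asdict(c) for c in self.criteria],
        }
        text = json.dumps(payload, indent=2, default=list)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, path) -> "ScoreModel":
        with open(path) as fh:
            payload = json.load(fh)
        crit = tuple(
            Criterion(
                name=c["name"], variable=c["variable"],
                rule=CategoryRule(
                    feature=c["rule"]["feature"], op=c["rule"]["op"],
                    value=tuple(c["rule"]["value"])
                    if isinstance(c["rule"]["value"], list)
                    else c["rule"]["value"],
                    floor_first=c["rule"]["floor_first"],
                ),
                coefficient=c["coefficient"], points=c["points"],
            )
            for c in payload["criteria"]
        )
        return cls(criteria=crit, divisor=payload["divisor"])


@dataclass(frozen=True)
class ScoreBreakdown:
    """Per-criterion awarded points and their sum."""

    points: dict[str, int]
    total: int


def build_score_table(
    coefficients: Mapping[str, float],
    rules: Mapping[str, CategoryRule] | None = None,
    variables: Mapping[str, str] | None = None,
) -> ScoreModel:
    """Turn named positive logistic coefficients into an integer score table.

    The divisor is the smallest coefficient; each coefficient is divided by
    it and rounded half away from zero to give that category's points.
    Reference categories carry no coefficient and implicitly score 0. A
    non-positive coefficient is rejected: its category coding must be
    flipped so the coefficient expresses added risk.
    """
    if not coefficients:
        raise ValueError("no coefficients given")
    for name, beta in coefficients.items():
        if not beta > 0:
            raise ValueError(
                f"coefficient for {name!r} is not positive ({beta}); flip the "
                "category coding so each coefficient expresses added risk"
            )
    divisor = min(coefficients.values())
    criteria = []
    for name, beta in coefficients.items():
        rule = (rules or {}).get(name, CategoryRule(feature=name, op="flag"))
        var = (variables or {}).get(name, name)
        criteria.append(Criterion(
            name=name, variable=var, rule=rule, coefficient=float(beta),
            points=_round_half_away(beta / divisor),
        ))
    return ScoreModel(criteria=tuple(criteria), divisor=float(divisor))


# ---------------------------------------------------------------------------
# The published SEDRSM instance

#: Unstandardized logistic coefficients of the published ten-variable model.
PUBLISHED_COEFFICIENTS: dict[str, float] = {
    "male": 0.773,
    "age_ge60": 0.323,
    "hr_le55": 1.510,
    "hr_56_114": 0.716,
    "st_elevation": 2.138,
    "st_depression": 2.382,
    "q_wave": 1.076,
    "qt_prolongation": 0.372,
    "avrr_lt_0.77": 0.415,
    "tinn_lt_0.11": 0.712,
    "tinn_gt_0.17": 0.277,
    "hf_lt_0.07": 0.531,
}

SEDRSM_RULES: dict[str, CategoryRule] = {
    "male": CategoryRule("sex", "eq", "male"),
    "age_ge60": CategoryRule("age_years", "ge", 60),
    "hr_le55": CategoryRule("hr_bpm", "le", 55, floor_first=True),
    "hr_56_114": CategoryRule("hr_bpm", "between", (56, 114), floor_first=True),
    "st_elevation": CategoryRule("ecg_ste", "flag"),
    "st_depression": CategoryRule("ecg_std", "flag"),
    "q_wave": CategoryRule("ecg_qwave", "flag"),
    "qt_prolongation": CategoryRule("ecg_qtprolong", "flag"),
    "avrr_lt_0.77": CategoryRule("avrr_s", "lt", 0.77),
    "tinn_lt_0.11": CategoryRule("tinn_s", "lt", 0.11),
    "tinn_gt_0.17": CategoryRule("tinn_s", "gt", 0.17),
    "hf_lt_0.07": CategoryRule("hf_power", "lt", 0.07),
}

SEDRSM_VARIABLES: dict[str, str] = {
    "male": "gender",
    "age_ge60": "age",
    "hr_le55": "heart_rate",
    "hr_56_114": "heart_rate",
    "st_elevation": "st_elevation",
    "st_depression": "st_depression",
    "q_wave": "q_wave",
    "qt_prolongation": "qt_prolongation",
    "avrr_lt_0.77": "avrr",
    "tinn_lt_0.11": "tinn",
    "tinn_gt_0.17": "tinn",
    "hf_lt_0.07": "hf_power",
}

_DEFAULT_SEDRSM: ScoreModel | None = None


def default_sedrsm() -> ScoreModel:
    """The published SEDRSM table, constructed from its coefficients."""
    global _DEFAULT_SEDRSM
    if _DEFAULT_SEDRSM is None:
        _DEFAULT_SEDRSM = build_score_table(
            PUBLISHED_COEFFICIENTS, SEDRSM_RULES, SEDRSM_VARIABLES)
    return _DEFAULT_SEDRSM


def _get_feature(features, name: str):
    try:
        x = features[name]
    except (KeyError, IndexError) as exc:
        raise IncompleteFeaturesError(f"missing feature {name!r}") from exc
    if x is None or (isinstance(x, float) and math.isnan(x)):
        raise IncompleteFeaturesError(f"feature {name!r} is missing/NaN")
    return x


def categorize_features(features, model: ScoreModel | None = None
                        ) -> dict[str, int]:
    """Indicator (0/1) per non-reference category; exclusive within a variable."""
    model = model or default_sedrsm()
    out: dict[str, int] = {}
    hits: dict[str, int] = {}
    for c in model.criteria:
        ind = int(c.rule.applies(_get_feature(features, c.rule.feature)))
        out[c.name] = ind
        hits[c.variable] = hits.get(c.variable, 0) + ind
    bad = [v for v, k in hits.items() if k > 1]
    if bad:
        raise ValueError(f"categories not mutually exclusive for {bad}")
    return out


def sedrsm_score(features, model: ScoreModel | None = None) -> ScoreBreakdown:
    """SEDRSM total and per-criterion points for one patient.

    ``features`` is any mapping (dict, pandas Series) with the documented
    cohort column names. All ten feature fields must be present; a missing
    or NaN field raises :class:`IncompleteFeaturesError`.
    """
    model = model or default_sedrsm()
    indicators = categorize_features(features, model)
    pts = {c.name: c.points * indicators[c.name] for c in model.criteria}
    return ScoreBreakdown(points=pts, total=int(sum(pts.values())))


#: The seven one-point TIMI UA/NSTEMI items (cohort column -> description).
TIMI_ITEMS: dict[str, str] = {
    "timi_age65": "age 65 years or older",
    "timi_riskfactors3": ">=3 coronary risk factors (family history, "
                         "hypertension, hypercholesterolemia, diabetes, "
                         "current smoking)",
    "timi_known_cad": "known coronary stenosis >=50 %",
    "timi_aspirin7d": "aspirin use in the prior 7 days",
    "timi_severe_angina": ">=2 anginal episodes in the last 24 h",
    "timi_st_deviation": "ST deviation >=0.5 mm on presentation ECG",
    "timi_elevated_markers": "elevated cardiac markers",
}


def timi_score(features) -> int:
    """TIMI UA/NSTEMI score (0-7): one point per positive item.

    ``timi_age65`` falls back to ``age_years >= 65`` and
    ``timi_riskfactors3`` to ``timi_riskfactor_count >= 3`` when the direct
    flag column is absent.
    """
    total = 0
    for item in TIMI_ITEMS:
        try:
            val = _get_feature(features, item)
        except IncompleteFeaturesError:
            if item == "timi_age65":
                val = _get_feature(features, "age_years") >= 65
            elif item == "timi_riskfactors3":
                val = _get_feature(features, "timi_riskfactor_count") >= 3
            else:
                raise
        total += int(bool(val))
    return total


def add_scores(cohort: pd.DataFrame, model: ScoreModel | None = None,
               sedrsm_col: str = "sedrsm_score", timi_col: str = "timi_score"
               ) -> pd.DataFrame:
    """Return a copy of the cohort with SEDRSM and TIMI score columns.

    SEDRSM scoring is vectorized over the table; TIMI is added only when the
    TIMI item columns (or their fallbacks) are available.
    """
    model = model or default_sedrsm()
    missing = sorted(model.required_features - set(cohort.columns))
    if missing:
        raise IncompleteFeaturesError(f"cohort lacks columns {missing}")
    out = cohort.copy()
    total = np.zeros(len(cohort), dtype=int)
    for c in model.criteria:
        col = cohort[c.rule.feature]
        if col.isna().any():
            raise IncompleteFeaturesError(
                f"column {c.rule.feature!r} contains missing values")
        total += c.points * c.rule.applies_vector(col).astype(int)
    out[sedrsm_col] = total
    try:
        out[timi_col] = [timi_score(row) for _, row in cohort.iterrows()]
    except IncompleteFeaturesError:
        pass
    return out
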