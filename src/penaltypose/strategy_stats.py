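"""Strategy-association statistics.

The analysis layer asks which notational and pose-derived variables are
associated with the dichotomized strategy of the penalty taker (goalkeeper
dependent vs. independent) or of the goalkeeper (kicker dependent vs.
independent):

* categorical variables: Pearson chi-squared test (no continuity
  correction) with Cramer's V effect size, banded weak (V <= 0.2),
  moderate (0.2 < V <= 0.6) and strong (V > 0.6);
* numeric variables: point-biserial correlation (Pearson r with 0/1
  coding of the strategy);
* repeated measurement runs: test-retest reliability (Pearson r) banded
  from perfect (r = 1) down to unacceptable (r < 0.5);
* retained variables (p < alpha, default 0.05) enter a logistic regression
  simultaneously ("enter" method, no stepwise selection), reported with the
  likelihood-ratio model chi-squared 2(LL_full - LL_null) and the in-sample
  classification accuracy at the 0.5 probability threshold.

No multiple-testing adjustment is applied at the screening stage; raw
p-values are compared against alpha.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import (
    ConvergenceWarning,
    PerfectSeparationError,
    PerfectSeparationWarning,
)

from .errors import (
    DegenerateTableError,
    ModelFitError,
    UndefinedCorrelationError,
)
from .ospaf_coding import OSPAF_VARIABLES, STRATEGY_VARIABLES

#: positive ("dependent") level of each strategy outcome
POSITIVE_LEVEL = {
    "gk_strategy": "kicker_dependent",
    "taker_strategy": "gk_dependent",
}
NEGATIVE_LEVEL = {
    "gk_strategy": "kicker_independent",
    "taker_strategy": "gk_independent",
}


# ---------------------------------------------------------------------------
# effect-size and reliability bands
# ---------------------------------------------------------------------------

def effect_class(v: float) -> str:
    """weak (V <= 0.2), moderate (0.2 < V <= 0.6), strong (V > 0.6)."""
    if v <= 0.2:
        return "weak"
    if v <= 0.6:
        return "moderate"
    return "strong"


def reliability_band(r: float) -> str:
    """Stability bands for test-retest coefficients.

    1 perfect; >= 0.9 excellent; >= 0.8 good; >= 0.7 acceptable;
    >= 0.6 questionable; >= 0.5 poor; < 0.5 unacceptable; 0 none.
    """
    if r == 1.0:
        return "perfect"
    if r == 0.0:
        return "none"
    if r >= 0.9:
        return "excellent"
    if r >= 0.8:
        return "good"
    if r >= 0.7:
        return "acceptable"
    if r >= 0.6:
        return "questionable"
    if r >= 0.5:
        return "poor"
    return "unacceptable"


# ---------------------------------------------------------------------------
# association tests
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChiSquareResult:
    chi2: float
    df: int
    p: float
    n: int
    cramers_v: float
    effect_class: str


@dataclass(frozen=True)
class ReliabilityResult:
    r: float
    band: str


def cramers_v(chi2: float, n: int, rows: int, cols: int) -> tuple[float, str]:
    """Cramer's V = sqrt(chi2 / (n * (min(rows, cols) - 1))) with its class."""
    if chi2 < 0 or n < 1 or rows < 2 or cols < 2:
        raise DegenerateTableError("cramers_v needs chi2 >= 0, n >= 1, dims >= 2")
    v = min(1.0, math.sqrt(chi2 / (n * (min(rows, cols) - 1))))
    return v, effect_class(v)


def chi_squared(table: Sequence[Sequence[float]]) -> ChiSquareResult:
    """Pearson chi-squared (no continuity correction) on an r x c table."""
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or np.any(t < 0):
        raise DegenerateTableError("contingency table must be 2-D with counts >= 0")
    if t.sum() <= 0:
        raise DegenerateTableError("contingency table is empty")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise DegenerateTableError("contingency table has an empty margin")
    if t.shape[0] < 2 or t.shape[1] < 2:
        raise DegenerateTableError("need >= 2 non-empty rows and columns")
    chi2, p, df, _ = sps.chi2_contingency(t, correction=False)
    n = int(round(t.sum()))
    v, cls = cramers_v(float(chi2), n, t.shape[0], t.shape[1])
    return ChiSquareResult(
        chi2=float(chi2), df=int(df), p=float(p), n=n, cramers_v=v, effect_class=cls
    )


def point_biserial(
    binary: Sequence[float], continuous: Sequence[float]
) -> tuple[float, float]:
    """Point-biserial correlation (= Pearson with 0/1 coding) and its p-value."""
    y = np.asarray(binary, dtype=float)
    x = np.asarray(continuous, dtype=float)
    if len(y) != len(x) or len(y) < 3:
        raise UndefinedCorrelationError("need equal-length sequences of >= 3")
    if set(np.unique(y)) - {0.0, 1.0}:
        raise UndefinedCorrelationError("binary input must be coded 0/1")
    if len(np.unique(y)) < 2:
        raise UndefinedCorrelationError("binary input has a single class")
    if np.ptp(x) == 0:
        raise UndefinedCorrelationError("continuous input is constant")
    res = sps.pointbiserialr(y, x)
    return float(res.statistic), float(res.pvalue)


def retest_reliability(
    run1: Sequence[float], run2: Sequence[float]
) -> ReliabilityResult:
    """Pearson correlation of two repeated measurement runs, banded."""
    a = np.asarray(run1, dtype=float)
    b = np.asarray(run2, dtype=float)
    if len(a) != len(b) or len(a) < 3:
        raise UndefinedCorrelationError("need equal-length runs of >= 3")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise UndefinedCorrelationError("a run is constant; r undefined")
    r = float(sps.pearsonr(a, b).statistic)
    return ReliabilityResult(r=r, band=reliability_band(r))


def summarize_confidence(scores: Sequence[float]) -> tuple[float, float]:
    """Mean and sample SD (n-1) of per-variable confidence scores, reported
    to 2 decimals.

    Rounding is done in decimal arithmetic (half away from zero) on the
    decimal string form of the inputs, so printed two-decimal summaries of
    two-decimal scores come out as a desk calculator would give them.
    """
    if len(scores) < 2:
        raise UndefinedCorrelationError("need >= 2 scores")
    dvals = [Decimal(str(float(s))) for s in scores]
    n = len(dvals)
    mean = sum(dvals) / n
    var = sum((d - mean) ** 2 for d in dvals) / (n - 1)
    sd = var.sqrt()
    q = Decimal("0.01")
    return (
        float(mean.quantize(q, rounding=ROUND_HALF_UP)),
        float(sd.quantize(q, rounding=ROUND_HALF_UP)),
    )


# ---------------------------------------------------------------------------
# logistic regression (enter method)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LogisticStrategyModel:
    coefficients: Mapping[str, float]
    model_chi2: float
    df: int
    p: float
    accuracy: float
    log_likelihood: float
    ll_null: float
    separation: bool = False
    predictors: tuple[str, ...] = ()


def _null_log_likelihood(y: np.ndarray) -> float:
    p = y.mean()
    if p in (0.0, 1.0):
        return 0.0
    n = len(y)
    return float(n * (p * math.log(p) + (1 - p) * math.log(1 - p)))


def logistic_fit(features: pd.DataFrame, labels: Sequence[int]) -> LogisticStrategyModel:
    """Maximum-likelihood logistic fit with all predictors entered at once.

    ``features`` is the design table (numeric / dummy-coded columns; may be
    empty for the null model); ``labels`` a 0/1 sequence.  Ties at predicted
    probability 0.5 classify as the positive class.  Complete separation is
    detected and reported via ``separation=True`` plus a UserWarning, with
    the fit obtained under capped iterations.
    """
    y = np.asarray(labels, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ModelFitError("labels must be coded 0/1")
    if len(np.unique(y)) < 2:
        raise ModelFitError("labels contain a single class; nothing to fit")
    x = pd.DataFrame(features).astype(float).reset_index(drop=True)
    if len(x) != len(y):
        raise ModelFitError("features and labels differ in length")
    design = sm.add_constant(x, has_constant="add")

    separation = False
    model = sm.Logit(y, design)
    with warnings.catch_warnings():
        warnings.simplefilter("error", PerfectSeparationWarning)
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        try:
            res = model.fit(disp=0, maxiter=200)
            if not res.mle_retvals.get("converged", True):
                raise PerfectSeparationError("newton did not converge")
        except (PerfectSeparationError, PerfectSeparationWarning, np.linalg.LinAlgError):
            separation = True
    if separation:
        warnings.warn(
            "complete separation detected; coefficients fitted with capped "
            "iterations are unstable",
            UserWarning,
            stacklevel=2,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(method="bfgs", maxiter=100, disp=0)

    llf = float(res.llf)
    ll_null = _null_log_likelihood(y)
    model_chi2 = max(0.0, 2.0 * (llf - ll_null))
    df = x.shape[1]
    p = float(sps.chi2.sf(model_chi2, df)) if df >= 1 else math.nan
    phat = np.asarray(res.predict(design))
    predicted = phat >= 0.5  # ties -> positive (dependent-strategy) class
    accuracy = float(np.mean(predicted == (y == 1.0)))
    return LogisticStrategyModel(
        coefficients=dict(zip(design.columns, map(float, res.params))),
        model_chi2=model_chi2,
        df=df,
        p=p,
        accuracy=accuracy,
        log_likelihood=llf,
        ll_null=ll_null,
        separation=separation,
        predictors=tuple(x.columns),
    )


def build_design(
    data: pd.DataFrame,
    categorical: Sequence[str] = (),
    numeric: Sequence[str] = (),
) -> pd.DataFrame:
    """Dummy-code categoricals (first alphabetical level as reference) and
    append numeric columns, yielding a logistic design table."""
    parts = []
    for col in categorical:
        levels = sorted(data[col].astype(str).unique())
        cat = pd.Categorical(data[col].astype(str), categories=levels)
        dummies = pd.get_dummies(cat, prefix=col, drop_first=True, dtype=float)
        parts.append(dummies.reset_index(drop=True))
    if numeric:
        parts.append(data[list(numeric)].astype(float).reset_index(drop=True))
    if not parts:
        return pd.DataFrame(index=range(len(data)))
    return pd.concat(parts, axis=1)


# ---------------------------------------------------------------------------
# full screening + modelling report
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScreeningRow:
    variable: str
    kind: str          # "categorical" | "numeric"
    statistic: float   # chi2 or r_pb
    p: float
    effect: float      # Cramer's V or |r_pb|
    effect_label: str
    retained: bool
    note: str = ""


@dataclass(frozen=True)
class StrategyReport:
    outcome: str
    positive_level: str
    alpha: float
    n_used: int
    n_excluded_unclear: int
    screening: tuple[ScreeningRow, ...]
    model_ospaf: LogisticStrategyModel | None
    model_with_pose: LogisticStrategyModel | None

    @property
    def retained_categorical(self) -> list[str]:
        return [s.variable for s in self.screening if s.retained and s.kind == "categorical"]

    @property
    def retained_numeric(self) -> list[str]:
        return [s.variable for s in self.screening if s.retained and s.kind == "numeric"]

    @property
    def accuracy_delta(self) -> float | None:
        if self.model_ospaf is None or self.model_with_pose is None:
            return None
        return self.model_with_pose.accuracy - self.model_ospaf.accuracy

    def to_dict(self) -> dict:
        def model_dict(m: LogisticStrategyModel | None) -> dict | None:
            if m is None:
                return None
            return {
                "predictors": list(m.predictors),
                "coefficients": dict(m.coefficients),
                "model_chi2": m.model_chi2,
                "df": m.df,
                "p": m.p,
                "accuracy": m.accuracy,
                "separation": m.separation,
            }

        return {
            "outcome": self.outcome,
            "positive_level": self.positive_level,
            "alpha": self.alpha,
            "n_used": self.n_used,
            "n_excluded_unclear": self.n_excluded_unclear,
            "screening": [vars(s) for s in self.screening],
            "model_ospaf": model_dict(self.model_ospaf),
            "model_with_pose": model_dict(self.model_with_pose),
            "accuracy_delta": self.accuracy_delta,
        }

    def to_text(self) -> str:
        lines = [
            f"Strategy report: outcome={self.outcome} "
            f"(positive level: {self.positive_level}), alpha={self.alpha}",
            f"n analysed = {self.n_used} "
            f"({self.n_excluded_unclear} 'unclear' rows excluded)",
            "",
            f"{'variable':<28}{'kind':<13}{'stat':>9}{'p':>9}{'effect':>9}  class",
        ]
        for s in self.screening:
            mark = "*" if s.retained else " "
            lines.append(
                f"{s.variable:<28}{s.kind:<13}{s.statistic:>9.3f}{s.p:>9.4f}"
                f"{s.effect:>9.3f}  {s.effect_label}{mark} {s.note}"
            )
        for name, m in (
            ("notational model", self.model_ospaf),
            ("notational + pose model", self.model_with_pose),
        ):
            lines.append("")
            if m is None:
                lines.append(f"{name}: not fitted (no retained predictors)")
            else:
                lines.append(
                    f"{name}: chi2({m.df}) = {m.model_chi2:.3f}, p = {m.p:.4f}, "
                    f"accuracy = {100 * m.accuracy:.1f}%"
                    + (" [separation warning]" if m.separation else "")
                )
        if self.accuracy_delta is not None:
            lines.append(f"accuracy delta = {100 * self.accuracy_delta:+.1f} points")
        return "\n".join(lines)


def dichotomize_strategy(
    data: pd.DataFrame, outcome: str
) -> tuple[pd.DataFrame, np.ndarray, int]:
    """Drop 'unclear' rows and code the strategy as 1 = dependent level.

    Returns (subset, 0/1 labels, number of excluded rows).
    """
    if outcome not in POSITIVE_LEVEL:
        raise ModelFitError(f"outcome must be one of {tuple(POSITIVE_LEVEL)}")
    keep = data[outcome].isin([POSITIVE_LEVEL[outcome], NEGATIVE_LEVEL[outcome]])
    subset = data.loc[keep].reset_index(drop=True)
    labels = (subset[outcome] == POSITIVE_LEVEL[outcome]).astype(int).to_numpy()
    return subset, labels, int((~keep).sum())


def strategy_report(
    data: pd.DataFrame,
    outcome: str = "gk_strategy",
    alpha: float = 0.05,
    numeric_vars: Sequence[str] | None = None,
) -> StrategyReport:
    """Screen every candidate variable against the dichotomized strategy and
    fit the enter-method logistic models.

    Model 1 uses the retained notational (categorical) variables; model 2
    adds the retained numeric (pose / ball-speed) variables.  When
    ``numeric_vars`` is None, every numeric column except confidence scores
    (``c_*``) and identifiers is screened.
    """
    if not 0 < alpha < 1:
        raise ModelFitError(f"alpha must be in (0, 1), got {alpha}")
    subset, labels, n_excluded = dichotomize_strategy(data, outcome)
    if len(np.unique(labels)) < 2:
        raise ModelFitError("dichotomized outcome has a single class")

    categoricals = [
        v
        for v in OSPAF_VARIABLES
        if v in subset.columns and v not in STRATEGY_VARIABLES
    ]
    if numeric_vars is None:
        numeric_vars = [
            c
            for c in subset.columns
            if pd.api.types.is_numeric_dtype(subset[c])
            and not c.startswith("c_")
            and c != "penalty_id"
        ]

    screening: list[ScreeningRow] = []
    for var in categoricals:
        table = pd.crosstab(labels, subset[var].astype(str))
        table = table.loc[:, table.sum(axis=0) > 0]
        try:
            res = chi_squared(table.to_numpy())
        except DegenerateTableError as exc:
            screening.append(
                ScreeningRow(var, "categorical", math.nan, math.nan, math.nan,
                             "n/a", False, note=f"skipped: {exc}")
            )
            continue
        screening.append(
            ScreeningRow(
                var, "categorical", res.chi2, res.p, res.cramers_v,
                res.effect_class, res.p < alpha,
            )
        )
    for var in numeric_vars:
        x = subset[var].astype(float)
        ok = x.notna().to_numpy()
        try:
            r, p = point_biserial(labels[ok], x.to_numpy()[ok])
        except UndefinedCorrelationError as exc:
            screening.append(
                ScreeningRow(var, "numeric", math.nan, math.nan, math.nan,
                             "n/a", False, note=f"skipped: {exc}")
            )
            continue
        screening.append(
            ScreeningRow(var, "numeric", r, p, abs(r), effect_class(abs(r)), p < alpha)
        )

    retained_cat = [s.variable for s in screening if s.retained and s.kind == "categorical"]
    retained_num = [s.variable for s in screening if s.retained and s.kind == "numeric"]

    model_ospaf = model_with_pose = None
    if retained_cat or retained_num:
        # numeric predictors may carry NaN flags for missing pose measures;
        # model rows are restricted to complete cases
        cols = retained_cat + retained_num
        complete = subset[cols].notna().all(axis=1).to_numpy()
        sub = subset.loc[complete].reset_index(drop=True)
        lab = labels[complete]
        if retained_cat:
            design1 = build_design(sub, categorical=retained_cat)
            model_ospaf = logistic_fit(design1, lab)
        if retained_num:
            design2 = build_design(sub, categorical=retained_cat, numeric=retained_num)
            model_with_pose = logistic_fit(design2, lab)
        elif retained_cat:
            model_with_pose = model_ospaf

    return StrategyReport(
        outcome=outcome,
        positive_level=POSITIVE_LEVEL[outcome],
        alpha=alpha,
        n_used=len(subset),
        n_excluded_unclear=n_excluded,
        screening=tuple(screening),
        model_ospaf=model_ospaf,
        model_with_pose=model_with_pose,
    )
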