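"""Aggregate statistics for duplicate-gene essentiality analyses.

Covers the summary layer of the pipeline: phenotype/masking/essentiality
rates per group, 2x2 association tests (chi-squared with or without
Yates continuity correction, and Fisher's exact test), equal-size-bin
divergence curves (rate of a binary outcome plotted at the median of a
predictor within equal-frequency bins), logistic-regression trends on
unbinned data, and an expression-controlled model of evolutionary rate:
an ANCOVA of ln(dN + 1) on log2 expression plus a two-level class flag,
with an interaction pretest (the class comparison is only interpretable
when the slopes are homogeneous).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction
from typing import Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats
from statsmodels.tools.sm_exceptions import PerfectSeparationError

__all__ = [
    "RateRecord",
    "BinnedCurvePoint",
    "TrendResult",
    "AncovaResult",
    "rate",
    "contingency_test",
    "binned_rate_curve",
    "logistic_trend",
    "expression_controlled_rate_model",
]


@dataclass(frozen=True)
class RateRecord:
    """An exact numerator/denominator rate with presentation rounding."""

    group: str
    numerator: int
    denominator: int

    def __post_init__(self) -> None:
        if self.denominator <= 0:
            raise ValueError(f"{self.group}: denominator must be positive")
        if not (0 <= self.numerator <= self.denominator):
            raise ValueError(f"{self.group}: numerator outside [0, denominator]")

    @property
    def fraction(self) -> Fraction:
        return Fraction(self.numerator, self.denominator)

    @property
    def rate(self) -> float:
        return self.numerator / self.denominator

    @property
    def percent(self) -> float:
        """Percent rounded half-up to one decimal (presentation only)."""
        exact = Decimal(self.numerator) / Decimal(self.denominator) * 100
        return float(exact.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def rate(numerator: int, denominator: int, group: str = "") -> RateRecord:
    return RateRecord(group=group, numerator=numerator, denominator=denominator)


def contingency_test(
    table: Sequence[Sequence[int]], method: str = "chi2_yates"
) -> tuple[float | None, float]:
    """2x2 association test: (statistic, p).

    ``method`` is "chi2" (Pearson, uncorrected), "chi2_yates"
    (continuity-corrected) or "fisher" (exact; statistic is the odds
    ratio). Emits a warning when an expected count is below 5 and a
    chi-squared variant was requested. Degenerate margins raise.
    """
    arr = np.asarray(table, dtype=float)
    if arr.shape != (2, 2) or np.any(arr < 0) or not np.all(arr == arr.astype(int)):
        raise ValueError("table must be 2x2 with non-negative integer counts")
    if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
        raise ValueError("degenerate margins: a row or column sums to zero")
    if method in ("chi2", "chi2_yates"):
        expected = stats.contingency.expected_freq(arr)
        if np.any(expected < 5):
            import warnings

            warnings.warn(
                "an expected count is below 5; Fisher's exact test is "
                "recommended for this table"
            )
        result = stats.chi2_contingency(arr, correction=(method == "chi2_yates"))
        return float(result.statistic), float(result.pvalue)
    if method == "fisher":
        odds, p = stats.fisher_exact(arr.astype(int), alternative="two-sided")
        return (None if np.isnan(odds) else float(odds)), float(p)
    raise ValueError(f"unknown method {method!r}")


@dataclass(frozen=True)
class BinnedCurvePoint:
    x: float  # median of the predictor within the bin
    y: float  # outcome rate within the bin
    n: int


def binned_rate_curve(
    x: Sequence[float], y: Sequence[bool], n_bins: int
) -> list[BinnedCurvePoint]:
    """Equal-frequency binned outcome-rate curve.

    Data are sorted by x (stable, so boundary ties resolve by input
    order) and split into ``n_bins`` contiguous bins whose sizes differ
    by at most one; the remainder is distributed to the lowest-x bins.
    Each point is (median x in bin, mean outcome in bin, bin size).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal lengths")
    n = x.size
    if n_bins < 1 or n_bins > n:
        raise ValueError("n_bins must be between 1 and the number of points")
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    base, rem = divmod(n, n_bins)
    sizes = [base + 1 if i < rem else base for i in range(n_bins)]
    points = []
    start = 0
    for size in sizes:
        stop = start + size
        points.append(
            BinnedCurvePoint(
                x=float(np.median(xs[start:stop])),
                y=float(np.mean(ys[start:stop])),
                n=size,
            )
        )
        start = stop
    return points


@dataclass(frozen=True)
class TrendResult:
    slope: float
    p_value: float | None
    intercept: float
    separation: bool = False


def logistic_trend(x: Sequence[float], y: Sequence[bool]) -> TrendResult:
    """Maximum-likelihood logistic fit of a binary outcome on unbinned x.

    Returns the slope and its Wald p-value. Complete separation is
    flagged and leaves the p-value undefined. Degenerate inputs (a
    single outcome class, or constant x) raise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal lengths")
    if np.unique(y).size < 2:
        raise ValueError("both outcome classes must be present")
    if np.unique(x).size < 2:
        raise ValueError("x must take at least two distinct values")
    design = sm.add_constant(x)
    import warnings

    from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

    separated = False
    try:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            with np.errstate(all="ignore"):
                fit = sm.Logit(y, design).fit(disp=0, maxiter=200)
        separated = any(
            issubclass(w.category, PerfectSeparationWarning) for w in caught
        )
    except (PerfectSeparationError, np.linalg.LinAlgError):
        return TrendResult(slope=np.nan, p_value=None, intercept=np.nan,
                           separation=True)
    slope = float(fit.params[1])
    p = float(fit.pvalues[1])
    if separated or not np.isfinite(p) or np.abs(slope) > 1e3:
        return TrendResult(slope=slope, p_value=None, intercept=float(fit.params[0]),
                           separation=True)
    return TrendResult(slope=slope, p_value=p, intercept=float(fit.params[0]))


@dataclass(frozen=True)
class AncovaResult:
    """Expression-controlled evolutionary-rate model output."""

    expression_coef: float
    expression_p: float
    class_coef: float
    class_p: float
    interaction_p: float
    interaction_significant: bool
    ancova_valid: bool
    nobs: int


def expression_controlled_rate_model(
    dN: Sequence[float],
    expression: Sequence[float],
    class_flag: Sequence[bool],
    interaction_alpha: float = 0.05,
) -> AncovaResult:
    """ANCOVA of evolutionary rate on expression with a class term.

    The response is ln(dN + 1) (rates of zero are common, hence the +1
    shift before the log); the covariate is log2 expression; the class
    flag is the two-level factor of interest. An interaction pretest is
    run first: when the expression-by-class interaction is significant
    the slopes are heterogeneous and the class comparison from the
    additive model is not interpretable (``ancova_valid`` is False); the
    additive-model coefficients are reported either way.
    """
    dN = np.asarray(dN, dtype=float)
    expr = np.asarray(expression, dtype=float)
    flag = np.asarray(class_flag, dtype=float)
    if not (dN.shape == expr.shape == flag.shape):
        raise ValueError("inputs must have equal lengths")
    if np.any(dN < 0):
        raise ValueError("dN must be non-negative")
    if np.any(expr <= 0):
        raise ValueError("expression values must be positive")
    y = np.log(dN + 1.0)
    x = np.log2(expr)
    with_interaction = sm.add_constant(
        np.column_stack([x, flag, x * flag]), has_constant="add"
    )
    additive = sm.add_constant(np.column_stack([x, flag]), has_constant="add")
    if np.linalg.matrix_rank(additive) < additive.shape[1]:
        raise ValueError("rank-deficient design (constant covariate or flag)")
    inter_fit = sm.OLS(y, with_interaction).fit()
    interaction_p = float(inter_fit.pvalues[3])
    fit = sm.OLS(y, additive).fit()
    interaction_significant = interaction_p < interaction_alpha
    return AncovaResult(
        expression_coef=float(fit.params[1]),
        expression_p=float(fit.pvalues[1]),
        class_coef=float(fit.params[2]),
        class_p=float(fit.pvalues[2]),
        interaction_p=interaction_p,
        interaction_significant=interaction_significant,
        ancova_valid=not interaction_significant,
        nobs=int(fit.nobs),
    )
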