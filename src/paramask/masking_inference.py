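"""The phenotype-masking statistic for double-knockdown screens.

If w is fitness and s_i the fitness reduction caused by knocking down
gene i, the multiplicative null model for the double knockdown is

    w_12 = (1 - s_1)(1 - s_2) = w_1 * w_2.

Quantitative phenotypes (brood size, embryonic viability, post-embryonic
viability, fraction morphologically normal) are normalised to control
animals to yield replicate-level fitness estimates w. Masking is inferred
when the observed double-knockdown fitness is significantly *lower* than
the multiplicative expectation (one-sided Mann-Whitney U, p < 0.05), or
when the double knockdown shows a qualitatively escalated phenotype —
an earlier developmental stage, or a more severe phenotype class, than
either single knockdown.

Masking is "full" when neither single knockdown has any penetrant
phenotype call, and "partial" otherwise.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .phenotype_screen import STAGE_RANKS, PhenotypeCall

__all__ = [
    "FitnessEstimate",
    "MeasureTest",
    "MaskingResult",
    "MEASURES",
    "normalize_fitness",
    "expected_double",
    "quantitative_masking_test",
    "qualitative_escalation",
    "classify_masking",
]

#: Quantitative measures, all oriented so larger = healthier.
MEASURES = (
    "brood",
    "embryonic_viability",
    "postembryonic_viability",
    "morphology_normal",
)

#: Minimum replicates per sample for the rank test (screens use 3-5).
MIN_REPLICATES = 3

#: Below this combined sample size the exact rank-test null is used.
EXACT_TEST_MAX_N = 20


@dataclass(frozen=True)
class FitnessEstimate:
    """Control-normalised fitness values, one per replicate."""

    condition_id: str
    measure: str
    w_values: tuple[float, ...]

    def __post_init__(self) -> None:
        if not self.w_values:
            raise ValueError(f"{self.condition_id}: empty fitness estimate")
        arr = np.asarray(self.w_values, dtype=float)
        if not np.all(np.isfinite(arr)) or np.any(arr < 0):
            raise ValueError(
                f"{self.condition_id}/{self.measure}: fitness values must be "
                "finite and non-negative"
            )

    @property
    def mean(self) -> float:
        return float(np.mean(self.w_values))


@dataclass(frozen=True)
class MeasureTest:
    measure: str
    w1_mean: float
    w2_mean: float
    expected: float
    observed_mean: float
    p_value: float
    significant: bool


@dataclass
class MaskingResult:
    pair_id: str
    measures: list[MeasureTest] = field(default_factory=list)
    qualitative_escalation: bool = False
    call: str = "none"  # "none" | "partial" | "full"


def normalize_fitness(
    condition_id: str,
    measure: str,
    observed: Sequence[float],
    controls: Sequence[float],
) -> FitnessEstimate:
    """w_i = observed_i / mean(controls); values may exceed 1.

    Measures must be oriented so that larger = healthier before
    normalisation (viability fractions, brood size, fraction normal).
    """
    controls = np.asarray(controls, dtype=float)
    if controls.size == 0:
        raise ValueError("empty control sample")
    cmean = float(controls.mean())
    if cmean <= 0:
        raise ValueError(f"{condition_id}/{measure}: control mean is not positive")
    w = tuple(float(x) / cmean for x in observed)
    return FitnessEstimate(condition_id=condition_id, measure=measure, w_values=w)


def expected_double(w1: float, w2: float) -> float:
    """Multiplicative-model expectation for the double knockdown."""
    if w1 < 0 or w2 < 0:
        raise ValueError("fitness values must be non-negative")
    return w1 * w2


def _expected_sample(
    w1: Sequence[float], w2: Sequence[float], null: str
) -> np.ndarray:
    if null == "cross-products":
        return np.array([a * b for a, b in itertools.product(w1, w2)])
    if null == "paired":
        if len(w1) != len(w2):
            raise ValueError("paired null requires equal replicate counts")
        return np.asarray(w1, dtype=float) * np.asarray(w2, dtype=float)
    raise ValueError(f"unknown null construction {null!r}")


def quantitative_masking_test(
    w1: FitnessEstimate,
    w2: FitnessEstimate,
    w12: FitnessEstimate,
    alpha: float = 0.05,
    null: str = "paired",
    min_replicates: int = MIN_REPLICATES,
) -> tuple[float, bool]:
    """One-sided rank test of the double knockdown against the null.

    The expected distribution is built from the single-knockdown
    replicates as paired products w1_i * w2_i (default) or as all
    cross-products {w1_i * w2_j}. The paired construction keeps the
    expected sample independent, which calibrates the test at its
    nominal level; the cross-products sample uses all information but
    its internal dependence makes the rank test anti-conservative at
    screen-typical replicate counts. The Mann-Whitney U test asks
    whether the observed double-knockdown replicates are stochastically
    *smaller* than the expected sample; ``significant`` iff p < alpha.
    The exact null distribution is used when the combined sample is
    small (<= 20) and tie-free, otherwise the normal approximation with
    tie correction.
    """
    for est in (w1, w2, w12):
        if len(est.w_values) < min_replicates:
            raise ValueError(
                f"{est.condition_id}/{est.measure}: fewer than "
                f"{min_replicates} replicates"
            )
    expected = _expected_sample(w1.w_values, w2.w_values, null)
    observed = np.asarray(w12.w_values, dtype=float)
    total = expected.size + observed.size
    pooled = np.concatenate([expected, observed])
    if np.ptp(pooled) == 0:
        # all values identical (e.g. noise-free multiplicative data):
        # no rank information, accept the null outright
        return 1.0, False
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (total <= EXACT_TEST_MAX_N and not has_ties) else "asymptotic"
    result = stats.mannwhitneyu(observed, expected, alternative="less", method=method)
    p = float(result.pvalue)
    return p, p < alpha


def _call_key(call: PhenotypeCall) -> tuple[int, int]:
    """Ordering key: severity class first, then stage earliness.

    Unstaged calls rank as the least-early stage, so an identical call
    with an earlier recorded stage strictly exceeds them.
    """
    latest = max(STAGE_RANKS.values())
    stage = call.stage_rank if call.stage_rank is not None else latest
    return (call.severity_rank, -stage)


def qualitative_escalation(
    single_calls_1: Sequence[PhenotypeCall],
    single_calls_2: Sequence[PhenotypeCall],
    double_calls: Sequence[PhenotypeCall],
) -> bool:
    """True iff the double knockdown shows a strictly stronger call.

    A call is stronger when its phenotype class is more severe, or the
    same class presents at an earlier developmental stage, than the
    strongest call across both single knockdowns. A penetrant call in the
    double with no penetrant single-knockdown calls at all counts as an
    escalation.
    """
    if not double_calls:
        return False
    singles = list(single_calls_1) + list(single_calls_2)
    if not singles:
        return True
    single_max = max(_call_key(c) for c in singles)
    return any(_call_key(c) > single_max for c in double_calls)


def classify_masking(
    pair_id: str,
    single_calls_1: Sequence[PhenotypeCall],
    single_calls_2: Sequence[PhenotypeCall],
    measure_tests: Sequence[MeasureTest],
    escalation: bool,
) -> MaskingResult:
    """Combine quantitative and qualitative evidence into a masking call.

    "none" when no measure is significant and there is no qualitative
    escalation. Otherwise "full" if neither single knockdown has any
    penetrant phenotype call (the defect was entirely hidden by the
    paralog), else "partial".
    """
    any_quant = any(t.significant for t in measure_tests)
    result = MaskingResult(
        pair_id=pair_id,
        measures=list(measure_tests),
        qualitative_escalation=escalation,
    )
    if not any_quant and not escalation:
        result.call = "none"
    elif not any(c.penetrant for c in single_calls_1) and not any(
        c.penetrant for c in single_calls_2
    ):
        result.call = "full"
    else:
        result.call = "partial"
    return result
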