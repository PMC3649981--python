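"""End-to-end composition: screen wells -> masking calls -> essentiality.

Mirrors the two-stage structure of a double-knockdown RNAi screen:

1. Every pair is scored qualitatively from replicate wells (penetrant
   phenotype calls, plus fertility/embryonic-lethality codes from the
   well counts). Pairs whose double knockdown shows a qualitatively
   stronger phenotype than either single knockdown become masking
   candidates.
2. Candidates are tested quantitatively: each control-normalised
   measure's double-knockdown replicates are compared with the
   multiplicative expectation by the one-sided rank test, and the
   combined evidence is classified as none / partial / full masking.

A pair is then essential when either member carried a prior-screen
knockdown phenotype or the pair shows masking.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from . import masking_inference as mi
from . import phenotype_screen as ps
from .phenotype_screen import PhenotypeCall, WellObservation

__all__ = [
    "condition_calls",
    "raw_measures",
    "condition_fitness",
    "analyze_pair",
    "PairAnalysis",
]


def condition_calls(
    wells: Sequence[WellObservation],
    vocabulary: Mapping[str, int] | None = None,
) -> list[PhenotypeCall]:
    """All penetrant calls for a condition: qualitative calls passing the
    penetrance thresholds, plus Ste/Lbd/Emb codes scored from counts in
    any replicate."""
    vocab = ps.PHENOTYPE_VOCABULARY if vocabulary is None else vocabulary
    calls = ps.assign_penetrant_calls(wells, vocab)
    seen = {c.phenotype_code for c in calls}
    count_codes: set[str] = set()
    for obs in wells:
        count_codes |= ps.score_brood_and_lethality(obs)
    for code in sorted(count_codes - seen):
        calls.append(
            PhenotypeCall(
                condition_id=wells[0].condition_id,
                phenotype_code=code,
                penetrant=True,
                severity_rank=vocab[code],
                stage_rank=None,
            )
        )
    return calls


def raw_measures(wells: Sequence[WellObservation]) -> dict[str, list[float]]:
    """Per-measure raw replicate values, oriented larger = healthier."""
    out: dict[str, list[float]] = {m: [] for m in mi.MEASURES}
    for obs in wells:
        out["brood"].append(float(obs.brood_count))
        if obs.f1_total > 0:
            out["embryonic_viability"].append(
                1.0 - obs.unhatched_count / obs.f1_total
            )
            out["postembryonic_viability"].append(
                1.0 - obs.postembryonic_dead / obs.f1_total
            )
            out["morphology_normal"].append(
                1.0 - obs.morphology_abnormal / obs.f1_total
            )
    return out


def condition_fitness(
    condition_id: str,
    wells: Sequence[WellObservation],
    control_wells: Sequence[WellObservation],
) -> dict[str, mi.FitnessEstimate]:
    """Control-normalised fitness estimates per quantitative measure."""
    raw = raw_measures(wells)
    controls = raw_measures(control_wells)
    out: dict[str, mi.FitnessEstimate] = {}
    for measure in mi.MEASURES:
        if raw[measure] and controls[measure]:
            out[measure] = mi.normalize_fitness(
                condition_id, measure, raw[measure], controls[measure]
            )
    return out


@dataclass
class PairAnalysis:
    pair_id: str
    masking: mi.MaskingResult
    essentiality: ps.EssentialityCall
    single_calls_1: list[PhenotypeCall]
    single_calls_2: list[PhenotypeCall]
    double_calls: list[PhenotypeCall]


def analyze_pair(
    pair_id: str,
    gene1: str,
    gene2: str,
    wells_by_condition: Mapping[str, Sequence[WellObservation]],
    control_wells: Sequence[WellObservation],
    prior_screen_flags: Mapping[str, bool],
    alpha: float = 0.05,
    null: str = "paired",
    vocabulary: Mapping[str, int] | None = None,
) -> PairAnalysis:
    """Score one pair through masking inference and essentiality.

    Quantitative rank tests are run for pairs nominated by the
    qualitative escalation rule (the double knockdown presents a
    stronger phenotype than both singles), matching the candidate ->
    quantitative-confirmation structure of the screen.
    """
    calls_1 = condition_calls(wells_by_condition[gene1], vocabulary)
    calls_2 = condition_calls(wells_by_condition[gene2], vocabulary)
    calls_12 = condition_calls(wells_by_condition[pair_id], vocabulary)
    escalation = mi.qualitative_escalation(calls_1, calls_2, calls_12)
    measure_tests: list[mi.MeasureTest] = []
    if escalation:
        fit_1 = condition_fitness(gene1, wells_by_condition[gene1], control_wells)
        fit_2 = condition_fitness(gene2, wells_by_condition[gene2], control_wells)
        fit_12 = condition_fitness(
            pair_id, wells_by_condition[pair_id], control_wells
        )
        for measure in mi.MEASURES:
            if measure not in fit_1 or measure not in fit_2 or measure not in fit_12:
                continue
            w1, w2, w12 = fit_1[measure], fit_2[measure], fit_12[measure]
            if min(len(w1.w_values), len(w2.w_values), len(w12.w_values)) < (
                mi.MIN_REPLICATES
            ):
                continue
            p, significant = mi.quantitative_masking_test(
                w1, w2, w12, alpha=alpha, null=null
            )
            measure_tests.append(
                mi.MeasureTest(
                    measure=measure,
                    w1_mean=w1.mean,
                    w2_mean=w2.mean,
                    expected=w1.mean * w2.mean,
                    observed_mean=w12.mean,
                    p_value=p,
                    significant=significant,
                )
            )
    masking = mi.classify_masking(
        pair_id, calls_1, calls_2, measure_tests, escalation
    )
    essentiality = ps.classify_pair_essential(
        pair_id, gene1, gene2, prior_screen_flags, masking.call
    )
    return PairAnalysis(
        pair_id=pair_id,
        masking=masking,
        essentiality=essentiality,
        single_calls_1=calls_1,
        single_calls_2=calls_2,
        double_calls=calls_12,
    )
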