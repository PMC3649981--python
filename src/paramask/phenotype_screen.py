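"""Scoring of replicate-level RNAi wells into qualitative phenotype calls.

The screen model follows the standard C. elegans RNAi-by-feeding design:
P0 mothers are fed dsRNA-expressing bacteria and scored for fertility
(Ste: sterile, Lbd: low brood) and for embryonic lethality among their F1
brood (Emb); P0s and F1s are additionally scored for a controlled
vocabulary of post-embryonic phenotypes. A phenotype is called penetrant
for a condition when at least one replicate reaches a penetrance of 10%
in the F1 population, or 50% among the P0 mothers.

Essentiality here is operational: a gene or pair is "essential" when any
observable defect appears upon knockdown under the screen's conditions.
A duplicate pair is classified essential if either member had a knockdown
phenotype in prior genome-wide screens, or if the pair shows phenotype
masking in the double-knockdown data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import yaml

__all__ = [
    "PHENOTYPE_VOCABULARY",
    "STAGE_RANKS",
    "QualitativeObservation",
    "WellObservation",
    "PhenotypeCall",
    "EssentialityCall",
    "load_vocabulary",
    "score_brood_and_lethality",
    "assign_penetrant_calls",
    "has_knockdown_phenotype",
    "classify_pair_essential",
    "concordance",
]

#: Controlled phenotype vocabulary with severity ranks used for the
#: qualitative ordering. Higher rank = more severe class of defect:
#: lethality/arrest classes outrank sterility, which outranks growth,
#: which outranks morphology/behaviour defects. The ordering is a
#: configurable convention (only relative order matters downstream).
PHENOTYPE_VOCABULARY: dict[str, int] = {
    # morphology / behaviour
    "Lon": 1, "Sma": 1, "Dpy": 1, "Bmd": 1, "Bli": 1, "Mlt": 1,
    "Him": 1, "Pvl": 1, "Muv": 1, "Egl": 1, "Ooc": 1,
    "Unc": 2, "Prz": 2, "Sck": 2, "Rup": 2, "Stp": 2,
    # growth
    "Gro": 3,
    # fertility
    "Lbd": 4, "Ste": 5,
    # lethality
    "Adl": 6, "Lvl": 6, "Emb": 6,
}

#: Developmental stages, earliest first. An earlier stage of the same
#: phenotype is the more severe observation.
STAGE_RANKS: dict[str, int] = {"L1": 1, "L2": 2, "L3": 3, "L4": 4, "Adult": 5}

#: Penetrance thresholds per scored generation.
F1_PENETRANCE_THRESHOLD = 0.10
P0_PENETRANCE_THRESHOLD = 0.50


def load_vocabulary(path) -> dict[str, int]:
    """Load a phenotype-code -> severity-rank mapping from YAML."""
    with open(path) as fh:
        vocab = yaml.safe_load(fh)
    if not isinstance(vocab, dict):
        raise ValueError(f"{path}: expected a mapping of code -> severity rank")
    return {str(k): int(v) for k, v in vocab.items()}


@dataclass(frozen=True)
class QualitativeObservation:
    """One qualitative phenotype observation within a well."""

    code: str
    penetrance: float
    stage: str | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.penetrance <= 1.0):
            raise ValueError(f"penetrance outside [0,1] for {self.code}")


@dataclass
class WellObservation:
    """Replicate-level counts and qualitative observations for one well."""

    condition_id: str
    replicate_index: int
    generation: str  # "P0" or "F1"
    brood_count: int = 0
    unhatched_count: int = 0
    f1_total: int = 0
    postembryonic_dead: int = 0
    morphology_abnormal: int = 0
    qualitative_calls: list[QualitativeObservation] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.unhatched_count > self.f1_total:
            raise ValueError(
                f"{self.condition_id}: unhatched_count exceeds f1_total"
            )
        if min(
            self.brood_count,
            self.unhatched_count,
            self.f1_total,
            self.postembryonic_dead,
            self.morphology_abnormal,
        ) < 0:
            raise ValueError(f"{self.condition_id}: negative count")


@dataclass(frozen=True)
class PhenotypeCall:
    """A penetrant phenotype call for a condition."""

    condition_id: str
    phenotype_code: str
    penetrant: bool
    severity_rank: int
    stage_rank: int | None = None


@dataclass(frozen=True)
class EssentialityCall:
    condition_id: str
    label: str  # "essential" | "non_essential"
    coverage_warning: bool = False


def score_brood_and_lethality(
    obs: WellObservation,
    ste_threshold: int = 10,
    lbd_threshold: int = 30,
    emb_fraction: float = 0.10,
    emb_min_brood: int = 10,
) -> set[str]:
    """Fertility and embryonic-lethality calls from one well's counts.

    Ste (sterile) when brood < 10; Lbd (low brood) when 10 <= brood < 30
    (the intervals nest, so Ste takes precedence); Emb when at least 10%
    of a brood of at least ``emb_min_brood`` failed to hatch. Raises on
    the inconsistent state unhatched > 0 with f1_total == 0.
    """
    if obs.f1_total == 0 and obs.unhatched_count > 0:
        raise ValueError(
            f"{obs.condition_id}: unhatched embryos recorded with f1_total=0"
        )
    codes: set[str] = set()
    if obs.brood_count < ste_threshold:
        codes.add("Ste")
    elif obs.brood_count < lbd_threshold:
        codes.add("Lbd")
    if (
        obs.f1_total >= emb_min_brood
        and obs.unhatched_count / obs.f1_total >= emb_fraction
    ):
        codes.add("Emb")
    return codes


def assign_penetrant_calls(
    replicates: Sequence[WellObservation],
    vocabulary: Mapping[str, int] | None = None,
    f1_threshold: float = F1_PENETRANCE_THRESHOLD,
    p0_threshold: float = P0_PENETRANCE_THRESHOLD,
) -> list[PhenotypeCall]:
    """Penetrant phenotype calls for one condition across replicates.

    A phenotype is called iff any replicate reaches the penetrance
    threshold of its scored generation (>=10% of the F1 population, or
    >=50% of P0 mothers). For called phenotypes with staged observations,
    the earliest penetrant stage is retained (most severe presentation).
    """
    vocab = PHENOTYPE_VOCABULARY if vocabulary is None else vocabulary
    if not replicates:
        return []
    condition = replicates[0].condition_id
    called: dict[str, int | None] = {}
    for obs in replicates:
        if obs.condition_id != condition:
            raise ValueError("replicates span multiple conditions")
        threshold = p0_threshold if obs.generation == "P0" else f1_threshold
        for q in obs.qualitative_calls:
            if q.code not in vocab:
                raise ValueError(f"unknown phenotype code {q.code!r}")
            if q.stage is not None and q.stage not in STAGE_RANKS:
                raise ValueError(f"unknown stage label {q.stage!r}")
            if q.penetrance >= threshold:
                stage_rank = STAGE_RANKS[q.stage] if q.stage else None
                if q.code not in called:
                    called[q.code] = stage_rank
                else:
                    prev = called[q.code]
                    if stage_rank is not None and (prev is None or stage_rank < prev):
                        called[q.code] = stage_rank
    return [
        PhenotypeCall(
            condition_id=condition,
            phenotype_code=code,
            penetrant=True,
            severity_rank=vocab[code],
            stage_rank=stage,
        )
        for code, stage in sorted(called.items())
    ]


def has_knockdown_phenotype(calls: Iterable[PhenotypeCall]) -> bool:
    """Any apparent phenotypic defect: the call set is non-empty."""
    return any(c.penetrant for c in calls)


def classify_pair_essential(
    pair_id: str,
    gene1: str,
    gene2: str,
    prior_screen_flags: Mapping[str, bool],
    masking_call: str,
) -> EssentialityCall:
    """Classify a duplicate pair as essential or non-essential.

    Essential iff (i) either member had a knockdown phenotype in the
    prior genome-wide screens (restricted upstream to genes covered by a
    uniquely-targeting reagent), or (ii) the pair shows phenotype masking
    (``masking_call`` != "none"). If neither gene has prior-screen
    coverage the classification is still returned but carries a coverage
    warning.
    """
    covered = [g for g in (gene1, gene2) if g in prior_screen_flags]
    prior = any(prior_screen_flags.get(g, False) for g in (gene1, gene2))
    essential = prior or masking_call != "none"
    return EssentialityCall(
        condition_id=pair_id,
        label="essential" if essential else "non_essential",
        coverage_warning=not covered,
    )


def concordance(
    calls_a: Mapping[str, bool], calls_b: Mapping[str, bool]
) -> float:
    """Fraction of genes positive in reference screen b also positive in a."""
    reference = [g for g, positive in calls_b.items() if positive]
    if not reference:
        raise ValueError("empty reference set: no positive calls in screen b")
    detected = sum(1 for g in reference if calls_a.get(g, False))
    return detected / len(reference)
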