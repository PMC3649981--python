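"""Synthetic genomes, screens, alignments and trees with known truth.

The generator encodes the evolutionary dynamics under study as explicit
rate ratios so that every downstream stage of the pipeline can be
exercised against an analytically known expectation:

* **Duplication bias.** Each duplication event picks a source gene with
  weight ``duplication_bias`` (beta) for non-essential genes and 1 for
  essential genes, so the probability that a new pair is essential is

      q = p / (p + (1 - p) * beta),     p = genome essentiality rate.

* **Retention bias.** After its origin epoch, a pair survives each
  subsequent epoch boundary with probability (1 - loss) for essential
  pairs and (1 - gamma * loss) for non-essential pairs, where
  ``retention_bias`` (gamma) > 1 makes non-essential duplicates more
  readily lost. The essential fraction among survivors of age ``a``
  epochs is therefore

      q_a = q * se**a / (q * se**a + (1 - q) * sn**a)

  with se, sn the per-epoch survival probabilities. These closed forms
  (``expected_essential_fraction``) are the oracle for end-to-end
  recovery tests: young pairs are depleted of essential genes relative
  to the genome and older survivors are enriched relative to young ones.

* **Divergence.** Expression levels are log-normal, with essential genes
  expressed higher on average; the nonsynonymous divergence rate of a
  pair decreases with expression, and divergence accrues with age.

* **Masking.** Surviving essential pairs retain phenotype masking with
  probability exp(-masking_decay * Ka): functional redundancy decays as
  the pair diverges. Masked pairs show no single-knockdown defect but a
  synergistic double-knockdown defect.

Every emitter is deterministic given the seed, and emits the plain-text
formats consumed by the analysis modules (tabular alignment files, codon
FASTA, Newick trees plus species maps, replicate screen tables with 111
control wells).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .evolution_rates import DEGENERACY, _STOPS
from .phenotype_screen import QualitativeObservation, WellObservation

__all__ = [
    "SimParams",
    "SimGene",
    "SimPair",
    "GroundTruth",
    "simulate_history",
    "expected_essential_fraction",
    "emit_hit_table",
    "emit_codon_alignments",
    "emit_gene_trees",
    "emit_screen_tables",
    "wells_from_frame",
    "write_screen_tsv",
    "read_screen_tsv",
]

#: ordered oldest -> youngest; ages are epoch labels of the origin event
EPOCHS = ("Eukaryota", "Bilateria", "Caenorhabditis", "Celegans")

#: time depth of each epoch's midpoint, in arbitrary divergence units,
#: used to scale accrued Ka with age
EPOCH_AGE_UNITS = {
    "Eukaryota": 4.5,
    "Bilateria": 3.0,
    "Caenorhabditis": 1.5,
    "Celegans": 0.5,
}


@dataclass
class SimParams:
    """Study conditions for the generator.

    Defaults encode the screened system: a genome knockdown-phenotype
    rate of 17.7%, strong duplication bias toward non-essential genes
    and a weaker retention bias toward essential pairs, 3-5 replicate
    wells with ~10% replicate noise, and 111 control animals.
    """

    n_genes: int = 3000
    p_essential: float = 0.177
    duplication_bias: float = 5.0  # beta: non-essential : essential fixation
    retention_bias: float = 3.0  # gamma: non-essential : essential loss
    #: duplication events per epoch, oldest first; sized so that roughly
    #: 2000 pairs survive with an age mix dominated by the middle epoch
    epoch_events: Mapping[str, int] = field(
        default_factory=lambda: {
            "Eukaryota": 540,
            "Bilateria": 490,
            "Caenorhabditis": 2200,
            "Celegans": 500,
        }
    )
    base_loss_rate: float = 0.15  # per-epoch loss probability, essential pairs
    masking_decay: float = 5.0  # exp(-decay * Ka) retention of masking
    masking_effect: float = 0.5  # double-knockdown fitness multiplier m
    replicate_count: int = 5
    noise_cv: float = 0.10
    n_controls: int = 111
    #: log2 expression means for essential / non-essential genes and sd
    log2_expression_essential: float = 11.66
    log2_expression_nonessential: float = 8.60
    log2_expression_sd: float = 1.5
    #: divergence-rate model: ka_rate = ka_rate_scale * 2**(-expression_exponent
    #: * (log2expr - 10)), accrued over EPOCH_AGE_UNITS with lognormal spread
    ka_rate_scale: float = 0.05
    expression_exponent: float = 0.15
    ka_lognorm_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.p_essential < 1.0):
            raise ValueError("p_essential must be in (0, 1)")
        if self.duplication_bias <= 0 or self.retention_bias <= 0:
            raise ValueError("bias ratios must be positive")
        if not (0.0 <= self.base_loss_rate <= 1.0):
            raise ValueError("base_loss_rate must be in [0, 1]")
        if self.retention_bias * self.base_loss_rate > 1.0:
            raise ValueError(
                "retention_bias * base_loss_rate exceeds 1: non-essential "
                "per-epoch loss probability is not a probability"
            )
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")
        if not (0.0 < self.masking_effect <= 1.0):
            raise ValueError("masking_effect must be in (0, 1]")
        for epoch in self.epoch_events:
            if epoch not in EPOCHS:
                raise ValueError(f"unknown epoch {epoch!r}")

    def survival(self) -> tuple[float, float]:
        """Per-epoch survival probabilities (essential, non-essential)."""
        se = 1.0 - self.base_loss_rate
        sn = 1.0 - min(1.0, self.retention_bias * self.base_loss_rate)
        return se, sn

    @property
    def q_new_pair_essential(self) -> float:
        """P(new pair is essential) under the duplication bias."""
        p, beta = self.p_essential, self.duplication_bias
        return p / (p + (1.0 - p) * beta)


@dataclass
class SimGene:
    gene_id: str
    essential: bool
    log2_expression: float
    single_fitness: float  # fitness on single knockdown (1 = wild type)


@dataclass
class SimPair:
    pair_id: str
    gene1: str
    gene2: str
    age_class: str
    essential: bool
    masked: bool
    ka_true: float
    log2_expression: float
    w1_true: float
    w2_true: float


@dataclass
class GroundTruth:
    genes: dict[str, SimGene]
    pairs: list[SimPair]

    def pairs_by_age(self) -> dict[str, list[SimPair]]:
        out: dict[str, list[SimPair]] = {e: [] for e in EPOCHS}
        for p in self.pairs:
            out[p.age_class].append(p)
        return out


def expected_essential_fraction(params: SimParams, age_class: str) -> float:
    """Closed-form essential fraction among survivors of one age class."""
    q = params.q_new_pair_essential
    se, sn = params.survival()
    a = EPOCHS.index(age_class)
    rounds = len(EPOCHS) - 1 - a  # loss rounds survived since origin
    num = q * se**rounds
    return num / (num + (1.0 - q) * sn**rounds)


def _draw_gene(
    rng: np.random.Generator, gene_id: str, essential: bool, params: SimParams
) -> SimGene:
    mu = (
        params.log2_expression_essential
        if essential
        else params.log2_expression_nonessential
    )
    log2expr = rng.normal(mu, params.log2_expression_sd)
    w = rng.uniform(0.2, 0.8) if essential else 1.0
    return SimGene(
        gene_id=gene_id,
        essential=essential,
        log2_expression=log2expr,
        single_fitness=w,
    )


def simulate_history(params: SimParams) -> GroundTruth:
    """Simulate duplication/loss history with essentiality biases.

    A background genome of single-copy genes is drawn first (essential
    with probability ``p_essential``). Each duplication event then
    samples a source gene by fixation weight (beta-fold higher for
    non-essential sources) and creates a pair of fresh gene copies that
    inherit the source's essentiality and expression; re-sampling the
    same source models re-duplication. After each epoch boundary every
    extant pair is lost independently with its essentiality-specific
    loss probability. Survivors carry their origin epoch as true age,
    accrue divergence with age at an expression-dependent rate, and
    (when essential) retain masking with probability exp(-decay * Ka).
    """
    rng = np.random.default_rng(params.seed)
    genes: dict[str, SimGene] = {}
    sources: list[SimGene] = []
    for i in range(params.n_genes):
        g = _draw_gene(
            rng, f"G{i:05d}", bool(rng.random() < params.p_essential), params
        )
        genes[g.gene_id] = g
        sources.append(g)
    weights = np.array(
        [1.0 if g.essential else params.duplication_bias for g in sources]
    )
    weights /= weights.sum()
    se, sn = params.survival()
    pairs: list[SimPair] = []
    counter = 0
    for epoch_idx, epoch in enumerate(EPOCHS):
        n_events = int(params.epoch_events.get(epoch, 0))
        if n_events == 0:
            continue
        rounds = len(EPOCHS) - 1 - epoch_idx
        chosen = rng.choice(len(sources), size=n_events, replace=True, p=weights)
        for src_idx in chosen:
            src = sources[src_idx]
            survival = se if src.essential else sn
            if rng.random() >= survival**rounds:
                continue  # pair lost before the present
            counter += 1
            pair_id = f"P{counter:05d}"
            copies = []
            for suffix in ("a", "b"):
                g = SimGene(
                    gene_id=f"{pair_id}{suffix}",
                    essential=src.essential,
                    log2_expression=src.log2_expression
                    + rng.normal(0.0, 0.25),
                    single_fitness=src.single_fitness,
                )
                genes[g.gene_id] = g
                copies.append(g)
            ka_rate = params.ka_rate_scale * 2.0 ** (
                -params.expression_exponent * (src.log2_expression - 10.0)
            )
            ka = (
                EPOCH_AGE_UNITS[epoch]
                * ka_rate
                * rng.lognormal(0.0, params.ka_lognorm_sd)
            )
            ka = float(min(ka, 1.5))
            masked = bool(
                src.essential
                and rng.random() < math.exp(-params.masking_decay * ka)
            )
            if masked:
                # full masking: each paralog covers for the other, so the
                # single knockdowns look wild type
                w1 = w2 = 1.0
            else:
                w1 = copies[0].single_fitness
                w2 = copies[1].single_fitness
            copies[0].single_fitness = w1
            copies[1].single_fitness = w2
            pairs.append(
                SimPair(
                    pair_id=pair_id,
                    gene1=copies[0].gene_id,
                    gene2=copies[1].gene_id,
                    age_class=epoch,
                    essential=src.essential,
                    masked=masked,
                    ka_true=ka,
                    log2_expression=src.log2_expression,
                    w1_true=w1,
                    w2_true=w2,
                )
            )
    return GroundTruth(genes=genes, pairs=pairs)


# ---------------------------------------------------------------------------
# alignment-evidence emitter


def _evalue_exponent(divergence: float, rng: np.random.Generator) -> float:
    """Fixed monotone map from divergence to log10 e-value, with jitter.

    Only the ordering matters downstream (reciprocal-best-hit and
    isolation logic), so the slope is an arbitrary convention.
    """
    base = -150.0 * (1.0 - min(divergence, 1.0))
    return float(np.clip(base + rng.normal(0.0, 2.0), -180.0, -10.0))


def emit_hit_table(
    truth: GroundTruth,
    params: SimParams,
    path,
    p_close_third: float = 0.05,
    p_distant_third: float = 0.10,
    protein_length: int = 400,
) -> dict[str, int]:
    """Write a 12-column tabular alignment file for the simulated pairs.

    Each true pair gets mutual hits whose e-value follows the monotone
    divergence map; a fraction of pairs additionally get a shared third
    gene that is nearly as close as the pair itself (to exercise the
    isolation filter) or a distant shared hit. Returns the protein-length
    table needed to parse the file back.
    """
    rng = np.random.default_rng(params.seed + 1)
    lengths: dict[str, int] = {}
    rows: list[str] = []
    span = int(protein_length * 0.9)

    def add_row(q: str, s: str, log10e: float) -> None:
        evalue = 10.0**log10e
        pident = max(20.0, 100.0 + 0.45 * log10e)
        bitscore = max(30.0, -1.8 * log10e)
        rows.append(
            f"{q}\t{s}\t{pident:.1f}\t{span}\t0\t0\t1\t{span}\t1\t{span}\t"
            f"{evalue:.3g}\t{bitscore:.1f}"
        )

    for pair in truth.pairs:
        for g in (pair.gene1, pair.gene2):
            lengths[g] = protein_length
        log10e = _evalue_exponent(pair.ka_true, rng)
        add_row(pair.gene1, pair.gene2, log10e)
        add_row(pair.gene2, pair.gene1, log10e)
        u = rng.random()
        if u < p_close_third:
            third = f"{pair.pair_id}t"
            lengths[third] = protein_length
            third_exp = 0.90 * log10e  # inside the pair's log-similarity
            add_row(pair.gene1, third, third_exp)
            add_row(pair.gene2, third, third_exp + rng.uniform(0.0, 1.0))
        elif u < p_close_third + p_distant_third:
            third = f"{pair.pair_id}t"
            lengths[third] = protein_length
            add_row(pair.gene1, third, -5.0)
            add_row(pair.gene2, third, -4.0)
    with open(path, "w") as fh:
        fh.write("\n".join(rows) + ("\n" if rows else ""))
    return lengths


# ---------------------------------------------------------------------------
# codon-alignment emitter

_SENSE_CODONS = sorted(DEGENERACY)
_TRANSITION_OF = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS_OF = {
    "A": ("C", "T"),
    "G": ("C", "T"),
    "C": ("A", "G"),
    "T": ("A", "G"),
}


def _apply_hit(
    codons: list[str],
    site: int,
    transition: bool,
    rng: np.random.Generator,
) -> None:
    """Apply one substitution at a flat site index, rejecting stops."""
    ci, pos = divmod(site, 3)
    codon = codons[ci]
    base = codon[pos]
    if transition:
        new_base = _TRANSITION_OF[base]
    else:
        new_base = _TRANSVERSIONS_OF[base][rng.integers(2)]
    new_codon = codon[:pos] + new_base + codon[pos + 1 :]
    if new_codon in _STOPS:
        return  # nonsense substitutions are purged
    codons[ci] = new_codon


def _evolve_branch(
    codons: list[str],
    d_nonsyn: float,
    d_syn: float,
    kappa: float,
    rng: np.random.Generator,
) -> list[str]:
    """Evolve one branch with class-specific substitution distances.

    Sites are classified by degeneracy in the starting sequence. At
    nondegenerate sites the full K2P process runs at distance d_nonsyn;
    at twofold sites transversions (nonsynonymous there) run at the K2P
    transversional share of d_nonsyn and transitions (synonymous) at
    d_syn's transitional share; at fourfold sites the full process runs
    at distance d_syn.
    """
    codons = list(codons)
    ts_frac = kappa / (kappa + 2.0)
    tv_frac = 2.0 / (kappa + 2.0)
    for ci, codon in enumerate(codons):
        classes = DEGENERACY[codon]
        for pos in range(3):
            site = 3 * ci + pos
            cls = classes[pos]
            if cls == 0:
                n_ts = rng.poisson(d_nonsyn * ts_frac)
                n_tv = rng.poisson(d_nonsyn * tv_frac)
            elif cls == 2:
                n_ts = rng.poisson(d_syn * ts_frac)
                n_tv = rng.poisson(d_nonsyn * tv_frac)
            else:
                n_ts = rng.poisson(d_syn * ts_frac)
                n_tv = rng.poisson(d_syn * tv_frac)
            for _ in range(n_ts):
                _apply_hit(codons, site, True, rng)
            for _ in range(n_tv):
                _apply_hit(codons, site, False, rng)
    return codons


def _random_coding_sequence(n_codons: int, rng: np.random.Generator) -> list[str]:
    idx = rng.integers(0, len(_SENSE_CODONS), size=n_codons)
    return [_SENSE_CODONS[i] for i in idx]


def emit_codon_alignment(
    target_ka: float,
    n_codons: int,
    rng: np.random.Generator,
    kappa: float = 2.0,
    syn_distance: float | None = None,
) -> tuple[str, str]:
    """Evolve a codon-aligned sequence pair with a target Ka.

    An ancestral sequence of random sense codons is evolved down two
    branches, each carrying half the pairwise distance. The
    nondegenerate-site distance is scaled so that the expected Li-1993
    estimate equals ``target_ka``: the estimator averages the full
    distance at L0 sites with only the transversional share at L2
    sites, so the per-site distance is target * (L0 + L2) /
    (L0 + L2 * 2/(kappa+2)). Synonymous divergence defaults to
    3 * target_ka (capped at 1.0).
    """
    if target_ka < 0:
        raise ValueError("target_ka must be non-negative")
    codons = _random_coding_sequence(n_codons, rng)
    if syn_distance is None:
        syn_distance = min(3.0 * target_ka, 1.0)
    counts = {0: 0, 2: 0, 4: 0}
    for codon in codons:
        for cls in DEGENERACY[codon]:
            counts[cls] += 1
    L0, L2 = counts[0], counts[2]
    tv_frac = 2.0 / (kappa + 2.0)
    scale = (L0 + L2) / (L0 + L2 * tv_frac) if (L0 + L2) else 1.0
    d_nonsyn = target_ka * scale
    left = _evolve_branch(codons, d_nonsyn / 2, syn_distance / 2, kappa, rng)
    right = _evolve_branch(codons, d_nonsyn / 2, syn_distance / 2, kappa, rng)
    return "".join(left), "".join(right)


def emit_codon_alignments(
    truth: GroundTruth,
    params: SimParams,
    outdir,
    n_codons: int = 500,
    kappa: float = 2.0,
) -> dict[str, str]:
    """Write one paired codon-alignment FASTA per pair; returns a map of
    pair id -> file path."""
    import os

    rng = np.random.default_rng(params.seed + 2)
    os.makedirs(outdir, exist_ok=True)
    paths: dict[str, str] = {}
    for pair in truth.pairs:
        s1, s2 = emit_codon_alignment(pair.ka_true, n_codons, rng, kappa=kappa)
        path = os.path.join(outdir, f"{pair.pair_id}.fasta")
        with open(path, "w") as fh:
            fh.write(f">{pair.gene1}\n{s1}\n>{pair.gene2}\n{s2}\n")
        paths[pair.pair_id] = path
    return paths


# ---------------------------------------------------------------------------
# gene-tree emitter

_SPECIES_FOR_AGE = {
    "Celegans": ["Caenorhabditis_elegans"],
    "Caenorhabditis": ["Caenorhabditis_elegans", "Caenorhabditis_briggsae"],
    "Bilateria": ["Caenorhabditis_elegans", "Homo_sapiens"],
    "Eukaryota": ["Caenorhabditis_elegans", "Saccharomyces_cerevisiae"],
}

#: reference species taxonomy used by the generated fixtures
DEFAULT_TAXONOMY_NEWICK = (
    "((((Caenorhabditis_elegans,(Caenorhabditis_briggsae,"
    "Caenorhabditis_remanei))Caenorhabditis,Drosophila_melanogaster,"
    "Homo_sapiens)Bilateria,Saccharomyces_cerevisiae,"
    "Arabidopsis_thaliana)Eukaryota);"
)


def emit_gene_tree(
    pair: SimPair,
    rng: np.random.Generator,
    high_support: bool = True,
) -> tuple[str, dict[str, str]]:
    """Newick tree + species map placing the pair's LCA at its true age.

    Supported fixtures draw all bootstraps in [85, 100]; unsupported
    fixtures draw the LCA bootstrap in [30, 60] so the strong-support
    rule fails.
    """
    g1, g2 = pair.gene1, pair.gene2

    def bs(low: int = 85, high: int = 100) -> int:
        return int(rng.integers(low, high + 1))

    lca_bs = bs() if high_support else bs(30, 60)
    species_map = {}
    if pair.age_class == "Celegans":
        out = f"{pair.pair_id}_cb"
        newick = f"(({g1}:0.1,{g2}:0.1){lca_bs}:0.1,{out}:0.3);"
        species_map = {
            g1: "Caenorhabditis_elegans",
            g2: "Caenorhabditis_elegans",
            out: "Caenorhabditis_briggsae",
        }
    else:
        # the pair's LCA spans C. elegans plus the age-defining species
        other = _SPECIES_FOR_AGE[pair.age_class][1]
        o1, o2 = f"{pair.pair_id}_o1", f"{pair.pair_id}_o2"
        sub_bs1, sub_bs2 = bs(), bs()
        newick = (
            f"(({g1}:0.1,{o1}:0.1){sub_bs1}:0.1,"
            f"({g2}:0.1,{o2}:0.1){sub_bs2}:0.1){lca_bs}:0.1;"
        )
        species_map = {
            g1: "Caenorhabditis_elegans",
            g2: "Caenorhabditis_elegans",
            o1: other,
            o2: other,
        }
    return newick, species_map


def emit_gene_trees(
    truth: GroundTruth,
    params: SimParams,
    releases: Sequence[str] = ("4", "5", "6"),
    frac_low_support: float = 0.0,
) -> dict[str, dict[str, tuple[str, dict[str, str]]]]:
    """Per-pair, per-release (newick, species map) fixtures.

    With ``frac_low_support`` > 0 that fraction of pairs gets low
    bootstraps in every release *and* topologies placed under a single
    release only, so the dating rules return Unknown for them.
    """
    rng = np.random.default_rng(params.seed + 3)
    out: dict[str, dict[str, tuple[str, dict[str, str]]]] = {}
    for pair in truth.pairs:
        low = rng.random() < frac_low_support
        per_release = {}
        use_releases = releases[-1:] if low else releases
        for rel in use_releases:
            per_release[rel] = emit_gene_tree(pair, rng, high_support=not low)
        out[pair.pair_id] = per_release
    return out


# ---------------------------------------------------------------------------
# screen-table emitter

_SCREEN_COLUMNS = [
    "condition_id",
    "replicate",
    "generation",
    "brood_count",
    "unhatched_count",
    "f1_total",
    "postembryonic_dead",
    "morphology_abnormal",
    "qualitative",
]


def _noisy(mean: float, cv: float, rng: np.random.Generator) -> float:
    if cv == 0:
        return mean
    return max(0.0, rng.normal(mean, cv * max(mean, 1e-12)))


def _defect_fraction(
    w: float, cv: float, rng: np.random.Generator, background: float = 0.02
) -> float:
    """Observed defect fraction for a well of true fitness w.

    Replicate noise is proportional to the true defect (healthy wells do
    not fluctuate into strong defects) plus a small background defect
    rate, as in real screen controls.
    """
    d = 1.0 - w
    if cv > 0:
        d = d * (1.0 + rng.normal(0.0, cv)) + background * rng.random()
    return float(min(max(d, 0.0), 1.0))


def _well_row(
    condition: str,
    replicate: int,
    w: float,
    cv: float,
    rng: np.random.Generator,
    brood0: int = 250,
) -> dict:
    """One replicate well whose four quantitative measures all reflect
    fitness w (a defect depresses brood, hatching, post-embryonic
    survival and morphology together)."""
    brood = int(round(_noisy(brood0 * w, cv, rng)))
    f1_total = brood
    unhatched = int(round(f1_total * _defect_fraction(w, cv, rng)))
    pe_dead = int(round(f1_total * _defect_fraction(w, cv, rng)))
    morph_defect = _defect_fraction(w, cv, rng)
    abnormal = int(round(f1_total * morph_defect))
    quals = []
    if morph_defect >= 0.10:
        quals.append(f"Gro:{morph_defect:.3f}:L3")
    return {
        "condition_id": condition,
        "replicate": replicate,
        "generation": "F1",
        "brood_count": brood,
        "unhatched_count": min(unhatched, f1_total),
        "f1_total": f1_total,
        "postembryonic_dead": min(pe_dead, f1_total),
        "morphology_abnormal": min(abnormal, f1_total),
        "qualitative": ";".join(quals),
    }


def emit_screen_tables(
    truth: GroundTruth, params: SimParams
) -> pd.DataFrame:
    """Replicate wells for singles, doubles and 111 control animals.

    Singles are drawn around each gene's true single-knockdown fitness;
    doubles around w1 * w2 * m with m = ``masking_effect`` for truly
    masked pairs and m = 1 otherwise (exactly multiplicative); controls
    around fitness 1.
    """
    rng = np.random.default_rng(params.seed + 4)
    rows: list[dict] = []
    for i in range(params.n_controls):
        rows.append(_well_row("control", i + 1, 1.0, params.noise_cv, rng))
    for pair in truth.pairs:
        g1 = truth.genes[pair.gene1]
        g2 = truth.genes[pair.gene2]
        m = params.masking_effect if pair.masked else 1.0
        w12 = pair.w1_true * pair.w2_true * m
        for rep in range(1, params.replicate_count + 1):
            rows.append(
                _well_row(pair.gene1, rep, pair.w1_true, params.noise_cv, rng)
            )
            rows.append(
                _well_row(pair.gene2, rep, pair.w2_true, params.noise_cv, rng)
            )
            rows.append(_well_row(pair.pair_id, rep, w12, params.noise_cv, rng))
    return pd.DataFrame(rows, columns=_SCREEN_COLUMNS)


def _parse_qualitative(cell: str) -> list[QualitativeObservation]:
    calls = []
    if not cell or (isinstance(cell, float) and math.isnan(cell)):
        return calls
    for token in str(cell).split(";"):
        if not token:
            continue
        parts = token.split(":")
        code, penetrance = parts[0], float(parts[1])
        stage = parts[2] if len(parts) > 2 and parts[2] else None
        calls.append(
            QualitativeObservation(code=code, penetrance=penetrance, stage=stage)
        )
    return calls


def wells_from_frame(frame: pd.DataFrame) -> dict[str, list[WellObservation]]:
    """Group a screen table into per-condition WellObservation lists."""
    out: dict[str, list[WellObservation]] = {}
    for row in frame.itertuples(index=False):
        obs = WellObservation(
            condition_id=row.condition_id,
            replicate_index=int(row.replicate),
            generation=str(row.generation),
            brood_count=int(row.brood_count),
            unhatched_count=int(row.unhatched_count),
            f1_total=int(row.f1_total),
            postembryonic_dead=int(row.postembryonic_dead),
            morphology_abnormal=int(row.morphology_abnormal),
            qualitative_calls=_parse_qualitative(row.qualitative),
        )
        out.setdefault(obs.condition_id, []).append(obs)
    return out


def write_screen_tsv(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, sep="\t", index=False)


def read_screen_tsv(path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", keep_default_na=False)
    return frame[_SCREEN_COLUMNS]
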