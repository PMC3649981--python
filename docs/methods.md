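# Methods

This note documents the models, rules and numerical conventions
implemented in `paramask`, the parameters that matter, and what the
synthetic-data generator does and does not emulate.

## Paralog discovery

Alignment evidence enters as the standard 12-column tabular format plus
per-gene protein lengths (longest isoform). Multiple HSPs per directed
gene pair are reduced to the single most significant HSP (smallest
e-value, ties by larger bitscore); coverage is that HSP's span divided
by the protein length on each side. Summed-HSP coverage is a defensible
alternative; the single-best-HSP convention was chosen because HSP
merging rules are aligner-specific and the single span is reproducible.

A pair (A, B) is a duplicate pair when each gene is the other's best
non-self hit (ties broken by bitscore, then lexicographic subject id,
for deterministic output), both directed e-values are < 1e-9 and both
coverages are ≥ 0.60 in both directions. The coverage rule is applied
as a filter on the mutual-best pair, not during best-hit selection. The
pair e-value is the smaller (more significant) of the two directed
values — a symmetric canonicalisation that is stable to query/subject
asymmetry. Single-copy genes are those with no non-self match below
e-value 0.01 in either direction.

**Isolation value.** Candidate shared hits are third genes matched by
both members at e-value < 0.01; each is scored by the *maximum* of its
two e-values (the weaker match best reflects sequence shared between
the pair members) and the closest shared hit minimises that score.
Isolation = −log10(closest score) / −log10(pair e-value), 0 with no
shared hit, clamped to [0, 1] (a third hit more significant than the
pair hit is possible in principle). E-values of exactly 0 (underflow)
are clamped to 1e-180 before logs so the value is finite and
engine-independent. The retention filter keeps isolation ≤ 0.83
(inclusive).

## Phenotype scoring

Well counts produce fertility and lethality codes: Ste (sterile) when
brood < 10, Lbd (low brood) on the half-open interval [10, 30) — the
thresholds nest, so Ste takes precedence — and Emb (embryonic lethal)
when ≥10% of a brood failed to hatch. Emb additionally requires at
least 10 scored F1s so that tiny broods are not scored for embryonic
lethality (configurable).

Qualitative phenotypes come from a controlled vocabulary (Unc, Prz,
Dpy, Bmd, Sck, Bli, Mlt, Him, Pvl, Muv, Lon, Sma, Gro, Egl, Stp, Adl,
Ooc, Rup, Lvl, plus Ste/Lbd/Emb) and are called penetrant when any
replicate reaches ≥10% penetrance in the F1 population or ≥50% among P0
mothers. Penetrance denominators are carried in the input (fractions
are precomputed by the reader); the scorer does not re-derive them.

Severity ranks order phenotype classes for qualitative comparisons:
lethality/arrest (Emb, Lvl, Adl) > sterility (Ste > Lbd) > growth
(Gro) > locomotion/integrity (Unc, Prz, Sck, Rup, Stp) > morphology
(Dpy, Lon, ...). Only the relative order matters; the table is a
package convention, configurable via YAML, since no complete ordering
is canonical.

## Masking inference

All quantitative measures are oriented so larger = healthier (brood
size, viability fractions, fraction morphologically normal — morphology
is carried as 1 − abnormal fraction) and normalised per replicate by
the mean of the control sample, giving fitness values w that may exceed
1. The multiplicative null for the double knockdown is w₁·w₂.

The rank test compares the observed double-knockdown replicates with an
expected sample built from the single-knockdown replicates, one-sided
(observed smaller). Two constructions are provided:

* `paired` (default): w₁ᵢ·w₂ᵢ, one product per replicate pair. The
  products are mutually independent, and Monte-Carlo calibration
  (10,000 multiplicative-null trials, 5 replicates, 10% CV) puts the
  type-I error at 0.049 for nominal α = 0.05.
* `cross-products`: all w₁ᵢ·w₂ⱼ. This uses every pairing but the 25
  products derive from only 10 independent draws; the internal
  dependence violates the rank-test's independence assumption and
  inflates the type-I error to ≈0.10 in the same calibration. It is
  kept as an option for sensitivity analyses, not as the default.

Exact p-values are used when the pooled sample is ≤ 20 values and
tie-free (replicate counts are tiny), otherwise the normal
approximation with tie correction. A pooled sample with zero spread
(noise-free multiplicative data) carries no rank information and is
accepted outright (p = 1). Each measure is tested at p < 0.05 with no
multiplicity correction; any significant measure contributes masking
evidence. At least 3 replicates per sample are required.

Qualitative escalation is true when the double knockdown has a
penetrant call whose (severity class, stage earliness) strictly exceeds
the strongest call across both singles — an earlier stage of the same
phenotype, or a more severe class, escalates; a penetrant double-only
call with silent singles also escalates. Unstaged calls rank as the
latest stage.

Classification: *none* without quantitative or qualitative evidence;
otherwise *full* if neither single knockdown has any penetrant call,
else *partial*. The end-to-end workflow runs the quantitative tests on
pairs nominated by qualitative escalation, mirroring the two-stage
candidate → quantitative-confirmation structure of real screens; this
keeps the screen-wide false-positive rate far below the per-test α.

## Protein divergence (Ka)

Codon positions are classified by degeneracy under the standard genetic
code: fourfold when all three changes are synonymous, nondegenerate
when none is, twofold otherwise (changes to stop codons count as
nonsynonymous). This generic rule reproduces the protocol's special
cases — isoleucine third positions count as twofold, as do the first
positions of CTA/CTG/TTA/TTG (Leu) and CGA/CGG/AGA/AGG (Arg).

Site counts are averaged over the two sequences; a differing position
contributes one transition or transversion with half-weight to the
class of the site in each sequence (implementations diverge here; the
half-site convention is stated explicitly). Differences in
multi-difference codons are counted position-wise directly, with no
pathway averaging. Gapped or ambiguous codon columns, and stop codons,
are dropped pairwise — the conservative standard. Per class,

    A = −½ ln(1 − 2P − Q) + ¼ ln(1 − 2Q)      B = −½ ln(1 − 2Q)

and Ka = [L₀(A₀+B₀) + L₂B₂] / (L₀+L₂). Non-positive log arguments mark
the estimate saturated (undefined). Half-site weighting and the Ile
convention can shift Ka in the third decimal relative to other
implementations of the same protocol; the conventions above are fixed
and tested. Pair-level evolutionary rate Ka_CeCb is the arithmetic mean
of the two ortholog-comparison estimates and is undefined when either
is saturated. Divergence-trend analyses exclude Ka ≥ 1 downstream.

## Duplication dating

Gene trees are read as rooted Newick with numeric internal labels as
bootstraps; genuinely unrooted inputs (basal polytomy) are
midpoint-rooted with a warning when branch lengths allow. Duplication
versus speciation at a node uses the species-overlap criterion
(children sharing a species ⇒ duplication), a reconstruction of
reconciliation annotations that are not part of the inputs. "No genes
lost" is operationalised as: the node's descendant species set equals
the reference taxonomy's species set for the node's taxonomic level —
a testable proxy for completeness bookkeeping.

The age class of a pair is the taxonomy label of the LCA of the species
below the pair's common-ancestor node; a clade containing only
C. elegans genes is the Celegans class. A call is confident when ≥2 of
the three most recent releases agree (ties broken by the most recent
release), or the most recent release passes the strong-support rule
(bootstrap ≥70% at the LCA and at every path node, speciation-complete
nodes exempt). Pairs split across two families that each contain human,
Drosophila and a Saccharomyces-or-Arabidopsis outgroup date to
Eukaryota. Everything else is Unknown. "Younger" pairs are the Celegans
class; "older" pairs are all other dated classes.

Ortholog inference accepts leaf pairs whose LCA is a speciation node
with bootstrap ≥70% (a root without any support value is exempt, since
Newick roots carry none by construction), restricted to one-to-one
cases.

## Aggregate statistics

Rates are exact rationals; presentation rounds half-up to one decimal
percent, and rounding never feeds back into computation. The 2×2
chi-squared defaults to the Yates continuity correction (the
uncorrected variant is available; both can be reported since sources
rarely state which was used), with a warning directing users to
Fisher's exact test when an expected count is below 5. Equal-frequency
binning sorts stably (boundary ties resolve by input order) and gives
any remainder to the lowest-x bins, for determinism. Logistic trends
are fit by maximum likelihood on unbinned data with Wald p-values;
complete separation is flagged and leaves the p-value undefined. The
expression-controlled model regresses ln(dN+1) (rates of zero are
common, hence the shift) on log₂ expression and a two-level class flag,
after an interaction pretest: when slopes are heterogeneous the class
comparison is marked invalid, though coefficients are still reported.

## Synthetic-data generator

The generator encodes the dynamics under study as two rate ratios over
a background genome with essentiality rate p = 0.177 (the fraction of
single-copy genes with an observable knockdown phenotype):

* duplication bias β = 5 by default: each duplication event samples its
  source gene with weight β for non-essential genes, so a new pair is
  essential with probability q = p / (p + (1−p)β) ≈ 0.041;
* retention bias γ = 3 by default: after its origin epoch a pair
  survives each epoch boundary with probability 1 − 0.15 (essential) or
  1 − γ·0.15 (non-essential), giving the closed-form essential fraction
  q·seᵃ / (q·seᵃ + (1−q)·snᵃ) among survivors of age a.

These closed forms are the oracle for the end-to-end recovery tests.
Sources are drawn with replacement (re-duplication), so q is constant
across events and the closed forms are exact. Epoch event counts
default to (540, 490, 2200, 500) for (Eukaryota, Bilateria,
Caenorhabditis, Celegans), sized so that roughly 2000 pairs survive
with an age mix dominated by the middle epochs, a scale at which the
recovery tests have tight binomial tolerances while the full pipeline
runs in seconds.

Expression is log-normal with log₂ means 11.66 (essential) and 8.60
(non-essential), sd 1.5 — essential genes are the more highly expressed
group. Pair divergence accrues with epoch depth (0.5, 1.5, 3.0, 4.5
arbitrary units, youngest to oldest) at a rate that halves for every
1/0.15 ≈ 6.7 log₂ units of expression, with log-normal spread; this
encodes the expression–rate anticorrelation. Essential pairs retain
masking with probability exp(−5·Ka): redundancy decays with
divergence. Masked pairs present wild-type singles (w = 1) and a
synergistic double knockdown w₁·w₂·m with m = 0.5; unmasked doubles are
exactly multiplicative.

Screen wells carry four quantitative measures per replicate (default 5
replicates, 111 control wells). Brood size is normal with CV =
`noise_cv` (default 10%). Fraction-type measures draw an observed
defect fraction proportional to the true defect (CV on the defect) plus
a ~2% background defect rate: healthy wells fluctuate around health,
as real screen controls do, rather than spuriously crossing penetrance
thresholds. Qualitative growth-defect calls are emitted when a well's
morphology defect reaches 10%.

Alignment evidence uses a fixed monotone map from divergence to log₁₀
e-value (−150·(1−d) with jitter); only the ordering matters to the RBH
and isolation logic. Codon alignments evolve an ancestral random
coding sequence down two branches with class-specific substitution
distances; the nondegenerate-site distance is scaled by
(L₀+L₂)/(L₀+L₂·2/(κ+2)) so the expected Li-1993 estimate equals the
target Ka (twofold sites contribute only their transversional share).
Substitutions creating stop codons are purged, which deflates realized
divergence by ≈3% at Ka = 0.1 — within the generator's stated ±0.01
calibration tolerance. Gene trees place each pair's LCA under the
species combination matching its true age, with bootstraps ≥85 for
supported fixtures and 30–60 for fixtures meant to fail the confidence
rules.

**What the generator does not emulate:** real genome sequence content
and codon usage, correlated phenotype spectra across measures,
population-genetic fixation dynamics beyond the rate-ratio
phenomenology, gene conversion, partial redundancy (masked pairs are
fully masked), and RNAi off-target structure. Passing recovery tests
therefore demonstrate that the pipeline's logic is faithful to its own
model, not that screen data of arbitrary quality would yield unbiased
estimates.

## Known limitations

* The rank test at 3–5 replicates has coarse attainable p-values; the
  α = 0.05 level is honoured but not finely graduated.
* Species-overlap duplication calls can be fooled by lineage sorting or
  horizontal transfer; the completeness proxy for "no genes lost" is
  conservative on sparsely sampled families.
* Ka saturates quickly at high divergence; estimates near saturation
  are flagged rather than extrapolated.
* The ANCOVA assumes homoscedastic normal residuals of ln(dN+1); the
  interaction pretest guards slope heterogeneity only.
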