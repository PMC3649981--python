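# paramask

Analysis tools for **phenotype masking between duplicate genes** in
double-knockdown RNAi screens, built around the *C. elegans* paralog-pair
setting: when a gene's knockdown shows no defect, is the phenotype being
masked by a redundant paralog, or was the gene simply non-essential to
begin with?

The package is aimed at computational biologists analysing systematic
single/double knockdown screens of paralog pairs together with the
comparative-genomic context of those pairs (sequence divergence,
duplication age, expression).

## What it computes

**Paralog pairs.** Pairs are reciprocal best hits in an all-vs-all
protein search (e-value < 10⁻⁹, alignment spanning ≥60% of both
proteins). Pairs with a close third paralog are removed using the
*duplicate isolation value*

```
isolation = -log10(max e-value to closest shared third hit) / -log10(pair e-value)
```

which is 0 for an isolated two-member family and 1 when a third paralog
is as close as the pair itself; pairs with isolation ≤ 0.83 are retained.
RNAi reagent specificity is modelled with primary targets (≥95%
nucleotide identity over ≥100 bp) and secondary targets (≥80% over
≥200 bp): a pair is screenable only if each member has a probe with
exactly one primary and no secondary targets.

**Masking statistic.** With fitness *w* and selection coefficients
*s*ᵢ = 1 − *w*ᵢ for the single knockdowns, the multiplicative null for
the double knockdown is

```
w₁,₂ = (1 − s₁)(1 − s₂) = w₁ · w₂
```

Replicate-level quantitative measures (brood size, embryonic viability,
post-embryonic viability, fraction morphologically normal) are
normalised to control animals, and masking is inferred when the observed
double-knockdown sample is significantly *below* the multiplicative
expectation (one-sided Mann–Whitney U, p < 0.05), or when the double
knockdown shows a qualitatively escalated phenotype (earlier
developmental stage, or a more severe phenotype class, than either
single knockdown). Masking is *full* when neither single knockdown has
any penetrant phenotype, *partial* otherwise. A pair is operationally
*essential* when either member had a prior-screen knockdown phenotype or
the pair shows masking.

**Divergence and age.** Protein divergence Ka between codon-aligned
sequences follows Li's 1993 site-degeneracy protocol with Kimura
two-parameter multiple-hit correction
(Ka = [L₀(A₀+B₀) + L₂B₂] / (L₀+L₂)). Duplication ages are read off
bootstrap-annotated gene trees: the age class
(Celegans < Caenorhabditis < Bilateria < Eukaryota) is the taxonomic
level of the pair's common-ancestor node, accepted when two of the three
most recent tree releases agree or the latest release has ≥70% bootstrap
support along both paths.

**Aggregates.** Exact count rates, 2×2 association tests (chi-squared ±
Yates, exact Fisher), equal-frequency-bin divergence curves, logistic
trends on unbinned data, and an expression-controlled ANCOVA of
ln(dN+1) on log₂ expression with an interaction pretest.

**Synthetic data.** A generator with explicit duplication bias (β: how
much more readily non-essential genes are successfully duplicated) and
retention bias (γ: how much more readily non-essential duplicates are
lost) produces hit tables, codon alignments, gene trees and replicate
screen tables with known ground truth, so the whole pipeline can be
validated against closed-form expectations.

## Worked example

Simulate a genome with duplication bias β = 5 and retention bias γ = 3,
run the screen pipeline, and compare essentiality rates by age with the
generator's closed-form expectations:

```python
import numpy as np
from paramask import synthetic_data as sd, workflow
from paramask.aggregate_stats import rate

params = sd.SimParams(seed=1)
truth = sd.simulate_history(params)
frame = sd.emit_screen_tables(truth, params)
wells = sd.wells_from_frame(frame)
controls = wells["control"]
prior = {g.gene_id: g.single_fitness < 1.0 for g in truth.genes.values()}

results = {
    p.pair_id: workflow.analyze_pair(p.pair_id, p.gene1, p.gene2,
                                     wells, controls, prior)
    for p in truth.pairs
}
masked = sum(r.masking.call != "none" for r in results.values())
r = rate(masked, len(truth.pairs))
print(f"masking rate: {r.percent}% ({r.numerator} of {r.denominator})")
for epoch in reversed(sd.EPOCHS):
    ps = truth.pairs_by_age()[epoch]
    ess = sum(results[p.pair_id].essentiality.label == "essential" for p in ps)
    print(f"{epoch:15s} n={len(ps):4d} essential {rate(ess, len(ps)).percent:5.1f}%"
          f"  (closed form {100 * sd.expected_essential_fraction(params, epoch):.1f}%)")
```

Output:

```
masking rate: 4.3% (87 of 2033)
Celegans        n= 500 essential   3.8%  (closed form 4.1%)
Caenorhabditis  n=1268 essential   6.1%  (closed form 6.2%)
Bilateria       n= 170 essential   7.6%  (closed form 9.3%)
Eukaryota       n=  95 essential  13.7%  (closed form 13.7%)
```

The young (Celegans-lineage) pairs are strongly depleted of essential
pairs relative to the genome rate (17.7%) — the duplication bias — and
the essential fraction climbs with duplication age — the retention
bias. Both recovered rates track the closed forms of the generative
model.

A `paramask` console script exposes the stages individually
(`simulate`, `discover-pairs`, `score-screen`, `test-masking`, `ka`,
`date-pairs`, `rates`, `bin-curve`, `trend`, `ancova`); run
`paramask --help` for details.

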