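# Methods

## The multinomial trio likelihood

A case-parent trio is summarized by the mutant-allele dosages of mother,
father and affected child, `(m, f, c)`. Of the 27 dosage triples, 15 are
compatible with biallelic Mendelian transmission; these are the observable
cells. Internally each cell is split into *sub-cells* by the unobserved
parental origin of the child's alleles (indicators `h_m`, `h_f` for a
mutant maternally / paternally inherited allele); only the heterozygous
child of two heterozygous parents is origin-ambiguous, and its two
sub-cells are summed inside the likelihood. This marginal summation is
mathematically identical to treating origin as missing data in an EM
scheme, but is exact and needs no iteration.

The sub-cell weight conditional on an affected child is

```
μ-baseline(m, f) × t(c, h_m, h_f | m, f)
  × R1^[c=1] R2^[c=2] × S1^[m=1] S1²^[m=2]
  × Im^h_m Ip^h_f × γ11^[m=1 ∧ c=1]
```

normalized by the sum `D` over all sub-cells. `μ` is a probability simplex
over the six unordered parental dosage pairs; an ordered heterotypic pair
receives half its unordered mass (the CEPG exchangeability assumption).
CEPG, rather than assuming Hardy-Weinberg founders, keeps risk-parameter
estimates honest when families are recruited through several affected
children, at some cost in power.

One dataset contributes five unit types to a shared likelihood: trios
(15-cell multinomial), mother- and father-child duos (7-cell marginals over
the missing parent), unrelated affected cases (3-cell marginal over both
parents), and population controls. Controls are modeled as draws from the
genotype distribution implied by `μ` with all risks at 1 — i.e. the
population distribution — so a large control panel pins down the nuisance
genotype frequencies for every other unit type. Duos, cases and controls
carry no parent-of-origin information on their own but sharpen the shared
nuisance parameters.

## Model ladder and testing

Named models free the following risk parameters (everything else fixed
at 1):

| model | free parameters | free dof (incl. 5 for μ) |
|---|---|---|
| null | — | 5 |
| CG | R1, R2 | 7 |
| MCG | R1, R2, S1 | 8 |
| Im | R1, R2, Im | 8 |
| MCG+interaction | R1, R2, S1, γ11 | 9 |
| full | R1, R2, S1, Im | 9 |

`R1` and `R2` are estimated independently (a single multiplicative dose
parameter is not imposed, because for loss-of-function alleles the
homozygote risk is far above the square of the heterozygote risk), while
the maternal effect is additive on the log scale by construction
(`S2 = S1²`). `Ip` is implemented for symmetry checks but excluded from the
ladder. Nested models are compared by likelihood-ratio tests with the
chi-square tail computed via `logsf`, so p-values at the 10⁻⁷⁷ scale are
reported exactly rather than underflowing. MCG and Im are not nested in
each other; each is instead compared against the full model with 1 df —
the mechanism-discrimination step: a maternal effect masquerading as
imprinting makes `full vs Im` highly significant while `full vs MCG` stays
flat.

## Optimization and uncertainty

Free risk parameters are optimized on the log scale and `μ` through an
additive log-ratio (softmax) transform, with L-BFGS-B, `ftol` near machine
precision, and up to five random restarts from a perturbed start. The
default start places `μ` at Hardy-Weinberg proportions at a pooled
allele-frequency estimate from the parents and controls (the same role the
classification step's starting-frequency option plays upstream), and all
risks at 1. Standard errors come from the inverse observed information
(numerical Hessian) at the optimum, on the log scale; Wald intervals are
`exp(β̂ ± z·SE)`.

Identifiability guards: a free parameter with no supporting data anywhere
(e.g. `R2` free with no homozygous affected child in any unit type, `S1`
free with no carrier mothers) is flagged `boundary/unidentifiable` instead
of being reported as a spurious point estimate, and its Wald interval is
marked unreliable. Tiny negative LRT statistics (below ~5×10⁻³, optimizer
round-off on nested fits) are clamped to zero; larger negatives raise.

## TDT and permutation

Transmissions are counted per heterozygous parent by Mendelian
subtraction; a het×het pair with a heterozygous child contributes exactly
one transmitted and one untransmitted allele even though the origin is
ambiguous. The odds ratio is reported as `T/U` without continuity
correction (an infinite ratio is flagged rather than corrected). The
empirical two-sided p-value flips each *family's* entire transmission set
jointly with probability ½ — flipping individual transmissions would break
the correlation between affected siblings that motivates the permutation
in the first place. With ≤ 20 informative families all `2^k` flip patterns
are enumerated exactly (and the plain hit fraction reported); otherwise
Monte-Carlo sampling uses the add-one estimator
`(1 + hits) / (1 + n_perm)`. The permutation p is discrete and therefore
conservative for small family counts.

The allelic test between strata is a 2×2 allele-count chi-square (1 df, no
continuity correction) with the Haldane-Anscombe 0.5 adjustment applied to
the odds ratio only when a cell is zero.

## Meta-analysis

Fixed-effect inverse-variance pooling of log relative risks
(`w = 1/SE²`), matching the usual GWAS-era convention; per-study SEs can be
back-derived from printed confidence intervals as
`(ln U − ln L) / (2 z)` with the exact normal quantile
`z(0.95) = 1.959964...` (1.96 truncated shifts results below reporting
precision, but the exact value is used throughout). Heterogeneity is
Cochran's Q with `k − 1` df. Random-effects pooling is out of scope.

## The synthetic-family generator

`SimulationConfig` defaults describe the study conditions the analysis
assumes: founder mutant-allele frequency `q = 0.1` (the combined
loss-of-function frequency in the motivating data is 0.085–0.105), child
relative risks 2.5 / 6, maternal relative risk 1.5, no imprinting, sibship
mix 43% / 52% / 5% for one / two / three children, ascertainment through at
least one affected child, 759 families. The baseline risk `K = 0.05` of a
non-carrier child of a non-carrier mother is not identified by any of the
published quantities (the multinomial model conditions it away), so it is
a free simulation knob set to a plausible early-childhood prevalence; the
risk law `K·R1^[c=1]R2^[c=2]·S1^m·Im^[maternal mutant]` is validated
against `K·R2·S1²·Im ≤ 1` before sampling. Parents are Hardy-Weinberg
draws; children inherit one allele per parent with origin tracked; the
maternal sensitization flag is Bernoulli with carrier-dependent rate and
can gate the maternal terms (the mechanism probed by the stratified
analysis). Four-variant mode assigns each mutant allele a named variant
identity by relative frequency so the combined-genotype and per-mutation
paths are exercised, including compound heterozygotes.

Unrelated cases are generated with a *latent* mother and father and
accepted if affected, so maternal and imprinting effects propagate into
the case genotype distribution exactly as the likelihood's case marginal
assumes; controls are population draws irrespective of phenotype.

What the generator does not emulate: linkage disequilibrium between
variants (none was observed in the motivating data), genotyping error and
missingness processes, population stratification, and environmental
correlation between siblings beyond the shared-parent structure. Passing
recovery tests therefore demonstrates correctness of the estimator under
the model's own assumptions, not robustness to these violations.

`expected_cell_counts` is the noise-free oracle: the exact expected
configuration counts for singleton-ascertained trios, computed by direct
enumeration over parental genotypes and transmissions — deliberately
independent of the likelihood module's cell machinery. Because the
multinomial MLE evaluated at expected counts equals the generating
parameters, feeding oracle counts to `fit_model` must return the
configuration's risk values to optimizer tolerance; this is the package's
strongest single correctness check. A vectorized sampler
(`simulate_trio_counts`) draws ascertained single-child trios in numpy
batches for replicated studies (parameter recovery, coverage, type-I
error) at roughly a thousand fits per minute.

## Parent-swap behaviour

Exchanging maternal and paternal genotypes and refitting the maternal
model is the standard check that a maternal effect is not an artifact of
labeling. A subtlety worth documenting: on *trio-only* data generated with
a pure maternal effect `S1`, the swapped fit does not return 1 — the
exchangeable mating-type distribution can absorb the swapped maternal term
as `μ'(m,f) ∝ g(m)g(f)S1^{m+f}` with the fitted parameter landing at
`1/S1` exactly. A population control panel anchors `μ` and pulls the
swapped estimate toward (but not onto) 1. The scientifically meaningful
property, and the one the tests assert, is one-sided: the swap must never
*produce* a positive paternal effect from a maternal one, and the direct
maternal estimate must exceed the swapped one.

## Problem sizes

Replicated validation uses 100 studies of 1 000 ascertained trios for bias
and coverage of `S1`, and 300–500 studies for the type-I error of the
maternal-effect LRT — sizes at which the Wald and chi-square asymptotics
the model relies on are comfortably accurate while a full run stays in the
tens of seconds.

## Known limitations

* General pedigrees, X-linked inheritance, phasing and maternal-fetal
  incompatibility models are out of scope; only nuclear families are
  parsed.
* `S2 = S1²` is hard-wired; a freely estimated `S2` is not available.
* The CEPG assumption is the only founder model offered (no
  Hardy-Weinberg variant of the likelihood).
* Trios with one missing parental genotype are downgraded to duos rather
  than dropped (the classification convention upstream of the published
  analysis is not documented; downgrading retains information and is the
  package's choice). The first affected child "per family" is defined by
  file order.
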