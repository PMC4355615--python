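# poetrio

Family-based analysis of **parent-of-origin effects** at a low-frequency
risk locus: does a mother's genotype influence her child's disease risk
beyond the allele the child inherits?

The package was built around the study design in which nuclear families are
ascertained through children affected by a common disease (the motivating
case: atopic dermatitis and the combined loss-of-function genotype of the
filaggrin gene *FLG*), and three competing transmission mechanisms must be
separated:

* a **child genotype effect** — relative risks `R1` (heterozygous) and `R2`
  (homozygous) for the child's own mutant-allele dosage;
* a **maternal genotype effect** — relative risks `S1` / `S2 = S1²` when the
  mother carries one / two mutant alleles, acting on the child regardless of
  transmission;
* **genomic imprinting** — relative risks `Im` / `Ip` when the child's
  maternally / paternally inherited allele is mutant.

## The model

The core is a multinomial maximum-likelihood model over the 15 observable
case-parent trio genotype configurations (mother, father, child dosages
`m, f, c ∈ {0,1,2}`). Conditional on the child being affected,

```
P(m, f, c, origin) ∝ μ(m,f) · t(c, origin | m, f)
                     · R1^[c=1] R2^[c=2] · S1^[m=1] S1²^[m=2]
                     · Im^[maternal allele mutant] · Ip^[paternal allele mutant]
                     · γ11^[m=1 ∧ c=1]
```

where `t` is the Mendelian transmission probability with the parental origin
of the child's alleles tracked, and `μ` is a free distribution over the six
unordered parental mating types under the *conditional-on-exchangeable-
parental-genotypes* (CEPG) assumption — robust to ascertainment through
multiple affected siblings. Configurations that differ only in unobservable
origin are summed. Mother/father-child duos and unrelated affected cases
enter through marginals of the same law; population controls are modeled as
draws from the genotype distribution implied by `μ`, sharpening the nuisance
frequencies. Models are compared along the nested ladder
`null ⊂ CG(R1,R2) ⊂ MCG(+S1) / Im(+Im) ⊂ full` with likelihood-ratio tests
(the non-nested MCG and Im models are compared indirectly through the full
model).

Around the likelihood engine sit:

* `family_data` — PED/MAP/covariate reading, the combined-locus genotype
  (compound heterozygotes for distinct mutations code as dosage 2),
  Mendelian validation, decomposition into trios/duos/cases/controls;
* `tdt` — the transmission disequilibrium test with family-level
  transmission-flip permutation p-values (exact enumeration for ≤ 20
  informative families) and the 2×2 allelic test between strata;
* `meta` — inverse-variance fixed-effect meta-analysis of log relative
  risks with Cochran's Q heterogeneity test;
* `simulate` — a synthetic nuclear-family generator (Hardy-Weinberg
  founders, origin-tracked transmission, multiplicative risk law, maternal
  sensitization gate, ascertainment) plus a closed-form expected-count
  oracle for validating the estimator without Monte-Carlo noise;
* `pipeline` / `cli` — orchestration of the full analysis (per-mutation and
  combined TDT, per-study ladders, stratified and robustness runs,
  cross-study meta-analysis).

## Worked example

```python
import poetrio as pt

# simulate one ascertained-family study and analyse it end to end
cfg = pt.SimulationConfig(q=0.1, r1=2.5, r2=6.0, s1=1.5,
                          n_families=500, n_controls=1500, seed=7)
families, truth = pt.simulate_families(cfg)
cases, controls = pt.simulate_unrelated(cfg)

units = pt.extract_units(families, controls)
counts = pt.tabulate_cells(units)

tdt = pt.empirical_p(pt.count_transmissions(units), n_perm=100_000, seed=7)
print(f"TDT: T/U = {tdt.t}/{tdt.u}, OR = {tdt.odds_ratio:.2f}, "
      f"empirical P = {tdt.p_empirical:.2g}")

ladder = pt.run_ladder(counts, seed=7)
mcg = ladder.fits["mcg"]
lo, hi, _ = pt.wald_ci(mcg)["s1"]
print(f"MCG: R1 = {mcg.estimates['r1']:.2f}, R2 = {mcg.estimates['r2']:.2f}, "
      f"S1 = {mcg.estimates['s1']:.2f} (95% CI {lo:.2f}-{hi:.2f})")
print(f"maternal effect LRT (MCG vs CG): P = {ladder.vs_cg['mcg'].p:.2g}")
```

Output:

```
TDT: T/U = 222/100, OR = 2.22, empirical P = 1e-05
MCG: R1 = 2.48, R2 = 5.03, S1 = 1.48 (95% CI 1.20-1.83)
maternal effect LRT (MCG vs CG): P = 0.00024
```

The mutant allele is transmitted to affected children about twice as often
as not (`OR = T/U`), the child's own genotype raises risk ~2.5-fold per
first allele, and children of carrier mothers have a ~1.5-fold elevated
risk on top of their own genotype — the fit recovers the generating
parameters. The same ladder discriminates the mechanism: on this dataset
adding the maternal parameter to a model already containing imprinting
improves it strongly (P = 0.011) whereas adding imprinting to the maternal
model does not (P = 0.88).

A command-line surface mirrors the library
(`poetrio simulate|tabulate|tdt|fit|ladder|meta|pipeline`).

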