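"""Synthetic nuclear-family generator for parent-of-origin analyses.

Emulates the statistical structure of a family-based association study of a
low-frequency loss-of-function locus: founder genotypes drawn from
Hardy-Weinberg proportions, Mendelian transmission with the parental origin
of each allele tracked, a multiplicative disease-risk law with child-dosage,
maternal-dosage and imprinting terms, an allergic-sensitization covariate of
the mother that can gate the maternal effect, ascertainment through a
minimum number of affected children, and unrelated case/control panels.

The disease law on the probability scale is

    P(affected) = K * R1^[c=1] * R2^[c=2] * S1^[m=1] * S1^2[m=2]
                    * Im^[maternal allele mutant]

with the S-terms applied only to sensitized mothers when the gate is on.
``K`` is the baseline risk of a non-carrier child of a non-carrier mother;
the combination ``K * R2 * S1^2 * Im`` must stay <= 1 for the law to define
probabilities.

:func:`expected_cell_counts` is a noise-free oracle: it enumerates the exact
expected trio-configuration counts for singleton-ascertained trios by direct
summation over parental genotypes and transmissions, independently of the
likelihood engine, so maximum-likelihood fits can be validated against the
generating parameters without Monte-Carlo error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .family_data import (CellCounts, FLG_PANEL, Individual, NuclearFamily,
                          TRIO_CONFIGS, VariantDef)

#: Single pseudo-variant panel for combined-locus simulations.
COMBINED_PANEL: tuple[VariantDef, ...] = (
    VariantDef("combined", "1", 152280000, "M", "W"),
)

#: Founder frequencies of the four FLG mutations in the Central European
#: families, used to split combined mutant alleles in four-variant mode.
FLG_VARIANT_FREQS: tuple[float, ...] = (0.059, 0.034, 0.010, 0.002)

# (m, f, c) -> observable-cell index lookup for vectorized tabulation.
_CFG_LUT = np.full((3, 3, 3), -1, dtype=np.int64)
for _i, (_m, _f, _c) in enumerate(TRIO_CONFIGS):
    _CFG_LUT[_m, _f, _c] = _i


@dataclass(frozen=True)
class SensitizationModel:
    """Maternal allergic-sensitization covariate.

    ``p_carrier``/``p_noncarrier`` are P(sensitized | mother carries >= 1
    mutant allele) and P(sensitized | non-carrier mother). With ``gates_s1``
    the maternal risk terms apply only to sensitized mothers — the mechanism
    the stratified analysis probes.
    """

    p_carrier: float = 0.6
    p_noncarrier: float = 0.4
    gates_s1: bool = False

    def p_sens(self, m: int) -> float:
        return self.p_carrier if m >= 1 else self.p_noncarrier


@dataclass(frozen=True)
class SimulationConfig:
    """Generating parameters of one synthetic study.

    Defaults describe a realistic ascertained-family study of a combined
    loss-of-function locus: founder frequency ``q = 0.1``, baseline child
    risk ``K = 0.05``, child relative risks 2.5 / 6, maternal relative risk
    1.5, no imprinting, sibship mix ~43% / 52% / 5% for 1 / 2 / 3 children,
    ascertainment through at least one affected child.
    """

    q: float = 0.1
    k_baseline: float = 0.05
    r1: float = 2.5
    r2: float = 6.0
    s1: float = 1.5
    im: float = 1.0
    sens: SensitizationModel = field(default_factory=SensitizationModel)
    sibship_probs: tuple[float, ...] = (0.43, 0.52, 0.05)
    min_affected: int = 1
    n_families: int = 759
    n_cases: int = 0
    n_controls: int = 0
    seed: int = 0
    variant_freqs: Optional[tuple[float, ...]] = None  # four-variant mode

    def __post_init__(self) -> None:
        if not 0.0 < self.q < 1.0:
            raise ValueError("q must be in (0, 1)")
        for name in ("r1", "r2", "s1", "im"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        worst = (self.k_baseline * max(1.0, self.r1, self.r2)
                 * max(1.0, self.s1) ** 2 * max(1.0, self.im))
        if worst > 1.0:
            raise ValueError(
                f"invalid risk law: K*R2*S1^2*Im = {worst:.3f} > 1")
        if abs(sum(self.sibship_probs) - 1.0) > 1e-8 or \
                any(p < 0 for p in self.sibship_probs):
            raise ValueError("sibship_probs must be a probability vector")
        if not 1 <= self.min_affected <= len(self.sibship_probs):
            raise ValueError("min_affected exceeds the largest sibship")
        if self.variant_freqs is not None:
            vf = self.variant_freqs
            if any(f < 0 for f in vf) or abs(sum(vf) - self.q) > 1e-8:
                raise ValueError("variant_freqs must be >= 0 and sum to q")

    @property
    def panel(self) -> tuple[VariantDef, ...]:
        if self.variant_freqs is None:
            return COMBINED_PANEL
        return FLG_PANEL[:len(self.variant_freqs)]

    def child_risk(self, c: int, m: int, maternal_mutant: bool,
                   sensitized: bool) -> float:
        r = self.k_baseline
        if c == 1:
            r *= self.r1
        elif c == 2:
            r *= self.r2
        if not self.sens.gates_s1 or sensitized:
            r *= self.s1 ** m          # additive maternal model: S2 = S1^2
        if maternal_mutant:
            r *= self.im
        return r


# ---------------------------------------------------------------------------
# Allele-identity sampling (0 = wild, j >= 1 = mutant allele of variant j-1)
# ---------------------------------------------------------------------------

def _draw_founder_alleles(rng: np.random.Generator, config: SimulationConfig,
                          n: int) -> np.ndarray:
    """(n, 2) founder allele identities at frequency q."""
    alleles = (rng.random((n, 2)) < config.q).astype(np.int64)
    if config.variant_freqs is not None:
        probs = np.asarray(config.variant_freqs) / config.q
        idx = alleles > 0
        alleles[idx] = rng.choice(len(probs), size=int(idx.sum()),
                                  p=probs) + 1
    return alleles


def _genotypes_from_alleles(alleles: Sequence[int],
                            panel: Sequence[VariantDef]) -> list[int]:
    return [sum(1 for a in alleles if a == j + 1) for j in range(len(panel))]


def _make_individual(fid: str, iid: str, alleles: Sequence[int],
                     panel: Sequence[VariantDef], affection: str,
                     father_id: str = "0", mother_id: str = "0",
                     sex: int = 0) -> Individual:
    ind = Individual(fid, iid, father_id, mother_id, sex, affection,
                     _genotypes_from_alleles(alleles, panel))
    ind.covariates["alleles"] = tuple(int(a) for a in alleles)
    return ind


def simulate_families(config: SimulationConfig,
                      rng: Optional[np.random.Generator] = None,
                      ) -> tuple[list[NuclearFamily], pd.DataFrame]:
    """Generate ascertained nuclear families plus a per-child truth table.

    Parents are independent Hardy-Weinberg draws at ``q``; each child gets
    one maternal and one paternal allele chosen uniformly; affection follows
    the multiplicative risk law; a family is retained iff its affected-child
    count reaches ``config.min_affected``, and generation continues until
    ``config.n_families`` are retained. The truth table records, per child,
    the true dosage, the maternal-origin indicator, affection, the mother's
    dosage and her sensitization flag.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    panel = config.panel
    families: list[NuclearFamily] = []
    truth_rows = []
    sib_sizes = np.arange(1, len(config.sibship_probs) + 1)
    while len(families) < config.n_families:
        mo = _draw_founder_alleles(rng, config, 1)[0]
        fa = _draw_founder_alleles(rng, config, 1)[0]
        m_dos = int((mo > 0).sum())
        sensitized = bool(rng.random() < config.sens.p_sens(m_dos))
        n_kids = int(rng.choice(sib_sizes, p=config.sibship_probs))
        kids = []
        for _ in range(n_kids):
            am = int(mo[rng.integers(2)])
            af = int(fa[rng.integers(2)])
            c_dos = int(am > 0) + int(af > 0)
            risk = config.child_risk(c_dos, m_dos, am > 0, sensitized)
            affected = bool(rng.random() < risk)
            kids.append((am, af, c_dos, affected))
        if sum(k[3] for k in kids) < config.min_affected:
            continue
        fid = f"fam{len(families) + 1:05d}"
        fam = NuclearFamily(fid)
        fam.mother = _make_individual(fid, "mo", mo, panel, "unknown", sex=2)
        fam.father = _make_individual(fid, "fa", fa, panel, "unknown", sex=1)
        for j, (am, af, c_dos, affected) in enumerate(kids, 1):
            child = _make_individual(
                fid, f"c{j}", (am, af), panel,
                "affected" if affected else "unaffected",
                father_id="fa", mother_id="mo")
            fam.children.append(child)
            truth_rows.append({
                "family_id": fid, "child_id": f"c{j}", "dosage": c_dos,
                "maternal_mutant": int(am > 0), "affected": int(affected),
                "mother_dosage": m_dos,
                "maternal_sensitization": int(sensitized),
            })
        # Parental AD history: the parent's own genotype acting through the
        # child-risk part of the law only (used by the history-filter stratum).
        for parent in (fam.mother, fam.father):
            p_dos = int((np.array(parent.covariates["alleles"]) > 0).sum())
            p_risk = config.child_risk(p_dos, 0, False, False)
            parent.covariates["AD_history"] = int(rng.random() < p_risk)
        fam.covariates = {
            "mother_AD_history": fam.mother.covariates["AD_history"],
            "father_AD_history": fam.father.covariates["AD_history"],
            "maternal_sensitization": int(sensitized),
        }
        families.append(fam)
    return families, pd.DataFrame(truth_rows)


def simulate_unrelated(config: SimulationConfig,
                       rng: Optional[np.random.Generator] = None,
                       ) -> tuple[list[Individual], list[Individual]]:
    """Unrelated affected cases and population controls.

    Controls are Hardy-Weinberg draws at ``q`` irrespective of phenotype
    (they estimate population genotype frequencies). Each case is the
    affected child of a latent simulated mother and father, so maternal and
    imprinting effects propagate into the case genotype distribution exactly
    as the likelihood's case marginal assumes.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    panel = config.panel
    controls = [
        _make_individual("ctrl", f"u{i + 1}", al, panel, "unknown")
        for i, al in enumerate(_draw_founder_alleles(rng, config,
                                                     config.n_controls))
    ]
    cases: list[Individual] = []
    while len(cases) < config.n_cases:
        mo = _draw_founder_alleles(rng, config, 1)[0]
        fa = _draw_founder_alleles(rng, config, 1)[0]
        m_dos = int((mo > 0).sum())
        sensitized = bool(rng.random() < config.sens.p_sens(m_dos))
        am = int(mo[rng.integers(2)])
        af = int(fa[rng.integers(2)])
        c_dos = int(am > 0) + int(af > 0)
        if rng.random() < config.child_risk(c_dos, m_dos, am > 0, sensitized):
            cases.append(_make_individual("case", f"a{len(cases) + 1}",
                                          (am, af), panel, "affected"))
    return cases, controls


def simulate_trio_counts(config: SimulationConfig, n_trios: int,
                         rng: Optional[np.random.Generator] = None,
                         ) -> CellCounts:
    """Fast vectorized sampler of ascertained single-child trios.

    Statistically identical to :func:`simulate_families` with one-child
    sibships and ascertainment >= 1, but draws candidate trios in numpy
    batches and tabulates the retained (m, f, c) configurations directly —
    the workhorse for replicated parameter-recovery and type-I-error studies.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    counts = CellCounts()
    # Acceptance rate is at least K, so size batches accordingly.
    batch = max(4 * int(n_trios / config.k_baseline ** 0.5), 4096)
    remaining = n_trios
    while remaining > 0:
        m = rng.binomial(2, config.q, batch)
        f = rng.binomial(2, config.q, batch)
        am = rng.random(batch) < m / 2.0
        af = rng.random(batch) < f / 2.0
        c = am.astype(int) + af.astype(int)
        risk = np.full(batch, config.k_baseline)
        risk[c == 1] *= config.r1
        risk[c == 2] *= config.r2
        s_on = np.ones(batch, dtype=bool)
        if config.sens.gates_s1:
            p_sens = np.where(m >= 1, config.sens.p_carrier,
                              config.sens.p_noncarrier)
            s_on = rng.random(batch) < p_sens
        risk *= np.where(s_on, config.s1 ** m, 1.0)
        risk *= np.where(am, config.im, 1.0)
        keep = rng.random(batch) < risk
        km, kf, kc = m[keep], f[keep], c[keep]
        take = min(remaining, km.size)
        idx = _CFG_LUT[km[:take], kf[:take], kc[:take]]
        np.add.at(counts.trio, idx, 1)
        remaining -= take
    return counts


def expected_cell_counts(config: SimulationConfig, n: int) -> CellCounts:
    """Exact expected trio-configuration counts for n ascertained trios.

    Direct closed-form enumeration over parental Hardy-Weinberg genotypes
    and Mendelian transmissions with tracked origin: P(cell | affected child)
    is the normalized sum of P(m) P(f) P(transmission) x risk over the
    transmissions compatible with each observable (m, f, c) cell. With the
    sensitization gate on, the maternal term enters through its expectation
    over the sensitization mixture. Independent of the likelihood module.
    """
    q = config.q
    hwe = {0: (1 - q) ** 2, 1: 2 * q * (1 - q), 2: q ** 2}
    weights = {}
    for m in range(3):
        if config.sens.gates_s1:
            ps = config.sens.p_sens(m)
            s_term = ps * config.s1 ** m + (1.0 - ps)
        else:
            s_term = config.s1 ** m
        for f in range(3):
            for am in (0, 1):
                p_am = m / 2.0 if am else 1.0 - m / 2.0
                if p_am == 0.0:
                    continue
                for af in (0, 1):
                    p_af = f / 2.0 if af else 1.0 - f / 2.0
                    if p_af == 0.0:
                        continue
                    c = am + af
                    risk = config.k_baseline * s_term
                    if c == 1:
                        risk *= config.r1
                    elif c == 2:
                        risk *= config.r2
                    if am:
                        risk *= config.im
                    key = (m, f, c)
                    weights[key] = weights.get(key, 0.0) + \
                        hwe[m] * hwe[f] * p_am * p_af * risk
    total = sum(weights.values())
    trio = np.zeros(15)
    for key, w in weights.items():
        trio[TRIO_CONFIGS.index(key)] = n * w / total
    return CellCounts(trio=trio)


# ---------------------------------------------------------------------------
# File output
# ---------------------------------------------------------------------------

def _ped_alleles(ind: Individual, panel: Sequence[VariantDef]) -> list[str]:
    tokens = []
    for j, var in enumerate(panel):
        dos = ind.genotypes[j]
        if dos is None:
            tokens += ["0", "0"]
        else:
            tokens += ([var.mutant_allele] * dos
                       + [var.wild_allele] * (2 - dos))
    return tokens


_AFFECTION_CODE = {"unaffected": "1", "affected": "2", "unknown": "0"}


def write_pedfile(families: Sequence[NuclearFamily], ped_path,
                  map_path=None, covariates_path=None,
                  unrelated: Sequence[Individual] = (),
                  panel: Optional[Sequence[VariantDef]] = None) -> None:
    """Write families (and optional unrelated individuals) as PED/MAP files.

    The PED round-trips losslessly through :func:`poetrio.family_data.
    read_pedfile`; the optional covariate file carries the per-family
    parental AD-history and maternal-sensitization flags.
    """
    if panel is None:
        n_var = (len(families[0].children[0].genotypes) if families
                 else len(unrelated[0].genotypes) if unrelated else 1)
        panel = COMBINED_PANEL if n_var == 1 else FLG_PANEL[:n_var]
    lines = []
    for fam in families:
        members = [m for m in (fam.mother, fam.father) if m is not None]
        members += fam.children
        for ind in members:
            lines.append(" ".join(
                [fam.family_id, ind.individual_id, ind.father_id,
                 ind.mother_id, str(ind.sex), _AFFECTION_CODE[ind.affection]]
                + _ped_alleles(ind, panel)))
    for ind in unrelated:
        lines.append(" ".join(
            [ind.family_id, ind.individual_id, "0", "0", str(ind.sex),
             _AFFECTION_CODE[ind.affection]] + _ped_alleles(ind, panel)))
    Path(ped_path).write_text("".join(line + "\n" for line in lines))
    if map_path is not None:
        Path(map_path).write_text("".join(
            f"{v.chrom}\t{v.id}\t0\t{v.pos}\n" for v in panel))
    if covariates_path is not None:
        rows = []
        for fam in families:
            cov = fam.covariates or {}
            rows.append({
                "family_id": fam.family_id,
                "mother_AD_history": cov.get("mother_AD_history", "NA"),
                "father_AD_history": cov.get("father_AD_history", "NA"),
                "maternal_sensitization": cov.get("maternal_sensitization",
                                                  "NA"),
            })
        pd.DataFrame(rows).to_csv(covariates_path, sep="\t", index=False)
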