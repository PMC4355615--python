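"""Multinomial maximum-likelihood engine for parent-of-origin effects.

The model follows the EMIM family of case-parent trio likelihoods under the
CEPG assumption ("conditional on exchangeable parental genotypes"): the
nuisance distribution over parental genotypes is a free 6-point distribution
``mu`` over unordered parental dosage pairs, with each ordered heterotypic
pair receiving half its unordered mass. Conditional on parents, children are
produced by Mendelian transmission with the parental origin of each allele
tracked, and the child being affected multiplies each configuration's weight
by a product of relative risks:

* ``R1``, ``R2`` — child carries one / two mutant alleles;
* ``S1`` — mother carries one mutant allele (``S2 = S1**2``, additive
  maternal model, is implied for carrier-homozygous mothers);
* ``Im`` / ``Ip`` — the child's maternally / paternally inherited allele is
  mutant (genomic-imprinting parameters);
* ``gamma11`` — interaction multiplier when mother and child each carry
  exactly one mutant allele.

Configurations that differ only in the unobservable parental origin of the
child's allele (a heterozygous child of two heterozygous parents) are summed,
which is exactly the marginal likelihood the EM treatment of the missing
origin maximizes. Trios, single-parent duos and unrelated cases are modeled
conditional on the child being affected; controls are population draws from
the genotype distribution implied by ``mu``, so pooling them into one fit
sharpens the nuisance genotype-frequency estimate.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy import optimize
from scipy.stats import chi2, norm
from statsmodels.tools.numdiff import approx_hess

from .family_data import CellCounts, DUO_CONFIGS, TRIO_CONFIGS

logger = logging.getLogger(__name__)

#: Unordered parental dosage pairs indexing the mating-type simplex ``mu``.
MATING_TYPES: tuple[tuple[int, int], ...] = (
    (0, 0), (1, 0), (1, 1), (2, 0), (2, 1), (2, 2))
_MT_INDEX = {mt: i for i, mt in enumerate(MATING_TYPES)}


def _mt_of(m: int, f: int) -> int:
    return _MT_INDEX[(max(m, f), min(m, f))]


# ---------------------------------------------------------------------------
# Sub-cell enumeration: ordered (m, f), child dosage c, transmission-origin
# indicators (hm: maternal allele mutant, hf: paternal allele mutant), and the
# Mendelian transmission probability t.  16 sub-cells project onto the 15
# observable (m, f, c) cells; only (1,1,c=1) is origin-ambiguous.
# ---------------------------------------------------------------------------
_SUBCELLS = [
    # (m, f, c, hm, hf, t)
    (2, 2, 2, 1, 1, 1.0),
    (2, 1, 2, 1, 1, 0.5), (2, 1, 1, 1, 0, 0.5),
    (1, 2, 2, 1, 1, 0.5), (1, 2, 1, 0, 1, 0.5),
    (2, 0, 1, 1, 0, 1.0),
    (0, 2, 1, 0, 1, 1.0),
    (1, 1, 2, 1, 1, 0.25), (1, 1, 1, 1, 0, 0.25),
    (1, 1, 1, 0, 1, 0.25), (1, 1, 0, 0, 0, 0.25),
    (1, 0, 1, 1, 0, 0.5), (1, 0, 0, 0, 0, 0.5),
    (0, 1, 1, 0, 1, 0.5), (0, 1, 0, 0, 0, 0.5),
    (0, 0, 0, 0, 0, 1.0),
]

_SUB_M = np.array([s[0] for s in _SUBCELLS])
_SUB_F = np.array([s[1] for s in _SUBCELLS])
_SUB_C = np.array([s[2] for s in _SUBCELLS])
_SUB_HM = np.array([s[3] for s in _SUBCELLS], dtype=float)
_SUB_HF = np.array([s[4] for s in _SUBCELLS], dtype=float)
_SUB_T = np.array([s[5] for s in _SUBCELLS])
_SUB_MT = np.array([_mt_of(m, f) for m, f, *_ in _SUBCELLS])
# CEPG baseline: ordered heterotypic pair gets mu/2, homotypic gets mu.
_SUB_MT_W = np.array([1.0 if m == f else 0.5 for m, f, *_ in _SUBCELLS])
_SUB_CELL = np.array([TRIO_CONFIGS.index((m, f, c))
                      for m, f, c, *_ in _SUBCELLS])
_SUB_MDUO = np.array([DUO_CONFIGS.index((m, c)) for m, _, c, *_ in _SUBCELLS])
_SUB_FDUO = np.array([DUO_CONFIGS.index((f, c)) for _, f, c, *_ in _SUBCELLS])
# exponents for the risk multipliers
_E_R1 = (_SUB_C == 1).astype(float)
_E_R2 = (_SUB_C == 2).astype(float)
_E_S1 = (_SUB_M == 1) + 2.0 * (_SUB_M == 2)  # additive maternal: S2 = S1^2
_E_G11 = ((_SUB_M == 1) & (_SUB_C == 1)).astype(float)


@dataclass(frozen=True)
class RiskParameters:
    """Relative-risk multipliers; an excluded parameter sits at exactly 1."""

    r1: float = 1.0
    r2: float = 1.0
    s1: float = 1.0
    im: float = 1.0
    ip: float = 1.0
    gamma11: float = 1.0

    def __post_init__(self) -> None:
        for name in PARAM_NAMES + ("ip",):
            if getattr(self, name) <= 0:
                raise ValueError(f"risk parameter {name} must be > 0")

    @property
    def s2(self) -> float:
        return self.s1 ** 2


PARAM_NAMES = ("r1", "r2", "s1", "im", "gamma11")

#: The model ladder. Free risk parameters per named model; the mating-type
#: simplex contributes 5 free parameters to every model.
MODELS: dict[str, tuple[str, ...]] = {
    "null": (),
    "cg": ("r1", "r2"),
    "mcg": ("r1", "r2", "s1"),
    "im": ("r1", "r2", "im"),
    "mcg_interaction": ("r1", "r2", "s1", "gamma11"),
    "full": ("r1", "r2", "s1", "im"),
}


@dataclass(frozen=True)
class ModelSpec:
    """A point on the model ladder: which risk parameters are free."""

    name: str
    free: tuple[str, ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.free is None:
            if self.name not in MODELS:
                raise ValueError(f"unknown model {self.name!r}; "
                                 f"known: {sorted(MODELS)}")
            object.__setattr__(self, "free", MODELS[self.name])
        unknown = set(self.free) - set(PARAM_NAMES)
        if unknown:
            raise ValueError(f"unknown risk parameters {sorted(unknown)}")

    @property
    def n_free(self) -> int:
        """Free parameters: 5 from the mating-type simplex + risk terms."""
        return 5 + len(self.free)

    def nests(self, other: "ModelSpec") -> bool:
        """True if ``self`` is nested within ``other``."""
        return set(self.free) <= set(other.free)


@dataclass
class CellTable:
    """Cell probabilities for every unit type at one parameter point."""

    trio: np.ndarray        # (15,) observable trio probabilities, sums to 1
    mother_duo: np.ndarray  # (7,)
    father_duo: np.ndarray  # (7,)
    case: np.ndarray        # (3,) affected-child genotype distribution
    control: np.ndarray     # (3,) population genotype distribution
    normalizer: float       # D, the trio normalizing constant


def _validate_mu(mu: np.ndarray) -> np.ndarray:
    mu = np.asarray(mu, dtype=float)
    if mu.shape != (6,):
        raise ValueError("mu must have 6 mating-type entries")
    if (mu < 0).any() or abs(mu.sum() - 1.0) > 1e-8:
        raise ValueError("mu must be a probability simplex over mating types")
    return mu


def cell_probabilities(risk: RiskParameters, mu: np.ndarray) -> CellTable:
    """Cell probabilities under CEPG for given risk parameters and ``mu``.

    Sub-cell weight = mu-baseline(m,f) x Mendelian transmission probability
    x R1^[c=1] R2^[c=2] x S1^[m=1] S1^2[m=2] x Im^hm Ip^hf x gamma11^[m=c=1];
    the trio normalizer D sums all sub-cells, and duo/case tables marginalize
    the normalized trio table. Controls use risk == 1 weights, i.e. the
    population genotype distribution implied by ``mu``.
    """
    mu = _validate_mu(mu)
    base = mu[_SUB_MT] * _SUB_MT_W * _SUB_T
    w = base * (risk.r1 ** _E_R1 * risk.r2 ** _E_R2 * risk.s1 ** _E_S1
                * risk.im ** _SUB_HM * risk.ip ** _SUB_HF
                * risk.gamma11 ** _E_G11)
    d = w.sum()
    sub = w / d
    trio = np.bincount(_SUB_CELL, weights=sub, minlength=15)
    return CellTable(
        trio=trio,
        mother_duo=np.bincount(_SUB_MDUO, weights=sub, minlength=7),
        father_duo=np.bincount(_SUB_FDUO, weights=sub, minlength=7),
        case=np.bincount(_SUB_C, weights=sub, minlength=3),
        control=np.bincount(_SUB_C, weights=base, minlength=3),
        normalizer=float(d),
    )


def total_loglik(counts: CellCounts, risk: RiskParameters,
                 mu: np.ndarray) -> float:
    """Multinomial log-likelihood summed over all unit types.

    Zero-count cells contribute nothing; a positive count on a
    zero-probability cell yields ``-inf`` with a diagnostic.
    """
    table = cell_probabilities(risk, mu)
    total = 0.0
    for obs, probs, label in ((counts.trio, table.trio, "trio"),
                              (counts.mother_duo, table.mother_duo, "mother_duo"),
                              (counts.father_duo, table.father_duo, "father_duo"),
                              (counts.case, table.case, "case"),
                              (counts.control, table.control, "control")):
        pos = obs > 0
        if not pos.any():
            continue
        p = probs[pos]
        if (p <= 0).any():
            logger.warning("positive %s count on zero-probability cell", label)
            return -math.inf
        total += float(obs[pos] @ np.log(p))
    return total


@dataclass
class FitResult:
    """A maximized model: estimates, log-scale SEs, diagnostics."""

    spec: ModelSpec
    estimates: dict            # risk parameters on the relative-risk scale
    se_log: dict               # log-scale standard errors (free params only)
    mu: np.ndarray             # fitted mating-type distribution
    loglik: float
    converged: bool
    boundary_flags: dict       # param -> reason, for unidentifiable params
    n_restarts_used: int = 0
    counts_signature: tuple = ()

    @property
    def n_free(self) -> int:
        return self.spec.n_free

    @property
    def risk(self) -> RiskParameters:
        return RiskParameters(**{k: self.estimates.get(k, 1.0)
                                 for k in PARAM_NAMES})

    def summary_row(self) -> dict:
        row = {"model": self.spec.name, "lnlik": self.loglik,
               "converged": self.converged}
        for k in self.spec.free:
            row[k.upper()] = self.estimates[k]
            row[f"{k.upper()}_se_log"] = self.se_log.get(k, float("nan"))
        return row


def _counts_signature(counts: CellCounts) -> tuple:
    return tuple(np.concatenate([counts.trio, counts.mother_duo,
                                 counts.father_duo, counts.case,
                                 counts.control]).tolist())


def _mu_from_theta(theta_mu: np.ndarray) -> np.ndarray:
    z = np.concatenate([theta_mu, [0.0]])
    z = z - z.max()
    e = np.exp(z)
    return e / e.sum()


def _theta_from_mu(mu: np.ndarray) -> np.ndarray:
    mu = np.clip(mu, 1e-9, None)
    logm = np.log(mu)
    return logm[:5] - logm[5]


def hwe_mating_types(q: float) -> np.ndarray:
    """Mating-type distribution under random mating at allele frequency q."""
    g = np.array([(1 - q) ** 2, 2 * q * (1 - q), q ** 2])
    mu = np.empty(6)
    for i, (a, b) in enumerate(MATING_TYPES):
        mu[i] = g[a] * g[b] if a == b else 2 * g[a] * g[b]
    return mu


def _allele_freq_guess(counts: CellCounts) -> float:
    """Crude pooled mutant-allele frequency for initialization (parents of
    trios/duos plus controls), mirroring PREMIM's starting-frequency role."""
    alleles = 0.0
    total = 0.0
    for (m, f, _), n in zip(TRIO_CONFIGS, counts.trio):
        alleles += n * (m + f)
        total += n * 4
    for (p, _), n in zip(DUO_CONFIGS, counts.mother_duo):
        alleles += n * p
        total += n * 2
    for (p, _), n in zip(DUO_CONFIGS, counts.father_duo):
        alleles += n * p
        total += n * 2
    for g in range(3):
        alleles += counts.control[g] * g
        total += counts.control[g] * 2
    if total == 0:
        return 0.1
    return float(min(max(alleles / total, 1e-3), 0.5))


def _support_checks(counts: CellCounts, free: Sequence[str]) -> dict:
    """Pre-fit identifiability screens: a free parameter with no supporting
    observations anywhere in the data is flagged rather than estimated."""
    flags = {}
    c2 = (sum(n for (_, _, c), n in zip(TRIO_CONFIGS, counts.trio) if c == 2)
          + sum(n for (_, c), n in zip(DUO_CONFIGS, counts.mother_duo) if c == 2)
          + sum(n for (_, c), n in zip(DUO_CONFIGS, counts.father_duo) if c == 2)
          + counts.case[2])
    if "r2" in free and c2 == 0:
        flags["r2"] = "no homozygous affected children anywhere in the data"
    c1 = (sum(n for (_, _, c), n in zip(TRIO_CONFIGS, counts.trio) if c >= 1)
          + sum(n for (_, c), n in zip(DUO_CONFIGS, counts.mother_duo) if c >= 1)
          + sum(n for (_, c), n in zip(DUO_CONFIGS, counts.father_duo) if c >= 1)
          + counts.case[1] + counts.case[2])
    if "r1" in free and c1 == 0:
        flags["r1"] = "no carrier affected children anywhere in the data"
    m1 = (sum(n for (m, _, _), n in zip(TRIO_CONFIGS, counts.trio) if m >= 1)
          + sum(n for (p, _), n in zip(DUO_CONFIGS, counts.mother_duo) if p >= 1))
    if "s1" in free and m1 == 0:
        flags["s1"] = "no carrier mothers among trios or mother duos"
    if "gamma11" in free:
        g11 = sum(n for (m, _, c), n in zip(TRIO_CONFIGS, counts.trio)
                  if m == 1 and c == 1)
        g11 += sum(n for (p, c), n in zip(DUO_CONFIGS, counts.mother_duo)
                   if p == 1 and c == 1)
        if g11 == 0:
            flags["gamma11"] = "no mother-het/child-het configurations observed"
    if "im" in free:
        # Im is informed by origin-resolvable transmissions in trios.
        inf_im = sum(n for (m, f, c), n in zip(TRIO_CONFIGS, counts.trio)
                     if m >= 1 and c >= 1)
        if inf_im == 0:
            flags["im"] = "no trios with a potentially maternal mutant allele"
    return flags


def fit_model(counts: CellCounts, spec: ModelSpec | str,
              init: Optional[dict] = None,
              n_restarts: int = 5, seed: int = 0) -> FitResult:
    """Maximize the multinomial likelihood for one model on one dataset.

    Risk parameters are optimized on the log scale and the mating-type
    simplex through an additive log-ratio transform; by default ``mu`` starts
    at Hardy-Weinberg proportions at the pooled allele-frequency guess and
    risk parameters at 1. Standard errors come from the inverse observed
    information at the optimum. Restarts perturb the start point and keep the
    best optimum found.
    """
    if isinstance(spec, str):
        spec = ModelSpec(spec)
    if counts.total == 0:
        raise ValueError("empty CellCounts")
    free = spec.free
    flags = _support_checks(counts, free)

    q0 = _allele_freq_guess(counts)
    mu0 = hwe_mating_types(q0)
    theta0 = np.concatenate([
        _theta_from_mu(mu0),
        [math.log((init or {}).get(k, 1.0)) for k in free],
    ])

    def unpack(theta: np.ndarray) -> tuple[RiskParameters, np.ndarray]:
        mu = _mu_from_theta(theta[:5])
        vals = {k: math.exp(v) for k, v in zip(free, theta[5:])}
        return RiskParameters(**vals), mu

    def negloglik(theta: np.ndarray) -> float:
        risk, mu = unpack(theta)
        ll = total_loglik(counts, risk, mu)
        return -ll if math.isfinite(ll) else 1e12

    rng = np.random.default_rng(seed)
    best = None
    restarts_used = 0
    for attempt in range(n_restarts + 1):
        start = theta0 if attempt == 0 else theta0 + rng.normal(0, 0.3, theta0.size)
        res = optimize.minimize(negloglik, start, method="L-BFGS-B",
                                options={"ftol": 1e-13, "gtol": 1e-8,
                                         "maxiter": 2000})
        if best is None or res.fun < best.fun - 1e-9:
            best = res
        restarts_used = attempt
        if best.success:
            break
    if best is None or not math.isfinite(best.fun) or not best.success:
        raise RuntimeError("likelihood maximization failed to converge "
                           f"after {restarts_used + 1} starts")

    risk, mu = unpack(best.x)
    estimates = {k: getattr(risk, k) for k in free}

    se_log: dict = {}
    if free:
        try:
            hess = approx_hess(best.x, negloglik)
            cov = np.linalg.inv(hess)
            diag = np.diag(cov)
            for i, k in enumerate(free):
                v = diag[5 + i]
                if v > 0:
                    se_log[k] = float(math.sqrt(v))
                else:
                    flags.setdefault(k, "non-positive variance at optimum")
        except np.linalg.LinAlgError:
            for k in free:
                flags.setdefault(k, "singular observed information")

    for k in free:
        if abs(math.log(estimates[k])) > math.log(100.0):
            flags.setdefault(k, "estimate at boundary of plausible range")

    return FitResult(spec=spec, estimates=estimates, se_log=se_log, mu=mu,
                     loglik=-float(best.fun), converged=bool(best.success),
                     boundary_flags=flags, n_restarts_used=restarts_used,
                     counts_signature=_counts_signature(counts))


@dataclass
class LrtResult:
    """Likelihood-ratio test between nested fits."""

    statistic: float
    df: int
    p: float
    log10_p: float

    def __repr__(self) -> str:  # readable scientific notation for tiny p
        return (f"LrtResult(statistic={self.statistic:.4g}, df={self.df}, "
                f"p={self.p:.3g}, log10_p={self.log10_p:.3f})")


def lrt_from_logliks(lnlik_small: float, lnlik_big: float, df: int) -> LrtResult:
    """LRT from two maximized log-likelihoods; p computed in log space so
    extreme values (1e-77 scale) do not underflow."""
    stat = 2.0 * (lnlik_big - lnlik_small)
    # tiny negative statistics are optimizer round-off on nested models
    if stat < -5e-3:
        raise ValueError(f"larger model has smaller lnlik (stat={stat:.3g}); "
                         "check nesting / convergence")
    stat = max(stat, 0.0)
    if df == 0:
        return LrtResult(stat, 0, 1.0, 0.0)
    logp = chi2.logsf(stat, df)
    return LrtResult(stat, df, float(math.exp(logp)),
                     float(logp / math.log(10.0)))


def lrt(small: FitResult, big: FitResult) -> LrtResult:
    """Likelihood-ratio test of two nested model fits on the same data.

    Non-nested pairs (e.g. the maternal-genotype and imprinting models) are
    rejected; compare those indirectly through the full model.
    """
    if not small.spec.nests(big.spec):
        raise ValueError(
            f"models {small.spec.name!r} and {big.spec.name!r} are not "
            "nested; compare them indirectly through the full model")
    if small.counts_signature and big.counts_signature and \
            small.counts_signature != big.counts_signature:
        raise ValueError("fits come from different datasets")
    return lrt_from_logliks(small.loglik, big.loglik,
                            big.n_free - small.n_free)


def wald_ci(fit: FitResult, level: float = 0.95) -> dict:
    """Wald confidence intervals on the relative-risk scale.

    Returns ``{param: (lower, upper, reliable)}``; intervals for
    boundary-flagged parameters are marked unreliable.
    """
    z = norm.ppf(0.5 + level / 2.0)
    out = {}
    for k in fit.spec.free:
        est = fit.estimates[k]
        se = fit.se_log.get(k)
        reliable = k not in fit.boundary_flags and se is not None
        if se is None:
            out[k] = (est, est, False)
        else:
            out[k] = (est * math.exp(-z * se), est * math.exp(z * se), reliable)
    return out


@dataclass
class LadderResult:
    """The step-by-step model ladder on one dataset."""

    fits: dict                      # model name -> FitResult
    vs_null: dict                   # model name -> LrtResult
    vs_cg: dict                     # model name -> LrtResult
    vs_full: dict                   # model name -> LrtResult (mcg, im)
    interaction_vs_mcg: Optional[LrtResult] = None

    def to_frame(self):
        import pandas as pd
        rows = []
        for name, fit in self.fits.items():
            row = fit.summary_row()
            for label, d in (("P_null", self.vs_null), ("P_CG", self.vs_cg),
                             ("P_full", self.vs_full)):
                row[label] = d[name].p if name in d else float("nan")
            rows.append(row)
        return pd.DataFrame(rows)


def run_ladder(counts: CellCounts, include_interaction: bool = False,
               seed: int = 0) -> LadderResult:
    """Fit the nested model ladder and its likelihood-ratio comparisons.

    Fits null, child-genotype (CG), maternal+child (MCG), imprinting (Im) and
    full models; tests each against the null, against CG, and MCG/Im against
    the full model (1 df each) — the discrimination logic for maternal versus
    imprinting explanations. Optionally adds the MCG+interaction model and
    its test against MCG.
    """
    names = ["null", "cg", "mcg", "im", "full"]
    if include_interaction:
        names.append("mcg_interaction")
    fits = {name: fit_model(counts, name, seed=seed) for name in names}
    vs_null = {n: lrt(fits["null"], fits[n]) for n in names if n != "null"}
    vs_cg = {n: lrt(fits["cg"], fits[n])
             for n in ("mcg", "im", "full") if n in fits}
    vs_full = {n: lrt(fits[n], fits["full"]) for n in ("mcg", "im")}
    inter = (lrt(fits["mcg"], fits["mcg_interaction"])
             if include_interaction else None)
    return LadderResult(fits, vs_null, vs_cg, vs_full, inter)


def swap_parents(counts: CellCounts) -> CellCounts:
    """Exchange maternal and paternal genotypes in the counts.

    Trio cell (m, f, c) maps to (f, m, c) and the duo tables swap roles, so
    refitting the maternal-effect model on the result estimates a *paternal*
    genotype effect — the parent-swap robustness analysis.
    """
    trio = np.zeros(15)
    for (m, f, c), n in zip(TRIO_CONFIGS, counts.trio):
        trio[TRIO_CONFIGS.index((f, m, c))] = n
    return CellCounts(trio=trio,
                      mother_duo=counts.father_duo.copy(),
                      father_duo=counts.mother_duo.copy(),
                      case=counts.case.copy(),
                      control=counts.control.copy())
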