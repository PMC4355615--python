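"""Transmission disequilibrium test with family-level flip permutation.

The TDT counts, over heterozygous parents of affected children, how often
the mutant allele was transmitted (T) versus untransmitted (U). Under the
null of no association/linkage each transmission is a fair coin, so
(T - U)^2 / (T + U) is asymptotically chi-square with 1 df. Because families
contribute several affected siblings (whose transmissions are correlated
through shared parents), the empirical p-value flips each family's entire
transmission set jointly with probability 1/2 — the transmission-flip
permutation scheme of PLINK's ``--tdt --perm``.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.stats import chi2, chi2_contingency

from .family_data import AnalysisUnits

logger = logging.getLogger(__name__)


@dataclass
class TransmissionCounts:
    """Transmitted/untransmitted mutant-allele counts with per-family detail.

    ``per_family`` maps family id -> (t, u) aggregated over that family's
    informative transmissions; the permutation flips these units jointly.
    """

    t: int = 0
    u: int = 0
    per_family: dict = field(default_factory=dict)
    locus: object = "combined"

    def add(self, family_id: str, t: int, u: int) -> None:
        self.t += t
        self.u += u
        ft, fu = self.per_family.get(family_id, (0, 0))
        self.per_family[family_id] = (ft + t, fu + u)


@dataclass
class TdtResult:
    t: int
    u: int
    odds_ratio: float           # T/U; math.inf when U == 0 (flagged)
    infinite_or: bool
    chi2: float
    p_asymptotic: float
    p_empirical: Optional[float] = None
    n_permutations: Optional[int] = None
    exact: bool = False
    seed: Optional[int] = None


def _transmissions_from_parent(het_parent_other: int, c: int) -> tuple[int, int]:
    """(t, u) contributed by one heterozygous parent given the other parent's
    dosage and the child dosage, by Mendelian subtraction."""
    other = het_parent_other
    if other == 0:          # child's other allele is wild
        return (1, 0) if c >= 1 else (0, 1)
    if other == 2:          # child's other allele is mutant
        return (1, 0) if c == 2 else (0, 1)
    # other parent heterozygous too: resolved jointly in count_transmissions
    raise AssertionError("het x het handled jointly")


def count_transmissions(units: AnalysisUnits) -> TransmissionCounts:
    """Count informative transmissions in complete trios.

    Heterozygous parents are informative; homozygous parents are not. For a
    het x het mating the child's two alleles identify the transmissions
    jointly: c=2 gives two T, c=0 two U, and a heterozygous child exactly one
    T and one U (the parental origin is ambiguous but the T/U tally is not).
    """
    counts = TransmissionCounts(locus=units.locus)
    for (m, f, c), (fid, _) in zip(units.trios, units.trio_families):
        if m == 1 and f == 1:
            if c == 2:
                counts.add(fid, 2, 0)
            elif c == 0:
                counts.add(fid, 0, 2)
            else:
                counts.add(fid, 1, 1)
            continue
        if m == 1:
            t, u = _transmissions_from_parent(f, c)
            counts.add(fid, t, u)
        if f == 1:
            t, u = _transmissions_from_parent(m, c)
            counts.add(fid, t, u)
    return counts


def tdt_statistics(counts: TransmissionCounts) -> TdtResult:
    """OR = T/U and the 1-df chi-square TDT statistic with asymptotic p."""
    t, u = counts.t, counts.u
    if t + u == 0:
        raise ValueError("no informative transmissions")
    if u == 0:
        odds_ratio, infinite = float(t), True
        logger.warning("U = 0: odds ratio is infinite; reporting T with flag")
    else:
        odds_ratio, infinite = t / u, False
    stat = (t - u) ** 2 / (t + u)
    return TdtResult(t=t, u=u, odds_ratio=odds_ratio, infinite_or=infinite,
                     chi2=stat, p_asymptotic=float(chi2.sf(stat, 1)))


def empirical_p(counts: TransmissionCounts, n_perm: int = 100_000,
                seed: int = 0, exact_limit: int = 20) -> TdtResult:
    """Two-sided empirical TDT p by family-level transmission flipping.

    Each permutation flips every family's (t, u) pair to (u, t) with
    probability 1/2 — jointly across all the family's transmissions, which
    preserves within-family sibling correlation. With ``<= exact_limit``
    informative families the 2^k flip patterns are enumerated exactly;
    otherwise ``n_perm`` Monte-Carlo permutations are drawn and the add-one
    estimator p = (1 + #{|T*-U*| >= |T-U|}) / (1 + n_perm) is reported.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    result = tdt_statistics(counts)
    # Families with t == u are invariant under flipping and can be dropped.
    fams = [(t, u) for t, u in counts.per_family.values() if t != u]
    obs = abs(counts.t - counts.u)
    k = len(fams)
    if k == 0:
        result.p_empirical, result.exact = 1.0, True
        result.n_permutations = 0
        return result
    diffs = np.array([t - u for t, u in fams])
    if k <= exact_limit:
        hits = total = 0
        for signs in itertools.product((1, -1), repeat=k):
            d = abs(int(np.dot(signs, diffs)))
            hits += d >= obs
            total += 1
        result.p_empirical = hits / total
        result.exact = True
        result.n_permutations = total
    else:
        rng = np.random.default_rng(seed)
        signs = rng.choice((1.0, -1.0), size=(n_perm, k))
        perm = np.abs(signs @ diffs)
        result.p_empirical = float((1 + (perm >= obs - 1e-9).sum())
                                   / (1 + n_perm))
        result.exact = False
        result.n_permutations = n_perm
        result.seed = seed
    return result


@dataclass
class AllelicTestResult:
    odds_ratio: float
    chi2: float
    p: float
    corrected: bool             # Haldane-Anscombe 0.5 applied (zero cell)


def allelic_test(alleles_group1: tuple[int, int],
                 alleles_group2: tuple[int, int]) -> AllelicTestResult:
    """Allelic 2x2 comparison between two groups of children.

    ``alleles_group*`` are (mutant, wild) allele counts. Returns the allele
    odds ratio (group1 vs group2) and the 1-df Pearson chi-square p without
    continuity correction; the Haldane-Anscombe 0.5 adjustment is applied to
    the OR only when a cell is zero.
    """
    (m1, w1), (m2, w2) = alleles_group1, alleles_group2
    if m1 + w1 == 0 or m2 + w2 == 0:
        raise ValueError("empty allele group")
    cells = np.array([[m1, w1], [m2, w2]], dtype=float)
    corrected = (cells == 0).any()
    oc = cells + 0.5 if corrected else cells
    odds_ratio = (oc[0, 0] * oc[1, 1]) / (oc[0, 1] * oc[1, 0])
    if corrected:
        logger.warning("zero cell in allelic test: Haldane-Anscombe "
                       "correction applied to the odds ratio")
    stat, p, _, _ = chi2_contingency(cells, correction=False)
    return AllelicTestResult(odds_ratio=float(odds_ratio), chi2=float(stat),
                             p=float(p), corrected=bool(corrected))


def child_allele_counts(units: AnalysisUnits) -> tuple[int, int]:
    """(mutant, wild) allele counts among affected children across all units."""
    mut = wt = 0
    for _, _, c in units.trios:
        mut += c
        wt += 2 - c
    for _, c in units.mother_duos:
        mut += c
        wt += 2 - c
    for _, c in units.father_duos:
        mut += c
        wt += 2 - c
    return mut, wt
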