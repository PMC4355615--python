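"""Pedigree and genotype handling for nuclear-family parent-of-origin analysis.

This module reads PLINK-style PED/MAP files describing nuclear families typed
at a small panel of biallelic loss-of-function variants, merges the panel into
a single combined locus (mutant-allele dosage 0/1/2), validates Mendelian
consistency, and decomposes the dataset into the analysis units the
multinomial likelihood consumes: case-parent trios, single-parent duos,
unrelated affected cases and population controls, together with their
genotype-configuration counts.

Dosage convention: an individual's genotype at a locus is the number of
mutant alleles carried, ``0``, ``1`` or ``2``; ``None`` marks a missing call.
Compound heterozygotes for two *different* panel mutations are coded dosage 2
at the combined locus, because loss-of-function mutations in one gene that
never co-occur on a haplotype must lie in trans.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Sentinel for a missing dosage (kept as None for clarity in Python code).
MISSING = None

Dosage = Optional[int]


@dataclass(frozen=True)
class VariantDef:
    """A biallelic variant in the panel.

    Parameters
    ----------
    id : str
        Variant label, e.g. ``"c.2282del4"``.
    chrom : str
        Chromosome label.
    pos : int
        1-based coordinate (GRCh37 for the default filaggrin panel).
    mutant_allele, wild_allele : str
        Allele tokens as they appear in the PED file.
    """

    id: str
    chrom: str
    pos: int
    mutant_allele: str
    wild_allele: str

    def __post_init__(self) -> None:
        if self.mutant_allele == self.wild_allele:
            raise ValueError(f"variant {self.id}: mutant and wild allele identical")


#: The four most prevalent European filaggrin (FLG) loss-of-function mutations.
#: Coordinates are approximate GRCh37 positions within FLG exon 3; the panel is
#: the default for four-variant simulations and file round-trips.
FLG_PANEL: tuple[VariantDef, ...] = (
    VariantDef("c.2282del4", "1", 152284896, "D", "I"),
    VariantDef("p.R501X", "1", 152285861, "T", "C"),
    VariantDef("p.R2447X", "1", 152280023, "T", "C"),
    VariantDef("p.S3247X", "1", 152277622, "A", "C"),
)


@dataclass
class Individual:
    """One genotyped person in a nuclear family (or an unrelated singleton)."""

    family_id: str
    individual_id: str
    father_id: str = "0"
    mother_id: str = "0"
    sex: int = 0
    affection: str = "unknown"  # {"affected", "unaffected", "unknown"}
    genotypes: list[Dosage] = field(default_factory=list)
    role: Optional[str] = None  # {"mother", "father", "child"} once placed
    covariates: dict = field(default_factory=dict)

    @property
    def combined(self) -> Dosage:
        """Combined-locus dosage across the panel (see :func:`combine_mutations`)."""
        return combine_dosages(self.genotypes)

    def dosage_at(self, locus) -> Dosage:
        """Dosage at ``locus``: ``"combined"`` or an integer panel index."""
        if locus == "combined":
            return self.combined
        return self.genotypes[locus]


@dataclass
class NuclearFamily:
    """A nuclear family: up to two parents plus >=1 children."""

    family_id: str
    mother: Optional[Individual] = None
    father: Optional[Individual] = None
    children: list[Individual] = field(default_factory=list)
    covariates: dict = field(default_factory=dict)

    @property
    def completeness(self) -> str:
        if self.mother is not None and self.father is not None:
            return "complete"
        if self.mother is not None:
            return "mother_only"
        if self.father is not None:
            return "father_only"
        return "children_only"

    def affected_children(self) -> list[Individual]:
        return [c for c in self.children if c.affection == "affected"]


@dataclass
class AnalysisUnits:
    """PREMIM-style decomposition of a dataset at one locus.

    ``trios`` holds (mother, father, child) dosage triples; duos the pairs with
    one parent missing; ``cases``/``controls`` hold child/singleton dosages.
    ``trio_families`` etc. record provenance (family id, child id) parallel to
    the unit lists, which the permutation TDT uses to flip whole families.
    """

    trios: list[tuple[int, int, int]] = field(default_factory=list)
    mother_duos: list[tuple[int, int]] = field(default_factory=list)
    father_duos: list[tuple[int, int]] = field(default_factory=list)
    cases: list[int] = field(default_factory=list)
    controls: list[int] = field(default_factory=list)
    trio_families: list[tuple[str, str]] = field(default_factory=list)
    mother_duo_families: list[tuple[str, str]] = field(default_factory=list)
    father_duo_families: list[tuple[str, str]] = field(default_factory=list)
    locus: object = "combined"

    @property
    def n_units(self) -> int:
        return (len(self.trios) + len(self.mother_duos) + len(self.father_duos)
                + len(self.cases) + len(self.controls))


# Canonical orderings of observable genotype configurations. All 15 trio
# configurations compatible with biallelic Mendelian transmission, and the 7
# compatible parent-child pairs, in lexicographic order.
def _mendelian_trios() -> list[tuple[int, int, int]]:
    out = []
    for m in range(3):
        for f in range(3):
            for c in range(3):
                if mendelian_check(m, f, c):
                    out.append((m, f, c))
    return out


def mendelian_check(m: int, f: int, c: int) -> bool:
    """True iff child dosage ``c`` is producible from parental dosages (m, f)."""
    mat = {0: (0,), 1: (0, 1), 2: (1,)}[m]
    pat = {0: (0,), 1: (0, 1), 2: (1,)}[f]
    return any(am + af == c for am in mat for af in pat)


def duo_check(p: int, c: int) -> bool:
    """True iff a parent-child dosage pair is compatible (other parent free)."""
    return any(mendelian_check(p, f, c) for f in range(3))


TRIO_CONFIGS: tuple[tuple[int, int, int], ...] = tuple(_mendelian_trios())
TRIO_INDEX = {cfg: i for i, cfg in enumerate(TRIO_CONFIGS)}
DUO_CONFIGS: tuple[tuple[int, int], ...] = tuple(
    (p, c) for p in range(3) for c in range(3) if duo_check(p, c)
)
DUO_INDEX = {cfg: i for i, cfg in enumerate(DUO_CONFIGS)}

assert len(TRIO_CONFIGS) == 15 and len(DUO_CONFIGS) == 7


@dataclass
class CellCounts:
    """Observed counts over genotype configurations for every unit type."""

    trio: np.ndarray = field(default_factory=lambda: np.zeros(15))
    mother_duo: np.ndarray = field(default_factory=lambda: np.zeros(7))
    father_duo: np.ndarray = field(default_factory=lambda: np.zeros(7))
    case: np.ndarray = field(default_factory=lambda: np.zeros(3))
    control: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.trio = np.asarray(self.trio, dtype=float)
        self.mother_duo = np.asarray(self.mother_duo, dtype=float)
        self.father_duo = np.asarray(self.father_duo, dtype=float)
        self.case = np.asarray(self.case, dtype=float)
        self.control = np.asarray(self.control, dtype=float)
        shapes = (self.trio.shape, self.mother_duo.shape, self.father_duo.shape,
                  self.case.shape, self.control.shape)
        if shapes != ((15,), (7,), (7,), (3,), (3,)):
            raise ValueError(f"bad CellCounts shapes: {shapes}")
        if (np.concatenate([self.trio, self.mother_duo, self.father_duo,
                            self.case, self.control]) < 0).any():
            raise ValueError("negative cell count")

    @property
    def total(self) -> float:
        return float(self.trio.sum() + self.mother_duo.sum()
                     + self.father_duo.sum() + self.case.sum()
                     + self.control.sum())

    @classmethod
    def from_trio_dict(cls, d: dict) -> "CellCounts":
        trio = np.zeros(15)
        for cfg, n in d.items():
            trio[TRIO_INDEX[tuple(cfg)]] = n
        return cls(trio=trio)

    def trio_count(self, m: int, f: int, c: int) -> float:
        return float(self.trio[TRIO_INDEX[(m, f, c)]])

    def to_frame(self) -> pd.DataFrame:
        """Long-format audit table (configuration label, count)."""
        rows = []
        for (m, f, c), n in zip(TRIO_CONFIGS, self.trio):
            rows.append(("trio", f"m{m}_f{f}_c{c}", n))
        for (p, c), n in zip(DUO_CONFIGS, self.mother_duo):
            rows.append(("mother_duo", f"m{p}_c{c}", n))
        for (p, c), n in zip(DUO_CONFIGS, self.father_duo):
            rows.append(("father_duo", f"f{p}_c{c}", n))
        for g, n in enumerate(self.case):
            rows.append(("case", f"c{g}", n))
        for g, n in enumerate(self.control):
            rows.append(("control", f"c{g}", n))
        return pd.DataFrame(rows, columns=["unit", "configuration", "count"])

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def __add__(self, other: "CellCounts") -> "CellCounts":
        return CellCounts(self.trio + other.trio,
                          self.mother_duo + other.mother_duo,
                          self.father_duo + other.father_duo,
                          self.case + other.case,
                          self.control + other.control)


# ---------------------------------------------------------------------------
# Combined genotype
# ---------------------------------------------------------------------------

def combine_dosages(dosages: Sequence[Dosage]) -> Dosage:
    """Merge per-variant dosages into the combined-locus dosage.

    Rules: observed mutant alleles are summed and capped at 2 (two different
    mutations are carried in trans, so a compound heterozygote is dosage 2 at
    the merged locus). If every variant is observed wild-type the combined
    dosage is 0. If any variant is missing and no mutant allele was seen, the
    combined dosage is missing — a hidden carrier cannot be excluded.
    """
    observed = [d for d in dosages if d is not None]
    total = sum(observed)
    if total >= 1:
        return min(2, total)
    if len(observed) == len(dosages):
        return 0
    return MISSING


def combine_mutations(individual: Individual,
                      panel: Optional[Sequence[VariantDef]] = None) -> Dosage:
    """Combined dosage for one individual (order-independent in the panel)."""
    if panel is not None and len(individual.genotypes) != len(panel):
        raise ValueError("genotype vector length does not match panel")
    return combine_dosages(individual.genotypes)


# ---------------------------------------------------------------------------
# PED/MAP reading
# ---------------------------------------------------------------------------

def read_mapfile(map_path) -> list[dict]:
    """Read a PLINK MAP file: columns chrom, id, cM, pos."""
    variants = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, 1):
            tok = line.split()
            if not tok:
                continue
            if len(tok) != 4:
                raise ValueError(f"{map_path}:{lineno}: expected 4 MAP columns, got {len(tok)}")
            variants.append({"chrom": tok[0], "id": tok[1], "pos": int(tok[3])})
    return variants


def _phenotype(token: str, coding: tuple[str, str] = ("1", "2")) -> str:
    unaff, aff = coding
    if token == aff:
        return "affected"
    if token == unaff:
        return "unaffected"
    return "unknown"


def read_pedfile(ped_path, map_path,
                 panel: Optional[Sequence[VariantDef]] = None,
                 phenotype_coding: tuple[str, str] = ("1", "2"),
                 ) -> tuple[list[NuclearFamily], list[Individual]]:
    """Read PED + MAP into nuclear families and unrelated individuals.

    The PED dialect is whitespace-separated with columns family-id,
    individual-id, father-id, mother-id, sex, phenotype, then two allele
    tokens per MAP variant; ``0`` is the missing-allele token. Mutant alleles
    are taken from ``panel`` (matched to MAP variant ids); without a panel the
    minor allele at each variant is treated as the mutant.

    Returns ``(families, unrelated)`` where unrelated individuals have both
    parental ids ``0`` and are referenced by no one.
    """
    variants = read_mapfile(map_path)
    n_var = len(variants)
    mutant: list[Optional[str]] = [None] * n_var
    if panel is not None:
        by_id = {v.id: v for v in panel}
        for j, v in enumerate(variants):
            if v["id"] in by_id:
                mutant[j] = by_id[v["id"]].mutant_allele

    rows: list[tuple[Individual, list[tuple[str, str]]]] = []
    seen: set[tuple[str, str]] = set()
    allele_counts: list[dict] = [dict() for _ in range(n_var)]
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            tok = line.split()
            if not tok:
                continue
            if len(tok) != 6 + 2 * n_var:
                raise ValueError(
                    f"{ped_path}:{lineno}: expected {6 + 2 * n_var} columns "
                    f"({n_var} variants), got {len(tok)}")
            fid, iid, pat, mat, sex, phe = tok[:6]
            if (fid, iid) in seen:
                raise ValueError(f"{ped_path}:{lineno}: duplicate individual "
                                 f"{iid!r} in family {fid!r}")
            seen.add((fid, iid))
            pairs = [(tok[6 + 2 * j], tok[7 + 2 * j]) for j in range(n_var)]
            for j, (a, b) in enumerate(pairs):
                for al in (a, b):
                    if al != "0":
                        allele_counts[j][al] = allele_counts[j].get(al, 0) + 1
            ind = Individual(fid, iid, pat, mat,
                             int(sex) if sex.isdigit() else 0,
                             _phenotype(phe, phenotype_coding))
            rows.append((ind, pairs))

    # Infer mutant allele as the minor allele where the panel did not say.
    for j in range(n_var):
        if mutant[j] is None:
            counts = allele_counts[j]
            mutant[j] = (min(counts, key=lambda a: (counts[a], a))
                         if counts else "?")

    for ind, pairs in rows:
        geno: list[Dosage] = []
        for j, (a, b) in enumerate(pairs):
            if a == "0" or b == "0":
                geno.append(MISSING)
            else:
                geno.append(int(a == mutant[j]) + int(b == mutant[j]))
        ind.genotypes = geno

    # Assemble nuclear families: children reference parents by id.
    by_family: dict[str, list[Individual]] = {}
    for ind, _ in rows:
        by_family.setdefault(ind.family_id, []).append(ind)

    families: list[NuclearFamily] = []
    unrelated: list[Individual] = []
    for fid, members in by_family.items():
        by_id2 = {m.individual_id: m for m in members}
        children = [m for m in members if m.father_id != "0" or m.mother_id != "0"]
        parent_ids = {c.mother_id for c in children} | {c.father_id for c in children}
        parent_ids.discard("0")
        if not children:
            unrelated.extend(members)
            continue
        mother_ids = {c.mother_id for c in children} - {"0"}
        father_ids = {c.father_id for c in children} - {"0"}
        if len(mother_ids) > 1 or len(father_ids) > 1:
            raise ValueError(f"family {fid!r}: multiple parent sets "
                             "(general pedigrees are not supported)")
        fam = NuclearFamily(fid)
        fam.mother = by_id2.get(next(iter(mother_ids), "0"))
        fam.father = by_id2.get(next(iter(father_ids), "0"))
        if fam.mother is not None:
            fam.mother.role = "mother"
        if fam.father is not None:
            fam.father.role = "father"
        for c in children:
            c.role = "child"
        fam.children = children
        families.append(fam)
        for m in members:
            if m not in children and m.individual_id not in parent_ids:
                unrelated.append(m)
    return families, unrelated


def read_covariates(path) -> pd.DataFrame:
    """Read the per-family covariate table.

    Tab-separated columns: ``family_id``, ``mother_AD_history`` {0,1,NA},
    ``father_AD_history``, ``maternal_sensitization`` {0,1,NA}.
    """
    df = pd.read_csv(path, sep="\t", dtype={"family_id": str},
                     na_values=["NA"])
    required = {"family_id", "mother_AD_history", "father_AD_history",
                "maternal_sensitization"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"covariate file missing columns: {sorted(missing)}")
    return df


def attach_covariates(families: Iterable[NuclearFamily],
                      covariates: pd.DataFrame) -> None:
    """Join covariate rows onto families by family id (in place)."""
    by_fid = covariates.set_index("family_id")
    for fam in families:
        if fam.family_id in by_fid.index:
            row = by_fid.loc[fam.family_id]
            fam.covariates = {
                k: (None if pd.isna(row[k]) else int(row[k]))
                for k in ("mother_AD_history", "father_AD_history",
                          "maternal_sensitization")
            }


# ---------------------------------------------------------------------------
# Unit extraction and tabulation
# ---------------------------------------------------------------------------

def extract_units(families: Iterable[NuclearFamily],
                  unrelated: Iterable[Individual] = (),
                  one_child_per_family: bool = False,
                  strata_filter: Optional[Callable[[NuclearFamily], bool]] = None,
                  locus="combined") -> AnalysisUnits:
    """Decompose families + unrelated individuals into analysis units.

    Every affected child in a complete family yields one trio sharing that
    family's parents (the families-as-independent-trios convention); with
    ``one_child_per_family`` only the first affected child in file order does.
    A trio whose mother or father has a missing genotype is downgraded to the
    corresponding duo; a missing child genotype drops the unit. Mendelian-
    inconsistent trios are excluded with a logged warning. ``strata_filter``
    drops whole families (used for sensitization / parental-history strata).
    Unrelated affected individuals become cases; the rest become controls
    (population controls are used irrespective of affection upstream).
    """
    units = AnalysisUnits(locus=locus)
    for fam in families:
        if strata_filter is not None and not strata_filter(fam):
            continue
        affected = fam.affected_children()
        if one_child_per_family:
            affected = affected[:1]
        m_dos = fam.mother.dosage_at(locus) if fam.mother is not None else MISSING
        f_dos = fam.father.dosage_at(locus) if fam.father is not None else MISSING
        for child in affected:
            c_dos = child.dosage_at(locus)
            if c_dos is MISSING:
                logger.warning("family %s child %s: missing genotype, unit dropped",
                               fam.family_id, child.individual_id)
                continue
            prov = (fam.family_id, child.individual_id)
            if m_dos is not MISSING and f_dos is not MISSING:
                if not mendelian_check(m_dos, f_dos, c_dos):
                    logger.warning("family %s child %s: Mendelian inconsistency "
                                   "(%s,%s,%s), trio excluded", fam.family_id,
                                   child.individual_id, m_dos, f_dos, c_dos)
                    continue
                units.trios.append((m_dos, f_dos, c_dos))
                units.trio_families.append(prov)
            elif m_dos is not MISSING:
                if not duo_check(m_dos, c_dos):
                    logger.warning("family %s child %s: impossible mother-child "
                                   "pair (%s,%s), duo excluded", fam.family_id,
                                   child.individual_id, m_dos, c_dos)
                    continue
                units.mother_duos.append((m_dos, c_dos))
                units.mother_duo_families.append(prov)
            elif f_dos is not MISSING:
                if not duo_check(f_dos, c_dos):
                    logger.warning("family %s child %s: impossible father-child "
                                   "pair (%s,%s), duo excluded", fam.family_id,
                                   child.individual_id, f_dos, c_dos)
                    continue
                units.father_duos.append((f_dos, c_dos))
                units.father_duo_families.append(prov)
            # both parents missing: the child alone carries no trio information
        # Unaffected children never yield units.
    for ind in unrelated:
        dos = ind.dosage_at(locus)
        if dos is MISSING:
            continue
        if ind.affection == "affected":
            units.cases.append(dos)
        else:
            units.controls.append(dos)
    return units


def tabulate_cells(units: AnalysisUnits) -> CellCounts:
    """Count analysis units over the observable genotype configurations."""
    counts = CellCounts()
    for t in units.trios:
        counts.trio[TRIO_INDEX[t]] += 1
    for d in units.mother_duos:
        counts.mother_duo[DUO_INDEX[d]] += 1
    for d in units.father_duos:
        counts.father_duo[DUO_INDEX[d]] += 1
    for c in units.cases:
        counts.case[c] += 1
    for c in units.controls:
        counts.control[c] += 1
    return counts


@dataclass
class FounderFrequency:
    """Mutant-allele frequency among family founders, split by parent."""

    overall: float
    mothers: Optional[float]
    fathers: Optional[float]
    n_founders: int


def founder_freq(families: Iterable[NuclearFamily],
                 locus="combined") -> FounderFrequency:
    """Mutant-allele frequency in founders, overall and by parental sex.

    The mother/father split supports the parental-asymmetry comparison: in
    families ascertained through affected children, a maternal genotype
    effect enriches mutations in mothers relative to fathers.
    """
    m_alleles = m_n = f_alleles = f_n = 0
    for fam in families:
        for parent, is_mother in ((fam.mother, True), (fam.father, False)):
            if parent is None:
                continue
            dos = parent.dosage_at(locus)
            if dos is MISSING:
                continue
            if is_mother:
                m_alleles += dos
                m_n += 2
            else:
                f_alleles += dos
                f_n += 2
    if m_n + f_n == 0:
        raise ValueError("no genotyped founders")
    return FounderFrequency(
        overall=(m_alleles + f_alleles) / (m_n + f_n),
        mothers=m_alleles / m_n if m_n else None,
        fathers=f_alleles / f_n if f_n else None,
        n_founders=(m_n + f_n) // 2,
    )
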