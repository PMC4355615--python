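"""Orchestration of the full family-based parent-of-origin analysis.

Runs, per study: combined and per-mutation TDT with permutation p-values,
the nested model ladder of the multinomial likelihood, stratified analyses
(maternal sensitization; parental-history-negative families) and robustness
variants (parent swap, one affected child per family, interaction model),
then pools risk-parameter estimates across studies by inverse-variance
meta-analysis with heterogeneity tests.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from . import family_data as fd
from . import likelihood as lk
from . import meta as mt
from . import tdt as td

logger = logging.getLogger(__name__)


@dataclass
class Study:
    """One study's in-memory data: families plus optional unrelated panels."""

    label: str
    families: list[fd.NuclearFamily]
    unrelated: list[fd.Individual] = field(default_factory=list)
    panel: Optional[Sequence[fd.VariantDef]] = None
    has_covariates: bool = False


def load_study(label: str, ped_path, map_path, covariates_path=None,
               panel: Optional[Sequence[fd.VariantDef]] = None) -> Study:
    """Read one study from PED/MAP (+ optional covariate) files."""
    families, unrelated = fd.read_pedfile(ped_path, map_path, panel=panel)
    has_cov = covariates_path is not None
    if has_cov:
        fd.attach_covariates(families, fd.read_covariates(covariates_path))
    return Study(label, families, unrelated, panel, has_cov)


# ---------------------------------------------------------------------------
# Stratification
# ---------------------------------------------------------------------------

STRATA_RULES: dict[str, Callable[[fd.NuclearFamily], bool]] = {
    # Families with a missing flag are dropped by both sensitization rules.
    "sensitized": lambda fam: fam.covariates.get("maternal_sensitization") == 1,
    "not_sensitized":
        lambda fam: fam.covariates.get("maternal_sensitization") == 0,
    # Both parents must have an explicitly negative AD history; positive or
    # unknown history excludes the family.
    "parents_negative_history":
        lambda fam: (fam.covariates.get("mother_AD_history") == 0
                     and fam.covariates.get("father_AD_history") == 0),
}


def stratify_families(families: Sequence[fd.NuclearFamily],
                      rule: str) -> list[fd.NuclearFamily]:
    """Select the family subset for a named stratum rule."""
    if rule not in STRATA_RULES:
        raise ValueError(f"unknown stratum rule {rule!r}; "
                         f"known: {sorted(STRATA_RULES)}")
    keep = STRATA_RULES[rule]
    return [fam for fam in families if keep(fam)]


# ---------------------------------------------------------------------------
# Report bundle
# ---------------------------------------------------------------------------

@dataclass
class ReportBundle:
    """All tables of one full analysis run."""

    tdt_table: pd.DataFrame
    ladder_tables: dict            # study label -> DataFrame
    ladders: dict                  # study label -> LadderResult
    meta_table: pd.DataFrame
    strata_tables: dict            # (study, rule) -> dict of tables
    robustness: dict               # name -> DataFrame / dict
    run_log: dict

    def write(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.tdt_table.to_csv(out / "tdt.tsv", sep="\t", index=False)
        for label, df in self.ladder_tables.items():
            df.to_csv(out / f"ladder_{label}.tsv", sep="\t", index=False)
        self.meta_table.to_csv(out / "meta.tsv", sep="\t", index=False)
        for (label, rule), tables in self.strata_tables.items():
            for name, df in tables.items():
                if isinstance(df, pd.DataFrame):
                    df.to_csv(out / f"strata_{label}_{rule}_{name}.tsv",
                              sep="\t", index=False)
        with open(out / "run_log.json", "w") as fh:
            json.dump(self.run_log, fh, indent=2, default=str)


def _tdt_row(study: str, locus_label: str, units: fd.AnalysisUnits,
             n_perm: int, seed: int) -> Optional[dict]:
    counts = td.count_transmissions(units)
    if counts.t + counts.u == 0:
        logger.warning("%s %s: no informative transmissions", study,
                       locus_label)
        return None
    res = td.empirical_p(counts, n_perm=n_perm, seed=seed)
    return {"study": study, "locus": locus_label, "T": res.t, "U": res.u,
            "OR": round(res.odds_ratio, 2), "OR_infinite": res.infinite_or,
            "P_asymptotic": res.p_asymptotic, "P_empirical": res.p_empirical,
            "exact": res.exact, "n_permutations": res.n_permutations}


def _ladder_frame(ladder: lk.LadderResult) -> pd.DataFrame:
    df = ladder.to_frame()
    cis = {name: lk.wald_ci(fit) for name, fit in ladder.fits.items()}
    for param in ("r1", "r2", "s1", "im"):
        lo, hi = [], []
        for name in df["model"]:
            ci = cis[name].get(param)
            lo.append(ci[0] if ci else float("nan"))
            hi.append(ci[1] if ci else float("nan"))
        if not all(np.isnan(lo)):
            df[f"{param.upper()}_lo"] = lo
            df[f"{param.upper()}_hi"] = hi
    return df


def run_full_analysis(studies: Sequence[Study],
                      one_child_per_family: bool = False,
                      parent_swap: bool = False,
                      per_mutation: bool = False,
                      strata: Sequence[str] = (),
                      include_interaction: bool = False,
                      include_unrelated: bool = True,
                      n_perm: int = 10_000,
                      seed: int = 0) -> ReportBundle:
    """Execute the full published-analysis workflow over one or more studies.

    Stratified runs exclude unrelated cases and controls (their covariates
    are unavailable by construction). Robustness variants run per flag:
    parent swap (paternal-effect check), one affected child per family,
    per-mutation TDT, parental-history filter via ``strata``, and the
    interaction model on the ladder.
    """
    if not studies:
        raise ValueError("need at least one study")
    for rule in strata:
        if rule not in STRATA_RULES:
            raise ValueError(f"unknown stratum rule {rule!r}")
        for study in studies:
            if not study.has_covariates:
                raise ValueError(
                    f"stratum {rule!r} requires covariates, absent for "
                    f"study {study.label!r}")

    tdt_rows = []
    ladder_tables: dict = {}
    ladders: dict = {}
    strata_tables: dict = {}
    robustness: dict = {}
    study_fits: dict = {}

    for study in studies:
        unrelated = study.unrelated if include_unrelated else []
        units = fd.extract_units(study.families, unrelated,
                                 one_child_per_family=one_child_per_family)
        row = _tdt_row(study.label, "combined", units, n_perm, seed)
        if row:
            tdt_rows.append(row)
        if per_mutation:
            n_var = len(study.families[0].children[0].genotypes)
            for j in range(n_var):
                vlabel = (study.panel[j].id if study.panel else f"variant{j}")
                u_j = fd.extract_units(study.families, unrelated,
                                       one_child_per_family=one_child_per_family,
                                       locus=j)
                row = _tdt_row(study.label, vlabel, u_j, n_perm, seed)
                if row:
                    tdt_rows.append(row)

        counts = fd.tabulate_cells(units)
        ladder = lk.run_ladder(counts, include_interaction=include_interaction,
                               seed=seed)
        ladders[study.label] = ladder
        ladder_tables[study.label] = _ladder_frame(ladder)
        study_fits[study.label] = ladder.fits

        if parent_swap:
            swapped = lk.swap_parents(counts)
            fit = lk.fit_model(swapped, "mcg", seed=seed)
            robustness.setdefault("parent_swap", {})[study.label] = {
                "S1_paternal": fit.estimates["s1"],
                "ci": lk.wald_ci(fit).get("s1"),
                "lnlik": fit.loglik,
            }

        for rule in strata:
            sub = stratify_families(study.families, rule)
            if not sub:
                logger.warning("%s: stratum %r is empty, skipped",
                               study.label, rule)
                continue
            # Unrelated cases/controls are excluded from stratified runs.
            s_units = fd.extract_units(sub, [],
                                       one_child_per_family=one_child_per_family)
            s_counts = fd.tabulate_cells(s_units)
            tables: dict = {"n_families": len(sub)}
            s_row = _tdt_row(f"{study.label}/{rule}", "combined", s_units,
                             n_perm, seed)
            if s_row:
                tables["tdt"] = pd.DataFrame([s_row])
            fits = {name: lk.fit_model(s_counts, name, seed=seed)
                    for name in ("null", "cg", "mcg")}
            rows = []
            for name in ("cg", "mcg"):
                fit = fits[name]
                row = fit.summary_row()
                row["P_null"] = lk.lrt(fits["null"], fit).p
                if name == "mcg":
                    row["P_MCG_vs_CG"] = lk.lrt(fits["cg"], fit).p
                rows.append(row)
            tables["models"] = pd.DataFrame(rows)
            tables["units"] = s_units
            strata_tables[(study.label, rule)] = tables

    # Allelic comparison of affected children between sensitization strata.
    for study in studies:
        key_pos = (study.label, "sensitized")
        key_neg = (study.label, "not_sensitized")
        if key_pos in strata_tables and key_neg in strata_tables:
            neg = td.child_allele_counts(strata_tables[key_neg]["units"])
            pos = td.child_allele_counts(strata_tables[key_pos]["units"])
            res = td.allelic_test(neg, pos)
            robustness.setdefault("allelic_sensitization", {})[study.label] = {
                "mut_freq_not_sensitized": neg[0] / sum(neg),
                "mut_freq_sensitized": pos[0] / sum(pos),
                "OR": res.odds_ratio, "P": res.p,
            }

    meta_rows = []
    if len(studies) >= 1:
        for model in ("cg", "mcg", "im", "full"):
            for param in lk.MODELS[model]:
                ests = []
                for study in studies:
                    fit = study_fits[study.label][model]
                    se = fit.se_log.get(param)
                    if se is not None and param not in fit.boundary_flags:
                        ests.append(mt.StudyEstimate(study.label,
                                                     np.log(fit.estimates[param]),
                                                     se))
                if not ests:
                    continue
                pooled = mt.inverse_variance_meta(ests)
                meta_rows.append({
                    "model": model, "parameter": param.upper(),
                    "pooled": pooled.rr, "ci_lo": pooled.ci[0],
                    "ci_hi": pooled.ci[1], "P_meta": pooled.p,
                    "Q": pooled.q, "P_het": pooled.p_heterogeneity,
                    "n_studies": pooled.n_studies,
                })
    meta_table = pd.DataFrame(meta_rows)

    run_log = {
        "seed": seed, "n_perm": n_perm,
        "one_child_per_family": one_child_per_family,
        "parent_swap": parent_swap, "per_mutation": per_mutation,
        "strata": list(strata), "include_unrelated": include_unrelated,
        "studies": [s.label for s in studies],
    }
    return ReportBundle(pd.DataFrame(tdt_rows), ladder_tables, ladders,
                        meta_table, strata_tables, robustness, run_log)
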