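"""Dual-cohort intersection of association signals and sensitivity metrics.

A SNP is concordant when it reaches P < alpha in both the family (TDT) and
case-control (logistic) cohorts with the effect in the same direction for
a harmonised effect allele.  Under two independent null cohorts the
expected concordant fraction is alpha^2 / 2 (both P below alpha and two
equiprobable directions agreeing).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass
class SensitivityRecord:
    n_total: int
    n_retained: int
    n_lost: int
    n_rescued: int

    @property
    def frac_retained(self) -> float:
        return self.n_retained / self.n_total if self.n_total else 0.0

    @property
    def frac_rescued(self) -> float:
        return self.n_rescued / self.n_total if self.n_total else 0.0

    @property
    def frac_combined(self) -> float:
        return self.frac_retained + self.frac_rescued


@dataclass
class ConcordanceReport:
    alpha: float
    table: pd.DataFrame
    snps_concordant: set[str]
    n_only_one_cohort: int = 0
    n_ambiguous_alleles: int = 0
    sensitivity: SensitivityRecord | None = None


def _harmonize(fam: pd.DataFrame, cc: pd.DataFrame) -> tuple[pd.DataFrame, int, int]:
    """Merge the two result sets on variant_id with effect alleles aligned.

    When the case-control effect allele is the family cohort's other
    allele, its direction is flipped and OR inverted.  Pairs that match
    neither directly nor by swap — including strand-ambiguous A/T / C/G
    flips — are dropped with a warning.
    """
    merged = fam.merge(cc, on="variant_id", suffixes=("_family", "_cc"))
    n_only_one = len(set(fam.variant_id) ^ set(cc.variant_id))

    ea_f = merged["effect_allele_family"].astype(str)
    oa_f = merged["other_allele_family"].astype(str)
    ea_c = merged["effect_allele_cc"].astype(str)
    oa_c = merged["other_allele_cc"].astype(str)
    same = (ea_f == ea_c) & (oa_f == oa_c)
    swapped = (ea_f == oa_c) & (oa_f == ea_c)
    ambiguous = ~(same | swapped)
    merged.loc[swapped, "direction_cc"] *= -1
    with np.errstate(divide="ignore"):
        merged.loc[swapped, "odds_ratio_cc"] = 1.0 / merged.loc[swapped, "odds_ratio_cc"]
    if ambiguous.any():
        warnings.warn(f"dropping {int(ambiguous.sum())} variants with "
                      "unharmonizable (possibly strand-flipped) alleles")
        merged = merged[~ambiguous]
    return merged.reset_index(drop=True), n_only_one, int(ambiguous.sum())


def intersect_snps(res_family: pd.DataFrame, res_cc: pd.DataFrame,
                   alpha: float = 0.05) -> ConcordanceReport:
    """SNPs with P < alpha (strict) in both cohorts and matching direction.

    Direction must be equal and nonzero after effect-allele harmonisation.
    Variants present in only one result set are excluded and counted in
    the report.
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0,1]")
    merged, n_only_one, n_ambig = _harmonize(res_family, res_cc)
    conc = ((merged["p_value_family"] < alpha)
            & (merged["p_value_cc"] < alpha)
            & (merged["direction_family"] == merged["direction_cc"])
            & (merged["direction_family"] != 0))
    table = merged[["variant_id", "p_value_family", "odds_ratio_family",
                    "direction_family", "p_value_cc", "odds_ratio_cc",
                    "direction_cc"]].copy()
    table["concordant"] = conc.to_numpy()
    return ConcordanceReport(
        alpha=alpha,
        table=table,
        snps_concordant=set(table.loc[table["concordant"], "variant_id"]),
        n_only_one_cohort=n_only_one,
        n_ambiguous_alleles=n_ambig,
    )


def sensitivity_reanalysis(full: ConcordanceReport, reduced: pd.DataFrame,
                           snp_to_gene: dict[str, list[str]],
                           alpha: float | None = None) -> SensitivityRecord:
    """Leave-samples-out robustness of the concordant SNP set.

    ``reduced`` holds the family-cohort reanalysis (some families
    excluded).  A concordant SNP is *retained* when its reduced-analysis P
    stays below alpha, *lost* otherwise; a lost SNP is *rescued* when it
    maps to a gene that still contains at least one retained SNP.  SNPs
    absent from the reduced results count as lost.
    """
    alpha = full.alpha if alpha is None else alpha
    reduced_p = dict(zip(reduced["variant_id"], reduced["p_value"]))
    concordant = sorted(full.snps_concordant)
    retained = {s for s in concordant
                if s in reduced_p and reduced_p[s] < alpha}
    lost = [s for s in concordant if s not in retained]
    retained_genes = {g for s in retained for g in snp_to_gene.get(s, ())}
    rescued = [s for s in lost
               if any(g in retained_genes for g in snp_to_gene.get(s, ()))]
    rec = SensitivityRecord(
        n_total=len(concordant),
        n_retained=len(retained),
        n_lost=len(lost),
        n_rescued=len(rescued),
    )
    full.sensitivity = rec
    return rec
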