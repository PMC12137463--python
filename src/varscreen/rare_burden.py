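"""Rare-variant qualification, carrier counting and gene-wide burden tests.

A *qualifying* variant is rare in the NFE reference population
(AF <= 0.001) and called damaging by at least one of 14 in-silico
predictor calls.  Carriers are counted once per gene per model:
HET (>= 1 qualifying het, no qualifying hom-alt), CH (unphased compound
het: >= 2 distinct qualifying hets, a subset of HET), HOM (>= 1 qualifying
hom-alt).  Dominant carriers = HET + HOM; recessive = CH + HOM.  The
burden test is the one-tailed (case-enrichment) Fisher exact test on
carriers vs non-carriers, with genome-wide significance at
alpha / 21,306 = 2.347E-06 under Bonferroni correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

from .containers import MISSING, PREDICTOR_FIELDS, CarrierTable, ExomeCohort

#: The 14 damaging-call predicates of the qualification rule, as
#: (annotation column, damaging value) pairs.
DEFAULT_PREDICATES: tuple[tuple[str, str], ...] = (
    ("SIFT_pred", "D"),
    ("Polyphen2_HDIV_pred", "D"),
    ("Polyphen2_HDIV_pred", "P"),
    ("Polyphen2_HVAR_pred", "D"),
    ("Polyphen2_HVAR_pred", "P"),
    ("LRT_pred", "D"),
    ("MutationTaster_pred", "A"),
    ("MutationTaster_pred", "D"),
    ("MutationAssessor_pred", "H"),
    ("MutationAssessor_pred", "M"),
    ("FATHMM_pred", "D"),
    ("PROVEAN_pred", "D"),
    ("MetaSVM_pred", "D"),
    ("MetaLR_pred", "D"),
)

GENES_TOTAL_DEFAULT = 21_306


@dataclass(frozen=True)
class QualifyingRule:
    """MAF ceiling plus a predictor vote (>= min_predicates must hit)."""

    maf_max: float = 0.001
    predicates: tuple[tuple[str, str], ...] = DEFAULT_PREDICATES
    min_predicates: int = 1

    def __post_init__(self) -> None:
        if not 0 < self.maf_max < 1:
            raise ValueError("maf_max must be in (0,1)")
        if self.min_predicates < 1:
            raise ValueError("min_predicates must be >= 1")


def qualify_variants(cohort: ExomeCohort, rule: QualifyingRule = QualifyingRule()
                     ) -> tuple[ExomeCohort, pd.DataFrame]:
    """Select variants of interest under the MAF + predictor-vote rule.

    Keeps variants with reference AF <= rule.maf_max (absent AF counts as
    0, i.e. novel) AND >= rule.min_predicates satisfied damaging-call
    predicates.  Returns (qualifying subset, per-variant exclusion report).
    """
    v = cohort.variants
    af = v["af_nfe"].fillna(0.0).to_numpy(dtype=float)
    rare = af <= rule.maf_max
    votes = np.zeros(len(v), dtype=int)
    for column, value in rule.predicates:
        if column in v.columns:
            votes += (v[column].astype(str).str.strip() == value).to_numpy()
    damaging = votes >= rule.min_predicates
    keep = rare & damaging
    reason = np.where(keep, "", np.where(~rare, "maf_above_max",
                      np.where(~damaging, "no_damaging_call", "")))
    # a variant can fail both tests; report the MAF reason first
    report = pd.DataFrame({
        "variant_id": v["variant_id"],
        "qualifying": keep,
        "reason": reason,
        "af_nfe": af,
        "n_damaging_calls": votes,
    })
    return cohort.subset_variants(keep), report


def count_carriers(qualifying: ExomeCohort) -> CarrierTable:
    """Per-gene HET / CH / HOM carrier counts for cases and controls.

    Each individual is classified once per gene from their qualifying
    genotypes: HOM if any homozygous-alternate call; otherwise HET if >= 1
    het call, with CH flagged for >= 2 distinct het variants (unphased).
    Missing genotypes simply do not contribute a carried allele.
    """
    v = qualifying.variants
    g = qualifying.genotypes
    rows = {}
    for gene, idx in v.groupby("gene", sort=True).indices.items():
        sub = g[:, idx]
        n_het = (sub == 1).sum(axis=1)
        any_hom = (sub == 2).any(axis=1)
        is_hom = any_hom
        is_het = (n_het >= 1) & ~any_hom
        is_ch = is_het & (n_het >= 2)
        case = qualifying.is_case
        rows[gene] = {
            "case_het": int((is_het & case).sum()),
            "case_ch": int((is_ch & case).sum()),
            "case_hom": int((is_hom & case).sum()),
            "ctrl_het": int((is_het & ~case).sum()),
            "ctrl_ch": int((is_ch & ~case).sum()),
            "ctrl_hom": int((is_hom & ~case).sum()),
        }
    counts = pd.DataFrame.from_dict(rows, orient="index")
    counts.index.name = "gene"
    return CarrierTable(counts, qualifying.n_cases, qualifying.n_controls)


def _one_tailed_fisher(k_case: int, n_cases: int, k_ctrl: int, n_controls: int) -> float:
    """P(X >= k_case) for the carriers-vs-noncarriers 2x2 table."""
    if k_case == 0:
        return 1.0
    table = [[k_case, n_cases - k_case], [k_ctrl, n_controls - k_ctrl]]
    return float(fisher_exact(table, alternative="greater")[1])


def fisher_burden(table: CarrierTable, model: str = "dominant",
                  n_cases: int | None = None, n_controls: int | None = None,
                  threshold: float | None = None) -> pd.DataFrame:
    """One-tailed Fisher burden P per gene under a dominant or recessive model.

    Dominant carriers are HET + HOM; recessive are CH + HOM.  Genes with
    zero case carriers get P = 1 and an ``untestable`` flag.  ``threshold``
    defaults to the Bonferroni genome-wide cut 0.05 / 21,306; the
    ``significant`` flag reports P < threshold.  Honours per-gene
    ``eff_n_controls`` when coverage normalisation has been applied.
    """
    if model not in ("dominant", "recessive"):
        raise ValueError("model must be 'dominant' or 'recessive'")
    n_cases = table.n_cases if n_cases is None else n_cases
    n_controls = table.n_controls if n_controls is None else n_controls
    if threshold is None:
        threshold = bonferroni_threshold(GENES_TOTAL_DEFAULT, 0.05)
    carriers = (table.dominant_carriers if model == "dominant"
                else table.recessive_carriers)
    k_case = carriers("case")
    k_ctrl = carriers("ctrl")
    eff_n_ctrl = (table.counts["eff_n_controls"]
                  if "eff_n_controls" in table.counts.columns
                  else pd.Series(n_controls, index=table.counts.index))
    rows = []
    for gene in table.counts.index:
        kc, kt = int(k_case[gene]), int(k_ctrl[gene])
        nt = int(eff_n_ctrl[gene])
        kt = min(kt, nt)
        p = _one_tailed_fisher(kc, n_cases, kt, nt)
        rows.append({
            "gene": gene, "model": model,
            "case_carriers": kc, "ctrl_carriers": kt,
            "n_cases": n_cases, "n_controls": nt,
            "p_value": p,
            "significant": p < threshold,
            "untestable": kc + kt == 0,
            "threshold": threshold,
        })
    return pd.DataFrame(rows).set_index("gene")


def burden_table(table: CarrierTable, threshold: float | None = None) -> pd.DataFrame:
    """Carrier counts with P_DOM and P_REC columns (report layout)."""
    dom = fisher_burden(table, "dominant", threshold=threshold)
    rec = fisher_burden(table, "recessive", threshold=threshold)
    out = table.counts.copy()
    out["P_DOM"] = dom["p_value"]
    out["P_REC"] = rec["p_value"]
    out["significant"] = dom["significant"]
    return out


def summary_control_burden(qualifying: ExomeCohort, case_table: CarrierTable,
                           control_ac: pd.Series, control_an: pd.Series,
                           threshold: float | None = None) -> pd.DataFrame:
    """Burden against summary-level controls (per-variant AC/AN only).

    Without control genotypes, the control dominant-carrier count per gene
    is approximated by the summed qualifying alternate-allele count,
    capped at the implied cohort size max(AN)/2; each control individual
    is assumed to carry at most one qualifying allele, the usual
    rare-variant approximation.  Output is labelled ``summary-control``.
    """
    v = qualifying.variants
    an = control_an.reindex(v["variant_id"]).to_numpy(dtype=float)
    ac = control_ac.reindex(v["variant_id"]).to_numpy(dtype=float)
    skip = ~(an > 0)
    if skip.any():
        import warnings
        warnings.warn(f"skipping {int(skip.sum())} variants with AN = 0")
    rows = []
    threshold = (bonferroni_threshold(GENES_TOTAL_DEFAULT, 0.05)
                 if threshold is None else threshold)
    for gene, idx in v.groupby("gene", sort=True).indices.items():
        ok = idx[~skip[idx]]
        if len(ok) == 0:
            continue
        n_ctrl = int(np.max(an[ok]) // 2)
        carriers_ctrl = int(min(np.sum(ac[ok]), n_ctrl))
        capped = np.sum(ac[ok]) > n_ctrl
        kc = int(case_table.dominant_carriers("case").get(gene, 0))
        p = _one_tailed_fisher(kc, case_table.n_cases, carriers_ctrl, n_ctrl)
        rows.append({
            "gene": gene, "mode": "summary-control",
            "case_carriers": kc, "ctrl_carriers": carriers_ctrl,
            "n_cases": case_table.n_cases, "n_controls": n_ctrl,
            "p_value": p, "significant": p < threshold, "capped": bool(capped),
        })
    return pd.DataFrame(rows).set_index("gene")


def coverage_normalize(table: CarrierTable) -> CarrierTable:
    """Scale the effective control cohort size by relative callable fraction.

    Per gene, eff_n_controls = round(n_controls * callable_frac_ctrl /
    callable_frac_case), floored at 1.  Case counts are never altered;
    with equal fractions the table is unchanged.  Requires the
    ``callable_frac_case`` / ``callable_frac_ctrl`` columns.
    """
    c = table.counts
    for col in ("callable_frac_case", "callable_frac_ctrl"):
        if col not in c.columns:
            raise ValueError(f"coverage normalisation requires column {col}")
        frac = c[col]
        if ((frac <= 0) | (frac > 1)).any():
            raise ValueError(f"{col} must lie in (0,1]")
    out = c.copy()
    eff = np.round(table.n_controls * c["callable_frac_ctrl"] / c["callable_frac_case"])
    out["eff_n_controls"] = np.maximum(eff.astype(int), 1)
    return CarrierTable(out, table.n_cases, table.n_controls)


def bonferroni_threshold(n_genes: int, alpha: float = 0.05) -> float:
    """Genome-wide significance cut alpha / n_genes."""
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    return alpha / n_genes


def load_reported_burden_counts() -> pd.DataFrame:
    """Published per-gene carrier counts (87 cases vs 2719 controls) for the
    55 burden-significant genes of the pediatric POTS exome study this
    package models, with the reported dominant-model P values."""
    from importlib.resources import files

    path = files("varscreen.data").joinpath("pots_burden_counts.tsv")
    with path.open() as fh:
        return pd.read_csv(fh, sep="\t")
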