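"""Pathogenic / likely-pathogenic classification and database consensus.

Each variant's ClinVar, InterVar and HGMD strings are parsed to three
boolean calls; the consensus keeps variants supported by at least
``min_support`` of the three databases.  Parsing is case-insensitive;
ClinVar/InterVar composite labels are split on the documented separators
and any "Conflicting" assertion vetoes the P/LP call.  Only the exact
HGMD class "DM" counts ("DM?", "DP", "FP" never do).
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import MISSING, ExomeCohort

_SPLIT = re.compile(r"[/,|;]")
_PLP_TOKENS = {"pathogenic", "likely_pathogenic", "likely pathogenic"}


def _is_plp(label: str) -> bool:
    if not isinstance(label, str):
        return False
    low = label.lower()
    if "conflicting" in low:
        return False
    tokens = {t.strip().strip("_ ") for t in _SPLIT.split(low)}
    return bool(tokens & _PLP_TOKENS)


def classify_plp(variants: pd.DataFrame) -> pd.DataFrame:
    """Per-variant database calls and support count.

    Expects ``clinvar``, ``intervar`` and ``hgmd`` columns (empty or
    missing strings yield all-false flags).  Returns a frame with
    ``clinvar_plp``, ``intervar_plp``, ``hgmd_dm`` and ``support_count``
    (their sum); a ``dominant_effect_reported`` column, when present in
    the input, is passed through.
    """
    out = pd.DataFrame({"variant_id": variants["variant_id"]})
    cv = variants.get("clinvar", pd.Series("", index=variants.index))
    iv = variants.get("intervar", pd.Series("", index=variants.index))
    hg = variants.get("hgmd", pd.Series("", index=variants.index))
    out["clinvar_plp"] = cv.map(_is_plp)
    out["intervar_plp"] = iv.map(_is_plp)
    out["hgmd_dm"] = hg.astype(str).str.strip().str.upper() == "DM"
    out["support_count"] = (out["clinvar_plp"].astype(int)
                            + out["intervar_plp"].astype(int)
                            + out["hgmd_dm"].astype(int))
    if "dominant_effect_reported" in variants.columns:
        out["dominant_effect_reported"] = variants["dominant_effect_reported"]
    if "gene" in variants.columns:
        out["gene"] = variants["gene"].to_numpy()
    return out


def consensus_support(calls: pd.DataFrame, min_support: int = 2) -> pd.DataFrame:
    """Calls supported by at least ``min_support`` of the three databases."""
    if not 1 <= min_support <= 3:
        raise ValueError("min_support must be in 1..3")
    return calls[calls["support_count"] >= min_support].reset_index(drop=True)


@dataclass
class PatientSummary:
    per_patient: pd.DataFrame
    carrier_fraction: float
    per_gene: pd.DataFrame
    genes_with_multiple_carriers: list[str]


def patient_summary(calls: pd.DataFrame, cohort: ExomeCohort,
                    case_only: bool = True) -> PatientSummary:
    """Per-patient carriage of the classified P/LP variants.

    A patient carries a variant when their genotype is >= 1.  Reports the
    per-patient variant count and any-carrier flag, the cohort carrier
    fraction, per-gene P/LP variant counts, and the genes whose (>= 2)
    P/LP variants are carried by at least two different individuals.
    """
    order = {v: i for i, v in enumerate(cohort.variants["variant_id"])}
    idx = [order[v] for v in calls["variant_id"] if v in order]
    sample_sel = cohort.is_case if case_only else np.ones(len(cohort.sample_ids), bool)
    g = cohort.genotypes[np.ix_(sample_sel, idx)]
    carried = (g != MISSING) & (g >= 1)
    ids = [s for s, keep in zip(cohort.sample_ids, sample_sel) if keep]
    per_patient = pd.DataFrame({
        "sample_id": ids,
        "n_plp": carried.sum(axis=1),
    })
    per_patient["any_plp"] = per_patient["n_plp"] >= 1
    frac = float(per_patient["any_plp"].mean()) if len(per_patient) else 0.0

    genes = cohort.variants["gene"].to_numpy()[idx]
    gene_rows = []
    multi = []
    for gene in sorted(set(genes)):
        cols = np.flatnonzero(genes == gene)
        n_variants = len(cols)
        carriers_per_variant = [set(np.flatnonzero(carried[:, c])) for c in cols]
        variants_carried = sum(1 for s in carriers_per_variant if s)
        all_carriers = set().union(*carriers_per_variant) if carriers_per_variant else set()
        gene_rows.append({"gene": gene, "n_plp_variants": n_variants,
                          "n_carriers": len(all_carriers)})
        # >= 2 distinct P/LP variants carried, by >= 2 different individuals
        if variants_carried >= 2 and len(all_carriers) >= 2:
            multi.append(gene)
    per_gene = pd.DataFrame(gene_rows)
    return PatientSummary(per_patient, frac, per_gene, multi)
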