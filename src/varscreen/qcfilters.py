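"""Pre-association quality control for array genotype cohorts.

Filter battery applied before any association testing, in the order
imputation quality (R^2) -> Mendelian errors -> parental sex effect ->
Hardy-Weinberg.  Every filter removes variants only, never samples, and is
idempotent; each returns a report frame alongside the filtered matrix so a
pipeline manifest can reconcile input = kept + removed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import fisher_exact

from .containers import MISSING, GenotypeMatrix, TrioSet


def filter_imputation_quality(gm: GenotypeMatrix, r2_min: float = 0.3
                              ) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Keep variants with imputation R^2 >= r2_min (boundary inclusive).

    Variants with no R^2 recorded are treated as directly genotyped and
    kept.  Returns (filtered matrix, per-variant report).
    """
    if not 0 <= r2_min <= 1:
        raise ValueError("r2_min must be in [0,1]")
    if "imputation_r2" in gm.variant_meta.columns:
        r2 = gm.variant_meta["imputation_r2"].to_numpy(dtype=float)
    else:
        r2 = np.full(gm.n_variants, np.nan)
    keep = np.isnan(r2) | (r2 >= r2_min)
    report = pd.DataFrame({
        "variant_id": gm.variant_ids,
        "filter": "imputation_r2",
        "statistic": r2,
        "p_value": np.nan,
        "kept": keep,
    })
    return gm.select_variants(keep), report


def count_mendelian_errors(gm: GenotypeMatrix, trios: TrioSet, max_errors: int = 3
                           ) -> tuple[np.ndarray, GenotypeMatrix, pd.DataFrame]:
    """Count per-variant Mendelian-inconsistent trios; drop counts > max_errors.

    A trio is inconsistent at a variant when the child's minor-allele count
    cannot be produced by one transmission from each parent (e.g. two
    homozygous-reference parents with a carrier child).  Trios with any
    missing member genotype are skipped at that variant.  Returns
    (error counts, filtered matrix, report); the retained set keeps
    variants with count <= max_errors.
    """
    trios.validate_against(gm)
    g = gm.genotypes
    errors = np.zeros(gm.n_variants, dtype=int)
    for t in trios.trios:
        f, m, c = g[t.father], g[t.mother], g[t.child]
        called = (f != MISSING) & (m != MISSING) & (c != MISSING)
        # minor alleles the child must have received from het parents:
        n_het = (f == 1).astype(int) + (m == 1).astype(int)
        forced = (f == 2).astype(int) + (m == 2).astype(int)
        from_het = c - forced
        bad = called & ((from_het < 0) | (from_het > n_het))
        errors += bad
    keep = errors <= max_errors
    report = pd.DataFrame({
        "variant_id": gm.variant_ids,
        "filter": "mendel",
        "statistic": errors.astype(float),
        "p_value": np.nan,
        "kept": keep,
    })
    return errors, gm.select_variants(keep), report


def sex_effect_filter(gm: GenotypeMatrix, alpha: float = 0.05, method: str = "fisher"
                      ) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Drop variants whose allele frequency differs between mothers and fathers.

    Two-sided test on the 2x2 allele-count table (parental sex x
    minor/major allele); replicated autosomal/sex-chromosome sequence
    artifacts surface as such differences.  ``method`` is ``fisher``
    (default, exact) or ``chi2``.
    """
    mothers = gm.roles == "mother"
    fathers = gm.roles == "father"
    if not mothers.any() or not fathers.any():
        raise ValueError("sex-effect filter requires both mother and father samples")

    def allele_counts(mask):
        g = gm.genotypes[mask]
        called = g != MISSING
        minor = np.where(called, g, 0).sum(axis=0)
        total = 2 * called.sum(axis=0)
        return minor, total - minor

    m_min, m_maj = allele_counts(mothers)
    f_min, f_maj = allele_counts(fathers)
    pvals = np.ones(gm.n_variants)
    for j in range(gm.n_variants):
        table = [[m_min[j], m_maj[j]], [f_min[j], f_maj[j]]]
        if method == "fisher":
            pvals[j] = fisher_exact(table, alternative="two-sided")[1]
        elif method == "chi2":
            from scipy.stats import chi2_contingency
            if min(m_min[j] + f_min[j], m_maj[j] + f_maj[j]) == 0:
                pvals[j] = 1.0
            else:
                pvals[j] = chi2_contingency(table, correction=False)[1]
        else:
            raise ValueError("method must be 'fisher' or 'chi2'")
    keep = pvals >= alpha
    report = pd.DataFrame({
        "variant_id": gm.variant_ids,
        "filter": "sex_effect",
        "statistic": np.nan,
        "p_value": pvals,
        "kept": keep,
    })
    return gm.select_variants(keep), report


def hwe_exact_test(n_homref: int, n_het: int, n_homalt: int, midp: bool = False) -> float:
    """Exact two-sided Hardy-Weinberg P conditioned on allele counts.

    Enumerates every heterozygote count compatible with the observed
    allele counts and sums the probabilities of all outcomes no more
    probable than the observed one (the standard exact-HWE two-sided
    convention); ``midp`` halves the observed outcome's own mass.
    """
    for v in (n_homref, n_het, n_homalt):
        if v < 0:
            raise ValueError("genotype counts must be >= 0")
    n = n_homref + n_het + n_homalt
    if n == 0:
        raise ValueError("at least one genotyped sample required")
    n_rare = 2 * min(n_homref, n_homalt) + n_het
    if n_rare == 0 or n_rare == 2 * n:
        return 1.0  # monomorphic: single possible outcome

    # log P(het = k | allele counts) up to a shared constant
    ks = np.arange(n_rare % 2, min(n_rare, 2 * n - n_rare) + 1, 2)
    hom_r = (n_rare - ks) // 2
    hom_c = n - ks - hom_r
    logp = (ks * math.log(2) - gammaln(ks + 1) - gammaln(hom_r + 1) - gammaln(hom_c + 1))
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    obs = np.flatnonzero(ks == n_het)[0]
    le = probs <= probs[obs] * (1 + 1e-10)  # tolerance for float ties
    p = probs[le].sum()
    if midp:
        p -= 0.5 * probs[obs]
    return float(min(p, 1.0))


def hwe_filter(gm: GenotypeMatrix, alpha: float = 0.01, sample_mask=None
               ) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Drop variants out of Hardy-Weinberg (exact P < alpha) in controls.

    ``sample_mask`` selects the samples the test is computed on; defaults
    to the ``control`` role, falling back to all samples when no controls
    are present (e.g. a family cohort).
    """
    if sample_mask is None:
        sample_mask = gm.roles == "control"
        if not sample_mask.any():
            sample_mask = np.ones(gm.n_samples, dtype=bool)
    g = gm.genotypes[sample_mask]
    pvals = np.ones(gm.n_variants)
    for j in range(gm.n_variants):
        col = g[:, j]
        n0 = int((col == 0).sum())
        n1 = int((col == 1).sum())
        n2 = int((col == 2).sum())
        if n0 + n1 + n2 == 0:
            pvals[j] = np.nan
            continue
        pvals[j] = hwe_exact_test(n0, n1, n2)
    keep = ~(pvals < alpha)
    report = pd.DataFrame({
        "variant_id": gm.variant_ids,
        "filter": "hwe",
        "statistic": np.nan,
        "p_value": pvals,
        "kept": keep,
    })
    return gm.select_variants(keep), report


@dataclass
class QCResult:
    """Filtered matrix plus the ordered per-filter reports (provenance)."""

    matrix: GenotypeMatrix
    reports: list[pd.DataFrame]

    @property
    def report(self) -> pd.DataFrame:
        return pd.concat(self.reports, ignore_index=True)


def run_qc(gm: GenotypeMatrix, trios: TrioSet | None = None, *,
           r2_min: float = 0.3, mendel_max: int = 3,
           sex_alpha: float = 0.05, hwe_alpha: float = 0.01) -> QCResult:
    """Apply the full filter battery in its canonical order.

    R^2 -> Mendelian errors (family cohorts) -> parental sex effect
    (family cohorts) -> HWE in controls.  Sex/Mendelian stages are skipped
    when the cohort has no trios.
    """
    reports = []
    gm, rep = filter_imputation_quality(gm, r2_min)
    reports.append(rep)
    if trios is not None and len(trios) > 0:
        errors, gm_f, rep = count_mendelian_errors(gm, trios, mendel_max)
        reports.append(rep)
        gm = gm_f
        gm, rep = sex_effect_filter(gm, sex_alpha)
        reports.append(rep)
    gm, rep = hwe_filter(gm, hwe_alpha)
    reports.append(rep)
    return QCResult(gm, reports)


def estimate_ibd(gm: GenotypeMatrix, prune_every: int = 1) -> pd.DataFrame:
    """Method-of-moments IBD sharing (Z0, Z1, Z2, PI_HAT) for all sample pairs.

    Counts identity-by-state classes per pair over called variants and
    solves the moment equations using the expected IBS-class probabilities
    at the observed allele frequencies (PLINK-style estimator, without the
    finite-sample bias correction).  ``prune_every`` keeps every k-th
    variant as a crude LD prune.  PI_HAT = Z1/2 + Z2.
    """
    if gm.n_samples < 2:
        raise ValueError("need at least two samples")
    idx = np.arange(0, gm.n_variants, prune_every)
    g = gm.genotypes[:, idx].astype(float)
    g[g == MISSING] = np.nan
    p = gm.minor_allele_freq()[idx]
    informative = (p > 0) & (p < 1) & ~np.isnan(p)
    if not informative.any():
        raise ValueError("no polymorphic variants to estimate IBD from")
    g = g[:, informative]
    p = p[informative]
    q = 1 - p

    # expected IBS-class probabilities given IBD state
    e0 = np.array([np.sum(2 * p**2 * q**2),
                   np.sum(4 * p**3 * q + 4 * p * q**3),
                   np.sum(p**4 + q**4 + 4 * p**2 * q**2)])
    e1_ibs1 = np.sum(2 * p**2 * q + 2 * p * q**2)
    m = p.size

    rows = []
    for i in range(gm.n_samples):
        for j in range(i + 1, gm.n_samples):
            gi, gj = g[i], g[j]
            ok = ~np.isnan(gi) & ~np.isnan(gj)
            n_ok = ok.sum()
            if n_ok == 0:
                continue
            diff = np.abs(gi[ok] - gj[ok])
            n_ibs0 = float((diff == 2).sum())
            n_ibs1 = float((diff == 1).sum())
            n_ibs2 = float((diff == 0).sum())
            scale = n_ok / m  # per-pair missingness rescales expectations
            z0 = n_ibs0 / (e0[0] * scale) if e0[0] > 0 else 0.0
            z1 = (n_ibs1 - z0 * e0[1] * scale) / (e1_ibs1 * scale)
            z2 = 1.0 - z0 - z1
            z0, z1, z2 = np.clip([z0, z1, z2], 0, 1)
            total = z0 + z1 + z2
            z0, z1, z2 = z0 / total, z1 / total, z2 / total
            rows.append({
                "sample_1": gm.sample_ids[i], "sample_2": gm.sample_ids[j],
                "z0": z0, "z1": z1, "z2": z2, "pi_hat": z1 / 2 + z2,
                "n_variants": int(n_ok),
            })
    return pd.DataFrame(rows)
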