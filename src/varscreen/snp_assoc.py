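"""Per-SNP association tests for the two cohort designs.

Family cohort: transmission disequilibrium test (TDT), which conditions on
parental genotypes and is therefore immune to population stratification.
Case-control cohort: additive logistic regression with the leading
principal components of the genotype matrix as ancestry covariates.

Both tests return one row per variant in a shared result-frame layout
(variant_id, cohort, test, effect_allele, odds_ratio, direction, p_value,
plus test-specific columns) so the concordance stage can intersect them
directly.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import chi2

from .containers import MISSING, GenotypeMatrix, TrioSet

RESULT_COLUMNS = ["variant_id", "chrom", "pos", "effect_allele", "other_allele",
                  "cohort", "test", "odds_ratio", "direction", "p_value"]


def _directions(odds_ratio: np.ndarray) -> np.ndarray:
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.sign(np.log(odds_ratio))
    d[~np.isfinite(odds_ratio)] = 1  # infinite OR: all-transmitted / separation
    d[odds_ratio == 0] = -1
    return np.nan_to_num(d)


def tdt_test(gm: GenotypeMatrix, trios: TrioSet) -> pd.DataFrame:
    """TDT per variant: b transmissions vs c non-transmissions of the
    effect allele from heterozygous parents to the affected child.

    Statistic (b - c)^2 / (b + c) ~ chi-square with 1 df (two-sided);
    OR = b/c.  Variants with no informative parent (b + c = 0) are flagged
    untestable (NaN P) rather than raising.  Assumes the Mendelian-error
    filter has already run; residual inconsistent trios are skipped.
    """
    trios.validate_against(gm)
    g = gm.genotypes
    b = np.zeros(gm.n_variants)
    c = np.zeros(gm.n_variants)
    for t in trios.trios:
        f, m, ch = g[t.father], g[t.mother], g[t.child]
        called = (f != MISSING) & (m != MISSING) & (ch != MISSING)
        n_het = (f == 1).astype(int) + (m == 1).astype(int)
        forced = (f == 2).astype(int) + (m == 2).astype(int)
        transmitted = ch - forced  # minor alleles received from het parents
        ok = called & (transmitted >= 0) & (transmitted <= n_het) & (n_het > 0)
        b += np.where(ok, transmitted, 0)
        c += np.where(ok, n_het - transmitted, 0)

    informative = b + c > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        stat = np.where(informative, (b - c) ** 2 / np.maximum(b + c, 1), np.nan)
        oddsr = np.where(c > 0, b / np.maximum(c, 1), np.inf)
    oddsr = np.where(informative, oddsr, np.nan)
    pvals = np.where(informative, chi2.sf(stat, df=1), np.nan)

    res = pd.DataFrame({
        "variant_id": gm.variant_ids,
        "chrom": gm.variant_meta["chrom"],
        "pos": gm.variant_meta["pos"],
        "effect_allele": gm.variant_meta["alt"],
        "other_allele": gm.variant_meta["ref"],
        "cohort": "family",
        "test": "tdt",
        "b_transmitted": b,
        "c_untransmitted": c,
        "statistic": stat,
        "odds_ratio": oddsr,
        "p_value": pvals,
    })
    res["direction"] = _directions(res["odds_ratio"].to_numpy(dtype=float))
    res.loc[res["b_transmitted"] == res["c_untransmitted"], "direction"] = 0.0
    res.loc[~informative, "direction"] = 0.0
    return res


def pca(gm: GenotypeMatrix, n_components: int = 10, scale: bool = True
        ) -> tuple[np.ndarray, np.ndarray]:
    """Genotype PCA: returns (sample scores, variant loadings).

    Missing entries are mean-imputed, columns centred and (optionally)
    scaled by sqrt(2 p (1 - p)) — the conventional genotype
    standardisation.  Zero-variance variants are dropped before the
    decomposition.  Component signs are fixed by making each component's
    largest-magnitude loading positive, so scores are fully deterministic.
    """
    if n_components > min(gm.n_samples, gm.n_variants):
        raise ValueError("n_components exceeds matrix rank")
    x = gm.genotypes.astype(float)
    x[x == MISSING] = np.nan
    means = np.nanmean(x, axis=0)
    inds = np.where(np.isnan(x))
    x[inds] = np.take(means, inds[1])
    keep = np.nanstd(x, axis=0) > 0
    x = x[:, keep] - means[keep]
    if scale:
        p = means[keep] / 2.0
        x = x / np.sqrt(2 * p * (1 - p))
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    if n_components > s.size:
        raise ValueError("n_components exceeds matrix rank")
    scores = u[:, :n_components] * s[:n_components]
    loadings = vt[:n_components]
    for k in range(n_components):
        j = np.argmax(np.abs(loadings[k]))
        if loadings[k, j] < 0:
            loadings[k] *= -1
            scores[:, k] *= -1
    return scores, loadings


def logistic_assoc(gm: GenotypeMatrix, phenotype: np.ndarray | None = None,
                   covariates: np.ndarray | None = None, n_pcs: int = 10
                   ) -> pd.DataFrame:
    """Additive logistic regression per SNP with PC ancestry covariates.

    Fits phenotype ~ genotype + PC1..PCn by IRLS (statsmodels Logit) and
    reports the Wald P for the genotype term with OR = exp(beta).
    ``phenotype`` defaults to the case/control roles; ``covariates``
    defaults to :func:`pca` scores computed on the same matrix (pass
    ``n_pcs=0`` for an unadjusted fit).  Zero-variance genotypes,
    separation and IRLS non-convergence are flagged untestable (NaN P).
    """
    if phenotype is None:
        phenotype = (gm.roles == "case").astype(int)
        if phenotype.sum() == 0 or phenotype.sum() == len(phenotype):
            raise ValueError("phenotype must contain both classes")
    phenotype = np.asarray(phenotype, dtype=float)
    if len(np.unique(phenotype)) < 2:
        raise ValueError("phenotype must contain both classes")
    if n_pcs > 0 and covariates is None:
        covariates, _ = pca(gm, n_components=n_pcs)
    if covariates is not None and n_pcs > covariates.shape[1]:
        raise ValueError("n_pcs exceeds available covariate columns")
    covs = covariates[:, :n_pcs] if (covariates is not None and n_pcs > 0) else None
    if covs is not None:
        informative = covs.std(axis=0) > 0  # constant columns are collinear
        covs = covs[:, informative] if informative.any() else None

    n_v = gm.n_variants
    beta = np.full(n_v, np.nan)
    se = np.full(n_v, np.nan)
    pvals = np.full(n_v, np.nan)
    x = gm.genotypes.astype(float)
    x[x == MISSING] = np.nan
    for j in range(n_v):
        gj = x[:, j]
        ok = ~np.isnan(gj)
        if gj[ok].std() == 0:
            continue  # untestable: no genotype variance
        cols = [np.ones(ok.sum()), gj[ok]]
        if covs is not None:
            cols.append(covs[ok])
        design = np.column_stack(cols)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = sm.Logit(phenotype[ok], design).fit(disp=0, maxiter=100)
            if not fit.mle_retvals.get("converged", False):
                continue
            if abs(fit.params[1]) > 15:  # de-facto separation
                continue
            beta[j] = fit.params[1]
            se[j] = fit.bse[1]
            pvals[j] = fit.pvalues[1]
        except Exception:
            continue  # separation / singular design: untestable

    res = pd.DataFrame({
        "variant_id": gm.variant_ids,
        "chrom": gm.variant_meta["chrom"],
        "pos": gm.variant_meta["pos"],
        "effect_allele": gm.variant_meta["alt"],
        "other_allele": gm.variant_meta["ref"],
        "cohort": "case_control",
        "test": "logistic",
        "beta": beta,
        "se": se,
        "odds_ratio": np.exp(beta),
        "p_value": pvals,
    })
    res["direction"] = np.sign(np.nan_to_num(beta))
    return res


def write_summary_stats(results: pd.DataFrame, path: str) -> None:
    """Write a per-variant summary-statistics TSV (one row per cohort)."""
    cols = [c for c in RESULT_COLUMNS if c in results.columns]
    extra = [c for c in ("b_transmitted", "c_untransmitted", "beta", "se", "statistic")
             if c in results.columns]
    results[cols + extra].to_csv(path, sep="\t", index=False)
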