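"""Gene-based association by Monte-Carlo sum-of-chi-squares (VEGAS-style),
SNP-to-gene mapping, and the expected-overlap-by-chance arithmetic.

The gene statistic is the sum over mapped SNPs of the 1-df chi-square
quantiles of their association P-values.  Its null distribution accounts
for LD by drawing z ~ MVN(0, R) with R the SNP correlation matrix and
comparing sum(z^2); the empirical P uses the add-one estimator
(1 + #exceedances) / (1 + n_sims) and therefore never returns 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binom, chi2

from .containers import MISSING, GenotypeMatrix


@dataclass
class GeneAssocResult:
    gene_symbol: str
    cohort: str
    n_snps: int
    observed_stat: float
    p_value: float
    n_sims_used: int


def _norm_chrom(c) -> str:
    c = str(c)
    return c[3:] if c.lower().startswith("chr") else c


def map_snps_to_genes(variant_meta: pd.DataFrame, gene_map: pd.DataFrame,
                      window: int = 50_000) -> tuple[dict[str, list[str]], list[str]]:
    """Assign SNPs to every gene whose +/-window interval contains them.

    ``gene_map`` columns: chrom, start, end, gene — 1-based inclusive
    coordinates.  Chromosome naming ("chr1" vs "1") is normalised.  A SNP
    may map to several genes.  Returns ({gene: [variant_id, ...]},
    [unmapped variant_ids]).
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    genes: dict[str, list[str]] = {}
    mapped = set()
    vm = variant_meta.assign(_chrom=variant_meta["chrom"].map(_norm_chrom))
    for _, row in gene_map.iterrows():
        chrom = _norm_chrom(row["chrom"])
        lo, hi = int(row["start"]) - window, int(row["end"]) + window
        sel = vm[(vm["_chrom"] == chrom) & (vm["pos"] >= lo) & (vm["pos"] <= hi)]
        if len(sel):
            genes.setdefault(str(row["gene"]), []).extend(sel["variant_id"])
            mapped.update(sel["variant_id"])
    unmapped = [v for v in vm["variant_id"] if v not in mapped]
    return genes, unmapped


def _nearest_psd(ld: np.ndarray, tol: float = 0.05) -> np.ndarray:
    """Clip tiny negative eigenvalues; error when the matrix is far from PSD."""
    w, v = np.linalg.eigh(ld)
    if w.min() < -tol:
        raise ValueError(f"LD matrix strongly non-PSD (min eigenvalue {w.min():.3g})")
    if w.min() < 0:
        warnings.warn("LD matrix slightly non-PSD; repairing by eigenvalue clipping")
    w = np.clip(w, 1e-10, None)
    return (v * w) @ v.T


def ld_from_genotypes(gm: GenotypeMatrix, variant_ids: list[str],
                      sample_mask=None) -> np.ndarray:
    """Pearson correlation of additive genotype codes (pairwise-complete)."""
    order = {v: i for i, v in enumerate(gm.variant_ids)}
    idx = [order[v] for v in variant_ids]
    g = gm.genotypes[:, idx].astype(float)
    if sample_mask is not None:
        g = g[sample_mask]
    g[g == MISSING] = np.nan
    df = pd.DataFrame(g)
    r = df.corr(min_periods=2).to_numpy()
    r[np.isnan(r)] = 0.0
    np.fill_diagonal(r, 1.0)
    return r


def gene_based_test(snp_p: np.ndarray, ld: np.ndarray, n_sims_max: int = 100_000,
                    seed: int = 0, gene_symbol: str = "", cohort: str = "",
                    stages: tuple[int, ...] = (1_000, 10_000, 100_000)
                    ) -> GeneAssocResult:
    """Monte-Carlo gene P for a set of SNP P-values under an LD-aware null.

    observed = sum_i qchisq(1 - p_i, 1); null draws z ~ MVN(0, ld) and
    compares sum z^2.  Simulation count escalates through ``stages``
    (capped at ``n_sims_max``) while the P estimate is still based on
    fewer than 10 exceedances, the usual adaptive-precision rule.
    """
    snp_p = np.asarray(snp_p, dtype=float)
    if snp_p.ndim != 1 or snp_p.size == 0:
        raise ValueError("snp_p must be a non-empty vector")
    if np.any((snp_p <= 0) | (snp_p > 1)):
        raise ValueError("per-SNP P values must lie in (0, 1]")
    m = snp_p.size
    ld = np.asarray(ld, dtype=float)
    if ld.shape != (m, m):
        raise ValueError("ld must be m x m for m SNPs")
    observed = float(chi2.isf(snp_p, df=1).sum())

    chol = np.linalg.cholesky(_nearest_psd(ld) + 1e-10 * np.eye(m))
    rng = np.random.default_rng(seed)
    n_done = 0
    n_exceed = 0
    for stage in stages:
        stage = min(stage, n_sims_max)
        todo = stage - n_done
        if todo <= 0:
            continue
        # chunked so memory stays bounded at large stage counts
        for start in range(0, todo, 50_000):
            k = min(50_000, todo - start)
            z = rng.standard_normal((k, m)) @ chol.T
            stat = np.einsum("ij,ij->i", z, z)
            n_exceed += int((stat >= observed).sum())
        n_done = stage
        if n_exceed >= 10 or n_done >= n_sims_max:
            break
    p = (1 + n_exceed) / (1 + n_done)
    return GeneAssocResult(gene_symbol, cohort, m, observed, p, n_done)


def gene_tests_for_cohort(results: pd.DataFrame, gm: GenotypeMatrix,
                          gene_to_snps: dict[str, list[str]], *,
                          n_sims_max: int = 10_000, seed: int = 0,
                          ld_sample_mask=None, cohort: str = "") -> pd.DataFrame:
    """Run the gene-based test for every mapped gene of one cohort."""
    pmap = dict(zip(results["variant_id"], results["p_value"]))
    rows = []
    for k, (gene, snps) in enumerate(sorted(gene_to_snps.items())):
        snps = [s for s in snps if s in pmap and np.isfinite(pmap[s])]
        if not snps:
            continue
        pvals = np.array([max(pmap[s], 1e-300) for s in snps])
        ld = ld_from_genotypes(gm, snps, ld_sample_mask)
        res = gene_based_test(pvals, ld, n_sims_max=n_sims_max,
                              seed=seed + k, gene_symbol=gene, cohort=cohort)
        rows.append(vars(res))
    return pd.DataFrame(rows)


def expected_overlap(n_genes: int, alpha: float) -> tuple[float, int]:
    """Genes expected to reach P < alpha in two independent cohorts by
    chance: n_genes * alpha^2.  Returns (expectation, nearest integer)."""
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if not 0 <= alpha < 1:
        raise ValueError("alpha must be in [0,1)")
    expect = n_genes * alpha * alpha
    return expect, int(round(expect))


def overlap_tail_test(observed: int, n_genes: int, alpha: float,
                      log: bool = False) -> float:
    """Binomial upper tail P(X >= observed), X ~ Bin(n_genes, alpha^2).

    One documented choice of test for "more dual-cohort genes than
    chance".  The tail is summed from log point masses (logsumexp) so it
    stays finite far beyond double-precision underflow; pass ``log=True``
    for the natural-log P.
    """
    if observed > n_genes:
        raise ValueError("observed cannot exceed n_genes")
    if observed <= 0:
        return 0.0 if log else 1.0
    from scipy.special import logsumexp

    ks = np.arange(observed, n_genes + 1)
    log_p = float(logsumexp(binom.logpmf(ks, n_genes, alpha * alpha)))
    log_p = min(log_p, 0.0)
    return log_p if log else float(np.exp(log_p))
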