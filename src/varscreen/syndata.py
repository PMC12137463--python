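"""Synthetic cohorts with the statistical structure the pipeline assumes.

Three generators: nuclear-family trios with controllable transmission
distortion (for the TDT), stratified case-control genotype cohorts with
blockwise LD (for PC-adjusted logistic association), and annotated exome
cohorts with per-gene qualifying-carrier rates and pathogenicity labels
(for the burden and P/LP stages).  Identical :class:`SimConfig` (seed
included) yields byte-identical output.

Default cohort sizes follow the study design this package models:
100 complete families, 207 cases vs 4063 controls on the array side, and
87 cases vs 2719 controls on the exome side.  Default per-gene carrier
rates for a true-effect gene (0.08 cases / 0.0018 controls) correspond to
the median burden-significant gene (7 of 87 case carriers vs 5 of 2719
control carriers).
"""

from __future__ import annotations

import os
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .containers import (
    MISSING,
    PREDICTOR_FIELDS,
    ExomeCohort,
    GenotypeMatrix,
    Trio,
    TrioSet,
)

# One qualifying call per predictor tool (any of these alone satisfies the
# "at least 1 predictor" rule); used when drawing damaging-call strings.
_DAMAGING_CALLS = {
    "SIFT_pred": "D",
    "Polyphen2_HDIV_pred": "D",
    "Polyphen2_HVAR_pred": "P",
    "LRT_pred": "D",
    "MutationTaster_pred": "A",
    "MutationAssessor_pred": "M",
    "FATHMM_pred": "D",
    "PROVEAN_pred": "D",
    "MetaSVM_pred": "D",
    "MetaLR_pred": "D",
}
_BENIGN_CALLS = {
    "SIFT_pred": "T",
    "Polyphen2_HDIV_pred": "B",
    "Polyphen2_HVAR_pred": "B",
    "LRT_pred": "N",
    "MutationTaster_pred": "N",
    "MutationAssessor_pred": "L",
    "FATHMM_pred": "T",
    "PROVEAN_pred": "N",
    "MetaSVM_pred": "T",
    "MetaLR_pred": "T",
}


@dataclass(frozen=True)
class SimConfig:
    """Parameters for every generator; validated at construction.

    ``causal_snps`` holds ``(snp_index, effect)`` pairs; the effect is an
    odds ratio (> 0) for the case-control generator and a minor-allele
    transmission probability tau in (0, 1) for the trio generator (null
    SNPs use tau = 0.5 / OR = 1).
    """

    seed: int = 0
    n_families: int = 100
    n_cases: int = 207
    n_controls: int = 4063
    n_snps: int = 1000
    maf_range: tuple[float, float] = (0.05, 0.5)
    causal_snps: tuple[tuple[int, float], ...] = ()
    ld_block_size: int = 1
    ld_rho: float = 0.0
    strat_fst: float = 0.0
    strat_case_bias: float = 0.0
    exome_genes: int = 100
    variants_per_gene: int = 4
    wes_cases: int = 87
    wes_controls: int = 2719
    carrier_rate_cases: float = 0.08
    carrier_rate_controls: float = 0.0018
    plp_label_rate: float = 0.1
    plp_db_overlap: float = 0.75
    qualifying_fraction: float = 0.75
    missing_rate: float = 0.0
    mendel_error_rate: float = 0.0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < low <= high <= 0.5")
        for name in ("n_families", "n_cases", "n_controls", "n_snps",
                     "exome_genes", "variants_per_gene", "wes_cases", "wes_controls"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.ld_block_size < 1:
            raise ValueError("ld_block_size must be >= 1")
        if not 0 <= self.ld_rho < 1:
            raise ValueError("ld_rho must be in [0,1)")
        if self.strat_fst < 0:
            raise ValueError("strat_fst must be >= 0")
        if not 0 <= self.strat_case_bias <= 1:
            raise ValueError("strat_case_bias must be in [0,1]")
        for name in ("carrier_rate_cases", "carrier_rate_controls",
                     "plp_label_rate", "plp_db_overlap", "qualifying_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be a probability in [0,1]")
        if not 0 <= self.missing_rate <= 0.1:
            raise ValueError("missing_rate must be in [0, 0.1]")
        if not 0 <= self.mendel_error_rate <= 0.1:
            raise ValueError("mendel_error_rate must be in [0, 0.1]")
        for idx, eff in self.causal_snps:
            if not 0 <= idx < self.n_snps:
                raise ValueError(f"causal SNP index {idx} outside [0, n_snps)")
            if eff <= 0:
                raise ValueError("causal effects (OR or tau) must be > 0")


def _rng(config: SimConfig, stream: str) -> np.random.Generator:
    # independent, reproducible stream per generator (crc32 is run-stable,
    # unlike the salted built-in str hash)
    return np.random.default_rng(np.random.SeedSequence(
        entropy=config.seed, spawn_key=(zlib.crc32(stream.encode()),)))


def _draw_mafs(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    lo, hi = config.maf_range
    return rng.uniform(lo, hi, size=config.n_snps)


def _variant_meta(config: SimConfig, mafs: np.ndarray) -> pd.DataFrame:
    n = config.n_snps
    # tile variants along chr1 at 5 kb spacing; ref/alt arbitrary but fixed
    pos = 10_000 + 5_000 * np.arange(n)
    return pd.DataFrame({
        "variant_id": [f"snp{i}" for i in range(n)],
        "chrom": "1",
        "pos": pos,
        "ref": "A",
        "alt": "G",
        "maf_true": mafs,
        "imputation_r2": np.nan,
    })


def _apply_missing(g: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    if rate > 0:
        mask = rng.random(g.shape) < rate
        g = np.where(mask, MISSING, g).astype(np.int8)
    return g


def simulate_trios(config: SimConfig) -> tuple[GenotypeMatrix, TrioSet]:
    """Simulate complete trios with per-SNP transmission probability tau.

    Parents are drawn from Hardy-Weinberg proportions at each SNP's MAF;
    each heterozygous parent transmits the minor allele with probability
    tau (0.5 for null SNPs), homozygous parents transmit their only
    allele.  Children are Mendelian-consistent by construction unless
    ``mendel_error_rate`` > 0, in which case that fraction of child
    genotypes is replaced by a value impossible given the parents
    (skipping parent pairs for which every child genotype is legal).
    """
    rng = _rng(config, "trios")
    mafs = _draw_mafs(config, rng)
    tau = np.full(config.n_snps, 0.5)
    for idx, t in config.causal_snps:
        if not 0 < t < 1:
            raise ValueError("trio transmission ratio tau must lie in (0,1)")
        tau[idx] = t

    n_fam, n_snp = config.n_families, config.n_snps

    def draw_parents() -> np.ndarray:
        u = rng.random((n_fam, n_snp))
        p = mafs[None, :]
        hom_ref = (1 - p) ** 2
        het = 2 * p * (1 - p)
        g = np.where(u < hom_ref, 0, np.where(u < hom_ref + het, 1, 2))
        return g.astype(np.int8)

    fathers = draw_parents()
    mothers = draw_parents()

    def transmit(parent: np.ndarray) -> np.ndarray:
        minor_from_het = (rng.random(parent.shape) < tau[None, :]).astype(np.int8)
        return np.where(parent == 2, 1, np.where(parent == 1, minor_from_het, 0))

    children = (transmit(fathers) + transmit(mothers)).astype(np.int8)

    if config.mendel_error_rate > 0:
        err = rng.random(children.shape) < config.mendel_error_rate
        for i, j in zip(*np.nonzero(err)):
            f, m = fathers[i, j], mothers[i, j]
            legal = {tf + tm
                     for tf in ({0, 1} if f == 1 else {f // 2})
                     for tm in ({0, 1} if m == 1 else {m // 2})}
            illegal = sorted({0, 1, 2} - legal)
            if illegal:
                children[i, j] = illegal[rng.integers(len(illegal))]

    genotypes = np.vstack([fathers, mothers, children])
    genotypes = _apply_missing(genotypes, config.missing_rate, rng)

    sample_ids = ([f"fam{i}_f" for i in range(n_fam)]
                  + [f"fam{i}_m" for i in range(n_fam)]
                  + [f"fam{i}_c" for i in range(n_fam)])
    roles = np.array(["father"] * n_fam + ["mother"] * n_fam + ["child"] * n_fam)
    child_sex = np.where(rng.random(n_fam) < 0.5, "female", "male")
    sex = np.concatenate([np.full(n_fam, "male"), np.full(n_fam, "female"), child_sex])

    gm = GenotypeMatrix(sample_ids, roles, sex, genotypes, _variant_meta(config, mafs))
    trios = TrioSet([Trio(f"fam{i}", i, n_fam + i, 2 * n_fam + i) for i in range(n_fam)])
    return gm, trios


def _balding_nichols(p: np.ndarray, fst: float, rng: np.random.Generator,
                     n_pops: int = 2) -> np.ndarray:
    """Subpopulation allele frequencies around ancestral p at divergence fst."""
    if fst == 0:
        return np.tile(p, (n_pops, 1))
    a = p * (1 - fst) / fst
    b = (1 - p) * (1 - fst) / fst
    freqs = rng.beta(a, b, size=(n_pops, p.size))
    return np.clip(freqs, 1e-4, 1 - 1e-4)


def _draw_genotypes_ld(freqs: np.ndarray, n: int, config: SimConfig,
                       rng: np.random.Generator) -> np.ndarray:
    """Genotypes for n individuals at the given per-SNP allele frequencies.

    LD is imposed blockwise through a Gaussian copula: each haplotype has a
    latent exchangeable-correlation normal vector per block (correlation
    ld_rho) thresholded at the allele-frequency quantile, so the latent
    correlation matrix is known exactly for the gene-based MVN null.
    """
    m = freqs.shape[0] if freqs.ndim == 1 else freqs.shape[1]
    thresholds = norm.ppf(freqs)  # minor allele iff latent < threshold
    rho, bs = config.ld_rho, config.ld_block_size
    g = np.zeros((n, m), dtype=np.int8)
    for _ in range(2):  # two haplotypes
        z = rng.standard_normal((n, m))
        if rho > 0 and bs > 1:
            for start in range(0, m, bs):
                stop = min(start + bs, m)
                shared = rng.standard_normal((n, 1))
                z[:, start:stop] = (np.sqrt(rho) * shared
                                    + np.sqrt(1 - rho) * z[:, start:stop])
        g += (z < thresholds).astype(np.int8)
    return g


def simulate_case_control(config: SimConfig) -> GenotypeMatrix:
    """Simulate a stratified case-control cohort with blockwise LD.

    Two subpopulations diverge from ancestral allele frequencies by a
    Balding-Nichols model at ``strat_fst``.  Disease follows a logistic
    liability with per-causal-SNP log odds ratios (baseline prevalence
    0.1); cases are drawn from subpopulation 1 with probability
    ``0.5 + strat_case_bias / 2`` while controls split evenly, so
    ``strat_case_bias = 1`` confounds ancestry with case status entirely.
    """
    rng = _rng(config, "case_control")
    mafs = _draw_mafs(config, rng)
    beta = np.zeros(config.n_snps)
    for idx, oddsr in config.causal_snps:
        beta[idx] = np.log(oddsr)
    pop_freqs = _balding_nichols(mafs, config.strat_fst, rng)
    has_effect = np.any(beta != 0)
    b0 = np.log(0.1 / 0.9)

    def sample_group(n_needed: int, want_case: bool, p_pop1: float):
        rows, pop_rows = [], []
        got = 0
        while got < n_needed:
            batch = max(64, 2 * (n_needed - got))
            pops = (rng.random(batch) < p_pop1).astype(int)
            g = np.empty((batch, config.n_snps), dtype=np.int8)
            for k in (0, 1):
                sel = pops == k
                if sel.any():
                    g[sel] = _draw_genotypes_ld(pop_freqs[k], int(sel.sum()), config, rng)
            if has_effect:
                eta = b0 + g @ beta
                pr = 1.0 / (1.0 + np.exp(-eta))
                accept = rng.random(batch) < (pr if want_case else 1 - pr)
                g, pops = g[accept], pops[accept]
            take = min(n_needed - got, g.shape[0])
            rows.append(g[:take])
            pop_rows.append(pops[:take])
            got += take
        return np.vstack(rows), np.concatenate(pop_rows)

    p1_cases = 0.5 + config.strat_case_bias / 2.0
    cases, case_pops = sample_group(config.n_cases, True, p1_cases)
    controls, ctrl_pops = sample_group(config.n_controls, False, 0.5)

    genotypes = _apply_missing(np.vstack([cases, controls]), config.missing_rate, rng)
    # subpopulation recorded in the sample id so it survives file round-trips
    sample_ids = ([f"case{i}_p{case_pops[i]}" for i in range(config.n_cases)]
                  + [f"ctrl{i}_p{ctrl_pops[i]}" for i in range(config.n_controls)])
    roles = np.array(["case"] * config.n_cases + ["control"] * config.n_controls)
    sex = np.where(rng.random(len(sample_ids)) < 0.5, "female", "male")
    return GenotypeMatrix(sample_ids, roles, sex, genotypes, _variant_meta(config, mafs))


def simulate_exome_cohort(config: SimConfig) -> ExomeCohort:
    """Simulate an annotated rare-variant exome cohort.

    Each gene carries ``variants_per_gene`` variants: a ``qualifying_fraction``
    share are rare (NFE AF <= 0.001) with at least one damaging predictor
    call; the remainder fail either the MAF cut or the predictor vote.
    Dominant-carrier status per sample is Bernoulli at
    ``carrier_rate_cases`` / ``carrier_rate_controls``; a carrier is a
    single het (90%), an unphased compound het on two distinct qualifying
    variants (8%) or a homozygote (2%).  A ``plp_label_rate`` share of
    qualifying variants receives a ClinVar P/LP label; InterVar and HGMD
    agree with probability ``plp_db_overlap`` each.
    """
    rng = _rng(config, "exome")
    n_cases, n_controls = config.wes_cases, config.wes_controls
    n_samples = n_cases + n_controls
    is_case = np.zeros(n_samples, dtype=bool)
    is_case[:n_cases] = True

    vpg = config.variants_per_gene
    n_qual = max(2, int(round(config.qualifying_fraction * vpg))) if vpg >= 2 else 1
    n_qual = min(n_qual, vpg)

    rows = []
    geno_cols = []
    for gi in range(config.exome_genes):
        gene = f"GENE{gi:04d}"
        for vi in range(vpg):
            qualifying = vi < n_qual
            if qualifying:
                af = 10.0 ** rng.uniform(-5, -3)
                calls = dict(_BENIGN_CALLS)
                field_name = list(_DAMAGING_CALLS)[rng.integers(len(_DAMAGING_CALLS))]
                calls[field_name] = _DAMAGING_CALLS[field_name]
            elif vi % 2 == 0:
                af = rng.uniform(0.0011, 0.01)  # too common
                calls = dict(_DAMAGING_CALLS)
            else:
                af = 10.0 ** rng.uniform(-5, -3)
                calls = dict(_BENIGN_CALLS)  # all-benign vote
            clinvar, intervar, hgmd = "Uncertain_significance", ".", "."
            if qualifying and rng.random() < config.plp_label_rate:
                clinvar = "Pathogenic" if rng.random() < 0.5 else "Likely_pathogenic"
                if rng.random() < config.plp_db_overlap:
                    intervar = "Likely_pathogenic"
                if rng.random() < config.plp_db_overlap:
                    hgmd = "DM"
            rows.append({
                "variant_id": f"{gene}_v{vi}",
                "gene": gene,
                "chrom": str(1 + gi % 22),
                "pos": 1_000_000 + 1000 * (gi * vpg + vi),
                "ref": "C",
                "alt": "T",
                "af_nfe": af,
                **calls,
                "clinvar": clinvar,
                "intervar": intervar,
                "hgmd": hgmd,
            })

        # carrier genotypes on this gene's qualifying variants
        gcols = np.zeros((n_samples, vpg), dtype=np.int8)
        rate = np.where(is_case, config.carrier_rate_cases, config.carrier_rate_controls)
        carrier = rng.random(n_samples) < rate
        kind = rng.random(n_samples)  # <0.90 het, <0.98 CH, else hom
        for s in np.flatnonzero(carrier):
            picks = rng.permutation(n_qual)
            if kind[s] < 0.90 or n_qual < 2:
                gcols[s, picks[0]] = 1
            elif kind[s] < 0.98:
                gcols[s, picks[0]] = 1
                gcols[s, picks[1]] = 1
            else:
                gcols[s, picks[0]] = 2
        geno_cols.append(gcols)

    genotypes = np.hstack(geno_cols) if geno_cols else np.zeros((n_samples, 0), np.int8)
    genotypes = _apply_missing(genotypes, config.missing_rate, rng)
    variants = pd.DataFrame(rows)
    sample_ids = ([f"wes_case{i}" for i in range(n_cases)]
                  + [f"wes_ctrl{i}" for i in range(n_controls)])
    return ExomeCohort(sample_ids, is_case, genotypes, variants)


@dataclass
class SyntheticStudy:
    """Bundle of everything one study run needs, for fixture writing."""

    config: SimConfig
    trio_gm: GenotypeMatrix
    trios: TrioSet
    cc_gm: GenotypeMatrix
    exome: ExomeCohort
    gene_map: pd.DataFrame
    gene_sets: dict[str, set[str]] = field(default_factory=dict)


def _make_gene_map(config: SimConfig) -> pd.DataFrame:
    """Tile genes along chr1 so every simulated SNP falls in >= 1 gene."""
    n_genes = max(1, config.n_snps // 10)
    span = 5_000 * 10
    return pd.DataFrame({
        "chrom": "1",
        "start": [1 + span * i for i in range(n_genes)],
        "end": [span * (i + 1) for i in range(n_genes)],
        "gene": [f"LOC{i:04d}" for i in range(n_genes)],
    })


def simulate_study(config: SimConfig) -> SyntheticStudy:
    """Run all three generators plus a gene map and toy GMT collections."""
    trio_gm, trios = simulate_trios(config)
    cc_gm = simulate_case_control(config)
    exome = simulate_exome_cohort(config)
    gene_map = _make_gene_map(config)
    rng = _rng(config, "gene_sets")
    genes = gene_map["gene"].tolist()
    gene_sets = {}
    for k in range(5):
        size = int(rng.integers(5, max(6, len(genes) // 3)))
        members = rng.choice(genes, size=min(size, len(genes)), replace=False)
        gene_sets[f"SET{k}"] = set(members)
    return SyntheticStudy(config, trio_gm, trios, cc_gm, exome, gene_map, gene_sets)


def write_fixtures(study: SyntheticStudy, directory: str) -> dict[str, str]:
    """Write a study to standard text formats; returns {kind: path}.

    Emits VCF 4.2 + trio index for the family cohort, PED/MAP for the
    case-control cohort, an annotation TSV + genotype TSV for the exome
    cohort, a BED-like gene map and one GMT file.  Round-trips through the
    io_cli readers losslessly.
    """
    from . import io_cli  # local import: io_cli depends on containers only

    if study.trio_gm.n_samples == 0 or study.cc_gm.n_samples == 0:
        raise ValueError("refusing to write fixtures for an empty cohort")
    os.makedirs(directory, exist_ok=True)
    paths = {
        "family_vcf": os.path.join(directory, "family.vcf"),
        "trio_index": os.path.join(directory, "trios.tsv"),
        "cc_ped": os.path.join(directory, "case_control.ped"),
        "cc_map": os.path.join(directory, "case_control.map"),
        "annotation": os.path.join(directory, "exome_annotation.tsv"),
        "exome_genotypes": os.path.join(directory, "exome_genotypes.tsv"),
        "gene_map": os.path.join(directory, "gene_map.tsv"),
        "gmt": os.path.join(directory, "gene_sets.gmt"),
    }
    io_cli.write_vcf(study.trio_gm, paths["family_vcf"])
    io_cli.write_trio_index(study.trios, study.trio_gm, paths["trio_index"])
    io_cli.write_ped_map(study.cc_gm, paths["cc_ped"], paths["cc_map"])
    io_cli.write_exome_cohort(study.exome, paths["annotation"], paths["exome_genotypes"])
    study.gene_map.to_csv(paths["gene_map"], sep="\t", index=False)
    from .ora import write_gmt
    write_gmt(study.gene_sets, paths["gmt"])
    return paths
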