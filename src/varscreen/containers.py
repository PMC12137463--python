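"""Shared in-memory containers for genotype cohorts and exome annotation.

Genotypes are additively coded as copies of the effect (minor/alternate)
allele: 0, 1, 2, with :data:`MISSING` (= -1) for a no-call.  Variant
metadata travels as a :class:`pandas.DataFrame` so downstream stages can
filter and join without bespoke accessors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Sentinel for a missing genotype call.
MISSING: int = -1

#: Columns every variant_meta frame must carry.
VARIANT_META_COLUMNS = ("variant_id", "chrom", "pos", "ref", "alt")

#: Annotation columns used by the rare-variant qualification rule.
PREDICTOR_FIELDS = (
    "SIFT_pred",
    "Polyphen2_HDIV_pred",
    "Polyphen2_HVAR_pred",
    "LRT_pred",
    "MutationTaster_pred",
    "MutationAssessor_pred",
    "FATHMM_pred",
    "PROVEAN_pred",
    "MetaSVM_pred",
    "MetaLR_pred",
)


@dataclass
class GenotypeMatrix:
    """Samples x variants additive genotype matrix with sample roles.

    Parameters
    ----------
    sample_ids
        Unique sample identifiers, one per row of ``genotypes``.
    roles
        Per-sample role: ``father``, ``mother``, ``child``, ``case`` or
        ``control``.
    sex
        Per-sample sex: ``male``, ``female`` or ``unknown``.
    genotypes
        ``(n_samples, n_variants)`` int8 array with values in
        {0, 1, 2, MISSING}.
    variant_meta
        One row per variant; requires :data:`VARIANT_META_COLUMNS` and may
        carry ``imputation_r2`` (NaN when directly genotyped).
    """

    sample_ids: list[str]
    roles: np.ndarray
    sex: np.ndarray
    genotypes: np.ndarray
    variant_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.roles = np.asarray(self.roles, dtype=object)
        self.sex = np.asarray(self.sex, dtype=object)
        n_s, n_v = self.genotypes.shape
        if len(self.sample_ids) != n_s:
            raise ValueError("sample_ids length does not match genotype rows")
        if len(set(self.sample_ids)) != n_s:
            raise ValueError("sample_ids must be unique")
        if len(self.variant_meta) != n_v:
            raise ValueError("variant_meta length does not match genotype columns")
        valid = np.isin(self.genotypes, (0, 1, 2, MISSING))
        if not valid.all():
            raise ValueError("genotype values restricted to {0,1,2,missing}")
        missing_cols = [c for c in VARIANT_META_COLUMNS if c not in self.variant_meta.columns]
        if missing_cols:
            raise ValueError(f"variant_meta lacks columns {missing_cols}")
        self.variant_meta = self.variant_meta.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_variants(self) -> int:
        return self.genotypes.shape[1]

    @property
    def variant_ids(self) -> np.ndarray:
        return self.variant_meta["variant_id"].to_numpy()

    def select_variants(self, mask_or_idx) -> "GenotypeMatrix":
        """Return a copy restricted to the given variant mask/index, order kept."""
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            roles=self.roles.copy(),
            sex=self.sex.copy(),
            genotypes=self.genotypes[:, idx],
            variant_meta=self.variant_meta.iloc[idx].reset_index(drop=True),
        )

    def select_samples(self, mask_or_idx) -> "GenotypeMatrix":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeMatrix(
            sample_ids=[self.sample_ids[i] for i in idx],
            roles=self.roles[idx],
            sex=self.sex[idx],
            genotypes=self.genotypes[idx],
            variant_meta=self.variant_meta.copy(),
        )

    def minor_allele_freq(self, sample_mask=None) -> np.ndarray:
        """Observed effect-allele frequency per variant, missing excluded."""
        g = self.genotypes if sample_mask is None else self.genotypes[sample_mask]
        called = g != MISSING
        n_alleles = 2 * called.sum(axis=0)
        counts = np.where(called, g, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n_alleles > 0, counts / np.maximum(n_alleles, 1), np.nan)


@dataclass(frozen=True)
class Trio:
    family_id: str
    father: int
    mother: int
    child: int


@dataclass
class TrioSet:
    """Index triples (father, mother, child) into a GenotypeMatrix."""

    trios: list[Trio] = field(default_factory=list)

    def __post_init__(self) -> None:
        children = [t.child for t in self.trios]
        if len(set(children)) != len(children):
            raise ValueError("a child may appear in exactly one trio")
        for t in self.trios:
            if len({t.father, t.mother, t.child}) != 3:
                raise ValueError(f"trio {t.family_id}: member indices must be distinct")

    def __len__(self) -> int:
        return len(self.trios)

    def validate_against(self, gm: GenotypeMatrix) -> None:
        n = gm.n_samples
        for t in self.trios:
            if not all(0 <= i < n for i in (t.father, t.mother, t.child)):
                raise IndexError(f"trio {t.family_id} indexes outside the cohort")


@dataclass
class ExomeCohort:
    """Annotated rare-variant call set for a case-control exome cohort.

    ``variants`` carries one row per variant with the annotation columns
    (gene symbol, NFE reference allele frequency, the in-silico predictor
    calls, ClinVar/InterVar/HGMD classification strings); ``genotypes`` is
    samples x variants additive-coded.
    """

    sample_ids: list[str]
    is_case: np.ndarray
    genotypes: np.ndarray
    variants: pd.DataFrame

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.is_case = np.asarray(self.is_case, dtype=bool)
        if self.genotypes.shape != (len(self.sample_ids), len(self.variants)):
            raise ValueError("genotype matrix shape mismatch")
        af = self.variants["af_nfe"].fillna(0.0)
        if ((af < 0) | (af > 1)).any():
            raise ValueError("af_nfe outside [0,1]")
        self.variants = self.variants.reset_index(drop=True)

    @property
    def n_cases(self) -> int:
        return int(self.is_case.sum())

    @property
    def n_controls(self) -> int:
        return int((~self.is_case).sum())

    def subset_variants(self, mask_or_idx) -> "ExomeCohort":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return ExomeCohort(
            sample_ids=list(self.sample_ids),
            is_case=self.is_case.copy(),
            genotypes=self.genotypes[:, idx],
            variants=self.variants.iloc[idx].reset_index(drop=True),
        )


@dataclass
class CarrierTable:
    """Per-gene qualifying-carrier counts for cases and controls.

    ``counts`` is indexed by gene symbol with columns ``case_het``,
    ``case_ch``, ``case_hom``, ``ctrl_het``, ``ctrl_ch``, ``ctrl_hom`` and
    optionally per-gene callable fractions ``callable_frac_case`` /
    ``callable_frac_ctrl`` (used by coverage normalisation).
    """

    counts: pd.DataFrame
    n_cases: int
    n_controls: int

    COUNT_COLUMNS = ("case_het", "case_ch", "case_hom", "ctrl_het", "ctrl_ch", "ctrl_hom")

    def __post_init__(self) -> None:
        for col in self.COUNT_COLUMNS:
            if col not in self.counts.columns:
                raise ValueError(f"carrier table lacks column {col}")
        c = self.counts
        if (c["case_ch"] > c["case_het"]).any() or (c["ctrl_ch"] > c["ctrl_het"]).any():
            raise ValueError("compound hets must be a subset of het carriers")
        if ((c["case_het"] + c["case_hom"]) > self.n_cases).any():
            raise ValueError("case carriers exceed cohort size")
        if ((c["ctrl_het"] + c["ctrl_hom"]) > self.n_controls).any():
            raise ValueError("control carriers exceed cohort size")

    def dominant_carriers(self, cohort: str) -> pd.Series:
        pre = "case" if cohort == "case" else "ctrl"
        return self.counts[f"{pre}_het"] + self.counts[f"{pre}_hom"]

    def recessive_carriers(self, cohort: str) -> pd.Series:
        pre = "case" if cohort == "case" else "ctrl"
        return self.counts[f"{pre}_ch"] + self.counts[f"{pre}_hom"]
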