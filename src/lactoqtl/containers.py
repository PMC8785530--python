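"""In-memory containers for genotype and phenotype data.

The genotype container holds hard-call allele dosages (0/1/2, -1 for
missing) for animals x variants together with a variant map (chromosome,
1-based position, ref, alt) and a per-variant imputation quality score
(dosage R^2, "DR2").  Phenotypes are per-animal lactation yield deviations
with an information weight equal to the number of aggregated test-day
records, plus breed fractions for the two ancestral pools.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1

VARIANT_COLUMNS = ("chrom", "pos", "ref", "alt")


def variant_ids(variants: pd.DataFrame) -> pd.Index:
    """Canonical string ids ``chrom:pos:ref:alt`` for a variant map."""
    return pd.Index(
        variants["chrom"].astype(str)
        + ":"
        + variants["pos"].astype(str)
        + ":"
        + variants["ref"].astype(str)
        + ":"
        + variants["alt"].astype(str)
    )


@dataclass
class GenotypeMatrix:
    """Animals x variants hard-call dosage matrix with map and DR2.

    Parameters
    ----------
    animals : array-like of str
        Ordered animal identifiers.
    variants : pandas.DataFrame
        One row per variant with columns ``chrom``, ``pos`` (1-based),
        ``ref``, ``alt`` and optionally ``dr2`` (defaults to 1.0).  Extra
        columns (e.g. a panel label) are carried along.
    dosage : ndarray of int8, shape (n_animals, n_variants)
        Alternate-allele dosage codes in {0, 1, 2}; -1 marks missing.
    fractional : ndarray of float or None
        Optional fractional dosages (VCF ``DS``) retained for output only;
        all computations use the hard calls.
    """

    animals: np.ndarray
    variants: pd.DataFrame
    dosage: np.ndarray
    fractional: np.ndarray | None = None

    def __post_init__(self):
        self.animals = np.asarray(self.animals)
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.shape != (len(self.animals), len(self.variants)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} inconsistent with "
                f"{len(self.animals)} animals x {len(self.variants)} variants"
            )
        for col in VARIANT_COLUMNS:
            if col not in self.variants.columns:
                raise ValueError(f"variant map lacks required column {col!r}")
        if "dr2" not in self.variants.columns:
            self.variants = self.variants.assign(dr2=1.0)
        self.variants = self.variants.reset_index(drop=True)
        self._check_sorted()

    def _check_sorted(self):
        for _, sub in self.variants.groupby("chrom", sort=False):
            pos = sub["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError("positions must be strictly increasing within chromosome")

    # -- basic geometry -------------------------------------------------
    @property
    def n_animals(self) -> int:
        return len(self.animals)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def ids(self) -> pd.Index:
        return variant_ids(self.variants)

    @property
    def dr2(self) -> np.ndarray:
        return self.variants["dr2"].to_numpy(dtype=float)

    # -- allele frequencies ---------------------------------------------
    def alt_freq(self) -> np.ndarray:
        """Alternate-allele frequency per variant over non-missing calls."""
        d = self.dosage
        obs = d != MISSING
        n_obs = obs.sum(axis=0)
        alt = np.where(obs, d, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n_obs > 0, alt / (2.0 * n_obs), np.nan)

    def maf(self) -> np.ndarray:
        """Folded minor-allele frequency per variant."""
        p = self.alt_freq()
        return np.minimum(p, 1.0 - p)

    # -- subsetting ------------------------------------------------------
    def subset_variants(self, index) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            animals=self.animals,
            variants=self.variants.iloc[index].reset_index(drop=True),
            dosage=self.dosage[:, index],
            fractional=None if self.fractional is None else self.fractional[:, index],
        )

    def subset_animals(self, index) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            animals=self.animals[index],
            variants=self.variants.copy(),
            dosage=self.dosage[index],
            fractional=None if self.fractional is None else self.fractional[index],
        )

    def swap_alleles(self) -> "GenotypeMatrix":
        """Return a copy with ref/alt swapped and dosages recoded 2-x."""
        d = self.dosage.copy()
        obs = d != MISSING
        d[obs] = 2 - d[obs]
        v = self.variants.copy()
        v[["ref", "alt"]] = v[["alt", "ref"]].to_numpy()
        return GenotypeMatrix(self.animals, v, d)

    def mean_imputed(self) -> np.ndarray:
        """Float dosage matrix with missing cells replaced by 2*alt_freq.

        Imputation happens only at model-fitting time, never during QC.
        """
        X = self.dosage.astype(np.float64)
        miss = self.dosage == MISSING
        if miss.any():
            fill = 2.0 * np.nan_to_num(self.alt_freq())
            X[miss] = np.broadcast_to(fill, X.shape)[miss]
        return X


@dataclass
class PhenotypeTable:
    """Per-animal yield deviations with record-count weights.

    ``y`` is the trait-unit yield deviation (already pre-adjusted for
    non-genetic effects upstream), ``w`` is the number of aggregated
    test-day records (the residual variance of a record is sigma2_e / w),
    and ``breed_frac_a`` the fraction of ancestry from pool A.
    """

    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    REQUIRED = ("animal_id", "y", "w")

    def __post_init__(self):
        t = self.table
        for col in self.REQUIRED:
            if col not in t.columns:
                raise ValueError(f"phenotype table lacks required column {col!r}")
        if "trait" not in t.columns:
            t = t.assign(trait="trait")
        if "breed_frac_a" not in t.columns:
            t = t.assign(breed_frac_a=np.nan)
        if t["y"].isna().any():
            raise ValueError("phenotype table contains missing y")
        if (t["w"] < 1).any():
            raise ValueError("record-count weights must be >= 1")
        self.table = t.reset_index(drop=True)

    @property
    def y(self) -> np.ndarray:
        return self.table["y"].to_numpy(dtype=float)

    @property
    def w(self) -> np.ndarray:
        return self.table["w"].to_numpy(dtype=float)

    @property
    def animal_id(self) -> np.ndarray:
        return self.table["animal_id"].to_numpy()

    def __len__(self) -> int:
        return len(self.table)
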