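"""Genotype quality control: per-variant statistics and filter cascades.

Two cascades are provided, mirroring how a structure-adjustment SNP panel
and an imputed-sequence test panel are curated in dairy-cattle GWAS:

* structure panel: call rate > 0.99, MAF >= 0.02, Hardy-Weinberg
  heterozygote-frequency deviation <= 0.15 (within breed stratum, max over
  strata), DR2 >= 0.9, then greedy LD pruning of pairs with R^2 > 0.9
  within 1 Mb keeping the higher-MAF member;
* sequence panel: drop variants with hom-alt count <= 5 or DR2 < 0.7.

All thresholds are strict inequalities exactly as stated.  Every removed
variant carries exactly one first-failure reason.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import MISSING, GenotypeMatrix


def expected_hom_count(maf: float, n: int) -> float:
    """Expected rare-homozygote count q^2 * n under Hardy-Weinberg.

    The count decreases quadratically in allele frequency, which is why
    detecting recessive effects at low MAF needs very large samples: at
    MAF 1% a sample of 10,000 is expected to contain a single minor-allele
    homozygote.
    """
    if not (0.0 <= maf <= 0.5):
        raise ValueError("maf must be in [0, 0.5]")
    return maf * maf * n


def variant_stats(G: GenotypeMatrix, strata: np.ndarray | None = None) -> pd.DataFrame:
    """Per-variant MAF, call rate, het frequency, hom-alt count, HWE deviation.

    Frequencies are computed over non-missing calls.  hwe_dev is
    |observed het freq - 2pq|; when ``strata`` (e.g. breed labels) are
    given it is computed per stratum and the maximum over strata with at
    least one call is reported.  All-missing variants are flagged and
    their stats are NaN.
    """
    d = G.dosage
    obs = d != MISSING
    n_obs = obs.sum(axis=0)
    alt = np.where(obs, d, 0).sum(axis=0)
    het = ((d == 1) & obs).sum(axis=0)
    hom_alt = ((d == 2) & obs).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_obs > 0, alt / (2.0 * n_obs), np.nan)
        het_freq = np.where(n_obs > 0, het / n_obs, np.nan)
    maf = np.minimum(p, 1.0 - p)
    call_rate = n_obs / G.n_animals

    def _hwe_dev(mask: np.ndarray) -> np.ndarray:
        dd = d[mask]
        oo = dd != MISSING
        m = oo.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            ps = np.where(m > 0, np.where(oo, dd, 0).sum(axis=0) / (2.0 * m), np.nan)
            hs = np.where(m > 0, ((dd == 1) & oo).sum(axis=0) / m, np.nan)
        return np.abs(hs - 2.0 * ps * (1.0 - ps))

    if strata is None:
        hwe_dev = np.abs(het_freq - 2.0 * p * (1.0 - p))
    else:
        strata = np.asarray(strata)
        devs = [
            _hwe_dev(strata == s) for s in pd.unique(strata)
        ]
        with np.errstate(invalid="ignore"):
            hwe_dev = np.nanmax(np.vstack(devs), axis=0) if devs else np.full(G.n_variants, np.nan)

    return pd.DataFrame({
        "maf": maf,
        "call_rate": call_rate,
        "het_freq": het_freq,
        "hom_alt_count": hom_alt,
        "hwe_dev": hwe_dev,
        "dr2": G.dr2,
        "all_missing": n_obs == 0,
    })


def ld_r2(G: GenotypeMatrix, window_bp: int) -> pd.DataFrame:
    """Pairwise squared allelic correlation for variant pairs within a window.

    R^2 is the squared Pearson correlation of dosage vectors over animals
    non-missing at both variants.  Pairs containing a zero-variance
    variant are skipped (R^2 undefined).  Returns columns i, j, r2 with
    i < j (indices into the variant map).
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be > 0")
    chrom = G.variants["chrom"].to_numpy()
    pos = G.variants["pos"].to_numpy()
    d = G.dosage
    rows: list[tuple[int, int, float]] = []
    for i in range(G.n_variants):
        j = i + 1
        while j < G.n_variants and chrom[j] == chrom[i] and pos[j] - pos[i] <= window_bp:
            r2 = pair_r2(d[:, i], d[:, j])
            if not np.isnan(r2):
                rows.append((i, j, r2))
            j += 1
    return pd.DataFrame(rows, columns=["i", "j", "r2"])


def pair_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared dosage correlation over jointly non-missing animals."""
    ok = (x != MISSING) & (y != MISSING)
    if ok.sum() < 2:
        return np.nan
    xs = x[ok].astype(float)
    ys = y[ok].astype(float)
    if xs.std() == 0 or ys.std() == 0:
        return np.nan
    r = np.corrcoef(xs, ys)[0, 1]
    return float(r * r)


@dataclass
class FilterThresholds:
    """Thresholds for the structure-panel cascade (strict inequalities)."""

    max_missing_rate: float = 0.01
    min_maf: float = 0.02
    max_hwe_dev: float = 0.15
    min_dr2: float = 0.9
    prune_r2: float | None = 0.9
    prune_window_bp: int = 1_000_000


@dataclass
class FilterResult:
    retained: np.ndarray  # variant indices retained, in map order
    report: pd.DataFrame  # per-variant stats + first_failure (empty string = kept)

    @property
    def removed(self) -> np.ndarray:
        ff = self.report["first_failure"].to_numpy()
        return np.flatnonzero(ff != "")


def structure_panel_filter(
    G: GenotypeMatrix,
    strata: np.ndarray | None = None,
    thresholds: FilterThresholds | None = None,
) -> FilterResult:
    """Structure-adjustment panel cascade with per-variant reason log.

    Rules are applied in a fixed order (missing rate, MAF, HWE deviation,
    DR2, LD prune) and each removed variant records its first failure
    only.  LD pruning is greedy left-to-right by position; when a
    candidate conflicts (R^2 > prune_r2 within the window) with an
    already-kept variant, the lower-MAF member of the pair is dropped.
    """
    t = thresholds or FilterThresholds()
    stats = variant_stats(G, strata)
    n = G.n_variants
    failure = np.full(n, "", dtype=object)

    miss_rate = 1.0 - stats["call_rate"].to_numpy()
    maf = stats["maf"].to_numpy()
    hwe = stats["hwe_dev"].to_numpy()
    dr2 = stats["dr2"].to_numpy()

    failure[np.asarray(stats["all_missing"]) & (failure == "")] = "all_missing"
    failure[(miss_rate > t.max_missing_rate) & (failure == "")] = "missing_rate"
    failure[(maf < t.min_maf) & (failure == "")] = "maf"
    failure[(hwe > t.max_hwe_dev) & (failure == "")] = "hwe_dev"
    failure[(dr2 < t.min_dr2) & (failure == "")] = "dr2"

    if t.prune_r2 is not None:
        chrom = G.variants["chrom"].to_numpy()
        pos = G.variants["pos"].to_numpy()
        kept: list[int] = []
        for i in range(n):
            if failure[i]:
                continue
            conflict = None
            for k in reversed(kept):
                if chrom[k] != chrom[i] or pos[i] - pos[k] > t.prune_window_bp:
                    break
                r2 = pair_r2(G.dosage[:, k], G.dosage[:, i])
                if not np.isnan(r2) and r2 > t.prune_r2:
                    conflict = k
                    break
            if conflict is None:
                kept.append(i)
            elif maf[i] > maf[conflict]:
                # replace the kept lower-MAF member
                failure[conflict] = "ld_prune"
                kept.remove(conflict)
                kept.append(i)
            else:
                failure[i] = "ld_prune"

    retained = np.flatnonzero(failure == "")
    if len(retained) == 0:
        raise ValueError("structure panel filter removed every variant")
    report = stats.assign(first_failure=failure)
    return FilterResult(retained=retained, report=report)


def sequence_panel_filter(
    G: GenotypeMatrix,
    max_hom_alt: int = 5,
    min_dr2: float = 0.7,
) -> FilterResult:
    """Imputed-sequence panel cascade: rare-homozygote and DR2 filters.

    Removes variants with hom-alt count <= max_hom_alt (very rare
    homozygotes cannot support a dominance contrast) or DR2 < min_dr2
    (strictly below; DR2 == min_dr2 is retained).
    """
    stats = variant_stats(G)
    n = G.n_variants
    failure = np.full(n, "", dtype=object)
    hom_alt = stats["hom_alt_count"].to_numpy()
    dr2 = stats["dr2"].to_numpy()
    failure[np.asarray(stats["all_missing"]) & (failure == "")] = "all_missing"
    failure[(hom_alt <= max_hom_alt) & (failure == "")] = "hom_alt_count"
    failure[(dr2 < min_dr2) & (failure == "")] = "dr2"
    retained = np.flatnonzero(failure == "")
    if len(retained) == 0:
        raise ValueError("sequence panel filter removed every variant")
    return FilterResult(retained=retained, report=stats.assign(first_failure=failure))
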