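"""Population-structure adjustment by whole-genome Bayesian regression.

A BayesC0-style single-site Gibbs sampler fits every structure SNP's
additive effect (dosage codes 0/1/2) and dominance effect (heterozygosity
codes 0/1/0) simultaneously with common effect variances:

    y = 1 mu + M_alpha alpha + M_delta delta + e,
    alpha_j ~ N(0, sigma2_alpha),  delta_j ~ N(0, sigma2_delta),
    e ~ N(0, R),  R = diag(sigma2_e / w_i),

with scaled inverse chi-squared priors on the three variances.  Retained
posterior draws of the SNP effects are then used to build
leave-one-segment-out (LOSO) adjusted phenotypes: for each 10-Mb genome
segment, the phenotype is adjusted for every sampled SNP effect except
those inside the segment, so association tests inside it are not shrunk
by locally absorbed signal.  Chain convergence is monitored on the three
variance chains with the Geweke diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from ._kernels import gibbs_bayesc0_kernel
from .containers import GenotypeMatrix


@dataclass
class GibbsConfig:
    """Sampler settings; the retained-draw count defaults to 500."""

    n_retained: int = 500
    burn_in: int = 1000
    thin: int = 10
    nu: float = 4.0
    # prior split of phenotypic variance into (additive, dominance, residual)
    var_split: tuple[float, float, float] = (0.45, 0.05, 0.5)
    seed: int = 0

    def __post_init__(self):
        if self.n_retained < 2:
            raise ValueError("n_retained must be >= 2")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")


@dataclass
class PosteriorSampleSet:
    """Retained Gibbs draws: chains over t of mu, alpha, delta, variances."""

    mu: np.ndarray          # (T,)
    alpha: np.ndarray       # (T, p)
    delta: np.ndarray       # (T, p)
    var_alpha: np.ndarray   # (T,)
    var_delta: np.ndarray
    var_e: np.ndarray
    meta: dict = field(default_factory=dict)

    @property
    def n_retained(self) -> int:
        return len(self.mu)

    def save(self, path: str) -> None:
        np.savez_compressed(
            path, mu=self.mu, alpha=self.alpha, delta=self.delta,
            var_alpha=self.var_alpha, var_delta=self.var_delta, var_e=self.var_e,
            meta=np.array([repr(self.meta)], dtype=object),
        )

    @classmethod
    def load(cls, path: str) -> "PosteriorSampleSet":
        z = np.load(path, allow_pickle=True)
        meta = eval(str(z["meta"][0])) if "meta" in z else {}  # noqa: S307 - own file
        return cls(z["mu"], z["alpha"], z["delta"],
                   z["var_alpha"], z["var_delta"], z["var_e"], meta)


class BayesC0Sampler(BaseEstimator):
    """Single-site Gibbs sampler for all-SNP additive + dominance effects.

    Covariate columns are centred internally (the stored column means are
    reused when reconstructing fitted values, so adjusted phenotypes are
    exact).  Zero-variance SNP columns have their effects pinned to 0.

    Fitted attributes: ``samples_`` (PosteriorSampleSet), ``geweke_``
    (z and degenerate flag per variance chain), ``col_means_alpha_``,
    ``col_means_delta_``, ``M_alpha_``, ``M_delta_`` (centred covariates,
    kept for LOSO adjustment), ``active_alpha_``, ``active_delta_``.
    """

    def __init__(self, n_retained: int = 500, burn_in: int = 1000, thin: int = 10,
                 nu: float = 4.0, var_split: tuple = (0.45, 0.05, 0.5),
                 include_dominance: bool = True, seed: int = 0):
        self.n_retained = n_retained
        self.burn_in = burn_in
        self.thin = thin
        self.nu = nu
        self.var_split = var_split
        self.include_dominance = include_dominance
        self.seed = seed

    def fit(self, X, y, sample_weight=None):
        cfg = GibbsConfig(self.n_retained, self.burn_in, self.thin, self.nu,
                          tuple(self.var_split), self.seed)
        if isinstance(X, GenotypeMatrix):
            X = X.mean_imputed()
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64)
        if not np.all(np.isfinite(y)):
            raise ValueError("phenotypes contain non-finite values")
        n, p = X.shape
        w = np.ones(n) if sample_weight is None else np.asarray(sample_weight, dtype=float)

        het = (X == 1.0).astype(np.float64)
        self.col_means_alpha_ = X.mean(axis=0)
        self.col_means_delta_ = het.mean(axis=0)
        Ma = np.ascontiguousarray((X - self.col_means_alpha_).T, dtype=np.float32)
        Md = np.ascontiguousarray((het - self.col_means_delta_).T, dtype=np.float32)
        self.active_alpha_ = Ma.var(axis=1) > 0
        self.active_delta_ = Md.var(axis=1) > 0

        vary = float(np.var(y))
        if vary == 0:
            vary = 1.0
        sa, sd, se = cfg.var_split
        var_alpha_target = sa * vary / max(float(np.sum(Ma.var(axis=1))), 1e-12)
        var_delta_target = sd * vary / max(float(np.sum(Md.var(axis=1))), 1e-12)
        var_e_target = se * vary
        # scale so the prior mean nu*S2/(nu-2) equals the target
        shrink = (cfg.nu - 2.0) / cfg.nu if cfg.nu > 2.0 else 1.0
        s2_a = var_alpha_target * shrink
        s2_d = var_delta_target * shrink
        s2_e = var_e_target * shrink

        T = cfg.n_retained
        out_mu = np.empty(T)
        out_alpha = np.empty((T, p))
        out_delta = np.empty((T, p))
        out_va = np.empty(T)
        out_vd = np.empty(T)
        out_ve = np.empty(T)
        gibbs_bayesc0_kernel(
            Ma, Md, w, y, int(cfg.seed) % (2**31 - 1),
            T, cfg.burn_in, cfg.thin,
            cfg.nu, s2_a, cfg.nu, s2_d, cfg.nu, s2_e,
            self.active_alpha_, self.active_delta_, self.include_dominance,
            out_mu, out_alpha, out_delta, out_va, out_vd, out_ve,
        )
        if not self.include_dominance:
            out_delta[:] = 0.0
            out_vd[:] = var_delta_target
        self.samples_ = PosteriorSampleSet(
            out_mu, out_alpha, out_delta, out_va, out_vd, out_ve,
            meta={"seed": cfg.seed, "burn_in": cfg.burn_in, "thin": cfg.thin,
                  "nu": cfg.nu, "var_split": cfg.var_split},
        )
        self.M_alpha_ = Ma.T
        self.M_delta_ = Md.T
        self.geweke_ = {
            name: geweke_diagnostic(chain)
            for name, chain in [("var_alpha", out_va), ("var_delta", out_vd),
                                ("var_e", out_ve)]
        }
        return self


def gibbs_bayesc0(y, w, M_alpha, M_delta=None, cfg: GibbsConfig | None = None,
                  include_dominance: bool = True) -> PosteriorSampleSet:
    """Functional wrapper over :class:`BayesC0Sampler` (dosage input)."""
    cfg = cfg or GibbsConfig()
    est = BayesC0Sampler(cfg.n_retained, cfg.burn_in, cfg.thin, cfg.nu,
                         cfg.var_split, include_dominance, cfg.seed)
    est.fit(np.asarray(M_alpha, dtype=float), y, sample_weight=w)
    return est.samples_


def geweke_diagnostic(chain: np.ndarray, first: float = 0.1,
                      last: float = 0.5) -> tuple[float, bool]:
    """Geweke convergence z-score comparing early vs late chain windows.

    z = (mean of first 10% - mean of last 50%) / sqrt(sum of
    spectral-density-at-zero variance estimates of the two windows).
    Returns (z, degenerate_flag); a constant chain gives z = 0 with the
    degenerate flag set.  |z| > 2 conventionally flags non-convergence.
    """
    chain = np.asarray(chain, dtype=float)
    m = len(chain)
    if m < 50:
        raise ValueError("chain too short for the Geweke diagnostic (need >= 50)")
    a = chain[: max(int(first * m), 2)]
    b = chain[-max(int(last * m), 2):]
    va = _spectral_var(a)
    vb = _spectral_var(b)
    denom = va / len(a) + vb / len(b)
    if denom == 0:
        return 0.0, True
    return float((a.mean() - b.mean()) / np.sqrt(denom)), False


def _spectral_var(x: np.ndarray) -> float:
    """Spectral density at frequency zero via a Bartlett-windowed sum."""
    x = x - x.mean()
    n = len(x)
    lag_max = min(n - 1, max(1, int(np.sqrt(n))))
    s = float(np.dot(x, x)) / n
    for k in range(1, lag_max + 1):
        gamma_k = float(np.dot(x[:-k], x[k:])) / n
        s += 2.0 * (1.0 - k / (lag_max + 1.0)) * gamma_k
    return max(s, 0.0)


@dataclass
class SegmentPlan:
    """Half-open 10-Mb genome tiling with variant assignment.

    A 1-based position p on chromosome c belongs to the tile with index
    floor((p - 1) / segment_bp) on that chromosome (0-based half-open bp
    intervals).  Segments are identified by a global integer id.
    """

    segments: pd.DataFrame  # seg_id, chrom, start_bp, end_bp (0-based half-open)
    segment_bp: int

    def assign(self, chrom: np.ndarray, pos: np.ndarray) -> np.ndarray:
        """Global segment id for each (chrom, 1-based pos)."""
        chrom = np.asarray(chrom)
        pos = np.asarray(pos)
        tile = (pos - 1) // self.segment_bp
        key = pd.MultiIndex.from_arrays(
            [self.segments["chrom"], self.segments["start_bp"] // self.segment_bp]
        )
        lookup = pd.Series(self.segments["seg_id"].to_numpy(), index=key)
        out = np.empty(len(pos), dtype=int)
        for i, (c, t) in enumerate(zip(chrom, tile)):
            try:
                out[i] = lookup.loc[(c, t)]
            except KeyError:
                raise KeyError(f"position {c}:{pos[i]} falls outside the segment plan") from None
        return out

    @property
    def seg_ids(self) -> np.ndarray:
        return self.segments["seg_id"].to_numpy()


def partition_segments(variant_map: pd.DataFrame, segment_bp: int = 10_000_000,
                       chrom_lengths: dict | None = None) -> SegmentPlan:
    """Tile each chromosome into half-open segment_bp intervals.

    Chromosome extents default to the maximum mapped position; the last
    interval is truncated at the chromosome end.  Every variant maps to
    exactly one segment.
    """
    rows = []
    seg_id = 0
    for c, sub in variant_map.groupby("chrom", sort=False):
        end = int(chrom_lengths[c]) if chrom_lengths else int(sub["pos"].max())
        n_seg = max(1, int(np.ceil(end / segment_bp)))
        for k in range(n_seg):
            rows.append({
                "seg_id": seg_id, "chrom": c,
                "start_bp": k * segment_bp,
                "end_bp": min((k + 1) * segment_bp, end),
            })
            seg_id += 1
    return SegmentPlan(segments=pd.DataFrame(rows), segment_bp=segment_bp)


class LosoAdjuster:
    """Leave-one-segment-out adjusted phenotypes, lazily materialised.

    For posterior sample t and segment s:

        ytilde(s, t) = y - mu_t - sum_{j not in s} (m_alpha_j alpha_jt
                                                    + m_delta_j delta_jt)

    implemented as the fully adjusted residual (cached once, n x T) plus
    the add-back of segment-s fitted contributions on demand.
    """

    def __init__(self, y: np.ndarray, samples: PosteriorSampleSet,
                 M_alpha: np.ndarray, M_delta: np.ndarray,
                 snp_chrom: np.ndarray, snp_pos: np.ndarray, plan: SegmentPlan):
        self.y = np.asarray(y, dtype=float)
        self.samples = samples
        self.M_alpha = np.asarray(M_alpha, dtype=float)
        self.M_delta = np.asarray(M_delta, dtype=float)
        self.plan = plan
        self.seg_of_snp = plan.assign(snp_chrom, snp_pos)
        full_fit = self.M_alpha @ samples.alpha.T + self.M_delta @ samples.delta.T
        self.base_ = self.y[:, None] - samples.mu[None, :] - full_fit
        self._cache: dict[int, np.ndarray] = {}

    @classmethod
    def from_sampler(cls, y, sampler: BayesC0Sampler, snp_chrom, snp_pos,
                     plan: SegmentPlan) -> "LosoAdjuster":
        return cls(y, sampler.samples_, sampler.M_alpha_, sampler.M_delta_,
                   snp_chrom, snp_pos, plan)

    @property
    def var_e(self) -> np.ndarray:
        return self.samples.var_e

    @property
    def n_retained(self) -> int:
        return self.samples.n_retained

    def addback(self, seg_id: int) -> np.ndarray:
        if seg_id not in set(self.plan.seg_ids):
            raise KeyError(f"unknown segment id {seg_id}")
        cols = np.flatnonzero(self.seg_of_snp == seg_id)
        if len(cols) == 0:
            return np.zeros_like(self.base_)
        return (self.M_alpha[:, cols] @ self.samples.alpha[:, cols].T
                + self.M_delta[:, cols] @ self.samples.delta[:, cols].T)

    def adjusted(self, seg_id: int) -> np.ndarray:
        """ytilde(seg, .) as an (n_animals, n_retained) array."""
        if seg_id in self._cache:
            return self._cache[seg_id]
        out = self.base_ + self.addback(seg_id)
        self._cache = {seg_id: out}  # keep only the most recent segment
        return out

    def adjusted_direct(self, seg_id: int) -> np.ndarray:
        """Reference implementation summing j-not-in-s terms explicitly."""
        keep = self.seg_of_snp != seg_id
        fit = (self.M_alpha[:, keep] @ self.samples.alpha[:, keep].T
               + self.M_delta[:, keep] @ self.samples.delta[:, keep].T)
        return self.y[:, None] - self.samples.mu[None, :] - fit


def loso_adjust(y, samples: PosteriorSampleSet, M_alpha, M_delta,
                snp_chrom, snp_pos, plan: SegmentPlan) -> LosoAdjuster:
    """Functional constructor for :class:`LosoAdjuster`."""
    return LosoAdjuster(y, samples, M_alpha, M_delta, snp_chrom, snp_pos, plan)
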