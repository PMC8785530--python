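"""Per-variant genotype-class MCMC association and QTL classification.

For every test variant, an MCMC chain of genotype-class effects
(b0, b1, b2) for (hom-ref, het, hom-alt) is built over the retained
posterior samples of LOSO-adjusted phenotypes: for sample t the weighted
least-squares class means are computed and a draw is taken from their
conditional normal, so posterior standard deviations combine
within-sample estimation error and between-sample adjustment
uncertainty.  Chains are summarised as three contrasts:

* genotypic additive effect  a = (b2 - b0) / 2,
* genotypic dominance effect d = b1 - (b0 + b2) / 2,
* standard-additive effect   alpha_std = weighted dosage-slope contrast,

with z = posterior mean / posterior SD, two-sided normal p-values,
Storey q-values on the dominance p, dominance coefficient k = d/|a| and
a class label (additive, partial-dominant, recessive-window,
over-dominant).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .containers import GenotypeMatrix


# ---------------------------------------------------------------------------
# class-effect chains
# ---------------------------------------------------------------------------

def class_weight_sums(X: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Summed weights per genotype class, shape (n_variants, 3)."""
    return np.stack([((X == c).T.astype(float) @ w) for c in (0, 1, 2)], axis=1)


def sample_class_effects(ytilde: np.ndarray, x: np.ndarray, w: np.ndarray,
                         var_e: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Chain of genotype-class effect draws for one variant, shape (3, T).

    For each posterior sample t, b_hat is the w-weighted mean of
    ytilde[:, t] per genotype class, and the draw is
    N(b_hat_c, var_e[t] / sum of w in class c).  Empty classes yield NaN.
    Requires at least two occupied classes.
    """
    x = np.asarray(x)
    T = ytilde.shape[1]
    b = np.full((3, T), np.nan)
    occupied = 0
    for c in (0, 1, 2):
        mask = x == c
        swc = float(w[mask].sum())
        if swc <= 0:
            continue
        occupied += 1
        bhat = (w[mask] @ ytilde[mask]) / swc
        b[c] = bhat + rng.standard_normal(T) * np.sqrt(var_e / swc)
    if occupied < 2:
        raise ValueError("variant has fewer than two occupied genotype classes")
    return b


def _batched_class_chains(ytilde: np.ndarray, X: np.ndarray, w: np.ndarray,
                          var_e: np.ndarray, rng: np.random.Generator
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Class-effect chains for a batch of variants.

    Returns (b, sw): b has shape (V, 3, T) with NaN for empty classes,
    sw the (V, 3) class weight sums.
    """
    WY = np.asarray(w[:, None] * ytilde, dtype=np.float32)   # (n, T)
    sw = class_weight_sums(X, w)                 # (V, 3)
    V, T = X.shape[1], ytilde.shape[1]
    b = np.full((V, 3, T), np.nan)
    for c in (0, 1, 2):
        ind = (X == c).T.astype(np.float32)      # (V, n)
        num = (ind @ WY).astype(np.float64)      # (V, T)
        swc = sw[:, c]
        ok = swc > 0
        noise = rng.standard_normal((int(ok.sum()), T))
        b[ok, c, :] = (num[ok] / swc[ok, None]
                       + noise * np.sqrt(var_e[None, :] / swc[ok, None]))
    return b, sw


# ---------------------------------------------------------------------------
# contrasts
# ---------------------------------------------------------------------------

def contrasts_from_b(b: np.ndarray, sw: np.ndarray) -> dict[str, np.ndarray]:
    """a, d and alpha_std chains from class-effect chains.

    ``b`` is (V, 3, T) (or (3, T) for a single variant), ``sw`` the class
    weight sums.  alpha_std is the weighted regression slope of phenotype
    on dosage expressed as a contrast of the class effects; it remains
    defined when one class is empty (slope over the two occupied
    classes), whereas a and d require their defining classes.
    """
    single = b.ndim == 2
    if single:
        b = b[None]
        sw = np.asarray(sw, dtype=float)[None]
    a = (b[:, 2] - b[:, 0]) / 2.0
    d = b[:, 1] - (b[:, 0] + b[:, 2]) / 2.0
    # slope contrast weights from class weight sums
    S = sw.sum(axis=1)
    xbar = (sw[:, 1] + 2.0 * sw[:, 2]) / S
    xc = np.stack([0.0 - xbar, 1.0 - xbar, 2.0 - xbar], axis=1)  # (V, 3)
    sxx = (sw * xc**2).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        u = sw * xc / sxx[:, None]
    b_filled = np.where(np.isnan(b), 0.0, b)
    u = np.where(sw > 0, u, 0.0)
    alpha = np.einsum("vc,vct->vt", u, b_filled)
    alpha[sxx <= 0] = np.nan
    out = {"a": a, "d": d, "alpha": alpha}
    if single:
        out = {k: v[0] for k, v in out.items()}
    return out


def _summarise(chain: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """(mean, sd, z, p) row-wise over the chain axis."""
    mean = chain.mean(axis=-1)
    sd = chain.std(axis=-1, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = mean / sd
    p = 2.0 * norm.sf(np.abs(z))
    return mean, sd, z, p


def zscore_pvalue(estimate: float, sd: float) -> tuple[float, float]:
    """Two-sided standard-normal p-value for an estimate/SD pair."""
    z = estimate / sd
    return z, float(2.0 * norm.sf(abs(z)))


def dominance_coefficient(a: float, d: float) -> float:
    """k = d / |a|; NaN when the additive effect is exactly zero."""
    return np.nan if a == 0 else d / abs(a)


def summarize_contrasts(b: np.ndarray, sw: np.ndarray) -> dict:
    """Posterior summaries for one variant's class-effect chain."""
    cons = contrasts_from_b(b, sw)
    out = {}
    for name, chain in cons.items():
        if np.isnan(chain).any():
            out.update({f"{name}_mean": np.nan, f"{name}_sd": np.nan,
                        f"{name}_z": np.nan, f"{name}_p": np.nan})
        else:
            m, s, z, p = _summarise(chain)
            out.update({f"{name}_mean": float(m), f"{name}_sd": float(s),
                        f"{name}_z": float(z), f"{name}_p": float(p)})
    out["k"] = dominance_coefficient(out["a_mean"], out["d_mean"]) \
        if np.isfinite(out["a_mean"]) else np.nan
    return out


# ---------------------------------------------------------------------------
# genome scan
# ---------------------------------------------------------------------------

def scan_variants(adjuster, G_test: GenotypeMatrix, w: np.ndarray,
                  rng: np.random.Generator, chunk: int = 256) -> pd.DataFrame:
    """Association summaries for every variant in a test panel.

    ``adjuster`` is any object exposing ``plan``, ``var_e`` and
    ``adjusted(seg_id) -> (n, T)`` (a :class:`~lactoqtl.gibbs.LosoAdjuster`
    or a conditioned accessor).  Variants are processed segment by
    segment so each LOSO phenotype matrix is materialised once.
    """
    chrom = G_test.variants["chrom"].to_numpy()
    pos = G_test.variants["pos"].to_numpy()
    seg = adjuster.plan.assign(chrom, pos)
    var_e = np.asarray(adjuster.var_e, dtype=float)
    maf = G_test.maf()
    frames = []
    for s in np.unique(seg):
        idx = np.flatnonzero(seg == s)
        ytil = adjuster.adjusted(int(s))
        for lo in range(0, len(idx), chunk):
            sl = idx[lo:lo + chunk]
            X = G_test.dosage[:, sl]
            b, sw = _batched_class_chains(ytil, X, w, var_e, rng)
            cons = contrasts_from_b(b, sw)
            rec: dict[str, np.ndarray] = {}
            for name in ("a", "d", "alpha"):
                m, sd, z, p = _summarise(cons[name])
                rec[f"{name}_mean"], rec[f"{name}_sd"] = m, sd
                rec[f"{name}_z"], rec[f"{name}_p"] = z, p
            with np.errstate(invalid="ignore", divide="ignore"):
                k = np.where(rec["a_mean"] != 0, rec["d_mean"] / np.abs(rec["a_mean"]), np.nan)
            frames.append(pd.DataFrame({
                "variant_index": sl, "chrom": chrom[sl], "pos": pos[sl],
                "seg_id": seg[sl], "maf": maf[sl],
                "n_hom_ref": (X == 0).sum(axis=0), "n_het": (X == 1).sum(axis=0),
                "n_hom_alt": (X == 2).sum(axis=0),
                **rec, "k": k,
            }))
    out = pd.concat(frames, ignore_index=True).sort_values("variant_index")
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# q-values (Storey)
# ---------------------------------------------------------------------------

def qvalues(p: np.ndarray, lambdas: np.ndarray | None = None,
            pi0: float | None = None) -> np.ndarray:
    """Storey q-values.

    pi0 is estimated from the lambda grid {0.05, ..., 0.95} with a cubic
    smoother evaluated at the largest lambda (pass ``pi0`` to override),
    then q_(i) = min_{j >= i} pi0 * m * p_(j) / j (ties share a q).
    With fewer than 100 p-values pi0 is fixed at 1 with a warning.  NaN
    p-values propagate as NaN and do not enter m.
    """
    p = np.asarray(p, dtype=float)
    ok = np.isfinite(p)
    ps = p[ok]
    if np.any((ps <= 0) | (ps > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    m = len(ps)
    q = np.full_like(p, np.nan)
    if m == 0:
        return q
    if pi0 is not None:
        pass
    elif m < 100:
        warnings.warn("fewer than 100 p-values: pi0 fixed at 1", stacklevel=2)
        pi0 = 1.0
    else:
        lambdas = np.arange(0.05, 0.96, 0.05) if lambdas is None else np.asarray(lambdas)
        pi0_l = np.array([np.mean(ps > lam) / (1.0 - lam) for lam in lambdas])
        coef = np.polyfit(lambdas, pi0_l, deg=3)
        pi0 = float(np.clip(np.polyval(coef, lambdas.max()), 1.0 / m, 1.0))
    order = np.argsort(ps, kind="mergesort")
    ranked = pi0 * m * ps[order] / np.arange(1, m + 1)
    qs = np.minimum.accumulate(ranked[::-1])[::-1]
    qs = np.clip(qs, 0.0, 1.0)
    out = np.empty(m)
    out[order] = qs
    q[ok] = out
    return q


# ---------------------------------------------------------------------------
# calling and classification
# ---------------------------------------------------------------------------

@dataclass
class ClassBins:
    """|k| bin edges for the dominance-class label."""

    additive_max: float = 0.1
    recessive_low: float = 0.7
    recessive_high: float = 1.3


def classify_k(k: float, bins: ClassBins | None = None) -> str:
    """Dominance class from k = d/|a| (negative k mirrored through |k|)."""
    bins = bins or ClassBins()
    if not np.isfinite(k):
        return "undefined"
    kk = abs(k)
    if kk <= bins.additive_max:
        return "additive"
    if kk < bins.recessive_low:
        return "partial-dominant"
    if kk < bins.recessive_high:
        return "recessive-window"
    return "over-dominant"


def call_and_classify(results: pd.DataFrame, phenotypic_sd: float,
                      fdr: float = 1e-3, effect_frac: float = 0.05,
                      bins: ClassBins | None = None) -> pd.DataFrame:
    """Add q_d, pass flags and dominance class; a call needs both flags.

    A variant is significant when its dominance q-value is below ``fdr``;
    it is retained when additionally max(|a|, |d|) exceeds
    ``effect_frac`` * phenotypic SD.  The q-value is computed over all
    tested variants in ``results`` (one trait at a time).
    """
    out = results.copy()
    out["q_d"] = qvalues(out["d_p"].to_numpy())
    effect = np.maximum(np.abs(out["a_mean"]), np.abs(out["d_mean"]))
    out["passes_fdr"] = out["q_d"] < fdr
    out["passes_effect"] = effect > effect_frac * phenotypic_sd
    out["is_call"] = out["passes_fdr"] & out["passes_effect"]
    out["dominance_class"] = [classify_k(k, bins) for k in out["k"]]
    return out
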