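"""Iterative conditional QTL mapping.

Co-locating QTL are differentiated by conditioning on called variants
and re-scanning: each round subtracts jointly fitted genotype-class
effects of the conditioned variants from every LOSO-adjusted phenotype
sample, re-runs the association scan on the chromosome, and stops when
no variant passes the FDR and effect-size thresholds.  Additive tag
variants are selected by genotype-level greedy stepwise conditioning on
the dosage slope (a direct-genotype replacement for summary-statistic
conditional-and-joint analysis).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .assoc import ClassBins, call_and_classify, qvalues, scan_variants
from .containers import GenotypeMatrix
from .qc import pair_r2


class ConditionedAccessor:
    """LOSO phenotype accessor with conditioned genotype-class effects removed.

    Conditioning fits, per segment and posterior sample, a joint weighted
    least-squares regression of the adjusted phenotype on the class
    indicators of every conditioned variant (plus an intercept) and
    subtracts the fit.  Rank-deficient designs (collinear class
    indicators across conditioned variants) are handled by
    pivoted-QR column dropping with a warning.
    """

    def __init__(self, base, dosages: np.ndarray, w: np.ndarray):
        self.base = base
        self.w = np.asarray(w, dtype=float)
        self.Z = self._design(np.atleast_2d(np.asarray(dosages).T).T)
        self._cache: dict[int, np.ndarray] = {}

    @staticmethod
    def _design(dosages: np.ndarray) -> np.ndarray:
        """Intercept + het/hom-alt indicators per conditioned variant."""
        n, k = dosages.shape
        cols = [np.ones(n)]
        for j in range(k):
            x = dosages[:, j]
            cols.append((x == 1).astype(float))
            cols.append((x == 2).astype(float))
        return np.column_stack(cols)

    @property
    def plan(self):
        return self.base.plan

    @property
    def var_e(self):
        return self.base.var_e

    @property
    def n_retained(self):
        return self.base.n_retained

    def _solve(self, Y: np.ndarray) -> np.ndarray:
        """WLS fit of Y (n x T) on self.Z, dropping collinear columns."""
        sw = np.sqrt(self.w)
        Zw = self.Z * sw[:, None]
        Yw = Y * sw[:, None]
        # pivoted rank detection via QR
        from scipy.linalg import qr
        _, R, piv = qr(Zw, mode="economic", pivoting=True)
        diag = np.abs(np.diag(R))
        tol = diag.max() * max(Zw.shape) * np.finfo(float).eps
        rank = int(np.sum(diag > tol))
        if rank < Zw.shape[1]:
            warnings.warn(
                f"dropping {Zw.shape[1] - rank} collinear conditioning columns",
                stacklevel=2,
            )
        keep = piv[:rank]
        coef = np.zeros((self.Z.shape[1], Y.shape[1]))
        coef[keep] = np.linalg.lstsq(Zw[:, keep], Yw, rcond=None)[0]
        return coef

    def adjusted(self, seg_id: int) -> np.ndarray:
        if seg_id in self._cache:
            return self._cache[seg_id]
        Y = self.base.adjusted(seg_id)
        coef = self._solve(Y)
        out = Y - self.Z @ coef
        self._cache = {seg_id: out}
        return out


def condition_phenotype(base, G: GenotypeMatrix, variant_indices, w) -> ConditionedAccessor:
    """Accessor with the listed variants' genotype-class effects removed."""
    idx = np.atleast_1d(np.asarray(variant_indices, dtype=int))
    return ConditionedAccessor(base, G.dosage[:, idx].astype(float), w)


@dataclass
class IterationState:
    chromosome: object
    conditioned: list[int] = field(default_factory=list)
    round_index: int = 0
    results: pd.DataFrame | None = None


def iterate_chromosome(
    adjuster,
    G_test: GenotypeMatrix,
    chromosome,
    w: np.ndarray,
    phenotypic_sd: float,
    rng: np.random.Generator,
    fdr: float = 1e-3,
    effect_frac: float = 0.05,
    bins: ClassBins | None = None,
    max_rounds: int = 5,
    candidates: list[int] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Iteratively condition on the top dominance variant and re-scan.

    Each round scans every test variant on the chromosome, computes
    q-values over that scan, and calls variants passing both the FDR and
    the effect-size thresholds.  The most significant dominance variant
    (or the next user-supplied candidate) is added to the conditioned
    set and the scan repeats until no call remains or ``max_rounds`` is
    reached.  Returns (calls with iteration indices, per-round log).
    """
    on_chrom = np.flatnonzero(G_test.variants["chrom"].to_numpy() == chromosome)
    if len(on_chrom) == 0:
        raise ValueError(f"no test variants on chromosome {chromosome!r}")
    G_chrom = G_test.subset_variants(on_chrom)
    state = IterationState(chromosome=chromosome)
    calls = []
    log = []
    accessor = adjuster
    candidates = list(candidates) if candidates is not None else None
    for rnd in range(1, max_rounds + 1):
        state.round_index = rnd
        res = scan_variants(accessor, G_chrom, w, rng)
        res["variant_index"] = on_chrom[res["variant_index"].to_numpy()]
        res = call_and_classify(res, phenotypic_sd, fdr=fdr,
                                effect_frac=effect_frac, bins=bins)
        state.results = res
        sig = res[res["is_call"] & np.isfinite(res["d_p"])]
        log.append({"round": rnd, "n_significant": int(sig.shape[0]),
                    "conditioned": ",".join(map(str, state.conditioned))})
        if sig.empty and not (candidates and rnd <= len(candidates)):
            break
        if candidates:
            if rnd > len(candidates):
                break
            pick = int(candidates[rnd - 1])
        else:
            pick = int(sig.sort_values("d_p").iloc[0]["variant_index"])
        if not sig.empty:
            row = res.loc[res["variant_index"] == pick]
            top = (row.iloc[0] if not row.empty else sig.sort_values("d_p").iloc[0]).to_dict()
            top["iteration"] = rnd
            calls.append(top)
        if pick in state.conditioned:
            raise RuntimeError(
                f"variant {pick} re-entered the conditioned set on round {rnd}; "
                "aborting to avoid oscillation"
            )
        state.conditioned.append(pick)
        accessor = condition_phenotype(adjuster, G_test, state.conditioned, w)
    calls_df = pd.DataFrame(calls)
    return calls_df, pd.DataFrame(log)


# ---------------------------------------------------------------------------
# stepwise additive tag selection
# ---------------------------------------------------------------------------

def _wls_slope_z(y: np.ndarray, x: np.ndarray, w: np.ndarray,
                 covariates: np.ndarray | None) -> tuple[float, float]:
    """Weighted partial-regression slope of y on x and its z-statistic."""
    sw = w / w.sum()
    if covariates is not None and covariates.size:
        Q = np.column_stack([np.ones(len(y)), covariates])
        WQ = Q * w[:, None]
        beta_x = np.linalg.lstsq(WQ.T @ Q, WQ.T @ x, rcond=None)[0]
        beta_y = np.linalg.lstsq(WQ.T @ Q, WQ.T @ y, rcond=None)[0]
        rx = x - Q @ beta_x
        ry = y - Q @ beta_y
    else:
        rx = x - np.sum(sw * x)
        ry = y - np.sum(sw * y)
    sxx = float(np.sum(w * rx * rx))
    if sxx <= 0:
        return np.nan, np.nan
    slope = float(np.sum(w * rx * ry)) / sxx
    resid = ry - slope * rx
    dof = max(len(y) - (2 if covariates is None else 2 + covariates.shape[1]), 1)
    sigma2 = float(np.sum(w * resid * resid)) / dof
    se = np.sqrt(sigma2 / sxx)
    return slope, slope / se


def stepwise_additive_tags(
    adjuster,
    G_test: GenotypeMatrix,
    w: np.ndarray,
    fdr: float = 1e-3,
    max_tags: int = 20,
    collinear_r2: float = 0.99,
) -> tuple[list[int], pd.DataFrame]:
    """Greedy forward selection of additive (dosage-slope) tag variants.

    Candidate slopes are fitted on the posterior-mean LOSO phenotype of
    each variant's own segment, jointly with all previously selected tag
    dosages as covariates.  The most significant candidate passing
    Storey q < ``fdr`` is added each round; candidates in near-perfect
    LD (R^2 > ``collinear_r2``) with a selected tag are skipped.
    Returns (selected variant indices, per-round log).
    """
    chrom = G_test.variants["chrom"].to_numpy()
    pos = G_test.variants["pos"].to_numpy()
    seg = adjuster.plan.assign(chrom, pos)
    ybar = {int(s): adjuster.adjusted(int(s)).mean(axis=1) for s in np.unique(seg)}
    w = np.asarray(w, dtype=float)
    selected: list[int] = []
    log = []
    for rnd in range(1, max_tags + 1):
        cov = G_test.dosage[:, selected].astype(float) if selected else None
        zs = np.full(G_test.n_variants, np.nan)
        for v in range(G_test.n_variants):
            if v in selected:
                continue
            if selected and any(
                (r2 := pair_r2(G_test.dosage[:, v], G_test.dosage[:, s])) is not None
                and not np.isnan(r2) and r2 > collinear_r2 for s in selected
            ):
                continue
            x = G_test.dosage[:, v].astype(float)
            _, z = _wls_slope_z(ybar[int(seg[v])], x, w, cov)
            zs[v] = z
        with np.errstate(invalid="ignore"):
            p = 2.0 * norm.sf(np.abs(zs))
        q = qvalues(p)
        if not np.any(np.nan_to_num(q, nan=1.0) < fdr):
            log.append({"round": rnd, "selected": -1, "min_q": float(np.nanmin(q))
                        if np.isfinite(q).any() else np.nan})
            break
        pick = int(np.nanargmin(np.where(q < fdr, p, np.nan)))
        selected.append(pick)
        log.append({"round": rnd, "selected": pick, "min_q": float(np.nanmin(q))})
    return selected, pd.DataFrame(log)
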