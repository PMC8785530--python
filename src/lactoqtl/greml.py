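"""Genomic REML with additive and dominance relationship matrices.

Additive relationships use VanRaden-style centred/scaled dosage codes
(x - 2p)/sqrt(2pq); dominance relationships use the orthogonal genotypic
coding (hom-ref, het, hom-alt) -> (-2p^2, 2pq, -2q^2) scaled by 2pq, so
both matrices have expected diagonal 1 under Hardy-Weinberg and the two
codings are uncorrelated in an HWE population.  Variance components for

    y ~ N(1 mu, G_add sigma2_a + G_dom sigma2_d + I sigma2_e)

are estimated by average-information REML with an EM fallback whenever
the AI step proposes a negative component or decreases the restricted
likelihood; components are constrained non-negative by projection onto a
small positive floor.  Standard errors come from the inverse AI matrix,
with the delta method for the heritability ratios h2 = sigma2_a / total
and delta2 = sigma2_d / total.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from sklearn.base import BaseEstimator

from .containers import GenotypeMatrix


@dataclass
class GRMPair:
    G_add: np.ndarray
    G_dom: np.ndarray
    n_snps: int


@dataclass
class VarianceComponents:
    sigma2_a: float
    sigma2_d: float
    sigma2_e: float
    h2: float
    delta2: float
    se_h2: float
    se_delta2: float
    loglik: float
    n_iter: int
    converged: bool

    @property
    def total(self) -> float:
        return self.sigma2_a + self.sigma2_d + self.sigma2_e


def dominance_codes(x: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Orthogonal dominance codes (-2p^2, 2pq, -2q^2) for dosages 0/1/2."""
    q = 1.0 - p
    return np.where(x == 1, 2.0 * p * q, np.where(x < 1, -2.0 * p**2, -2.0 * q**2))


def build_grms(G: GenotypeMatrix | np.ndarray, freqs: np.ndarray | None = None) -> GRMPair:
    """Additive and dominance GRMs from a genotype matrix.

    Monomorphic variants are excluded with a warning.  Frequencies
    default to the analysis-sample allele frequencies; missing dosages
    are mean-imputed at this point (model-fitting time).
    """
    if isinstance(G, GenotypeMatrix):
        X = G.mean_imputed()
    else:
        X = np.asarray(G, dtype=float)
    p = X.mean(axis=0) / 2.0 if freqs is None else np.asarray(freqs, dtype=float)
    poly = (p > 0.0) & (p < 1.0)
    if not poly.all():
        warnings.warn(f"excluding {int((~poly).sum())} monomorphic variants from GRMs",
                      stacklevel=2)
    X = X[:, poly]
    p = p[poly]
    m = X.shape[1]
    pq = p * (1.0 - p)
    Z = (X - 2.0 * p[None, :]) / np.sqrt(2.0 * pq)[None, :]
    D = dominance_codes(X.round(), p) / (2.0 * pq)[None, :]
    G_add = (Z @ Z.T) / m
    G_dom = (D @ D.T) / m
    return GRMPair(G_add=G_add, G_dom=G_dom, n_snps=m)


class AdditiveDominanceREML(BaseEstimator):
    """AI-REML estimator of additive + dominance variance components.

    Parameters
    ----------
    max_iter : int
        Maximum AI/EM iterations.
    tol : float
        Convergence threshold on the restricted log-likelihood change.
    floor_frac : float
        Non-negativity floor for each component as a fraction of var(y).
    jitter : float
        Relative diagonal jitter used when the covariance fails Cholesky.

    Fitted attributes: ``sigma2_a_``, ``sigma2_d_``, ``sigma2_e_``,
    ``h2_``, ``delta2_``, ``se_h2_``, ``se_delta2_``, ``loglik_``,
    ``loglik_trace_``, ``n_iter_``, ``converged_``, ``ai_cov_``.

    Record-count weights are deliberately not used here (homoscedastic
    residual): heritability is estimated on the yield deviations as-is.
    """

    def __init__(self, max_iter: int = 60, tol: float = 1e-6,
                 floor_frac: float = 1e-6, jitter: float = 1e-8):
        self.max_iter = max_iter
        self.tol = tol
        self.floor_frac = floor_frac
        self.jitter = jitter

    # -- internal -------------------------------------------------------
    def _chol(self, V: np.ndarray):
        scale = np.mean(np.diag(V))
        for k in range(4):
            try:
                return cho_factor(V + np.eye(len(V)) * scale * self.jitter * (10.0**k - 1.0),
                                  lower=True)
            except np.linalg.LinAlgError:
                continue
        raise np.linalg.LinAlgError("covariance not positive definite after jitter retries")

    @staticmethod
    def _loglik(cf, V1_logdet_terms, y, Py):
        logdet_V, logdet_xvx = V1_logdet_terms
        return -0.5 * (logdet_V + logdet_xvx + float(y @ Py))

    def fit(self, grms: GRMPair, y: np.ndarray):
        y = np.asarray(y, dtype=float)
        n = len(y)
        if grms.G_add.shape != (n, n):
            raise ValueError("GRM order does not match the number of phenotypes")
        vary = float(np.var(y))
        floor = self.floor_frac * vary
        K = [grms.G_add, grms.G_dom, np.eye(n)]
        theta = np.array([0.3, 0.1, 0.6]) * vary
        X = np.ones((n, 1))
        trace = []
        step_types = []
        prev_ll = -np.inf
        converged = False
        it = 0
        for it in range(1, self.max_iter + 1):
            V = theta[0] * K[0] + theta[1] * K[1] + theta[2] * K[2]
            cf = self._chol(V)
            logdet_V = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
            Vinv = cho_solve(cf, np.eye(n))
            VinvX = Vinv @ X
            xvx = float((X.T @ VinvX).item())
            P = Vinv - VinvX @ VinvX.T / xvx
            Py = P @ y
            ll = self._loglik(cf, (logdet_V, np.log(xvx)), y, Py)
            trace.append(ll)
            if abs(ll - prev_ll) < self.tol and it > 1:
                converged = True
                break
            KPy = [Kk @ Py for Kk in K]
            score = np.array([
                -0.5 * (float(np.sum(P * Kk)) - float(Py @ KPy_k))
                for Kk, KPy_k in zip(K, KPy)
            ])
            AI = 0.5 * np.array([[float(KPy[i] @ P @ KPy[j]) for j in range(3)]
                                 for i in range(3)])
            use_em = prev_ll > -np.inf and ll < prev_ll - 10 * self.tol
            if not use_em:
                # components pinned at the floor with a negative gradient
                # stay fixed; the rest take a minimum-norm AI step
                fixed = (theta <= floor * 1.001) & (score < 0)
                free = ~fixed
                step = np.zeros(3)
                if free.any():
                    sub = np.ix_(free, free)
                    step[free] = np.linalg.lstsq(AI[sub], score[free], rcond=None)[0]
                proposal = np.maximum(theta + step, floor)
            if use_em:
                # EM-REML update (monotone in the restricted likelihood)
                proposal = np.array([
                    (theta[k] ** 2 * float(Py @ KPy[k])
                     + theta[k] * n - theta[k] ** 2 * float(np.sum(P * K[k]))) / n
                    for k in range(3)
                ])
            step_types.append("em" if use_em else "ai")
            theta = np.maximum(proposal, floor)
            prev_ll = ll
        else:
            raise RuntimeError(
                f"REML did not converge in {self.max_iter} iterations; "
                f"log-likelihood trace: {np.round(trace, 4).tolist()}"
            )
        # final quantities & SEs at the optimum
        self.sigma2_a_, self.sigma2_d_, self.sigma2_e_ = map(float, theta)
        total = float(theta.sum())
        self.h2_ = self.sigma2_a_ / total
        self.delta2_ = self.sigma2_d_ / total
        try:
            C = np.linalg.inv(AI)
        except np.linalg.LinAlgError:
            C = np.linalg.pinv(AI)
        self.ai_cov_ = C
        ga = np.array([total - theta[0], -theta[0], -theta[0]]) / total**2
        gd = np.array([-theta[1], total - theta[1], -theta[1]]) / total**2
        self.se_h2_ = float(np.sqrt(max(ga @ C @ ga, 0.0)))
        self.se_delta2_ = float(np.sqrt(max(gd @ C @ gd, 0.0)))
        self.loglik_ = trace[-1]
        self.loglik_trace_ = np.array(trace)
        self.step_types_ = step_types
        self.n_iter_ = it
        self.converged_ = converged
        return self

    def components_(self) -> VarianceComponents:
        return VarianceComponents(
            sigma2_a=self.sigma2_a_, sigma2_d=self.sigma2_d_, sigma2_e=self.sigma2_e_,
            h2=self.h2_, delta2=self.delta2_, se_h2=self.se_h2_, se_delta2=self.se_delta2_,
            loglik=self.loglik_, n_iter=self.n_iter_, converged=self.converged_,
        )


def reml_ad(y, grms: GRMPair, **kwargs) -> VarianceComponents:
    """Functional wrapper around :class:`AdditiveDominanceREML`."""
    est = AdditiveDominanceREML(**kwargs)
    est.fit(grms, y)
    return est.components_()


# ---------------------------------------------------------------------------
# GRM file formats
# ---------------------------------------------------------------------------

def write_grm_binary(G: np.ndarray, ids, n_snps: int, prefix: str) -> None:
    """GCTA-compatible layout: float32 lower triangle (.grm.bin), per-pair
    SNP counts (.grm.N.bin) and a two-column id list (.grm.id)."""
    n = len(ids)
    tri = G[np.tril_indices(n)].astype("<f4")
    tri.tofile(f"{prefix}.grm.bin")
    np.full(tri.shape, n_snps, dtype="<f4").tofile(f"{prefix}.grm.N.bin")
    with open(f"{prefix}.grm.id", "w") as fh:
        for i in ids:
            fh.write(f"{i}\t{i}\n")


def read_grm_binary(prefix: str) -> tuple[np.ndarray, list, int]:
    """Read a GCTA-layout GRM; returns (matrix, ids, n_snps)."""
    with open(f"{prefix}.grm.id") as fh:
        ids = [line.split()[1] for line in fh if line.strip()]
    n = len(ids)
    tri = np.fromfile(f"{prefix}.grm.bin", dtype="<f4")
    if len(tri) != n * (n + 1) // 2:
        raise ValueError(f"GRM triangle size {len(tri)} inconsistent with {n} ids")
    G = np.zeros((n, n))
    G[np.tril_indices(n)] = tri
    G = G + np.tril(G, -1).T
    counts = np.fromfile(f"{prefix}.grm.N.bin", dtype="<f4")
    n_snps = int(counts[0]) if len(counts) else 0
    return G, ids, n_snps


def write_grm_tsv(G: np.ndarray, ids, path: str) -> None:
    """Dense TSV option: header of animal ids, one row per animal."""
    import pandas as pd

    df = pd.DataFrame(G, columns=list(ids))
    df.insert(0, "animal_id", list(ids))
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_grm_tsv(path: str) -> tuple[np.ndarray, list]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", comment="#")
    ids = df["animal_id"].astype(str).tolist()
    return df.drop(columns="animal_id").to_numpy(dtype=float), ids
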