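"""End-to-end dominance genome scan as a single estimator.

Combines the BayesC0 structure adjustment, 10-Mb LOSO phenotype
construction and per-variant genotype-class association into one
fit call operating on a genotype container plus phenotype table.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .assoc import ClassBins, call_and_classify, scan_variants
from .containers import GenotypeMatrix, PhenotypeTable
from .gibbs import BayesC0Sampler, LosoAdjuster, partition_segments


class DominanceScan(BaseEstimator):
    """Non-additive GWAS scan: adjust, LOSO, per-variant class effects.

    Parameters mirror the pipeline stages: Gibbs settings for the
    structure adjustment, the LOSO segment size, and the calling
    thresholds (FDR on the dominance q-value, minimum effect as a
    fraction of the phenotypic SD, |k| class bins).

    Fitted attributes: ``sampler_`` (the BayesC0 fit), ``adjuster_``
    (LOSO accessor), ``results_`` (per-variant association table with
    q_d, pass flags and dominance class), ``calls_`` (the called rows),
    ``phenotypic_sd_``.
    """

    def __init__(self, n_retained: int = 500, burn_in: int = 1000, thin: int = 10,
                 nu: float = 4.0, var_split: tuple = (0.45, 0.05, 0.5),
                 segment_bp: int = 10_000_000, fdr: float = 1e-3,
                 effect_frac: float = 0.05, bins: ClassBins | None = None,
                 seed: int = 0):
        self.n_retained = n_retained
        self.burn_in = burn_in
        self.thin = thin
        self.nu = nu
        self.var_split = var_split
        self.segment_bp = segment_bp
        self.fdr = fdr
        self.effect_frac = effect_frac
        self.bins = bins
        self.seed = seed

    def fit(self, G: GenotypeMatrix, phenotypes: PhenotypeTable,
            structure_index: np.ndarray | None = None,
            test_index: np.ndarray | None = None):
        if structure_index is None or test_index is None:
            panel = G.variants.get("panel")
            if panel is None:
                raise ValueError("provide structure_index/test_index or a 'panel' column")
            panel = panel.to_numpy()
            structure_index = np.flatnonzero(panel == "structure")
            test_index = np.flatnonzero(panel == "test")
        y = phenotypes.y
        w = phenotypes.w
        G_struct = G.subset_variants(structure_index)
        G_test = G.subset_variants(test_index)

        sampler = BayesC0Sampler(
            n_retained=self.n_retained, burn_in=self.burn_in, thin=self.thin,
            nu=self.nu, var_split=self.var_split, seed=self.seed,
        )
        sampler.fit(G_struct, y, sample_weight=w)

        plan = partition_segments(G.variants, segment_bp=self.segment_bp)
        adjuster = LosoAdjuster.from_sampler(
            y, sampler,
            G_struct.variants["chrom"].to_numpy(), G_struct.variants["pos"].to_numpy(),
            plan,
        )
        rng = np.random.default_rng(self.seed + 7)
        results = scan_variants(adjuster, G_test, w, rng)
        results["variant_index"] = np.asarray(test_index)[results["variant_index"].to_numpy()]
        self.phenotypic_sd_ = float(np.std(y))
        results = call_and_classify(results, self.phenotypic_sd_, fdr=self.fdr,
                                    effect_frac=self.effect_frac, bins=self.bins)
        self.sampler_ = sampler
        self.adjuster_ = adjuster
        self.plan_ = plan
        self.results_ = results
        self.calls_ = results[results["is_call"]].reset_index(drop=True)
        self.G_test_ = G_test
        self.test_index_ = np.asarray(test_index)
        self.w_ = w
        return self
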