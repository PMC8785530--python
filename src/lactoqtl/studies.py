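"""Replication studies: canned simulate-and-measure experiments.

These functions define the package's benchmark conditions — a planted
low-MAF fully recessive QTL recovered by the full pipeline, a QTL-free
null scan, GREML parameter recovery, and the R^2/R^4 LD-decay law — at
problem sizes a single CPU handles in seconds to minutes.  Both the test
suite and the reproduction script run them, so the reported numbers are
always recomputed from scratch.
"""

from __future__ import annotations

import numpy as np

from . import qc
from .assoc import contrasts_from_b, sample_class_effects
from .containers import GenotypeMatrix
from .greml import build_grms, reml_ad
from .scan import DominanceScan
from .simdata import PopulationConfig, QTLSpec, plant_qtl, plant_tag_variant, \
    simulate_haplotype_pools, simulate_study


def recessive_recovery_replicate(
    seed: int,
    n_animals: int = 20_000,
    n_structure_snps: int = 500,
    n_test_variants: int = 2_000,
    maf: float = 0.03,
    deficit_sd: float = 1.0,
    h2: float = 0.25,
    delta2: float = 0.03,
) -> dict:
    """One full-pipeline replicate with a planted fully recessive QTL.

    The minor-allele homozygote deficit is ``deficit_sd`` phenotypic SDs
    (a = -deficit/2, d = +deficit/2, so k_true = 1).  QC cascades run
    before the scan; the causal variant can therefore be lost to the
    rare-homozygote filter, which counts as a miss.  Returns the causal
    variant's k-hat, dominance q-value and whether it was called.
    """
    cfg = PopulationConfig(
        n_animals=n_animals, n_structure_snps=n_structure_snps,
        n_dense_variants=n_test_variants, n_chromosomes=4,
        chrom_length_bp=60_000_000, seed=seed,
    )
    pools = simulate_haplotype_pools(cfg)
    pos = int(pools.variants.query("chrom == 2 and panel == 'test'")["pos"].iloc[100])
    spec = QTLSpec(chrom=2, pos=pos, maf_target=maf,
                   a_true=-deficit_sd / 2.0, d_true=deficit_sd / 2.0)
    study = simulate_study(cfg, [spec], h2=h2, delta2=delta2)
    G = study.genotypes

    strata = np.where(study.breed_fracs[:, 0] >= 1.0, "A",
                      np.where(study.breed_fracs[:, 0] <= 0.0, "B", "X"))
    keep_struct = study.structure_index[
        qc.structure_panel_filter(G.subset_variants(study.structure_index),
                                  strata).retained]
    keep_test = study.test_index[
        qc.sequence_panel_filter(G.subset_variants(study.test_index)).retained]

    scan = DominanceScan(n_retained=500, burn_in=200, thin=1, seed=seed + 1)
    scan.fit(G, study.phenotypes, structure_index=keep_struct, test_index=keep_test)

    ci = int(study.truth["variant_index"].iloc[0])
    row = scan.results_[scan.results_["variant_index"] == ci]
    if row.empty:  # causal variant removed by QC
        return {"khat": np.nan, "q_d": np.nan, "called": False,
                "maf_realized": float(study.truth["maf_realized"].iloc[0]),
                "n": n_animals}
    row = row.iloc[0]
    return {
        "khat": float(row["k"]), "q_d": float(row["q_d"]),
        "d_z": float(row["d_z"]),
        "called": bool(row["is_call"]),
        "maf_realized": float(study.truth["maf_realized"].iloc[0]),
        "n": n_animals,
    }


def null_scan_replicate(
    seed: int,
    n_animals: int = 2_000,
    n_structure_snps: int = 300,
    n_test_variants: int = 2_000,
    fdr: float = 1e-3,
) -> dict:
    """QTL-free pipeline replicate; counts dominance q-values under fdr."""
    cfg = PopulationConfig(
        n_animals=n_animals, n_structure_snps=n_structure_snps,
        n_dense_variants=n_test_variants, n_chromosomes=4,
        chrom_length_bp=60_000_000, seed=seed,
    )
    study = simulate_study(cfg, [], h2=0.25, delta2=0.03)
    scan = DominanceScan(n_retained=500, burn_in=200, thin=1, fdr=fdr, seed=seed + 1)
    scan.fit(study.genotypes, study.phenotypes)
    n_false = int((scan.results_["q_d"] < fdr).sum())
    return {"n_false": n_false, "n_tests": int(len(scan.results_)), "n": n_animals}


def greml_recovery(
    seed: int,
    n_animals: int = 2_000,
    n_snps: int = 5_000,
    h2: float = 0.296,
    delta2: float = 0.044,
) -> dict:
    """GREML additive+dominance recovery at the generating heritabilities.

    Simulates a purebred sample (single pool, one record per animal, as
    in a within-breed heritability analysis) and re-estimates (h2,
    delta2) from GRMs built on the same SNP panel that generated the
    polygenic values.
    """
    cfg = PopulationConfig(
        n_animals=n_animals, n_structure_snps=n_snps, n_dense_variants=10,
        n_chromosomes=5, chrom_length_bp=60_000_000,
        breed_mix=(1.0, 0.0, 0.0), seed=seed,
    )
    study = simulate_study(cfg, [], h2=h2, delta2=delta2, record_counts=1)
    G = study.genotypes.subset_variants(study.structure_index)
    grms = build_grms(G)
    vc = reml_ad(study.phenotypes.y, grms)
    return {
        "h2_hat": vc.h2, "se_h2": vc.se_h2,
        "delta2_hat": vc.delta2, "se_delta2": vc.se_delta2,
        "h2_true": h2, "delta2_true": delta2, "n": n_animals,
    }


def ld_decay_measurements(
    seed: int,
    n_animals: int = 40_000,
    maf: float = 0.3,
    deficit_sd: float = 1.0,
    r2_targets: tuple = (1.0, 0.8, 0.5),
    n_chain: int = 400,
) -> list[dict]:
    """Additive/dominance variance captured at tags of decreasing LD.

    One fully recessive causal variant plus tag variants at target
    allelic R^2; class effects estimated through the association
    machinery on the raw phenotype.  The captured additive variance
    should decay as R^2 and the dominance variance as R^4.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    n_var = 1 + len(r2_targets)
    dosage = np.zeros((n_animals, n_var), dtype=np.int8)
    dosage[:, 0] = rng.binomial(2, maf, size=n_animals)
    variants = pd.DataFrame({
        "chrom": 1, "pos": np.arange(1, n_var + 1) * 1000,
        "ref": "A", "alt": "C", "dr2": 1.0,
    })
    G = GenotypeMatrix(np.array([f"a{i}" for i in range(n_animals)]),
                       variants, dosage)
    for t, r2 in enumerate(r2_targets, start=1):
        plant_tag_variant(G, 0, t, np.sqrt(r2), rng)

    spec = QTLSpec(chrom=1, pos=1000, maf_target=maf,
                   a_true=-deficit_sd / 2.0, d_true=deficit_sd / 2.0)
    g, _ = plant_qtl(G, [spec])
    y = g + rng.standard_normal(n_animals)
    var_e = float(np.var(y - g))
    ytil = y[:, None] * np.ones((1, n_chain))
    w = np.ones(n_animals)
    ve_chain = np.full(n_chain, var_e)

    targets = (1.0,) + tuple(r2_targets)
    out = []
    base = None
    for v in range(n_var):
        x = G.dosage[:, v]
        b = sample_class_effects(ytil, x, w, ve_chain, rng)
        sw = np.array([float((x == c).sum()) for c in (0, 1, 2)])
        cons = contrasts_from_b(b, sw)
        p = x.mean() / 2.0
        pq2 = 2.0 * p * (1.0 - p)
        a_hat = float(np.mean(cons["alpha"]))
        d_hat = float(np.mean(cons["d"]))
        var_add = pq2 * a_hat**2
        var_dom = (pq2 * d_hat) ** 2
        r2_real = qc.pair_r2(G.dosage[:, 0], x)
        rec = {"variant": v, "r2_target": targets[v], "r2_realized": float(r2_real),
               "var_add": var_add, "var_dom": var_dom}
        if v == 0:
            base = rec
        rec["add_ratio"] = var_add / base["var_add"]
        rec["dom_ratio"] = var_dom / base["var_dom"]
        out.append(rec)
    return out
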