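"""Config-driven pipeline: simulate -> qc -> greml -> adjust -> assoc ->
iterate -> report.

Every stage reads its declared inputs from the output directory and
writes TSV artifacts stamped with the config hash and global seed, so a
rerun with an identical config is byte-identical and stages are
resumable from cached artifacts.  Per-stage seeds are derived
deterministically from the global seed and the stage name.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import assoc, gibbs, greml, io, itergwas, qc, simdata
from .containers import GenotypeMatrix, PhenotypeTable
from .scan import DominanceScan

STAGES = ("simulate", "qc", "greml", "adjust", "assoc", "iterate", "report")

DEFAULT_CONFIG: dict = {
    "outdir": "lactoqtl_run",
    "seed": 0,
    "trait": "milk",
    "stages": list(STAGES),
    "genotypes": None,       # external dosage TSV (else simulated)
    "genotype_map": None,
    "phenotypes": None,
    "simulate": {
        "n_animals": 800, "breed_mix": [0.3, 0.2, 0.5],
        "n_structure_snps": 200, "n_dense_variants": 600,
        "n_chromosomes": 2, "chrom_length_bp": 40_000_000,
        "recombination_rate": 1e-8, "n_founders": 60,
        "divergence": 0.1, "ar1_rho": 0.95,
        "h2": 0.25, "delta2": 0.04, "record_count_lambda": 7.0,
        "write_vcf": False,
        "qtl": [],           # list of {chrom,pos,maf,a,d}
    },
    "qc": {
        "max_missing_rate": 0.01, "min_maf": 0.02, "max_hwe_dev": 0.15,
        "min_dr2_structure": 0.9, "prune_r2": 0.9, "prune_window_bp": 1_000_000,
        "max_hom_alt": 5, "min_dr2_sequence": 0.7,
    },
    "greml": {"min_stratum_n": 50},
    "gibbs": {"n_retained": 500, "burn_in": 1000, "thin": 10, "nu": 4.0,
              "var_split": [0.45, 0.05, 0.5]},
    "segment_bp": 10_000_000,
    "calling": {"fdr": 1e-3, "effect_frac": 0.05,
                "bins": [0.1, 0.7, 1.3], "max_rounds": 5},
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(base.get(k), dict):
            out[k] = _merge(base[k], v)
        else:
            out[k] = v
    return out


def load_config(path: str | None = None, overrides: dict | None = None) -> dict:
    cfg = DEFAULT_CONFIG
    if path is not None:
        with open(path) as fh:
            cfg = _merge(cfg, yaml.safe_load(fh) or {})
    if overrides:
        cfg = _merge(cfg, overrides)
    return cfg


def config_hash(cfg: dict) -> str:
    return hashlib.sha1(json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:10]


def stage_seed(cfg: dict, stage: str) -> int:
    return (int(cfg["seed"]) * 1000003 + zlib.crc32(stage.encode())) % (2**31 - 1)


def _stamp(cfg: dict) -> str:
    return f"lactoqtl config={config_hash(cfg)} seed={cfg['seed']}"


def _write_tsv(df: pd.DataFrame, path: Path, cfg: dict) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {_stamp(cfg)}\n")
        df.to_csv(fh, sep="\t", index=False)


def _read_tsv(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def _load_genotypes(cfg: dict, outdir: Path) -> GenotypeMatrix:
    if cfg["genotypes"]:
        return io.read_dosage_tsv(cfg["genotypes"], cfg["genotype_map"])
    return io.read_dosage_tsv(outdir / "genotypes.tsv", outdir / "variants.tsv")


def _load_phenotypes(cfg: dict, outdir: Path) -> PhenotypeTable:
    path = cfg["phenotypes"] or outdir / "phenotypes.tsv"
    return io.read_phenotypes(path)


def _breed_strata(phen: PhenotypeTable) -> np.ndarray:
    frac = phen.table["breed_frac_a"].to_numpy(dtype=float)
    strata = np.full(len(frac), "X", dtype=object)
    strata[frac >= 1.0] = "A"
    strata[frac <= 0.0] = "B"
    return strata


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_simulate(cfg: dict, outdir: Path) -> None:
    s = cfg["simulate"]
    pc = simdata.PopulationConfig(
        n_animals=s["n_animals"], breed_mix=tuple(s["breed_mix"]),
        n_structure_snps=s["n_structure_snps"], n_dense_variants=s["n_dense_variants"],
        n_chromosomes=s["n_chromosomes"], chrom_length_bp=s["chrom_length_bp"],
        recombination_rate=s["recombination_rate"], n_founders=s["n_founders"],
        divergence=s["divergence"], ar1_rho=s["ar1_rho"],
        seed=stage_seed(cfg, "simulate"),
    )
    specs = [
        simdata.QTLSpec(chrom=q["chrom"], pos=q["pos"], maf_target=q["maf"],
                        a_true=q["a"], d_true=q["d"],
                        breed_restricted=q.get("breed"))
        for q in s["qtl"]
    ]
    study = simdata.simulate_study(
        pc, specs, h2=s["h2"], delta2=s["delta2"],
        record_counts=("poisson", s["record_count_lambda"]), trait=cfg["trait"],
    )
    io.write_dosage_tsv(study.genotypes, outdir / "genotypes.tsv",
                        outdir / "variants.tsv", header_comment=_stamp(cfg))
    io.write_phenotypes(study.phenotypes, outdir / "phenotypes.tsv",
                        header_comment=_stamp(cfg))
    _write_tsv(study.truth, outdir / "truth.tsv", cfg)
    if s["write_vcf"]:
        io.write_vcf(study.genotypes, outdir / "genotypes.vcf")


def stage_qc(cfg: dict, outdir: Path) -> None:
    G = _load_genotypes(cfg, outdir)
    phen = _load_phenotypes(cfg, outdir)
    strata = _breed_strata(phen)
    q = cfg["qc"]
    panel = G.variants["panel"].to_numpy() if "panel" in G.variants else \
        np.full(G.n_variants, "test", dtype=object)
    struct_idx = np.flatnonzero(panel == "structure")
    test_idx = np.flatnonzero(panel == "test")
    thresholds = qc.FilterThresholds(
        max_missing_rate=q["max_missing_rate"], min_maf=q["min_maf"],
        max_hwe_dev=q["max_hwe_dev"], min_dr2=q["min_dr2_structure"],
        prune_r2=q["prune_r2"], prune_window_bp=q["prune_window_bp"],
    )
    res_s = qc.structure_panel_filter(G.subset_variants(struct_idx), strata, thresholds)
    res_t = qc.sequence_panel_filter(G.subset_variants(test_idx),
                                     max_hom_alt=q["max_hom_alt"],
                                     min_dr2=q["min_dr2_sequence"])
    rep_s = res_s.report.assign(variant_index=struct_idx)
    rep_t = res_t.report.assign(variant_index=test_idx)
    _write_tsv(rep_s, outdir / "qc_structure_report.tsv", cfg)
    _write_tsv(rep_t, outdir / "qc_sequence_report.tsv", cfg)
    _write_tsv(pd.DataFrame({"variant_index": struct_idx[res_s.retained]}),
               outdir / "structure_panel.tsv", cfg)
    _write_tsv(pd.DataFrame({"variant_index": test_idx[res_t.retained]}),
               outdir / "test_panel.tsv", cfg)


def stage_greml(cfg: dict, outdir: Path) -> None:
    G = _load_genotypes(cfg, outdir)
    phen = _load_phenotypes(cfg, outdir)
    struct = _read_tsv(outdir / "structure_panel.tsv")["variant_index"].to_numpy()
    strata = _breed_strata(phen)
    rows = []
    for label in ("A", "B"):
        keep = np.flatnonzero(strata == label)
        if len(keep) < cfg["greml"]["min_stratum_n"]:
            continue
        sub = G.subset_animals(keep).subset_variants(struct)
        grms = greml.build_grms(sub)
        try:
            vc = greml.reml_ad(phen.y[keep], grms)
        except (RuntimeError, np.linalg.LinAlgError) as exc:
            rows.append({"stratum": label, "trait": cfg["trait"], "error": str(exc)})
            continue
        rows.append({
            "stratum": label, "trait": cfg["trait"], "n": len(keep),
            "h2": vc.h2, "se_h2": vc.se_h2, "delta2": vc.delta2,
            "se_delta2": vc.se_delta2, "sigma2_a": vc.sigma2_a,
            "sigma2_d": vc.sigma2_d, "sigma2_e": vc.sigma2_e,
            "converged": vc.converged,
        })
    _write_tsv(pd.DataFrame(rows), outdir / "varcomp.tsv", cfg)


def stage_adjust(cfg: dict, outdir: Path) -> None:
    G = _load_genotypes(cfg, outdir)
    phen = _load_phenotypes(cfg, outdir)
    struct = _read_tsv(outdir / "structure_panel.tsv")["variant_index"].to_numpy()
    g = cfg["gibbs"]
    sampler = gibbs.BayesC0Sampler(
        n_retained=g["n_retained"], burn_in=g["burn_in"], thin=g["thin"],
        nu=g["nu"], var_split=tuple(g["var_split"]), seed=stage_seed(cfg, "adjust"),
    )
    sampler.fit(G.subset_variants(struct), phen.y, sample_weight=phen.w)
    s = sampler.samples_
    np.savez_compressed(
        outdir / "posterior.npz",
        mu=s.mu, alpha=s.alpha, delta=s.delta, var_alpha=s.var_alpha,
        var_delta=s.var_delta, var_e=s.var_e,
        col_means_alpha=sampler.col_means_alpha_,
        col_means_delta=sampler.col_means_delta_,
        structure_index=struct,
    )
    gz = pd.DataFrame(
        [{"chain": k, "geweke_z": z, "degenerate": flag}
         for k, (z, flag) in sampler.geweke_.items()]
    )
    _write_tsv(gz, outdir / "adjust_log.tsv", cfg)


def _rebuild_adjuster(cfg: dict, outdir: Path, G: GenotypeMatrix,
                      phen: PhenotypeTable) -> gibbs.LosoAdjuster:
    z = np.load(outdir / "posterior.npz")
    struct = z["structure_index"]
    samples = gibbs.PosteriorSampleSet(
        z["mu"], z["alpha"], z["delta"], z["var_alpha"], z["var_delta"], z["var_e"],
    )
    X = G.subset_variants(struct).mean_imputed()
    Ma = X - z["col_means_alpha"][None, :]
    Md = (X == 1.0).astype(float) - z["col_means_delta"][None, :]
    plan = gibbs.partition_segments(G.variants, segment_bp=cfg["segment_bp"])
    vm = G.variants.iloc[struct]
    return gibbs.LosoAdjuster(phen.y, samples, Ma, Md,
                              vm["chrom"].to_numpy(), vm["pos"].to_numpy(), plan)


def stage_assoc(cfg: dict, outdir: Path) -> None:
    G = _load_genotypes(cfg, outdir)
    phen = _load_phenotypes(cfg, outdir)
    test_idx = _read_tsv(outdir / "test_panel.tsv")["variant_index"].to_numpy()
    adjuster = _rebuild_adjuster(cfg, outdir, G, phen)
    rng = np.random.default_rng(stage_seed(cfg, "assoc"))
    res = assoc.scan_variants(adjuster, G.subset_variants(test_idx), phen.w, rng)
    res["variant_index"] = test_idx[res["variant_index"].to_numpy()]
    c = cfg["calling"]
    bins = assoc.ClassBins(*c["bins"])
    res = assoc.call_and_classify(res, float(np.std(phen.y)), fdr=c["fdr"],
                                  effect_frac=c["effect_frac"], bins=bins)
    res.insert(0, "trait", cfg["trait"])
    _write_tsv(res, outdir / "assoc.tsv", cfg)


def stage_iterate(cfg: dict, outdir: Path) -> None:
    G = _load_genotypes(cfg, outdir)
    phen = _load_phenotypes(cfg, outdir)
    test_idx = _read_tsv(outdir / "test_panel.tsv")["variant_index"].to_numpy()
    res = _read_tsv(outdir / "assoc.tsv")
    adjuster = _rebuild_adjuster(cfg, outdir, G, phen)
    G_test = G.subset_variants(test_idx)
    c = cfg["calling"]
    bins = assoc.ClassBins(*c["bins"])
    sd = float(np.std(phen.y))
    rng = np.random.default_rng(stage_seed(cfg, "iterate"))
    chroms_with_calls = sorted(set(res.loc[res["is_call"], "chrom"]))
    all_calls, all_logs = [], []
    for chrom in chroms_with_calls:
        calls, log = itergwas.iterate_chromosome(
            adjuster, G_test, chrom, phen.w, sd, rng, fdr=c["fdr"],
            effect_frac=c["effect_frac"], bins=bins, max_rounds=c["max_rounds"],
        )
        if not calls.empty:
            # map back to the full variant index space
            calls["variant_index"] = test_idx[calls["variant_index"].astype(int)]
            all_calls.append(calls)
        log.insert(0, "chrom", chrom)
        all_logs.append(log)
    calls_df = pd.concat(all_calls, ignore_index=True) if all_calls else pd.DataFrame()
    if not calls_df.empty:
        calls_df.insert(0, "trait", cfg["trait"])
    logs_df = pd.concat(all_logs, ignore_index=True) if all_logs else pd.DataFrame()
    tags, tag_log = itergwas.stepwise_additive_tags(adjuster, G_test, phen.w, fdr=c["fdr"])
    _write_tsv(calls_df, outdir / "qtl_calls.tsv", cfg)
    _write_tsv(logs_df, outdir / "iteration_log.tsv", cfg)
    _write_tsv(pd.DataFrame({"variant_index": test_idx[np.asarray(tags, dtype=int)]
                             if tags else []}),
               outdir / "additive_tags.tsv", cfg)


def stage_report(cfg: dict, outdir: Path) -> None:
    res = _read_tsv(outdir / "assoc.tsv")
    with np.errstate(divide="ignore"):
        manhattan = pd.DataFrame({
            "chrom": res["chrom"], "pos": res["pos"],
            "neglog10_p_additive": -np.log10(res["alpha_p"]),
            "neglog10_p_dominance": -np.log10(res["d_p"]),
        })
    calls_path = outdir / "qtl_calls.tsv"
    calls = _read_tsv(calls_path) if calls_path.exists() else pd.DataFrame()
    if not calls.empty:
        maf_effect = calls[["trait", "chrom", "pos", "maf", "a_mean", "d_mean",
                            "k", "dominance_class", "iteration"]].copy()
        maf_effect["abs_d"] = maf_effect["d_mean"].abs()
        maf_effect["homozygote_effect"] = 2.0 * maf_effect["a_mean"].abs()
        arch = (calls.groupby("dominance_class")
                .agg(n=("k", "size"), mean_abs_d=("d_mean", lambda v: float(np.mean(np.abs(v)))),
                     mean_maf=("maf", "mean")).reset_index())
    else:
        maf_effect = pd.DataFrame(columns=["trait", "chrom", "pos", "maf", "a_mean",
                                           "d_mean", "k", "dominance_class",
                                           "iteration", "abs_d", "homozygote_effect"])
        arch = pd.DataFrame(columns=["dominance_class", "n", "mean_abs_d", "mean_maf"])
    _write_tsv(manhattan, outdir / "manhattan.tsv", cfg)
    _write_tsv(maf_effect, outdir / "maf_vs_effect.tsv", cfg)
    _write_tsv(arch, outdir / "architecture.tsv", cfg)


_STAGE_FUNCS = {
    "simulate": stage_simulate, "qc": stage_qc, "greml": stage_greml,
    "adjust": stage_adjust, "assoc": stage_assoc, "iterate": stage_iterate,
    "report": stage_report,
}

_STAGE_OUTPUTS = {
    "simulate": ["genotypes.tsv", "variants.tsv", "phenotypes.tsv", "truth.tsv"],
    "qc": ["structure_panel.tsv", "test_panel.tsv"],
    "greml": ["varcomp.tsv"],
    "adjust": ["posterior.npz", "adjust_log.tsv"],
    "assoc": ["assoc.tsv"],
    "iterate": ["qtl_calls.tsv", "iteration_log.tsv", "additive_tags.tsv"],
    "report": ["manhattan.tsv", "maf_vs_effect.tsv", "architecture.tsv"],
}


def run_stage(cfg: dict, stage: str, force: bool = True) -> None:
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    if not force and all((outdir / f).exists() for f in _STAGE_OUTPUTS[stage]):
        return
    try:
        _STAGE_FUNCS[stage](cfg, outdir)
    except Exception as exc:
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc


def run_pipeline(cfg: dict, stages: list[str] | None = None, force: bool = True) -> Path:
    """Execute the requested stages in dependency order; returns outdir."""
    stages = stages if stages is not None else cfg["stages"]
    for stage in STAGES:
        if stage in stages:
            run_stage(cfg, stage, force=force)
    return Path(cfg["outdir"])
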