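"""Synthetic mixed-breed genotype and lactation-phenotype generator.

Emulates the statistical structure of a two-breed dairy population
(pool A ~ Holstein-Friesian, pool B ~ Jersey, plus crossbreds): a sparse
"structure" SNP panel with local linkage disequilibrium, a dense panel of
test variants, planted QTL with genotypic additive (a) and dominance (d)
effects, and phenotypes expressed as yield deviations that are weighted
means of repeated test-day records.

LD is produced by copy-with-crossover from a small founder set whose
haplotypes follow a latent Gaussian AR(1) along each chromosome, so the
median adjacent-variant R^2 is tunable via the AR(1) correlation.  Breed
effects enter only through allele-frequency divergence between pools and
through polygenic values; the phenotypes emitted are already adjusted for
non-genetic effects, mirroring yield deviations from a national
evaluation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import norm

from .containers import GenotypeMatrix, PhenotypeTable


@dataclass
class PopulationConfig:
    """Parameters of the simulated population.

    breed_mix is (pure-A, pure-B, crossbred) proportions.  divergence is
    the target mean absolute allele-frequency difference between the two
    breed pools.  ar1_rho controls founder-haplotype LD between adjacent
    variants (0 = linkage equilibrium, ->1 = long haplotype blocks).
    """

    n_animals: int = 2000
    breed_mix: tuple[float, float, float] = (0.3, 0.2, 0.5)
    n_structure_snps: int = 500
    n_dense_variants: int = 2000
    n_chromosomes: int = 2
    chrom_length_bp: int = 50_000_000
    recombination_rate: float = 1e-8
    n_founders: int = 60
    divergence: float = 0.1
    ar1_rho: float = 0.95
    freq_range: tuple[float, float] = (0.05, 0.95)
    frac_dr2_below_07: float = 0.03
    frac_dr2_07_09: float = 0.07
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.breed_mix) - 1.0) > 1e-12:
            raise ValueError("breed_mix proportions must sum to 1")
        for name in ("n_animals", "n_structure_snps", "n_dense_variants",
                     "n_chromosomes", "chrom_length_bp", "n_founders"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    @property
    def n_variants(self) -> int:
        return self.n_structure_snps + self.n_dense_variants


@dataclass
class QTLSpec:
    """A planted biallelic QTL.

    a_true is the genotypic additive effect (half the homozygote
    difference, trait units), d_true the heterozygote deviation from the
    homozygote midpoint.  Genotype-class values are (-a, d, +a) about the
    class midpoint, so a fully recessive deleterious minor allele has
    a < 0 and d = -a (k = d/|a| = 1).
    """

    chrom: int
    pos: int
    maf_target: float
    a_true: float
    d_true: float
    breed_restricted: str | None = None  # "A" or "B"

    def __post_init__(self):
        if not (0.0 < self.maf_target <= 0.5):
            raise ValueError("maf_target must be in (0, 0.5]")

    @property
    def k_true(self) -> float:
        return self.d_true / abs(self.a_true) if self.a_true != 0 else np.nan


@dataclass
class HaplotypePools:
    """Founder haplotype panels for the two breed pools."""

    founders_a: np.ndarray  # (n_founders, n_variants) int8
    founders_b: np.ndarray
    freq_a: np.ndarray  # per-variant target alt frequency, pool A
    freq_b: np.ndarray
    variants: pd.DataFrame  # chrom, pos, ref, alt, panel
    config: PopulationConfig


def _variant_map(config: PopulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Random sorted variant positions with a structure/test panel label."""
    n = config.n_variants
    per_chrom = np.full(config.n_chromosomes, n // config.n_chromosomes)
    per_chrom[: n % config.n_chromosomes] += 1
    if np.any(per_chrom > config.chrom_length_bp // 2):
        raise ValueError("more variants requested than positions available on the map")
    rows = []
    for c, m in enumerate(per_chrom, start=1):
        pos = np.sort(rng.choice(np.arange(1, config.chrom_length_bp + 1), size=m, replace=False))
        rows.append(pd.DataFrame({"chrom": c, "pos": pos}))
    vm = pd.concat(rows, ignore_index=True)
    # spread structure SNPs evenly across the genome
    idx = np.linspace(0, n - 1, config.n_structure_snps).round().astype(int)
    panel = np.full(n, "test", dtype=object)
    panel[idx] = "structure"
    alleles = np.array(["A", "C", "G", "T"])
    ref = rng.choice(alleles, size=n)
    alt = np.array([rng.choice(alleles[alleles != r]) for r in ref])
    vm["ref"] = ref
    vm["alt"] = alt
    vm["panel"] = panel
    return vm


def _ar1_haplotypes(freq: np.ndarray, chrom: np.ndarray, n_hap: int,
                    rho: float, rng: np.random.Generator) -> np.ndarray:
    """Binary haplotypes from a latent Gaussian AR(1), marginal Bern(freq)."""
    n_var = len(freq)
    z = np.empty((n_hap, n_var))
    start = 0
    for c in pd.unique(chrom):
        m = int(np.sum(chrom == c))
        zc = np.empty((n_hap, m))
        zc[:, 0] = rng.standard_normal(n_hap)
        innov = rng.standard_normal((n_hap, m))
        s = np.sqrt(1.0 - rho**2)
        for j in range(1, m):
            zc[:, j] = rho * zc[:, j - 1] + s * innov[:, j]
        z[:, start:start + m] = zc
        start += m
    thresh = norm.ppf(freq)
    return (z < thresh[None, :]).astype(np.int8)


def simulate_haplotype_pools(config: PopulationConfig,
                             rng: np.random.Generator | None = None) -> HaplotypePools:
    """Generate two founder haplotype pools with divergent allele frequencies.

    Pool frequencies are f +/- delta/2 where delta ~ N(0, divergence *
    sqrt(pi/2)), so the mean absolute pool difference targets
    ``config.divergence`` (before clipping at the frequency range).
    Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    vm = _variant_map(config, rng)
    lo, hi = config.freq_range
    f = rng.uniform(lo, hi, size=config.n_variants)
    sd = config.divergence * np.sqrt(np.pi / 2.0)
    delta = rng.normal(0.0, sd, size=config.n_variants) if sd > 0 else np.zeros(config.n_variants)
    freq_a = np.clip(f + delta / 2.0, 0.02, 0.98)
    freq_b = np.clip(f - delta / 2.0, 0.02, 0.98)
    chrom = vm["chrom"].to_numpy()
    founders_a = _ar1_haplotypes(freq_a, chrom, config.n_founders, config.ar1_rho, rng)
    founders_b = _ar1_haplotypes(freq_b, chrom, config.n_founders, config.ar1_rho, rng)
    return HaplotypePools(founders_a, founders_b, freq_a, freq_b, vm, config)


def _gamete(founders: np.ndarray, chrom_slices: list[tuple[int, int, np.ndarray]],
            rec_rate: float, rng: np.random.Generator) -> np.ndarray:
    """One gamete: a founder mosaic with Poisson crossovers per chromosome."""
    n_f, n_var = founders.shape
    hap = np.empty(n_var, dtype=np.int8)
    for start, stop, pos in chrom_slices:
        length = pos[-1] - pos[0] if len(pos) > 1 else 1
        n_x = rng.poisson(rec_rate * length)
        if n_x == 0:
            hap[start:stop] = founders[rng.integers(n_f), start:stop]
            continue
        breaks = np.sort(rng.integers(pos[0], pos[-1] + 1, size=n_x))
        bounds = np.searchsorted(pos, np.concatenate([breaks, [pos[-1] + 1]]))
        prev = 0
        for b in bounds:
            hap[start + prev:start + b] = founders[rng.integers(n_f), start + prev:start + b]
            prev = b
    return hap


def simulate_crossbred_genotypes(
    pools: HaplotypePools,
    config: PopulationConfig | None = None,
    rng: np.random.Generator | None = None,
    qtl_specs: list[QTLSpec] | None = None,
) -> tuple[GenotypeMatrix, np.ndarray]:
    """Draw animals as pairs of founder-mosaic gametes.

    Pure-A and pure-B animals draw both gametes from their pool; a
    crossbred animal gets an A-fraction beta drawn from {0.25, 0.5, 0.75}
    and each gamete independently comes from pool A with probability beta.
    Planted QTL positions (which must exist in the map) bypass the founder
    mosaic: each gamete carries the alternate allele as an independent
    Bernoulli(maf_target) draw, optionally restricted to gametes of one
    pool.  Returns the genotype matrix plus (n, 2) breed fractions.
    """
    config = pools.config if config is None else config
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    vm = pools.variants.copy()
    n = config.n_animals

    breed_class = rng.choice(3, size=n, p=np.asarray(config.breed_mix))
    beta = np.where(breed_class == 0, 1.0, 0.0)
    cross = breed_class == 2
    beta[cross] = rng.choice([0.25, 0.5, 0.75], size=int(cross.sum()))

    chrom = vm["chrom"].to_numpy()
    pos_all = vm["pos"].to_numpy()
    chrom_slices = []
    for c in pd.unique(chrom):
        idx = np.flatnonzero(chrom == c)
        chrom_slices.append((idx[0], idx[-1] + 1, pos_all[idx]))

    dosage = np.empty((n, config.n_variants), dtype=np.int8)
    gamete_pool = np.empty((n, 2), dtype=np.int8)  # 0 = pool A, 1 = pool B
    for i in range(n):
        g = np.zeros(config.n_variants, dtype=np.int8)
        for side in range(2):
            from_a = rng.random() < beta[i]
            gamete_pool[i, side] = 0 if from_a else 1
            founders = pools.founders_a if from_a else pools.founders_b
            g += _gamete(founders, chrom_slices, config.recombination_rate, rng)
        dosage[i] = g

    # plant QTL alleles
    if qtl_specs:
        mix = np.asarray(config.breed_mix)
        for spec in qtl_specs:
            hits = np.flatnonzero((chrom == spec.chrom) & (pos_all == spec.pos))
            if len(hits) == 0:
                raise ValueError(f"QTL position {spec.chrom}:{spec.pos} not in the variant map")
            j = hits[0]
            if spec.breed_restricted is None:
                alleles = rng.random((n, 2)) < spec.maf_target
            else:
                pool_code = 0 if spec.breed_restricted.upper() == "A" else 1
                # scale the within-pool frequency so the overall MAF hits target
                share = float(np.mean(gamete_pool == pool_code))
                q_pool = min(spec.maf_target / max(share, 1e-9), 0.5)
                alleles = (rng.random((n, 2)) < q_pool) & (gamete_pool == pool_code)
            dosage[:, j] = alleles.sum(axis=1).astype(np.int8)

    # simulated imputation quality, independent of genotype by design:
    # only the filter behaviour is exercised downstream, not imputation
    u = rng.random(config.n_variants)
    dr2 = rng.uniform(0.9, 1.0, size=config.n_variants)
    low = u < config.frac_dr2_below_07
    mid = (~low) & (u < config.frac_dr2_below_07 + config.frac_dr2_07_09)
    dr2[low] = rng.uniform(0.3, 0.7, size=int(low.sum()))
    dr2[mid] = rng.uniform(0.7, 0.9, size=int(mid.sum()))
    vm["dr2"] = dr2

    animals = np.array([f"an{i:06d}" for i in range(n)])
    G = GenotypeMatrix(animals=animals, variants=vm, dosage=dosage)
    breed_fracs = np.column_stack([beta, 1.0 - beta])
    return G, breed_fracs


def plant_qtl(G: GenotypeMatrix, specs: list[QTLSpec]) -> tuple[np.ndarray, pd.DataFrame]:
    """Genetic values from planted QTL plus a truth table.

    g_i = sum over loci of a*(x-1) + d*1{x=1}, i.e. genotype-class values
    (-a, d, +a) about the homozygote midpoint.  A spec at a monomorphic
    simulated variant warns and contributes nothing.
    """
    chrom = G.variants["chrom"].to_numpy()
    pos = G.variants["pos"].to_numpy()
    g = np.zeros(G.n_animals)
    rows = []
    for spec in specs:
        hits = np.flatnonzero((chrom == spec.chrom) & (pos == spec.pos))
        if len(hits) == 0:
            raise ValueError(f"QTL position {spec.chrom}:{spec.pos} not in the variant map")
        j = hits[0]
        x = G.dosage[:, j].astype(float)
        counts = np.array([(x == c).sum() for c in (0, 1, 2)])
        maf = G.maf()[j]
        if counts.max() == G.n_animals:
            warnings.warn(
                f"planted QTL at {spec.chrom}:{spec.pos} is monomorphic; contributes 0",
                stacklevel=2,
            )
            contrib = np.zeros_like(x)
        else:
            contrib = spec.a_true * (x - 1.0) + spec.d_true * (x == 1.0)
        g += contrib
        class_means = [float(contrib[x == c].mean()) if counts[c] else np.nan for c in (0, 1, 2)]
        rows.append({
            "chrom": spec.chrom, "pos": spec.pos, "variant_index": j,
            "a_true": spec.a_true, "d_true": spec.d_true, "k_true": spec.k_true,
            "maf_target": spec.maf_target, "maf_realized": maf,
            "n_hom_ref": counts[0], "n_het": counts[1], "n_hom_alt": counts[2],
            "mean_hom_ref": class_means[0], "mean_het": class_means[1],
            "mean_hom_alt": class_means[2],
        })
    return g, pd.DataFrame(rows)


def class_effects_from_means(mu0: float, mu1: float, mu2: float) -> tuple[float, float]:
    """(a, d) from genotype-class means: a=(mu2-mu0)/2, d=mu1-(mu0+mu2)/2."""
    a = (mu2 - mu0) / 2.0
    d = mu1 - (mu0 + mu2) / 2.0
    return a, d


def draw_record_counts(n: int, rng: np.random.Generator,
                       distribution: tuple | int = ("poisson", 7.0)) -> np.ndarray:
    """Test-day record counts per animal; shifted Poisson (minimum 1)."""
    if isinstance(distribution, (int, np.integer)):
        w = np.full(n, int(distribution))
    else:
        kind, lam = distribution
        if kind != "poisson":
            raise ValueError(f"unknown record-count distribution {kind!r}")
        w = 1 + rng.poisson(lam, size=n)
    if np.any(w < 1):
        raise ValueError("record counts must be >= 1")
    return w.astype(int)


def _scaled_component(codes: np.ndarray, target_var: float,
                      rng: np.random.Generator) -> np.ndarray:
    """Random linear combination of columns rescaled to an exact sample variance."""
    if target_var <= 0:
        return np.zeros(codes.shape[0])
    beta = rng.standard_normal(codes.shape[1])
    u = codes @ beta
    sd = u.std()
    if sd == 0:
        return np.zeros(codes.shape[0])
    return u * (np.sqrt(target_var) / sd)


def simulate_yield_deviations(
    genetic_values: np.ndarray,
    structure_dosage: np.ndarray,
    var_poly_add: float,
    var_poly_dom: float,
    var_e: float,
    record_counts: np.ndarray | tuple | int,
    rng: np.random.Generator,
    breed_frac_a: np.ndarray | None = None,
    trait: str = "milk",
) -> tuple[PhenotypeTable, dict]:
    """Yield deviations y = g + u_add + u_dom + mean of w test-day residuals.

    Polygenic components are built from the structure SNPs (additive from
    centred dosages, dominance from orthogonally coded heterozygosity) and
    rescaled to exact sample variances, so the generator's heritability
    decomposition is internally consistent.  var_e is the residual
    variance of a single test-day record; the aggregated residual has
    variance var_e / w_i.
    """
    if min(var_poly_add, var_poly_dom, var_e) < 0:
        raise ValueError("variances must be >= 0")
    g = np.asarray(genetic_values, dtype=float)
    n = len(g)
    X = np.asarray(structure_dosage, dtype=float)
    p = X.mean(axis=0) / 2.0
    poly = (0 < p) & (p < 1)
    Xc = X[:, poly] - 2.0 * p[None, poly]
    pq = p[poly] * (1.0 - p[poly])
    het = (X[:, poly] == 1).astype(float)
    # orthogonal dominance codes (-2p^2, 2pq, -2q^2)
    Dc = np.where(het == 1, 2.0 * pq, np.where(X[:, poly] < 1, -2.0 * p[poly] ** 2,
                                               -2.0 * (1.0 - p[poly]) ** 2))
    u_add = _scaled_component(Xc, var_poly_add, rng)
    u_dom = _scaled_component(Dc, var_poly_dom, rng)

    if isinstance(record_counts, np.ndarray):
        w = record_counts.astype(int)
        if np.any(w < 1):
            raise ValueError("record counts must be >= 1")
    else:
        w = draw_record_counts(n, rng, record_counts)
    ebar = rng.standard_normal(n) * np.sqrt(var_e / w) if var_e > 0 else np.zeros(n)
    y = g + u_add + u_dom + ebar
    table = pd.DataFrame({
        "animal_id": [f"an{i:06d}" for i in range(n)],
        "trait": trait,
        "y": y,
        "w": w,
        "breed_frac_a": breed_frac_a if breed_frac_a is not None else np.nan,
    })
    components = {"g": g, "u_add": u_add, "u_dom": u_dom, "ebar": ebar}
    return PhenotypeTable(table), components


@dataclass
class SimulatedStudy:
    """Bundle of all artifacts for one simulated trait."""

    genotypes: GenotypeMatrix
    phenotypes: PhenotypeTable
    breed_fracs: np.ndarray
    truth: pd.DataFrame
    components: dict
    config: PopulationConfig
    qtl_specs: list[QTLSpec] = field(default_factory=list)

    @property
    def structure_index(self) -> np.ndarray:
        return np.flatnonzero(self.genotypes.variants["panel"].to_numpy() == "structure")

    @property
    def test_index(self) -> np.ndarray:
        return np.flatnonzero(self.genotypes.variants["panel"].to_numpy() == "test")


def simulate_study(
    config: PopulationConfig,
    qtl_specs: list[QTLSpec] | None = None,
    h2: float = 0.25,
    delta2: float = 0.04,
    sigma2_p: float = 1.0,
    record_counts: tuple | int = ("poisson", 7.0),
    trait: str = "milk",
) -> SimulatedStudy:
    """One-call generator used by the pipeline and the test suite.

    h2 / delta2 are the target polygenic additive and dominance fractions
    of the phenotypic variance sigma2_p; planted QTL effects are in trait
    units on that same scale.  Residual variance takes up the remainder
    after the realized planted-QTL variance (floored at 20% of sigma2_p).
    """
    qtl_specs = qtl_specs or []
    rng = np.random.default_rng(config.seed)
    pools = simulate_haplotype_pools(config, rng)
    G, breed_fracs = simulate_crossbred_genotypes(pools, config, rng, qtl_specs)
    g, truth = plant_qtl(G, qtl_specs)
    var_qtl = float(np.var(g))
    resid_target = max(0.2 * sigma2_p, sigma2_p * (1.0 - h2 - delta2) - var_qtl)
    struct_idx = np.flatnonzero(G.variants["panel"].to_numpy() == "structure")
    # convert the y-level residual target to a single-record variance
    if isinstance(record_counts, np.ndarray):
        w = record_counts
    else:
        w = draw_record_counts(config.n_animals, rng, record_counts)
    var_e_single = resid_target / float(np.mean(1.0 / w))
    phen, comps = simulate_yield_deviations(
        g, G.dosage[:, struct_idx], h2 * sigma2_p, delta2 * sigma2_p,
        var_e_single, w, rng, breed_frac_a=breed_fracs[:, 0], trait=trait,
    )
    return SimulatedStudy(G, phen, breed_fracs, truth, comps, config, qtl_specs)


def plant_tag_variant(G: GenotypeMatrix, causal_index: int, tag_index: int,
                      r_target: float, rng: np.random.Generator) -> None:
    """Overwrite a variant so its alleles tag the causal variant at R ~ r_target.

    Each tag gamete copies the causal gamete's allele with probability
    r_target, else draws an independent Bernoulli at the causal allele
    frequency, giving allelic correlation ~ r_target (R^2 ~ r_target^2).
    Used to exercise the R^2 / R^4 LD-decay law.  In-place.
    """
    x = G.dosage[:, causal_index]
    q = x.mean() / 2.0
    # split dosage into pseudo-gametes (het phase is arbitrary)
    g1 = (x >= 1).astype(np.int8)
    g2 = (x == 2).astype(np.int8)
    tag = np.empty_like(G.dosage[:, tag_index])
    copy1 = rng.random(len(x)) < r_target
    copy2 = rng.random(len(x)) < r_target
    t1 = np.where(copy1, g1, (rng.random(len(x)) < q).astype(np.int8))
    t2 = np.where(copy2, g2, (rng.random(len(x)) < q).astype(np.int8))
    tag[:] = t1 + t2
    G.dosage[:, tag_index] = tag
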