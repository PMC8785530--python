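# lactoqtl

Non-additive (dominance/recessive) QTL mapping for quantitative
lactation traits in mixed-breed dairy cattle.

Deleterious recessive alleles segregate at surprising frequencies in
cattle, and routinely recorded milk traits can act as proxies for
underlying genetic disorders: a cow homozygous for a damaging allele
produces measurably less milk, fat or protein, while heterozygous
carriers look normal.  Standard additive GWAS largely misses such loci —
the variance an observed tag variant captures decays as R² for additive
effects but as R⁴ for dominance effects, and rare-allele homozygotes are
scarce (at 1% MAF, 10,000 animals are expected to contain a single one).
`lactoqtl` implements a genome scan built for exactly this regime, for
quantitative geneticists and animal-breeding researchers who want to run
or study it on their own or simulated data.

## The method

For each dense test variant the scan targets the model

    y = 1μ + T b + M_α α + M_δ δ + e,     e ~ N(0, diag(σ²ₑ / wᵢ)),

with genotype-class effects **b** for the variant of interest, and
genome-wide random additive (α, dosage codes 0/1/2) and dominance
(δ, codes 0/1/0) SNP effects adjusting for population structure; the
weight wᵢ is the number of test-day records behind animal *i*'s yield
deviation.  In practice this is run in two steps: (1) 500 posterior
samples of all SNP effects by BayesC0 single-site Gibbs sampling, and
(2) for each 10-Mb leave-one-segment-out (LOSO) interval, phenotypes
adjusted by every sampled effect *outside* the interval, with
genotype-class effects then sampled per variant and per posterior draw.
Chains are summarised as the genotypic additive effect a = (b₂−b₀)/2,
the dominance effect d = b₁ − (b₀+b₂)/2, and the standard-additive
dosage slope, each with a Z-test; Storey q-values on the dominance p
control the FDR.  The dominance coefficient **k = d/|a|** classifies
each locus (k≈0 additive, k≈1 fully recessive, 0.7 < k < 1.3 the
recessive window, k > 1.3 over-dominant).  The package also provides
additive+dominance GREML (h², δ² with SEs), the two QC filter cascades,
iterative conditional scanning to split co-locating QTL, stepwise
additive tag selection, and a synthetic mixed-breed data generator —
everything needed to exercise the scan without access to real herd data.

## Worked example

Simulate a mixed Holstein-Friesian × Jersey-style population with one
planted fully recessive QTL (MAF 0.08, one-SD homozygote deficit) and
scan it:

```python
import lactoqtl as lq

cfg = lq.PopulationConfig(
    n_animals=5000, n_structure_snps=300, n_dense_variants=1200,
    n_chromosomes=2, chrom_length_bp=50_000_000, seed=11,
)
pools = lq.simulate_haplotype_pools(cfg)
pos = int(pools.variants.query("chrom == 1 and panel == 'test'")["pos"].iloc[200])
qtl = lq.QTLSpec(chrom=1, pos=pos, maf_target=0.08, a_true=-0.45, d_true=0.45)
study = lq.simulate_study(cfg, [qtl], h2=0.25, delta2=0.04)

scan = lq.DominanceScan(n_retained=500, burn_in=200, thin=1, seed=12)
scan.fit(study.genotypes, study.phenotypes)

ci = int(study.truth["variant_index"].iloc[0])
hit = scan.results_.set_index("variant_index").loc[ci]
print(f"calls: {len(scan.calls_)}")
print(f"causal variant 1:{pos}  MAF={hit.maf:.3f}")
print(f"  a = {hit.a_mean:+.3f} (sd {hit.a_sd:.3f})   d = {hit.d_mean:+.3f} (sd {hit.d_sd:.3f})")
print(f"  k = {hit.k:.2f}   q_d = {hit.q_d:.2e}   class = {hit.dominance_class}")
```

prints

```
calls: 1
causal variant 1:15758952  MAF=0.081
  a = -0.422 (sd 0.075)   d = +0.412 (sd 0.081)
  k = 0.98   q_d = 4.51e-04   class = recessive-window
```

The scan calls exactly one locus: the planted variant, recovered with
a ≈ −0.45 and d ≈ +0.45 (in phenotypic-SD units), a dominance
coefficient k̂ = 0.98 — a fully recessive pattern — and a dominance
q-value below the 10⁻³ FDR threshold.

The same pipeline runs from a shell on a YAML config:

```bash
lactoqtl run-all --config config.yaml --seed 11
```

with subcommands `simulate`, `qc`, `greml`, `adjust`, `assoc`,
`iterate`, `report` for individual stages; every output TSV is stamped
with the config hash and seed, and reruns are byte-identical.

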