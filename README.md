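# germscan

Diversity, divergence and breeding-selection analysis of functional-marker
germplasm panels.

Crop breeding over the last century left measurable footprints in the genes
that control yield, quality, adaptation and stress resistance.  Panels of
accessions — landraces, modern cultivars, introduced material — genotyped
with biallelic functional markers (e.g. KASP assays on cloned genes) let a
breeder ask: which favorable alleles did selection drive up, which were
fixed before systematic breeding began, and which remain untapped targets?
`germscan` implements the full analysis such a panel needs, for people
working on germplasm characterization and pre-breeding:

- **Allele frequencies** per subgroup/decade, with heterozygotes counted as
  one copy of each allele and per-locus missingness handled throughout.
- **Nei gene diversity** `H = 1 − p² − (1−p)²`, **Nei's standard genetic
  distance** `D = −ln(J_xy / √(J_x J_y))`, **Gst-type Fst**
  `1 − ΣH_S / ΣH_T`, and island-model **gene flow**
  `N_m = ¼ (1 − F_ST)/F_ST`.
- **Population structure**: Saitou–Nei neighbor joining (exact on additive
  matrices, deterministic tie-breaking, Newick output) and dosage-coded
  genotype PCA.
- **Selection scan**: pooled two-proportion Z test per locus between a
  reference group (landraces) and a test group (modern cultivars), judged
  against a `−log10(P) = 1.3` line, plus a four-way classification
  (positively/negatively selected, fixed pre-improvement, future target)
  and per-decade frequency trajectories.
- **Phenotypes**: BLUP-style shrinkage of multi-environment accession
  values, 10-class binning around mean ± 2σ, Shannon-Weaver diversity
  `H = −Σ P_i ln P_i`, and one-way ANOVA marker-trait association with
  variance explained (`R² = SS_between / SS_total`).
- **Synthetic panels**: a Balding–Nichols generator producing subgroups
  diverged at a target Fst, logistic decade trajectories at selected loci,
  and phenotypes with additive locus effects — so every stage is testable
  without any download.

## Worked example

```python
from germscan import (SimulationConfig, simulate_genotypes_bn,
                      allele_frequencies, gene_diversity, pairwise_fst_nm)

cfg = SimulationConfig(n_loci=200, populations={"CL": 157, "MCC": 323},
                       target_fst=0.05, seed=7)
genotypes, metadata, catalog = simulate_genotypes_bn(cfg)
freqs = allele_frequencies(genotypes, metadata, catalog)

diversity = gene_diversity(freqs)
for _, row in diversity[diversity.locus_id == "ALL"].iterrows():
    print(f"mean gene diversity {row.population}: {row.H_exp:.3f}")
row = pairwise_fst_nm(freqs).iloc[0]
print(f"Fst({row.pop_a}, {row.pop_b}) = {row.fst:.4f}  ->  Nm = {row.nm:.2f}")
```

prints (this is `examples/02_diversity_divergence.py`):

```
mean gene diversity CL: 0.318
mean gene diversity MCC: 0.336
Fst(CL, MCC) = 0.0530  ->  Nm = 4.47
```

meaning: both subgroups keep roughly a third of the maximal biallelic
diversity (0.5); about 5% of the total diversity separates landraces from
modern cultivars — matching the 0.05 divergence the panel was generated
at — which corresponds to an island-model exchange of ≈4.5 effective
migrants per generation.

The `examples/` directory holds one short script per capability
(simulation, diversity/divergence, tree + PCA, selection scan, phenotype
diversity + association, full pipeline); each prints the numbers it
computes and a line on what they mean.

## Command line

Every stage is also a subcommand of the `germscan` tool:

```bash
germscan simulate --seed 1 --out panel/
germscan freqs panel/genotypes.tsv panel/metadata.tsv panel/locus_catalog.tsv --out freqs.tsv
germscan scan freqs.tsv --ref CL --test MCC --out scan.tsv
germscan run config.yaml --out results/
```

`run` executes the whole pipeline from a YAML config and writes every
table as TSV plus a JSON report with provenance (config hash, seed,
version) that validates against the shipped schema.

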