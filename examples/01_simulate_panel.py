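"""Generate a synthetic germplasm panel and look at its shape.

The generator emulates a worldwide wheat collection genotyped at functional
loci: six subgroups (landraces CL, modern cultivars MCC, and four introduced
groups) diverged at a target Fst under the Balding–Nichols model, with
inbred-line genotypes and multi-environment phenotypes.
"""

from germscan import SimulationConfig, simulate_genotypes_bn, simulate_phenotypes

cfg = SimulationConfig(seed=42)  # defaults: 47 loci, 1152 accessions
genotypes, metadata, catalog = simulate_genotypes_bn(cfg)
phenotypes = simulate_phenotypes(cfg, genotypes, catalog)

print(f"panel: {genotypes.n_accessions} accessions x {genotypes.n_loci} loci")
print("subgroup sizes:", metadata["subgroup"].value_counts().to_dict())
print("trait categories:", catalog["trait_category"].value_counts().to_dict())
print(f"phenotype records: {len(phenotypes)} "
      f"({phenotypes['trait'].nunique()} traits x "
      f"{phenotypes['environment'].nunique()} environments)")
# Each accession carries one biallelic call per locus; the subgroup sizes
# mirror a landrace/modern-cultivar collection with introduced accessions.
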