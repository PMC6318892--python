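"""Full-panel analysis pipeline: load or simulate a panel, then chain
frequencies → diversity/divergence → tree/PCA → selection scan and
classification → phenotypic diversity and association → report.

The run is deterministic given the config and seed; every table in the
machine-readable report is also written as a standalone delimited file in
the output directory.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field

from . import __version__
from .io import (
    GenotypeMatrix,
    read_genotype_table,
    read_locus_catalog,
    read_phenotype_table,
    read_sample_metadata,
    validate_dataset,
    write_frequency_table,
    write_genotype_table,
    write_locus_catalog,
    write_phenotype_table,
    write_sample_metadata,
)
from .phenotype import (
    bin_trait_values,
    blup_accession_values,
    shannon_weaver_diversity,
    association_grid,
)
from .popgen import (
    allele_frequencies,
    gene_diversity,
    pairwise_distance_matrix,
    pairwise_fst_nm,
)
from .selection import category_counts, classify_allele_status, scan_loci
from .simulate import SelectedLocus, SimulationConfig, TraitEffect, simulate_genotypes_bn, simulate_phenotypes
from .structure import genotype_pca, neighbor_joining, write_newick, write_pca_scores

logger = logging.getLogger(__name__)


class ScanSettings(BaseModel):
    threshold_neg_log10_p: float = 1.3


class ClassifySettings(BaseModel):
    high_thresh: float = 0.90
    low_thresh: float = 0.15


class SimulationSettings(BaseModel):
    n_loci: int = 47
    populations: dict[str, int] = Field(
        default_factory=lambda: {"CL": 157, "MCC": 323, "North_America": 153,
                                 "CIMMYT": 53, "Europe": 384, "former_USSR": 82}
    )
    target_fst: float = 0.05
    inbreeding: float = 0.95
    missing_rate: float = 0.0
    selected_loci: list[dict[str, float]] = Field(default_factory=list)
    trait_effects: list[dict[str, Any]] = Field(default_factory=list)
    phenotypes: bool = True


class InputSettings(BaseModel):
    genotypes: str
    metadata: str
    catalog: str
    phenotypes: str | None = None


class AnalysisConfig(BaseModel):
    """Pipeline configuration; either ``inputs`` or ``simulation`` is set."""

    inputs: InputSettings | None = None
    simulation: SimulationSettings | None = None
    ref_population: str = "CL"
    test_population: str = "MCC"
    scan: ScanSettings = Field(default_factory=ScanSettings)
    classify: ClassifySettings = Field(default_factory=ClassifySettings)
    tree_level: str = "population"  # or "individual"
    pca_components: int = 2
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.model_validate(data)

    def content_hash(self) -> str:
        blob = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


class AnalysisReport(BaseModel):
    """Machine-readable run summary; doubles as the report's JSON schema
    (``AnalysisReport.model_json_schema()``)."""

    subgroup_counts: dict[str, int]
    mean_gene_diversity: dict[str, float]
    fst_nm: list[dict[str, Any]]
    scan_category_counts: dict[str, int]
    n_significant_loci: int
    shannon_by_trait: dict[str, dict[str, float]]
    association_significant_cells: int | None = None
    provenance: dict[str, Any]


def _load_panel(cfg: AnalysisConfig, outdir: Path):
    if cfg.simulation is not None:
        sim = cfg.simulation
        sc = SimulationConfig(
            n_loci=sim.n_loci,
            populations=dict(sim.populations),
            target_fst=sim.target_fst,
            inbreeding=sim.inbreeding,
            missing_rate=sim.missing_rate,
            selected_loci=[
                SelectedLocus(int(s["locus_index"]), float(s["start_freq"]), float(s["end_freq"]))
                for s in sim.selected_loci
            ],
            trait_effects=[
                TraitEffect(str(t["trait"]), int(t["locus_index"]), float(t["beta"]))
                for t in sim.trait_effects
            ],
            seed=cfg.seed,
        )
        g, metadata, catalog = simulate_genotypes_bn(sc)
        pheno = simulate_phenotypes(sc, g, catalog) if sim.phenotypes else None
        write_genotype_table(g, outdir / "genotypes.tsv")
        write_sample_metadata(metadata, outdir / "metadata.tsv")
        write_locus_catalog(catalog, outdir / "locus_catalog.tsv")
        if pheno is not None:
            write_phenotype_table(pheno, outdir / "phenotypes.tsv")
        return g, metadata, catalog, pheno
    if cfg.inputs is None:
        raise ValueError("config must provide either 'inputs' or 'simulation'")
    g = read_genotype_table(cfg.inputs.genotypes)
    metadata = read_sample_metadata(cfg.inputs.metadata)
    catalog = read_locus_catalog(cfg.inputs.catalog)
    pheno = read_phenotype_table(cfg.inputs.phenotypes) if cfg.inputs.phenotypes else None
    return g, metadata, catalog, pheno


def run_full_analysis(cfg: AnalysisConfig, output_dir: str | Path) -> AnalysisReport:
    """Run every analysis stage and write all outputs under ``output_dir``."""
    outdir = Path(output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    g, metadata, catalog, pheno = _load_panel(cfg, outdir)

    report_issues = validate_dataset(g, metadata, catalog)
    if report_issues.issues:
        raise ValueError(
            "dataset validation failed: " + "; ".join(report_issues.issues[:10])
        )
    for pop in (cfg.ref_population, cfg.test_population):
        if pop not in set(metadata["subgroup"]):
            raise KeyError(f"population {pop!r} not present in metadata subgroups")

    logger.info("scan threshold -log10(P) = %.3f; classify high/low = %.2f/%.2f",
                cfg.scan.threshold_neg_log10_p,
                cfg.classify.high_thresh, cfg.classify.low_thresh)

    # frequencies, diversity, divergence
    freqs = allele_frequencies(g, metadata, catalog)
    write_frequency_table(freqs, outdir / "allele_frequencies.tsv")
    div = gene_diversity(freqs)
    div.to_csv(outdir / "gene_diversity.tsv", sep="\t", index=False, float_format="%.6f")
    fst_nm = pairwise_fst_nm(freqs)
    fst_nm.to_csv(outdir / "fst_nm.tsv", sep="\t", index=False, float_format="%.6f")

    # structure: distance matrix, NJ tree, PCA
    dm = pairwise_distance_matrix(g, metadata, catalog, level=cfg.tree_level)
    dm.write_tsv(outdir / "distances.tsv")
    dm.write_phylip(outdir / "distances.phy")
    finite = np.isfinite(dm.values).all()
    if len(dm.labels) >= 3 and finite:
        tree = neighbor_joining(dm)
        write_newick(tree, outdir / "tree.nwk")
    else:
        logger.warning("tree skipped (need >= 3 units with finite distances)")
    pca = genotype_pca(g, catalog, n_components=cfg.pca_components)
    write_pca_scores(pca, outdir / "pca_scores.tsv")

    # selection scan + classification
    scan = scan_loci(freqs, cfg.ref_population, cfg.test_population,
                     threshold_neg_log10_p=cfg.scan.threshold_neg_log10_p)
    classified = classify_allele_status(
        scan, high_thresh=cfg.classify.high_thresh, low_thresh=cfg.classify.low_thresh
    )
    classified.to_csv(outdir / "selection_scan.tsv", sep="\t", index=False, float_format="%.6g")
    counts = category_counts(classified)

    # phenotypes: Shannon diversity per trait/population + association grid
    shannon: dict[str, dict[str, float]] = {}
    assoc_cells: int | None = None
    if pheno is not None:
        shannon_rows = []
        for trait in sorted(pheno["trait"].unique()):
            values = blup_accession_values(pheno, trait)
            binning = bin_trait_values(values, trait)
            shannon[trait] = {}
            for pop in (cfg.ref_population, cfg.test_population):
                sd = shannon_weaver_diversity(binning, metadata, population=pop)
                shannon[trait][pop] = sd.H
                shannon_rows.append((trait, pop, sd.H))
        pd.DataFrame(shannon_rows, columns=["trait", "population", "H"]).to_csv(
            outdir / "shannon_diversity.tsv", sep="\t", index=False, float_format="%.6f"
        )
        grid = association_grid(pheno, g, metadata, population=cfg.test_population)
        grid.to_csv(outdir / "association_grid.tsv", sep="\t", float_format="%.4f")
        assoc_cells = int((grid.to_numpy() >= -np.log10(0.05)).sum())

    report = AnalysisReport(
        subgroup_counts=metadata["subgroup"].value_counts().to_dict(),
        mean_gene_diversity={
            row["population"]: float(row["H_exp"])
            for _, row in div[div["locus_id"] == "ALL"].iterrows()
        },
        fst_nm=fst_nm.to_dict(orient="records"),
        scan_category_counts=counts,
        n_significant_loci=int(classified["significant"].sum()),
        shannon_by_trait=shannon,
        association_significant_cells=assoc_cells,
        provenance={
            "config_hash": cfg.content_hash(),
            "seed": cfg.seed,
            "version": __version__,
        },
    )
    with open(outdir / "report.json", "w") as fh:
        fh.write(report.model_dump_json(indent=2))
    with open(outdir / "report.schema.json", "w") as fh:
        json.dump(AnalysisReport.model_json_schema(), fh, indent=2)
    return report
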