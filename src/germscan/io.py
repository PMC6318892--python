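"""Panel data model and delimited-text input/output.

A germplasm panel is described by four tables:

* a **genotype table** — accessions × loci, biallelic calls in
  ``{A, B, HET, MISSING}`` (the calls a fluorescence-based KASP assay yields
  for a functional SNP/InDel marker);
* **sample metadata** — subgroup (e.g. landraces vs modern cultivars,
  geographic origin groups), country and release decade per accession;
* a **locus catalog** — gene name, trait category and favorable allele per
  locus;
* a **phenotype table** — long-format trait values per accession and
  environment (year).

All files are UTF-8 delimited text; the delimiter is inferred from the
extension (``.csv`` → comma, anything else → tab) and can be overridden.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

# Integer codes for genotype calls. HET is one copy of each allele.
A = 0
B = 1
HET = 2
MISSING = 3

CALL_NAMES = {A: "A", B: "B", HET: "H", MISSING: "NA"}

#: Default mapping of input tokens onto call codes (KASP-export convention).
DEFAULT_TOKEN_MAP: dict[str, int] = {
    "A": A,
    "B": B,
    "H": HET,
    "NA": MISSING,
    "-": MISSING,
    "": MISSING,
}

TRAIT_CATEGORIES = ("yield", "quality", "adaptation", "stress_resistance")

#: Release decades in chronological order; accessions may lack a decade
#: (landraces predate systematic release) and are then skipped by
#: decade-stratified analyses.
DECADE_ORDER = (
    "pre-1950s",
    "1950s",
    "1960s",
    "1970s",
    "1980s",
    "1990s",
    "2000s",
)

TRAITS = ("HD", "FD", "PH", "ETN", "SL", "SN", "KN", "TKW", "KL", "KW", "KT")


def _sep_for(path: str | Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "," if str(path).endswith(".csv") else "\t"


@dataclass
class GenotypeMatrix:
    """Accessions × loci grid of biallelic calls.

    ``calls`` holds the integer codes ``A``/``B``/``HET``/``MISSING`` in an
    ``int8`` array of shape ``(n_accessions, n_loci)``.
    """

    accession_ids: list[str]
    locus_ids: list[str]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        n_acc, n_loc = self.calls.shape
        if n_acc != len(self.accession_ids) or n_loc != len(self.locus_ids):
            raise ValueError(
                f"call grid {self.calls.shape} does not match "
                f"{len(self.accession_ids)} accessions x {len(self.locus_ids)} loci"
            )
        for name, ids in (("accession", self.accession_ids), ("locus", self.locus_ids)):
            dupes = pd.Index(ids)[pd.Index(ids).duplicated()].unique()
            if len(dupes):
                raise ValueError(f"duplicate {name} id(s): {', '.join(map(str, dupes))}")

    @property
    def n_accessions(self) -> int:
        return len(self.accession_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)

    def missing_fraction(self) -> pd.Series:
        """Per-locus fraction of MISSING calls."""
        frac = (self.calls == MISSING).mean(axis=0)
        return pd.Series(frac, index=self.locus_ids, name="missing_fraction")

    def dosage(self, favorable: Mapping[str, str] | None = None) -> pd.DataFrame:
        """Favorable-allele dosage per accession and locus.

        A homozygous favorable call is 1, HET is 0.5, the other homozygote 0
        and MISSING is NaN.  ``favorable`` maps locus id → "A"/"B"; loci not
        listed (or ``favorable=None``) are oriented on allele A.
        """
        d = np.full(self.calls.shape, np.nan)
        fav_is_b = np.zeros(self.n_loci, dtype=bool)
        if favorable is not None:
            fav_is_b = np.array(
                [favorable.get(loc, "A") == "B" for loc in self.locus_ids]
            )
        d[self.calls == A] = 1.0
        d[self.calls == B] = 0.0
        d[self.calls == HET] = 0.5
        d[:, fav_is_b] = 1.0 - d[:, fav_is_b]  # NaN stays NaN
        return pd.DataFrame(d, index=self.accession_ids, columns=self.locus_ids)

    def subset(self, accessions: Sequence[str]) -> "GenotypeMatrix":
        idx = pd.Index(self.accession_ids).get_indexer(list(accessions))
        if (idx < 0).any():
            missing = [a for a, i in zip(accessions, idx) if i < 0]
            raise KeyError(f"unknown accession id(s): {', '.join(missing)}")
        return GenotypeMatrix(list(accessions), list(self.locus_ids), self.calls[idx])


def read_genotype_table(
    path: str | Path,
    token_map: Mapping[str, int] | None = None,
    delimiter: str | None = None,
) -> GenotypeMatrix:
    """Read an accession × locus call table.

    The header row carries locus ids; the first column carries accession ids.
    Tokens are mapped through ``token_map`` (default :data:`DEFAULT_TOKEN_MAP`);
    an unmappable token raises with its row and column named.
    """
    tmap = dict(DEFAULT_TOKEN_MAP if token_map is None else token_map)
    sep = _sep_for(path, delimiter)
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str, keep_default_na=False)
    if df.shape[1] == 0:
        raise ValueError(f"{path}: no locus columns found")
    accession_ids = [str(a) for a in df.index]
    locus_ids = [str(c) for c in df.columns]
    calls = np.empty(df.shape, dtype=np.int8)
    values = df.to_numpy()
    for j, locus in enumerate(locus_ids):
        col = values[:, j]
        for i, tok in enumerate(col):
            tok = tok.strip()
            try:
                calls[i, j] = tmap[tok]
            except KeyError:
                raise ValueError(
                    f"{path}: unmappable genotype token {tok!r} at accession "
                    f"{accession_ids[i]!r}, locus {locus!r}"
                ) from None
    return GenotypeMatrix(accession_ids, locus_ids, calls)


def write_genotype_table(
    g: GenotypeMatrix, path: str | Path, delimiter: str | None = None
) -> None:
    sep = _sep_for(path, delimiter)
    tokens = np.array([CALL_NAMES[A], CALL_NAMES[B], CALL_NAMES[HET], CALL_NAMES[MISSING]])
    df = pd.DataFrame(tokens[g.calls], index=g.accession_ids, columns=g.locus_ids)
    df.index.name = "accession_id"
    df.to_csv(path, sep=sep)


def read_sample_metadata(path: str | Path, delimiter: str | None = None) -> pd.DataFrame:
    """Read per-accession metadata (accession_id, subgroup, country, decade).

    Decade may be empty; a non-empty decade must belong to :data:`DECADE_ORDER`.
    """
    sep = _sep_for(path, delimiter)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    required = {"accession_id", "subgroup"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: metadata requires columns {sorted(required)}")
    if "country" not in df.columns:
        df["country"] = ""
    if "decade" not in df.columns:
        df["decade"] = ""
    dupes = df["accession_id"][df["accession_id"].duplicated()].unique()
    if len(dupes):
        raise ValueError(f"{path}: duplicate accession id(s): {', '.join(dupes)}")
    bad = sorted(set(df["decade"]) - set(DECADE_ORDER) - {""})
    if bad:
        raise ValueError(f"{path}: unknown decade label(s): {', '.join(bad)}")
    return df


def write_sample_metadata(m: pd.DataFrame, path: str | Path, delimiter: str | None = None) -> None:
    m.to_csv(path, sep=_sep_for(path, delimiter), index=False)


def read_locus_catalog(path: str | Path, delimiter: str | None = None) -> pd.DataFrame:
    """Read the locus catalog (locus_id, gene_name, trait_category, favorable_allele)."""
    sep = _sep_for(path, delimiter)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    required = {"locus_id", "gene_name", "trait_category", "favorable_allele"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: locus catalog requires columns {sorted(required)}")
    dupes = df["locus_id"][df["locus_id"].duplicated()].unique()
    if len(dupes):
        raise ValueError(f"{path}: duplicate locus id(s): {', '.join(dupes)}")
    bad_cat = sorted(set(df["trait_category"]) - set(TRAIT_CATEGORIES))
    if bad_cat:
        raise ValueError(f"{path}: unknown trait categor{{y,ies}}: {', '.join(bad_cat)}")
    bad_fav = sorted(set(df["favorable_allele"]) - {"A", "B"})
    if bad_fav:
        raise ValueError(f"{path}: favorable_allele must be A or B, got {', '.join(bad_fav)}")
    return df


def write_locus_catalog(c: pd.DataFrame, path: str | Path, delimiter: str | None = None) -> None:
    c.to_csv(path, sep=_sep_for(path, delimiter), index=False)


def read_phenotype_table(path: str | Path, delimiter: str | None = None) -> pd.DataFrame:
    """Read a long-format phenotype table (accession_id, trait, environment, value)."""
    sep = _sep_for(path, delimiter)
    df = pd.read_csv(
        path,
        sep=sep,
        dtype={"accession_id": str, "trait": str, "environment": str},
    )
    required = {"accession_id", "trait", "environment", "value"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: phenotype table requires columns {sorted(required)}")
    keys = df[["accession_id", "trait", "environment"]]
    if keys.duplicated().any():
        first = keys[keys.duplicated()].iloc[0]
        raise ValueError(
            f"{path}: duplicate (accession, trait, environment) key "
            f"({first['accession_id']}, {first['trait']}, {first['environment']})"
        )
    df["value"] = pd.to_numeric(df["value"], errors="coerce")
    if np.isinf(df["value"].to_numpy()).any():
        raise ValueError(f"{path}: non-finite phenotype value")
    return df


def write_phenotype_table(p: pd.DataFrame, path: str | Path, delimiter: str | None = None) -> None:
    p.to_csv(path, sep=_sep_for(path, delimiter), index=False, float_format="%.6f")


# ---------------------------------------------------------------------------
# allele-frequency table I/O (columns: population, locus_id, p_fav, n_eff)

def write_frequency_table(t: pd.DataFrame, path: str | Path, delimiter: str | None = None) -> None:
    """Write an allele-frequency table with 6-decimal frequencies (stable diffs)."""
    cols = ["population", "locus_id", "p_fav", "n_eff"]
    out = t[cols].copy()
    out.to_csv(path, sep=_sep_for(path, delimiter), index=False, float_format="%.6f")


def read_frequency_table(path: str | Path, delimiter: str | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, sep=_sep_for(path, delimiter), dtype={"population": str, "locus_id": str})
    required = {"population", "locus_id", "p_fav", "n_eff"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: frequency table requires columns {sorted(required)}")
    return df


# ---------------------------------------------------------------------------
# dataset validation

@dataclass
class ValidationReport:
    """Consistency report for a panel; reporting only, inputs untouched."""

    issues: list[str] = field(default_factory=list)
    missing_fractions: dict[str, float] = field(default_factory=dict)
    flagged_loci: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.issues


def validate_dataset(
    g: GenotypeMatrix,
    metadata: pd.DataFrame,
    catalog: pd.DataFrame,
    missing_threshold: float = 0.10,
) -> ValidationReport:
    """Cross-check genotype matrix, metadata and catalog.

    Accessions without metadata and loci without catalog entries are issues;
    loci whose missing-call fraction exceeds ``missing_threshold`` are flagged
    (not errors — they remain usable).
    """
    report = ValidationReport()
    meta_ids = set(metadata["accession_id"])
    for acc in g.accession_ids:
        if acc not in meta_ids:
            report.issues.append(f"accession {acc!r} has no metadata record")
    cat_ids = set(catalog["locus_id"])
    for loc in g.locus_ids:
        if loc not in cat_ids:
            report.issues.append(f"locus {loc!r} has no catalog entry")
    frac = g.missing_fraction()
    report.missing_fractions = {k: float(v) for k, v in frac.items()}
    report.flagged_loci = [k for k, v in frac.items() if v > missing_threshold]
    for loc in report.flagged_loci:
        logger.warning(
            "locus %s missing fraction %.3f exceeds threshold %.2f",
            loc, report.missing_fractions[loc], missing_threshold,
        )
    return report
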