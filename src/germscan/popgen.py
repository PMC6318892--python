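"""Allele frequencies, Nei gene diversity, Nei's standard distance, Gst-type
Fst and island-model gene flow.

All statistics work on favorable-allele frequencies at biallelic loci.  Each
non-missing call contributes two allele observations (a heterozygote one of
each), matching standard diploid frequency estimation; for fully inbred lines
this degrades gracefully to line counting.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import A, B, HET, GenotypeMatrix

logger = logging.getLogger(__name__)

FREQ_TOL = 1e-9


def allele_frequencies(
    g: GenotypeMatrix,
    metadata: pd.DataFrame,
    catalog: pd.DataFrame,
    group_col: str = "subgroup",
) -> pd.DataFrame:
    """Favorable-allele frequency per (population, locus).

    Returns a frame with columns ``population``, ``locus_id``, ``p_fav``,
    ``n_eff`` where ``n_eff`` is the number of allele observations
    (2 × non-missing calls).  A (population, locus) cell with no calls is
    omitted with a warning.
    """
    fav = dict(zip(catalog["locus_id"], catalog["favorable_allele"]))
    missing_fav = [loc for loc in g.locus_ids if loc not in fav]
    if missing_fav:
        raise KeyError(f"no favorable allele for locus/loci: {', '.join(missing_fav)}")

    meta = metadata.set_index("accession_id").reindex(g.accession_ids)
    if meta[group_col].isna().any():
        absent = meta.index[meta[group_col].isna()].tolist()
        raise KeyError(f"accession(s) without metadata: {', '.join(map(str, absent))}")

    rows = []
    fav_is_a = np.array([fav[loc] == "A" for loc in g.locus_ids])
    for pop, acc_idx in meta.groupby(group_col, sort=True).groups.items():
        idx = pd.Index(g.accession_ids).get_indexer(acc_idx)
        calls = g.calls[idx]
        n_a = 2 * (calls == A).sum(axis=0) + (calls == HET).sum(axis=0)
        n_b = 2 * (calls == B).sum(axis=0) + (calls == HET).sum(axis=0)
        n_eff = n_a + n_b
        fav_count = np.where(fav_is_a, n_a, n_b)
        for j, loc in enumerate(g.locus_ids):
            if n_eff[j] == 0:
                logger.warning("no calls for population %s at locus %s; row omitted", pop, loc)
                continue
            rows.append((pop, loc, fav_count[j] / n_eff[j], float(n_eff[j])))
    return pd.DataFrame(rows, columns=["population", "locus_id", "p_fav", "n_eff"])


def gene_diversity(freqs: pd.DataFrame) -> pd.DataFrame:
    """Nei gene diversity (expected heterozygosity) per locus and population.

    For a biallelic locus ``H = 1 - p^2 - (1-p)^2``, bounded by 0.5.  One
    extra row per population with ``locus_id == "ALL"`` carries the unweighted
    mean across that population's loci.
    """
    p = freqs["p_fav"].to_numpy()
    if ((p < -FREQ_TOL) | (p > 1 + FREQ_TOL)).any():
        raise ValueError("allele frequency outside [0, 1]")
    out = freqs[["population", "locus_id"]].copy()
    out["H_exp"] = 1.0 - p**2 - (1.0 - p) ** 2
    means = (
        out.groupby("population", sort=True)["H_exp"]
        .mean()
        .reset_index()
        .assign(locus_id="ALL")[["population", "locus_id", "H_exp"]]
    )
    return pd.concat([out, means], ignore_index=True)


def nei_distance(fx: np.ndarray, fy: np.ndarray) -> float:
    """Nei's standard genetic distance between two frequency vectors.

    ``fx``/``fy`` are favorable-allele frequencies over the same loci.
    ``D = -ln(Jxy / sqrt(Jx * Jy))`` with J the mean (over loci) gene
    identities.  Disjoint allele sets (``Jxy == 0``) give ``inf``.
    """
    fx = np.asarray(fx, dtype=float)
    fy = np.asarray(fy, dtype=float)
    if fx.shape != fy.shape:
        raise ValueError("frequency vectors must cover the same loci")
    jx = float(np.mean(fx**2 + (1 - fx) ** 2))
    jy = float(np.mean(fy**2 + (1 - fy) ** 2))
    jxy = float(np.mean(fx * fy + (1 - fx) * (1 - fy)))
    if jxy <= 0.0:
        return np.inf
    return float(-np.log(jxy / np.sqrt(jx * jy)))


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative distance matrix with zero diagonal."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T, equal_nan=True):
            raise ValueError("distance matrix must be symmetric")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def write_tsv(self, path) -> None:
        df = self.to_frame()
        df.index.name = "id"
        df.to_csv(path, sep="\t", float_format="%.6f")

    def write_phylip(self, path) -> None:
        """Square PHYLIP format for interoperability with tree tools."""
        with open(path, "w") as fh:
            fh.write(f"{len(self.labels)}\n")
            for label, row in zip(self.labels, self.values):
                name = label[:10].ljust(10)
                fh.write(name + "  " + "  ".join(f"{v:.6f}" for v in row) + "\n")


def _frequency_vectors(
    g: GenotypeMatrix,
    metadata: pd.DataFrame | None,
    catalog: pd.DataFrame,
    level: str,
    group_col: str,
) -> pd.DataFrame:
    """Unit × locus favorable-frequency matrix (NaN where no calls)."""
    if level == "individual":
        fav = dict(zip(catalog["locus_id"], catalog["favorable_allele"]))
        return g.dosage(fav)
    if metadata is None:
        raise ValueError("population-level distances require metadata")
    freqs = allele_frequencies(g, metadata, catalog, group_col=group_col)
    return freqs.pivot(index="population", columns="locus_id", values="p_fav")


def pairwise_distance_matrix(
    g: GenotypeMatrix,
    metadata: pd.DataFrame | None,
    catalog: pd.DataFrame,
    level: str = "population",
    group_col: str = "subgroup",
) -> DistanceMatrix:
    """Nei distances between populations, or between accessions treated as
    populations of one.

    Each pair is compared over the loci where both units have calls; a pair
    with disjoint alleles gets ``inf``.
    """
    pivot = _frequency_vectors(g, metadata, catalog, level, group_col)
    labels = [str(x) for x in pivot.index]
    if len(labels) < 2:
        raise ValueError("need at least 2 units for a distance matrix")
    P = pivot.to_numpy(dtype=float)
    valid = ~np.isnan(P)
    Pz = np.where(valid, P, 0.0)
    Qz = np.where(valid, 1.0 - P, 0.0)
    V = valid.astype(float)
    # pairwise sums over shared loci via matrix products
    shared = V @ V.T
    sxy = Pz @ Pz.T + Qz @ Qz.T                       # sum of x*y + (1-x)(1-y)
    self_sq = np.where(valid, Pz**2 + Qz**2, 0.0)     # per-unit sum of p^2+q^2
    sx = self_sq @ V.T                                # restricted to shared loci
    with np.errstate(divide="ignore", invalid="ignore"):
        jxy = sxy / shared
        jx = sx / shared
        jy = jx.T
        ratio = jxy / np.sqrt(jx * jy)
        d = -np.log(ratio)
    d[jxy <= 0] = np.inf
    d[shared == 0] = np.nan
    np.fill_diagonal(d, 0.0)
    d = np.maximum(d, 0.0)  # guard tiny negative rounding
    d = (d + d.T) / 2.0
    return DistanceMatrix(labels, d)


def gst_fst(freqs: pd.DataFrame, populations: list[str] | None = None) -> float:
    """Multilocus Gst-type Fst across two or more populations.

    Per locus: ``Hs`` is the unweighted mean within-population diversity and
    ``Ht`` the diversity of the mean frequency vector; the multilocus value is
    ``1 - sum(Hs) / sum(Ht)`` over loci with ``Ht > 0`` (no sample-size
    correction).  Returns NaN when every locus is monomorphic overall.
    """
    f = freqs if populations is None else freqs[freqs["population"].isin(populations)]
    pops = f["population"].unique()
    if len(pops) < 2:
        raise ValueError("Fst requires at least 2 populations")
    pivot = f.pivot(index="locus_id", columns="population", values="p_fav").dropna()
    if pivot.empty:
        raise ValueError("no shared loci across populations")
    P = pivot.to_numpy(dtype=float)
    H = 1.0 - P**2 - (1.0 - P) ** 2
    hs = H.mean(axis=1)
    pbar = P.mean(axis=1)
    ht = 1.0 - pbar**2 - (1.0 - pbar) ** 2
    keep = ht > 0
    if not keep.any():
        return float("nan")
    fst = 1.0 - hs[keep].sum() / ht[keep].sum()
    return float(min(max(fst, 0.0), 1.0))


def gene_flow_nm(fst: float) -> float:
    """Island-model gene flow ``Nm = 0.25 (1 - Fst) / Fst``.

    ``Fst = 0`` gives ``inf`` (unbounded migration), undefined Fst propagates
    NaN.
    """
    if np.isnan(fst):
        return float("nan")
    if fst < 0 or fst > 1:
        raise ValueError(f"Fst must lie in [0, 1], got {fst}")
    if fst == 0:
        return np.inf
    return 0.25 * (1.0 - fst) / fst


def pairwise_fst_nm(freqs: pd.DataFrame) -> pd.DataFrame:
    """Fst and Nm for every pair of populations in a frequency table."""
    pops = sorted(freqs["population"].unique())
    rows = []
    for a, b in itertools.combinations(pops, 2):
        fst = gst_fst(freqs, [a, b])
        rows.append((a, b, fst, gene_flow_nm(fst)))
    return pd.DataFrame(rows, columns=["pop_a", "pop_b", "fst", "nm"])
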