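"""Phenotype statistics: multi-environment accession values with BLUP-style
shrinkage, descriptive summaries, 10-class binned Shannon-Weaver diversity,
and one-way ANOVA marker-trait association.

The accession value for a trait observed over several environments (years)
is a shrinkage estimate from a one-way random-accession model fitted after
removing environment means: variance components come from the
method-of-moments one-way ANOVA decomposition (clamped at zero) and each
accession mean is pulled toward the grand mean by
``k_i = s2_g / (s2_g + s2_e / r_i)`` where ``r_i`` counts the environments
that accession was observed in.  With no residual variance the value is the
plain mean; with no genetic variance every accession collapses to the grand
mean.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import A, B, GenotypeMatrix

logger = logging.getLogger(__name__)

N_CLASSES = 10


def blup_accession_values(pheno: pd.DataFrame, trait: str) -> pd.DataFrame:
    """Shrunken accession values for one trait across environments.

    Returns a frame with ``accession_id``, ``value`` (the BLUP-style
    estimate), ``raw_mean`` and ``n_env``.
    """
    sub = pheno[(pheno["trait"] == trait) & pheno["value"].notna()].copy()
    if sub.empty:
        raise ValueError(f"no observations for trait {trait!r}")
    grand = sub["value"].mean()
    # remove environment (year) effects, keep the trait scale
    env_means = sub.groupby("environment")["value"].transform("mean")
    sub["adj"] = sub["value"] - env_means + grand

    groups = sub.groupby("accession_id")["adj"]
    means = groups.mean()
    counts = groups.count()
    n_total = len(sub)
    n_acc = len(means)
    mu = sub["adj"].mean()

    if n_total > n_acc and n_acc > 1:
        ss_within = float(((sub["adj"] - means.reindex(sub["accession_id"]).to_numpy()) ** 2).sum())
        ss_between = float((counts * (means - mu) ** 2).sum())
        ms_within = ss_within / (n_total - n_acc)
        ms_between = ss_between / (n_acc - 1)
        # unbalanced-design effective replicate number for the MoM estimator
        r_bar = (n_total - (counts**2).sum() / n_total) / (n_acc - 1)
        s2_e = ms_within
        s2_g = max((ms_between - ms_within) / r_bar, 0.0)
    else:
        # single observation per accession: no residual replication
        s2_e = 0.0
        s2_g = float(means.var(ddof=1)) if n_acc > 1 else 0.0

    denom = s2_g + s2_e / counts
    with np.errstate(invalid="ignore", divide="ignore"):
        k = np.where(denom > 0, s2_g / denom, 0.0)
    values = mu + k * (means - mu)
    return pd.DataFrame(
        {
            "accession_id": means.index,
            "value": values.to_numpy(dtype=float),
            "raw_mean": means.to_numpy(dtype=float),
            "n_env": counts.to_numpy(dtype=int),
        }
    ).reset_index(drop=True)


def trait_summary(
    values: pd.DataFrame,
    metadata: pd.DataFrame,
    group_col: str = "subgroup",
    compare: tuple[str, str] | None = None,
    equal_var: bool = False,
) -> pd.DataFrame:
    """Per-group descriptive statistics with an optional two-group test.

    ``values`` is the output of :func:`blup_accession_values`.  When
    ``compare`` names two groups, a Welch two-sample t test (pooled if
    ``equal_var``) between them is attached to every row as ``p_diff``.
    Groups of fewer than two accessions get descriptives only.
    """
    merged = values.merge(
        metadata[["accession_id", group_col]], on="accession_id", how="left"
    )
    rows = []
    for grp, sub in merged.groupby(group_col, sort=True):
        v = sub["value"].to_numpy(dtype=float)
        rows.append(
            {
                group_col: grp,
                "n": len(v),
                "mean": float(np.mean(v)),
                "sd": float(np.std(v, ddof=1)) if len(v) > 1 else np.nan,
                "min": float(np.min(v)),
                "max": float(np.max(v)),
            }
        )
    out = pd.DataFrame(rows)
    if compare is not None:
        a = merged.loc[merged[group_col] == compare[0], "value"].to_numpy(dtype=float)
        b = merged.loc[merged[group_col] == compare[1], "value"].to_numpy(dtype=float)
        if len(a) < 2 or len(b) < 2:
            warnings.warn("comparison group with < 2 accessions; test skipped", stacklevel=2)
            out["p_diff"] = np.nan
        else:
            res = stats.ttest_ind(a, b, equal_var=equal_var)
            p = float(res.pvalue)
            if np.isnan(p):  # both groups constant: P=1 iff means coincide
                p = 1.0 if np.mean(a) == np.mean(b) else 0.0
            out["p_diff"] = p
    return out


@dataclass
class TraitBinning:
    """10-class partition of accession values around the mean.

    Class 1 is everything below ``X - 2σ``, class 10 everything at or above
    ``X + 2σ``; classes 2–9 are half-open ``0.5σ`` bins in between (boundary
    values belong to the upper class).
    """

    trait: str
    mean: float
    sd: float
    boundaries: np.ndarray                  # the 9 class boundaries
    class_index: pd.Series                  # accession_id -> 1..10


def bin_trait_values(
    values: pd.DataFrame,
    trait: str,
    mean: float | None = None,
    sd: float | None = None,
) -> TraitBinning:
    """Assign each accession value to one of 10 frequency classes.

    Mean and SD default to those of the supplied values.  A degenerate
    ``σ = 0`` puts every accession in the central class 6 with a warning.
    """
    v = values.set_index("accession_id")["value"].astype(float)
    x = float(v.mean()) if mean is None else float(mean)
    s = float(v.std(ddof=1)) if sd is None else float(sd)
    if not np.isfinite(s) or s <= 0:
        warnings.warn("zero/undefined spread; all accessions assigned class 6", stacklevel=2)
        cls = pd.Series(6, index=v.index, dtype=int)
        return TraitBinning(trait, x, 0.0, np.full(9, x), cls)
    boundaries = x + np.arange(-2.0, 2.5, 0.5) * s
    idx = np.floor((v.to_numpy() - (x - 2.0 * s)) / (0.5 * s)).astype(int) + 2
    cls = pd.Series(np.clip(idx, 1, 10), index=v.index, dtype=int)
    return TraitBinning(trait, x, s, boundaries, cls)


@dataclass
class ShannonDiversity:
    """Shannon-Weaver index over the 10 phenotype classes."""

    trait: str
    population: str
    H: float
    class_proportions: np.ndarray  # length 10, sums to 1


def shannon_weaver_diversity(
    binning: TraitBinning,
    metadata: pd.DataFrame | None = None,
    population: str = "ALL",
    group_col: str = "subgroup",
) -> ShannonDiversity:
    """``H = -Σ P_i ln P_i`` over the classes, for one population.

    ``P_i`` is the share of the population's accessions in class ``i``;
    empty classes contribute nothing.  ``H`` ranges from 0 (all accessions
    in one class) to ``ln 10`` (uniform spread).
    """
    cls = binning.class_index
    if population != "ALL":
        if metadata is None:
            raise ValueError("population filter requires metadata")
        keep = set(metadata.loc[metadata[group_col] == population, "accession_id"])
        cls = cls[cls.index.isin(keep)]
    if cls.empty:
        raise ValueError(f"no accessions in population {population!r}")
    counts = np.bincount(cls.to_numpy(), minlength=N_CLASSES + 1)[1:]
    p = counts / counts.sum()
    nz = p[p > 0]
    h = float(-(nz * np.log(nz)).sum())
    return ShannonDiversity(binning.trait, population, h, p)


@dataclass
class AssociationResult:
    """One-way ANOVA of a trait on the two allele classes at one locus."""

    locus_id: str
    trait: str
    population: str
    F: float
    p_value: float
    r_squared: float       # SS_between / SS_total
    n: int
    significant: bool      # at P < 0.05

    @property
    def neg_log10_p(self) -> float:
        return float(-np.log10(self.p_value))


def anova_association(
    values: pd.DataFrame,
    g: GenotypeMatrix,
    locus_id: str,
    trait: str,
    metadata: pd.DataFrame | None = None,
    population: str = "ALL",
    group_col: str = "subgroup",
    include_het: bool = False,
    alpha: float = 0.05,
) -> AssociationResult | None:
    """Marker-trait association by one-way fixed-effects ANOVA.

    Accession values are grouped by allele class at the locus (HET and
    MISSING excluded unless ``include_het`` adds HET as a third class).
    Returns ``None``, with a log message, when the locus is monomorphic in
    the population or a class has fewer than two accessions.
    """
    if locus_id not in g.locus_ids:
        raise KeyError(f"locus {locus_id!r} not in genotype matrix")
    j = g.locus_ids.index(locus_id)
    calls = pd.Series(g.calls[:, j], index=g.accession_ids)
    v = values.set_index("accession_id")["value"].astype(float)
    if population != "ALL":
        if metadata is None:
            raise ValueError("population filter requires metadata")
        keep = set(metadata.loc[metadata[group_col] == population, "accession_id"])
        v = v[v.index.isin(keep)]
    wanted = (A, B, 2) if include_het else (A, B)  # 2 is the HET code
    groups = []
    for allele in wanted:
        members = calls.index[calls == allele]
        vals = v.reindex(members).dropna().to_numpy()
        if len(vals) >= 2:
            groups.append(vals)
    if len(groups) < 2:
        logger.info(
            "locus %s monomorphic or underpowered in %s; association skipped",
            locus_id, population,
        )
        return None
    all_vals = np.concatenate(groups)
    grand = all_vals.mean()
    ss_total = float(((all_vals - grand) ** 2).sum())
    ss_between = float(sum(len(x) * (x.mean() - grand) ** 2 for x in groups))
    ss_within = ss_total - ss_between
    df_b = len(groups) - 1
    df_w = len(all_vals) - len(groups)
    if ss_total <= 0 or df_w <= 0:
        logger.info("degenerate values at locus %s; association skipped", locus_id)
        return None
    if ss_within <= 0:
        f_stat, p = np.inf, 0.0
    else:
        f_stat = (ss_between / df_b) / (ss_within / df_w)
        p = float(stats.f.sf(f_stat, df_b, df_w))
    return AssociationResult(
        locus_id=locus_id,
        trait=trait,
        population=population,
        F=float(f_stat),
        p_value=p,
        r_squared=ss_between / ss_total,
        n=len(all_vals),
        significant=p < alpha,
    )


def association_grid(
    pheno: pd.DataFrame,
    g: GenotypeMatrix,
    metadata: pd.DataFrame | None = None,
    population: str = "ALL",
    traits: list[str] | None = None,
    include_het: bool = False,
) -> pd.DataFrame:
    """Locus × trait association matrix of -log10(P) values.

    Cells where the test is skipped (monomorphic locus, too few accessions)
    are NaN.  No multiple-testing correction is applied: every cell holds a
    raw per-test P, as the significance heat-map convention in functional
    marker studies.
    """
    traits = traits or sorted(pheno["trait"].unique())
    grid = pd.DataFrame(np.nan, index=g.locus_ids, columns=traits)
    for trait in traits:
        values = blup_accession_values(pheno, trait)
        for locus in g.locus_ids:
            res = anova_association(
                values, g, locus, trait,
                metadata=metadata, population=population, include_het=include_het,
            )
            if res is not None:
                grid.loc[locus, trait] = res.neg_log10_p
    grid.index.name = "locus_id"
    return grid
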