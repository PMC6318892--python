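"""Improvement-selection scan: two-proportion Z tests on favorable-allele
frequencies between a reference population (landraces) and a test population
(modern cultivars), four-way allele classification, and decade trajectories.

A locus is called *selected* when the frequency difference clears a
-log10(P) threshold (default 1.3, i.e. P < 0.05, with no multiple-testing
correction — every raw per-locus P is compared to the same line).  Loci
nearly fixed in both populations predate improvement selection; loci rare in
both are future breeding targets.  These saturation checks take precedence
over Z significance.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from dataclasses import dataclass

from scipy import stats

from .io import GenotypeMatrix
from .popgen import allele_frequencies

CATEGORY_POSITIVE = "positive_selection"
CATEGORY_NEGATIVE = "negative_selection"
CATEGORY_FIXED = "fixed_pre_improvement"
CATEGORY_FUTURE = "future_target"
CATEGORY_UNCLASSIFIED = "unclassified"

CATEGORIES = (
    CATEGORY_POSITIVE,
    CATEGORY_NEGATIVE,
    CATEGORY_FIXED,
    CATEGORY_FUTURE,
    CATEGORY_UNCLASSIFIED,
)


def two_proportion_z(p1: float, n1: float, p2: float, n2: float) -> tuple[float, float]:
    """Pooled two-proportion Z test (no continuity correction).

    ``n1``/``n2`` are allele counts.  The pooled estimate is
    ``p̂ = (p1 n1 + p2 n2) / (n1 + n2)`` and
    ``z = (p2 - p1) / sqrt(p̂ (1-p̂) (1/n1 + 1/n2))`` with a two-sided normal
    P value.  When the pooled frequency is 0 or 1 (both samples monomorphic
    for the same allele) there is no variation to test: z = 0, P = 1.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("allele counts must be positive")
    if not (0 <= p1 <= 1 and 0 <= p2 <= 1):
        raise ValueError("proportions must lie in [0, 1]")
    pooled = (p1 * n1 + p2 * n2) / (n1 + n2)
    if pooled <= 0.0 or pooled >= 1.0:
        return 0.0, 1.0
    se = np.sqrt(pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n2))
    if se == 0.0:  # pooled variance underflow at extreme frequencies
        return 0.0, 1.0
    z = (p2 - p1) / se
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(max(p, np.nextafter(0, 1)))


def scan_loci(
    freqs: pd.DataFrame,
    ref_pop: str,
    test_pop: str,
    threshold_neg_log10_p: float = 1.3,
) -> pd.DataFrame:
    """Z-test every locus shared by the reference and test populations.

    Returns one row per shared locus (sorted by locus id) with the two
    frequencies, allele counts, z, two-sided P, -log10(P), direction of the
    frequency change and a significance flag at the threshold.
    """
    pops = set(freqs["population"])
    for pop in (ref_pop, test_pop):
        if pop not in pops:
            raise KeyError(f"population {pop!r} not present in frequency table")
    ref = freqs[freqs["population"] == ref_pop].set_index("locus_id")
    test = freqs[freqs["population"] == test_pop].set_index("locus_id")
    shared = sorted(set(ref.index) & set(test.index))
    if not shared:
        raise ValueError(f"no shared loci between {ref_pop!r} and {test_pop!r}")
    rows = []
    for locus in shared:
        p1, n1 = float(ref.loc[locus, "p_fav"]), float(ref.loc[locus, "n_eff"])
        p2, n2 = float(test.loc[locus, "p_fav"]), float(test.loc[locus, "n_eff"])
        z, p = two_proportion_z(p1, n1, p2, n2)
        nlp = float(-np.log10(p))
        if p2 > p1:
            direction = "increase"
        elif p2 < p1:
            direction = "decrease"
        else:
            direction = "none"
        rows.append(
            {
                "locus_id": locus,
                "p_ref": p1,
                "p_test": p2,
                "n_ref": n1,
                "n_test": n2,
                "z": z,
                "p_value": p,
                "neg_log10_p": nlp,
                "direction": direction,
                "significant": nlp >= threshold_neg_log10_p,
            }
        )
    return pd.DataFrame(rows)


def classify_allele_status(
    scan: pd.DataFrame,
    high_thresh: float = 0.90,
    low_thresh: float = 0.15,
) -> pd.DataFrame:
    """Four-way favorable-allele classification of scanned loci.

    ``fixed_pre_improvement``: frequency ≥ ``high_thresh`` in both
    populations; ``future_target``: ≤ ``low_thresh`` in both.  These
    saturation states take precedence over significance.  Otherwise a
    significant increase is ``positive_selection``, a significant decrease
    ``negative_selection``, anything else ``unclassified``.
    """
    out = scan.copy()

    def categorize(row) -> str:
        if row["p_ref"] >= high_thresh and row["p_test"] >= high_thresh:
            return CATEGORY_FIXED
        if row["p_ref"] <= low_thresh and row["p_test"] <= low_thresh:
            return CATEGORY_FUTURE
        if row["significant"] and row["direction"] == "increase":
            return CATEGORY_POSITIVE
        if row["significant"] and row["direction"] == "decrease":
            return CATEGORY_NEGATIVE
        return CATEGORY_UNCLASSIFIED

    out["category"] = out.apply(categorize, axis=1)
    return out


@dataclass
class DecadeTrajectory:
    """Favorable-allele frequency of one locus across release decades."""

    locus_id: str
    decades: list[str]
    p_fav: np.ndarray
    n: np.ndarray
    trend: float  # Spearman rank correlation of frequency vs decade order

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"locus_id": self.locus_id, "decade": self.decades,
             "p_fav": self.p_fav, "n": self.n}
        )


def decade_trajectory(
    g: GenotypeMatrix,
    metadata: pd.DataFrame,
    catalog: pd.DataFrame,
    locus_id: str,
    decade_order: tuple[str, ...] | None = None,
) -> DecadeTrajectory:
    """Per-decade favorable-allele frequency with a monotone-trend statistic.

    Accessions without a decade label are skipped; empty decades are dropped.
    The trend is the Spearman correlation between frequency and decade rank
    (0 when all per-decade frequencies coincide).
    """
    from .io import DECADE_ORDER

    order = decade_order or DECADE_ORDER
    if locus_id not in g.locus_ids:
        raise KeyError(f"locus {locus_id!r} not in genotype matrix")
    meta = metadata[metadata["decade"].isin(order) & (metadata["decade"] != "")]
    if meta.empty:
        raise ValueError("no accession carries a decade label")
    sub = g.subset([a for a in g.accession_ids if a in set(meta["accession_id"])])
    freqs = allele_frequencies(sub, meta, catalog, group_col="decade")
    freqs = freqs[freqs["locus_id"] == locus_id]
    present = [d for d in order if d in set(freqs["population"])]
    f = freqs.set_index("population").loc[present]
    p = f["p_fav"].to_numpy(dtype=float)
    n = f["n_eff"].to_numpy(dtype=float)
    if len(p) < 2 or np.allclose(p, p[0]):
        trend = 0.0
    else:
        trend = float(stats.spearmanr(np.arange(len(p)), p).statistic)
    return DecadeTrajectory(locus_id, present, p, n, trend)


def category_counts(classified: pd.DataFrame) -> dict[str, int]:
    """Count loci per category; counts always sum to the number scanned."""
    counts = {c: 0 for c in CATEGORIES}
    counts.update(classified["category"].value_counts().to_dict())
    return counts
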