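"""Synthetic germplasm panels with the statistical structure the analysis
assumes: subpopulations diverged at a target Fst under the Balding–Nichols
model, decade-structured frequency trajectories at selected loci, and
phenotypes with additive locus effects, environment offsets and residual
noise.

Defaults mirror the shape of a worldwide functional-marker wheat panel:
47 biallelic loci over four trait categories and six subgroups —
landraces (CL, 157), modern cultivars (MCC, 323), North America (153),
CIMMYT (53), Europe (384) and the former USSR (82) — phenotyped in three
year-environments.  Accessions are inbred lines, so heterozygous calls are
rare: two allele draws are forced identical with probability
``inbreeding`` (default 0.95).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import (
    A,
    B,
    DECADE_ORDER,
    HET,
    MISSING,
    TRAIT_CATEGORIES,
    TRAITS,
    GenotypeMatrix,
)

DEFAULT_POPULATIONS = {
    "CL": 157,
    "MCC": 323,
    "North_America": 153,
    "CIMMYT": 53,
    "Europe": 384,
    "former_USSR": 82,
}

POP_COUNTRY = {
    "CL": "China",
    "MCC": "China",
    "North_America": "USA",
    "CIMMYT": "Mexico",
    "Europe": "Italy",
    "former_USSR": "USSR",
}

#: Plausible trait scales (mean, genetic SD^2, residual SD^2) for the eleven
#: agronomic traits: heading/flowering date (days), plant height (cm),
#: tiller and spikelet/kernel counts, 1000-kernel weight (g), kernel
#: dimensions (mm).
DEFAULT_TRAIT_MODELS: dict[str, tuple[float, float, float]] = {
    "HD": (180.0, 9.0, 2.0),
    "FD": (185.0, 9.0, 2.0),
    "PH": (100.0, 100.0, 16.0),
    "ETN": (8.0, 1.5, 0.8),
    "SL": (9.0, 1.0, 0.3),
    "SN": (20.0, 3.0, 1.0),
    "KN": (35.0, 16.0, 6.0),
    "TKW": (40.0, 16.0, 4.0),
    "KL": (6.5, 0.16, 0.04),
    "KW": (3.2, 0.04, 0.01),
    "KT": (3.0, 0.04, 0.01),
}


@dataclass
class SelectedLocus:
    """A locus whose favorable-allele frequency shifts during breeding."""

    locus_index: int
    start_freq: float
    end_freq: float


@dataclass
class TraitEffect:
    """Additive favorable-allele effect of one locus on one trait."""

    trait: str
    locus_index: int
    beta: float


@dataclass
class SimulationConfig:
    """Everything the panel generator needs, seeded once."""

    n_loci: int = 47
    populations: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_POPULATIONS))
    target_fst: float = 0.05
    ancestral_low: float = 0.05
    ancestral_high: float = 0.95
    inbreeding: float = 0.95
    missing_rate: float = 0.0
    selected_loci: list[SelectedLocus] = field(default_factory=list)
    trait_effects: list[TraitEffect] = field(default_factory=list)
    n_environments: int = 3
    env_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.target_fst < 1.0):
            raise ValueError("target_fst must lie in (0, 1)")
        if any(n < 1 for n in self.populations.values()):
            raise ValueError("population sizes must be >= 1")
        for sel in self.selected_loci:
            if not (0 <= sel.locus_index < self.n_loci):
                raise ValueError(f"selected locus index {sel.locus_index} out of range")
        for eff in self.trait_effects:
            if not (0 <= eff.locus_index < self.n_loci):
                raise ValueError(f"effect locus index {eff.locus_index} out of range")


def _draw_calls(freq: float, n: int, inbreeding: float, rng: np.random.Generator) -> np.ndarray:
    """Biallelic calls for ``n`` accessions at favorable frequency ``freq``."""
    a1 = rng.random(n) < freq
    a2 = np.where(rng.random(n) < inbreeding, a1, rng.random(n) < freq)
    calls = np.full(n, HET, dtype=np.int8)
    calls[a1 & a2] = A
    calls[~a1 & ~a2] = B
    return calls


def logistic_trajectory(start: float, end: float, n_steps: int, eps: float = 1e-6) -> np.ndarray:
    """Frequencies along a logistic (logit-linear) curve from start to end."""
    if n_steps < 2:
        raise ValueError("need at least 2 steps")
    lo = np.clip([start, end], eps, 1.0 - eps)
    logits = np.linspace(np.log(lo[0] / (1 - lo[0])), np.log(lo[1] / (1 - lo[1])), n_steps)
    return 1.0 / (1.0 + np.exp(-logits))


def simulate_genotypes_bn(
    cfg: SimulationConfig,
) -> tuple[GenotypeMatrix, pd.DataFrame, pd.DataFrame]:
    """Generate (genotypes, metadata, locus catalog) under Balding–Nichols.

    Per locus an ancestral frequency ``p`` is drawn uniformly on
    ``[ancestral_low, ancestral_high]``; each subpopulation then draws its
    own frequency from ``Beta(p (1-phi)/phi, (1-p)(1-phi)/phi)``, and
    accessions draw two alleles at that frequency (identical with
    probability ``inbreeding``).  ``phi`` is the per-deme divergence
    parameter mapped from ``target_fst`` so that the *measured* multilocus
    Gst of the generated panel has expectation ``target_fst``.  Two layers
    separate the raw Balding–Nichols parameter from the measured Gst:
    (i) total diversity is computed from the mean frequency of the K
    sampled demes rather than the ancestral one, and (ii) finite accession
    counts add binomial sampling noise that the uncorrected Gst estimator
    absorbs.  With ``a_i = (1 + inbreeding) / n_i`` the sampling-variance
    coefficient of deme ``i`` (``n_i`` allele observations) and ``abar``
    their mean, taking expectations per locus gives

        ``E[Gst] = 1 - (1 - phi)(1 - abar) / (1 - phi/K - (1 - phi) abar/K)``

    which is solved for ``phi`` at ``E[Gst] = target_fst``.  For one-allele
    demes sampled exhaustively (``abar = 0``) and K → ∞ this reduces to
    plain Balding–Nichols ``phi = F``.  Loci listed in
    ``selected_loci`` instead follow a logistic decade trajectory: the
    reference population (first in ``populations``) sits at ``start_freq``,
    and the second population's decade bins walk the curve to ``end_freq``.

    All randomness flows from ``cfg.seed``; identical configs give
    byte-identical outputs.
    """
    rng = np.random.default_rng(cfg.seed)
    pops = list(cfg.populations)
    locus_ids = [f"L{j + 1:03d}" for j in range(cfg.n_loci)]
    accession_ids: list[str] = []
    subgroup: list[str] = []
    for pop, size in cfg.populations.items():
        accession_ids.extend(f"{pop}_{i + 1:04d}" for i in range(size))
        subgroup.extend([pop] * size)
    n_total = len(accession_ids)
    sub = np.array(subgroup)

    # decade labels: reference pop (landraces) predates release decades;
    # every other population spreads uniformly over the post-1950 decades
    decades = np.empty(n_total, dtype=object)
    modern_decades = [d for d in DECADE_ORDER if d != "pre-1950s"]
    ref_pop = pops[0]
    for pop in pops:
        mask = sub == pop
        if pop == ref_pop:
            decades[mask] = "pre-1950s"
        else:
            decades[mask] = rng.choice(modern_decades, size=mask.sum())

    f = cfg.target_fst
    k = len(pops)
    # map target Gst -> per-deme Beta parameter, absorbing the finite-deme
    # and finite-sample layers of the estimator (see docstring)
    if k > 1:
        n_alleles = np.array(
            [2 * size * max(1.0 - cfg.missing_rate, 1e-9) for size in cfg.populations.values()]
        )
        abar = float(np.mean((1.0 + cfg.inbreeding) / n_alleles))
        phi = ((1 - abar) - (1 - f) * (1 - abar / k)) / ((1 - abar) * (1 - (1 - f) / k))
        phi = float(np.clip(phi, 1e-9, 1 - 1e-9))
    else:
        phi = f
    ancestral = rng.uniform(cfg.ancestral_low, cfg.ancestral_high, size=cfg.n_loci)
    calls = np.empty((n_total, cfg.n_loci), dtype=np.int8)
    selected = {s.locus_index: s for s in cfg.selected_loci}
    test_pop = pops[1] if len(pops) > 1 else None

    for j in range(cfg.n_loci):
        sel = selected.get(j)
        for pop in pops:
            mask = sub == pop
            n_pop = int(mask.sum())
            if sel is not None and pop == ref_pop:
                calls[mask, j] = _draw_calls(sel.start_freq, n_pop, cfg.inbreeding, rng)
            elif sel is not None and pop == test_pop:
                # walk the logistic trajectory decade bin by decade bin
                traj = logistic_trajectory(sel.start_freq, sel.end_freq, len(modern_decades))
                pop_calls = np.empty(n_pop, dtype=np.int8)
                pop_dec = decades[mask]
                for di, dec in enumerate(modern_decades):
                    dmask = pop_dec == dec
                    if dmask.any():
                        pop_calls[dmask] = _draw_calls(
                            traj[di], int(dmask.sum()), cfg.inbreeding, rng
                        )
                calls[mask, j] = pop_calls
            else:
                p_pop = rng.beta(
                    ancestral[j] * (1 - phi) / phi, (1 - ancestral[j]) * (1 - phi) / phi
                )
                calls[mask, j] = _draw_calls(p_pop, n_pop, cfg.inbreeding, rng)

    if cfg.missing_rate > 0:
        drop = rng.random(calls.shape) < cfg.missing_rate
        calls[drop] = MISSING

    g = GenotypeMatrix(accession_ids, locus_ids, calls)
    metadata = pd.DataFrame(
        {
            "accession_id": accession_ids,
            "subgroup": subgroup,
            "country": [POP_COUNTRY.get(p, "unknown") for p in subgroup],
            "decade": decades,
        }
    )
    catalog = pd.DataFrame(
        {
            "locus_id": locus_ids,
            "gene_name": [f"gene{j + 1}" for j in range(cfg.n_loci)],
            "trait_category": [TRAIT_CATEGORIES[j % 4] for j in range(cfg.n_loci)],
            "favorable_allele": ["A"] * cfg.n_loci,
        }
    )
    return g, metadata, catalog


def simulate_breeding_trajectory(
    cfg: SimulationConfig,
    locus_id: str,
    start_freq: float,
    end_freq: float,
    decades: list[str],
    n_per_decade: int,
    seed: int | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Decade-labelled calls at one locus along a logistic frequency curve.

    Returns ``(frame, true_freqs)`` where the frame has one row per
    accession (``accession_id``, ``decade``, ``call``) and ``true_freqs``
    holds the per-decade generating frequencies.
    """
    if len(decades) < 2:
        raise ValueError("need at least 2 decades")
    if n_per_decade < 1:
        raise ValueError("empty decade bins")
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    traj = logistic_trajectory(start_freq, end_freq, len(decades))
    rows = []
    for di, dec in enumerate(decades):
        calls = _draw_calls(traj[di], n_per_decade, cfg.inbreeding, rng)
        for i, call in enumerate(calls):
            rows.append((f"{dec}_{i + 1:04d}", dec, int(call)))
    frame = pd.DataFrame(rows, columns=["accession_id", "decade", "call"])
    frame["locus_id"] = locus_id
    return frame, traj


def simulate_phenotypes(
    cfg: SimulationConfig,
    g: GenotypeMatrix,
    catalog: pd.DataFrame,
    trait_models: dict[str, tuple[float, float, float]] | None = None,
) -> pd.DataFrame:
    """Phenotypes with additive locus effects, accession effects, fixed
    environment offsets and residual noise.

    ``y_ite = mu_t + sum_L beta_L * dosage_iL + g_i + env_e + eps_ite`` with
    ``g_i ~ N(0, s2_g)``, one fixed offset per environment drawn once from
    ``N(0, env_sd^2)``, and ``eps ~ N(0, s2_e)``.  Returns the long-format
    phenotype table.
    """
    models = trait_models or DEFAULT_TRAIT_MODELS
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 7]))
    fav = dict(zip(catalog["locus_id"], catalog["favorable_allele"]))
    dosage = g.dosage(fav).to_numpy()
    dosage = np.nan_to_num(dosage, nan=0.5)
    envs = [f"env{e + 1}" for e in range(cfg.n_environments)]
    effects: dict[str, list[TraitEffect]] = {}
    for eff in cfg.trait_effects:
        effects.setdefault(eff.trait, []).append(eff)

    frames = []
    for trait in TRAITS:
        if trait not in models:
            continue
        mu, s2_g, s2_e = models[trait]
        g_i = rng.normal(0.0, np.sqrt(s2_g), size=g.n_accessions)
        env_off = rng.normal(0.0, cfg.env_sd, size=cfg.n_environments)
        locus_part = np.zeros(g.n_accessions)
        for eff in effects.get(trait, []):
            locus_part += eff.beta * dosage[:, eff.locus_index]
        base = mu + locus_part + g_i
        for e, env in enumerate(envs):
            eps = rng.normal(0.0, np.sqrt(s2_e), size=g.n_accessions)
            frames.append(
                pd.DataFrame(
                    {
                        "accession_id": g.accession_ids,
                        "trait": trait,
                        "environment": env,
                        "value": base + env_off[e] + eps,
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)
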