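# Methods

This note records the statistical model behind each `germscan` component,
the defaults and why they were chosen, what the synthetic panels do and do
not emulate, and the numerical conventions that make runs reproducible.

## Data model

A panel is an accession × locus grid of biallelic calls
`{A, B, HET, MISSING}`, the call vocabulary of fluorescence-based
allele-specific assays (KASP and kin) on functional SNP/InDel markers.
Every locus carries a declared *favorable allele* — the allele associated
with the breeding-desirable phenotype — and all frequency-based statistics
are oriented on it.  Accessions carry a subgroup (e.g. Chinese landraces
CL, modern Chinese cultivars MCC, introduced regional groups), a country,
and optionally a release decade from the ordered set
pre-1950s … 2000s; accessions without a decade (landraces predate release
registration) are simply skipped by decade-stratified analyses.

Allele counting treats each accession as diploid: a non-missing call
contributes two allele observations, a heterozygote one of each.  Wheat
accessions are inbred lines and HET calls are rare, so this degrades
gracefully to line counting while staying correct when residual
heterozygosity exists.

## Diversity and divergence

*Gene diversity* is Nei's expected heterozygosity, `H = 1 − p² − (1−p)²`
per biallelic locus (bounded by 0.5), summarized per population as the
unweighted mean across loci — no locus weighting is implied by the
frequency table, and the unweighted mean is the reproducible default.

*Nei's standard genetic distance* between frequency vectors x, y over L
loci uses the mean gene identities `J_x = mean(Σ x_k²)`,
`J_y = mean(Σ y_k²)`, `J_xy = mean(Σ x_k y_k)` and
`D = −ln(J_xy/√(J_x J_y))`.  Disjoint allele sets (`J_xy = 0`) yield an
infinite-distance flag rather than an exception; individual-level
distances treat each accession as a population of one (dosage 1/0.5/0) and
restrict each pair to the loci where both accessions have calls.

*Fst* is Nei's Gst with no sample-size correction, aggregated over loci as
`1 − ΣH_S / ΣH_T` where per locus `H_S` is the unweighted mean
within-population diversity and `H_T` the diversity of the unweighted mean
frequency vector; loci with `H_T = 0` drop out, and an entirely
monomorphic panel returns NaN.  *Gene flow* uses the diploid island-model
constant: `N_m = 0.25 (1 − F_ST)/F_ST`, infinite at `F_ST = 0`.  The
uncorrected Gst form is the one classic population-genetics packages
report and is what keeps `N_m(0.05) = 4.75` exactly reproducible.

Not implemented by design: PIC, rarefied allelic richness, AMOVA and
Weir–Cockerham variance-component Fst.

## Neighbor joining and PCA

Neighbor joining follows the Saitou–Nei agglomeration: select the pair
minimizing `Q(i,j) = (n−2) d(i,j) − r_i − r_j`, assign branch lengths
`l_i = d/2 + (r_i − r_j)/(2(n−2))`, collapse, repeat; the final three
nodes join a single internal vertex by the three-point formulas.  Two
conventions the algorithm itself does not fix:

- **Tie-breaking** in the Q minimum is lexicographic on the sorted pair of
  subtree labels (each subtree keyed by its smallest leaf label), making
  output identical across platforms and input orders.
- **Negative branch lengths** are clamped to zero with the deficit shifted
  to the sister branch — the common readability convention — unless
  `allow_negative_branches` preserves exactness.

On additive matrices the reconstruction is exact (property-tested against
randomly generated trees and cross-checked against scikit-bio's NJ).
Newick output writes branch lengths at 6 decimals and single-quotes labels
containing reserved characters.

"PCA" of genotypes is an eigendecomposition of the covariance of
favorable-allele dosage (1 / 0.5 / 0), with missing calls mean-imputed per
locus before centering so they contribute nothing to the covariance.
This is equivalent to principal coordinates on squared-Euclidean distances
of the same coding; field usage blurs the PCA/PCoA distinction and the
dosage-PCA choice is documented rather than asserted as canonical.
Components beyond the matrix rank are truncated with a warning.

## Selection scan

The scan compares favorable-allele frequencies between a reference
population (landraces) and a test population (modern cultivars) with a
pooled two-proportion Z test on allele counts:
`p̂ = (p₁n₁ + p₂n₂)/(n₁+n₂)`,
`z = (p₂ − p₁)/√(p̂(1−p̂)(1/n₁ + 1/n₂))`, two-sided normal P.  No
continuity correction is applied (the textbook pooled form).  A locus
monomorphic across both populations has nothing to test: z = 0, P = 1.
Significance is judged against `−log10(P) ≥ 1.3` (P < 0.05) with **no
multiple-testing correction** — each locus is a pre-specified candidate
gene, not one point of a dense genome scan; a Bonferroni option exists
downstream but is off by default.

Classification is a total function with saturation taking precedence over
significance: frequency ≥ 0.90 in both groups → *fixed pre-improvement*;
≤ 0.15 in both → *future target*; otherwise a significant
increase/decrease → *positive/negative selection*; else *unclassified*.
The 0.90/0.15 thresholds are conventions of this package (qualitative
category descriptions in the literature give no numbers); both are
configurable.  Decade trajectories report the per-decade favorable
frequency plus a Spearman rank correlation of frequency against decade
order (defined as 0 when all frequencies coincide, where the rank
correlation itself is degenerate).

## Phenotype statistics

**Accession values.**  Multi-environment trait values are reduced to one
value per accession by a closed-form shrinkage estimator: environment
(year) means are removed first (fixed effects by centering, grand mean
restored), then a one-way random-accession model
`y_ij = μ + g_i + e_ij` is fitted by method-of-moments from the ANOVA
table — `σ̂²_e = MS_within`, `σ̂²_g = (MS_between − MS_within)/r̄` with the
unbalanced-design effective replicate number
`r̄ = (N − Σr_i²/N)/(a−1)`, clamped at zero — and each accession mean is
shrunk as `BLUP_i = μ + k_i(ȳ_i − μ)`, `k_i = σ̂²_g/(σ̂²_g + σ̂²_e/r_i)`.
With no residual variance this is the plain mean; with no genetic variance
everything collapses to μ; shrinkage never expands
(`|BLUP_i − μ| ≤ |ȳ_i − μ|`).  A full mixed-model engine (REML with
arbitrary random terms) is deliberately out of scope; the closed form is
transparent, fast, and its gap to a general mixed model is confined to
strongly unbalanced multi-trial designs.

**Binning and Shannon-Weaver diversity.**  Values are split into 10
classes around the mean: class 1 below `X − 2σ`, class 10 at or above
`X + 2σ`, classes 2–9 half-open `0.5σ` intervals between (boundary values
join the upper class — a determinism convention).  `σ = 0` sends all
accessions to the central class 6 with a warning.  Diversity is
`H = −Σ_{P_i>0} P_i ln P_i` over the class proportions of a population:
0 when one class holds everything, `ln 10 ≈ 2.3026` at uniform occupancy.

**Association.**  One-way fixed-effects ANOVA of the accession value on
the two allele classes at a locus; HET and MISSING calls are excluded by
default (HET is rare in inbred lines; an option adds HET as a third
class).  Reported per test: F, P from the F(k−1, N−k) tail,
`R² = SS_between/SS_total`, and a significance flag at raw P < 0.05 — the
same no-correction convention as the scan, stated in the outputs.
Monomorphic or underpowered loci (a class with < 2 accessions) are skipped
with a reason rather than forced.

The two-group trait comparison uses Welch's t by default (robust to
unequal variances and group sizes); `equal_var=True` restores the pooled
test.

## Synthetic panels

The generator emulates the statistical structure of a worldwide
functional-marker wheat collection; defaults mirror that shape: 47 loci
over the four trait categories, subgroups CL = 157, MCC = 323,
North America = 153, CIMMYT = 53, Europe = 384, former USSR = 82 (1152
accessions), three year-environments, inbreeding 0.95 (the probability an
accession's two allele draws are forced identical), missingness 0 by
default.

**Divergence.**  Per locus an ancestral frequency is drawn uniformly on
[0.05, 0.95]; each subpopulation draws its frequency from the
Balding–Nichols Beta distribution with per-deme parameter φ.  `target_fst`
is defined as the *measured* multilocus Gst of the generated panel, so φ
is solved from the expectation of the estimator, which differs from φ for
two reasons: with K sampled demes the total diversity uses their mean
frequency (a (K−1)/K effect), and finite accession samples add binomial
variance that the uncorrected Gst absorbs.  With
`a_i = (1+inbreeding)/n_i` and `ā` their mean,

```
E[Gst] = 1 − (1−φ)(1−ā) / (1 − φ/K − (1−φ) ā/K)
```

is inverted at `E[Gst] = target_fst`.  This is an expectation-level
calibration fixed before any data are drawn; it makes the generator's
parameter mean what its name says.

**Selection trajectories.**  A selected locus holds the reference
population at its start frequency while the test population's decade bins
walk a logistic (logit-linear) curve from start to end frequency —
matching the sigmoidal adoption pattern of favorable alleles under
sustained directional selection.  Note the test population's *overall*
frequency is the average along the curve, so the realized scan contrast is
smaller than `end − start`.

**Phenotypes.**  `y_ite = μ_t + Σ_L β_L·dosage_iL + g_i + env_e + ε_ite`
with accession effects `g_i ~ N(0, σ²_g)`, one fixed offset per
environment drawn once from `N(0, env_sd²)`, and i.i.d. residuals.  Trait
scales (means, variance components) are set to agronomically plausible
values for the eleven traits (days for heading/flowering, cm for plant
height, g for 1000-kernel weight, mm for kernel dimensions, counts for
tillers/spikelets/kernels).

**What the generator does not emulate** — and hence what passing tests do
not show about real panels: linkage between loci (loci are independent, as
a per-gene candidate analysis assumes), pedigree and family structure
within subgroups, admixture/introgression gradients, genotype ×
environment interaction, ascertainment bias of marker panels, and
non-random missingness.  Conclusions about those features need real data.

## Numerical conventions and problem sizes

- Frequencies validated to 1e−9; NJ additivity asserted to 1e−9; PCA
  variance conservation to 1e−8; zero-distance detection at 1e−12.
- All randomness flows from a single integer seed through
  `numpy.random.default_rng`; identical seeds give byte-identical outputs,
  and the pipeline report embeds the config hash + seed.
- The pipeline builds its NJ tree at subgroup level by default;
  individual-level distances and trees are available
  (`tree_level="individual"`) but cubic-time NJ on panels of a thousand
  accessions is a deliberate opt-in.
- Simulation-based checks in the test suite and acceptance script use 500
  loci for divergence recovery, 1000 loci for scan calibration, 100 random
  trees for NJ, and 200 replicates for power, R² recovery and BLUP error
  comparisons — sizes chosen so each check's Monte-Carlo error is well
  inside the asserted tolerance.

## Known limitations

- The BLUP stand-in is a one-way random-accession model, not a general
  REML mixed model; with strong unbalance or genotype × environment
  interaction the two diverge.
- Gst carries no sample-size correction, so very small subgroups bias it
  upward; the generator's calibration accounts for this in simulation but
  real small-sample panels inherit the bias.
- The scan's raw-P convention reflects candidate-gene practice; users
  scanning many more loci should enable the correction option.
- Association is plain one-way ANOVA without kinship or structure
  correction; in structured panels P values are anti-conservative and
  should be read as descriptive, population-stratified screens (the
  population filter exists precisely to run CL and MCC separately).
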