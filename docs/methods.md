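# Methods

This note documents the models, estimators and numerical choices behind
`woodpool`, and what the synthetic data can and cannot show about real
surveys.

## Dead-wood item model

Every dead-wood item carries one recorded diameter (at 1.3 m for standing
dead wood, top diameter for stumps, basal diameter for downed wood), a
length or height, and a bark-cover fraction.  Volume and surface area use a
**cylinder model**: V = π(d/200)²·L m³ and lateral area π(d/100)·L m²,
split by the bark fraction into bark and bark-free area.  With a single
diameter per item no taper model is identifiable; the cylinder is the
standard single-measurement convention and keeps all three amount measures
(volume, bark area, bark-free area) mutually consistent.

Substrate classes follow the field definitions: FWD 1–10 cm diameter;
stumps and snags standing with diameter > 10 cm, separated at 50 cm height;
logs lying with diameter > 10 cm.  The I/O layer enforces these bounds row
by row and reports offending rows.

## Amount estimation

FWD, stumps and snags: plot-based density, total measure divided by
surveyed plot area (0.1 ha of small circular plots and a 0.2 ha snag plot
per stand by default).  Logs: **line-intersect sampling** on 400 m of
transect per stand.  Volume uses Van Wagner's estimator V = π²Σd²/(8L)
(d cm, L m, V m³/ha); other per-item attributes use the general expansion
Σ π·yᵢ/(2·lᵢ·L)·10⁴, which reduces to the volume formula when yᵢ is the
cylinder volume.  The estimator's unbiasedness is verified by Monte-Carlo
simulation of logs dropped on a torus-wrapped field (the wrap removes edge
effects, making the estimator exactly unbiased in the simulation).

## Landscape weighting and weighted t tests

Sampled stands are unequal representatives of the landscape: stand *s* of
type *k* receives weight w_s = (A_k/ΣA)/n_k, with A_k the landscape area of
type *k* and n_k the number of sampled stands of that type.  Class means
renormalize weights to sum to one; the error bars use
SE = √(Σw²(x−x̄_w)²), the plug-in standard error of a weighted sum of
independent stand estimates.

The managed/unmanaged comparison is a **Welch-type t test on weighted
moments**: weights are rescaled to sum to the group size, weighted mean and
weighted sample variance (denominator Σw−1) are formed, and the Welch
statistic with Satterthwaite degrees of freedom is evaluated.  Under unit
weights this reduces exactly to the classical Welch test (tested against
scipy).  The convention (effective n = stand count) is one of several
defensible weighted-variance conventions and is documented rather than
claimed to be uniquely correct.  The twelve per-tree-species tests are
corrected with Holm's sequential Bonferroni (step-down: p_(i) vs
α/(m−i+1)); the four substrate-level tests address distinct hypotheses and
stay unadjusted.  Managed stands older than 100 years are excluded by
default (older than a rotation, unrepresentative of current management),
plus any explicitly blacklisted stands.

## Rarefaction

Sample-based rarefaction with dead-wood items (bark samples for beetles) as
units, computed analytically: E[S_m] = Σᵢ(1 − C(n−Yᵢ,m)/C(n,m)), with
binomial coefficients in log space (gammaln) for numerical stability; the
residual error of the log-space evaluation is below ~1e-6 species.
Confidence bands are **percentile bootstrap over sampling units** (200
replicates by default) — a deliberate, assumption-light choice in place of
any package's analytic variance, and documented as such.  Bands are clipped
to contain the analytic point estimate.

For lichens and beetles the unit axis is rescaled by the mean per-unit
habitat measure (bark-free/bark area), putting substrates on a common
surveyed-amount axis; fungal drill samples are one per item regardless of
item size, so fungi stay on the item-count axis.  The cross-substrate
comparison interpolates each curve at a standard amount — by default the
largest surveyed amount of the smallest substrate, mirroring the
standardize-to-minimum logic of the density analysis — and reports
Kendall's τ between rarefied richness and the unmanaged per-ha amount of
each substrate.  With four substrates τ is a coarse summary; it is reported
with its tied-value caveat (NaN when all richness values tie).

## Habitat quality (relative densities)

Taxon-specific densities: fungi, proportion of surveyed items occupied;
lichens, cover per surveyed bark-free area; beetles, individuals per
sampled bark area.  Survey effort differs by orders of magnitude between
substrates, so densities are computed on **effort-standardized subsamples**:
the substrate with the smallest total effort (item count for fungi, area
for lichens/beetles) is the base; each other substrate is subsampled 20
times and densities averaged.  Subsampling draws whole sampling units
without replacement until the target effort is first reached or exceeded,
and divides by the realized effort — drawing protocol and
with-replacement variant are config-exposed since either is defensible.
Per species the four mean densities are normalized to sum to one; species
with fewer than five occurrences (an occurrence = one item with the species
present, counted on the full pre-subsampling data for filter stability) are
dropped first.  The per-substrate **quality score** is the column sum of
this matrix: equal weight per species, total equal to the species count.

Differences among substrates are tested with the Kruskal–Wallis rank-sum
test (scipy's tie-corrected implementation; verified against a hand
fixture, H = 7.2, p ≈ 0.0273, and a brute-force tie-correction
transcription) and **Dunn's post hoc z tests**,
z_ij = (R̄_i−R̄_j)/√((N(N+1)/12 − Σ(t³−t)/(12(N−1)))(1/nᵢ+1/nⱼ)),
implemented in-package (no environment package provides it) with unadjusted
two-sided p values by default and an optional Holm flag.  Species are the
replicates throughout; relative densities of one species are not
independent across substrates (they sum to one), which the rank tests
tolerate better than parametric alternatives but do not eliminate — a known
limitation inherited from the analysis design.

## Composition

Morisita–Horn similarity
C = 2Σxᵢyᵢ/((Σxᵢ²/X² + Σyᵢ²/Y²)·X·Y) on per-substrate density profiles:
scale-invariant, 1 iff identical relative profiles, 0 iff disjoint.
PermANOVA runs on the 1−C distance matrix with the standard
pseudo-F = (SS_between/(g−1))/(SS_within/(N−g)) computed from squared
distances, p = (#{F* ≥ F}+1)/(n_perm+1) over label permutations (999 by
default), switching to exhaustive enumeration of distinct relabelings when
that is cheaper — then the p value is exact with the identity included.
Replication for the substrate test comes from computing community vectors
per stand-type × tree-species × substrate cell and grouping cells by
substrate; this replication unit is a modelling choice (config-exposed via
the stratification columns), and results should be read conditional on it.
Pseudo-F is verified to match classical one-way ANOVA F on univariate
Euclidean fixtures to 1e-10 relative error, and cross-checked against
scikit-bio's PERMANOVA; type-I error is calibrated on 1,000 null
simulations.

## Synthetic landscape generator

The generator emulates a stratified survey of a managed boreal landscape:
four stand types (clearcut, young, old, unmanaged; 12 sampled stands each
by default), three tree species (pine/spruce/birch at a 45/40/15 mix),
lognormal stand areas, and landscape-type areas of 2,100/7,100/8,400/2,650
ha (unmanaged ≈ 13% of the forested area).  Item counts are Poisson with
intensities encoding the management asymmetry — stumps and FWD concentrated
in clearcuts and young stands, logs and snags in unmanaged stands; the
direction is empirically motivated, the absolute rates are this package's
own "realistic boreal" choices.  Diameters and lengths are truncated
lognormals within the class bounds; bark fractions are Beta distributed.

Each species has a Dirichlet substrate preference (concentration 0.5:
moderately specialist), a tree-species bias, and a lognormal overall
abundance.  The observation intensity per item is
λ = base_rate·abundance·4·pref[dw]·3·bias[tree]; fungi and lichens are
detected with probability 1−e^(−λ) (lichens then receive a Beta cover
fraction of the item's bark-free area, guaranteeing cover ≤ available
area), and beetle counts per bark sample are negative binomial with mean
λ·area and dispersion k = 1.  `true_relative_densities` computes the exact
relative-density rows implied by this model (mixing over each substrate's
expected tree-species composition), which is what the parameter-recovery
tests check against.  Per-taxon abundance distributions are **placeholders**
— no empirical abundance data back them — and are labelled as such here.

Random streams for stands, items, affinities and each taxon are split
separately from the master seed, so enlarging a species pool never perturbs
the item table; all pipeline randomness descends from one seed and CSV
outputs are byte-identical across reruns.

What passing tests show: the estimators are unbiased/consistent and the
pipeline is deterministic *under this generative model* — independent
Bernoulli/NB observations, no spatial autocorrelation, no decay dynamics,
no detection covariance between species, communities surveyed on every
item.  Real surveys violate all of these to some degree; the tests validate
the statistical machinery, not ecological conclusions about any real
landscape.

## Problem sizes and defaults

| Parameter | Default | Why |
|---|---|---|
| stands per type | 12 | tens of stands per management class, typical of stratified stand surveys |
| transect length | 400 m/stand | four 100 m lines |
| plot areas | 0.1 ha (FWD/stumps), 0.2 ha (snags) | 10×100 m² circular plots; 10 m buffer on transects |
| subsamples | 20 | effort standardization; variance of the subsample mean shrinks ~1/k |
| occurrence filter | ≥ 5 | below this, substrate distribution of a species is too uncertain |
| bootstrap replicates | 200 | band quantiles stable at ~1% of richness |
| permutations | 999 | p floor 0.001; exhaustive mode when cheaper |

Validation experiments run at sizes chosen for tight Monte-Carlo error:
line-intersect calibration uses 400 fixed logs × 500 random placements;
PermANOVA type-I uses 1,000 simulations × 199 permutations; parameter
recovery uses 20 replicates of a 24-stand landscape (estimator bias from
the ratio-and-normalize step decays ~1/n and is negligible against the
Monte-Carlo SE at this size).

## Known limitations

- The weighted-variance/df convention of the weighted t test is one
  defensible choice; alternatives (e.g. design-effect effective n) would
  change borderline p values.
- Kendall's τ over four substrates takes only 25 distinct values; it is a
  direction summary, not a test.
- The PermANOVA replication unit (stand-type × tree-species cells) is an
  analysis choice; per-stand or per-item replication would give different
  power and p values.
- No spatial structure, decay classes, snag-fall or temporal dynamics in
  the generator; no coverage-based rarefaction or richness extrapolation.
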