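# Methods

`snailguild` implements a comparative life-history analysis for a guild
of trematode parasitic castrators that share a single snail host. A
castrator takes over its host's body, so selection on the allocation of
the stolen body to growth versus reproduction acts on the castrator,
not the host. With several castrator species operating the same host
phenotype in the same environment, the guild supports a cross-species
test of a core life-history prediction: groups facing higher extrinsic
mortality should allocate less to growth and more to current
reproduction. The package provides the full chain — shell-geometry
growth quantification, an overdispersed Poisson growth model, a
dominance-hierarchy mortality estimator, reproductive-allocation
indices, and the comparative inference layer — together with a
synthetic-data generator carrying exact ground truth.

## Shell geometry

Each marked snail contributes initial and final shell length/width (mm,
0.1 mm resolution) and the degrees of new coiling around the columellar
axis. New-growth volume is the aperture area — a circle of radius one
quarter the (final) shell width — swept through degrees/360. Degrees
above 360 denote more than one new whorl and are not reduced. Initial
shell volume is approximated by a cone; the cone's base is taken over
the full basal width (radius = width/2), the natural reading of the
approximation, and is the module's one open geometric choice (it cancels
from any cross-group comparison, since all groups share the host
morphology). Shell length and volume interconvert through a cube-root
scaling relation, volume^(1/3) = 0.326·length + 0.497 by default,
refittable by OLS on any (length, volume) sample. Note a small internal
tension of the printed relation: inverting it at the mean-sized snail
volume 705 mm³ gives 25.78 mm, slightly below the conventionally quoted
~25.9 mm; the package does not force these to agree.

## Growth model

Observed individual growth (mm³) is strongly overdispersed — many
snails grow little or nothing, a few grow a great deal — so the model
is a log-link GLM with Poisson variance inflated by a multiplicative
dispersion φ (quasi-Poisson). Point estimates equal Poisson ML;
φ is estimated as Pearson χ²/df and scales all covariances. The
negative-binomial family would be an alternative; quasi-Poisson is the
default because the generator's gamma-mixed Poisson has exactly the
variance = φ·mean structure the quasi-likelihood assumes.

The design is: group (castrator species or uninfected gender) ×
initial volume, estuary, habitat nested in estuary, site nested in
(estuary, habitat), and growing time nested in estuary, all fixed
factors with treatment coding (alphabetically first level as
reference; nesting as within-cell dummies). Nesting reproduces the
standard df decomposition — with 17 sites in 3 estuaries and one
two-habitat estuary: estuary 2, habitat[estuary] 1,
site[estuary, habitat] 13, growing time[estuary] 2. Per-term tests are
quasi-likelihood-ratio χ²: the deviance difference of nested refits
divided by the full-model dispersion.

Derived quantities are standardized to a reference site and the first
growing period (configurable; default the baseline levels):

* **growth curve** per group: exp(linear predictor) along initial
  volume, evaluable over the pooled sampled size range;
* **growth at the mean-sized snail**: a single curve evaluation
  (default at the mean initial volume of retained records);
* **total growth allocation**: the definite integral of the curve
  between common limits — the across-group means of per-group minimum
  and maximum sizes — by adaptive quadrature (abs. tolerance 1e-8 of
  the integrand scale);
* **pairwise contrasts**: all C(k,2) differences of linear predictors
  at one size, Wald z on the log scale (the nested site/time terms
  cancel), with Benjamini–Hochberg control at FDR 0.05 alongside the
  nominal 0.05 calls.

A proportional-growth response (growth/initial volume) is a
response-column switch, not a separate model.

## Differential extrinsic mortality

Within a host, dominant trematode species kill subordinates, so
observed infections are survivors. For a focal species at one site, let
p be its prevalence among snails free of *its* dominants (not free of
all trematodes — the focal's recruitment is undisturbed there), D the
number of snails carrying at least one dominant, and C the observed
focal-with-dominant co-infections. Then expected co-recruits E = pD,
kills K = E − C, total recruits R = (observed focal among
dominant-free) + E, and site mortality is K/R. Negative values are
retained: they indicate co-occurrence above independent expectation
(facilitation, e.g. a tissue refuge). Sites with an empty dominant-free
subset or no recruits are skipped with a warning, never zero-filled.
Per-site values pool by a mean weighted with the focal's observed site
prevalence (weights normalized within species across its sites; site
sample size is deliberately not folded in, since the per-site estimates
are already proportions).

The hierarchy is a strict, acyclic, not-necessarily-transitive
relation; tolerated pairs are expressed by omitting edges. For
uninfected snails the analogue is castration risk: the gender-specific
trematode prevalence, averaged unweighted across sites (a
size-weighted option exists). Gender susceptibility is tested by a
binomial GLM of infection on gender controlling for site, growing time
and size, with a 1-df likelihood-ratio χ².

## Allocation indices

The gonadosomatic index (GSI) is reproductive tissue mass over total
mass; for a castrator, trematode tissue mass over infected-snail mass.
The combined female GSI adds accessory reproductive tissue (pallial
gonoduct, ovipositor) to the ovary fraction, errors combining in
quadrature. Relative reproductive allocation (RRA) divides the GSI by
the proportional allocation to growth at the mean-sized snail, which
reduces algebraically to reproductive mass over new-growth mass; both
routes are computed and asserted equal. Volume becomes mass through a
density constant (default 1 mg/mm³) — the module's main free constant,
which cancels from RRA itself. GSI and RRA need not agree: a group can
rank high on standing-stock GSI and low on RRA once its growth is
factored in, and the test suite includes such a configuration.

## Comparative inference

Correlations are tested by permutation: observed Pearson r against the
null from permuting one variable, two-tailed,
p = (1 + #{|r_perm| ≥ |r_obs|})/(B + 1) with B = 100,000 by default
(never exactly zero). SMA lines summarize bivariate scatter
(slope = sign(r)·sd(y)/sd(x)); regression through the origin
(slope = Σxy/Σx², df = n−1) complements the contrast-level
correlations. The plasticity check asks whether groups grow less at
sites where their local risk (prevalence of their dominants; overall
prevalence for uninfected snails) is higher: a linear model of site-
mean growth on group plus per-group risk slopes, with the joint F over
all risk slopes.

**Two-stage guard (a reconstruction).** Because growth sits in the RRA
denominator, a strong negative growth–mortality correlation can alone
manufacture a positive RRA–mortality correlation. The guard permutes
the growth values across groups, rebuilds pseudo-RRAs from the fixed
GSIs, and correlates them with the unpermuted mortality vector; the
observed correlation is compared two-tailed to this compound null. The
published analysis this mirrors described such a guard only in outline;
the scheme here is this package's own formulation, targeted at exactly
the denominator artifact, and is documented as such rather than
asserted to match the original.

## Independent contrasts

Tip traits on a rooted, fully bifurcating tree with unit branch lengths
(reflecting ignorance of evolutionary rates along these lineages) are
converted to n−1 standardized contrasts by the classic pruning pass:
contrast (x_i − x_j)/√(v_i + v_j), ancestral value the 1/v-weighted
mean, parent branch extended by v_i·v_j/(v_i + v_j). Polytomies are
rejected rather than silently resolved — with unit branches an
arbitrary resolution changes the contrasts. The uninfected genders
enter as sister tips, an acknowledged non-independence carried for
comparability, not corrected. Contrast-level correlation fixes the sign
convention by making each x-contrast positive. The bundled ten-tip
Newick is an illustrative synthetic topology, not a published tree.

## Record filters

The exclusion chain, first matching rule wins: surviving mixed-species
infections (original infection status uncertain); records with
undetermined initial size, gender or infection status; flagged outliers
(default rule: |Studentized deviance residual| > 4 from a preliminary
fit, recorded in the run manifest); then species retained with ≤ 20
individuals — strictly more than 20 are required, because small samples
underestimate the mean of overdispersed data; the boundary case n = 20
is excluded and unit-tested. Uninfected groups are never rare-dropped.
The filter report conserves counts by construction (asserted in the
dataclass).

## Synthetic worlds

The generator is first-class, tested code and defines the study
conditions. Default world: 17 sites in 3 estuaries (one estuary with a
second, poorer "pan" habitat), ~120 snails per site, growing periods of
94 days everywhere plus 154 days in the two southern estuaries,
reference standardization 105 days (3.5 months). Each snail
independently acquires each species at the site's configured prevalence
(0.01–0.15 by default); within a host every species dominated by a
co-recruit is removed; two or more survivors make a mixed infection.
Independence of recruitment is exactly the assumption the mortality
estimator leans on, so the realized kill fractions are its estimand by
construction. The default hierarchy is a linear order with two
deliberate decouplings of rank from mortality: a tissue-refuge species
killed only by the top rank, and a spatial-refuge species recruiting
mostly at four dominant-poor sites.

Growth is drawn as a Poisson count mixed over a gamma mean
(variance = φ·mean, default φ = 4, so the quasi-Poisson analysis is
correctly specified), with mean exp(intercept + slope·initial volume +
site effect)·(days/105). Default growth at the mean-sized snail
(705 mm³) spans 9–32 mm³ across groups, ordered inversely to expected
mortality, with uninfected snails slowest — the built-in negative
growth–mortality coupling. Default GSIs (0.146–0.28) rise gently with
expected mortality, giving a positive reproduction–mortality coupling
beyond the denominator artifact. Per-species castrator GSIs have no
in-package empirical source and are free generator parameters. Shell
measurements are back-computed from drawn volumes through the cone and
aperture geometry (width = 0.39·length) and rounded to 0.1 mm.

What the generator does **not** emulate: multi-clone same-species
infections, temporal recruitment dynamics, snail movement, size- or
season-dependent infection risk, and measurement error beyond rounding.
Passing tests therefore certify the estimators and the inference chain
under the stated assumptions — independent recruitment, multiplicative
site effects, log-linear size dependence — not robustness to their
violation in field data.

## Problem sizes and numerical choices

The stochastic suites run at deliberately chosen desk sizes: estimator
recovery at 2,000 snails/site (3 sites, two species); coefficient
coverage over 100 seeds per dispersion level (φ ∈ {1, 4}, ~700 snails
each), requiring ≥ 90% coverage of 95% Wald bands and mean dispersion
within 10%; null calibration over 500 seeds at B = 2,000 permutations
(a scaled-down stand-in for the production default B = 100,000, whose
only effect is the attainable p floor); end-to-end sign recovery over
15 seeds at ~2,040 snails each. Ties in permutation counts are broken
conservatively (|r_perm| ≥ |r_obs| − 1e-12 counts as extreme).
Quadrature tolerance is 1e-8 relative to the integrand scale; singular
designs are reported with the first aliased column named; degenerate
GLM starts fall back to a flat-mean initialization.

## Known limitations

The mortality estimator assumes independent recruitment; real guilds
with spatial covariance of recruitment will bias it (the sign of the
bias is the sign of the covariance). The RRA's numerator is
standing-stock tissue mass, not an allocation rate. The two-stage guard
is a reconstruction (above). The quasi-Poisson treatment models only
the first two moments; heavier-tailed growth would widen the
dispersion's sampling error without biasing coefficients. Site effects
are fixed, not random — appropriate for controlling site variation, not
for generalizing to unsampled sites.
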