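# Methods

## Data model

The unit of analysis is the species × site × era × interval detection
datum.  Sites are square cells of a configurable size (default
100 × 100 km) on a spherical Albers equal-area conic projection
(standard parallels 20° N and 60° N, origin 40° N 96° W, authalic
radius 6 371 007.2 m).  The spherical rather than ellipsoidal form
keeps the transform dependency-free; the area distortion it introduces
is far below one cell at every modelled latitude.  Cell membership is
half-open (`[edge, edge + size)`), so every point belongs to exactly
one cell.  Years 1901–2020 partition into six 20-year eras and four
5-year intervals per era; both bin edges follow the same half-open
convention.

Record-level cleaning keeps rows with parseable coordinates and a
4-digit year, inside a configurable North America polygon (default a
generous continental bounding box), in 1901–2020, excluding
*B. cockerelli* and *B. kluanensis* (poor coverage / newly described).
Duplicates are unique on (species, coordinates rounded to 1e-6°, date
— the full ISO date when present, else the year — observer).  The
1e-6° rounding (≈0.1 m) only collapses floating-point noise; any real
georeferencing difference survives.

Site retention (default) requires records in ≥2 eras and, in at least
one era, records in ≥2 distinct intervals.  Because a "visit" is
defined by the site's own records, the two candidate readings of the
multiple-interval clause (records in ≥2 intervals vs ≥2 visited
intervals) are provably identical, so no switch is exposed.  The
strict variant requires ≥5 records in *every* era.  Retention runs on
raw per-site tallies before range hulls are traced, so hulls use
retained sites only; each species' range is the convex hull of its
occupied site centroids in projected coordinates, boundary counted as
inside, with a fallback to exactly the occupied sites when fewer than
three non-collinear sites exist.

Non-detections are inferred: any record of any species marks the
site-interval as visited, and every other in-range species gets a zero
there.  Missingness is carried as a boolean mask, never a sentinel, so
the likelihood cannot silently read an unvisited interval as a zero.

## Covariates

Temperature and precipitation are era means of monthly values over the
climate cells overlapping a site, cells weighted equally (no partial
area weighting; at 100 km resolution the within-site gradient is small
against the across-site signal).  The floral-resource score FR is
built in three steps: seasonal expert scores per crop class are
area-averaged into land-use-category scores using an overlap table;
seasons (spring, summer, autumn) are summed; each site × era gets the
composition-weighted mean of category totals.  The category score
table is era-invariant — temporal FR variation comes only from
land-use composition change.

All three predictors are z-scored with the population standard
deviation over the modelled site × era set, and the constants are
stored so derived quantities (thermal optimum) can be reported in °C.
The era index in the Era model is z-scored the same way, which puts
`mu_psi_era` on a scale comparable to the environmental slopes.

## Model and priors

Occupancy and detection are as in the README.  The supplement
specifying the original priors is not distributed with the paper's main
text, so the package declares its own weakly informative defaults, all
configurable: Normal(0, 2.5²) for community means, the detection
intercept, the era fixed effect and the community quadratic;
half-Normal(0, 1.5²) for community sds and the detection random-effect
sd; the species intercepts are themselves hierarchical
(`alpha_i ~ Normal(mu_alpha, sigma_alpha²)`).  On the logit scale these
admit essentially any plausible occupancy/detection surface while
regularizing the tails.  Posterior agreement with the published
estimates is therefore expected in sign and interval overlap rather
than digit-for-digit.

Detection probability is constant across the four intervals within a
site-era, so each species × site-era history enters through its
sufficient statistics (d detections out of V visited intervals); the
latent occupancy state is marginalized analytically.  Species
detection intercepts are off by default but available as a flag.

## Inference

The sampler is a self-contained No-U-Turn sampler: multinomial
proposal over the doubling trajectory, dual-averaging step-size
adaptation (target acceptance 0.8), diagonal mass-matrix estimation in
expanding warmup windows, divergence threshold 1000 on the Hamiltonian
error.  Species coefficients and the detection random effect are
non-centered; sds are log-transformed with the Jacobian included.
Gradients of the marginalized log-posterior are analytic and fully
vectorized: writing W for the per-history posterior occupancy
probability, `d logL / d logit-psi = W - psi` and
`d logL / d logit-p = W (d - V p)`, which the tests verify against
finite differences.  Random effects for unvisited site-eras carry no
information and are dropped from the parameter vector.

Draws from ≥2 chains feed arviz for split R-hat and effective sample
size; `fit()` warns above R-hat 1.05.  Runs are bitwise reproducible
given the seed (chains use spawned child seeds).

Numerical choices: logistic quantities go through `log_expit` to avoid
underflow; the degenerate-history branch uses `logaddexp`; a
non-finite log-density at initialization raises with a parameter dump;
thermal-optimum draws with a non-concave temperature response
(psi_temp2 ≥ 0) are excluded and counted, and an all-convex posterior
is an error rather than a silent NaN.

## Counterfactuals

Per posterior draw, a species' occupancy change is the unweighted mean
over its in-range sites of psi(last era) − psi(first era).  "Held
constant at its mean" pins the covariate at the per-site across-era
mean — removing temporal change while preserving spatial gradients,
which isolates exactly the temporal signal being decomposed; a
global-mean alternative is a config switch.  The quadratic temperature
term stays in the evaluated surface.  Classification uses the paired
per-draw difference D = delta_actual − delta_held (both axes of the
published-style scatter carry posterior uncertainty; pairing draws is
the interpretation implemented): BCI of D covering zero → unaffected;
otherwise a full sign flip of the two marginal BCIs → winner-to-loser
or loser-to-winner; otherwise affected by the sign of mean(D).

## Synthetic data

The generator mirrors the model's own data-generating process plus the
features of aggregated occurrence data the analysis must survive:
spatial covariate gradients (temperature 5–25 °C across sites), linear
era drifts calibrated to the observed century-scale changes
(+0.83 °C, +0.36 kg m⁻² month⁻¹, −0.04 FR first→last era), species
coefficients drawn around community means, Bernoulli occupancy and
detection, and a visit process whose per-era probabilities rise from
0.10 to 0.80 — reproducing the strong recency bias of museum data.
Detection defaults p0 = −0.5, sigma_p = 0.75 yield ≈2 visits and a few
detections per site-era, matching the effort statistics of the real
compiled dataset.  Default experiment scale is 20 species × 150 sites
× 6 eras × 4 intervals — large enough that the community
hyperparameters are identifiable, small enough to refit in minutes on
one CPU; calibration-style checks (interval coverage across replicates)
run at 8 species × 30 sites.

What the generator does not emulate: spatial autocorrelation of
detections, taxonomic misidentification, within-interval effort
heterogeneity, and non-exogenous visits (real visits are defined by the
records themselves; simulated visits are exogenous draws).  Passing
recovery tests therefore demonstrate correctness of the estimator under
the model's assumptions, not robustness to their violation.

## Known limitations

* Occupancy is static within an era; no colonization/extinction
  dynamics, no spatial autocorrelation.
* The floral score inherits the coarseness of expert, all-bee scores
  aggregated to 100 km / 20 yr; weak or puzzling floral effects are
  expected.
* Range hulls are convex and era-invariant: range shifts express as
  occupancy change inside a fixed candidate set.
* The era model and environmental model answer related but different
  questions; the environmental model's temporal signal is entirely
  mediated by the three covariates, so missing drivers surface as a
  mean offset between the two models' implied trends.
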