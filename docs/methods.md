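# Methods

`petrelmig` reconstructs, end to end, the analysis chain used to quantify
individual consistency in the migrations of a tropical pelagic seabird
tracked with light-level geolocators (GLS): raw light / immersion / SST
series → position estimation → behavioural segmentation → migration
phenology → spatial and spatiotemporal similarity → repeatability and GLM
inference. Because the real tracking data are access-restricted, the package
ships a synthetic-population generator with known ground truth, so every
stage can be validated by parameter recovery.

## Geolocation

**Threshold method.** A twilight is the time the light curve crosses a
threshold (4 for low-range tags, 1 for full-range tags). Longitude follows
from the equation-of-time-corrected midpoint of a sunrise–sunset pair
(local solar noon), latitude from the day length given the solar declination
and a zenith angle. The solar ephemeris is the standard low-precision
algorithm (declination and equation of time accurate to ≪ 0.01° over
1950–2050). Because tags store the *maximum* light per 10-minute bin, a
sample represents its whole bin; crossings are therefore interpolated
between bin midpoints, which removes an otherwise systematic one-bin timing
bias. Near equinoxes day length is ~12 h at every latitude; such positions
are flagged and imputed from neighbours in the initial track only — the
refined track resolves them through the movement and SST models.

**Zenith calibration.** The tag-specific zenith angle is estimated from a
3–5-day window at a known location. Two estimators are provided: the median
rule (zenith that zeroes the median observed-minus-predicted twilight
discrepancy; appropriate when calibration twilights are unshaded) and a
maximum-likelihood estimator under a log-normal shading model
(meanlog 2.2, sdlog 1.0 log-minutes), which corrects the bias that
one-sided shading otherwise folds into the zenith. The pipeline uses the
median rule because the simulator renders the calibration window with the
tag exposed; the MLE is the right tool when calibration data are shaded.

**Bayesian refinement.** One position is estimated per twilight event by
Metropolis-within-Gibbs sampling of the posterior combining:

* *twilight model* — one-sided shading error (sunrise only late, sunset only
  early), log-normal in minutes with meanlog 2.2, sdlog 1.0 by default;
* *movement model* — gamma(shape 2.0, rate 0.1) prior on great-circle speed
  (km/h) between consecutive positions;
* *spatial mask* — probability zero on land. The mask is rasterised at 0.2°
  for the sampler; positions outside the rasterised study window
  (20°W–160°E, 65°S–45°N) also count as excluded;
* *SST likelihood* — Gaussian (default SD 1.0 °C) between the daily median
  tag temperature and the gridded weekly 1°×1° field, bilinear in space and
  nearest in week. The SD is deliberately wider than the tag noise
  (0.3 °C) to absorb field mismatch.

Sampling details that the original description leaves open were fixed as
follows. Checkerboard (odd/even) site updates are used because only adjacent
positions interact through the speed prior, making each parity conditionally
independent. Longitude and latitude are updated in separate sub-steps with
*per-site* proposal scales adapted during burn-in to ~30 % acceptance
(Robbins–Monro on the log scale): twilight timing pins longitude tightly
everywhere, while latitude can be nearly flat near equinoxes or on days when
a dry tag records no SST, so the two coordinates need very different step
sizes — often an order of magnitude apart. A heavy-tailed proposal mixture
(15 % of proposals at 4× scale) and random block-translation moves (a
contiguous window of positions shifted jointly) cross the wide, weakly
identified latitude basins that single-site moves traverse too slowly.

The schedule follows the standard design: 2000 burn-in sweeps under a
relaxed model (speed-prior rate halved; mask and one-sided twilight support
softened to penalties), then three runs of 300 retained draws to check
split-chain R̂ < 1.1 on every site's longitude and latitude, then 4 chains ×
3000 retained samples. The convergence draws are thinned in proportion to
track length (longer tracks mix more slowly); a failed check doubles the
span and redraws, and a track that still fails after the configured restarts
raises an error — the population pipeline treats such a track like a failed
deployment (excluded, logged). Positions during the calibration window are
pinned at the known colony, the standard way of anchoring known-location
periods. The initial state comes from the threshold track, shifted east
(sunrise) / west (sunset) by the prior median shading delay so that it lies
inside the one-sided twilight support. Tracks are summarised per twilight
epoch by the componentwise median and 2.5/97.5 percentiles.

The production schedule is used for single-track work; population runs use a
reduced preset (500 burn-in, 3 × 150 convergence draws, 2 × 750 retained),
chosen so a ~270-day deployment refines in tens of seconds on one CPU. The
posterior summaries of the two schedules agree to well within the
geolocator error scale.

## Behavioural segmentation

Three daily features separate colony attendance from migration: the
proportion of daylight light samples below the tag's interference threshold
(64 low-range / 100 full-range) — high when a sitting bird shades the tag;
the daily sum of 10-minute wet counts — near zero ashore; and the WGS84
geodesic distance (Vincenty) from the day's mean median position to the
colony. The daylight window is that day's detected twilights shrunk by a
30-minute margin ("core daylight hours" is not precisely defined anywhere;
the margin avoids counting the twilight transition itself as interference
and is configurable).

The two-state HMM emits, conditionally on state, Gaussian colony distance,
Gaussian wet sum (support mismatch for a bounded count accepted as is) and
binomial interference counts with the day's daylight samples as trials.
Fitting is Baum–Welch EM (relative log-likelihood tolerance 1e-6, ≤ 500
iterations) with seeded random restarts; Gaussian features are standardised
internally for numerics, and missing features are marginalised out of the
emission density rather than imputed. The state with the smaller mean colony
distance is canonicalised as "ashore", making the fit invariant to restart
order and label switching. One model is fitted per deployment.

A migration bout is a maximal run of at-sea days of at least 90 days
("three months" fixed at 90, configurable) bounded by ashore days; runs
truncated by the record edges are flagged partial and excluded from
phenology. Departure is the first at-sea day, arrival the first ashore day
after the run, so duration = arrival − departure by construction.

## Calendar conventions

The annual calendar starts 1 June (day 1), when colony activity is minimal;
a petrel year has 365 or 366 days according to whether it contains a 29
February. For repeated events of one individual that straddle the origin,
dates are converted to signed days (day 364 → −1) choosing the encoding
with the smaller spread; ties keep the positive encoding. Seasons follow
the monsoon circulation: May–September is austral winter, October–April
summer, classified by the event's calendar month.

## Similarity

**EMD.** The earth mover's distance between two migrations is the exact
optimal-transport cost between their twice-daily median location sets
(uniform weights — position uncertainty is not used as a weight) with
great-circle ground distance (sphere radius 6371 km). The transportation
problem is solved exactly by an in-package primal transportation simplex
(north-west-corner start, block pricing over reduced costs, incremental
dual updates on the smaller cut side), JIT-compiled and validated against a
`scipy.optimize.linprog` oracle; equal-size uniform instances take the
linear-assignment fast path. Typical full-resolution pairs (~350 × 350)
solve in ~50 ms, so all-pairs matrices over a few dozen tracks cost
seconds to minutes.

**Kernel UDs and BA.** Utilisation distributions are Gaussian-kernel
surfaces with a fixed 200-km bandwidth — chosen to absorb geolocator
precision error, not to estimate a home range — evaluated on 50-km cells of
a Lambert azimuthal equal-area plane centred on the data (one shared centre
per analysis; pairwise grids span the union extent plus a 3-bandwidth
margin). Bhattacharyya's affinity Σ√(p·q) ranges from 0 (disjoint) to 1
(identical) and carries no information about how far apart non-overlapping
distributions are — which is exactly the contrast with EMD the analysis
exploits.

**Stages and periods.** Spatiotemporal similarity compares matched parts of
the same individual's migrations: consecutive 30-day *periods* from
departure (trailing remainder dropped, truncated to the shorter migration)
or six *stages* of equal duration covering the whole bout (balanced
partition; when the duration is not divisible by six the longer blocks come
first — an arbitrary but fixed and configurable tie-break). Stage/period
EMD is computed within individuals only; whole-migration EMD and BA for all
track pairs. The departure-difference covariate is the absolute circular
difference of annual departure timing in days (symmetry of unordered pairs
forces the absolute value).

## Statistics

**Repeatability.** R = σ²_among/(σ²_among + σ²_residual) from a Gaussian
random-intercept model fitted by REML. The variance ratio is profiled
analytically, leaving a one-dimensional optimisation — this makes the
1000-refit parametric bootstrap (simulate from the fitted model, refit,
2.5/97.5 percentiles) and the coverage simulations cheap. The p-value is a
maximum-likelihood LRT of the among-individual variance against the
boundary null, referred to the ½χ²₀ + ½χ²₁ mixture. On balanced data the
REML estimate coincides with the one-way ANOVA ICC closed form, which the
tests verify to 1e-6.

**GLMs.** The suite implements IRLS for gaussian, gamma and binomial
families with identity, log and logit links. Gamma models use the Pearson
dispersion estimator; the identity-link gamma (EMD models: effects additive
in km on a positive, right-skewed response) is guarded by step-halving that
keeps fitted means positive and enforces deviance non-increase (the
oscillation guard matters for the non-canonical log-link binomial used for
BA values, which are continuous proportions treated quasi-binomially).
Backwards stepwise deletion removes the least significant term with
p ≥ 0.05, testing deletions by analysis of deviance (F with estimated
dispersion for gamma/gaussian, χ² for binomial) and respecting marginality
(interactions leave before their main effects). Pairwise level contrasts
use estimated marginal means — covariates at their means or a supplied
value (the stage/period contrasts are evaluated at the median departure
difference), other factors averaged with equal weights — with familywise
Tukey adjustment via the studentized range distribution.

**Seasonal variability.** Per-individual ranges (days between earliest and
latest signed event dates, separately for departures and arrivals) are
computed for individuals whose events all fall in one season (≥ 2 events;
zero ranges are set to 0.5 d to stay inside the gamma support) and
modelled by gamma/log GLMs with season as a fixed effect. The correlation
between individuals' departure and arrival ranges is the product-moment
correlation with t = r√(df/(1−r²)), df = n−2.

## Synthetic data generator

The generator defines the study conditions under which everything is
tested. Each individual draws a latent mean departure day
μ_i ~ N(100, 48²) (days from 1 June); its realised departure in year y is
N(μ_i, 25²), giving a true departure repeatability of 48²/(48²+25²) ≈ 0.787
by construction — matching the study-scale estimate. Durations are
N(175, 28²) clipped to [104, 256] d. The population has 62 individuals
with mostly two (occasionally three or four) tracked years.

Destinations are five mid-ocean centroids spanning the basin (Somali Basin,
Arabian Sea, central Indian Ocean, Bay of Bengal, Western Australian
Basin); each individual's home destination adds an individual offset
(SD 250 km) and is reused across years with probability 0.9 (plus ~100 km
of year-to-year jitter), producing within-individual spatial consistency
against large between-individual variation. Movement is waypoint travel
along the great circle at 20 km/h for 12 h/day with Ornstein–Uhlenbeck-style
residency around the destination, rejected against the land mask — enough
to generate realistic EMD/BA structure without claiming a behavioural
model; at-sea behaviour is deliberately homogeneous (no foraging/transit
sub-structure).

The observation model renders raw series: light rises/falls at the true
solar twilights delayed (sunrise) or advanced (sunset) by log-normal
shading draws with meanlog 2.2, sdlog 1.0 — i.e. the data are generated
under the analysis' own error model by default (set `twilight_sdlog=0` for
a mis-specification-free configuration, or change the parameters for a
mis-specified one); daytime samples are shaded below the interference
threshold with probability 0.9 ashore vs 0.1 at sea; wet counts are
binomial per 10-minute interval (rate 0.01 ashore, 0.5 at sea); SST is
sampled six times per at-sea day at the true position plus N(0, 0.3 °C)
noise. The first four days (the calibration window) are rendered clean,
emulating an exposed tag at the colony.

The synthetic SST field has the dominant real-basin structure on the real
product's grid layout (weekly means, 1° × 1°): nearly flat through the
tropics and steepening toward the southern subtropics (so SST carries
little latitude information near the equator and a lot in the south), a
weak north-warm linear tilt (0.12 °C/° — the enclosed northern basins run
warmer than the open southern subtropics at equal |lat|, which keeps SST
informative about the hemisphere), an opposite-phase seasonal cycle across
the equator (amplitude 2 °C) and a weak zonal harmonic. The built-in land
mask is a set of coarse continental polygons (east Africa/Arabia, India,
Indochina–Sunda, Borneo, Australia, Madagascar, and the Eurasian interior
band) adequate at geolocator resolution; user GeoJSON overrides it.

**What passing tests do and do not show.** The simulator produces data that
match the analysis' structural assumptions (log-normal one-sided twilight
errors, state-homogeneous feature distributions, a smooth SST field).
Recovery under these conditions validates the implementation and the
identifiability of the design, not robustness to the many ways real tags
misbehave (sensor drift, weather-dependent shading, behaviour-dependent
twilight error, SST fronts). The mis-specification toggles exist precisely
so such robustness questions can be asked, but no claim about real-data
performance follows from the shipped tests.

## Problem sizes used by the test suite and acceptance script

All checks run on one CPU. The suite uses reduced but structurally
faithful sizes chosen by compute budget: the full production MCMC schedule
is exercised on a 30-day track; the population pipeline on 6–10 individuals
× 2 years; EMD throughput on a 12–30-track all-pairs matrix at ~350 points
per track; repeatability calibration on 50–120 replicates of the 76 × 2–3
study design (bootstrap CIs at 200 draws in the coverage loop, 1000
elsewhere); phenology recovery on 50 feature-level bouts. The acceptance
script (`scripts/acceptance.py`) recomputes the same quantities from
scratch at these sizes and writes them as JSON.

## Known limitations

* The mask raster (0.2°) and the coarse polygon coastlines limit how close
  to shore positions can be meaningfully constrained.
* Latitude remains weakly identified for dry-tag (ashore) periods near
  equinoxes; the sampler mixes across the wide basin rather than
  pretending precision, and a track whose chains still disagree is dropped
  like a failed deployment rather than summarised badly.
* The gamma identity-link similarity models can be infeasible for extreme
  tables; the model-reduction helpers fall back to smaller term sets rather
  than failing the whole analysis.
* EMD instances beyond ~500 points per side get slow (transportation
  simplex is ~O(n² ) per pivot set); thin the tracks first if needed.
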