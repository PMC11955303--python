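# Methods

`catchassoc` infers aggregation behaviour — and distinguishes its social
and non-social drivers — from tabular catch records of the kind produced
by fisheries-independent gillnet surveys of juvenile sharks. This note
documents the statistical machinery, the simulator that stands in for
field data during validation, the numerical choices, and the limits of
what the package's own tests demonstrate.

## Co-occurrence events

Under the gambit of the group, individuals recorded in the same sampling
event are treated as associating. Two temporal scales are built from the
same records:

* **deployment scale** — one event per (site, date, set number): the
  grouping available from any fishing report;
* **simultaneous scale** — within a deployment, maximal greedy
  left-to-right time windows over per-individual capture times
  (minute resolution). With the default tolerance of 0 minutes this is
  exact-timestamp grouping; a positive tolerance absorbs clock coarseness.
  The greedy convention (window anchored at the earliest unassigned
  capture) is deterministic, with record-ID tie-breaks. Note that greedy
  windows are *not* monotone in tolerance — a wider window can pull a
  capture away from its later companions — but identical timestamps are
  never split, so the tolerance-0 pairs survive at every tolerance.

Interval summaries (first-to-last span, consecutive gaps) are computed
over multi-shark deployments with timed captures; deployments soaking
longer than 20 h (night-fishing pilots) are excluded from interval
reporting only, never from the metric or model stages.

## The five metrics

1. **Catch size** — event-size histogram and the prevalence of
   multi-individual events (n ≥ 2, the standard aggregation threshold).
2. **Trait composition** — per-event sex ratio (males / sexed members;
   0 = all female, 1 = all male) and fork-length range
   (max FL − min FL, mm; "size variance" in the field's usage), with a
   square-root transform downstream against right skew.
3. **Drivers** — site fidelity of recaptures, plus the regression stage's
   site/month terms.
4. **Individual identity** — recapture accounting: a *recapture event* is
   any capture of a tagged individual after its first; it counts as
   *recaptured together* iff a co-member of the current event shared an
   earlier event with the focal individual. The dyad-level view (distinct
   pairs sharing ≥ 2 events) is reported alongside.
5. **Kin structure** — sibship among co-captured (or recaptured-together)
   dyads against a pre-computed pairwise kinship table; pairs absent from
   the table count as unknown and leave the assessed denominator.

Unsexed and unmeasured members are excluded from the respective metric but
still count toward event size.

## Permutation null models

Three seeded Monte-Carlo tests, each reporting the add-one p-value
p = (r + 1)/(n + 1). Defaults: 10 000 replicates (validation experiments
use 200; the p-grid at 200 replicates is fine enough for α = 0.05); swap
chains use burn-in = 10 × (number of ones) and thinning = number of ones,
counting attempted swaps.

**Aggregation.** Statistic: prevalence of multi-individual events
(`mean_size_nonempty` selectable). Null: each individual assigned
independently and uniformly to one event. Two refinements matter in
survey data, and both are exact conditioning arguments rather than
corrections:

* *Strata.* Site-faithful juveniles and the 94% parturition-season effort
  weighting mean a pooled uniform null is wrong by construction —
  independent individuals restricted to their own site's events collide
  more often than uniform scattering predicts. The pipeline therefore
  assigns within site × season × (peak/off-peak) strata; capture intensity
  is homogeneous within these cells. With a single stratum the test
  reduces to the plain uniform null.
* *Occupancy conditioning.* Catch-defined events exist only because
  something was caught. Given *which* deployments were nonempty,
  independent attendance at equal within-stratum rates yields exactly the
  uniform assignment conditioned on every event receiving ≥ 1 individual
  — regardless of how many further deployments caught nothing. The
  conditioned law is sampled exactly via surjection counts (computed as
  exact integers by inclusion–exclusion), cell by cell.

**Trait assortment.** Statistics: for sex, the mean per-event imbalance
|males − females| / members (direction greater; the pipeline's choice —
its null has no coarse lattice) or the classic single-sex event fraction
(the function's default, whose lattice of event-count fractions makes the
add-one p-value tie-conservative at realistic survey sizes); for fork
length, the mean within-event range (direction less). Null: trait labels
permuted across *individuals* — a
recaptured individual's slots carry one canonical value (its first
observed) and move together, since a slot-level shuffle would destroy
within-individual correlation and overstate significance under heavy
recapture. Permutation is confined to strata defined by the individual's
first-capture season-month: fork length drifts with growth and sex
composition can shift seasonally, and pooled permutation would read
either drift as assortment. Within-event tilt — the actual signature of
trait-based grouping — remains fully detectable.

**Companion preference.** Statistic: the repeated-pair count
Σ_d C(x_d, 2) over dyads, where x_d is the number of events dyad d
shares. The more readable count of distinct dyads with x_d ≥ 2 is
available (`statistic="repeat_dyads"`), but it saturates — and can even
fall *below* its null mean — when stable companionship concentrates
repeats on few dyads, which is exactly the pattern persistent pairs or
littermate groups produce; the repeated-pair count is a concentration
measure and retains power there. Null: checkerboard (2×2) swaps on the
binary events-by-individuals incidence, preserving all row and column
totals; rejected proposals count as self-loops, so the stationary law is
uniform over the connected fixed-margin set. Chains run within
site × season blocks (cross-site swaps would place site-faithful
juveniles in events they could never attend), and columns for
once-captured individuals are dropped (they cannot form repeat dyads;
conditioning on the reduced margins is the corresponding exact
statement).

## Regression stage

Two models per temporal scale over multi-shark events:

* sex ratio: binomial (males, females) counts;
* √(size range): Gaussian, variance-weighted by event shark count.

Structure: smooth terms (cubic B-splines) for total shark number and
year, month categorical (reference month October, season start), site as
per-site intercept offsets standing in for a penalized random intercept.
Basis dimension is capped at 5 (year has ~10 levels at most); predictors
with fewer than 5 distinct values drop to linear terms, centred on the
range midpoint (invariant to row weighting); constant predictors are
dropped. The binomial model fits via `statsmodels` GLMGam with a mild
curvature penalty (α = 1), which contains quasi-separation along sparse
basis directions; the weighted Gaussian model takes the basis as plain
GLM columns (no separation pathology arises there). Coefficient
covariance and effective degrees of freedom are computed in-package from
the weighted Fisher information, cov = (XᵀWX + S)⁻¹XᵀWX(XᵀWX + S)⁻¹·φ and
edf = diag[(XᵀWX + S)⁻¹XᵀWX], with W carrying binomial trial counts or
the variance weights — quantities the backend's own summaries do not
propagate for these model forms.

Each full model is compared with its intercept-only null by a
generalized likelihood-ratio test: deviance difference (scaled by the
dispersion estimate for the Gaussian response) against χ² with the
effective-dimension difference as df. The outlier-sensitivity rerun
removes the largest mixed-sex event with the most extreme sex ratio
(configurable rule; ambiguity is an error listing candidates) and reports
the sign of the shark-number partial-response trend under both fits.

Exact coefficients, R² and edf are smoothing-engine-dependent and are not
reproduction targets; term significance and partial-response signs are
the contract.

## Classification

Rules, applied to the metric summaries and test results at α = 0.05
(single-threshold; the metrics are treated as converging lines of
evidence, not a joint test family — a documented limitation):

1. *Aggregation supported* iff the aggregation test is significant OR
   multi-capture prevalence ≥ 0.5 ("most events multi-individual" — the
   descriptive route; it is also what flags cross-site environmental
   concentration, which the site-conditioned test deliberately cannot
   see).
2. *Specific social* iff the companion test is significant.
3. *Non-specific social* iff an assortment (or externally supplied kin)
   test is significant without companion significance.
4. *Non-social* otherwise, iff site/temporal structure dominates: site
   fidelity ≥ 0.9 or significant site/month model terms.
5. *Undetermined* when aggregation is supported but no driver line fires;
   conflicting signals are logged.

Precedence specific > non-specific > non-social encodes the increasing
evidence each typology level requires. Kin summaries are reported but do
not trigger rule 3 by themselves: litters share natal nurseries, so
sibling co-capture arises by chance under purely spatial drivers, and no
kin-specific permutation test is built in (one can be supplied under
`null_results["kin"]`).

## The simulator

The generator emulates the survey that motivates the package: 10 nursery
sites around a reef island sampled twice per month at dusk (17:00–20:00)
across October–April seasons, 94% of capture intensity in the
October–February parturition peak, 6 litters per site-season of 3–5 pups,
sex ratio 0.5 at birth, fork lengths uniform on 392–792 mm growing at
individual rates of 0.1–0.4 mm/day, complete site fidelity, and permanent
per-deployment dispersal/mortality hazard of 0.01. Capture probability
per present individual per deployment is the scenario's density knob.

Scenario structure (effect-size defaults in parentheses):

* `solitary` — independent attendance at capture probability 0.035,
  i.e. expected catch ≈ 0.85/deployment and expected multi-capture
  prevalence ≈ 0.36 under independence: co-occurrence happens but carries
  no driver.
* `non_social_env` — two high-quality sites (attendance ×4) against
  depressed ordinary sites (×0.15), chosen so that ≥ 70% of expected
  multi-capture mass sits at the good sites and pooled prevalence lands
  in the case-study-like 0.6–0.7 regime.
* `non_specific_social_sex` / `_size` — each deployment draws a latent
  trait tilt (a favoured sex, strength 0.7; or a fork-length centre with
  80 mm bandwidth): assortment without identity.
* `specific_social` — persistent random pairs within site-cohorts; a
  captured individual recruits its partner with probability θ = 0.8, and
  recruited partners share the recruiter's capture minute with
  probability θ (the generative analogue of simultaneous capture).
* `kin_structured` — littermates as the companion set (same θ).
* `seasonal_sex` — in October, male odds ×3 with expected event size
  unchanged (male attendance ×2b/(1+b), female ×2/(1+b)): a pure
  composition effect for the regression stage to recover.

What the simulator does **not** emulate: burst arrivals of sharks at the
net (capture times are uniform over the soak, so simulated capture spans
are longer than a field median of tens of minutes), tides and lunar
phase, gear selectivity and saturation, tag loss, and measurement error
in fork length. Passing validation therefore shows the *inference* is
calibrated and powered under the survey's sampling structure — not that
any particular field dataset satisfies the tests' assumptions.

## Validation experiments and problem sizes

All experiments are seeded, derive per-replicate seeds from one base seed,
and run on a few-site, one-to-two-season survey footprint so hundreds of
replicates complete in minutes:

* **Type-I calibration** — 1000 solitary datasets at 4 sites × 2 seasons
  × capture probability 0.25: dense enough that all three test statistics
  have non-degenerate nulls (at sparse densities the companion statistic
  is identically zero and its p-value identically 1, which is
  conservative but uninformative about calibration). Each test's
  rejection rate at α = 0.05 is required to sit at 5% ± 2 points.
* **Scenario recovery** — 100 seeded runs per scenario (3 sites × 1
  season; 5 sites where the scenario needs them): the classifier must
  return the generating scenario's verdict ≥ 80% of the time for the
  solitary, environmental, and specific-social scenarios, with
  opposite-branch (social vs non-social) misroutes ≤ 10%.
* **Seasonal structure** — the October–February capture fraction averages
  0.94 (± 0.03 over 50 seeds) by construction of the month weights; the
  slight upward pull comes from within-season attrition thinning the
  late off-peak months.
* **Regression stage** — the October composition skew is recovered as a
  positive, significant October coefficient and a significant full-vs-null
  LRT in ≥ 80–90% of seeded runs; no-effect data reject the LRT at ≤ the
  nominal rate; removing a constructed extreme event (a large, heavily
  female catch appended to weak-male-trend data) reverses the fitted
  shark-number trend and is flagged.

Size assortment is the weakest line of evidence at survey densities: the
within-month stratified permutation pays for its calibration with power,
and the size-assorted scenario is recovered in only roughly half of
small-footprint runs (misroutes land in the non-social branch). This
mirrors the general experience that event-level size-range signals are
ambiguous, and is the main reason the classifier treats assortment as one
converging line rather than a gate.

## Known limitations

* The single-verdict output simplifies a typology whose categories need
  not be mutually exclusive; all per-metric support flags are retained in
  the ledger so mixed regimes stay visible.
* No multiplicity correction across the test battery (documented choice);
  with three tests at α = 0.05 the social branch fires spuriously in
  roughly 15% of purely environmental datasets (1 − 0.95³ ≈ 0.14), so a
  single non-social survey has a sizeable chance of one spurious social
  line of evidence — converging evidence across surveys, not one verdict,
  is the intended reading.
* The aggregation test conditions on site, so purely cross-site
  concentration reaches the verdict only through the descriptive
  prevalence gate and the model stage's site terms.
* Clock resolution behind "simultaneous" is assumed to be one minute;
  the tolerance parameter exists because field clocks are coarser than
  capture dynamics.
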