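# Methods

## Experimental design being modelled

decaylab analyses destructive-sampling decay experiments: every specimen
decays undisturbed in its own sealed container and is dissected exactly once,
at one day of a logarithmically spaced sampling schedule (dense early, when
decay is fast; sparse late). At dissection each anatomical character is
scored with a 3-state condition code — pristine (0), decaying (1), lost (2) —
and characters carry a body-region label from the closed set {anterior,
trunk, limbs, posterior, internal}. A character that could not be assessed
on a specimen is marked `not_scored` and excluded from aggregation. Because
sampling is destructive, successive days observe *different* specimens, so
aggregated trajectories need not be monotone; the `is_monotone` flag on an
aggregated series reports this rather than forcing monotonicity.

## Ordinal aggregation and milestones

Specimen conditions for one character on one day pool into a 5-state ordinal
condition: 0 if all specimens are pristine; 1 if some are decaying but none
lost and some pristine remain; 2 if all are decaying-or-worse with none
lost; 3 if some but not all are lost; 4 if all are lost. Milestone times are
the **first sampled day at which the series reaches at least** each state
(1 → onset of decay, 2 → complete decay, 3 → onset of loss, 4 → complete
loss). Using "at least" means a series that jumps a state between samplings
still yields the skipped milestone. A milestone never reached is *censored*
and represented as +inf, which automatically sorts after every finite day.

## Decay ranks

Characters are ordered most decay-prone → most decay-resistant by the key
tuple (complete loss, onset of loss, complete decay, onset of decay): the
primary criterion is the timing of complete loss, with ties broken by each
subsequent key in turn. Censored values sort last at every level, and a
censored-vs-censored comparison at one level falls through to the next.
Characters tied on the full tuple receive midranks, so ranks always sum to
n(n+1)/2 and are invariant to input order. Rank dominance holds by
construction: if one character's milestones are all ≤ another's with at
least one strictly earlier, it ranks strictly more decay-prone.

## Synapomorphic ranks and the slippage battery

A phylogenetic hypothesis is a rooted tree with labelled internal nodes, a
focal terminal, and a character → node assignment restricted to the
root-to-focal-terminal path. A character's depth is the number of edges from
its node down to the focal terminal (depth 1 = apomorphy of the
least-inclusive clade containing the focal terminal); midranks over depths
give the synapomorphic ranking. Characters of contested homology carry an
explicit alternative node used under the *homoplasy* treatment — the
mechanics of reassignment are deliberately user data, not a built-in rule,
since they depend on the systematic argument being made. Each hypothesis
contributes one test per treatment (two when any character is contested),
so four alternative hypotheses with contested characters yield a battery of
eight correlation tests.

Sign convention: decay rank 1 = most decay-prone, synapomorphic rank 1 =
most apomorphic. Under this pairing, the chordate-style slippage pattern
(synapomorphies decaying early) produces a *positive* r_s, while
decay-resistant apomorphies with decay-prone symplesiomorphies — the pattern
expected when the diagnostic characters are cuticular — produce a negative
one.

The *filtered* variant removes characters assigned to the two extremes of
the focal path (apomorphies of the focal taxon itself, and symplesiomorphies
at the root-adjacent node): neither can move a fossil's position within the
path, so they are uninformative for placement and can bias the correlation.
Both rankings are recomputed over the survivors; at least three characters
must remain.

## Spearman correlation and p-values

r_s is the Pearson correlation of midranked vectors (ties handled by
midranks, identical to the standard tie-corrected estimator). Two-sided
p-values come from, in order of preference:

- **exact_permutation** (n ≤ 8): full enumeration of all n! pairings;
  the tail includes permutations with |r*| ≥ |r| − 1e-12 to absorb float
  noise at ties.
- **monte_carlo** (default above n = 8): B seeded random permutations with
  the add-one estimator p = (1 + hits)/(1 + B), a valid p-value for any B;
  default B = 100,000, default seed fixed (1234567) and overridable.
- **t_approx**: t = r_s·√((n−2)/(1−r_s²)) on n−2 df; used for large n or
  when speed matters.

No multiple-testing correction is applied across the battery by default
(raw p-values are reported, as is conventional for this design); a Holm
step-down option exists. The cross-taxon comparison re-ranks each taxon's
decay ranks within the shared character set before correlating, so
differing overall decay *rates* do not mask agreement in decay *sequence*.

## Morphometrics

Change is expressed relative to the dimension at death:
change(%) = 100·(decayed − original)/original, so increases (bloating,
elongation) are positive; a `literal_sign` flag provides the opposite
orientation. Each of the six metrics (body length, outer/inner body width,
limb length, outer/inner limb width) is fitted independently by OLS of
change on raw day — the log scale is reserved for the ordinal trajectories.
Reports carry slope, intercept, R², F = R²/(1−R²)·(n−2) on (1, n−2) df, and
the upper-tail F probability, which equals the squared-t two-sided slope
test exactly. A constant response is reported as slope 0, R² 0, F 0, p 1.

## Region trajectories and comparisons

Within each region, all character-level (log day, state) points are pooled —
matching the one-line-per-region presentation of such data — rather than
modelling per-character effects; a mixed or cumulative-link model would be a
defensible refinement but is out of scope. Characters pristine at every
sampled day (immune, e.g. sclerotised jaws and claws) carry no trajectory
information and are excluded. The time axis is ln(day + 1); the +1 offset
makes day 0 representable, and both base and offset are configurable.
Regions with fewer than 3 points are dropped with a warning.

Slope heterogeneity is the extra-sum-of-squares F test of
`state ~ region * log_day` against `state ~ region + log_day`
(numerator df k−1, denominator N−2k); with k = 2 it reduces exactly to the
squared slope-difference t. The onset-of-loss comparison is a one-way ANOVA
of ln(onset + 1) by region with Tukey HSD over all k(k−1)/2 pairs; censored
onsets are excluded (no imputation rule is defensible here) and fully
censored regions are dropped with a warning. The ANOVA F is computed from
the between/within sums of squares directly so that the degenerate
all-equal case yields F = 0 rather than 0/0.

## Synthetic generator

`simulate_experiment` draws, per specimen × character, an onset time
T1 = frailty · LogNormal(ln median_onset, σ₁) and a loss time T2 = T1 +
frailty · LogNormal(ln median_duration, σ₂); the observed condition at the
specimen's sampling day d is pristine (d < T1), decaying (T1 ≤ d < T2) or
lost (d ≥ T2). Lognormal waiting times were chosen for strictly positive,
right-skewed decay times; any positive family reproducing the region
ordering would serve. The specimen-level multiplicative frailty (lognormal,
σ = 0.25) models between-specimen variation and is what makes aggregated
series non-monotone, as the destructive design allows. Immune characters
(jaws, terminal claws) are always pristine.

Defaults are chosen to emulate the canonical decay staging of a velvet-worm
experiment: internal organs begin decaying within the first days (median
onset 1.5 d) and are completely lost by roughly day 8–12; external regions
begin decaying after 1.5–3 weeks and lose characters late in the experiment,
with a mild ordering anterior < trunk < posterior < limbs. 54 specimens are
spread round-robin over a 14-point log-spaced schedule
(0, 1, 2, 3, 5, 8, 12, 19, 30, 47, 73, 113, 176, 273 days); the per-day
allocation of the original experiments is not published, so an even spread
is the neutral choice. The Tukey-isolation calibration instead uses a
variant with *identical* external-region timing — the condition "internal
far faster than mutually similar external regions" — under which the unique
isolation rate is limited only by Tukey's family-wise error control and sits
at ≈ 1 − α ≈ 0.95; under the fully differentiated defaults, occasional
external-pair flags are genuine signal.

`simulate_measurements` generates value_at_day = value_at_death ·
(1 + (min(slope·day, asymptote) + ε)/100) with ε ~ N(0, sd²); default
asymptotes put terminal trunk drift at ~20–24% (within the realistic 10–30%
band) and limb drift at ~13–20% (within 10–25%), with 4-percentage-point
measurement noise and 3 measurements per metric per day. Slope-recovery
checks use an effectively infinite asymptote so the truth is linear over
the schedule. `simulate_rank_pairs` ranks a bivariate Gaussian sample with
latent correlation ρ — the null (ρ = 0) and power testbed for the
correlation machinery.

What the generator does **not** emulate: correlated loss of topologically
associated characters (each character decays independently given the
frailty), chemical/microbial mechanism, osmotic effects, and observer error
in scoring. Tests passing on synthetic data therefore validate the
statistical machinery and its calibration, not the biology of any
particular experiment.

## Numerical and interface choices

- Decay-stage boundaries default to days {0, 2, 8, 34, 109, 220} delimiting
  stages 1–5; intervals are half-open [start, end) — day-range notation like
  "days 2–8" is ambiguous at shared endpoints, and half-open intervals
  partition [0, ∞) with stage 5 open-ended — so day 8 is stage 3.
- Condition tokens are case-insensitive; numeric {0,1,2} and text
  {pristine, decaying, lost} encodings are both accepted.
- Newick trees need labelled internal nodes only for assignment targets;
  branch lengths are ignored (only topology enters the ranking).
- Tukey adjusted p-values from the studentized-range table saturate below
  ~0.001; comparisons against unadjusted p respect that resolution.
- The test suite and the acceptance script use deliberately modest problem
  sizes (e.g. 200-replicate calibrations, 999-permutation Monte Carlo in
  calibration loops) chosen to estimate each rate to well within the
  tolerance being asserted.

## Known limitations

- Aggregation weights every specimen equally; no account of specimen size
  or condition covariates.
- The heterogeneity test treats ordinal states as numeric — standard for
  this design, but a cumulative-link model would respect the scale.
- The synapomorphic ranking assumes all assigned nodes lie on a single
  root-to-focal path; reticulate or multi-focal designs are unsupported.
- Censoring is handled by exclusion (ANOVA) or by sort-last semantics
  (ranking); no survival-analysis estimators are used, by design.
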