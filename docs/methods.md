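# Methods

## Body angle and movement events

The body angle at frame *t* is the angle subtended at the mid-trunk point M
by the head H and tail T, mapped as θ = 360° − (180/π)·arccos(cosφ) where
cosφ is the normalized dot product of H−M and T−M, clamped to [−1, 1] to
absorb floating-point overshoot on collinear points. Because the arccos lies
in [0°, 180°], θ is confined to [180°, 360°]: a straight larva reads 180°
and the magnitude of a bend raises θ regardless of side. The side is
recovered from the sign of the planar cross product (H−M)×(T−M); positive
is left, so left-directed movements plot above the resting line. This
automates a direction call that is otherwise made by replaying video.

Event detection uses a rest band of ±5° about 180° (the resting position is
"close to 180°" rather than exact; the half-width is configurable, and exit
and re-entry use the same threshold). An event spans from the first frame
outside the band to the first frame back inside — the rest-to-rest duration
rule — and is classified by its peak: wag ≤ 200°, LAM strictly between 200°
and 270°, extreme ≥ 270°. The class definitions use strict inequalities, so
ties at exactly 200° resolve to wag and at 270° to extreme. Extreme events
are reported but never enter LAM statistics. Excursions that reverse side
without touching the rest band are split at signed-angle zero crossings and
flagged; an excursion still in progress at the end of the trace is flagged
truncated and excluded from duration statistics. Events shorter than 3
frames are discarded (noise floor at 300 fps ≈ 10 ms). No smoothing is
applied by default. Durations are reported in ms at frame-period resolution
(3.33 ms at 300 fps); summary windows are half-open [0, window).

Because the rest band is entered only once the angle exceeds 185°, the
measured rest-to-rest duration of a smooth excursion is slightly shorter
than the full rest-to-rest span of the underlying movement — about 4–10%
for half-sine excursions peaking 20–90° above rest. Closed-loop recovery
tests therefore compare duration means at a 10% tolerance.

## Fictive motor patterns

Spikes are detected as rising-edge threshold crossings separated by a 1-ms
refractory period. When no threshold is supplied, the threshold is
median + 5·(MAD/0.6745), a robust estimate of baseline noise that tolerates
a high spike fraction; the multiplier 5 is conventional for extracellular
recordings. An all-constant trace under the automatic rule is an error, not
an empty result.

Segmentation is a single left-to-right pass over ISIs: < 10 ms continues a
burst; 10–100 ms starts a new burst in the same episode; > 100 ms starts a
new episode. The band edges are not covered by the defining inequalities
("<10", "between 10 and 100"), so the package resolves them as: same burst
iff ISI < 10 ms, same episode iff ISI ≤ 100 ms; both thresholds are
configurable. A lone spike is a burst of one with duration zero and is
included in spikes-per-burst statistics (the definitions force this).
Burst period — the difference between successive burst start times — is
computed only within an episode; computing it across the > 100 ms episode
gaps would conflate quiescence with swim cycle period, so with one burst
per episode the period list is empty (undefined, not zero).

## Group statistics

*Phenotype scoring.* Pearson chi-square without continuity correction on
the pooled 2×C affected/unaffected table is the default (df = C − 1). A
batch-stratified layout that keeps each condition × batch cell as a column
is also offered, because published degrees of freedom for two-condition
comparisons sometimes reflect batch-stratified constructions; with two
conditions and three batches the stratified df is 5 and the pooled df is 1.
The asymptotic chi-square p agrees with an exact conditional permutation
null only up to the discreteness of the count lattice (≈0.004 absolute at
tables of ~120 larvae); the test suite checks agreement at Monte-Carlo
error plus a 0.005 discreteness allowance.

*Rank tests.* The Wilcoxon rank-sum (Mann-Whitney) test uses the exact null
distribution for combined samples of ≤ 25 without ties and the normal
approximation otherwise; Bonferroni multiplies each raw p by the number of
requested pairs, capped at 1. Kruskal–Wallis uses the tie-corrected H with
a chi-square reference; all-identical observations return H = 0, p = 1
rather than an error. For two groups the Kruskal–Wallis p equals the
continuity-uncorrected two-sided rank-sum p.

*Normality-gated paired test.* Each condition is screened with the
Lilliefors test (KS distance to the normal fitted by sample mean and
ddof-1 standard deviation). The p-value is Monte-Carlo: 10,000 null samples
per sample size, simulated once with a fixed seed and cached, because the
classical table is approximate; the add-one rule keeps p > 0. If every
condition passes at α = 0.05 the package runs a one-way repeated-measures
ANOVA (statsmodels AnovaRM, subjects = pair index); otherwise the Friedman
test. With exactly two conditions the Friedman test degenerates; the
package substitutes the exact sign test on within-pair differences, to
which Friedman reduces analytically at k = 2. With a per-condition gate at
α = 0.05, the probability that normal data takes the parametric branch is
0.95^k; gate-calibration simulations in the test suite use 16 paired
observations per condition, where the gate selects the correct branch in
≈95% of runs for both normal and heavy-tailed (Cauchy) generators — at
n = 8 the Lilliefors power against heavy tails is only ~66%, so small
samples will often take the parametric branch on non-normal data.

*LC50.* The default estimator mirrors reading the value off a survival
curve: if some dose shows exactly 50% survival it is returned; otherwise
survival is interpolated linearly in log dose between the first adjacent
bracketing pair (plain linear if the lower dose is zero, where log dose is
undefined). The estimator is therefore scale-equivariant and passes
exactly through a printed (2 mM, 50%) point. A two-parameter log-logistic
survival curve p(d) = 1/(1 + (d/LC50)^h) fitted by binomial maximum
likelihood (Nelder–Mead on log-parameters) is available when counts are
given. On the default design (doses 0.2–10 mM, 20 larvae per dose) the
interpolation estimate has a median within 0.25 mM of a true 2 mM LC50
across 50 simulations, with single-draw spread of roughly ±0.5 mM.

## Synthetic data

The generators emulate the study conditions the analyses assume, with all
defaults overridable and every output bit-for-bit reproducible from
(params, seed).

*Trajectories.* 20 s at 300 fps. The signed angle is Gaussian rest jitter
(s.d. 0.8°, well inside the ±5° band) plus half-sine excursions for each
scheduled event — a half-sine passes smoothly through the rest band, so the
rest-to-rest duration rule is well-posed on synthetic data. Event counts
are Poisson (the simplest law for sparse spontaneous/evoked events) with
uniform placement, a 20-ms rest margin between events and internal
rescheduling of overlaps; an error is raised only if the window cannot fit
the requested events. Wags arrive in Poisson-count clusters of
alternating-side beats separated by 10 ms. Phenotype presets encode the
reported group values: control 13.2 LAMs per 20 s of 57 ms mean duration
with alternating laterality; Mn-treated 2 LAMs of 163.4 ms, unilateral;
recovered 15.3 LAMs of 54.7 ms. Only per-group means and s.e.m. are
reported for the real data, so the per-event duration spread is a modeling
choice (normal with s.d. 14–40 ms, floored at 5 frames); wag durations use
the reported ~37–40 ms means. LAM peak angles are uniform on (210°, 260°)
and wag peaks on (187°, 196°), keeping scheduled peaks clear of the class
boundaries so closed-loop tests can demand exact class recovery. The tail
point is reconstructed on the unit circle about M with H = (0, 1) and
M = (0, 0) fixed (embedded head); the angle equation normalizes the
segment lengths, so unit distance is immaterial.

*Spike trains.* 2-min recordings. Episode count is Poisson at 5 per
minute; episodes are placed uniformly with ≥ 150 ms margins so
inter-episode gaps always exceed 100 ms. Within an episode, burst starts
follow the cycle-period law with inter-burst gaps clipped into
(10.5, 99) ms, and spikes are evenly spaced across the burst duration
(clipped so intra-burst ISIs stay below 9.5 ms). The control-like rhythm
(period 35 ms, 4 spikes per ~10 ms burst) is plausible invented plumbing —
the source values are plotted, not printed — and the Mn-like (8 spikes,
19 ms bursts, 32 ms period) and recovered-like (7 spikes, 17 ms bursts,
control period) presets encode the reported orderings: more spikes per
longer burst, shorter period under treatment; period recovers but burst
duration stays long. The voltage trace is Gaussian noise (0.05 mV) plus a
1-ms exponential-decay waveform of 1 mV at each spike time; the waveform
rises at the spike sample, so threshold detection recovers spike times to
within one sample at 10 kHz.

*Survival and behavior counts.* Survival is binomial per dose around the
log-logistic curve with LC50 2 mM and Hill slope 2 (slope chosen to give a
realistic spread over the 0.2–10 mM ladder). Behavior counts are binomial
per batch (three batches of 20) with the reported proportions where
printed — sideways floating 0/0.98/0.12 and curved spine 0/0.65/0.27 for
control/Mn/recovered — and plot-anchored choices for circling (0.90 under
Mn for both modes; recovery to 0.02 spontaneous and 0.50 on-tap, matching
complete vs partial recovery).

What the generators do not emulate: tracking noise and dropped frames,
multi-peak compound movements, slow baseline drift in recordings,
non-stereotyped spike waveforms and bursts riding on field potentials,
overdispersion between batches, and any within-larva correlation between
kinematic and fictive phenotypes. Passing closed-loop tests therefore
demonstrates correctness of the detection and estimation logic under the
stated statistical structure, not robustness to real-world artifacts.

## Numerical and design choices

- arccos argument clamped to [−1, 1]; angle error near collinearity stays
  below 1e-6 deg (verified by round-trip tests at 1e-6).
- Direction at a detected peak uses the cross-product sign at the peak
  frame; within-excursion constancy is available via `assign_direction`.
- Pipeline substream seeds derive from one master seed via numpy's
  SeedSequence and are kept below 2^31.
- Reports use fixed formatting (angles 0.01°, times 0.01 ms, p to three
  significant figures); undefined metrics are written as `NA`, never 0.
- Test problem sizes: 20 recordings per preset for recovery, 200
  simulations for power/rejection-rate checks, 1,000 random trains for the
  segmentation oracle, 10,000 resamples for permutation and Lilliefors
  nulls — sizes at which the checked properties are stable from run to run.

## Known limitations

- Whether real analyses counted stimulus-evoked and spontaneous LAMs
  jointly is unspecified; the detector counts every LAM in the window.
- The construction behind a published df = 3 for two-condition phenotype
  comparisons is not reconstructible; both pooled (df = 1) and stratified
  layouts are provided instead of guessing.
- The automatic spike threshold stands in for an unreported manual
  threshold-search setting; polarity is assumed positive.
- The normality gate is applied uniformly even where the source analysis
  mentions a different (ambiguous) normality screen for one data set.
- The interpolation LC50 has no confidence interval; use the logistic fit
  with counts when uncertainty matters.
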