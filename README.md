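# larvamotor

Locomotor phenotyping analyses for larval zebrafish, built for studies of
movement disorders such as manganese-induced motor deficits (manganism
models). The package turns raw behavioral and electrophysiological
measurements — tracked tail coordinates, extracellular motor-neuron
recordings, dose–survival tables and phenotype-score sheets — into the
quantities such studies report: movement-event rates and durations, swim
motor-pattern metrics, LC50 estimates and group-comparison statistics. A
synthetic-data module emulates control, Mn-treated and recovered phenotypes
so every analysis can be exercised end to end with no external data.

## What it computes

**Tail kinematics.** A head-embedded larva is filmed at 300 fps for 20 s and
three points are tracked per frame: head H, mid-trunk M (swim bladder) and
tail T. The body angle is

θ(deg) = 360 − (180/π)·arccos[ ((H−M)·(T−M)) / (‖H−M‖‖T−M‖) ],

so a straight larva reads 180° and θ ∈ [180°, 360°]. Left/right direction
comes from the sign of the planar cross product (H−M)×(T−M). Excursions out
of a ±5° rest band are events, classified by peak angle: *wags* (≤200°,
clustered low-amplitude beats), *LAMs* (200–270°, startle/escape-scale
large-angle movements) and *extreme* (≥270°, reported separately). Event
duration is rest-to-rest; the module summarizes LAM counts per 20-s window,
duration means ± s.e.m. and the ECDF of LAM durations.

**Fictive motor patterns.** Spike times from a 2-min extracellular
recording (rising-edge threshold detection with a robust median + 5·MAD/0.6745
automatic threshold) are sorted by inter-spike intervals: ISI < 10 ms keeps
spikes in one *burst*, ISIs of 10–100 ms group bursts into an *episode*,
ISIs > 100 ms separate episodes. From the segmentation: spikes per burst,
burst duration, within-episode burst period, bursts per episode.

**Group statistics.** Pearson chi-square phenotype scoring (pooled 2×C or
batch-stratified layouts), Wilcoxon rank-sum with Bonferroni correction
(exact for small tie-free samples), tie-corrected Kruskal–Wallis, a
Lilliefors-normality-gated choice between repeated-measures ANOVA and the
Friedman test for paired data (Monte-Carlo Lilliefors p, fixed seed), and
LC50 estimation by log-linear interpolation or a two-parameter log-logistic
maximum-likelihood fit.

## Worked example

```sh
python examples/01_tail_kinematics.py
```

```
[control] 16 LAMs and 48 wags in a 20-s window
  mean LAM duration 48.7 ms (s.e.m. 3.0 ms); scheduled ground truth had 16 LAMs
[mn] 3 LAMs and 25 wags in a 20-s window
  mean LAM duration 137.8 ms (s.e.m. 9.7 ms); scheduled ground truth had 3 LAMs
```

The detector recovered every scheduled large-angle movement in both
simulated recordings; the Mn-treated-like larva shows the characteristic
phenotype of few but long unilateral LAMs, while the control larva produces
an order of magnitude more LAMs of ~50 ms. Similarly:

```sh
python examples/03_lc50.py
```

```
    0.2 mM : 100.0 % surviving
    ...
    2.0 mM :  45.0 % surviving
    4.0 mM :   5.0 % surviving
LC50 (interpolation): 1.81 mM (log-linear interpolation)
LC50 (logistic fit):  1.63 mM, Hill slope 2.54
```

Both estimators read an LC50 near the true 2 mM from one binomial draw of
20 larvae per dose. The other examples cover burst/episode segmentation
(`02`), phenotype scoring and the normality-gated paired test (`04`) and the
full reproducible pipeline with its manifest (`05`). A thin CLI wraps the
same functions (`larvamotor simulate|kinematics|fictive|stats|run --help`).

## Layout

- `src/larvamotor/kinematics.py` — body angle, event detection, summaries
- `src/larvamotor/fictive.py` — spike detection, ISI segmentation, metrics
- `src/larvamotor/group_stats.py` — chi-square, rank tests, gated paired
  test, LC50
- `src/larvamotor/synthetic.py` — phenotype-preset generators with ground
  truth
- `src/larvamotor/io.py`, `pipeline.py`, `cli.py` — text formats, the
  reproducible pipeline and the thin CLI
- `docs/methods.md` — model assumptions, parameter choices, limitations
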