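# Methods

## Behavior model

Each behavior channel (rumination, lying) is an alternating-renewal
process at 1 s resolution: bouts (runs of 1) and gaps (runs of 0) with
i.i.d. durations. Defaults emulate grazing dairy cows: rumination bouts
log-normal with median 30 min (σ = 0.5), lying bouts median 45 min
(σ = 0.5); target time-budgets of 12% ruminating and 25% lying. Gap
distributions are derived from the targets: E[gap] = E[bout](1−p)/p, with
the gap log-normal sharing the bout σ. The σ = 0.5 dispersion is a
field-realistic choice (bout coefficients of variation near 0.5); no
bout-duration statistics were available to estimate it from, so it is a
stand-in, exposed in `ChannelConfig`.

Rumination preferentially starts while lying. With coupling multiplier
c ≠ 1 (default 2), rumination gap durations come from a state-modulated
exponential hazard λ(t) = λ₀·(c if lying else 1) rather than the
configured gap distribution; λ₀ = 1/(G·m̄) with G the target mean gap and
m̄ = 1 + (c−1)·p_lying, so the marginal prevalence still converges to the
target. This is an approximation (it assumes lying occupancy during
rumination gaps equals the marginal lying prevalence); empirically the
bias is below 0.01 at 500 h.

The process starts in a bout with probability equal to the target
prevalence, drawing a full (not length-biased residual) duration. The
resulting edge bias is O(one bout) and negligible beyond ~50 h.

Prevalence estimates from a renewal process converge slowly — with ~60
bout/gap cycles per 200 h the SD of the empirical prevalence is ≈ 0.02 —
so fixed-seed recovery tests run at 200–500 h, sizes at which the sampling
noise sits comfortably inside the asserted bands.

## Sensor error model

Three error modes, applied to the 1-min gold labels in a fixed order:

1. **Boundary jitter** — each bout's start and end shifted by an
   independent rounded Gaussian (SD in minutes), clipped to the window;
   a bout whose jittered extent collapses is lost.
2. **Whole-bout deletion** with probability `bout_miss_prob` (sensors that
   miss entire rumination bouts).
3. **Spurious isolated minutes** — independent per-minute Bernoulli with
   p = rate/60 on minutes that are 0 after steps 1–2 (misclassification of
   chewing-like activity as rumination). An optional per-minute weight
   vector scales the intensity, which is the hook used to emulate
   heat-dependent degradation. The resulting count is Binomial, which at
   these rates is indistinguishable from Poisson.

Missing minutes are never corrupted and never receive insertions.

The tilt generator places lying at 90° and standing at 20° — both far from
the 60° threshold so the noise-free round trip through the classifier is
exact — plus Gaussian noise and Poisson "kick" events (5–45 s excursions to
the opposite set-point).

What the simulator does **not** model: diurnal behavior rhythms (real
heat-stress data confound time of day with THI), dependence between cows,
drift in sensor calibration, and raw accelerometer waveforms (it targets
the 1 s / 1 min abstraction the analysis operates on). Passing tests
therefore demonstrate correctness of the computation chain under the
stated statistical structure, not sensor performance on real herds.

## Temporal conventions

- Predominant-behavior rule: minute label = 1 iff ≥ 30 of its 60 seconds
  are positive. The exact 30/30 tie goes to the positive class; ties are
  measure-zero for physical sensors but must be deterministic, and the
  convention is flippable (`tie_positive=False`).
- Only complete, fully observed minutes are labeled; anything else is
  missing (no interpolation).
- 10-min windows are half-open [t, t+10), aligned to the series start;
  a window containing a missing minute is dropped rather than prorated
  (short observation windows make prorating misleading).
- Sources are outer-joined on timestamp; every pairwise statistic uses
  that pair's complete rows, so each sensor keeps its own N.

## Correction algorithm

Within each gap-free segment, repeatedly relabel the **leftmost** interior
maximal run of length ≤ `max_run_to_remove` (default 2 min) to the
flanking label, until a fixed point. Properties: idempotent; edge runs
preserved (their context is unknown); after correction no interior run of
length ≤ the limit remains; missing values split segments. The
leftmost-first order mirrors sequential macro-style sweeps of a recording
and pins down dense ambiguous patterns (e.g. `0,1,1,0,1,1,0` → all
zeros: the first 2-min event is removed before the 1-min gap could be
bridged). The default symmetric mode corrects short runs of both classes
(deleting spurious events *and* bridging short gaps inside bouts);
`symmetric=False` deletes short positive runs only, for sensitivity
analysis. The implementation (run-length encoding, doubly linked run list,
start-keyed heap) is verified against a naive fixed-point oracle on all
binary series of length ≤ 12.

## Agreement battery

- AC = (SE+SP)/2 is used rather than raw accuracy because prevalence is
  far from 50%.
- PPV is computed through the SE/SP/prevalence formula; a property test
  confirms the algebraic identity with TP/(TP+FP) to 1e−12.
- Lin's CCC uses population (1/N) moments; |CCC| ≤ |Pearson r| and CCC = 1
  only for identical series. At 1-min resolution CCC and r_S are computed
  directly on the 0/1 labels (point-biserial equivalence).
- R² is the squared Pearson correlation, identical to the R² of the simple
  least-squares regression of sensor on gold.
- Undefined statistics (empty truth class, constant series, κ with
  degenerate marginals) are NaN, never 0 — degenerate strata must be
  visible in reports.
- Report formatting rounds half-up: percentages to one decimal,
  coefficients to two.

## THI stratification

THI = (1.8T + 32) − (0.55 − 0.0055·RH)(1.8T − 26); at 1.8T = 26 the
humidity term vanishes (THI = 58 for all RH). The coefficient set is a
config object so alternative THI variants can be swapped; no result in
this package depends on the specific variant. Intervals are joined to the
nearest *preceding* weather record within 10 min (weather-station
cadence); unmatched intervals are excluded and counted. Strata partition
the covered rows, so pooling them and recomputing reproduces the
unstratified metrics exactly.

## Pipeline

A single top-level seed derives per-stage seeds by hashing the stage name
(BLAKE2s, reduced below 2³¹), so adding a sensor or stage never perturbs
the randomness of earlier ones; identical config + seed give byte-identical
reports. The manifest records per-stage row counts and every exclusion
(incomplete minutes, dropped windows, weather-uncovered intervals) so that
inputs = used + excluded balances at each stage. Default problem size is
200 h of herd time (12,000 min; 1,200 ten-min windows), which keeps a full
run in the low seconds while leaving metric sampling noise well below the
effects being demonstrated.

## Known limitations

- The coupling calibration is approximate (see above); exact prevalence
  targeting under coupling would require solving the joint process.
- The alternating-renewal model has no refractory structure or diurnal
  rhythm, so THI strata differ only through the error-rate hook, never
  through behavior itself.
- The CA's leftmost-first order is one of several defensible fixed-point
  orders; results differ only on dense patterns of adjacent short runs,
  which the error model makes rare.
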