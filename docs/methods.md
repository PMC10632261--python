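# Methods

This note documents the models, algorithms and numerical choices behind
cprkit, and what the synthetic-data generator does and does not emulate.

## Protocol model

A subject's timeline is: 5 min pre-arrest baseline, a configurable
untreated ventricular-fibrillation phase (default 3 min), then CPR (default
20 min), with t = 0 at CPR start and negative times for the pre-arrest
phases. Chest compressions run at `compression_rate` (default 102/min)
throughout CPR. Ventilation follows the mode:

* **CCC** — one manual breath every `ccc_vent_interval` (default 6 s,
  i.e. 10/min), asynchronous to compressions. The first breath is placed
  half an interval after CPR start so breath onsets are asynchronous to
  compressions and clear of minute boundaries.
* **30:2** — blocks of `compressions_per_cycle` (30) compressions followed
  by a `pause_duration` (3.2 s) pause containing `breaths_per_pause` (2)
  breaths; the first breath starts 0.2 s into the pause and breaths are
  spaced (pause − 0.4)/2 apart. Over 20 min this yields 57 pauses and 114
  breaths, i.e. 5.7 breaths/min.

Arterial blood gases are sampled pre-arrest (the baseline sample) and every
`abg_interval` (5 min) during CPR.

## Synthetic waveforms

The generator is phenomenological: it reproduces the morphology and the
statistics that the extraction chain consumes, not cardiovascular physics
(no compliance/valve model, no closed circulatory loop).

**Flow** (l/min, inspiration positive): each breath is a half-sine
inspiratory pulse over the drawn Ti whose peak is set by the closed form
Vti = (2/π)·peak·Ti, followed by passive exponential expiration (time
constant 0.4 s) balancing the inspired volume. A compression-frequency
sinusoid (default amplitude 3 l/min) is added while compressions are
active.

**Airway pressure** (cmH2O): baseline (default 2, the paper-agnostic
PEEP-equivalent exposed as a parameter) plus, within each breath, an
elastic half-sine combined with a compression ripple where the breath
overlaps active compressions; the within-breath shape is normalized so its
noise-free maximum equals the drawn per-breath PIP exactly. Between
breaths a compression oscillation of 12 cmH2O remains. The two arms get
their default PIP means (58.6 vs 35.1 cmH2O) from the configuration, so
the CCC > 30:2 pressure difference is carried by the configured magnitudes
while the waveform morphology (ripple during overlapped breaths) stays
mode-specific.

**CO2** (mmHg): zero during inspiration, an expiratory upstroke reaching
the drawn per-breath peak after 0.8 s, then a plateau corrupted by downward
compression dips (fraction 0.15) clipped at the plateau level — so the
curve shows the characteristic compression noise while its maximum still
equals the generating PECO2, which is exactly why the peak, not the
end-tidal value, is the extracted feature.

**Arterial and venous pressure** (mmHg): each compression cycle is a
piecewise-cosine excursion through four anchors — end-decompression level,
compression peak (phase 0.30), decompression trough (phase 0.75) and an
end-decompression plateau (phase 0.90–1.0). Per-cycle anchor values are
drawn around per-minute generating means; CPP is enforced by construction
as AP − CVP at the plateau. 30:2 pauses decay exponentially toward
arrest-level pressures. The pre-arrest baseline is a pulsatile trace whose
segment mean equals the configured MAP/CVP exactly and whose pulse rate is
the configured heart rate.

**Trends.** Per-minute generating means follow mean-preserving linear
trends: value(m) = mean + slope·((M+1)/2 − m), so a positive slope gives a
monotone decline while the 20-min average stays at the configured mean
(the published whole-experiment estimands). Defaults: CPP, maxAP and
maxCVP decline in both arms, maxCVP faster in 30:2; PECO2 declines in CCC
and rises in 30:2; blood gases drift accordingly (PaCO2 and lactate up,
pH down, PaO2 flat).

**Noise and variability.** Channel noise is additive Gaussian (flow 0.5
l/min, airway pressure 0.5 cmH2O, CO2 0.25 mmHg, vascular pressures 1
mmHg). Within-subject breath-to-breath and cycle-to-cycle jitter is 4–5%
CV. Between subjects, `simulate_cohort` jitters ventilation magnitudes at
5% CV (manual bagging was feedback-guided, hence tight), hemodynamic
magnitudes at 20% CV (arrest hemodynamics vary widely between animals;
additive 1.5 mmHg on near-zero pressures), and draws weight from a
truncated normal around 33.5 kg. Per-subject seeds derive from the master
seed via `SeedSequence(master, spawn_key=(group, index))`; identical
config + seed is bit-identical.

What passing tests on this generator show: that the detection, feature,
binning and statistical code is correct on signals with the protocol's
timing structure, realistic artifact and noise. What they do not show:
robustness to monitor-specific failure modes absent from the model —
sensor drift and recalibration steps, airway leaks, secretions, transducer
flushes, ECG cross-talk, or compression-rate drift.

## Breath detection

Segmentation runs on low-pass-filtered flow (4th-order zero-phase
Butterworth, cutoff 1.4 Hz — above the ~1.2 Hz content of a 0.4 s
inspiration, attenuating the 1.7 Hz compression band by ~6x after forward-
backward filtering). An inspiration is a supra-threshold episode (default
5 l/min for ≥ 50 ms). The onset is then refined on the raw flow as the
crossing of an adaptive epsilon (twice the robust MAD of the preceding
0.7 s of flow, clipped to [0.5, 5] l/min): this stops the backtrack at the
inspiratory upstroke instead of inside the compression oscillation. End of
inspiration is the first non-positive raw sample after the filtered peak;
the breath window extends to the next onset (capped at 10 s). On
noise-free signals onsets are within one sample of truth; with default
artifact and noise, per-breath biases are ≤ 2% and per-minute counts are
exact.

PIP is searched over the whole breath window by default (compressions can
raise airway pressure outside inspiration; configurable to
inspiration-only). PECO2 is the raw CO2 maximum from end-inspiration to
the next onset, capped at 5 s; smoothing before the peak pick is available
but off by default because any filter that keeps the DC of the plateau
averages the compression dips into the peak and biases it low. Minute
binning is by inspiration onset (minute = floor(onset/60) + 1); empty
minutes carry NaN, never zero, and propagate as missing into the mixed
model.

## Compression-cycle detection

Peaks are found on 10 Hz-smoothed arterial pressure with minimum spacing
0.7 × the nominal compression period and ≥ 10 mmHg prominence; the
decompression trough is the minimum between consecutive peaks. The
upstroke is where the smoothed derivative first exceeds 25% of the
cycle's peak derivative; "end of decompression" is the last sample before
the next upstroke minus a 20 ms guard, capped at 1.05 periods after the
cycle's own upstroke (this cap makes the last cycle before a 30:2 pause
read its plateau rather than the pause decay). Sampling both channels at
the trough instead is a documented switch (`end_decomp_at_trough`).
maxAP/maxCVP are independent per-channel maxima over upstroke → trough,
minAP/minCVP minima over trough → end; CPP = AP − CVP at the
end-decompression sample, an identity asserted for every emitted cycle.
Cycles truncated by the recording edge are dropped with a logged count.
No non-negativity clamp is applied to vascular pressures (decompression
minAP is legitimately negative).

## Mixed models

The marginal model treats time as a categorical factor with group, time
and group × time fixed effects (treatment coding, 2T parameters for two
groups), subjects independent, and within-subject residual covariance per
structure: AD(1) (σ_1..σ_T, ρ_1..ρ_{T−1}), compound symmetry, AR(1), or
independence with common variance. Estimation maximizes the restricted
likelihood, profiled over the fixed effects, on transformed parameters
(log σ, atanh ρ; the CS correlation is mapped into its positive-definite
range (−1/(T−1), 1)). Three fixed starting points (empirical
per-time SDs and lag-1 correlations; iid; high correlation), L-BFGS-B with
bounds ±12 on the transformed scale, tolerance 1e−12 on the objective;
identical data give identical fits. If every start fails the fit raises a
`ConvergenceError` — never a silent fallback. The REML value follows the
−½[(n−p)log 2π + log|V| + log|X'V⁻¹X| + r'V⁻¹r] convention and
AIC = −2ℓ_R + 2q counts covariance parameters only; both are stated
because conventions differ between packages.

Marginal group means average the fitted cell means over time levels;
the group difference is reported CCC − 30:2. 1-df contrasts use
Satterthwaite degrees of freedom (numerical gradient of the contrast
variance and numerical REML information), falling back to residual
n − p df when the information matrix is singular; multi-df Wald F tests
for the time and interaction effects use residual denominator df — a
simpler documented choice. Missing cells are handled by the likelihood
(no imputation). Model selection refits every candidate structure on
identical data and ranks by AIC with ties broken toward fewer parameters;
a failed candidate is recorded, not fatal.

## Exact tests

The exact Mann–Whitney two-sided p doubles the smaller tail of the exact
permutation distribution of the midrank sum, computed by dynamic
programming over doubled ranks (exact for n1 + n2 ≤ 25; beyond that a
tie-corrected normal approximation without continuity correction).
Fisher's exact test uses the point-probability method — summing
hypergeometric probabilities ≤ that of the observed table, with a 1e−7
relative tolerance on the comparison; mid-p is deliberately not used, and
an empty margin returns p = 1 by convention. Pearson p-values come from
the t transform on n − 2 df. Bonferroni adjustment is min(1, m·p) with m =
the number of lung locations actually tested per measure (not the total
across measures).

## Post-mortem analyses

The wet–dry ratio is wet/dry (the common lung-water index); the water
fraction (wet − dry)/wet is provided as a secondary output since either
operationalization is defensible. Regional comparisons run the exact
Mann–Whitney test per location for continuous measures and Fisher's exact
test for binary incidence, Bonferroni-adjusted across locations. The
bundled post-mortem table generator is synthetic by construction
(beta-distributed percentages, ordinal grades with an optional group
shift) and exists so the pipeline is testable without animal data.

## Problem sizes used in the test suite

Unit tests run on single subjects or reduced protocols (2–5 min).
The cohort-recovery check uses 20 full-protocol cohorts of 8 + 8 subjects
and compares the mixed-model group means of PIP, PECO2 and MV against each
cohort's realized generating means (the mean of the drawn per-subject
parameters — the quantity the pipeline can be unbiased for; the
configured population mean differs from it by between-subject sampling).
Confidence-interval calibration uses 200 directly simulated
repeated-measures cohorts with T = 5 under AD(1) noise.

## Known limitations

* Waveforms are phenomenological; parameter recovery results do not
  certify performance on monitors or animals outside the modelled noise.
* Satterthwaite df are computed numerically; with very small cohorts and
  the 39-parameter AD(1) structure at T = 20 the REML information can be
  ill-conditioned, in which case the residual-df fallback is used and
  flagged on the fit object.
* The 30:2 extraction emits no cycles inside ventilation pauses (by
  design), so 30:2 per-minute hemodynamic means average fewer cycles.
* Multi-df tests use residual denominator df, which is anticonservative
  relative to Satterthwaite for small cohorts.
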