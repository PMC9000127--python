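# Methods

This note documents the models, defaults and numerical choices behind
`fecghybrid`, and what the synthetic study conditions do and do not
establish about real abdominal recordings.

## Signal model and pipeline

An abdominal channel is modelled as maternal ECG plus a weaker fetal
ECG, each passed through a short per-electrode FIR path, plus baseline
wander and broadband noise. The extraction pipeline is:

    bandpass (3–150 Hz) → FastICA → role assignment → adaptive
    cancellation (primary aECG*, reference mECG*) → CWT R-peak
    detection → windowed Se/PPV/F1 and fHR.

### Preprocessing

Butterworth bandpass, default corners 3 and 150 Hz, order 4 per edge,
applied forward–backward (`sosfiltfilt`) with reflect padding. Zero
phase is essential: the downstream evaluation matches beats at ±50 ms,
so the filter must not move R peaks. For sampling rates ≤ 300 Hz the
upper corner is clamped to 0.45·fs with a logged warning. The 0.3 Hz
baseline wander injected by the generator lies below the 3 Hz corner by
design, so the preprocessing contract is exercised by the tests.

### ICA block

FastICA (log-cosh contrast, PCA whitening to unit variance, seeded
initialization) with as many components as input channels. The
abdominal mixture is mildly convolutive (FIR paths of ~10 ms), which an
instantaneous ICA can only approximately unmix; the adaptive block
exists precisely to remove the residual maternal content.

Roles are assigned by periodicity: for each component the
autocorrelation of its squared, demeaned samples is scanned over lags
corresponding to 40–220 bpm; the fundamental is the shortest local
maximum within 85 % of the global best (this resolves the harmonic
ambiguity where a 140 bpm train also peaks at 70 bpm). The most
periodic component whose rate falls in the maternal band (40–120 bpm)
becomes mECG*; among the rest, the most periodic in the fetal band
(100–200 bpm) — falling back to the strongest residual periodicity —
becomes aECG*; everything else is noise. Ties break toward the lower
component index, making the rule invariant to component permutation and
sign. If no maternal candidate exists the block raises, advising a
different channel subset.

### Adaptive block

All five kernels share the transversal structure
x_vec(n) = [x(n), …, x(n−M+1)] with zero-padded history, emit the
a-priori error e(n) = d(n) − wᵀ(n−1)x_vec(n) as fECG_est, and start
from zero weights. Defaults: M = 5, μ = 0.01, λ = 0.999, η = 0.01,
p = 5, RLS seed P(0) = I/δ with δ = 0.01, sign(0) = 0 in SE-LMS,
ADALINE bias off (bias on adds one trained offset weight).

Numerical choices worth recording:

* **RLS** uses the standard Riccati recursion with explicit
  re-symmetrization of P each sample; without it the update loses
  symmetry and positive definiteness on runs of ~10⁴ samples with
  λ < 1. With λ = 1 the terminal weights equal the ridge-regularized
  batch solution (XᵀX + δI)w = Xᵀd exactly; tests assert this identity
  at 1e-6.
* **FTF** is derived from the order-(M+1) decompositions of the
  regularized correlation matrix; the forward and backward
  cross-correlation vectors are carried explicitly so both prediction
  error energies come from their definitions rather than scalar
  recursions. The conversion factor γ is computed twice — through the
  classical order recursion and directly as 1 − uᵀk — and a gap above
  0.02, γ leaving (0, 1], a non-positive forward energy or any
  non-finite state triggers a rescue. A rescue re-creates exactly the
  state of a fresh prewindowed filter at the current sample (including
  its single-sample gain), with restart regularization scaled to the
  running reference power, while the joint-process weights are kept and
  keep predicting from the true (un-truncated) regressor history.
  This keeps FTF at the RLS noise floor for λ ∈ [0.95, 1] and M up to
  100 over 30 k samples, with isolated rescues; the rescue budget
  (default 50) turns pathological settings into a reported failure
  rather than silent garbage.
* Divergence (non-finite error) raises with the sample index; inside
  the optimizer such cells are recorded as failed and excluded from the
  optimum.

### Detector

Ricker (Mexican-hat) CWT, 8 log-spaced scales mapped to 10–30 Hz where
QRS energy concentrates; detection function is the mean |coefficient|
across scales. The threshold is 3× a rolling 2 s median of that
magnitude (evaluated every 0.25 s and interpolated), making detection
invariant to positive rescaling and robust to amplitude drift across
the optimizer's 1-minute windows. A 250 ms refractory period (fHR
ceiling 240 bpm, above the physiological 180 bpm) suppresses the weaker
of two close candidates; surviving peaks are refined to the extremum of
|fECG_est| within ±20 ms, so polarity does not matter.

### Evaluation

Matching is chronological two-pointer (earliest feasible pairing),
which is maximum-cardinality-optimal for points on a line with a fixed
tolerance; tests verify agreement with exhaustive bipartite matching on
all instances with ≤ 8 beats per side. The ±50 ms tolerance is the
Challenge-2013 scoring convention. Undefined metrics (zero denominator)
return None, never NaN, and windowed aggregation sums counts before
computing the micro-averaged Se/PPV/F1. fHR traces use instantaneous
60·fs/RR at interval midpoints, a 5-point median filter, resampling to
a 0.25 s grid and a 7.5 s moving average — a deliberate imitation of
CTG-style smoothing; the averaging window is exposed in config.

### Optimizer

Default grids: μ, η log-spaced over [1e-3, 0.1] (25 points); λ linear
over [0.98, 1.0] (21 points); M, p ∈ {1, 5, 10, …, 100}. A `fine` mode
uses step 1 on M and 0.001 (or 0.0005 for λ) on the first axis for
interval-style optimum reporting. Declared hard ranges: μ, η ∈ (0,
0.1], λ ∈ [0.9, 1], M, p ∈ [1, 100]. The optimum is the global maximum
over non-failed cells; plateaus within 1e-9 are reported whole, with
the canonical representative at the smallest filter length and the most
stable first-axis value (smallest μ/η, largest λ). Searches are
row-major, deterministic, and resumable from a JSON checkpoint with
bit-identical results.

## Synthetic study conditions

Defaults: fs = 500 Hz, 120 s, maternal 75 bpm, fetal 140 bpm, R-peak
amplitude ratio 0.25, 4 channels, 5-tap unit-norm mixing FIRs with a
dominant positive-DC leading tap, 0.3 Hz / 0.05 mV baseline wander,
0.02 mV white noise, 2 % beat-interval jitter — a desk-scale imitation
of a term-pregnancy abdominal recording. PQRST complexes are sums of
five Gaussian bumps (P, Q, R, S, T) with fixed relative offsets, widths
and amplitudes, compressed for fast rates so adjacent beats stay
disjoint. The generator is a pure function of its spec (seed included)
and emits ground-truth R-peak indices for both sources.

The known-FIR cancellation fixture used by the identification oracles
adds 0.1 mV broadband noise to the maternal reference and demeans both
sources. Both choices are deliberate: a noiseless Gaussian-bump ECG is
so smooth that the 5-tap identification problem is ill-conditioned
(weights are unidentifiable even when cancellation is excellent), and
unremoved DC couples the two sources' means into a non-decaying weight
bias. The pipeline's 3 Hz high-pass performs the equivalent demeaning
on real data, and a real ICA-estimated reference is never noise-free.

What passing these tests shows: the blocks implement their contracts
exactly (oracle identities at 1e-6–1e-12), the pipeline separates and
scores a realistic-amplitude mixture essentially perfectly, and the
grid search recovers a planted channel length. What they do not show:
performance under fetal movement artifacts, uterine EMG, electrode
drop-outs, morphological overlap of maternal and fetal QRS, or truly
convolutive long channels — real recordings degrade all blocks, which
is exactly why per-recording optimization of the adaptive parameters
(the package's central feature) matters: on synthetic seeds where ICA
separation is imperfect, the default RLS setting can drop to ~91 % F1
while the grid-optimized setting restores ~99.6 %.

## Known limitations

* Instantaneous ICA only; convolutive/temporal extensions are out of
  scope.
* The role heuristic assumes maternal and fetal rates fall in disjoint
  declared bands; bradycardic fetuses overlapping the maternal band
  would need different bands.
* WFDB support is a minimal format-16 single-`.dat` subset with a
  1/gain mV quantization (gain 1000); CSV is the lossless path.
* FTF at λ < 0.98 with large M restarts frequently; RLS is the
  reference implementation for those regimes.
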