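# Methods

## Problem and model

Long monotonous driving induces mental fatigue, and fatigue reorganizes
large-scale brain synchronization. `plidrift` analyzes this as a
*network-trend* problem: estimate a functional connectivity network from
EEG repeatedly across a session, then ask which connections drift
monotonically as the session wears on, and whether those drifting
connections are idiosyncratic to individuals or shared by the group.

### Phase Lag Index

Connectivity is measured with the Phase Lag Index. For a real channel
x(t), the analytic signal w(t) = x(t) + i x_H(t) (x_H the Hilbert
transform, computed with the standard frequency-domain construction on
the full epoch) yields the instantaneous phase φ(t). For channels a, b:

    PLI_ab = | (1/N) Σ_n sign(φ_a(n) − φ_b(n)) |,

with phase differences wrapped to (−π, π] and sign(0) = 0. PLI ∈ [0, 1];
it is 0 when the phase-difference distribution is symmetric around zero
— in particular for the zero-lag correlations produced by volume
conduction, the reason PLI is preferred over coherence-like measures
here — and 1 for perfect phase locking at a non-zero lag.

Numerical choices:

- sign(0) contributes 0, which makes the PLI of a channel against itself
  exactly 0 rather than undefined.
- The sign sum is accumulated as an exact integer, so the production
  kernel (numba-jitted loop over the 1891 pairs, with a pure-numpy
  fallback) agrees bit-for-bit with a naive per-sample reference loop.
- The phase-difference wrap is a single conditional ±2π step. This is
  exact for differences of two already-wrapped phases and avoids the
  rounding a modulo-based wrap would introduce near ±π.
- No edge-tapering margin is trimmed by default (`trim_samples=0`):
  with multi-minute epochs the Hilbert boundary region is a negligible
  fraction of samples. The option exists for short epochs.

Networks are stored as condensed upper-triangular weight vectors (1891
edges for the default 62-channel montage) in montage order.

### Edge-wise trend regression

Each edge's PLI trajectory across the session's epochs is fit by
ordinary least squares, y = β₀ + β₁x + ε, with x the epoch index
(0, 1, …). Any affine recoding of the time axis changes β₁'s units but
not R², p, or the slope sign, so the unitless epoch index is used. The
p-value is the two-sided test of β₁ = 0 via F(1, n−2) — identical to the
t-test in simple regression. An edge is *significant* when

    R² > 0.25   and   p < 0.05   (both strict).

With n = 20 epochs the R² condition is the binding one: R² = 0.25 maps
to F = 6 and p ≈ 0.0247, so the p-condition is redundant at that n but
retained for other epoch counts (QC exclusions shorten n, and n is
recorded per fit). No multiple-testing correction is applied across the
1891 edges; the report carries the implied family-wise null expectation
(`expected_null_hits`) so the false-positive load is explicit.
Degenerate all-constant series return slope 0, R² = 0, p = 1.

### Individual vs. global networks

- **IN (individual network) analysis**: each subject's gated edge set is
  kept separate. *Prevalence* counts, per edge, the subjects in which it
  is significant; edges present in at least a threshold fraction
  (default 0.40) form the *shared edge set*. Each shared edge carries a
  consensus direction — the sign of the mean slope over contributing
  subjects, with exact ties reported separately — and a topographic
  class derived from the 10–20 label suffix (odd = left, even = right,
  z = midline; any midline endpoint makes the edge midline-involving,
  otherwise intra-left / intra-right / interhemispheric, a partition).
- **GN (global network) analysis**: the edge-wise arithmetic mean of all
  subjects' PLI weights per epoch, gated by the same trend criterion.
- **Overlap**: per subject, 100·|IN_s ∩ GN| / |GN|. The denominator is
  the GN edge count, so every reported percentage times |GN|/100 is an
  integer edge count (an internal consistency check the test suite
  enforces). The summary reports mean, standard deviation (population
  convention, divide by n — recorded in the output metadata), min and
  max across subjects.

## Preprocessing

The chain for continuous recordings: polyphase down-sampling (default
512 → 256 Hz, down-sampling only), optional 50 Hz notch (IIR, Q = 30,
zero-phase via filtfilt; applied only on the real-data path — synthetic
data carry no mains), zero-phase FIR band-pass 1–45 Hz, linked-mastoid
re-referencing (mean of M1/M2 subtracted, reference channels dropped
from the network space; labels configurable for TP9/TP10-style caps),
epoching, whole-epoch baseline (mean) removal, and high-frequency QC.

- **FIR design**: Hamming windowed-sinc, odd tap count, applied as one
  linear-phase pass with group-delay compensation (`same`-mode FFT
  convolution) — exactly zero-phase, stop-band > 50 dB. Transition
  bandwidth per edge: a quarter of the edge frequency, raised to at
  least 2 Hz but never above half the edge (the 1 Hz high-pass edge thus
  gets 0.5 Hz). Upper-edge transitions are additionally capped at 5 Hz
  so the 1–45 Hz filter completes its roll-off inside the 45→50 Hz gap
  below mains.
- **Frequency bands**: delta 1–4 Hz (nominally 0.5–4; the 1 Hz high-pass
  makes 1 Hz the effective edge, and the nominal value is kept as
  metadata), theta 4–7, alpha 8–12, beta 13–30, gamma 31–45.
- **Epoching**: windows of 300 s every 150 s (50 % overlap); windows
  overlapping the first or last 300 s of the recording are excluded
  (containment rule). The epoch count is always taken from the data —
  standard conventions yield 19–23 epochs for a nominal 1-h session
  depending on rounding, so no count is hard-coded. The synthetic
  generator emits exactly 20 epochs per subject directly on the analysis
  grid.
- **QC**: per epoch, mean 20–40 Hz power across channels (periodogram
  integration); epochs more than 6 dB above the per-recording median are
  flagged. The median reference is a design choice — it is robust and
  self-contained where an absolute reference would depend on amplifier
  scaling. QC applies at epoch granularity. Flagged epochs are dropped
  for *all* subjects (grid intersection) so group epoch grids stay
  aligned; the drop is recorded.
- Input is assumed artifact-cleaned; no ocular-component (ICA) removal
  is implemented.

## Synthetic data generator

The generator emulates a cohort of sessions in which band-specific,
phase-lagged couplings drift linearly — the fatigue surrogate. Per
epoch, each channel receives pink (1/f-amplitude) Gaussian noise
(sd `noise_sd`, default 1), plus a shared broadband pink source added
identically to every channel (`common_source_gain`, default 0.5) as a
volume-conduction surrogate: being zero-lag, it inflates amplitude
correlations but not PLI. For a planted edge (a, b) in band B with
coupling κ(e) = base + slope·e at epoch e:

    b's band component = κ·(a's component phase-shifted by the lag)
                         + sqrt(1 − κ²)·independent band noise,

both components unit-variance band-limited Gaussian noise scaled by
`component_sd` (default 1). Phase-shift-and-mix was chosen over coupled
oscillators because it controls the phase-difference distribution — the
quantity PLI measures — directly. Phase lags are restricted away from 0
and π (invisible to PLI by construction); benchmark lags are drawn from
U(π/4, 3π/4) where PLI sensitivity is greatest.

Measured on the generator itself, PLI ≈ 0.96·κ for mid-range lags, so a
linear κ schedule plants a linear PLI trend with a known slope sign.
The default schedule runs κ from 0.35 to 0.66, a PLI change of ≈ 0.3
per session.

Seeding is hierarchical — (master_seed, subject, epoch) spawns an
independent stream — so recordings are bit-reproducible and epochs
reproducible in isolation. A continuous-output mode concatenates the
epoch grid with lead-in/lead-out background segments (and optional
mastoid channels of independent pink noise) so the epoching stage can be
tested end-to-end; interior windows recover the generator's epochs
bit-exactly.

What the generator does *not* emulate: lead-field/dipole forward
physics, ocular or muscle artifacts, mains interference,
non-stationarity beyond the linear coupling drift, or non-monotonic
fatigue adaptation. Passing recovery tests therefore show that the
pipeline detects linear phase-coupling drifts of the planted magnitude
under realistic noise — not that real fatigue produces such drifts.

## Benchmark scale and calibration

The recovery benchmark (`make_recovery_config`) uses 10 subjects × 5
bands × 20 epochs with 15 planted edges per band — 12 in every subject,
2 in half the cohort, 1 in a single subject, so the ≥ 40 % shared-edge
rule has planted edges on both sides of its threshold. Epochs are 60 s
at 256 Hz: at that length the per-epoch PLI estimator noise is
sd ≈ 0.04–0.05, which against the planted ΔPLI ≈ 0.3 puts planted edges
far above the R² gate while keeping the whole benchmark a few minutes of
CPU. Full 300 s epochs change only the estimator noise (smaller), not
the logic. Expected behavior of the null side: the gate passes
≈ 2.5–3.5 % of unplanted edges per subject-band (the analytic F-tail,
slightly inflated because PLI values are folded, hence non-Gaussian), so
at the prevalence level (≥ 4 of 10 subjects) false shared edges are rare
(≲ 10⁻⁴ per edge) but not impossible; the recovery criteria bound them
at 1 % per band rather than demanding exact set equality.

One interaction worth knowing about: adjacent frequency bands abut, and
their filter transition bands overlap (the delta filter passes energy up
to ~5 Hz while the theta filter's skirt reaches down to ~3 Hz), so a
coupling planted at a band edge is genuinely detectable in the
neighbouring band. In the benchmark this shows up as delta- and
alpha-planted edges surfacing in the theta shared set. These are true
couplings seen through band overlap — the same thing happens with real
EEG band definitions — so recovery statistics count an edge as a false
positive only if it carries no planted coupling in any band.

## Design choices on genuinely open points

- Consensus slope sign across subjects = sign of the mean contributing
  slope (ties reported separately, not forced into either tally).
- Overlap denominator = |GN|; the alternative |IN_s| breaks the
  integer-count consistency above.
- Shared-edge threshold "at least 40 %" = fraction ≥ 0.40 (9 of 21
  subjects; 4 of 10 in the benchmark); the threshold is a config value,
  not a constant.
- p-values from the F-form of the test (equivalent to the t-form at
  k = 1); computed with the regularized incomplete-beta tail
  (`scipy.special.fdtrc`) for speed across ~10⁵ fits.
- QC-dropped epochs shorten n for that subject and shift the R² ⇔ p
  correspondence; n is recorded per fit.

## Known limitations

- The trend model is a straight line by design; non-monotonic fatigue
  dynamics (adaptation, self-regulation) will be under-detected.
- No multiple-testing correction, matching the gate's definition; the
  family-wise expectation is reported, not corrected for.
- EDF export requires MNE's optional `edfio` backend; without it the
  exporter raises with guidance. Reading EDF/BDF/BrainVision needs only
  `mne`.
- The real-data path holds one subject's five band copies in memory at
  a time; very long recordings at high rates may need chunking upstream.
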