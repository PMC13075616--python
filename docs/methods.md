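# Methods

This note documents the models, numerical choices, and deliberate
design decisions behind `iednet`, and what its synthetic cohorts do and
do not demonstrate.

## Problem and pipeline

The package analyses how medial temporal interictal discharges that are
invisible on scalp EEG (scalp-negative) change spectral power and
large-scale functional networks, contrasting discharge-locked epochs
against quiet epochs within patient and testing across a small cohort.
Stages: preprocessing → source-space ROI time courses → spike-locked
time–frequency statistics → band spectra → wPLI connectivity → weighted
network metrics → group tests. Every stage is importable on its own;
the `analysis/` drivers and `iednet.pipeline.run_pipeline` compose
them.

## Preprocessing

Signals are decimated to 200 Hz (zero-phase 8th-order Chebyshev-I
anti-alias at 0.8× the new Nyquist; polyphase resampling for
non-integer ratios) and then band-passed 1–35 Hz with a zero-phase
forward–backward 4th-order Butterworth (effective 8th order). The
decimate-then-filter order follows the clinical processing narrative
the pipeline reproduces; the operations are linear and the
order-sensitivity tests pass either way. Scalp channels are
re-referenced to the common average (idempotent). Depth contacts form
bipolar pairs along each shaft between adjacent contacts; a pair is
kept when at least one member is in gray matter. When both members are
gray with different labels, the pair inherits the deeper (lower-index)
contact's region — the source convention is silent here and a
deterministic rule is required for channel→ROI aggregation. Bad
channels are dropped on read rather than interpolated; the synthetic
cohorts contain none.

## Epochs and windows

Band analyses use a window of five cycles of the band's lowest
frequency, with the discharge peak at 3/8 of the window
(`round(fs·5/f_low)` samples; round-half-up for the peak index), and a
Tukey taper with cosine fraction r = 0.25 — the flat plateau spans
[0.125, 0.875] of the window, so the 3/8 peak sits on it and the peak
amplitude is preserved (the reason for Tukey over Hann). Wavelet
analyses use untapered −2..+3 s spans around discharge peaks and
±2.5 s around quiet markers (both 5 s, so per-condition maps share a
shape); edges are handled by the cone of influence instead of a taper.
Condition imbalance is removed by a seeded uniform subsample to the
smaller surviving count, never below it; the seed is recorded in the
run log.

## Time–frequency

Generalized Morse wavelet, γ = 3, time-bandwidth P² = 40
(β = P²/γ), one-sided in frequency (analytic), unit energy per scale,
on a log axis with 10 voices/octave from 1 to 40 Hz. Since ERSP is
baseline-relative and ITC is amplitude-invariant, the absolute wavelet
normalization cancels everywhere it is used. The cone of influence is
the e-folding time of each wavelet's temporal envelope, computed
numerically from the discretized wavelet; COI half-width scales as 1/f.
Boundary pixels are flagged (`TFMap.valid_mask`), not removed; cluster
formation runs on all pixels and each cluster's COI overlap is
reported.

**ERSP baseline.** Per patient and unit: mean no-IED power per
frequency, pooled over trials and times, used for both conditions. The
group contrast is a paired t on condition differences, in which any
common positive baseline cancels; this choice additionally makes the
no-IED map ≈ 0 dB, which aids inspection.

## Spectra and connectivity

Band power is the taper-energy-normalized periodogram
(density, µV²/Hz), averaged across trials and then across FFT bins with
centers in [f_low, f_high) — half-open so the shared edges at 4, 8 and
13 Hz are counted once. Spectral ITC is the per-bin mean unit phasor
magnitude across trials, band-averaged. Channel values aggregate to
regions by the arithmetic mean.

wPLI is estimated across trials per FFT bin of the band-tapered
epochs — epochs are short (five cycles), so across-time estimation
would have almost no degrees of freedom — then band-averaged.
Non-debiased form; estimator recorded in the matrix metadata. A zero
denominator (no imaginary cross-spectral mass) yields 0 by convention,
with the zero threshold set relative to the total cross-spectral
magnitude so float round-off on exactly real cross-spectra does not
register as synchrony. Intracranial channel pairs aggregate to region
pairs by the mean over cross-region channel pairs; within-region pairs
are never used; uncovered region pairs stay missing and enter the
network metrics as absent edges.

## Network metrics

On symmetric matrices with entries in [0, 1] (missing → 0): Onnela
weighted clustering, ŵ = W/max(W),
C_i = Σ_{j,h} (ŵ_ij ŵ_ih ŵ_jh)^{1/3} / (k_i(k_i−1)), which is invariant
to uniform weight scaling; and nodal efficiency with edge lengths 1/w
and Dijkstra shortest paths, which scales linearly with a uniform
weight factor. The binary clustering citation in the source narrative
is generalized to Onnela's form — the standard weighted generalization
in brain-connectivity practice for unthresholded matrices; the choice
is recorded in the output metadata. Brute-force enumeration oracles
(all triples; all simple paths on ≤ 6 nodes) and networkx serve as
independent cross-checks in the tests.

## Group statistics

Cluster-based permutation: one-sided paired t per pixel, cluster
formation above the one-sided t threshold at p_form, 4-connectivity
(the most conservative standard adjacency), cluster mass = summed t,
null = max cluster mass over all 2^n sign assignments for n ≤ 20
patients (seeded random assignments beyond that), identity included.
Including the identity guarantees validity and makes p-values
deterministic with min p = 1/2^n. Consequence worth stating: with nine
patients (512 assignments) the stricter ERSP cluster alpha of 0.001 can
never be met — 1/512 ≈ 0.00195 is the floor — so ERSP clusters are
reported with their exact p but cannot be flagged significant; the ITC
alpha (0.05) is unaffected. The observed map is taken from the identity
row of the same vectorized computation as the null so the comparison is
float-exact.

Scalar measures: one-sided Wilcoxon signed-rank (alternative:
increase during discharges), exact distribution for n ≤ 25 via scipy,
BH-FDR per family: whole-network measures across the 4 bands;
region-level measures across regions × 4 bands. Intracranial ROI
families are gated to regions sampled in at least five patients (the
default cohort is constructed so exactly the 12 core regions pass).
Source-space families span the regions that have reconstructed time
courses — the generator's 16 source regions, not all 72 atlas regions.

## Source reconstruction stand-in

Head modelling is out of scope; the pipeline consumes a linear inverse
operator. For synthetic cohorts it is built from the generator's own
effective mixing matrix: common-average-corrected forward, prewhitened
with the sensor covariance estimated from the quiet epochs, ridge
pseudo-inverse with λ = 0.1 × the trace-normalized whitened Gram
matrix. Region series are the first temporal singular vector of the
member-source stack, computed per epoch (keeping trials independent
for ITC), scaled by the singular value, sign fixed once per patient
(non-negative correlation with the region-mean series) so phase-locked
averages are consistent across trials.

## Synthetic cohorts: what they emulate

Defaults are the study conditions the pipeline targets: nine patients,
40 epochs per condition, alternating discharge hemisphere (exercising
the ipsi/contra relabelling), 1000 Hz raw sampling, ~9.3 min per
recording, 16 source regions, 32 scalp channels, three-contact depth
shafts (two gray, one white-matter) in 12 core + rotating extra
regions.

- **Background**: per-source 1/f noise (slope verified within ±0.3).
- **Pairwise couplings**: a shared band-passed oscillation added to
  both sources, one copy rotated via its analytic signal — the lag is
  analytically known and recovered within ±0.2 rad.
- **Network-wide drive** (one per band): one shared band-limited
  oscillation reaching *every* source with per-source phase offsets
  (0.18 rad steps, maximal pairwise lag < π so all pairs stay visible
  to wPLI), gain 0.25 → 0.9 inside ±2.5 s of each discharge
  (raised-cosine ramps). This models the large-scale synchronization
  increase the discharges produce. A deliberately broad effect is
  essential: strengthening only a few edges *lowers* max-normalized
  mean clustering, whereas a network-wide lift raises integration and
  segregation together — which is the phenomenon under study.
- **Transient**: difference-of-Gaussians spike (70 ms, amplitude 8
  background SDs) plus half-cosine slow wave (300 ms, amplitude 2.5),
  injected at discharge markers in the hippocampal-ipsi source.
- **Scalp mixing**: random dense matrix, deep sources (hippocampus,
  amygdala) attenuated ×0.15; the transient row is iteratively rescaled
  so its scalp footprint stays below `scalp_negative_margin` (default
  0.5) × the per-channel background SD. "Not visible" has no published
  quantification; the < 1 SD criterion on the trial-averaged footprint
  is this package's operationalization, exposed as a config knob.
- **Events**: jittered grid, minimum spacing 5.5 s (≥ the longest
  analysis window, preventing epoch overlap), conditions randomly
  interleaved; detector-style events concentrated on the hippocampal
  contact with a 40% amygdala co-fire and rare (5%) frontal events
  below the 1/10-of-max irritative-zone cut.
- **Determinism**: all randomness from one root seed expanded per
  patient (`SeedSequence(seed, spawn_key=(patient,))`); identical
  config + index ⇒ bit-identical output.

**What passing does not show.** The cohorts have no head-model realism
(single multiplicative depth factor, random topographies), no artifacts
(ICA and interpolation are consumed upstream in real data), stationary
backgrounds, no arousal states, and an effect programmed to be strong
(within-patient Wilcoxon floors are reached). Recovery here validates
the machinery — estimator correctness, calibration, wiring — not the
detectability of real scalp-negative discharges at clinical SNR.

## Problem sizes

Monte-Carlo checks use sizes chosen to make the suite comfortably
reproducible on a laptop core: 200-repetition cluster-FWER nulls on
9 × 12 × 20 maps, 500-repetition FDR nulls on 72 × 4 tables, and
reduced null cohorts (20 epochs/condition, 400 Hz, 5 min, 16 scalp
channels) for the 20-seed specificity sweep; the effect cohort runs at
the full default size. Group time–frequency maps are decimated ×10 in
time (to 50 ms resolution) before cluster statistics.

## Known limitations

- EDF export writes whole-second recordings (zero-padded final record).
- The ROI singular-vector sign convention can still flip between
  *patients* (not trials); group contrasts use within-patient
  differences, which are unaffected.
- With one gray bipolar pair per contact pair and one shaft per region,
  the iEEG(ROI) aggregation averages two pairs per region; real
  implantations are denser and more heterogeneous.
- Exhaustive sign-flip enumeration is capped at 2^20; larger cohorts
  fall back to seeded random assignments.
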