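# Methods

`clickpam` reimplements, as a testable pipeline, the analysis used to
describe and classify the echolocation clicks of two sympatric dolphin
species — the Indian Ocean humpback dolphin (*Sousa plumbea*) and the
Indo-Pacific bottlenose dolphin (*Tursiops aduncus*) — from
single-hydrophone passive acoustic recordings.  This note documents the
models, the numerical choices, and what the synthetic data do and do not
establish.

## Recording model and calibration

Audio is treated as a calibrated pressure time series.  A normalized
digital amplitude x in [-1, 1] maps to pressure `x * 10^(L/20)` uPa,
where L is the recorder's full-scale level (default 173 dB re 1 uPa,
peak convention — the standard way autonomous recorders are specified).
The absolute scale cancels in every SNR-relative criterion; it matters
only for the clipping rule (80% of full scale) and for writing WAV
files.  Preprocessing is a 4th-order Butterworth band-pass, 10-200 kHz,
applied forward-backward.  Zero-phase filtering was chosen because
inter-click intervals and envelope-peak positions must not be skewed by
group delay; the price is that the effective magnitude response is the
square of the one-pass design (attenuation doubles in dB), which the
tests account for by asserting against the analytic squared response.
The high cut is clamped to 0.99x Nyquist so the same specification works
on reduced-rate synthetic material.

## Click detection

The detector mirrors a segment-wise spectral energy test: 5 ms segments
are reduced to Welch power spectra (576-point FFT, Hanning window, 50%
sub-frame overlap; 1 kHz bins at 576 kHz), and a segment is flagged when
at least 13% of the bins between 15 and 95 kHz (inclusive; 81 bins, so
ceil(0.13 x 81) = 11) exceed the noise floor by more than 15 dB.

Two points are under-determined by that description and were resolved as
follows:

* **Noise floor.**  Segments are ranked by total power, the loudest 20%
  are discarded (clicks are loud and occupy few segments), and the rest
  are averaged per bin.  A plain low per-bin quantile was rejected: Welch
  powers are chi-squared distributed, so a 20th percentile sits 1-2 dB
  below the click-free mean and silently shifts the effective threshold.
* **Segment boundaries.**  Disjoint 5 ms tiles have a blind spot: a
  click on a tile boundary falls where every Hanning sub-frame tapers to
  zero, and measured recall dropped to ~93%.  Segments therefore advance
  by half their length, so every instant is interior to some segment;
  runs of consecutive flagged segments are merged and one candidate is
  placed per local envelope maximum (analytic-signal magnitude) separated
  by at least 1 ms and reaching half the run's peak.

False-positive rules follow the published procedure: candidates whose
waveform spectral peak lies below 20 kHz (vessel noise, snapping-shrimp
surrogates) and candidates whose envelope peak exceeds 80% of full scale
(clipping) are dropped, with machine-readable flags.  Only the highest
amplitude click per train goes on to feature extraction — the standard
single-receiver surrogate for on-axis selection; ties break toward the
earlier click.

## Train qualification

Candidates are grouped into trains at gaps longer than 0.3 s (three
times the ICI ceiling, so slow trains are never split).  A train
qualifies when it has at least 8 clicks, its mean inter-click interval
lies strictly between 10 ms and 0.1 s (excluding buzzes and burst
pulses), and it is "loud and clear": click-window RMS at least 10 dB
above the broadband background implied by the integrated noise spectrum.
The original screening was done by ear and eye; the RMS contract is the
closest automatable surrogate, and its measurement bandwidth is the full
detector band.  Each recording session is capped at twice the estimated
group size of trains, drawn uniformly with a reproducible seed.

## The eight click parameters

Each selected click is reduced to 32 raw samples centered on its
envelope peak (peak at index 16; zero-padded at recording edges).  The
short window excludes bottom/surface reflections.  From this window:

* **-10 dB duration** (us): the envelope (analytic-signal magnitude) is
  linearly interpolated 10x; duration is the time between the outermost
  crossings of `peak x 10^(-10/20)`.  Scale-invariant by construction.
* **Spectrum**: a single 32-point Hanning frame (the degenerate Welch
  case), refined 10x by zero-padding the windowed waveform to 320 points
  — the classical low-pass interpolation of a spectrum — giving a
  1.8 kHz grid at 576 kHz.
* **Peak frequency** F_P: bin of maximum power (ties to the lower bin);
  **centroid** F_C and **RMS bandwidth** BW_RMS: power-weighted mean and
  standard deviation of frequency; **-3/-10 dB bandwidths** and their
  **lower edges** F_L3/F_L10: outermost crossings of thresholds 3 and
  10 dB below the spectral peak, with linear interpolation between bins.
  Thresholds are defined on the *power* spectrum (-3 dB = half power =
  1/sqrt(2) amplitude; -10 dB = one-tenth power): the published table's
  "1/10 of amplitude" phrasing is internally inconsistent with its own
  -10 dB label, and the power convention keeps both thresholds on one
  scale.  All spectral sums are restricted to the 10-200 kHz band of the
  preprocessing filter so filtered-out bins cannot bias the moments.

Numerical caveats established by the tests: duration accuracy is limited
by the sampling period (1.74 us at 576 kHz) once the envelope sigma
approaches two samples, and the spectral maximum of a sub-single-cycle
pulse (under ~0.3 carrier cycles per envelope sigma) genuinely sits
below its nominal carrier — both implementation and independent
dense-FFT oracle agree on this.

## Statistics

Parameters are summarized per species by median with 5th/95th
percentiles (linear interpolation between order statistics — the common
default; no convention was published).  Species are compared with
two-sided Mann-Whitney U tests: exact null enumeration when both groups
have at most 20 untied values, otherwise the normal approximation with
tie correction.  Normality (one-sample KS against a fitted normal),
variance homogeneity (Levene) and log-normality screens are provided to
document the nonparametric route; note the KS screen uses fitted
parameters and is therefore anti-conservative (the Lilliefors issue) —
it is retained as a descriptive mirror of the original analysis, not as
a calibrated test.  No multiple-testing correction is applied, matching
the original analysis.

## Random-Forest classification

Forests use 3000 trees, bootstrap resampling per tree, and m_try =
floor(sqrt(M)) = 2 of the M = 8 parameters per split; class labels are
majority votes.  Out-of-bag (OOB) rows — the expected `(1 - 1/n)^n ~ 37%`
of rows left out of each bootstrap — give the correct-classification
rate without a held-out set.  A single forest yields one OOB rate, so
the published median-with-quantiles report is reproduced by refitting
the forest 100 times with independent seeds and taking the median and
5th/95th quantiles of the per-repeat rates; quantiles of per-tree error
rates are available as a diagnostic alternative (`per_tree_quantiles`).
Variable importance is Breiman-style permutation importance: per tree,
OOB accuracy minus OOB accuracy after permuting one predictor, averaged
over trees and over the first 10 repeats (a cost-bounding default;
importance estimates stabilize well before rate quantiles do).  Classes
are left unweighted: with a 27.6/72.4 prior imbalance, the majority
species is classified far above its prior while the minority species
barely clears it — expected majority-vote behavior, and exactly the
pattern the original study reports.  Expected chance rates equal the
empirical class priors.

## Synthetic data

`make_click` renders Gabor pulses — Gaussian envelopes (sigma in
microseconds) on cosine carriers, truncated at +/-4 sigma — because every
extractor then has a closed form: envelope = the Gaussian, -10 dB
duration = `2 sigma sqrt(ln 10) ~ 3.035 sigma`, amplitude spectrum
Gaussian with spectral sigma `1/(2 pi sigma)`.

`render_scene` mixes band-limited Gaussian noise (4th-order Butterworth
colored, default 2-150 kHz at 100 dB re 1 uPa broadband — a quiet
shallow bay), optional low-frequency impulsive interferers (rejected by
the 20 kHz rule), and click trains with jittered 10-100 ms ICIs and a
designated loudest click per train, returning a per-click truth table.
Scene SNR is specified on the scale the detector thresholds: the
per-bin spectral SNR of the click at its carrier in a 5 ms Welch
segment, calibrated deterministically (`amplitude_for_snr`).  Peak
amplitude over noise RMS would be misleading here — the 5 ms average
dilutes a tens-of-microseconds transient by roughly 25 dB.

`make_feature_table` skips audio and samples per-click parameter vectors
from a correlated log-normal family per species, with log-medians fixed
to the published per-species medians and log-spreads to the published
5-95% ranges (35 *S. plumbea* and 92 *T. aduncus* rows by default — the
study's sample sizes).  Correlations are fixed a priori at values
plausible for click spectra (frequencies mutually 0.6, bandwidths 0.5,
frequency-bandwidth -0.2, duration-bandwidth -0.3), and the physical
orderings F_L10 <= F_L3 <= F_P, BW_3 <= BW_10 are enforced after sampling.

What the synthetic data do **not** establish: the real joint dependence
structure between the eight parameters (only marginals are published),
off-axis distortion, propagation and multipath, real interferer
statistics, or recorder frequency response.  Consequently the
Random-Forest rates measured on the synthetic table (overall ~78%,
minority class ~40%, majority ~92% at the default seed) characterize a
table with the published marginals — not the published rates themselves,
which depend on the unpublished joint structure.  Passing tests show the
machinery is correct at the published operating points, not that the
synthetic bay is the real one.

## Problem sizes

Default test and acceptance runs use: 10-train/100-click scenes
(~16 s of audio at 576 kHz) for detector scoring, 10 s of click-free
noise for false alarms, 500 single-click snippets for parameter-recovery
statistics, and the full 3000-tree x 100-repeat forest protocol on the
127-row table.
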