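# clickpam

Detection, description and species classification of odontocete
echolocation clicks from single-hydrophone passive acoustic monitoring
(PAM) recordings.

Sympatric dolphin species can only be monitored acoustically if their
clicks can be told apart.  `clickpam` implements the full analysis chain
used to ask that question for the Indian Ocean humpback dolphin
(*Sousa plumbea*) and the Indo-Pacific bottlenose dolphin
(*Tursiops aduncus*): calibrated WAV audio is band-pass filtered
(Butterworth, 10–200 kHz, zero phase), clicks are detected with a
segment-wise spectral energy detector (5 ms Welch segments, 576-point
Hanning spectra; a segment is a candidate when ≥ 13% of the bins between
15 and 95 kHz exceed the noise floor by > 15 dB), false positives are
removed (spectral peak < 20 kHz, or clipped above 80% of full scale),
click trains are qualified (≥ 8 clicks, 10 ms < mean ICI < 0.1 s,
≥ 10 dB above background) and capped at twice the group size per
session, and the highest-amplitude click per train is reduced to eight
parameters:

| symbol | parameter |
|---|---|
| D₋₁₀dB | −10 dB envelope duration (µs) |
| F_P | peak frequency (kHz) |
| F_C | centroid frequency Σf·S(f)/ΣS(f) (kHz) |
| F_L3, F_L10 | lower −3 / −10 dB frequencies (kHz) |
| BW₋₃dB, BW₋₁₀dB | −3 / −10 dB bandwidths (kHz) |
| BW_RMS | RMS bandwidth √(Σ(f−F_C)²·S(f)/ΣS(f)) (kHz) |

computed from a 32-sample window around the envelope peak with 10×
low-pass interpolation (1.8 kHz spectral resolution at 576 kHz).
Species are then compared per parameter (median with 5th/95th
percentiles; two-sided Mann–Whitney U) and classified with a Random
Forest (n_tree = 3000, m_try = ⌊√8⌋ = 2) evaluated out-of-bag over 100
repeated fits, reporting median and 5th/95th quantile correct-
classification rates, chance baselines (class priors), and permutation
variable importance (mean decrease in accuracy).

A synthetic-data module generates ground-truthed Gabor click trains in
colored noise and species-labeled feature tables matched to the
published per-species medians and percentile ranges, so every stage is
testable without field recordings.  See `docs/methods.md` for the
modeling details and caveats.

## Worked example

```python
import clickpam as cp

# three click trains at 30 dB spectral SNR in a synthetic bay
scene = cp.detection_scene(n_trains=3, clicks_per_train=10, snr_db=30.0, seed=1)
rec, truth = cp.render_scene(scene)
rec = cp.bandpass(rec)

cands = cp.remove_false_positives(cp.detect_candidates(rec), rec=rec)
trains = [cp.qualify_train(t) for t in cp.group_into_trains(cands)]
print(f"{len(cands)} clicks in {sum(t.qualified for t in trains)} qualified trains")

feats = [cp.extract_features(cp.select_highest_amplitude(t), rec) for t in trains]
df = cp.features_to_frame(feats)
print(df[["fp_khz", "fc_khz", "d10_us", "bwrms_khz"]].round(1).to_string(index=False))
```

prints

```
30 clicks in 3 qualified trains
 fp_khz  fc_khz  d10_us  bwrms_khz
  117.0   116.0    13.4       27.2
   72.0    72.5    15.4       24.2
   79.2    78.9    15.8       23.6
```

— all 30 injected clicks are recovered in three qualified trains, and
the peak/centroid frequencies of the loudest click per train sit within
a spectral bin of the generating carriers (116.5, 71.8 and 78.6 kHz);
durations near 15 µs and RMS bandwidths near 25 kHz match the Gabor
models' closed forms.

The same stages are available from the shell:

```bash
clickpam simulate scene.yaml --out scene.wav --truth truth.csv
clickpam detect scene.wav --out candidates.csv
clickpam extract candidates.csv scene.wav --out features.csv
clickpam stats features.csv --out table3.csv
clickpam classify features.csv --ntree 3000 --repeats 100 --seed 1 --out rf.json
```

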