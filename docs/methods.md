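# Methods

This note documents the models, parameters and numerical choices behind
`ecgpeaks`, what the synthetic data does and does not emulate, and the known
limitations.

## Detection model

The detector treats R-peak detection as "find candidate energy bumps
cheaply, then let a classifier reject the false ones":

1. **Variational mode decomposition (VMD).** The ECG is decomposed into
   K narrow-band modes by minimising the summed bandwidth of the modes
   around jointly estimated centre frequencies, subject to (approximate)
   reconstruction. The solver is the standard ADMM iteration in the Fourier
   domain: each mode update is a Wiener filter of the residual centred on
   its frequency; each centre frequency moves to its mode's spectral
   centroid. We work on the one-sided (analytic) spectrum and rebuild real
   modes by conjugate symmetry.
2. **Hilbert spectrum.** Per mode, the analytic signal yields instantaneous
   amplitude a(t), unwrapped phase θ(t), instantaneous frequency
   ω(t) = (1/2π)·dθ/dt in Hz (first differences, last value repeated,
   negative excursions clamped to 0) and energy E(t) = a(t)².
3. **Dynamic mode selection (DMSE).** A mode is a QRS component when its
   frequency spread — mean ± one standard deviation over the whole series —
   lies inside the band [fl, fh]. Per-sample masks then remove out-of-band
   samples; the selected modes' in-band energy sums to Re, their in-band
   frequency to Rω, and the complement-masked energy of **all** K modes to
   the noise series Rn. Energy is partitioned exactly: per mode and sample,
   masked-in + masked-out energy equals E(t).
4. **Adaptive window sizing (AWS).** Local maxima of Re (prominence at
   least `min_prominence_frac` of the global maximum; width measured at
   half prominence) each spawn a window of ⌊width/2⌋ samples (minimum 1) on
   either side of the peak, clipped to the record. The threshold is
   deliberately permissive: a false candidate costs the classifier a vote,
   a missed energy peak is unrecoverable.
5. **Features and selection.** 25 features per window (peak height /
   frequency / prominence / width, previous and forward peak distances, and
   mean, population σ, SNR μ/σ, RMS, power, area, Shannon entropy, kurtosis
   and skewness over both the Re and the Rω slice, plus ΣRe/ΣRn). Greedy
   sequential forward selection with a depth-5 decision-tree wrapper and
   5-fold cross-validated misclassification MSE picks up to 8 features,
   stopping when the improvement drops below 1e-4.
6. **Subset ensemble.** One unpruned CART tree (Gini impurity) per
   non-empty subset of the n selected features — 2ⁿ−1 trees, each fit on an
   independent random 75% sample of the training windows restricted to its
   subset. Validation accuracy is the mean 10-fold cross-validation
   accuracy over the training partition; the top 16 trees are kept (ties
   broken toward larger subsets, then lexicographic order, so builds are
   deterministic). A window is R when at least half the trees vote R; the
   even-split tie resolves to R because a missed beat is costlier than a
   false alarm that deduplication can still absorb.
7. **R-location correction (RLC).** Each detection is moved to the argmax
   of the raw ECG within ± h samples, h = round(4·fs/360) — the printed
   ±4-sample window is specific to 360 Hz. Ties go to the earliest index.
   An optional `rlc.absolute` flag scores |e − median(e)| instead, for
   inverted-QRS leads; it is off by default so that a deliberate choice is
   required.

Training labels come from annotated beats: a window is R when an annotation
falls inside it after dilating the window by 50 ms per side. The dilation
absorbs the small systematic lag between the energy peak and the annotated
R sample introduced by the decomposition's filtering (RLC corrects the same
lag at detection time).

## Parameters that matter

| parameter | default | unit | why |
|---|---|---|---|
| `vmd.K` | 9 | modes | spreads 0–180 Hz finely enough to isolate a QRS-band mode at 360 Hz |
| `vmd.alpha` | 2000 | – | reference bandwidth penalty of the ADMM formulation |
| `vmd.tau` | 0 | – | no exact-reconstruction constraint, tolerates noise |
| `vmd.tol`, `max_iter` | 1e-7, 500 | – | non-convergence returns the best iterate with a logged warning |
| `dmse.fl`, `dmse.fh` | 3, 30 | Hz | see "Band choice" below |
| `roi.min_prominence_frac` | 0.01 | – | under-filter; the classifier rejects false peaks |
| `roi.label_tolerance_s` | 0.05 | s | decomposition lag absorption (¼ of the 150 ms matching window) |
| `features.max_features` | 8 | – | keeps the subset enumeration at ≤ 255 trees |
| `detector.*` | 0.8 / 10 / 0.75 / 16 | – | train fraction, CV folds, per-tree sample, ensemble size |
| `window_s`, `hop_s` | 1.5, 1.0 | s | streaming segmentation: 1.5 s windows, 0.5 s overlap |
| `dedup_refractory_s` | 0.2 | s | below the ~0.25 s physiological RR floor |
| `match_tolerance_s` | 0.15 | s | conventional QRS evaluation window |

**Band choice.** The classic QRS energy concentration is 8–20 Hz, but the
selection rule requires a mode's entire μ ± σ frequency spread inside the
band, and the QRS-band mode of a clean ECG carries σ ≈ 5–8 Hz around
μ ≈ 10–15 Hz (the instantaneous frequency wanders in the low-amplitude
stretches between beats). With a literal 8–20 Hz band the containment test
rejects every mode and the detector emits nothing. The default [3, 30] Hz
leaves room for the spread while still excluding baseline-wander modes
(≪ 1 Hz), 50/60 Hz powerline modes and broadband muscle noise. Both edges
are exposed in the config because detection quality depends on them.

**Coordinates.** Sample indices are 0-based; windows are half-open
[start, end). The AWS window is symmetric about its peak (the right edge is
inclusive of peak + half-width, implemented as end = peak + half-width + 1).

## Statistic conventions

The window statistics keep the stated forms even where they differ from the
textbook estimators: σ is the population standard deviation (denominator
N); kurtosis and skewness normalise by (N−1)·σ⁴ and (N−1)·σ³; SNR = μ/σ is
capped at 1e6 on flat windows, where kurtosis/skewness are set to 0;
entropy shifts the window by its minimum, normalises to a probability
vector and uses natural log with 0·log 0 = 0; area is the plain sample sum.
Frequency statistics are computed over the masked Rω slice including its
zeros — the simplest reading of the elementwise product (excluding the
masked samples instead is a defensible alternative; it changes the means of
partially masked windows). Edge windows with no previous/next peak receive
the record-median peak-to-peak distance so their feature vector stays
complete.

HRV: MRR is the mean of the N−1 R-R intervals, SDNN the root mean square
deviation of the intervals around MRR (divisor = interval count), RMSSD the
root mean square of the N−2 successive interval differences. Multi-record
aggregation offers both pooled intervals and per-record averaging
(`aggregate_hrv`), since published multi-record HRV figures rarely state
which convention they use.

The six classification metrics keep their printed forms, including the
nonstandard DER = (FP+FN)/TP, Accuracy = TP/(TP+FP+FN) and
Recall = TP/(TP+TN); percentages are rounded half-up to two decimals only
at the reporting layer.

## Synthetic data

The generator emulates a single-lead adult ECG at 360 Hz: five Gaussian
bumps per beat (P 0.15 mV/25 ms at −200 ms, Q −0.10 mV/10 ms at −30 ms,
R 1.0 mV/12 ms, S −0.15 mV/10 ms at +30 ms, T 0.35 mV/45 ms at +250 ms),
RR intervals Gaussian around 60/HR with a 0.25 s floor, plus baseline
wander (0.1 mV at 0.33 Hz), 60 Hz powerline (0.05 mV) and white sensor
noise. The benchmark cohorts cycle the white-noise SD through
0.02/0.05/0.1/0.2 mV across records so the training set contains both true
beats and noise-induced false candidates; 0.02 mV records form the "clean"
subset.

What it does **not** emulate: pathological morphologies (bundle-branch
blocks, paced beats, flutter waves), electrode motion artefacts,
respiration modulation, polarity inversion, or the beat-type diversity of a
real arrhythmia database. Passing the synthetic study therefore shows the
chain is implemented coherently and localises beats to within the RLC
window under additive noise — it does not certify clinical-grade
performance; for that, run `scripts/evaluate_mitdb.py` against the MIT-BIH
arrhythmia database.

## Numerical choices and degenerate inputs

- The signal is mirror-extended by half its length per side before VMD and
  trimmed after, suppressing boundary transients; decomposition is exactly
  time-reversal-equivariant and fully deterministic (uniform
  centre-frequency initialisation, no randomness).
- Reconstruction Σu_k ≈ x holds to ≤ 5% relative error for band-limited
  inputs (tones, noise-free synthetic ECG). Broadband white noise is *not*
  reconstructible by K narrow-band modes (≈ 15% residual at 0.02 mV noise);
  that residual is by design — it is the noise the decomposition removes.
- Empty mode selection is a recoverable condition: the segment yields zero
  detections and an info-level log line, never an exception.
- Flat-zero energy gives no peaks; constant windows trigger the statistic
  capping rules; records shorter than 2K samples are rejected up front.
- Problem sizes in the shipped study — 40 training and 10 evaluation
  records of 60 s — were chosen so the full suite and the reproduction
  script each run in a few minutes on one CPU while still exercising
  several thousand candidate windows.

## Known limitations

- **Sliding-window sensitivity.** On 1.5 s segments the μ ± σ containment
  test fails for roughly a quarter of windows (short segments inflate σ),
  so streaming-mode sensitivity (~76% at hop 1.0 s, ~93% at hop 0.5 s on
  clean synthetic data) trails batch-mode sensitivity (100%). Batch mode is
  the recommended offline path; a per-segment band or an amplitude-weighted
  frequency spread would be the natural extensions.
- The SFS step often stops after one or two features on synthetic data —
  peak height alone separates true from false candidates there. Real
  recordings with diverse morphologies are expected to drive the selection
  toward the larger subsets the ensemble is designed for.
- The WFDB reader supports signal formats 212 and 16 and beat annotations
  only — sufficient for the MIT-BIH arrhythmia database; other PhysioNet
  formats (multi-frequency, EDF) are out of scope.
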