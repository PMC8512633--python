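"""Build adaptive ROI windows around energy peaks and extract features.

Every local maximum of the QRS-band energy spawns one window of half the
peak's width on either side; windows are labelled R / False-R by whether a
ground-truth annotation falls inside (with a 50 ms alignment tolerance) and
described by a 25-dimensional feature vector.
"""

from ecgpeaks import PipelineConfig, SynthConfig, feature_matrix, generate, label_windows
from ecgpeaks.pipeline import segment_rois

record = generate(SynthConfig(duration=30.0, seed=2, white_noise_sd=0.1))
config = PipelineConfig()

component, windows = segment_rois(record.samples, record.fs, config)
label_windows(windows, record.annotation_indices(), record.fs, config.roi.label_tolerance_s)
X = feature_matrix(windows, component)

n_r = sum(w.label == "R" for w in windows)
print(f"candidate windows: {len(windows)} ({n_r} R, {len(windows) - n_r} False-R)")
print(f"ground-truth beats: {len(record.annotations)}")
w = windows[1]
print(f"\nexample window [{w.start}, {w.end}) around energy peak at sample {w.peak.location} "
      f"(width {w.peak.width:.1f} samples) -> label {w.label}")
print("\nfirst feature rows (peak height FhP, in-band energy mean FmuE, SNR FsnrS):")
print(X[["FhP", "FmuE", "FsnrS"]].head().to_string())
print("\nR windows sit on tall energy bumps with high signal-to-noise;")
print("False-R windows (noise peaks) are shorter and noisier — that contrast")
print("is what the decision-tree ensemble learns.")
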