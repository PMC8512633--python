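"""End-to-end orchestration: signal → QRS component → ROIs → features → R peaks.

Two inference modes share the same five stages:

* batch — decompose the whole record at once (training, offline analysis);
* sliding-window — segment the record into 1.5 s windows with 0.5 s overlap
  (hop 1.0 s), run the stages per segment, and deduplicate detections in the
  overlap regions (the mode a streaming device would run).

Training builds a labelled ROI dataset over a set of annotated records,
selects features by sequential forward selection, splits it stratified by
beat type 80/20 with a 10-fold partition of the training part, and trains
the feature-subset tree ensemble.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
import yaml

from .decomposition import VMDConfig, hilbert_spectrum, vmd_decompose
from .detector import SplitConfig, TrainedEnsemble, rlc_correct, rlc_half_window, split_dataset, train_ensemble
from .dmse import BandConfig, QRSComponent, aggregate, select_modes
from .evaluation import ConfusionCounts, classification_metrics
from .features import SFSResult, feature_matrix, sfs_select
from .roi import ROIWindow, aws_windows, find_energy_peaks, label_windows
from .signal_io import ECGRecord

__all__ = [
    "RoiConfig",
    "FeatureConfig",
    "RlcConfig",
    "PipelineConfig",
    "DetectorModel",
    "extract_component",
    "segment_rois",
    "build_dataset",
    "train_model",
    "run_detection",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RoiConfig:
    min_prominence_frac: float = 0.01
    label_tolerance_s: float = 0.05


@dataclass(frozen=True)
class FeatureConfig:
    max_features: int = 8
    sfs_tol: float = 1e-4


@dataclass(frozen=True)
class RlcConfig:
    absolute: bool = False


@dataclass
class PipelineConfig:
    vmd: VMDConfig = field(default_factory=VMDConfig)
    dmse: BandConfig = field(default_factory=BandConfig)
    roi: RoiConfig = field(default_factory=RoiConfig)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    detector: SplitConfig = field(default_factory=SplitConfig)
    match_tolerance_s: float = 0.15
    rlc: RlcConfig = field(default_factory=RlcConfig)
    window_s: float = 1.5   # sliding-window length
    hop_s: float = 1.0      # 0.5 s overlap between consecutive windows
    dedup_refractory_s: float = 0.2

    def __post_init__(self) -> None:
        if not self.window_s > self.hop_s > 0:
            raise ValueError("need window_s > hop_s > 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        for key, sub in (
            ("vmd", VMDConfig), ("dmse", BandConfig), ("roi", RoiConfig),
            ("features", FeatureConfig), ("detector", SplitConfig), ("rlc", RlcConfig),
        ):
            if key in raw:
                kwargs[key] = sub(**raw[key])
        for key in ("match_tolerance_s", "window_s", "hop_s", "dedup_refractory_s"):
            if key in raw:
                kwargs[key] = raw[key]
        return cls(**kwargs)


def extract_component(samples: np.ndarray, fs: float, config: PipelineConfig) -> QRSComponent:
    """Stages 2–3 on one segment: VMD → Hilbert spectrum → DMSE aggregate."""
    vmfs = vmd_decompose(np.asarray(samples, dtype=float), config.vmd, fs=fs)
    spectrum = hilbert_spectrum(vmfs)
    selected = select_modes(spectrum, config.dmse)
    return aggregate(spectrum, selected, config.dmse)


def segment_rois(samples: np.ndarray, fs: float, config: PipelineConfig) -> tuple[QRSComponent, list[ROIWindow]]:
    """Stages 2–4: QRS component plus adaptive ROI windows for one segment."""
    component = extract_component(samples, fs, config)
    if not component.selected_modes:
        logger.info("no mode inside [%g, %g] Hz; segment yields no candidates", config.dmse.fl, config.dmse.fh)
        return component, []
    peaks = find_energy_peaks(component, config.roi.min_prominence_frac)
    windows = aws_windows(peaks, len(samples))
    return component, windows


def build_dataset(
    records: list[ECGRecord], config: PipelineConfig
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Labelled ROI feature dataset over annotated records (batch mode).

    Returns (features X, labels y with 1 = R, strata) where a window's
    stratum is the beat symbol of the annotation it contains (windows with
    no annotation are the "False-R" stratum), enabling the stratified split.
    """
    frames, labels, strata = [], [], []
    for rec in records:
        component, windows = segment_rois(rec.samples, rec.fs, config)
        if not windows:
            logger.warning("record %s produced no ROI windows", rec.name)
            continue
        ann_idx = rec.annotation_indices()
        label_windows(windows, ann_idx, rec.fs, config.roi.label_tolerance_s)
        X = feature_matrix(windows, component)
        frames.append(X)
        tol = int(round(config.roi.label_tolerance_s * rec.fs))
        ann_sym = {i: s for i, s in rec.annotations}
        for w in windows:
            labels.append(1 if w.label == "R" else 0)
            if w.label == "R":
                inside = [i for i in ann_idx if w.start - tol <= i < w.end + tol]
                strata.append(ann_sym[inside[0]] if inside else "N")
            else:
                strata.append("False-R")
    if not frames:
        raise ValueError("no ROI windows produced from the given records")
    return pd.concat(frames, ignore_index=True), np.asarray(labels), np.asarray(strata)


@dataclass
class DetectorModel:
    """A trained detector: ensemble + the config it was trained under."""

    ensemble: TrainedEnsemble
    selected_features: list[str]
    sfs: SFSResult
    config: PipelineConfig
    fs: float
    test_report: dict = field(default_factory=dict)

    def save(self, path: str | Path) -> None:
        joblib.dump(self, Path(path))

    @staticmethod
    def load(path: str | Path) -> "DetectorModel":
        model = joblib.load(Path(path))
        if not isinstance(model, DetectorModel):
            raise TypeError(f"{path} does not contain a DetectorModel")
        return model


def train_model(records: list[ECGRecord], config: PipelineConfig | None = None) -> DetectorModel:
    """Train a global detector over a list of annotated records.

    Feature selection, the 80/20 stratified split and ensemble training are
    all driven by ``config.detector.seed``; retraining with the same records
    and seed reproduces identical trees and votes. The held-out 20% is scored
    into ``test_report``.
    """
    config = config or PipelineConfig()
    fs = records[0].fs
    if any(r.fs != fs for r in records):
        raise ValueError("all training records must share one sampling rate")
    X, y, strata = build_dataset(records, config)
    logger.info("dataset: %d windows (%d R / %d False-R)", len(y), int(y.sum()), int((1 - y).sum()))
    sfs = sfs_select(
        X, y,
        max_features=config.features.max_features,
        tol=config.features.sfs_tol,
        seed=config.detector.seed,
    )
    split = split_dataset(strata, config.detector)
    pos = {int(i): p for p, i in enumerate(split.train_idx)}
    folds = [
        (np.array([pos[int(i)] for i in a]), np.array([pos[int(i)] for i in b]))
        for a, b in split.folds
    ]
    Xtr = X.iloc[split.train_idx].reset_index(drop=True)
    ensemble = train_ensemble(Xtr, y[split.train_idx], sfs.selected, config.detector, folds)

    test_report: dict = {}
    if split.test_idx.size:
        Xte = X.iloc[split.test_idx].reset_index(drop=True)
        yte = y[split.test_idx]
        pred = ensemble.predict(Xte)
        counts = ConfusionCounts(
            tp=int(((pred == 1) & (yte == 1)).sum()),
            fp=int(((pred == 1) & (yte == 0)).sum()),
            tn=int(((pred == 0) & (yte == 0)).sum()),
            fn=int(((pred == 0) & (yte == 1)).sum()),
        )
        test_report = {"counts": counts, "metrics": classification_metrics(counts).rounded()}
    return DetectorModel(
        ensemble=ensemble,
        selected_features=sfs.selected,
        sfs=sfs,
        config=config,
        fs=fs,
        test_report=test_report,
    )


def _dedup(locations: np.ndarray, amplitudes: np.ndarray, refractory: int) -> np.ndarray:
    """Merge detections closer than ``refractory`` samples, keeping the one
    with the larger corrected amplitude."""
    order = np.argsort(locations)
    locs, amps = locations[order], amplitudes[order]
    kept_locs: list[int] = []
    kept_amps: list[float] = []
    for loc, amp in zip(locs, amps):
        if kept_locs and loc - kept_locs[-1] < refractory:
            if amp > kept_amps[-1]:
                kept_locs[-1], kept_amps[-1] = int(loc), float(amp)
        else:
            kept_locs.append(int(loc))
            kept_amps.append(float(amp))
    return np.asarray(kept_locs, dtype=int)


def run_detection(
    record: ECGRecord,
    model: DetectorModel,
    config: PipelineConfig | None = None,
    sliding: bool = True,
) -> np.ndarray:
    """Detect corrected R-peak sample indices in a record.

    ``sliding=True`` processes overlapping windows (window_s / hop_s from
    the config) as a streaming device would; ``sliding=False`` decomposes
    the whole record at once. Output is sorted, strictly increasing, with
    no two detections closer than the dedup refractory distance.
    """
    config = config or model.config
    if record.fs != model.fs:
        raise ValueError(f"record fs {record.fs} != model fs {model.fs}")
    n = record.samples.size
    if sliding:
        win = int(round(config.window_s * record.fs))
        hop = int(round(config.hop_s * record.fs))
        starts = list(range(0, max(n - win, 0) + 1, hop))
        if not starts:
            starts = [0]
        if starts[-1] + win < n:
            starts.append(n - win)
        segments = [(s, record.samples[s : min(s + win, n)]) for s in starts]
    else:
        segments = [(0, record.samples)]

    raw_locs: list[int] = []
    for offset, seg in segments:
        if seg.size < 2 * config.vmd.K:
            continue
        component, windows = segment_rois(seg, record.fs, config)
        if not windows:
            continue
        X = feature_matrix(windows, component)
        pred = model.ensemble.predict(X)
        for w, p in zip(windows, pred):
            if p == 1:
                raw_locs.append(offset + w.peak.location)
    if not raw_locs:
        return np.array([], dtype=int)
    corrected = np.array(
        [rlc_correct(record, loc, absolute=config.rlc.absolute) for loc in raw_locs], dtype=int
    )
    amps = record.samples[corrected]
    if config.rlc.absolute:
        amps = np.abs(amps - np.median(record.samples))
    refractory = int(round(config.dedup_refractory_s * record.fs))
    return _dedup(corrected, amps, refractory)
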