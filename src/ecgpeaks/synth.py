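"""Synthetic single-lead ECG with known R-peak ground truth.

Each heartbeat is the sum of five Gaussian bumps (P, Q, R, S, T) placed at
fixed offsets around the R peak; RR intervals are Gaussian around the mean
heart rate, truncated at a 0.25 s physiological floor. Optional additive
contaminants model the usual ECG noise sources: baseline wander (slow
sinusoid), powerline interference (50/60 Hz sinusoid), and white sensor
noise. Ground-truth R sample indices are returned as the record's
annotations (sentinel beat symbol "N").

The morphology is a Gaussian-bump simplification (ECGSYN-flavoured, without
the dynamical phase model): closed-form ground truth makes every downstream
stage testable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .signal_io import ECGRecord

__all__ = ["SynthConfig", "WaveParams", "generate"]


@dataclass(frozen=True)
class WaveParams:
    """One fiducial wave as a Gaussian bump.

    amplitude in mV; width is the Gaussian standard deviation in seconds;
    offset is the bump centre relative to the R peak in seconds.
    """

    amplitude: float
    width: float
    offset: float

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("wave width must be positive")


def _default_waves() -> dict[str, WaveParams]:
    # Textbook adult lead-II morphology, amplitudes in mV, times in s.
    return {
        "P": WaveParams(0.15, 0.025, -0.20),
        "Q": WaveParams(-0.10, 0.010, -0.030),
        "R": WaveParams(1.00, 0.012, 0.0),
        "S": WaveParams(-0.15, 0.010, 0.030),
        "T": WaveParams(0.35, 0.045, 0.25),
    }


@dataclass
class SynthConfig:
    fs: float = 360.0
    duration: float = 60.0
    mean_hr: float = 70.0           # beats/min
    rr_jitter_sd: float = 0.05      # s
    wave_params: dict[str, WaveParams] = field(default_factory=_default_waves)
    baseline_wander: tuple[float, float] = (0.10, 0.33)  # (mV, Hz)
    powerline: tuple[float, float] = (0.05, 60.0)        # (mV, Hz)
    white_noise_sd: float = 0.02    # mV
    seed: int = 0

    #: hard floor on RR intervals so beats never overlap
    RR_FLOOR: float = 0.25

    def __post_init__(self) -> None:
        if self.fs <= 0 or self.duration <= 0:
            raise ValueError("fs and duration must be positive")
        if not 20.0 < self.mean_hr < 300.0:
            raise ValueError(f"mean_hr {self.mean_hr} outside (20, 300) bpm")


def generate(config: SynthConfig) -> ECGRecord:
    """Generate one synthetic record; deterministic for a given seed."""
    rng = np.random.default_rng(config.seed)
    n = int(round(config.fs * config.duration))
    t = np.arange(n) / config.fs

    rr_mean = 60.0 / config.mean_hr
    # First beat half an interval in, so a jitter-free record holds exactly
    # duration/rr_mean beats spaced rr_mean apart.
    r_indices: list[int] = []
    beat_time = rr_mean / 2.0
    while beat_time < config.duration:
        idx = int(round(beat_time * config.fs))
        if idx >= n:
            break
        r_indices.append(idx)
        rr = rr_mean + (rng.normal(0.0, config.rr_jitter_sd) if config.rr_jitter_sd > 0 else 0.0)
        beat_time += max(config.RR_FLOOR, rr)

    sig = np.zeros(n)
    for idx in r_indices:
        r_time = idx / config.fs  # sample-aligned so the R apex sits on the annotation
        for wave in config.wave_params.values():
            centre = r_time + wave.offset
            lo = max(0, int((centre - 5 * wave.width) * config.fs))
            hi = min(n, int((centre + 5 * wave.width) * config.fs) + 1)
            if lo < hi:
                sig[lo:hi] += wave.amplitude * np.exp(
                    -0.5 * ((t[lo:hi] - centre) / wave.width) ** 2
                )

    amp_bw, f_bw = config.baseline_wander
    if amp_bw > 0:
        sig += amp_bw * np.sin(2 * np.pi * f_bw * t)
    amp_pl, f_pl = config.powerline
    if amp_pl > 0:
        sig += amp_pl * np.sin(2 * np.pi * f_pl * t)
    if config.white_noise_sd > 0:
        sig += rng.normal(0.0, config.white_noise_sd, size=n)

    annotations = [(idx, "N") for idx in r_indices]
    return ECGRecord(sig, fs=config.fs, name=f"synth-{config.seed}", annotations=annotations)
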