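"""Adaptive window sizing (AWS): peak-driven regions of interest.

Local maxima of the aggregated QRS-band energy Re mark candidate beats. Each
peak spawns one ROI window of half the peak's width (measured at half
prominence) on either side of the peak — wide energy bumps get wide windows,
narrow ones stay tight, which keeps P/T-wave samples out of QRS feature
windows. The peak threshold is deliberately permissive (1% of the maximum
prominence by default): false candidates are cheap because the downstream
classifier rejects them, while a missed energy peak can never be recovered.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import signal as sps

from .dmse import QRSComponent

__all__ = ["PeakInfo", "ROIWindow", "find_energy_peaks", "aws_windows", "label_windows"]


@dataclass(frozen=True)
class PeakInfo:
    location: int      # sample index
    height: float      # Re at the peak
    prominence: float
    width: float       # samples, at half prominence

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("peak width must be positive")
        if self.prominence > self.height + 1e-12:
            raise ValueError("prominence cannot exceed height")


@dataclass
class ROIWindow:
    """Half-open window [start, end) containing its generating peak."""

    start: int
    end: int
    peak: PeakInfo
    label: str | None = None  # "R" | "False-R" once labelled

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"bad window [{self.start}, {self.end})")
        if not self.start <= self.peak.location < self.end:
            raise ValueError("window must contain its peak")


def find_energy_peaks(component: QRSComponent, min_prominence_frac: float = 0.01) -> list[PeakInfo]:
    """All local maxima of Re with prominence >= frac * max(Re), by location."""
    re = np.asarray(component.Re, dtype=float)
    if re.size == 0 or re.max() <= 0:
        return []
    locs, props = sps.find_peaks(
        re,
        prominence=min_prominence_frac * re.max(),
        width=1e-9,  # request width measurement; excludes nothing
        rel_height=0.5,
    )
    return [
        PeakInfo(
            location=int(loc),
            height=float(re[loc]),
            prominence=float(props["prominences"][i]),
            width=float(props["widths"][i]),
        )
        for i, loc in enumerate(locs)
    ]


def aws_windows(peaks: Sequence[PeakInfo], signal_length: int) -> list[ROIWindow]:
    """One window per peak: half the peak width each side, clipped to bounds.

    The half-width is floored (minimum 1 sample) and the right edge is
    inclusive of location + half-width, so the window is symmetric about
    the peak before clipping.
    """
    out = []
    for p in peaks:
        q = max(1, int(p.width // 2))
        start = max(0, p.location - q)
        end = min(signal_length, p.location + q + 1)
        out.append(ROIWindow(start=start, end=end, peak=p))
    return out


def label_windows(
    windows: Sequence[ROIWindow],
    annotations: Sequence[int] | np.ndarray,
    fs: float,
    tolerance_s: float = 0.05,
) -> list[ROIWindow]:
    """Label each window R / False-R by annotated-beat containment.

    The window is dilated by round(tolerance_s * fs) samples on each side
    before the containment test, absorbing the small systematic shift of
    energy peaks relative to the annotated R sample that the decomposition's
    filtering introduces.
    """
    ann = np.sort(np.asarray(annotations, dtype=int))
    tol = int(round(tolerance_s * fs))
    for w in windows:
        lo, hi = w.start - tol, w.end + tol  # half-open [lo, hi)
        i = np.searchsorted(ann, lo, side="left")
        w.label = "R" if i < ann.size and ann[i] < hi else "False-R"
    return list(windows)
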