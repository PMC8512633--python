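"""Per-ROI feature extraction and sequential forward selection.

Twenty-five features per window: four peak descriptors (energy height,
frequency at the peak, prominence, width), two neighbour distances, nine
window statistics computed twice — once over the in-band energy slice (Re)
and once over the in-band frequency slice (Rω) — and one signal-level
signal-to-noise ratio ΣRe/ΣRn over the window.

Statistic conventions (kept exactly as stated, including the nonstandard
moment normalisations):

* σ is the population standard deviation (denominator N);
* kurtosis  = Σ(x−μ)⁴ / ((N−1)·σ⁴) and skewness = Σ(x−μ)³ / ((N−1)·σ³);
* SNR = μ/σ, capped at 1e6 when σ = 0 (flat window);
* entropy is Shannon entropy of the window values normalised to a
  probability vector (shifted by the window minimum first; 0·log 0 := 0);
* area is the plain sample sum (unit sample spacing);
* power = (1/N)Σx² and rms = √power.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.tree import DecisionTreeClassifier

from .dmse import QRSComponent
from .roi import ROIWindow

__all__ = ["FEATURE_NAMES", "SFSResult", "extract_features", "feature_matrix", "sfs_select"]

SNR_CAP = 1e6

_STAT_SUFFIXES = ["mu", "sigma", "snr", "rms", "p", "a", "h", "k", "s"]

#: canonical column order of the 25-feature vector
FEATURE_NAMES: list[str] = (
    ["FhP", "FfP", "FpP", "FwP", "FpD", "FfD"]
    + [f"F{s}E" for s in _STAT_SUFFIXES]
    + [f"F{s}f" for s in _STAT_SUFFIXES]
    + ["FsnrS"]
)


def _window_stats(x: np.ndarray) -> dict[str, float]:
    n = x.size
    mu = float(x.mean())
    sigma = float(np.sqrt(np.mean((x - mu) ** 2)))
    power = float(np.mean(x**2))
    rms = float(np.sqrt(power))
    area = float(x.sum())
    if sigma > 0:
        snr = mu / sigma
        if n > 1:
            kurt = float(np.sum((x - mu) ** 4) / ((n - 1) * sigma**4))
            skew = float(np.sum((x - mu) ** 3) / ((n - 1) * sigma**3))
        else:
            kurt = skew = 0.0
    else:
        snr = SNR_CAP if mu != 0 else 0.0
        kurt = skew = 0.0
    shifted = x - x.min()
    tot = shifted.sum()
    if tot > 0:
        p = shifted / tot
        nz = p[p > 0]
        entropy = float(-(nz * np.log(nz)).sum())
    else:
        entropy = 0.0
    return {
        "mu": mu, "sigma": sigma, "snr": snr, "rms": rms,
        "p": power, "a": area, "h": entropy, "k": kurt, "s": skew,
    }


def extract_features(
    window: ROIWindow,
    component: QRSComponent,
    prev_peak_loc: int | None,
    next_peak_loc: int | None,
    edge_distance: float,
) -> dict[str, float]:
    """The 25-feature vector of one ROI.

    ``edge_distance`` fills the previous/forward peak distance at record
    edges where a neighbour is missing (callers pass the record-median
    peak-to-peak distance so edge beats keep a complete, plausible vector).
    """
    p = window.peak
    e_slice = component.Re[window.start : window.end]
    f_slice = component.Rw[window.start : window.end]
    n_slice = component.Rn[window.start : window.end]

    feats: dict[str, float] = {
        "FhP": p.height,
        "FfP": float(component.Rw[p.location]),
        "FpP": p.prominence,
        "FwP": p.width,
        "FpD": float(p.location - prev_peak_loc) if prev_peak_loc is not None else edge_distance,
        "FfD": float(next_peak_loc - p.location) if next_peak_loc is not None else edge_distance,
    }
    for suffix, value in _window_stats(e_slice).items():
        feats[f"F{suffix}E"] = value
    for suffix, value in _window_stats(f_slice).items():
        feats[f"F{suffix}f"] = value
    noise = float(n_slice.sum())
    sig = float(e_slice.sum())
    feats["FsnrS"] = sig / noise if noise > 0 else (SNR_CAP if sig > 0 else 0.0)
    return feats


def feature_matrix(windows: Sequence[ROIWindow], component: QRSComponent) -> pd.DataFrame:
    """Feature vectors for a location-sorted window list, as a DataFrame.

    The edge-distance sentinel is the median peak-to-peak distance of the
    record (or the signal length if fewer than two peaks exist).
    """
    locs = [w.peak.location for w in windows]
    if len(locs) >= 2:
        edge = float(np.median(np.diff(locs)))
    else:
        edge = float(component.Re.size)
    rows = []
    for i, w in enumerate(windows):
        rows.append(
            extract_features(
                w,
                component,
                locs[i - 1] if i > 0 else None,
                locs[i + 1] if i + 1 < len(locs) else None,
                edge,
            )
        )
    return pd.DataFrame(rows, columns=FEATURE_NAMES)


@dataclass
class SFSResult:
    selected: list[str]        # in order of inclusion
    criterion: list[float]     # cross-validated MSE after each inclusion


def sfs_select(
    X: pd.DataFrame,
    y: np.ndarray,
    max_features: int = 8,
    tol: float = 1e-4,
    cv: int = 5,
    seed: int = 0,
    max_depth: int = 5,
) -> SFSResult:
    """Greedy sequential forward selection with a decision-tree wrapper.

    At each step the feature whose addition minimises the cross-validated
    misclassification MSE of a depth-limited tree is added; selection stops
    at ``max_features`` or when the best improvement falls below ``tol``.
    The criterion trajectory is non-increasing up to the stopping step.
    """
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("sfs_select requires both classes present")
    splitter = StratifiedKFold(n_splits=cv, shuffle=True, random_state=seed)
    folds = list(splitter.split(X, y))

    def cv_mse(cols: list[str]) -> float:
        Xs = X[cols].to_numpy()
        errs = []
        for tr, va in folds:
            clf = DecisionTreeClassifier(criterion="gini", max_depth=max_depth, random_state=seed)
            clf.fit(Xs[tr], y[tr])
            pred = clf.predict(Xs[va])
            errs.append(float(np.mean((pred != y[va]).astype(float))))
        return float(np.mean(errs))

    selected: list[str] = []
    trajectory: list[float] = []
    current = np.inf
    remaining = list(X.columns)
    while remaining and len(selected) < min(max_features, X.shape[1]):
        scores = [(cv_mse(selected + [c]), c) for c in remaining]
        best_mse, best_col = min(scores, key=lambda t: (t[0], X.columns.get_loc(t[1])))
        if np.isfinite(current) and current - best_mse < tol:
            break
        selected.append(best_col)
        remaining.remove(best_col)
        trajectory.append(best_mse)
        current = best_mse
    return SFSResult(selected=selected, criterion=trajectory)
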