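"""Feature-subset decision-tree ensemble and R-location correction.

The classifier is an ensemble of CART trees, one per non-empty subset of the
n selected features (2ⁿ−1 trees in total). Each tree trains on an
independent random 75% sample of the training set restricted to its feature
subset; its validation accuracy is the mean 10-fold cross-validation
accuracy over the training partition. The ensemble keeps the top trees by
validation accuracy (16 by default) and classifies a window as R when at
least half the trees vote R — the even-split tie goes to R, since a missed
beat is costlier than a false alarm that location correction and
deduplication can still absorb.

R-location correction (RLC) snaps a detection to the raw-ECG argmax within
± h samples (h = 4 at 360 Hz, scaled with the sampling rate): the energy
peak is systematically a few samples off the R apex because of the filtering
inside the decomposition.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold
from sklearn.tree import DecisionTreeClassifier

from .signal_io import ECGRecord

__all__ = [
    "SplitConfig",
    "SplitResult",
    "TrainedEnsemble",
    "gini_index",
    "split_dataset",
    "train_ensemble",
    "rlc_correct",
    "rlc_half_window",
]

logger = logging.getLogger(__name__)

MAX_SUBSET_FEATURES = 16  # 2^16 - 1 trees is already the enumeration limit


def gini_index(class_probs) -> float:
    """Gini impurity 1 − Σ pⱼ² of a class-probability vector."""
    p = np.asarray(class_probs, dtype=float)
    if (p < 0).any():
        raise ValueError("probabilities must be non-negative")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"probabilities must sum to 1, got {p.sum()!r}")
    return float(1.0 - np.sum(p**2))


@dataclass(frozen=True)
class SplitConfig:
    train_frac: float = 0.8
    cv_folds: int = 10
    per_tree_sample_frac: float = 0.75
    ensemble_size: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.train_frac < 1:
            raise ValueError("train_frac must be in (0, 1)")
        if self.ensemble_size < 1:
            raise ValueError("ensemble_size must be >= 1")


@dataclass
class SplitResult:
    train_idx: np.ndarray
    test_idx: np.ndarray
    folds: list[tuple[np.ndarray, np.ndarray]]  # (fit, validate) within train_idx


def split_dataset(strata, config: SplitConfig = SplitConfig()) -> SplitResult:
    """Stratified train/test split plus a K-fold partition of the train set.

    ``strata`` is one hashable group key per sample (e.g. the beat type of
    the annotation a window contains, or "False-R"); each stratum is split
    train_frac/(1−train_frac) independently. A stratum with fewer than two
    members goes wholly to training. Deterministic for a given seed.
    """
    strata = np.asarray(strata)
    rng = np.random.default_rng(config.seed)
    train_parts, test_parts = [], []
    for value in sorted(pd.unique(strata), key=str):
        idx = np.flatnonzero(strata == value)
        if idx.size < 2:
            logger.warning("stratum %r has %d member(s); placed wholly in training", value, idx.size)
            train_parts.append(idx)
            continue
        perm = rng.permutation(idx)
        n_train = int(round(config.train_frac * idx.size))
        n_train = min(max(n_train, 1), idx.size - 1)
        train_parts.append(perm[:n_train])
        test_parts.append(perm[n_train:])
    train_idx = np.sort(np.concatenate(train_parts))
    test_idx = np.sort(np.concatenate(test_parts)) if test_parts else np.array([], dtype=int)
    kf = KFold(n_splits=config.cv_folds, shuffle=True, random_state=config.seed)
    folds = [(train_idx[a], train_idx[b]) for a, b in kf.split(train_idx)]
    return SplitResult(train_idx=train_idx, test_idx=test_idx, folds=folds)


@dataclass
class EnsembleMember:
    tree: DecisionTreeClassifier
    features: tuple[str, ...]
    val_accuracy: float


@dataclass
class TrainedEnsemble:
    """Majority-vote ensemble over feature-subset trees.

    A window is classified R when votes_R * 2 >= number of trees, i.e.
    strict majority with even ties resolved toward R.
    """

    members: list[EnsembleMember]
    feature_names: list[str] = field(default_factory=list)

    def vote_fractions(self, X: pd.DataFrame) -> np.ndarray:
        """Fraction of trees voting R per row — the score used for the ROC."""
        if not self.members:
            raise ValueError("empty ensemble")
        votes = np.zeros(len(X))
        for m in self.members:
            votes += m.tree.predict(X[list(m.features)].to_numpy()).astype(float)
        return votes / len(self.members)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Per-row labels: 1 for R, 0 for False-R."""
        return (self.vote_fractions(X) >= 0.5).astype(int)


def train_ensemble(
    X: pd.DataFrame,
    y: np.ndarray,
    selected_features: list[str],
    config: SplitConfig = SplitConfig(),
    folds: list[tuple[np.ndarray, np.ndarray]] | None = None,
) -> TrainedEnsemble:
    """Train one tree per non-empty subset of the selected features.

    ``X``/``y`` are the training rows (labels 1 = R, 0 = False-R); ``folds``
    are (fit, validate) row-index pairs from :func:`split_dataset` (a fresh
    10-fold partition is built when omitted). Each subset's validation
    accuracy is the mean fold accuracy of a tree fit on the complementary
    folds; the returned ensemble holds the top ``ensemble_size`` subsets by
    accuracy, ties broken toward larger subsets then lexicographic order,
    each refit on an independent random 75% sample of all training rows.
    """
    n = len(selected_features)
    if n < 1:
        raise ValueError("need at least one selected feature")
    if n > MAX_SUBSET_FEATURES:
        raise ValueError(
            f"{n} features would enumerate 2^{n}-1 trees; reduce max_features to <= {MAX_SUBSET_FEATURES}"
        )
    y = np.asarray(y).astype(int)
    if folds is None:
        kf = KFold(n_splits=config.cv_folds, shuffle=True, random_state=config.seed)
        idx = np.arange(len(X))
        folds = [(idx[a], idx[b]) for a, b in kf.split(idx)]

    # Row positions: folds refer to positions within X.
    subsets = [
        combo
        for size in range(1, n + 1)
        for combo in itertools.combinations(selected_features, size)
    ]
    rng = np.random.default_rng(config.seed)
    scored: list[tuple[float, int, tuple[str, ...], DecisionTreeClassifier]] = []
    Xnp = {c: X[c].to_numpy() for c in selected_features}
    for subset in subsets:
        cols = np.column_stack([Xnp[c] for c in subset])
        accs = []
        for fit_idx, val_idx in folds:
            clf = DecisionTreeClassifier(criterion="gini", random_state=config.seed)
            clf.fit(cols[fit_idx], y[fit_idx])
            accs.append(float(np.mean(clf.predict(cols[val_idx]) == y[val_idx])))
        val_acc = float(np.mean(accs))
        n_sample = max(1, int(round(config.per_tree_sample_frac * len(X))))
        rows = rng.choice(len(X), size=n_sample, replace=False)
        final = DecisionTreeClassifier(criterion="gini", random_state=config.seed)
        final.fit(cols[rows], y[rows])
        scored.append((val_acc, len(subset), subset, final))

    scored.sort(key=lambda t: (-t[0], -t[1], t[2]))
    members = [
        EnsembleMember(tree=tree, features=subset, val_accuracy=acc)
        for acc, _, subset, tree in scored[: config.ensemble_size]
    ]
    return TrainedEnsemble(members=members, feature_names=list(selected_features))


def rlc_half_window(fs: float) -> int:
    """± search half-window in samples: 4 at 360 Hz, scaled with fs."""
    return max(1, int(round(4.0 * fs / 360.0)))


def rlc_correct(
    record: ECGRecord,
    detected_location: int,
    half_window: int | None = None,
    absolute: bool = False,
) -> int:
    """Snap a detection to the raw-signal argmax within ± half_window.

    ``absolute`` scores |e − median(e)| instead of e, for inverted-QRS leads.
    Ties go to the earliest index; the result never moves more than
    half_window samples and its amplitude is >= the original.
    """
    if not 0 <= detected_location < record.samples.size:
        raise ValueError("detected location outside record")
    h = rlc_half_window(record.fs) if half_window is None else half_window
    lo = max(0, detected_location - h)
    hi = min(record.samples.size, detected_location + h + 1)
    seg = record.samples[lo:hi]
    if absolute:
        seg = np.abs(seg - np.median(record.samples))
    return lo + int(np.argmax(seg))
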