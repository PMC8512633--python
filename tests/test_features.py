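import math

import numpy as np
import pandas as pd
import pytest

from ecgpeaks import FEATURE_NAMES, extract_features, feature_matrix, sfs_select
from ecgpeaks.dmse import QRSComponent
from ecgpeaks.features import SNR_CAP, _window_stats
from ecgpeaks.roi import PeakInfo, ROIWindow


def naive_stats(x):
    """Independent loop implementation of the nine window statistics."""
    x = list(map(float, x))
    n = len(x)
    mu = sum(x) / n
    sigma = math.sqrt(sum((v - mu) ** 2 for v in x) / n)
    power = sum(v * v for v in x) / n
    rms = math.sqrt(power)
    area = sum(x)
    if sigma > 0:
        snr = mu / sigma
        kurt = sum((v - mu) ** 4 for v in x) / ((n - 1) * sigma**4) if n > 1 else 0.0
        skew = sum((v - mu) ** 3 for v in x) / ((n - 1) * sigma**3) if n > 1 else 0.0
    else:
        snr = SNR_CAP if mu != 0 else 0.0
        kurt = skew = 0.0
    shifted = [v - min(x) for v in x]
    tot = sum(shifted)
    ent = -sum((s / tot) * math.log(s / tot) for s in shifted if s > 0) if tot > 0 else 0.0
    return dict(mu=mu, sigma=sigma, snr=snr, rms=rms, p=power, a=area, h=ent, k=kurt, s=skew)


def make_component(re, rw=None, rn=None, fs=360.0):
    re = np.asarray(re, dtype=float)
    n = re.size
    rw = np.zeros(n) if rw is None else np.asarray(rw, dtype=float)
    rn = np.zeros(n) if rn is None else np.asarray(rn, dtype=float)
    return QRSComponent([0], np.ones((1, n), dtype=bool), re, rw, rn, fs)


def window_at(loc, start, end, width=8.0):
    return ROIWindow(start=start, end=end, peak=PeakInfo(location=loc, height=1.0, prominence=0.5, width=width))


class TestWindowStats:
    def test_arithmetic_on_1_2_3(self):
        s = _window_stats(np.array([1.0, 2.0, 3.0]))
        assert s["mu"] == pytest.approx(2.0)
        assert s["sigma"] == pytest.approx(math.sqrt(2.0 / 3.0))
        assert s["rms"] == pytest.approx(math.sqrt(14.0 / 3.0))
        assert s["p"] == pytest.approx(14.0 / 3.0)
        assert s["a"] == pytest.approx(6.0)

    def test_values_symmetric_about_mean_have_zero_skew(self):
        # deviations (-1, 0, 1) cancel in the third moment
        assert _window_stats(np.array([1.0, 2.0, 3.0]))["s"] == pytest.approx(0.0)

    def test_constant_window_capping(self):
        s = _window_stats(np.full(5, 3.0))
        assert s["snr"] == SNR_CAP
        assert s["k"] == 0.0 and s["s"] == 0.0 and s["h"] == 0.0

    def test_zero_window(self):
        s = _window_stats(np.zeros(4))
        assert s["snr"] == 0.0 and s["a"] == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_random_window_matches_naive_oracle(self, seed):
        x = np.random.default_rng(seed).normal(size=64)
        got = _window_stats(x)
        expected = naive_stats(x)
        for key in expected:
            assert got[key] == pytest.approx(expected[key], rel=1e-10), key


class TestExtractFeatures:
    def test_full_vector_matches_naive_oracle(self):
        rng = np.random.default_rng(1)
        n = 400
        re, rw, rn = rng.uniform(0, 2, n), rng.uniform(0, 30, n), rng.uniform(0, 1, n)
        comp = make_component(re, rw, rn)
        w = window_at(200, 168, 233)
        w.peak = PeakInfo(location=200, height=float(re[200]), prominence=0.3, width=9.0)
        feats = extract_features(w, comp, prev_peak_loc=100, next_peak_loc=320, edge_distance=250.0)
        assert list(feats) == FEATURE_NAMES
        assert feats["FhP"] == re[200]
        assert feats["FfP"] == rw[200]
        assert feats["FpP"] == 0.3 and feats["FwP"] == 9.0
        assert feats["FpD"] == 100.0 and feats["FfD"] == 120.0
        e_oracle = naive_stats(re[168:233])
        f_oracle = naive_stats(rw[168:233])
        for suffix in "mu sigma snr rms p a h k s".split():
            short = {"mu": "mu", "sigma": "sigma", "snr": "snr", "rms": "rms",
                     "p": "p", "a": "a", "h": "h", "k": "k", "s": "s"}[suffix]
            assert feats[f"F{short}E"] == pytest.approx(e_oracle[suffix], rel=1e-10)
            assert feats[f"F{short}f"] == pytest.approx(f_oracle[suffix], rel=1e-10)
        assert feats["FsnrS"] == pytest.approx(re[168:233].sum() / rn[168:233].sum())

    def test_edge_windows_use_sentinel_distance(self):
        comp = make_component(np.ones(100))
        w = window_at(50, 45, 56)
        feats = extract_features(w, comp, None, None, edge_distance=77.0)
        assert feats["FpD"] == 77.0 and feats["FfD"] == 77.0

    def test_shift_equivariance(self):
        rng = np.random.default_rng(4)
        n, shift = 500, 60
        re, rw = rng.uniform(0, 2, n), rng.uniform(0, 30, n)
        comp_a = make_component(re, rw)
        comp_b = make_component(np.roll(re, shift), np.roll(rw, shift))
        wa = window_at(200, 180, 221)
        wb = window_at(200 + shift, 180 + shift, 221 + shift)
        fa = extract_features(wa, comp_a, 140, 260, 100.0)
        fb = extract_features(wb, comp_b, 140 + shift, 260 + shift, 100.0)
        for name in FEATURE_NAMES:
            assert fa[name] == pytest.approx(fb[name], rel=1e-12), name

    def test_feature_matrix_edge_sentinel_is_median_gap(self):
        comp = make_component(np.ones(1000))
        wins = [window_at(loc, loc - 5, loc + 6) for loc in (100, 300, 520, 700)]
        X = feature_matrix(wins, comp)
        med = np.median(np.diff([100, 300, 520, 700]))
        assert X.loc[0, "FpD"] == med
        assert X.loc[3, "FfD"] == med
        assert X.loc[1, "FpD"] == 200.0


class TestSFS:
    @staticmethod
    def dataset(n=200, seed=0):
        rng = np.random.default_rng(seed)
        y = (rng.uniform(size=n) > 0.5).astype(int)
        X = pd.DataFrame(
            {
                "noise1": rng.normal(size=n),
                "signal": y * 10.0 + rng.normal(scale=0.1, size=n),
                "noise2": rng.normal(size=n),
            }
        )
        return X, y

    def test_perfectly_separating_feature_chosen_first(self):
        X, y = self.dataset()
        res = sfs_select(X, y, max_features=3)
        assert res.selected[0] == "signal"
        assert res.criterion[0] == 0.0
        # oracle: exhaustive single-feature sweep confirms nothing beats it
        assert res.criterion[0] <= min(
            sfs_select(X[[c]], y, max_features=1).criterion[0] for c in X.columns
        )

    def test_duplicate_of_selected_feature_not_added(self):
        X, y = self.dataset()
        X["signal_copy"] = X["signal"]
        res = sfs_select(X, y, max_features=4)
        # once separation is perfect the duplicate brings no improvement
        assert not {"signal", "signal_copy"} <= set(res.selected)

    def test_max_features_one(self):
        X, y = self.dataset()
        res = sfs_select(X, y, max_features=1)
        assert len(res.selected) == 1

    def test_single_class_rejected(self):
        X, _ = self.dataset()
        with pytest.raises(ValueError):
            sfs_select(X, np.zeros(len(X), dtype=int), max_features=2)

    def test_criterion_trajectory_non_increasing(self):
        rng = np.random.default_rng(2)
        n = 300
        y = (rng.uniform(size=n) > 0.5).astype(int)
        X = pd.DataFrame(rng.normal(size=(n, 6)), columns=list("abcdef"))
        X["a"] += y * 1.5  # weakly informative
        X["b"] += y * 0.7
        res = sfs_select(X, y, max_features=6, tol=0.0)  # add while strictly improving or equal
        assert all(b <= a + 1e-12 for a, b in zip(res.criterion, res.criterion[1:]))
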