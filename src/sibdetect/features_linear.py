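"""Time-domain (57) and frequency-domain (12) features per window.

Nineteen time-domain features and four frequency-domain features are computed
per channel (X, Y, Z), from the low-pass-filtered window.  The two
cross-channel features (cross-correlation coefficient and mean channel
difference) use the cyclic pairing X:XY, Y:YZ, Z:ZX.

Feature names follow ``<feature>_<channel>``, e.g. ``rms_x``,
``pct50_y``, ``fft_freq1_z``.
"""

from __future__ import annotations

import numpy as np

from .preprocess import Window

__all__ = [
    "TIME_FEATURE_NAMES",
    "FREQ_FEATURE_NAMES",
    "LINEAR_FEATURE_NAMES",
    "time_domain_features",
    "frequency_domain_features",
    "linear_features",
]

_CHANNELS = ("x", "y", "z")
# cyclic channel->pair assignment for the two cross-channel features
_PAIRS = {"x": (0, 1), "y": (1, 2), "z": (2, 0)}

_PERCENTILES = (1, 10, 25, 50, 75, 90, 99)

# The 19 per-channel time-domain features. "Mean absolute value" completes
# the per-channel count of 19 (it also appears throughout the component
# loadings reported for this feature set).
_TIME_BASE = (
    ["crosscorr", "mean_diff", "variance", "local_minima", "local_maxima",
     "peak", "minimum"]
    + [f"pct{p}" for p in _PERCENTILES]
    + ["zero_crossings", "average", "mean_abs", "rms", "jerk"]
)
assert len(_TIME_BASE) == 19

_FREQ_BASE = ("fft_freq1", "fft_freq2", "fft_amp1", "fft_amp2")

TIME_FEATURE_NAMES = tuple(f"{f}_{c}" for c in _CHANNELS for f in _TIME_BASE)
FREQ_FEATURE_NAMES = tuple(f"{f}_{c}" for c in _CHANNELS for f in _FREQ_BASE)
LINEAR_FEATURE_NAMES = TIME_FEATURE_NAMES + FREQ_FEATURE_NAMES


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation; 0 (not NaN) when either channel is constant.

    Constancy is judged relative to the channel's magnitude so that the
    round-off variance of a constant offset (the mean of n copies of a
    float is not exactly that float) does not register as signal.
    """
    sa, sb = a.std(), b.std()
    if sa <= 1e-12 * np.abs(a).max() or sb <= 1e-12 * np.abs(b).max() or sa == 0 or sb == 0:
        return 0.0
    return float(np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb))


def _count_local_extrema(x: np.ndarray) -> tuple[int, int]:
    """Strict interior local minima / maxima counts."""
    if len(x) < 3:
        return 0, 0
    left, mid, right = x[:-2], x[1:-1], x[2:]
    minima = int(np.sum((mid < left) & (mid < right)))
    maxima = int(np.sum((mid > left) & (mid > right)))
    return minima, maxima


def _zero_crossings(x: np.ndarray) -> int:
    """Sign changes of the mean-centred signal; exact zeros are skipped."""
    centred = x - x.mean()
    s = np.sign(centred)
    s = s[s != 0]
    if len(s) < 2:
        return 0
    return int(np.sum(s[:-1] != s[1:]))


def time_domain_features(window: Window, rate_hz: float) -> dict[str, float]:
    """57 time-domain features from the filtered window (19 per channel)."""
    w = window.filtered
    if w.shape[0] < 2:
        raise ValueError("window must hold at least 2 samples")
    out: dict[str, float] = {}
    for ci, c in enumerate(_CHANNELS):
        x = w[:, ci]
        p1, p2 = _PAIRS[c]
        out[f"crosscorr_{c}"] = _pearson(w[:, p1], w[:, p2])
        out[f"mean_diff_{c}"] = float(np.mean(w[:, p1] - w[:, p2]))
        out[f"variance_{c}"] = float(np.var(x))
        n_min, n_max = _count_local_extrema(x)
        out[f"local_minima_{c}"] = float(n_min)
        out[f"local_maxima_{c}"] = float(n_max)
        out[f"peak_{c}"] = float(np.max(x))
        out[f"minimum_{c}"] = float(np.min(x))
        for p, v in zip(_PERCENTILES, np.percentile(x, _PERCENTILES)):
            out[f"pct{p}_{c}"] = float(v)
        out[f"zero_crossings_{c}"] = float(_zero_crossings(x))
        out[f"average_{c}"] = float(np.mean(x))
        out[f"mean_abs_{c}"] = float(np.mean(np.abs(x)))
        out[f"rms_{c}"] = float(np.sqrt(np.mean(x**2)))
        out[f"jerk_{c}"] = float(np.mean(np.abs(np.diff(x))) * rate_hz)
    return out


def _spectral_peaks(x: np.ndarray, rate_hz: float) -> tuple[float, float, float, float]:
    """Two largest local maxima of the magnitude spectrum (DC excluded).

    Returns (f1, f2, a1, a2) ordered by descending amplitude, ties broken
    toward lower frequency; missing peaks are reported as 0.
    """
    n = len(x)
    mag = np.abs(np.fft.rfft(x - x.mean()))
    freqs = np.fft.rfftfreq(n, d=1.0 / rate_hz)
    # local maxima over bins 1..end, one-sided comparison at the edges
    peaks = []
    for i in range(1, len(mag)):
        left_ok = mag[i] > mag[i - 1] if i - 1 >= 1 else True
        right_ok = mag[i] > mag[i + 1] if i + 1 < len(mag) else True
        if left_ok and right_ok and mag[i] > 0:
            peaks.append(i)
    # descending amplitude, ties toward lower frequency
    peaks.sort(key=lambda i: (-mag[i], freqs[i]))
    amp_scale = 2.0 / n  # single-sided amplitude of a pure sinusoid
    vals = []
    for i in peaks[:2]:
        vals.append((float(freqs[i]), float(mag[i] * amp_scale)))
    while len(vals) < 2:
        vals.append((0.0, 0.0))
    (f1, a1), (f2, a2) = vals
    return f1, f2, a1, a2


def frequency_domain_features(window: Window, rate_hz: float) -> dict[str, float]:
    """12 frequency-domain features: the two dominant spectral peaks per channel."""
    w = window.filtered
    if w.shape[0] < 4:
        raise ValueError("window must hold at least 4 samples")
    out: dict[str, float] = {}
    for ci, c in enumerate(_CHANNELS):
        f1, f2, a1, a2 = _spectral_peaks(w[:, ci], rate_hz)
        out[f"fft_freq1_{c}"] = f1
        out[f"fft_freq2_{c}"] = f2
        out[f"fft_amp1_{c}"] = a1
        out[f"fft_amp2_{c}"] = a2
    return out


def linear_features(window: Window, rate_hz: float) -> dict[str, float]:
    """All 69 time- plus frequency-domain features for one window."""
    out = time_domain_features(window, rate_hz)
    out.update(frequency_domain_features(window, rate_hz))
    return out
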