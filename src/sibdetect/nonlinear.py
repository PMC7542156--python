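"""Nonlinear motor-variability battery: delay embedding, sample entropy,
cross-sample entropy, recurrence quantification analysis (RQA), and
detrended fluctuation analysis (DFA).

These metrics quantify the dynamical structure of short acceleration
segments — regularity (sample entropy), inter-channel synchrony
(cross-sample entropy), phase-space predictability and intermittency (RQA),
and long-range correlation / persistence (DFA).  They are computed on the
raw (unfiltered) signal so that high-frequency dynamical structure is not
attenuated before measurement.

Per window and channel the battery emits 9 values (DFA exponent, sample
entropy, cross-sample entropy against the cyclically paired channel, and six
RQA summaries), i.e. 27 nonlinear features across the three channels.

Conventions
-----------
* Phase-space reconstruction: ``X(t) = [x(t), x(t+tau), ..., x(t+(M-1)tau)]``
  with ``K = N - (M-1)*tau`` embedded vectors; defaults ``tau=5``, ``M=4``
  (selected by mutual-information / autocorrelation convergence and false
  nearest neighbors on this kind of data).
* Sample-entropy templates use delay 1 with tolerance ``r = 0.2 * SD``,
  Chebyshev distance, self-matches excluded; the tau-delayed embedding is
  used for RQA.  (A tau-delayed entropy variant is available via the
  ``tau`` argument.)
* The match relation is ``<= r`` (the standard template-counting
  convention); RQA thresholding uses strict ``<`` against the selected
  radius.
* RQA excludes a Theiler band of width 1 (the main diagonal) from all
  counts; minimum diagonal and vertical line lengths are 2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import pdist, squareform

from .preprocess import Window

__all__ = [
    "EmbeddingParams",
    "PhaseSpace",
    "RecurrencePlot",
    "RQAMetrics",
    "DFAResult",
    "DelaySelection",
    "select_time_delay",
    "select_embedding_dimension",
    "reconstruct_phase_space",
    "sample_entropy",
    "cross_sample_entropy",
    "rqa_threshold",
    "rqa_metrics",
    "dfa_exponent",
    "nonlinear_features",
    "NONLINEAR_FEATURE_NAMES",
]

_CHANNELS = ("x", "y", "z")
_PAIRS = {"x": (0, 1), "y": (1, 2), "z": (2, 0)}

_NONLINEAR_BASE = (
    "dfa_alpha",
    "sampen",
    "cross_sampen",
    "rqa_recurrence",
    "rqa_determinism",
    "rqa_laminarity",
    "rqa_divergence",
    "rqa_max_diag",
    "rqa_trapping_time",
)

NONLINEAR_FEATURE_NAMES = tuple(
    f"{f}_{c}" for c in _CHANNELS for f in _NONLINEAR_BASE
)


@dataclass(frozen=True)
class EmbeddingParams:
    tau: int = 5
    m: int = 4

    def __post_init__(self) -> None:
        if self.tau < 1 or self.m < 1:
            raise ValueError("tau and m must be positive integers")


@dataclass
class PhaseSpace:
    vectors: np.ndarray  # (K, M)
    source_length: int
    params: EmbeddingParams


@dataclass
class RecurrencePlot:
    matrix: np.ndarray       # (K, K) binary
    radius: float
    recurrence_pct: float    # % of off-Theiler cells that are recurrent
    theiler_w: int = 1


@dataclass
class RQAMetrics:
    recurrence: float      # %
    determinism: float     # %
    laminarity: float      # %
    divergence: float      # 1/samples
    max_diag_len: int      # samples
    trapping_time: float   # samples
    flagged: bool = False  # True when no recurrent points exist


@dataclass
class DFAResult:
    alpha: float
    box_sizes: np.ndarray
    fluctuations: np.ndarray
    fit_r2: float
    flagged: bool = False


@dataclass
class DelaySelection:
    """Outcome of the two-method time-delay selection."""

    tau: int
    tau_ami: int | None
    tau_acf: int
    diverged: bool  # True when the two methods disagree by more than 1 lag

    def __int__(self) -> int:
        return self.tau


# ---------------------------------------------------------------------------
# embedding-parameter selection
# ---------------------------------------------------------------------------

def _autocorrelation(x: np.ndarray, max_lag: int) -> np.ndarray:
    x = x - x.mean()
    denom = np.dot(x, x)
    if denom == 0:
        return np.ones(max_lag + 1)
    return np.array([np.dot(x[: len(x) - k], x[k:]) / denom for k in range(max_lag + 1)])


def _mutual_information(x: np.ndarray, lag: int, bins: int = 16) -> float:
    a, b = x[:-lag], x[lag:]
    joint, _, _ = np.histogram2d(a, b, bins=bins)
    pxy = joint / joint.sum()
    px = pxy.sum(axis=1, keepdims=True)
    py = pxy.sum(axis=0, keepdims=True)
    nz = pxy > 0
    return float(np.sum(pxy[nz] * np.log(pxy[nz] / (px @ py)[nz])))


def select_time_delay(x: np.ndarray, max_lag: int | None = None, bins: int = 16) -> DelaySelection:
    """Select the embedding delay by two converging heuristics.

    (1) the first local minimum of the average mutual information over lags;
    (2) the first lag at which the autocorrelation drops below 1/e.
    The AMI minimum is returned as the delay; when the two lags differ by
    more than 1 the selection is flagged as diverged.  When no AMI minimum
    exists within ``max_lag`` (default N/3) the autocorrelation lag is
    returned, flagged.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 20:
        raise ValueError("series too short for delay selection (need >= 20)")
    if max_lag is None:
        max_lag = n // 3

    acf = _autocorrelation(x, max_lag)
    below = np.nonzero(acf[1:] < np.exp(-1.0))[0]
    tau_acf = int(below[0] + 1) if len(below) else max_lag

    ami = np.array([_mutual_information(x, lag, bins) for lag in range(1, max_lag + 1)])
    tau_ami: int | None = None
    for i in range(1, len(ami) - 1):
        if ami[i] < ami[i - 1] and ami[i] < ami[i + 1]:  # strict local minimum
            tau_ami = i + 1
            break
    if tau_ami is None:
        return DelaySelection(tau=tau_acf, tau_ami=None, tau_acf=tau_acf, diverged=True)
    diverged = abs(tau_ami - tau_acf) > 1
    return DelaySelection(tau=tau_ami, tau_ami=tau_ami, tau_acf=tau_acf, diverged=diverged)


def select_embedding_dimension(
    x: np.ndarray,
    tau: int,
    m_max: int = 10,
    rtol: float = 15.0,
    atol: float = 2.0,
    threshold: float = 0.01,
) -> tuple[int, bool]:
    """Global false-nearest-neighbors selection of the embedding dimension.

    A nearest neighbor in dimension m is false when adding the (m+1)-th
    coordinate separates the pair, by either of the two standard criteria:
    relative separation exceeding ``rtol``, or the augmented distance
    exceeding ``atol`` times the data's standard deviation (the second
    criterion keeps stochastic series flagged at high dimensions, where
    sparse sampling deflates the relative test).

    Returns ``(M, flagged)`` where M is the smallest dimension at which the
    false-neighbor fraction falls below ``threshold``; when no dimension up
    to ``m_max`` achieves this, ``m_max`` is returned flagged (the signature
    of a stochastic series).
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n <= (m_max - 1) * tau + 1:
        raise ValueError("series too short for the requested m_max and tau")
    for m in range(1, m_max + 1):
        frac = _fnn_fraction(x, tau, m, rtol, atol)
        if frac < threshold:
            return m, False
    return m_max, True


def _fnn_fraction(x: np.ndarray, tau: int, m: int, rtol: float, atol: float) -> float:
    """Fraction of nearest neighbors in dimension m that separate in m+1."""
    n = len(x)
    k = n - m * tau  # need x[i + m*tau] for the (m+1)-th coordinate
    if k < 2:
        return 1.0
    sd = x.std()
    if sd == 0:
        return 0.0
    emb = np.column_stack([x[j * tau : j * tau + k] for j in range(m)])
    tree = cKDTree(emb)
    dists, idx = tree.query(emb, k=2)
    nn_dist, nn_idx = dists[:, 1], idx[:, 1]
    extra = np.abs(x[np.arange(k) + m * tau] - x[nn_idx + m * tau])
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio_false = extra > rtol * nn_dist
    ratio_false &= extra > 1e-10 * sd  # exact recurrences are true neighbors
    size_false = np.sqrt(nn_dist**2 + extra**2) / sd > atol
    return float(np.mean(ratio_false | size_false))


def reconstruct_phase_space(x: np.ndarray, params: EmbeddingParams) -> PhaseSpace:
    """Delay embedding: row t is [x(t), x(t+tau), ..., x(t+(M-1)tau)]."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    tau, m = params.tau, params.m
    k = n - (m - 1) * tau
    if k < 1:
        raise ValueError(f"series of length {n} too short to embed with tau={tau}, M={m}")
    vectors = np.column_stack([x[j * tau : j * tau + k] for j in range(m)])
    return PhaseSpace(vectors=vectors, source_length=n, params=params)


# ---------------------------------------------------------------------------
# entropy
# ---------------------------------------------------------------------------

def _templates(x: np.ndarray, m: int, tau: int = 1) -> np.ndarray:
    k = len(x) - (m - 1) * tau
    return np.column_stack([x[j * tau : j * tau + k] for j in range(m)])


def _phi(x: np.ndarray, m: int, r: float, tau: int) -> float:
    """Average, over templates of length m, of the fraction of other
    templates within Chebyshev distance r (self-matches excluded)."""
    t = _templates(x, m, tau)
    nt = t.shape[0]
    if nt < 2:
        return np.nan
    d = squareform(pdist(t, metric="chebyshev"))
    matches = (d <= r).sum(axis=1) - 1  # drop the self-match on the diagonal
    return float(np.mean(matches / (nt - 1)))


def sample_entropy(
    x: np.ndarray, m: int = 4, r_coeff: float = 0.2, tau: int = 1
) -> float:
    """Sample entropy: -ln(phi^{M+1}(r) / phi^M(r)) with r = r_coeff * SD(x).

    Template vectors use delay ``tau`` (default 1); matches use the
    Chebyshev norm with self-matches excluded.  A constant series returns 0
    (every template matches every other at both lengths); zero matches at
    length M+1 return ``inf`` as an out-of-band sentinel.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < (m + 1 - 1) * tau + 2:
        raise ValueError(f"series of length {n} too short for sample entropy at M={m}")
    sd = x.std()
    if sd == 0:
        return 0.0
    r = r_coeff * sd
    phi_m = _phi(x, m, r, tau)
    phi_m1 = _phi(x, m + 1, r, tau)
    if phi_m == 0 or np.isnan(phi_m) or np.isnan(phi_m1):
        return np.inf
    if phi_m1 == 0:
        return np.inf
    return float(-np.log(phi_m1 / phi_m))


def cross_sample_entropy(
    x: np.ndarray, y: np.ndarray, m: int = 4, r_coeff: float = 0.2, tau: int = 1
) -> float:
    """Asynchrony between two streams; the cross-stream analogue of SaEn.

    Both series are standardized (zero mean, unit SD) before matching, and
    the tolerance r = ``r_coeff`` applies on the standardized scale, so the
    statistic compares waveform shape rather than amplitude.  Each template
    of x is matched against the *time-aligned* template of y, so the
    statistic measures synchronous similarity between the streams; it is
    symmetric in (x, y), and identical streams give exactly 0.  Low values
    indicate synchronous, similar dynamics.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("series must have equal length")
    n = len(x)
    if n < (m + 1 - 1) * tau + 2:
        raise ValueError("series too short for cross-sample entropy")
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return 0.0
    xs = (x - x.mean()) / sx
    ys = (y - y.mean()) / sy

    def phi_cross(mm: int) -> float:
        tx = _templates(xs, mm, tau)
        ty = _templates(ys, mm, tau)
        # Chebyshev distance between time-aligned (x, y) template pairs
        d = np.max(np.abs(tx - ty), axis=1)
        return float(np.mean(d <= r_coeff))

    p_m = phi_cross(m)
    p_m1 = phi_cross(m + 1)
    if p_m == 0 or p_m1 == 0:
        return np.inf
    return float(-np.log(p_m1 / p_m))


# ---------------------------------------------------------------------------
# recurrence quantification analysis
# ---------------------------------------------------------------------------

def _offband_mask(k: int, w: int) -> np.ndarray:
    i, j = np.indices((k, k))
    return np.abs(i - j) > w


def rqa_threshold(
    ps: PhaseSpace,
    target_band_pct: tuple[float, float] = (0.1, 2.0),
    target_pct: float = 1.0,
    theiler_w: int = 1,
) -> RecurrencePlot:
    """Build a recurrence plot whose recurrence rate sits inside a target band.

    Pairwise Euclidean distances between embedded vectors form the distance
    matrix; the radius is the quantile of off-Theiler distances aiming at
    ``target_pct`` (the band midpoint by default) recurrent points, and the
    realized recurrence percentage is recomputed from the thresholded matrix
    and verified inside ``target_band_pct``.  Fails loudly for degenerate
    inputs (e.g. all vectors identical) where no positive radius can keep
    the rate within the band.
    """
    k = ps.vectors.shape[0]
    if k < 10:
        raise ValueError("need at least 10 embedded vectors for RQA")
    lo, hi = target_band_pct
    dmat = squareform(pdist(ps.vectors, metric="euclidean"))
    mask = _offband_mask(k, theiler_w)
    offband = dmat[mask]

    def realized(radius: float) -> tuple[np.ndarray, float]:
        rec = (dmat < radius) & mask
        return rec, 100.0 * rec.sum() / mask.sum()

    radius = float(np.quantile(offband, target_pct / 100.0))
    rec, pct = realized(radius)
    if not (lo <= pct <= hi):
        # ties or discreteness pushed the rate out of band: bisect on the quantile
        q_lo, q_hi = 0.0, 0.05
        for _ in range(60):
            q = 0.5 * (q_lo + q_hi)
            radius = float(np.quantile(offband, q))
            rec, pct = realized(radius)
            if pct < lo:
                q_lo = q
            elif pct > hi:
                q_hi = q
            else:
                break
        if not (lo <= pct <= hi):
            raise ValueError(
                f"no radius keeps the recurrence rate inside [{lo}, {hi}]% "
                f"(degenerate or duplicate-heavy input)"
            )
    return RecurrencePlot(
        matrix=rec.astype(np.int8), radius=radius, recurrence_pct=pct, theiler_w=theiler_w
    )


def _diagonal_runs(matrix: np.ndarray, w: int) -> list[int]:
    """Run lengths of recurrent points along all diagonals outside the
    Theiler band (both triangles of the symmetric matrix)."""
    k = matrix.shape[0]
    runs: list[int] = []
    for d in range(w + 1, k):
        for diag in (np.diagonal(matrix, d), np.diagonal(matrix, -d)):
            runs.extend(_run_lengths(diag))
    return runs


def _vertical_runs(matrix: np.ndarray, w: int) -> list[int]:
    """Run lengths of recurrent points down each column, with Theiler-band
    cells treated as non-recurrent."""
    k = matrix.shape[0]
    masked = matrix * _offband_mask(k, w)
    runs: list[int] = []
    for j in range(k):
        runs.extend(_run_lengths(masked[:, j]))
    return runs


def _run_lengths(line: np.ndarray) -> list[int]:
    runs = []
    count = 0
    for v in line:
        if v:
            count += 1
        elif count:
            runs.append(count)
            count = 0
    if count:
        runs.append(count)
    return runs


def rqa_metrics(rp: RecurrencePlot, lmin: int = 2, vmin: int = 2) -> RQAMetrics:
    """Six recurrence-plot summaries.

    * recurrence — % of off-Theiler cells that are recurrent;
    * determinism — % of recurrent points lying on diagonal lines of length
      >= ``lmin`` (predictable, periodic structure);
    * laminarity — analogous on vertical lines of length >= ``vmin``
      (intermittent, trapped states);
    * divergence — 1 / max diagonal length (related to the maximal Lyapunov
      exponent);
    * max_diag_len — the longest off-Theiler diagonal line;
    * trapping_time — mean length of vertical lines >= ``vmin``.
    """
    k = rp.matrix.shape[0]
    mask = _offband_mask(k, rp.theiler_w)
    n_rec = int((rp.matrix.astype(bool) & mask).sum())
    recurrence = 100.0 * n_rec / mask.sum()
    if n_rec == 0:
        return RQAMetrics(
            recurrence=0.0, determinism=0.0, laminarity=0.0,
            divergence=np.inf, max_diag_len=0, trapping_time=0.0, flagged=True,
        )
    diag_runs = _diagonal_runs(rp.matrix, rp.theiler_w)
    vert_runs = _vertical_runs(rp.matrix, rp.theiler_w)
    diag_pts = sum(r for r in diag_runs if r >= lmin)
    vert_pts = sum(r for r in vert_runs if r >= vmin)
    max_diag = max(diag_runs) if diag_runs else 0
    long_verts = [r for r in vert_runs if r >= vmin]
    return RQAMetrics(
        recurrence=recurrence,
        determinism=100.0 * diag_pts / n_rec,
        laminarity=100.0 * vert_pts / n_rec,
        divergence=(1.0 / max_diag) if max_diag >= 1 else np.inf,
        max_diag_len=max_diag,
        trapping_time=float(np.mean(long_verts)) if long_verts else 0.0,
        flagged=max_diag == 0,
    )


# ---------------------------------------------------------------------------
# detrended fluctuation analysis
# ---------------------------------------------------------------------------

def dfa_exponent(
    x: np.ndarray,
    box_range: tuple[int, int] | None = None,
    n_boxes: int = 12,
) -> DFAResult:
    """Scaling exponent of detrended fluctuations vs box size.

    The profile (cumulative sum of the mean-centred series) is cut into
    non-overlapping boxes of each log-spaced size, linearly detrended per
    box (both from the start and from the end of the profile, so trailing
    samples are used), and the RMS fluctuation F(n) computed; alpha is the
    least-squares slope of log F against log n.  alpha ~ 0.5 for white
    noise, > 0.5 for persistent and < 0.5 for anti-persistent series,
    ~ 1.5 for integrated white noise.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 16:
        raise ValueError("series too short for DFA (need >= 16)")
    if box_range is None:
        box_range = (4, n // 4)
    lo, hi = box_range
    if not (4 <= lo < hi <= n // 2):
        raise ValueError("invalid box range")
    sizes = np.unique(
        np.round(np.exp(np.linspace(np.log(lo), np.log(hi), n_boxes))).astype(int)
    )

    profile = np.cumsum(x - x.mean())
    fluct = np.empty(len(sizes))
    for si, s in enumerate(sizes):
        n_seg = n // s
        segs = []
        for arr in (profile[: n_seg * s], profile[n - n_seg * s :]):
            segs.append(arr.reshape(n_seg, s))
        seg = np.concatenate(segs, axis=0)
        t = np.arange(s, dtype=float)
        # per-box linear detrend via least squares
        tm = t - t.mean()
        denom = np.dot(tm, tm)
        slope = (seg @ tm) / denom
        fitted = seg.mean(axis=1)[:, None] + slope[:, None] * tm[None, :]
        fluct[si] = np.sqrt(np.mean((seg - fitted) ** 2))

    if np.any(fluct == 0):
        return DFAResult(
            alpha=np.nan, box_sizes=sizes, fluctuations=fluct, fit_r2=0.0, flagged=True
        )
    log_n, log_f = np.log(sizes), np.log(fluct)
    slope, intercept = np.polyfit(log_n, log_f, 1)
    pred = slope * log_n + intercept
    ss_res = np.sum((log_f - pred) ** 2)
    ss_tot = np.sum((log_f - log_f.mean()) ** 2)
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return DFAResult(
        alpha=float(slope), box_sizes=sizes, fluctuations=fluct, fit_r2=float(r2)
    )


# ---------------------------------------------------------------------------
# per-window battery
# ---------------------------------------------------------------------------

def nonlinear_features(
    window: Window,
    params: EmbeddingParams | None = None,
    sampen_m: int = 4,
    r_coeff: float = 0.2,
) -> dict[str, float]:
    """All 27 nonlinear features for one window, computed from raw samples.

    Degenerate inputs (constant channels, empty recurrence structure)
    produce the documented sentinel values rather than NaN: sample entropy
    0 for a constant channel, DFA NaN-flagged mapped to 0.5 (the neutral
    no-correlation exponent), RQA zeros.
    """
    if params is None:
        params = EmbeddingParams()
    w = window.raw
    out: dict[str, float] = {}
    for ci, c in enumerate(_CHANNELS):
        x = w[:, ci]
        p1, p2 = _PAIRS[c]

        dfa = dfa_exponent(x)
        out[f"dfa_alpha_{c}"] = 0.5 if dfa.flagged else dfa.alpha

        se = sample_entropy(x, m=sampen_m, r_coeff=r_coeff)
        out[f"sampen_{c}"] = se if np.isfinite(se) else _SAMPEN_CAP

        cse = cross_sample_entropy(w[:, p1], w[:, p2], m=sampen_m, r_coeff=r_coeff)
        out[f"cross_sampen_{c}"] = cse if np.isfinite(cse) else _SAMPEN_CAP

        try:
            rp = rqa_threshold(reconstruct_phase_space(x, params))
            rq = rqa_metrics(rp)
        except ValueError:
            rq = RQAMetrics(0.0, 0.0, 0.0, np.inf, 0, 0.0, flagged=True)
        out[f"rqa_recurrence_{c}"] = rq.recurrence
        out[f"rqa_determinism_{c}"] = rq.determinism
        out[f"rqa_laminarity_{c}"] = rq.laminarity
        out[f"rqa_divergence_{c}"] = 0.0 if not np.isfinite(rq.divergence) else rq.divergence
        out[f"rqa_max_diag_{c}"] = float(rq.max_diag_len)
        out[f"rqa_trapping_time_{c}"] = rq.trapping_time
    return out


# finite stand-in for an infinite-entropy sentinel so downstream tables stay
# numeric; larger than any entropy attainable on 2-s windows
_SAMPEN_CAP = 10.0
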