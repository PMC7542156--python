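"""Session I/O, low-pass filtering, and sliding-window segmentation.

Raw tri-axial wrist acceleration is recorded at 60 Hz.  Time- and
frequency-domain features are computed from data passed through a 4th-order
recursive (causal) low-pass Butterworth filter with a 20 Hz cutoff, while
nonlinear motor-variability features are computed from the raw signal, so
each window retains both versions.  Sessions are cut into 2-s windows with
1-s overlap; a window is labelled positive when any sample in its span is
labelled SIB (presence rule), and carries the analogous prompt flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "AccelSession",
    "Window",
    "WindowSet",
    "read_session",
    "butterworth_lowpass",
    "segment_windows",
    "label_window",
]


@dataclass
class AccelSession:
    """One participant's 3-channel acceleration stream with per-sample labels."""

    participant_id: str
    rate_hz: float
    samples: np.ndarray  # (N, 3), acceleration in g
    labels: np.ndarray   # (N,), binary SIB label
    prompts: np.ndarray  # (N,), binary prompt flag

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        self.labels = np.asarray(self.labels)
        self.prompts = np.asarray(self.prompts)
        if self.samples.ndim != 2 or self.samples.shape[1] != 3:
            raise ValueError("samples must be an N x 3 matrix")
        n = self.samples.shape[0]
        if n < 1:
            raise ValueError("session must contain at least one sample")
        if len(self.labels) != n or len(self.prompts) != n:
            raise ValueError("labels and prompts must match the sample count")
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate_hz


@dataclass
class Window:
    """A 2-s segment carrying both filtered and raw samples.

    ``filtered`` feeds time/frequency features; ``raw`` feeds the nonlinear
    motor-variability battery.
    """

    participant_id: str
    start_s: float
    filtered: np.ndarray  # (W, 3)
    raw: np.ndarray       # (W, 3)
    outcome: int
    prompt: int


@dataclass
class WindowSet:
    windows: list[Window]
    rate_hz: float

    def __len__(self) -> int:
        return len(self.windows)

    def __iter__(self):
        return iter(self.windows)


_REQUIRED_COLUMNS = ["time_s", "ax_g", "ay_g", "az_g", "label", "prompt"]


def read_session(path: str | Path, participant_id: str, rate_hz: float = 60.0) -> AccelSession:
    """Parse a delimited-text session file written by the synthetic writer.

    Raises ``ValueError`` naming the offending column for a missing column,
    a non-numeric acceleration sample, or a label/prompt outside {0, 1}.
    """
    df = pd.read_csv(path)
    for col in _REQUIRED_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"session file {path} is missing column '{col}'")
    for col in ("ax_g", "ay_g", "az_g", "time_s"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            raise ValueError(f"non-numeric value in column '{col}'")
        df[col] = vals
    for col in ("label", "prompt"):
        if not df[col].isin([0, 1]).all():
            raise ValueError(f"column '{col}' must contain only 0/1 values")
    return AccelSession(
        participant_id=participant_id,
        rate_hz=rate_hz,
        samples=df[["ax_g", "ay_g", "az_g"]].to_numpy(dtype=float),
        labels=df["label"].to_numpy(dtype=np.int8),
        prompts=df["prompt"].to_numpy(dtype=np.int8),
    )


def butterworth_lowpass(
    session: AccelSession, cutoff_hz: float = 20.0, order: int = 4
) -> AccelSession:
    """Causal low-pass Butterworth filtering of each channel (DC gain 1).

    Single-pass recursive filtering is used rather than zero-phase
    forward-backward filtering: the intended application is (near)
    real-time monitoring, where future samples are unavailable.
    """
    nyq = session.rate_hz / 2.0
    if not (0 < cutoff_hz < nyq):
        raise ValueError(f"cutoff_hz must lie in (0, {nyq}) (below Nyquist)")
    sos = signal.butter(order, cutoff_hz, btype="low", fs=session.rate_hz, output="sos")
    filtered = signal.sosfilt(sos, session.samples, axis=0)
    return AccelSession(
        participant_id=session.participant_id,
        rate_hz=session.rate_hz,
        samples=filtered,
        labels=session.labels,
        prompts=session.prompts,
    )


def label_window(labels: np.ndarray) -> int:
    """Window outcome under the presence rule: 1 iff any sample is labelled 1."""
    return int(np.any(np.asarray(labels) == 1))


def segment_windows(
    session: AccelSession,
    window_s: float = 2.0,
    step_s: float = 1.0,
    filtered_session: AccelSession | None = None,
) -> WindowSet:
    """Cut a session into overlapping windows aligned to step boundaries.

    Windows start at multiples of ``step_s`` from sample 0; the trailing
    remainder shorter than one window is dropped, giving
    ``floor((N/rate - window)/step) + 1`` windows.  When
    ``filtered_session`` is omitted the default 20 Hz low-pass filter is
    applied internally.
    """
    if filtered_session is None:
        filtered_session = butterworth_lowpass(session)
    n = session.n_samples
    w = int(round(window_s * session.rate_hz))
    step = int(round(step_s * session.rate_hz))
    if n < w:
        raise ValueError(
            f"session of {session.duration_s:.2f}s is shorter than one "
            f"{window_s}s window"
        )
    n_windows = (n - w) // step + 1
    windows = []
    for k in range(n_windows):
        i0 = k * step
        i1 = i0 + w
        windows.append(
            Window(
                participant_id=session.participant_id,
                start_s=i0 / session.rate_hz,
                filtered=filtered_session.samples[i0:i1],
                raw=session.samples[i0:i1],
                outcome=label_window(session.labels[i0:i1]),
                prompt=label_window(session.prompts[i0:i1]),
            )
        )
    return WindowSet(windows=windows, rate_hz=session.rate_hz)
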