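"""Synthetic cohorts of wrist-accelerometer sessions and multilevel feature data.

The study population this package targets (children exhibiting self-injurious
behavior, SIB) cannot be redistributed, so every downstream stage is exercised
on simulated data with the statistical structure the analysis assumes:

* **Signal level** — per-participant 3-channel acceleration streams at 60 Hz in
  which sparse rhythmic SIB bursts (seconds-long sinusoidal episodes with a
  participant-specific dominant frequency and amplitude) ride on naturalistic
  background motion (pink noise plus slow postural drift).  Per-sample binary
  SIB labels and prompt flags are emitted alongside.
* **Feature level** — windows drawn directly from the multilevel logistic
  model the group classifier assumes: per-participant intercepts and slopes
  Gaussian around population coefficients, Bernoulli outcomes through the
  inverse-logit link.  True parameters are returned so estimator-recovery
  tests have a ground truth.

All generators are deterministic given their seed; per-participant child
seeds are spawned from the cohort seed so participants are independent but
reproducible.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .preprocess import AccelSession

__all__ = [
    "ParticipantProfile",
    "CohortSpec",
    "MultilevelSimSpec",
    "MultilevelSimResult",
    "generate_session",
    "generate_cohort",
    "generate_multilevel_features",
    "write_session",
    "write_cohort",
    "read_cohort_manifest",
]


@dataclass(frozen=True)
class ParticipantProfile:
    """Knobs describing one participant's motion signature.

    Parameters
    ----------
    sib_frequency_hz : dominant burst frequency of SIB episodes (typically
        2-5 Hz for rhythmic topographies such as head banging); must lie
        below the 30 Hz Nyquist limit of the 60 Hz recordings.
    sib_amplitude_g : peak episode amplitude in g.
    baseline_activity_scale : standard deviation (g) of the pink-noise
        background motion.
    episode_rate_per_min : expected SIB episodes per minute.
    episode_duration_range_s : (low, high) uniform range of episode length;
        episodes in the field run from ~2 s bursts to ~90 s picking bouts.
    random_slope_shift : optional per-feature deviation applied when this
        profile is used to emit feature-level data.
    """

    participant_id: str
    sib_frequency_hz: float = 3.0
    sib_amplitude_g: float = 1.0
    baseline_activity_scale: float = 0.15
    episode_rate_per_min: float = 1.0
    episode_duration_range_s: tuple[float, float] = (2.0, 8.0)
    random_slope_shift: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        lo, hi = self.episode_duration_range_s
        if not (0 < lo <= hi):
            raise ValueError("episode_duration_range_s must satisfy 0 < low <= high")
        if not (0 < self.sib_frequency_hz < 30.0):
            raise ValueError("sib_frequency_hz must lie in (0, 30) Hz (Nyquist at 60 Hz)")
        if self.sib_amplitude_g <= 0:
            raise ValueError("sib_amplitude_g must be positive")
        if self.baseline_activity_scale <= 0:
            raise ValueError("baseline_activity_scale must be positive")
        if self.episode_rate_per_min < 0:
            raise ValueError("episode_rate_per_min must be nonnegative")


@dataclass(frozen=True)
class CohortSpec:
    """A cohort of participants to simulate at the signal level."""

    profiles: tuple[ParticipantProfile, ...]
    session_duration_s: float = 120.0
    sampling_rate_hz: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.profiles) == 0:
            raise ValueError("CohortSpec requires at least one profile")
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        if self.session_duration_s <= 0:
            raise ValueError("session_duration_s must be positive")

    @property
    def n_participants(self) -> int:
        return len(self.profiles)


@dataclass(frozen=True)
class MultilevelSimSpec:
    """Feature-level simulation following the multilevel logistic model.

    Windows for participant ``j`` have features X ~ N(0, I_K) and outcome

        Y ~ Bernoulli(logit^-1(alpha_j + sum_k beta_jk X_k)),

    with alpha_j ~ N(gamma_0, sigma_alpha^2) and
    beta_jk ~ N(gamma_k, sigma_beta_k^2) independent across participants and
    features (random effects centred on the population coefficients).
    """

    n_participants: int
    windows_per_participant: int
    fixed_coeffs: tuple[float, ...]  # (intercept, slope_1, ..., slope_K)
    intercept_sd: float = 0.0
    slope_sds: tuple[float, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        k = len(self.fixed_coeffs) - 1
        if k < 1:
            raise ValueError("fixed_coeffs must hold an intercept and >= 1 slope")
        slope_sds = self.slope_sds or tuple(0.0 for _ in range(k))
        object.__setattr__(self, "slope_sds", tuple(slope_sds))
        if len(self.slope_sds) != k:
            raise ValueError("slope_sds length must equal the number of slopes")
        if self.intercept_sd < 0 or any(s < 0 for s in self.slope_sds):
            raise ValueError("random-effect standard deviations must be nonnegative")
        if self.n_participants < 1 or self.windows_per_participant < 1:
            raise ValueError("n_participants and windows_per_participant must be >= 1")

    @property
    def n_features(self) -> int:
        return len(self.fixed_coeffs) - 1


@dataclass(frozen=True)
class MultilevelSimResult:
    """Simulated feature table plus the true parameters that generated it."""

    table: pd.DataFrame
    true_intercepts: np.ndarray  # shape (J,)
    true_slopes: np.ndarray      # shape (J, K)
    spec: MultilevelSimSpec


# ---------------------------------------------------------------------------
# signal-level generation
# ---------------------------------------------------------------------------

def _pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """1/f-amplitude noise via spectral shaping, unit variance."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    scale = np.ones_like(freqs)
    nonzero = freqs > 0
    scale[nonzero] = 1.0 / np.sqrt(freqs[nonzero])
    scale[0] = 0.0
    x = np.fft.irfft(spec * scale, n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _draw_episodes(
    duration_s: float,
    profile: ParticipantProfile,
    rng: np.random.Generator,
) -> list[tuple[float, float]]:
    """Non-overlapping (start_s, dur_s) episode intervals, truncated at the end."""
    expected = profile.episode_rate_per_min * duration_s / 60.0
    n_episodes = int(rng.poisson(expected)) if expected > 0 else 0
    lo, hi = profile.episode_duration_range_s
    intervals: list[tuple[float, float]] = []
    for _ in range(n_episodes):
        dur = float(rng.uniform(lo, hi))
        for _attempt in range(50):  # rejection sampling for non-overlap
            start = float(rng.uniform(0, duration_s))
            end = min(start + dur, duration_s)
            if all(start >= s2 + d2 or end <= s2 for s2, d2 in intervals):
                intervals.append((start, end - start))
                break
    intervals.sort()
    return intervals


def generate_session(
    profile: ParticipantProfile,
    duration_s: float,
    rate_hz: float = 60.0,
    seed: int = 0,
    episodes: list[tuple[float, float]] | None = None,
) -> AccelSession:
    """Simulate one participant's tri-axial session with embedded SIB bursts.

    Background motion per channel is pink (1/f) noise scaled to
    ``baseline_activity_scale`` plus a 0.1 Hz sinusoidal postural drift.
    Each episode adds an amplitude- and frequency-jittered sinusoidal burst
    to all three channels (random per-channel weights) and sets the sample
    labels to 1 over its span.  A prompt flag is raised over the 2 s
    preceding roughly half of the episodes, mimicking instigation prompts.

    Parameters
    ----------
    episodes : explicit list of (start_s, duration_s) intervals; when given
        it overrides the profile's stochastic episode process (useful for
        controlled tests).
    """
    if duration_s < 2:
        raise ValueError("duration_s must be at least one 2-s window")
    if rate_hz <= 0:
        raise ValueError("rate_hz must be positive")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * rate_hz))
    t = np.arange(n) / rate_hz

    sig = np.empty((n, 3))
    for c in range(3):
        drift_phase = rng.uniform(0, 2 * np.pi)
        drift_amp = 0.5 * profile.baseline_activity_scale
        sig[:, c] = (
            profile.baseline_activity_scale * _pink_noise(n, rng)
            + drift_amp * np.sin(2 * np.pi * 0.1 * t + drift_phase)
        )

    if episodes is None:
        episodes = _draw_episodes(duration_s, profile, rng)

    labels = np.zeros(n, dtype=np.int8)
    prompts = np.zeros(n, dtype=np.int8)
    for start_s, dur_s in episodes:
        i0 = int(round(start_s * rate_hz))
        i1 = min(int(round((start_s + dur_s) * rate_hz)), n)
        if i1 <= i0:
            continue
        seg_t = t[i0:i1]
        freq = profile.sib_frequency_hz * rng.uniform(0.9, 1.1)
        amp = profile.sib_amplitude_g * rng.uniform(0.8, 1.2)
        phase = rng.uniform(0, 2 * np.pi)
        weights = rng.uniform(0.5, 1.0, size=3)
        burst = amp * np.sin(2 * np.pi * freq * (seg_t - seg_t[0]) + phase)
        # mild amplitude modulation so bursts are not perfectly stationary
        envelope = 1.0 + 0.1 * np.sin(2 * np.pi * 0.5 * (seg_t - seg_t[0]))
        for c in range(3):
            sig[i0:i1, c] += weights[c] * burst * envelope
        labels[i0:i1] = 1
        if rng.uniform() < 0.5:
            p0 = max(0, i0 - int(round(2 * rate_hz)))
            prompts[p0:i0] = 1

    return AccelSession(
        participant_id=profile.participant_id,
        rate_hz=rate_hz,
        samples=sig,
        labels=labels,
        prompts=prompts,
    )


def generate_cohort(spec: CohortSpec) -> list[AccelSession]:
    """One session per profile, with per-participant seeds derived from
    ``spec.seed`` by fixed increment so participants are independent yet the
    cohort is reproducible from a single seed."""
    return [
        generate_session(
            profile,
            duration_s=spec.session_duration_s,
            rate_hz=spec.sampling_rate_hz,
            seed=spec.seed + 1000 * (j + 1),
        )
        for j, profile in enumerate(spec.profiles)
    ]


# ---------------------------------------------------------------------------
# feature-level generation
# ---------------------------------------------------------------------------

def generate_multilevel_features(spec: MultilevelSimSpec) -> MultilevelSimResult:
    """Draw a window-level feature table from the multilevel logistic model."""
    rng = np.random.default_rng(spec.seed)
    j_n, n_w, k = spec.n_participants, spec.windows_per_participant, spec.n_features
    gamma = np.asarray(spec.fixed_coeffs, dtype=float)

    alphas = gamma[0] + spec.intercept_sd * rng.standard_normal(j_n)
    slopes = gamma[1:] + np.asarray(spec.slope_sds) * rng.standard_normal((j_n, k))

    frames = []
    for j in range(j_n):
        x = rng.standard_normal((n_w, k))
        eta = alphas[j] + x @ slopes[j]
        p = 1.0 / (1.0 + np.exp(-eta))
        y = (rng.uniform(size=n_w) < p).astype(int)
        df = pd.DataFrame(x, columns=[f"x{i + 1}" for i in range(k)])
        df.insert(0, "participant_id", f"P{j + 1}")
        df["outcome"] = y
        frames.append(df)
    table = pd.concat(frames, ignore_index=True)
    return MultilevelSimResult(
        table=table, true_intercepts=alphas, true_slopes=slopes, spec=spec
    )


# ---------------------------------------------------------------------------
# on-disk representation
# ---------------------------------------------------------------------------

_SESSION_COLUMNS = ["time_s", "ax_g", "ay_g", "az_g", "label", "prompt"]


def write_session(session: AccelSession, path: str | Path) -> None:
    """Write one session as delimited text with the documented header."""
    n = session.samples.shape[0]
    df = pd.DataFrame(
        {
            "time_s": np.arange(n) / session.rate_hz,
            "ax_g": session.samples[:, 0],
            "ay_g": session.samples[:, 1],
            "az_g": session.samples[:, 2],
            "label": session.labels.astype(int),
            "prompt": session.prompts.astype(int),
        }
    )
    df.to_csv(path, index=False)


def write_cohort(spec: CohortSpec, out_dir: str | Path) -> Path:
    """Generate a cohort, write one CSV per participant plus a YAML manifest.

    Returns the manifest path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sessions = generate_cohort(spec)
    manifest = {
        "sampling_rate_hz": spec.sampling_rate_hz,
        "session_duration_s": spec.session_duration_s,
        "seed": spec.seed,
        "participants": [],
    }
    for profile, session in zip(spec.profiles, sessions):
        fname = f"{profile.participant_id}.csv"
        write_session(session, out_dir / fname)
        entry = dataclasses.asdict(profile)
        entry["file"] = fname
        entry["episode_duration_range_s"] = list(profile.episode_duration_range_s)
        entry["random_slope_shift"] = list(profile.random_slope_shift)
        manifest["participants"].append(entry)
    manifest_path = out_dir / "cohort.yaml"
    with open(manifest_path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return manifest_path


def read_cohort_manifest(path: str | Path) -> CohortSpec:
    """Rebuild a CohortSpec from a written manifest (round-trip of write_cohort)."""
    with open(path) as fh:
        manifest = yaml.safe_load(fh)
    profiles = tuple(
        ParticipantProfile(
            participant_id=p["participant_id"],
            sib_frequency_hz=p["sib_frequency_hz"],
            sib_amplitude_g=p["sib_amplitude_g"],
            baseline_activity_scale=p["baseline_activity_scale"],
            episode_rate_per_min=p["episode_rate_per_min"],
            episode_duration_range_s=tuple(p["episode_duration_range_s"]),
            random_slope_shift=tuple(p["random_slope_shift"]),
        )
        for p in manifest["participants"]
    )
    return CohortSpec(
        profiles=profiles,
        session_duration_s=manifest["session_duration_s"],
        sampling_rate_hz=manifest["sampling_rate_hz"],
        seed=manifest["seed"],
    )
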