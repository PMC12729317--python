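"""Synthetic tremor-perturbed force recordings and synthetic session logs.

The physical study induces tremor-like oscillations by neuromuscular
stimulation of the forearm at two representative frequencies: 6 Hz (the
most frequent parkinsonian resting tremor) and 8 Hz (the upper bound seen
in severe cases), superimposed on the user's voluntary hand motion and
recorded by the haptic device's force sensors at 50 Hz on two axes.

This module replaces the stimulation rig with a parametric generator that
produces the same statistical structure - a band-limited voluntary
component (< 2 Hz), a tremor-band oscillation, and white Gaussian sensor
noise - *with ground truth*: every component is returned separately so the
filtering pipeline can be scored against what it should remove and what it
should preserve.

A second generator emits synthetic session event logs for the three-way
within-subject design (no tremor / tremor unfiltered / tremor filtered),
with per-condition mean shifts of the Cell Completion Time, for exercising
the metrics and statistics stages.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .metrics import CONDITIONS, SessionEvent
from .signal import SignalTrace

__all__ = [
    "TremorProfile",
    "VoluntaryMotionModel",
    "SimulatedRecording",
    "SessionLog",
    "TREMOR_PRESETS",
    "simulate_recording",
    "simulate_session_logs",
    "save_recording",
]

#: named stimulation-protocol presets (fundamental frequency in Hz)
TREMOR_PRESETS = {"pd_resting": 6.0, "pd_severe": 8.0}


@dataclass(frozen=True)
class TremorProfile:
    """Frequency/amplitude description of the pathological oscillation.

    ``amplitude_jitter_sd`` is the relative SD of a slow (<= 0.5 Hz)
    multiplicative amplitude modulation mimicking physiological
    nonstationarity; 0 gives a deterministic pure oscillation.
    """

    frequency: float
    amplitude: float = 1.0
    phase: float = 0.0
    amplitude_jitter_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.frequency <= 0:
            raise ValueError(f"frequency must be positive, got {self.frequency}")
        if self.amplitude < 0:
            raise ValueError(f"amplitude must be >= 0, got {self.amplitude}")
        if self.amplitude_jitter_sd < 0:
            raise ValueError("amplitude_jitter_sd must be >= 0")

    @classmethod
    def preset(cls, name: str, amplitude: float = 1.0, **kw) -> "TremorProfile":
        """``pd_resting`` (6 Hz) or ``pd_severe`` (8 Hz)."""
        try:
            freq = TREMOR_PRESETS[name]
        except KeyError:
            raise ValueError(
                f"unknown preset {name!r}; available: {sorted(TREMOR_PRESETS)}"
            ) from None
        return cls(frequency=freq, amplitude=amplitude, **kw)


@dataclass(frozen=True)
class VoluntaryMotionModel:
    """Parametric stand-in for intentional, low-frequency hand motion.

    ``sum_of_sines`` superimposes three equal-amplitude sinusoids at random
    frequencies below ``band_limit``; ``smoothed_random_walk`` low-passes an
    integrated white-noise path to the same band and rescales it.
    """

    band_limit: float = 2.0
    amplitude: float = 0.5
    kind: str = "sum_of_sines"
    n_components: int = 3

    def __post_init__(self) -> None:
        if self.band_limit <= 0:
            raise ValueError("band_limit must be positive")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.kind not in ("sum_of_sines", "smoothed_random_walk"):
            raise ValueError(f"unknown voluntary-motion kind {self.kind!r}")


@dataclass
class SimulatedRecording:
    """Mixed trace plus its ground-truth decomposition.

    Invariant: ``mixed = voluntary + tremor + noise`` channel-wise, where
    the noise sequence is exactly reproducible from ``seed`` via
    :meth:`regenerate_noise`.
    """

    mixed: SignalTrace
    voluntary: SignalTrace
    tremor: SignalTrace
    noise_sd: float
    seed: int

    @property
    def fs(self) -> float:
        return self.mixed.fs

    def regenerate_noise(self) -> SignalTrace:
        """Re-derive the exact noise realisation from the stored seed."""
        rngs = _channel_rngs(self.seed)
        channels = {
            name: _noise(self.mixed.n_samples, self.noise_sd, rngs[f"noise_{name}"])
            for name in self.mixed.channel_names
        }
        return self.mixed.copy_with(channels)


_CHANNEL_NAMES = ("force_x", "force_y")


def _channel_rngs(seed: int) -> dict[str, np.random.Generator]:
    """Deterministic, purpose-keyed RNG streams derived from one seed."""
    ss = np.random.SeedSequence(seed)
    keys = []
    for name in _CHANNEL_NAMES:
        keys += [f"voluntary_{name}", f"jitter_{name}", f"noise_{name}"]
    return {k: np.random.default_rng(c) for k, c in zip(keys, ss.spawn(len(keys)))}


def _noise(n: int, sd: float, rng: np.random.Generator) -> np.ndarray:
    if sd == 0.0:
        return np.zeros(n)
    return rng.normal(0.0, sd, size=n)


def _slow_modulation(t: np.ndarray, sd: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-mean multiplicative envelope with relative SD ``sd``, band <= 0.5 Hz."""
    if sd == 0.0:
        return np.ones_like(t)
    freqs = rng.uniform(0.05, 0.5, size=3)
    phases = rng.uniform(0.0, 2 * np.pi, size=3)
    s = np.sum(
        [np.sin(2 * np.pi * f * t + ph) for f, ph in zip(freqs, phases)], axis=0
    )
    s /= np.sqrt(3.0 / 2.0)  # unit RMS for a sum of three unit sinusoids
    return 1.0 + sd * s


def _voluntary(
    t: np.ndarray, fs: float, model: VoluntaryMotionModel, rng: np.random.Generator
) -> np.ndarray:
    if model.amplitude == 0.0:
        return np.zeros_like(t)
    if model.kind == "sum_of_sines":
        lo = min(0.1, model.band_limit / 2)
        freqs = rng.uniform(lo, model.band_limit, size=model.n_components)
        phases = rng.uniform(0.0, 2 * np.pi, size=model.n_components)
        amp = model.amplitude / model.n_components
        return amp * np.sum(
            [np.sin(2 * np.pi * f * t + ph) for f, ph in zip(freqs, phases)],
            axis=0,
        )
    # smoothed random walk: integrate white noise, low-pass, rescale
    walk = np.cumsum(rng.standard_normal(t.size))
    wn = min(0.99, model.band_limit / (fs / 2))
    sos = butter(4, wn, btype="low", output="sos")
    x = sosfiltfilt(sos, walk)
    x = x - np.mean(x)
    sd = np.std(x)
    if sd > 0:
        x *= (model.amplitude / np.sqrt(2.0)) / sd
    return x


def simulate_recording(
    profile: TremorProfile,
    voluntary: VoluntaryMotionModel | None = None,
    noise_sd: float = 0.0,
    duration: float = 60.0,
    fs: float = 50.0,
    seed: int = 0,
) -> SimulatedRecording:
    """Generate a two-axis force recording with ground-truth components.

    The tremor component on the second axis is phase-shifted by pi/2 so the
    two channels trace an ellipse, as a physical oscillation would.
    Identical arguments give bit-identical output.

    Raises
    ------
    ValueError
        If ``duration <= 0``, if ``fs <= 2 * profile.frequency`` (the tremor
        would alias), or if an active voluntary model's band reaches into
        the tremor separation margin (``band_limit >= frequency - 1``).
    """
    if duration <= 0:
        raise ValueError(f"duration must be positive, got {duration}")
    if fs <= 2 * profile.frequency:
        raise ValueError(
            f"fs={fs} Hz aliases a {profile.frequency} Hz tremor; need fs > "
            f"{2 * profile.frequency} Hz"
        )
    if (
        voluntary is not None
        and voluntary.amplitude > 0
        and profile.amplitude > 0
        and voluntary.band_limit >= profile.frequency - 1.0
    ):
        raise ValueError(
            "voluntary band_limit must stay below frequency - 1 Hz so the "
            "adaptive attenuation boundary can separate the components"
        )
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    rngs = _channel_rngs(seed)

    vol: dict[str, np.ndarray] = {}
    trem: dict[str, np.ndarray] = {}
    mixed: dict[str, np.ndarray] = {}
    for i, name in enumerate(_CHANNEL_NAMES):
        phase = profile.phase + i * np.pi / 2
        env = _slow_modulation(
            t, profile.amplitude_jitter_sd, rngs[f"jitter_{name}"]
        )
        trem[name] = (
            profile.amplitude * env * np.sin(2 * np.pi * profile.frequency * t + phase)
        )
        if voluntary is None:
            vol[name] = np.zeros(n)
        else:
            vol[name] = _voluntary(t, fs, voluntary, rngs[f"voluntary_{name}"])
        noise = _noise(n, noise_sd, rngs[f"noise_{name}"])
        mixed[name] = vol[name] + trem[name] + noise

    make = lambda ch: SignalTrace(fs=fs, t=t.copy(), channels=ch)  # noqa: E731
    return SimulatedRecording(
        mixed=make(mixed),
        voluntary=make(vol),
        tremor=make(trem),
        noise_sd=noise_sd,
        seed=seed,
    )


def save_recording(rec: SimulatedRecording, path) -> None:
    """Write the mixed trace as CSV plus a JSON sidecar with its provenance."""
    rec.mixed.to_csv(path)
    sidecar = {
        "fs": rec.fs,
        "seed": rec.seed,
        "noise_sd": rec.noise_sd,
        "channels": rec.mixed.channel_names,
    }
    with open(f"{path}.json", "w", encoding="utf-8") as fh:
        json.dump(sidecar, fh, indent=2)


# -- synthetic session logs ----------------------------------------------

@dataclass
class SessionLog:
    subject: str
    condition: str
    events: list[SessionEvent]


def simulate_session_logs(
    n_subjects: int,
    conditions,
    effect_profile,
    seed: int = 0,
    *,
    n_cells: int = 35,
    base_cct: float = 4.0,
    subject_sd: float = 1.0,
    within_sd: float = 1.0,
    cell_sd: float = 1.0,
    wrong_entry_rate: float = 0.1,
    inter_cell_gap: float = 0.5,
) -> list[SessionLog]:
    """Synthetic event logs for a within-subject multi-condition study.

    Per subject ``i`` and condition ``c`` the latent mean CCT is
    ``base_cct + b_i + effect_c + w_ic`` with ``b_i ~ N(0, subject_sd^2)``
    (between-subject) and ``w_ic ~ N(0, within_sd^2)`` (subject-by-condition
    variability); individual cells add ``N(0, cell_sd^2)``.  With a zero
    ``effect_profile`` the design is an exact null for the repeated-measures
    ANOVA.  Defaults mirror the study task: one easy puzzle (35 empty
    cells) per session.

    ``effect_profile`` is a sequence of per-condition mean CCT shifts in
    seconds, aligned with ``conditions`` (or a mapping condition -> shift).
    """
    conditions = list(conditions)
    if not conditions:
        raise ValueError("conditions must be non-empty")
    unknown = [c for c in conditions if c not in CONDITIONS]
    if unknown:
        raise ValueError(f"unknown conditions {unknown}; allowed: {CONDITIONS}")
    if n_subjects < 2:
        raise ValueError(f"need at least 2 subjects, got {n_subjects}")
    if isinstance(effect_profile, dict):
        effects = [float(effect_profile.get(c, 0.0)) for c in conditions]
    else:
        effects = [float(e) for e in effect_profile]
        if len(effects) != len(conditions):
            raise ValueError(
                f"effect_profile length {len(effects)} != {len(conditions)} conditions"
            )
    rng = np.random.default_rng(seed)
    logs: list[SessionLog] = []
    for i in range(n_subjects):
        subject = f"s{i + 1:02d}"
        b_i = rng.normal(0.0, subject_sd)
        for cond, eff in zip(conditions, effects):
            w_ic = rng.normal(0.0, within_sd)
            mu = base_cct + b_i + eff + w_ic
            events = [
                SessionEvent(t=float(k), type="countdown", value=v)
                for k, v in enumerate(["3", "2", "1", "Start"])
            ]
            t = 3.0
            for k in range(n_cells):
                cell = (k // 9, k % 9)
                select_t = t
                events.append(SessionEvent(t=select_t, type="select", cell=cell))
                cct = max(0.2, mu + rng.normal(0.0, cell_sd))
                n_wrong = 0
                while rng.random() < wrong_entry_rate and n_wrong < 3:
                    n_wrong += 1
                for j in range(1, n_wrong + 1):
                    events.append(
                        SessionEvent(
                            t=select_t + cct * j / (n_wrong + 1),
                            type="entry",
                            cell=cell,
                            value=int(rng.integers(1, 10)),
                            correct=False,
                        )
                    )
                events.append(
                    SessionEvent(
                        t=select_t + cct,
                        type="entry",
                        cell=cell,
                        value=int(rng.integers(1, 10)),
                        correct=True,
                    )
                )
                t = select_t + cct + inter_cell_gap
            events.append(SessionEvent(t=t, type="complete"))
            logs.append(SessionLog(subject=subject, condition=cond, events=events))
    return logs
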