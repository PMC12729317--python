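"""Headless simulated user: end-to-end sessions under the three conditions.

The study's participants steered a cursor with a haptic device while
neuromuscular stimulation injected tremor.  This module closes the loop
without a human: a simulated recording provides the cursor trajectory
(voluntary pointing motion, plus tremor unless the condition is
``no_tremor``, passed through the filtering pipeline when the condition is
``tremor_filtered``), and a noisy proportional-control pointer model turns
the trajectory's residual high-frequency jitter into per-cell acquisition
times, entry delays and miss probabilities.  Every session plays a real
carved puzzle through the game-state validator and emits a standard event
log, so the whole metrics/statistics chain downstream runs on it unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .metrics import CONDITIONS, MetricsRecord, SessionEvent, compute_metrics
from .pipeline import run_pipeline
from .signal import band_power
from .sudoku import GameState, Puzzle, countdown_sequence, make_puzzle
from .tremor import TremorProfile, VoluntaryMotionModel, simulate_recording

__all__ = ["UserModel", "SessionResult", "run_session", "run_batch"]

#: jitter is measured as RMS amplitude above this frequency (Hz) - above the
#: voluntary band, covering tremor and sensor noise
_JITTER_BAND_LO = 3.0
#: seconds of trajectory skipped before measuring jitter (pipeline warm-up)
_JITTER_SKIP_S = 2.0


@dataclass(frozen=True)
class UserModel:
    """Noisy proportional-control pointer with dwell-based selection.

    Acquisition and confirmation slow down, and the miss probability grows,
    with a perturbation index combining the RMS jitter of the *displayed*
    cursor with the RMS of the *physical* (pre-filter) tremor: the
    suppression acts only at the visual level, so a filtered cursor still
    leaves the hand mechanically perturbed.  ``physical_gain`` weights the
    physical term relative to the visual one; it is what makes filtering
    restore performance only partially.  Times are in seconds, gains per
    unit RMS (signal units, Newtons for force traces).
    """

    base_select_s: float = 1.5
    select_jitter_gain: float = 2.0
    select_sd: float = 0.3
    entry_delay_s: float = 0.6
    entry_jitter_gain: float = 2.0
    entry_sd: float = 0.15
    base_miss_p: float = 0.02
    miss_jitter_gain: float = 0.25
    max_miss_p: float = 0.6
    physical_gain: float = 0.5


@dataclass
class SessionResult:
    subject: str
    condition: str
    events: list[SessionEvent]
    metrics: MetricsRecord
    jitter_rms: float          # visual (displayed-cursor) jitter
    physical_rms: float        # mechanical (pre-filter) tremor + noise
    seed: int


def _sub_seed(*keys: int) -> int:
    return int(np.random.SeedSequence(list(keys)).generate_state(1)[0] % 2**31)


def cursor_jitter_rms(trace, skip_s: float = _JITTER_SKIP_S) -> float:
    """RMS of the cursor's content above the voluntary band, averaged over
    channels, after discarding the warm-up interval."""
    fs = trace.fs
    i0 = min(int(skip_s * fs), max(0, trace.n_samples - 2))
    powers = [
        band_power(trace[name][i0:], fs, _JITTER_BAND_LO, fs / 2)
        for name in trace.channel_names
    ]
    return float(np.sqrt(np.mean(powers)))


def run_session(
    condition: str,
    seed: int,
    *,
    subject: str = "s01",
    user: UserModel | None = None,
    profile: TremorProfile | None = None,
    voluntary: VoluntaryMotionModel | None = None,
    noise_sd: float = 0.05,
    trajectory_s: float = 12.0,
    fs: float = 50.0,
    difficulty: str = "easy",
    puzzle: Puzzle | None = None,
) -> SessionResult:
    """Play one puzzle headlessly under ``condition``; deterministic in
    ``seed``.

    The cursor trajectory is simulated, filtered when the condition asks
    for it, and summarised into an RMS jitter figure that drives the
    pointer model.  Pass ``puzzle`` to reuse a carved puzzle across
    sessions (a batch plays one standardized easy puzzle, as in the study
    protocol); otherwise one is carved from the seed.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}; allowed: {CONDITIONS}")
    user = user or UserModel()
    profile = profile or TremorProfile.preset("pd_resting")
    voluntary = voluntary or VoluntaryMotionModel(band_limit=1.0, amplitude=0.5)

    if condition == "no_tremor":
        eff_profile = TremorProfile(
            frequency=profile.frequency,
            amplitude=0.0,
            phase=profile.phase,
            amplitude_jitter_sd=profile.amplitude_jitter_sd,
        )
    else:
        eff_profile = profile
    rec = simulate_recording(
        eff_profile,
        voluntary,
        noise_sd=noise_sd,
        duration=trajectory_s,
        fs=fs,
        seed=_sub_seed(seed, 1),
    )
    cursor = rec.mixed
    if condition == "tremor_filtered":
        cursor = run_pipeline(rec.mixed).filtered
    jitter = cursor_jitter_rms(cursor)
    physical = cursor_jitter_rms(rec.mixed)
    # filtering is visual-only: the hand still feels the mechanical tremor
    perturb = jitter + user.physical_gain * physical

    if puzzle is None:
        puzzle = make_puzzle(difficulty, _sub_seed(seed, 2))
    state = GameState(puzzle=puzzle)
    rng = np.random.default_rng(_sub_seed(seed, 3))

    events = countdown_sequence()
    t = events[-1].t  # clock starts at the "Start" cue
    miss_p = min(user.max_miss_p, user.base_miss_p + user.miss_jitter_gain * perturb)
    for cell in puzzle.empty_cells():
        acq = max(
            0.3,
            rng.normal(
                user.base_select_s * (1.0 + user.select_jitter_gain * perturb),
                user.select_sd,
            ),
        )
        t += acq
        state.select(*cell)
        events.append(SessionEvent(t=t, type="select", cell=cell))
        solution_digit = int(puzzle.solution[cell])
        entry_t = t
        while rng.random() < miss_p:
            entry_t += max(
                0.2,
                rng.normal(
                    user.entry_delay_s * (1.0 + user.entry_jitter_gain * perturb),
                    user.entry_sd,
                ),
            )
            wrong = int(rng.choice([d for d in range(1, 10) if d != solution_digit]))
            state.enter(cell[0], cell[1], wrong)
            events.append(
                SessionEvent(t=entry_t, type="entry", cell=cell, value=wrong, correct=False)
            )
        entry_t += max(
            0.2,
            rng.normal(
                user.entry_delay_s * (1.0 + user.entry_jitter_gain * perturb),
                user.entry_sd,
            ),
        )
        state.enter(cell[0], cell[1], solution_digit)
        events.append(
            SessionEvent(
                t=entry_t, type="entry", cell=cell, value=solution_digit, correct=True
            )
        )
        t = entry_t
    assert state.is_complete
    events.append(SessionEvent(t=t, type="complete"))
    metrics = compute_metrics(events, condition, subject)
    assert metrics.n_errors == state.n_errors
    return SessionResult(
        subject=subject,
        condition=condition,
        events=events,
        metrics=metrics,
        jitter_rms=jitter,
        physical_rms=physical,
        seed=seed,
    )


def run_batch(
    n_subjects: int = 15,
    conditions=CONDITIONS,
    seed: int = 0,
    **session_kwargs,
) -> list[MetricsRecord]:
    """One simulated cohort: every subject plays every condition.

    All sessions in a batch share one carved easy puzzle (the study used a
    single standardized difficulty level); per-session randomness comes
    from sub-seeds of ``seed``.
    """
    conditions = list(conditions)
    difficulty = session_kwargs.pop("difficulty", "easy")
    puzzle = session_kwargs.pop("puzzle", None) or make_puzzle(
        difficulty, _sub_seed(seed, 0)
    )
    records = []
    for i in range(n_subjects):
        for j, cond in enumerate(conditions):
            res = run_session(
                cond,
                _sub_seed(seed, 100 + i, j),
                subject=f"s{i + 1:02d}",
                puzzle=puzzle,
                **session_kwargs,
            )
            records.append(res.metrics)
    return records
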