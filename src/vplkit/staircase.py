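"""Adaptive 3-down/1-up staircase on motion coherence, with reversal-based
threshold estimation, session orchestration and plateau detection.

Rule: after three consecutive correct responses the coherence is reduced by
10% (multiplicative, x0.90); after any single error it is raised by 10%
(x1.10, capped at 1.0). The consecutive-correct counter resets on every step.
A reversal is logged whenever the step direction changes, and the recorded
reversal value is the coherence at which the direction change occurred (the
level actually tested). The block threshold is the mean of the reversals that
remain after discarding the first four (even total) or five (odd total).
This transformed up/down rule converges to the accuracy p solving p**3 = 1/2,
i.e. ~79.4% correct.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .observers import ObserverParams, GroupDesign, simulate_response

__all__ = [
    "DOWN_FACTOR",
    "UP_FACTOR",
    "StaircaseState",
    "TrialRecord",
    "ThresholdEstimate",
    "InsufficientReversalsError",
    "update_staircase",
    "threshold_from_reversals",
    "run_block",
    "run_session",
    "run_test",
    "detect_plateau",
    "staircase_convergence_level",
]

DOWN_FACTOR = 0.90
UP_FACTOR = 1.10
N_DOWN = 3  # consecutive correct responses required for a down step
COHERENCE_CAP = 1.0
DEFAULT_START_COHERENCE = 0.80

#: Reversals discarded from the start of a block: 4 if the total is even,
#: 5 if odd; at least two reversals must remain to average.
_DROP_EVEN, _DROP_ODD = 4, 5


class InsufficientReversalsError(RuntimeError):
    """A staircase block produced too few reversals for a threshold estimate."""

    def __init__(self, n_reversals: int):
        self.n_reversals = n_reversals
        super().__init__(
            f"need at least 6 (even) or 7 (odd) reversals, got {n_reversals}"
        )


@dataclass
class StaircaseState:
    """Mutable state of one running staircase."""

    coherence: float
    consecutive_correct: int = 0
    last_direction: Literal["down", "up", None] = None
    reversals: list[float] = field(default_factory=list)
    trial_count: int = 0


@dataclass(frozen=True)
class TrialRecord:
    """One 2AFC trial in the log (indices are 1-based)."""

    observer_id: str
    session: int
    block: int
    trial: int
    coherence: float
    correct: bool
    reversal: bool


@dataclass(frozen=True)
class ThresholdEstimate:
    """A session- or test-level threshold with its reversal provenance."""

    observer_id: str
    session: int
    kind: Literal["training", "test_trained_location", "test_untrained_location"]
    threshold: float
    n_reversals_total: int
    n_reversals_used: int


def update_staircase(state: StaircaseState, correct: bool) -> bool:
    """Advance the staircase by one response, in place.

    Returns True when this trial is a reversal (the applied step direction
    differs from the previous non-null direction); the pre-step coherence is
    then appended to ``state.reversals``.
    """
    pre = state.coherence
    state.trial_count += 1
    if correct:
        state.consecutive_correct += 1
        if state.consecutive_correct < N_DOWN:
            return False
        direction: Literal["down", "up"] = "down"
        state.coherence = pre * DOWN_FACTOR
    else:
        direction = "up"
        state.coherence = min(pre * UP_FACTOR, COHERENCE_CAP)
    state.consecutive_correct = 0
    is_reversal = state.last_direction is not None and direction != state.last_direction
    if is_reversal:
        state.reversals.append(pre)
    state.last_direction = direction
    return is_reversal


def threshold_from_reversals(reversals: Sequence[float]) -> tuple[float, int]:
    """Mean of the late reversals: drop the first 4 (even total) or 5 (odd).

    Returns ``(threshold, n_used)``; raises :class:`InsufficientReversalsError`
    if fewer than two reversals would remain.
    """
    n = len(reversals)
    drop = _DROP_EVEN if n % 2 == 0 else _DROP_ODD
    if n - drop < 2:
        raise InsufficientReversalsError(n)
    kept = np.asarray(reversals[drop:], dtype=float)
    return float(kept.mean()), len(kept)


def _run_staircase(
    obs: ObserverParams,
    t: int,
    n_trials: int,
    start_coherence: float,
    rng: np.random.Generator,
    block: int,
) -> tuple[list[TrialRecord], list[float], float]:
    """Drive one staircase for ``n_trials`` trials; returns the trial log,
    the reversal values and the final (post-update) coherence."""
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    state = StaircaseState(coherence=start_coherence)
    records: list[TrialRecord] = []
    for trial in range(1, n_trials + 1):
        coherence = state.coherence
        correct = simulate_response(obs, coherence, t, rng)
        is_reversal = update_staircase(state, correct)
        records.append(
            TrialRecord(
                observer_id=obs.observer_id,
                session=t,
                block=block,
                trial=trial,
                coherence=coherence,
                correct=correct,
                reversal=is_reversal,
            )
        )
    return records, state.reversals, state.coherence


def run_block(
    obs: ObserverParams,
    t: int,
    n_trials: int,
    start_coherence: float,
    rng: np.random.Generator,
    *,
    block: int = 1,
    kind: str = "training",
) -> tuple[list[TrialRecord], ThresholdEstimate]:
    """Run one staircase block of ``n_trials`` trials against a simulated observer."""
    records, reversals, _ = _run_staircase(obs, t, n_trials, start_coherence, rng, block)
    threshold, n_used = threshold_from_reversals(reversals)
    estimate = ThresholdEstimate(
        observer_id=obs.observer_id,
        session=t,
        kind=kind,  # type: ignore[arg-type]
        threshold=threshold,
        n_reversals_total=len(reversals),
        n_reversals_used=n_used,
    )
    return records, estimate


def run_session(
    obs: ObserverParams,
    t: int,
    design: GroupDesign,
    rng: np.random.Generator,
    start_coherence: float = DEFAULT_START_COHERENCE,
) -> tuple[list[TrialRecord], ThresholdEstimate]:
    """One training session: several staircase blocks, thresholds averaged.

    The first block starts at ``start_coherence``; each later block starts
    where the previous block ended, so only the first block pays the descent
    transient. Each block is an independent staircase otherwise (fresh
    counters and reversal log) and contributes one reversal-averaged
    threshold; the session threshold is their mean. Blocks that end with too
    few reversals are dropped; if every block fails, the session raises
    :class:`InsufficientReversalsError`.
    """
    records: list[TrialRecord] = []
    block_thresholds: list[float] = []
    n_total = n_used = 0
    coherence = start_coherence
    for block in range(1, design.blocks_per_training_session + 1):
        block_records, reversals, coherence = _run_staircase(
            obs, t, design.trials_per_block, coherence, rng, block
        )
        records.extend(block_records)
        try:
            threshold, used = threshold_from_reversals(reversals)
        except InsufficientReversalsError:
            continue
        block_thresholds.append(threshold)
        n_total += len(reversals)
        n_used += used
    if not block_thresholds:
        raise InsufficientReversalsError(0)
    estimate = ThresholdEstimate(
        observer_id=obs.observer_id,
        session=t,
        kind="training",
        threshold=float(np.mean(block_thresholds)),
        n_reversals_total=n_total,
        n_reversals_used=n_used,
    )
    return records, estimate


def run_test(
    obs: ObserverParams,
    t: int,
    location: Literal["trained", "untrained"],
    design: GroupDesign,
    rng: np.random.Generator,
    start_coherence: float = DEFAULT_START_COHERENCE,
) -> tuple[list[TrialRecord], ThresholdEstimate]:
    """One 120-trial test staircase at the trained or untrained location.

    The location affects only the record label; any transfer attenuation is
    applied upstream by adjusting the observer's effective learning rate.
    """
    kind = f"test_{location}_location"
    if kind not in ("test_trained_location", "test_untrained_location"):
        raise ValueError(f"unknown test location {location!r}")
    return run_block(
        obs, t, design.trials_per_test, start_coherence, rng, block=1, kind=kind
    )


def detect_plateau(daily_thresholds: Sequence[float]) -> int | None:
    """First day at which learning has plateaued, or None.

    The plateau criterion is a relative day-over-day threshold reduction
    ``r_i = (theta_{i-1} - theta_i) / theta_{i-1}`` below 1% on two
    consecutive days; the returned value is the 0-based index of the day
    ending the second sub-1% reduction. Negative reductions (a worsening)
    count as below 1%.
    """
    thresholds = np.asarray(daily_thresholds, dtype=float)
    if len(thresholds) < 3:
        raise ValueError("need at least 3 daily thresholds")
    if np.any(thresholds <= 0):
        raise ValueError("thresholds must be positive")
    reductions = (thresholds[:-1] - thresholds[1:]) / thresholds[:-1]
    small = reductions < 0.01
    for i in range(1, len(small)):
        if small[i - 1] and small[i]:
            return i + 1
    return None


def staircase_convergence_level(n_down: int = N_DOWN) -> float:
    """Equilibrium accuracy of an n-down/1-up rule: p solving p**n = 1/2.

    For the 3-down/1-up rule this is 0.5**(1/3) ~ 0.7937 (79.4% correct);
    for 1-down/1-up it is 0.5.
    """
    if n_down < 1:
        raise ValueError("n_down must be >= 1")
    return 0.5 ** (1.0 / n_down)
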