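"""Synthetic observers for coherent-motion perceptual learning experiments.

Each simulated participant carries a latent power-law learning curve

    C(t) = C0 * t**(-rho)

where ``C0`` is the initial coherence threshold, ``t`` the 1-based session
number and ``rho`` the learning rate, plus a psychometric function that turns
a presented motion coherence into the probability of a correct response in a
two-alternative forced-choice (2AFC) direction judgement.

The psychometric function is a Weibull on coherence with a 0.5 guess floor,
scaled so that, lapse-free, performance at the latent threshold equals the
equilibrium accuracy of a 3-down/1-up staircase, ``0.5**(1/3) ~ 79.4%``.
With that calibration the staircase's reversal-averaged threshold estimate is
an (asymptotically) unbiased readout of the latent threshold, which is the
property the downstream learning-curve analysis assumes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "GUESS_RATE_2AFC",
    "ObserverParams",
    "GroupDesign",
    "true_threshold",
    "p_correct",
    "simulate_response",
    "generate_cohort",
    "cohort_table",
]

#: Chance performance in a two-alternative forced choice task.
GUESS_RATE_2AFC = 0.5

#: Accuracy to which a 3-down/1-up staircase converges: p solving p**3 = 1/2.
_EQUILIBRIUM_P = 0.5 ** (1.0 / 3.0)

# Weibull scale constant chosen so that the lapse-free psychometric function
# passes through the staircase equilibrium accuracy exactly at the latent
# threshold: guess + (1 - guess) * (1 - exp(-K)) = 0.5**(1/3).
_WEIBULL_K = -math.log1p(-(_EQUILIBRIUM_P - GUESS_RATE_2AFC) / (1.0 - GUESS_RATE_2AFC))


class InvalidSessionError(ValueError):
    """Raised when a session index smaller than 1 is requested."""


@dataclass(frozen=True)
class ObserverParams:
    """Latent parameters of one simulated participant.

    Parameters
    ----------
    observer_id : str
        Unique identifier.
    group : str
        Stimulation-group label.
    c0 : float
        Initial coherence threshold, a proportion in (0, 1].
    rho : float
        Learning rate of the power-law decay, >= 0 (0 means no learning).
    slope : float
        Weibull steepness of the psychometric function, > 0.
    lapse : float
        Lapse rate (stimulus-independent errors), in [0, 0.1].
    guess : float
        Guess rate; fixed at 0.5 for 2AFC.
    """

    observer_id: str
    group: str
    c0: float
    rho: float
    slope: float = 3.5
    lapse: float = 0.02
    guess: float = GUESS_RATE_2AFC

    def __post_init__(self) -> None:
        if not 0.0 < self.c0 <= 1.0:
            raise ValueError(f"c0 must lie in (0, 1], got {self.c0}")
        if self.rho < 0.0:
            raise ValueError(f"rho must be >= 0, got {self.rho}")
        if self.slope <= 0.0:
            raise ValueError(f"slope must be > 0, got {self.slope}")
        if not 0.0 <= self.lapse <= 0.1:
            raise ValueError(f"lapse must lie in [0, 0.1], got {self.lapse}")
        if self.guess != GUESS_RATE_2AFC:
            raise ValueError("guess rate is fixed at 0.5 for the 2AFC task")


def true_threshold(obs: ObserverParams, t: int) -> float:
    """Latent coherence threshold ``C0 * t**(-rho)`` at session ``t`` (1-based)."""
    if t < 1 or int(t) != t:
        raise InvalidSessionError(f"session index must be an integer >= 1, got {t}")
    return obs.c0 * float(t) ** (-obs.rho)


def p_correct(obs: ObserverParams, coherence: float, t: int) -> float:
    """Probability of a correct 2AFC response at the given motion coherence.

    Weibull psychometric function with guess floor and lapse ceiling::

        p = guess + (1 - guess - lapse) * (1 - exp(-K * (c / theta_t)**slope))

    where ``theta_t`` is the latent threshold at session ``t`` and ``K`` is
    fixed so that ``p(theta_t) = 0.5**(1/3)`` when ``lapse = 0``.
    """
    if not 0.0 <= coherence <= 1.0:
        raise ValueError(f"coherence must lie in [0, 1], got {coherence}")
    theta = true_threshold(obs, t)
    psi = -math.expm1(-_WEIBULL_K * (coherence / theta) ** obs.slope)
    return obs.guess + (1.0 - obs.guess - obs.lapse) * psi


def simulate_response(
    obs: ObserverParams, coherence: float, t: int, rng: np.random.Generator
) -> bool:
    """Draw one Bernoulli trial outcome at the given coherence and session."""
    return bool(rng.random() < p_correct(obs, coherence, t))


@dataclass(frozen=True)
class GroupDesign:
    """Between-group design and generative distributions for a cohort.

    Defaults mirror a five-group tDCS motion-learning study: 12 observers per
    group, a pretest, three training sessions and a posttest per stage, five
    70-trial staircase blocks per training session and 120-trial tests.
    Real-stimulation groups learn faster (larger mean ``rho``) than the sham
    and ipsilateral-control groups; initial thresholds are drawn from one
    common distribution so the groups start matched.
    """

    groups: tuple[str, ...] = ("rDLPFC+rMT", "rDLPFC", "rMT", "lMT", "sham")
    n_per_group: int = 12
    c0_mean: float = 0.45
    c0_sd: float = 0.10
    rho_by_group: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "rDLPFC+rMT": (0.30, 0.05),
            "rDLPFC": (0.30, 0.05),
            "rMT": (0.30, 0.05),
            "lMT": (0.15, 0.05),
            "sham": (0.15, 0.05),
        }
    )
    sessions_early: int = 5  # pretest + 3 training + posttest
    blocks_per_training_session: int = 5
    trials_per_block: int = 70
    trials_per_test: int = 120
    slope: float = 3.5
    lapse: float = 0.02

    def __post_init__(self) -> None:
        if len(set(self.groups)) != len(self.groups):
            raise ValueError("group labels must be unique")
        for name, value in (
            ("n_per_group", self.n_per_group),
            ("sessions_early", self.sessions_early),
            ("blocks_per_training_session", self.blocks_per_training_session),
            ("trials_per_block", self.trials_per_block),
            ("trials_per_test", self.trials_per_test),
        ):
            if value < 1:
                raise ValueError(f"{name} must be >= 1, got {value}")
        missing = set(self.groups) - set(self.rho_by_group)
        if missing:
            raise ValueError(f"rho_by_group lacks entries for groups: {sorted(missing)}")
        if self.c0_sd < 0:
            raise ValueError("c0_sd must be >= 0")
        for g, (_, sd) in self.rho_by_group.items():
            if sd < 0:
                raise ValueError(f"rho sd for group {g!r} must be >= 0")


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float
) -> float:
    """One draw from N(mean, sd) truncated to [lo, hi] by rejection."""
    if sd == 0.0:
        return float(np.clip(mean, lo, hi))
    for _ in range(10_000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    raise RuntimeError("truncated-normal rejection sampling failed to converge")


def generate_cohort(
    design: GroupDesign, seed: int | np.random.Generator
) -> list[ObserverParams]:
    """Draw a full cohort of observers, ``n_per_group`` per group.

    ``c0`` is drawn from a normal truncated to (0, 1]; ``rho`` from the
    group's normal truncated to >= 0. Deterministic under a fixed seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cohort: list[ObserverParams] = []
    for group in design.groups:
        rho_mean, rho_sd = design.rho_by_group[group]
        for i in range(design.n_per_group):
            c0 = _truncated_normal(rng, design.c0_mean, design.c0_sd, 1e-6, 1.0)
            rho = _truncated_normal(rng, rho_mean, rho_sd, 0.0, np.inf)
            cohort.append(
                ObserverParams(
                    observer_id=f"{group}-{i + 1:02d}",
                    group=group,
                    c0=c0,
                    rho=rho,
                    slope=design.slope,
                    lapse=design.lapse,
                )
            )
    return cohort


def cohort_table(cohort: Iterable[ObserverParams]) -> pd.DataFrame:
    """Cohort as a tidy table (observer_id, group, c0, rho, slope, lapse)."""
    return pd.DataFrame(
        [
            {
                "observer_id": o.observer_id,
                "group": o.group,
                "c0": o.c0,
                "rho": o.rho,
                "slope": o.slope,
                "lapse": o.lapse,
            }
            for o in cohort
        ]
    )


def transfer_observer(obs: ObserverParams, transfer: float) -> ObserverParams:
    """Observer whose learning only partially transfers to an untrained location.

    A transfer factor ``tau`` scales the log-threshold improvement:
    ``theta_u(t) = c0 * (theta(t)/c0)**tau``, which is the same power law with
    learning rate ``tau * rho``.
    """
    if not 0.0 <= transfer <= 1.0:
        raise ValueError("transfer factor must lie in [0, 1]")
    return replace(obs, rho=obs.rho * transfer)
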