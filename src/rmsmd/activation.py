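"""Five-state Markov model of fluorophore photoswitching.

Each emitter is independently in one of five states per frame: state 0
is dark, states 1-4 are activated (emitting).  The transition
probability from state i to state j is written r_ji.  From the dark
state the emitter stays dark with probability r00 or activates into
state 1; from activated state j it either returns to dark (probability
r0j) or advances to state j+1; state 4 always relaxes to dark (r04 = 1).
All other transitions have probability zero.  For 0 < r00 < 1 the chain
is irreducible and aperiodic with a unique stationary distribution whose
dark-state probability has the closed form

    p0 = 1 / (1 + sum_{j=1..4} prod_{k=0..j-1} r_{k+1,k}),

and the stationary activation probability is p_a = 1 - p0.

The defaults r01 = 0.5, r02 = 0.7, r03 = 0.8, r04 = 1 are fixed;
r00 controls the duty cycle and hence the density of activated emitters
per frame.  ``experiment_size`` derives the frame count N so the mean
number of activations per emitter reaches a target (30 by default), and
``simulate_states`` draws per-emitter state paths started from the
stationary distribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ActivationChain",
    "StationaryDist",
    "ExperimentSize",
    "stationary",
    "experiment_size",
    "simulate_states",
]

N_STATES = 5


@dataclass(frozen=True)
class ActivationChain:
    """Transition probabilities of the photoswitching chain.

    ``r00`` is the dark-state self-transition (the experiment's control
    knob); ``r01``..``r04`` are the activated-to-dark return
    probabilities.  The complementary forward probabilities are derived:
    r10 = 1 - r00, r21 = 1 - r01, r32 = 1 - r02, r43 = 1 - r03.
    """

    r00: float
    r01: float = 0.5
    r02: float = 0.7
    r03: float = 0.8
    r04: float = 1.0

    def __post_init__(self) -> None:
        for name in ("r00", "r01", "r02", "r03", "r04"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} = {v} outside [0, 1]")

    @property
    def r10(self) -> float:
        return 1.0 - self.r00

    @property
    def r21(self) -> float:
        return 1.0 - self.r01

    @property
    def r32(self) -> float:
        return 1.0 - self.r02

    @property
    def r43(self) -> float:
        return 1.0 - self.r03

    def transition_matrix(self) -> np.ndarray:
        """Row-stochastic 5x5 matrix P with P[i, j] = Pr(j at t+1 | i at t)."""
        p = np.zeros((N_STATES, N_STATES))
        p[0, 0], p[0, 1] = self.r00, self.r10
        p[1, 0], p[1, 2] = self.r01, self.r21
        p[2, 0], p[2, 3] = self.r02, self.r32
        p[3, 0], p[3, 4] = self.r03, self.r43
        p[4, 0] = self.r04
        return p


@dataclass(frozen=True)
class StationaryDist:
    """Stationary state probabilities p0..p4 and activation probability."""

    p: np.ndarray  # shape (5,)

    @property
    def p0(self) -> float:
        return float(self.p[0])

    @property
    def p_a(self) -> float:
        return 1.0 - self.p0


@dataclass(frozen=True)
class ExperimentSize:
    """Derived sizes of an imaging experiment at one duty cycle.

    ``m_active`` is the mean number of activated emitters per frame,
    ``n_frames`` the number of frames giving the target mean activations
    per emitter, ``density_um2`` the mean activated-emitter density.
    """

    p_a: float
    m_active: float
    n_frames: int
    density_um2: float


def stationary(chain: ActivationChain) -> StationaryDist:
    """Closed-form stationary distribution of the chain.

    Requires 0 < r00 < 1 (otherwise the chain is degenerate: never
    activating, or never resting in the dark state).
    """
    if not 0.0 < chain.r00 < 1.0:
        raise ValueError(f"r00 = {chain.r00} gives a degenerate chain")
    forward = [chain.r10, chain.r21, chain.r32, chain.r43]
    # cumulative products prod_{k=0..j-1} r_{k+1,k} for j = 1..4
    cumprod = np.cumprod(forward)
    p0 = 1.0 / (1.0 + cumprod.sum())
    p = np.concatenate(([p0], p0 * cumprod))
    return StationaryDist(p=p)


def experiment_size(
    chain: ActivationChain,
    n_emitters: int,
    target_activations: float = 30.0,
    frame_area_um2: float = 2.048 * 2.048,
) -> ExperimentSize:
    """Sizes of the sweep experiment for one duty-cycle setting.

    The frame count is the largest N with p_a * N not exceeding the
    target mean activations per emitter, i.e. floor(target / p_a).
    """
    if n_emitters < 1:
        raise ValueError("need at least one emitter")
    if not frame_area_um2 > 0:
        raise ValueError("frame area must be positive")
    p_a = stationary(chain).p_a
    if p_a <= 0:
        raise ValueError("activation probability is zero")
    m_active = p_a * n_emitters
    return ExperimentSize(
        p_a=p_a,
        m_active=m_active,
        n_frames=int(math.floor(target_activations / p_a)),
        density_um2=m_active / frame_area_um2,
    )


def simulate_states(
    chain: ActivationChain,
    n_emitters: int,
    n_frames: int,
    seed,
    init_state: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate per-emitter state paths over frames.

    Each emitter's path is a Markov chain started from the stationary
    distribution (or from ``init_state`` if given), driven by its own
    independent random stream (spawned from ``seed``, so adding emitters
    never perturbs existing paths).

    Returns ``(states, active)``: an (n_emitters, n_frames) int array of
    states and the boolean activation matrix ``states != 0``.
    """
    if n_emitters < 1 or n_frames < 1:
        raise ValueError("n_emitters and n_frames must be >= 1")
    p = chain.transition_matrix()
    cum_p = np.cumsum(p, axis=1)

    # one uniform stream per emitter, all frames drawn up front
    seq = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    u = np.empty((n_emitters, n_frames + 1))
    for i, child in enumerate(seq.spawn(n_emitters)):
        u[i] = np.random.default_rng(child).random(n_frames + 1)

    states = np.empty((n_emitters, n_frames), dtype=np.int8)
    if init_state is None:
        cum_pi = np.cumsum(stationary(chain).p)
        current = np.searchsorted(cum_pi, u[:, 0], side="right").astype(np.int8)
    else:
        if not 0 <= init_state < N_STATES:
            raise ValueError(f"init_state {init_state} outside 0..{N_STATES - 1}")
        current = np.full(n_emitters, init_state, dtype=np.int8)
    for t in range(n_frames):
        # inverse-CDF step, vectorized over emitters
        current = (u[:, t + 1, None] > cum_p[current]).sum(axis=1).astype(np.int8)
        states[:, t] = current
    return states, states != 0
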