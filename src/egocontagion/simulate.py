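"""Synchronous discrete-time simulation of coexisting adoption mechanisms.

Three mechanisms can move a node from susceptible (0) to infected (1), after
which the state is absorbing:

* simple contagion (``Sm``): at every step each infected neighbour
  independently transmits with probability beta, so the per-step adoption
  hazard with n infected neighbours is ``1 - (1-beta)**n``;
* complex contagion (``Cx``): deterministic Watts threshold — the node adopts
  at the step after its infected-neighbour count first exceeds ``phi * k``
  (strict Heaviside inequality, minimal adopting count m* = floor(k*phi)+1);
* spontaneous adoption (``St``): network-independent Bernoulli(r) per step.

Updates are fully synchronous: all states at t+1 are computed from states at
t. When a mechanism event and a spontaneous event fire in the same step the
adoption is attributed to the network mechanism, mirroring the likelihood
scenario in which a spontaneous adoption requires the network event not to
fire.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .networks import Network

__all__ = [
    "SM",
    "CX",
    "ST",
    "SEED",
    "NEVER",
    "NodeConfig",
    "SimConfig",
    "Trajectory",
    "EgoObservation",
    "threshold_met",
    "threshold_count",
    "run_ego_experiment",
    "simulate_ego_star_batch",
    "run_static_contagion",
    "count_stimuli",
]

SM = "Sm"
CX = "Cx"
ST = "St"
SEED = "seed"
NEVER = "never"


@dataclass(frozen=True)
class NodeConfig:
    """Mechanism assignment of one node: ``Sm`` with beta or ``Cx`` with phi."""

    mechanism: str
    beta: float | None = None
    phi: float | None = None

    def __post_init__(self) -> None:
        if self.mechanism == SM:
            if self.beta is None or self.phi is not None:
                raise ValueError("Sm node requires beta only")
            if not 0.0 <= self.beta <= 1.0:
                raise ValueError("beta must be in [0, 1]")
        elif self.mechanism == CX:
            if self.phi is None or self.beta is not None:
                raise ValueError("Cx node requires phi only")
            if not 0.0 <= self.phi <= 1.0:
                raise ValueError("phi must be in [0, 1]")
        else:
            raise ValueError(f"unknown mechanism {self.mechanism!r}")


@dataclass(frozen=True)
class SimConfig:
    """Global simulation parameters.

    ``r`` is the spontaneous adoption probability per step; ``r_nb`` is the
    spontaneous rate of the leaves in the isolated ego-star setting; ``horizon``
    caps the number of steps; ``stop_frac`` terminates a network run once that
    fraction of nodes is infected.
    """

    r: float = 0.005
    r_nb: float = 0.05
    horizon: int = 10_000
    stop_frac: float = 1.0

    def __post_init__(self) -> None:
        for name in ("r", "r_nb"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if not 0.0 < self.stop_frac <= 1.0:
            raise ValueError("stop_frac must be in (0, 1]")
        if self.horizon < 1:
            raise ValueError("horizon must be >= 1")


@dataclass
class Trajectory:
    """Outcome of a whole-network run.

    Because states are absorbing, the full binary trajectory of every node is
    encoded by its adoption time (``-1`` = never infected within the horizon).
    """

    net: Network
    adoption_time: np.ndarray  # int, -1 for never
    label: np.ndarray  # object array over {Sm, Cx, St, seed, never}
    t_end: int
    seed_node: int
    stalled: bool = False

    def states_at(self, t: int) -> np.ndarray:
        return (self.adoption_time >= 0) & (self.adoption_time <= t)

    def ego_observation(self, node: int) -> "EgoObservation":
        nbs = np.array(self.net.neighbors(node), dtype=np.int64)
        t_a = int(self.adoption_time[node])
        return EgoObservation(
            degree=len(nbs),
            adoption_time=None if t_a < 0 else t_a,
            neighbor_adoption_times=self.adoption_time[nbs].copy(),
            horizon=self.t_end,
            true_label=str(self.label[node]),
        )


@dataclass
class EgoObservation:
    """Egocentric view of a contagion: the only input the classifiers see.

    ``neighbor_adoption_times[j]`` is the step at which neighbour j became
    infected (``-1`` = never, within ``horizon``). In the synchronous model a
    stimulus is one infected neighbour during one step while the ego is
    susceptible; in event-time data ``stimulus_times`` instead lists the
    explicit influencing-post times per neighbour.
    """

    degree: int
    adoption_time: int | None
    neighbor_adoption_times: np.ndarray
    horizon: int
    true_label: str | None = None
    stimulus_times: list[np.ndarray] | None = None

    def __post_init__(self) -> None:
        self.neighbor_adoption_times = np.asarray(self.neighbor_adoption_times)
        if len(self.neighbor_adoption_times) != self.degree:
            raise ValueError("neighbour count must equal ego degree")

    @property
    def adopted(self) -> bool:
        return self.adoption_time is not None

    def n_infected_neighbors(self, t: int) -> int:
        ts = self.neighbor_adoption_times
        return int(((ts >= 0) & (ts <= t)).sum())

    def neighbor_counts_series(self, t_max: int) -> np.ndarray:
        """n(t) for t = 0..t_max (number of infected neighbours at step t)."""
        ts = self.neighbor_adoption_times
        grid = np.arange(t_max + 1)
        return ((ts[None, :] >= 0) & (ts[None, :] <= grid[:, None])).sum(axis=1)


def threshold_count(k: int, phi: float) -> int:
    """Minimal infected-neighbour count m* satisfying the Watts condition.

    The Heaviside condition n > k*phi is met first at m* = floor(k*phi) + 1,
    which coincides with ceil(k*phi) whenever k*phi is not an integer.
    """
    return int(np.floor(k * phi)) + 1


def threshold_met(n_infected_neighbors: int, k: int, phi: float) -> bool:
    """Strict Watts threshold: true iff n > phi * k."""
    if k < 1:
        raise ValueError("degree must be >= 1")
    if not 0 <= n_infected_neighbors <= k:
        raise ValueError("infected neighbour count outside [0, degree]")
    return n_infected_neighbors >= threshold_count(k, phi)


def run_ego_experiment(
    degree: int,
    config: NodeConfig,
    sim: SimConfig,
    rng: np.random.Generator,
) -> EgoObservation:
    """One isolated ego-star contagion, simulated step by step.

    Leaves flip S -> I independently with probability ``sim.r_nb`` per step;
    the ego follows its assigned mechanism and is never spontaneously
    infected. Runs until the ego adopts or the horizon is exhausted.
    """
    if degree < 1:
        raise ValueError("degree must be >= 1")
    leaf_t = np.full(degree, -1, dtype=np.int64)
    leaves = np.zeros(degree, dtype=bool)
    m_star = threshold_count(degree, config.phi) if config.mechanism == CX else None
    t_a: int | None = None
    for t in range(sim.horizon):
        n_inf = int(leaves.sum())
        # ego transition t -> t+1 from neighbour states at t
        if config.mechanism == SM:
            if n_inf > 0 and rng.random() < 1.0 - (1.0 - config.beta) ** n_inf:
                t_a = t + 1
        else:
            if n_inf >= m_star:
                t_a = t + 1
        # leaves transition synchronously
        flip = (~leaves) & (rng.random(degree) < sim.r_nb)
        leaf_t[flip] = t + 1
        leaves |= flip
        if t_a is not None:
            break
    return EgoObservation(
        degree=degree,
        adoption_time=t_a,
        neighbor_adoption_times=leaf_t,
        horizon=sim.horizon if t_a is None else t_a,
        true_label=config.mechanism,
    )


def simulate_ego_star_batch(
    degrees: np.ndarray,
    mechanism: str,
    param: float,
    r_nb: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Event-driven batch equivalent of :func:`run_ego_experiment`.

    Exploits that each leaf's infection time is Geometric(r_nb) on {1,2,...}
    and that, between neighbour infections, the ego's per-step hazard is
    constant, so the ego adoption time can be drawn segment-by-segment without
    stepping through time. Exact for the synchronous dynamics, including
    simultaneous leaf infections (zero-length segments).

    Returns ``(ego_adoption_times, leaf_times)`` with ``leaf_times`` padded to
    the maximum degree with -1 (shape ``(n, k_max)``), leaf columns sorted.
    """
    degrees = np.asarray(degrees, dtype=np.int64)
    n = len(degrees)
    k_max = int(degrees.max())
    leaf_times = np.full((n, k_max), np.iinfo(np.int64).max, dtype=np.int64)
    for k in np.unique(degrees):
        rows = np.nonzero(degrees == k)[0]
        leaf_times[rows[:, None], np.arange(k)[None, :]] = rng.geometric(
            r_nb, size=(len(rows), k)
        )
    leaf_times.sort(axis=1)

    t_a = np.full(n, -1, dtype=np.int64)
    if mechanism == CX:
        m_star = np.floor(degrees * param).astype(np.int64) + 1
        # adoption one step after the m*-th leaf infection
        t_a = leaf_times[np.arange(n), m_star - 1] + 1
    elif mechanism == SM:
        beta = param
        done = np.zeros(n, dtype=bool)
        if beta <= 0.0:
            pass  # never adopts
        else:
            for j in range(1, k_max + 1):
                active = (~done) & (degrees >= j)
                if not active.any():
                    break
                idx = np.nonzero(active)[0]
                seg_start = leaf_times[idx, j - 1]
                b_j = 1.0 - (1.0 - beta) ** j
                g = rng.geometric(b_j, size=len(idx))
                if j < k_max:
                    seg_len = np.where(
                        degrees[idx] > j,
                        np.minimum(leaf_times[idx, j], np.iinfo(np.int64).max - 1)
                        - seg_start,
                        np.iinfo(np.int64).max,
                    )
                else:
                    seg_len = np.full(len(idx), np.iinfo(np.int64).max)
                hit = g <= seg_len
                t_a[idx[hit]] = seg_start[hit] + g[hit]
                done[idx[hit]] = True
    else:
        raise ValueError(f"ego mechanism must be Sm or Cx, got {mechanism!r}")

    big = leaf_times == np.iinfo(np.int64).max
    leaf_times = np.where(big, -1, leaf_times)
    return t_a, leaf_times


def _assign_labels(
    configs: Sequence[NodeConfig],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mech = np.array([c.mechanism == CX for c in configs], dtype=bool)  # True = Cx
    beta = np.array([c.beta if c.mechanism == SM else 0.0 for c in configs])
    phi = np.array([c.phi if c.mechanism == CX else 0.0 for c in configs])
    return mech, beta, phi


def run_static_contagion(
    net: Network,
    configs: Sequence[NodeConfig],
    sim: SimConfig,
    rng: np.random.Generator,
    seed_node: int | None = None,
) -> Trajectory:
    """Whole-network synchronous contagion with coexisting mechanisms.

    One uniformly random node is infected at t=0 (label ``seed``); at every
    step each susceptible node draws a spontaneous Bernoulli(r) event and its
    mechanism event against the neighbour states of the previous step. Runs
    until ``stop_frac`` of nodes are infected, the horizon is exhausted, or
    (with r=0) no susceptible node retains a positive hazard.
    """
    n = net.n_nodes
    if len(configs) != n:
        raise ValueError("one NodeConfig required per node")
    is_cx, beta, phi = _assign_labels(configs)
    k = net.degrees
    m_star = np.floor(k * phi).astype(np.int64) + 1
    A = net.adjacency().astype(np.float64)

    if seed_node is None:
        seed_node = int(rng.integers(n))
    infected = np.zeros(n, dtype=bool)
    infected[seed_node] = True
    adoption_time = np.full(n, -1, dtype=np.int64)
    adoption_time[seed_node] = 0
    label = np.full(n, NEVER, dtype=object)
    label[seed_node] = SEED

    target = int(np.ceil(sim.stop_frac * n))
    stalled = False
    t = 0
    for t in range(1, sim.horizon + 1):
        if infected.sum() >= target:
            t = t - 1
            break
        s = A @ infected  # infected-neighbour counts at t-1
        sus = ~infected
        hazard_sm = np.where(~is_cx, 1.0 - (1.0 - beta) ** s, 0.0)
        mech_fire = np.where(
            is_cx, s >= m_star, rng.random(n) < hazard_sm
        ) & sus
        spont_fire = (rng.random(n) < sim.r) & sus
        new = mech_fire | spont_fire
        if not new.any():
            if sim.r == 0.0:
                # positive hazard only for Sm nodes with infected neighbours
                # or Cx nodes at/over threshold (which would have fired)
                any_hope = (sus & ~is_cx & (s > 0) & (beta > 0)).any()
                if not any_hope:
                    stalled = infected.sum() < target
                    t = t - 1
                    break
            continue
        adoption_time[new] = t
        infected |= new
        # mechanism event takes precedence over a same-step spontaneous event
        label[new & mech_fire & is_cx] = CX
        label[new & mech_fire & ~is_cx] = SM
        label[new & ~mech_fire] = ST
    return Trajectory(
        net=net,
        adoption_time=adoption_time,
        label=label,
        t_end=t,
        seed_node=seed_node,
        stalled=stalled,
    )


def count_stimuli(obs: EgoObservation) -> np.ndarray:
    """Per-neighbour stimuli received by the ego before its adoption.

    Synchronous mode: one stimulus per infected neighbour per step strictly
    before the ego's adoption, so neighbour j (infected at t_j) delivers
    ``max(0, t_a - t_j)`` stimuli. Event-time mode counts the neighbour's
    influencing posts before the adoption index.
    """
    t_a = obs.adoption_time if obs.adopted else obs.horizon
    if obs.stimulus_times is not None:
        return np.array(
            [int((np.asarray(st) < t_a).sum()) for st in obs.stimulus_times],
            dtype=np.int64,
        )
    ts = obs.neighbor_adoption_times
    return np.where(ts >= 0, np.maximum(0, t_a - ts), 0).astype(np.int64)
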