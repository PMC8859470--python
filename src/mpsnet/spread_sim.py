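"""Discrete-time SEI diffusion over a multi-pathway graph.

Each labeled edge carries a per-step transmission probability
``1 - exp(-alpha * rho(source, t))`` (flow-weighted for the long-distance
pathway).  Updates are synchronous: during step ``t`` every infectious node
draws one independent Bernoulli per outgoing labeled edge toward a
susceptible neighbor; newly exposed nodes become infectious once
``t - exposure_step >= latency`` and first transmit on the following step.

One uniform draw is made per directed labeled edge per step regardless of
state, so runs that share an RNG seed are coupled by common random numbers:
raising any pathway parameter can only grow the infected set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .graph_model import MultiPathwayGraph, PathwayLabel

__all__ = [
    "SpreadParams",
    "InfectivitySchedule",
    "Trajectory",
    "EnsembleSummary",
    "edge_probability",
    "select_seeds",
    "run",
    "run_ensemble",
    "pathway_unravel",
]

S, E, I = 0, 1, 2


@dataclass(frozen=True)
class SpreadParams:
    """Diffusion configuration: pathway parameters, latency, seeding, horizons."""

    alpha_s: float = 0.0
    alpha_l: float = 0.0
    alpha_ld: float = 0.0
    latency: int = 0
    seed_fraction: float = 0.05
    horizons: tuple[int, ...] = (6, 12, 18, 24)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if min(self.alpha_s, self.alpha_l, self.alpha_ld) < 0:
            raise ValueError("pathway parameters must be nonnegative")
        if self.latency < 0:
            raise ValueError("latency must be a nonnegative integer")
        if not 0 <= self.seed_fraction <= 1:
            raise ValueError("seed_fraction must lie in [0, 1]")
        hs = tuple(self.horizons)
        if any(h <= 0 for h in hs) or any(b <= a for a, b in zip(hs, hs[1:])):
            raise ValueError("horizons must be strictly increasing positive integers")

    @property
    def max_horizon(self) -> int:
        return max(self.horizons)


@dataclass(frozen=True)
class InfectivitySchedule:
    """Periodic per-node infectivity rho(v, t); constant 1 by default.

    ``values`` may be ``None`` (constant 1), a scalar, a length-n vector
    (time-constant), or an ``(n, period)`` array with
    ``rho(v, t) = values[v, t mod period]``.
    """

    period: int = 12
    values: np.ndarray | float | None = None

    def rho(self, t: int, n: int) -> np.ndarray:
        if self.values is None:
            return np.ones(n)
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim == 0:
            return np.full(n, float(vals))
        if vals.ndim == 1:
            return vals
        return vals[:, t % self.period]

    def is_constant(self) -> bool:
        return self.values is None or np.asarray(self.values).ndim <= 1


def edge_probability(pathway: PathwayLabel | str, alpha: float, rho: float, flow_weight: float = 1.0) -> float:
    """Per-step transmission probability along one labeled edge.

    ``1 - exp(-alpha * rho)`` for the short-range and intra-locality
    pathways; ``1 - exp(-alpha * flow * rho)`` for the long-distance one.
    """
    if alpha < 0 or rho < 0 or flow_weight < 0:
        raise ValueError("alpha, rho, and flow weight must be nonnegative")
    pathway = PathwayLabel(pathway)
    exponent = alpha * rho * (flow_weight if pathway is PathwayLabel.LD else 1.0)
    return float(-math.expm1(-exponent))


def select_seeds(n: int, seed_fraction: float, rng: np.random.Generator) -> np.ndarray:
    """Uniformly chosen initially-infectious vertices, floor(fraction * n) of them."""
    if not 0 < seed_fraction <= 1:
        raise ValueError("seed_fraction must lie in (0, 1]")
    count = int(math.floor(seed_fraction * n))
    if count == 0:
        raise ValueError(f"seed_fraction {seed_fraction} yields zero seed vertices for n = {n}")
    return np.sort(rng.choice(n, size=count, replace=False))


@dataclass
class _DirectedEdges:
    """Directed expansion of the labeled multigraph with per-edge alpha*flow."""

    src: np.ndarray
    dst: np.ndarray
    alpha_flow: np.ndarray  # alpha * flow weight per directed edge

    @classmethod
    def from_graph(cls, g: MultiPathwayGraph, params: SpreadParams) -> "_DirectedEdges":
        srcs, dsts, afs = [], [], []
        alphas = {
            PathwayLabel.S: params.alpha_s,
            PathwayLabel.L: params.alpha_l,
            PathwayLabel.LD: params.alpha_ld,
        }
        for label in PathwayLabel:
            edges = g.layer_edges(label)
            if len(edges) == 0:
                continue
            flow = g.layer_weights(label) if label is PathwayLabel.LD else np.ones(len(edges))
            # both directions of every undirected labeled edge
            srcs.extend((edges[:, 0], edges[:, 1]))
            dsts.extend((edges[:, 1], edges[:, 0]))
            afs.extend((alphas[label] * flow, alphas[label] * flow))
        if not srcs:
            empty = np.empty(0, dtype=np.int64)
            return cls(src=empty, dst=empty, alpha_flow=np.empty(0))
        return cls(
            src=np.concatenate(srcs),
            dst=np.concatenate(dsts),
            alpha_flow=np.concatenate(afs),
        )


@dataclass
class Trajectory:
    """Per-step compartment counts of one run; index 0 is the seeded state."""

    s_counts: np.ndarray
    e_counts: np.ndarray
    i_counts: np.ndarray
    cumulative: np.ndarray  # vertices ever exposed or infectious, seeds included
    seeds: np.ndarray
    rng_seed: object
    infected_sets: list | None = None

    @property
    def n(self) -> int:
        return int(self.s_counts[0] + self.e_counts[0] + self.i_counts[0])

    def at_horizon(self, t: int) -> int:
        return int(self.cumulative[t])


def step(
    state: np.ndarray,
    exposure_step: np.ndarray,
    edges: _DirectedEdges,
    params: SpreadParams,
    schedule: InfectivitySchedule,
    t: int,
    rng: np.random.Generator,
    prob_cache: np.ndarray | None = None,
) -> None:
    """Advance one synchronous step in place.

    Transmissions use the infectious set at the start of the step; exposure
    happens first, then every exposed node with ``t - exposure_step >=
    latency`` is promoted (so latency 0 promotes within the same step but, by
    synchrony, first transmits next step).
    """
    draws = rng.random(len(edges.src))  # one draw per labeled directed edge per step
    if len(edges.src):
        if prob_cache is not None:
            prob = prob_cache
        else:
            rho = schedule.rho(t, len(state))
            prob = -np.expm1(-edges.alpha_flow * rho[edges.src])
        hit = (state[edges.src] == I) & (state[edges.dst] == S) & (draws < prob)
        if hit.any():
            exposed = np.unique(edges.dst[hit])
            state[exposed] = E
            exposure_step[exposed] = t
    promote = (state == E) & (t - exposure_step >= params.latency)
    state[promote] = I


def run(
    g: MultiPathwayGraph,
    params: SpreadParams,
    schedule: InfectivitySchedule | None = None,
    rng: np.random.Generator | None = None,
    record_infected: bool = False,
) -> Trajectory:
    """Execute ``max(horizons)`` steps and record counts after each.

    ``cumulative[t]`` is the number of vertices ever exposed or infectious
    after ``t`` completed steps (seeds included).
    """
    schedule = schedule or InfectivitySchedule()
    seed_token = params.rng_seed
    if rng is None:
        rng = np.random.default_rng(params.rng_seed)
    n = g.n
    edges = _DirectedEdges.from_graph(g, params)
    prob_cache = None
    if schedule.is_constant() and len(edges.src):
        rho0 = schedule.rho(0, n)
        prob_cache = -np.expm1(-edges.alpha_flow * rho0[edges.src])

    state = np.zeros(n, dtype=np.int8)
    exposure_step = np.full(n, -1, dtype=np.int64)
    seeds = select_seeds(n, params.seed_fraction, rng)
    state[seeds] = I

    t_max = params.max_horizon
    s_counts = np.zeros(t_max + 1, dtype=np.int64)
    e_counts = np.zeros(t_max + 1, dtype=np.int64)
    i_counts = np.zeros(t_max + 1, dtype=np.int64)
    infected_sets = [] if record_infected else None

    def _record(idx: int) -> None:
        s_counts[idx] = int((state == S).sum())
        e_counts[idx] = int((state == E).sum())
        i_counts[idx] = int((state == I).sum())
        if infected_sets is not None:
            infected_sets.append(np.flatnonzero(state != S))

    _record(0)
    for t in range(t_max):
        step(state, exposure_step, edges, params, schedule, t, rng, prob_cache)
        _record(t + 1)
    cumulative = n - s_counts
    return Trajectory(
        s_counts=s_counts,
        e_counts=e_counts,
        i_counts=i_counts,
        cumulative=cumulative,
        seeds=seeds,
        rng_seed=seed_token,
        infected_sets=infected_sets,
    )


@dataclass
class EnsembleSummary:
    """Mean/variance of cumulative infections per horizon over an ensemble."""

    horizons: tuple[int, ...]
    means: np.ndarray
    variances: np.ndarray
    n_runs: int
    samples: np.ndarray = field(repr=False)  # (n_runs, n_horizons)

    def standard_errors(self) -> np.ndarray:
        return np.sqrt(self.variances / self.n_runs)

    def as_dict(self) -> dict:
        return {
            int(t): {"mean": float(m), "variance": float(v), "n": self.n_runs}
            for t, m, v in zip(self.horizons, self.means, self.variances)
        }


def run_ensemble(
    g: MultiPathwayGraph,
    params: SpreadParams,
    schedule: InfectivitySchedule | None = None,
    n_runs: int = 100,
) -> EnsembleSummary:
    """Independent runs with per-run streams derived from (rng_seed, run index)."""
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    horizons = tuple(params.horizons)
    samples = np.zeros((n_runs, len(horizons)))
    for i in range(n_runs):
        rng = np.random.default_rng([params.rng_seed, i])
        traj = run(g, params, schedule, rng=rng)
        samples[i] = [traj.at_horizon(t) for t in horizons]
    return EnsembleSummary(
        horizons=horizons,
        means=samples.mean(axis=0),
        variances=samples.var(axis=0, ddof=1) if n_runs > 1 else np.zeros(len(horizons)),
        n_runs=n_runs,
        samples=samples,
    )


def pathway_unravel(
    g: MultiPathwayGraph,
    c: float,
    horizons: tuple[int, ...] = (6, 12, 18, 24),
    n_runs: int = 100,
    rng_seed: int = 0,
    latency: int = 0,
    seed_fraction: float = 0.05,
    schedule: InfectivitySchedule | None = None,
) -> tuple[EnsembleSummary, EnsembleSummary, EnsembleSummary]:
    """Incrementally activate the pathways: (c,0,0), (c,c,0), (c,c,c).

    All three configurations share the network, seed policy, and RNG streams
    (common random numbers), so the returned means are stochastically ordered.
    """
    if not 0 <= c < 1:
        raise ValueError("c must lie in [0, 1)")
    configs = [(c, 0.0, 0.0), (c, c, 0.0), (c, c, c)]
    out = []
    for a_s, a_l, a_ld in configs:
        params = SpreadParams(
            alpha_s=a_s,
            alpha_l=a_l,
            alpha_ld=a_ld,
            latency=latency,
            seed_fraction=seed_fraction,
            horizons=horizons,
            rng_seed=rng_seed,
        )
        out.append(run_ensemble(g, params, schedule, n_runs=n_runs))
    return tuple(out)
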