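"""Discrete-time SIR/SIS epidemic simulation, thresholds, calibration and
ground-truth rankings.

The epidemic models serve as ground-truth identifiers of node spreading
efficiency.  Both run in discrete time with synchronous updates; "probability
per unit time" is read as a per-period probability.

SIR
    States susceptible/infected/recovered.  Each period every infected node
    independently infects each susceptible neighbour with probability β, then
    recovers with probability γ (infections before recoveries, and newly
    infected nodes neither transmit nor recover until the next period — with
    γ=1 each node is infectious for exactly one period).  The spreading
    efficiency M_i of node i is the number of ever-infected nodes of an
    epidemic seeded at i (seed included, so M_i ≥ 1).  The epidemic threshold
    of the control parameter T = β/γ is T^c = ⟨k⟩ / (⟨k²⟩ − ⟨k⟩).

SIS
    States susceptible/infected; recovered nodes become susceptible again.
    Infections with probability ν per infected–susceptible edge, recoveries
    with probability δ.  Above the threshold λ^c = ⟨k⟩/⟨k²⟩ of the effective
    spreading rate λ = ν/δ, the process settles into a dynamically stable
    equilibrium; the persistence ρ_i is the long-run fraction of periods node
    i is infected, measured after equilibrium is declared.

Equilibrium is declared by tracking Δ(I) = I(t+1) − I(t) of the infected
density: after the first non-negative Δ(I), the system rests for
``rest_periods``; equilibrium is declared at the first later period where the
running mean of Δ(I) over a window of at least ``window_periods`` is close to
zero.

Both models come with a calibration scan over T = p·T^c (resp. λ = p·λ^c),
p = 1, 1.1, 1.2, …, that picks the smallest supercritical parameter that
yields a usable ground truth: for SIR, the smallest p at which the top-20%
nodes of every simulation instance average an outbreak larger than 1% of the
graph; for SIS, the smallest λ̂ with a non-zero long-run density and the
smallest λ* ≥ λ̂ whose equilibrium density is at least 1% of the graph.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import networkx as nx
import numpy as np

from .centrality import RankedList, rank_nodes
from .graph import DegreeMoments, degree_moments

__all__ = [
    "SIRConfig",
    "SISConfig",
    "EquilibriumPolicy",
    "GroundTruth",
    "SISResult",
    "CalibrationError",
    "NoEquilibriumError",
    "sir_threshold",
    "sis_threshold",
    "simulate_sir",
    "simulate_sir_batch",
    "sir_ground_truth",
    "calibrate_sir",
    "simulate_sis",
    "detect_equilibrium",
    "calibrate_sis",
    "sis_ground_truth",
]

_MAX_SIR_PERIODS = 1_000_000  # safety cap; γ>0 terminates a.s. long before


class CalibrationError(RuntimeError):
    """No grid point satisfied the calibration criterion."""


class NoEquilibriumError(RuntimeError):
    """SIS dynamics exceeded max_periods without reaching equilibrium."""


@dataclass(frozen=True)
class SIRConfig:
    """SIR parameters: per-period infection β and recovery γ (γ=1 by default).

    The control parameter T = β/γ is derived, never stored.
    """

    beta: float
    gamma: float = 1.0
    n_simulations: int = 1000
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.beta <= 1.0:
            raise ValueError("beta must be in [0, 1]")
        if not 0.0 < self.gamma <= 1.0:
            raise ValueError("gamma must be in (0, 1]")
        if self.n_simulations < 1:
            raise ValueError("n_simulations must be positive")

    @property
    def control_parameter(self) -> float:
        """T = β/γ."""
        return self.beta / self.gamma


@dataclass(frozen=True)
class EquilibriumPolicy:
    """Protocol for declaring the SIS dynamically stable equilibrium.

    ``tolerance`` is in density units (|mean Δ(I)| per period); ``None`` means
    0.5 nodes per period, i.e. 0.5/|N|, resolved against the simulated graph.
    """

    rest_periods: int = 100
    window_periods: int = 100
    tolerance: float | None = None
    max_periods: int = 20_000

    def __post_init__(self) -> None:
        if min(self.rest_periods, self.window_periods, self.max_periods) <= 0:
            raise ValueError("all equilibrium periods must be positive")
        if self.tolerance is not None and self.tolerance < 0:
            raise ValueError("tolerance must be non-negative")

    def resolve_tolerance(self, n_nodes: int | None) -> float:
        if self.tolerance is not None:
            return self.tolerance
        return 0.5 / n_nodes if n_nodes else 0.0


@dataclass(frozen=True)
class SISConfig:
    """SIS parameters: per-period infection ν and recovery δ (δ=0.8 default).

    The effective spreading rate λ = ν/δ is derived, never stored.  Runs start
    with ⌈initial_infected_fraction·|N|⌉ uniformly drawn infected nodes (20%
    by default); persistence is measured over ``measurement_periods`` periods
    after equilibrium and averaged over ``n_simulations`` independent runs.
    """

    nu: float
    delta: float = 0.8
    initial_infected_fraction: float = 0.2
    n_simulations: int = 1000
    rng_seed: int = 0
    equilibrium: EquilibriumPolicy = field(default_factory=EquilibriumPolicy)
    measurement_periods: int = 100

    def __post_init__(self) -> None:
        if not 0.0 <= self.nu <= 1.0:
            raise ValueError("nu must be in [0, 1]")
        if not 0.0 < self.delta <= 1.0:
            raise ValueError("delta must be in (0, 1]")
        if not 0.0 < self.initial_infected_fraction < 1.0:
            raise ValueError("initial_infected_fraction must be in (0, 1)")
        if self.n_simulations < 1 or self.measurement_periods < 1:
            raise ValueError("simulation counts must be positive")

    @property
    def effective_spreading_rate(self) -> float:
        """λ = ν/δ."""
        return self.nu / self.delta


@dataclass(frozen=True)
class GroundTruth:
    """Node → spreading-efficiency map with its derived ranking.

    ``kind`` is ``"sir_efficiency"`` (mean outbreak size M̄_i, in [1, |N|]) or
    ``"sis_persistence"`` (equilibrium infection frequency ρ_i, in [0, 1]).
    """

    kind: str
    values: dict
    ranking: RankedList = field(compare=False)
    provenance: dict = field(compare=False, default_factory=dict)


@dataclass
class SISResult:
    """One SIS run: per-node persistence plus the density trajectory I(t)."""

    persistence: dict
    density_trajectory: list[float]
    equilibrium_reached: bool
    equilibrium_start: int | None
    extinct: bool

    @property
    def equilibrium_density(self) -> float:
        """Mean infected density over the persistence measurement window."""
        if not self.persistence:
            return 0.0
        return float(np.mean(list(self.persistence.values())))


def sir_threshold(moments: DegreeMoments) -> float:
    """SIR epidemic threshold T^c = ⟨k⟩ / (⟨k²⟩ − ⟨k⟩)."""
    denom = moments.mean_squared_degree - moments.mean_degree
    if denom <= 0:
        raise ValueError(
            "SIR threshold undefined: mean_squared_degree must exceed mean_degree"
        )
    return moments.mean_degree / denom


def sis_threshold(moments: DegreeMoments) -> float:
    """SIS epidemic threshold λ^c = ⟨k⟩ / ⟨k²⟩."""
    if moments.mean_squared_degree <= 0:
        raise ValueError("SIS threshold undefined: mean_squared_degree is zero")
    return moments.mean_degree / moments.mean_squared_degree


class _GraphArrays:
    """Indexed sparse-adjacency view of a graph for vectorized epidemics."""

    def __init__(self, graph: nx.Graph):
        self.nodes = sorted(graph.nodes, key=repr)
        self.index = {v: i for i, v in enumerate(self.nodes)}
        self.n = len(self.nodes)
        if self.n:
            self.adjacency = nx.to_scipy_sparse_array(
                graph, nodelist=self.nodes, dtype=np.float32, format="csr"
            )
        else:
            self.adjacency = None


def _sir_outbreaks(
    arrays: _GraphArrays,
    seed_index: int,
    beta: float,
    gamma: float,
    n_runs: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Ever-infected counts of ``n_runs`` independent SIR epidemics.

    Runs are vectorized as (runs × nodes) boolean state matrices; finished
    runs are dropped from the working set each period.
    """
    n = arrays.n
    susceptible = np.ones((n_runs, n), dtype=bool)
    susceptible[:, seed_index] = False
    infected = np.zeros((n_runs, n), dtype=bool)
    infected[:, seed_index] = True

    active = np.arange(n_runs)
    for _ in range(_MAX_SIR_PERIODS):
        live = infected[active].any(axis=1)
        active = active[live]
        if active.size == 0:
            break
        inf = infected[active]
        # P(a susceptible node escapes all its infected neighbours) =
        # (1-β)^(# infected neighbours); attempts on distinct targets are
        # independent, so node-level draws are exact.
        pressure = inf.astype(np.float32) @ arrays.adjacency
        p_infect = 1.0 - np.power(1.0 - beta, pressure, dtype=np.float64)
        newly = (rng.random(p_infect.shape) < p_infect) & susceptible[active]
        recovers = rng.random(inf.shape) < gamma
        susceptible[active] &= ~newly
        infected[active] = (inf & ~recovers) | newly
    else:  # pragma: no cover - unreachable for gamma > 0 in practice
        raise RuntimeError("SIR simulation exceeded the period safety cap")
    return (~susceptible).sum(axis=1)


def simulate_sir(graph: nx.Graph, config: SIRConfig, seed_node) -> int:
    """Outbreak size M_i of one SIR epidemic seeded at ``seed_node``."""
    return int(simulate_sir_batch(graph, config, seed_node, n_runs=1)[0])


def simulate_sir_batch(
    graph: nx.Graph,
    config: SIRConfig,
    seed_node,
    n_runs: int,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Outbreak sizes of ``n_runs`` independent SIR epidemics from one seed."""
    arrays = _GraphArrays(graph)
    if seed_node not in arrays.index:
        raise ValueError(f"seed node {seed_node!r} is not in the graph")
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    return _sir_outbreaks(
        arrays, arrays.index[seed_node], config.beta, config.gamma, n_runs, rng
    )


def _sir_efficiency_matrix(
    graph: nx.Graph, config: SIRConfig
) -> tuple[list, np.ndarray]:
    """(nodes, M) with M[i, r] the outbreak size of node i in instance r.

    The RNG stream of node i is seeded with (rng_seed, i), so the sweep is
    reproducible and each node's trials are independent of the others'.
    """
    arrays = _GraphArrays(graph)
    outbreaks = np.empty((arrays.n, config.n_simulations), dtype=np.int64)
    for i in range(arrays.n):
        rng = np.random.default_rng([config.rng_seed, i])
        outbreaks[i] = _sir_outbreaks(
            arrays, i, config.beta, config.gamma, config.n_simulations, rng
        )
    return arrays.nodes, outbreaks


def sir_ground_truth(graph: nx.Graph, config: SIRConfig) -> GroundTruth:
    """Mean outbreak size M̄_i per node over n_simulations instances, ranked."""
    nodes, outbreaks = _sir_efficiency_matrix(graph, config)
    values = {v: float(m) for v, m in zip(nodes, outbreaks.mean(axis=1))}
    return GroundTruth(
        kind="sir_efficiency",
        values=values,
        ranking=rank_nodes(values, rng_seed=config.rng_seed),
        provenance={
            "config": config,
            "n_simulations": config.n_simulations,
            "rng_seed": config.rng_seed,
        },
    )


def default_p_grid(start: float = 1.0, stop: float = 3.0, step: float = 0.1):
    """The calibration grid p = 1, 1.1, 1.2, … used by both scans."""
    count = int(round((stop - start) / step)) + 1
    return [round(start + i * step, 10) for i in range(count)]


def calibrate_sir(
    graph: nx.Graph,
    base: SIRConfig,
    p_grid: Sequence[float] | None = None,
    top_fraction: float = 0.2,
    outbreak_fraction: float = 0.01,
) -> float:
    """Scan T = p·T^c ascending and return the first usable T* = p·T^c.

    A grid point passes when, in *every* simulation instance, the top 20%
    most effective nodes of that instance average an outbreak strictly larger
    than ``outbreak_fraction`` (1%) of the graph.
    """
    if p_grid is None:
        p_grid = default_p_grid()
    if not p_grid:
        raise ValueError("p_grid must be nonempty")
    t_critical = sir_threshold(degree_moments(graph))
    n = graph.number_of_nodes()
    k_top = max(1, math.ceil(top_fraction * n))
    last_p = None
    for p in p_grid:
        t = p * t_critical
        beta = t * base.gamma
        if beta > 1.0:
            break
        last_p = p
        config = replace(base, beta=beta)
        _, outbreaks = _sir_efficiency_matrix(graph, config)
        # Per instance: mean outbreak of that instance's own top-20% nodes.
        top = np.sort(outbreaks, axis=0)[-k_top:, :]
        if bool((top.mean(axis=0) > outbreak_fraction * n).all()):
            return t
    raise CalibrationError(
        f"no p on the grid satisfied the SIR outbreak criterion (last tried p={last_p})"
    )


def detect_equilibrium(
    density_trajectory: Sequence[float],
    policy: EquilibriumPolicy,
    n_nodes: int | None = None,
) -> tuple[bool, int | None]:
    """Apply the Δ(I) equilibrium protocol to a density trajectory.

    Waits for the first period t with Δ(I) = I(t+1) − I(t) ≥ 0, rests
    ``rest_periods``, then accumulates Δ(I); equilibrium is declared at the
    first period where the accumulated window spans at least
    ``window_periods`` and |mean Δ(I)| ≤ tolerance.  Returns
    ``(reached, start_period)`` with the period at which equilibrium was
    declared, or ``(False, None)``.
    """
    trajectory = list(density_trajectory)
    tolerance = policy.resolve_tolerance(n_nodes)
    first_rise = None
    for t in range(len(trajectory) - 1):
        if trajectory[t + 1] - trajectory[t] >= 0:
            first_rise = t
            break
    if first_rise is None:
        return False, None
    window_start = first_rise + policy.rest_periods
    for t in range(window_start + policy.window_periods, len(trajectory)):
        # Mean of Δ(I) over [window_start, t) telescopes to a difference.
        mean_delta = (trajectory[t] - trajectory[window_start]) / (t - window_start)
        if abs(mean_delta) <= tolerance:
            return True, t
    return False, None


def simulate_sis(
    graph: nx.Graph,
    config: SISConfig,
    rng: np.random.Generator | None = None,
) -> SISResult:
    """One SIS run: equilibrate, then measure per-node persistence.

    Starts from ⌈initial_infected_fraction·|N|⌉ uniformly drawn infected
    nodes and runs synchronous periods (infections with probability ν per
    infected–susceptible edge, then recoveries with probability δ; a node
    infected this period cannot recover this period).  Once the equilibrium
    protocol declares the stable state, ρ_v is measured as the fraction of
    the next ``measurement_periods`` periods node v is infected.

    Extinction (density hitting zero) satisfies the protocol with Δ(I) = 0,
    so an extinct run returns an all-zero, ``extinct``-flagged persistence.

    Raises
    ------
    NoEquilibriumError
        If ``max_periods`` elapse without equilibrium ("no equilibrium").
    """
    arrays = _GraphArrays(graph)
    n = arrays.n
    if n == 0:
        raise ValueError("cannot simulate an empty graph")
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    policy = config.equilibrium
    tolerance = policy.resolve_tolerance(n)

    infected = np.zeros(n, dtype=bool)
    n_init = min(n, math.ceil(config.initial_infected_fraction * n))
    infected[rng.choice(n, size=n_init, replace=False)] = True

    trajectory = [infected.mean()]
    first_rise: int | None = None
    equilibrium_start: int | None = None

    def step() -> None:
        nonlocal infected
        if infected.any():
            pressure = infected.astype(np.float32) @ arrays.adjacency
            p_infect = 1.0 - np.power(1.0 - config.nu, pressure, dtype=np.float64)
            newly = (rng.random(n) < p_infect) & ~infected
            recovers = rng.random(n) < config.delta
            infected = (infected & ~recovers) | newly
        trajectory.append(infected.mean())

    # Phase 1: equilibration under the online Δ(I) protocol.
    while equilibrium_start is None:
        if len(trajectory) - 1 >= policy.max_periods:
            raise NoEquilibriumError(
                f"no equilibrium within {policy.max_periods} periods"
            )
        step()
        t = len(trajectory) - 2  # period whose Δ(I) just became known
        if first_rise is None:
            if trajectory[t + 1] - trajectory[t] >= 0:
                first_rise = t
            continue
        window_start = first_rise + policy.rest_periods
        now = len(trajectory) - 1
        if now >= window_start + policy.window_periods:
            mean_delta = (trajectory[now] - trajectory[window_start]) / (
                now - window_start
            )
            if abs(mean_delta) <= tolerance:
                equilibrium_start = now

    # Phase 2: persistence measurement.
    counts = np.zeros(n, dtype=np.int64)
    for _ in range(config.measurement_periods):
        counts += infected
        step()

    persistence = {
        v: counts[i] / config.measurement_periods for i, v in enumerate(arrays.nodes)
    }
    return SISResult(
        persistence=persistence,
        density_trajectory=[float(x) for x in trajectory],
        equilibrium_reached=True,
        equilibrium_start=equilibrium_start,
        extinct=not infected.any() and counts.sum() == 0,
    )


def calibrate_sis(
    graph: nx.Graph,
    base: SISConfig,
    p_grid: Sequence[float] | None = None,
    n_runs: int = 10,
    density_fraction: float = 0.01,
) -> tuple[float, float]:
    """Scan λ = p·λ^c ascending; return (λ̂, λ*).

    λ̂ is the first grid point whose runs reach a non-zero-density long-run
    state (mean equilibrium density over ``n_runs`` independent runs > 0);
    λ* is the first grid point ≥ λ̂ whose mean equilibrium density is at
    least ``density_fraction`` (1%) of the graph.
    """
    if p_grid is None:
        p_grid = default_p_grid()
    if not p_grid:
        raise ValueError("p_grid must be nonempty")
    lambda_critical = sis_threshold(degree_moments(graph))
    lambda_hat = None
    for p in p_grid:
        lam = p * lambda_critical
        nu = lam * base.delta
        if nu > 1.0:
            break
        config = replace(base, nu=nu)
        densities = []
        for r in range(n_runs):
            rng = np.random.default_rng([config.rng_seed, r])
            densities.append(simulate_sis(graph, config, rng=rng).equilibrium_density)
        mean_density = float(np.mean(densities))
        if lambda_hat is None and mean_density > 0.0:
            lambda_hat = lam
        if lambda_hat is not None and mean_density >= density_fraction:
            return lambda_hat, lam
    raise CalibrationError(
        "grid exhausted before the SIS equilibrium-density criterion was met"
    )


def sis_ground_truth(graph: nx.Graph, config: SISConfig) -> GroundTruth:
    """Persistence ρ_i per node, averaged over n_simulations independent runs.

    Extinct runs contribute zeros; their count is reported in provenance.
    """
    arrays = _GraphArrays(graph)
    totals = np.zeros(arrays.n)
    n_extinct = 0
    for r in range(config.n_simulations):
        rng = np.random.default_rng([config.rng_seed, r])
        result = simulate_sis(graph, config, rng=rng)
        totals += [result.persistence[v] for v in arrays.nodes]
        n_extinct += int(result.extinct)
    values = {v: float(t / config.n_simulations) for v, t in zip(arrays.nodes, totals)}
    return GroundTruth(
        kind="sis_persistence",
        values=values,
        ranking=rank_nodes(values, rng_seed=config.rng_seed),
        provenance={
            "config": config,
            "n_simulations": config.n_simulations,
            "rng_seed": config.rng_seed,
            "n_extinct_runs": n_extinct,
        },
    )
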