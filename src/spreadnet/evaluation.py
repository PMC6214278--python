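"""Top-k evaluation statistics and the four-step experiment driver.

Given a ground-truth ranking of spreading efficiency (SIR mean outbreak size
or SIS persistence) and a candidate ranking built from centrality values —
computed either in a sample subgraph or in the full graph — four statistics
compare them on each top-k interval (1%…10% of the original graph's nodes):

imprecision ε(top-k) = 1 − M̄_C(top-k) / M̄_eff(top-k)
    One minus the ratio of the mean ground-truth efficiency of the
    candidate's top-k nodes to that of the true top-k.  Its SIS analogue,
    the persistence-distance δρ, replaces efficiencies by persistences.
OSim(top-k) = |A ∩ B| / k
    Fraction of shared nodes between the two top-k sets, order-ignored.
Kendall tau (top-k)
    Rank correlation between the candidate's ordering of its own top-k nodes
    and the ordering those same nodes have by their ground-truth values,
    regardless of where they sit in the full ground-truth ranking.
    Tie-adjusted (tau-b) by default because centrality scores tie heavily;
    the plain tau-a variant is selectable.

:func:`run_experiment` drives the full protocol: ground truth, repeated
sampling, sample-based and full-information rankings per centrality, and all
statistics per top-k, aggregated as mean ± sd over the samples.  Cells where
a sample discovered fewer than k nodes are recorded as missing and excluded
from the means, with the missing count reported.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .centrality import RankedList, betweenness, degree_centrality, k_core, rank_nodes
from .epidemic import (
    GroundTruth,
    SIRConfig,
    SISConfig,
    sir_ground_truth,
    sis_ground_truth,
)
from .sampling import SAMPLERS, SamplerConfig, sample_subgraph

__all__ = [
    "TopKSpec",
    "EvaluationReport",
    "imprecision",
    "persistence_distance",
    "osim",
    "kendall_top_k",
    "run_experiment",
    "DEFAULT_TOPK_FRACTIONS",
    "CENTRALITY_MEASURES",
]

DEFAULT_TOPK_FRACTIONS: tuple[float, ...] = tuple(
    round(0.01 * i, 2) for i in range(1, 11)
)

CENTRALITY_MEASURES: dict[str, Callable[[nx.Graph], dict]] = {
    "degree": degree_centrality,
    "kcore": k_core,
    "betweenness": betweenness,
}


@dataclass(frozen=True)
class TopKSpec:
    """A top-k interval as a fraction of the *original* graph's node count."""

    fraction: float
    population_size: int

    def __post_init__(self) -> None:
        if not 0.0 < self.fraction <= 1.0:
            raise ValueError("fraction must be in (0, 1]")
        if self.population_size < 1:
            raise ValueError("population_size must be positive")

    @property
    def k(self) -> int:
        # Nearest integer with a floor of 1.
        return max(1, int(math.floor(self.fraction * self.population_size + 0.5)))


def _mean_topk_value(ground_truth: GroundTruth, nodes: Iterable) -> float:
    values = ground_truth.values
    total = 0.0
    count = 0
    for node in nodes:
        if node not in values:
            raise KeyError(f"node {node!r} has no ground-truth value")
        total += values[node]
        count += 1
    return total / count


def _value_gap(ground_truth: GroundTruth, candidate: RankedList, spec: TopKSpec) -> float:
    k = spec.k
    if len(candidate) < k:
        raise ValueError(
            f"candidate ranking has {len(candidate)} nodes, fewer than top-k = {k}"
        )
    mean_candidate = _mean_topk_value(ground_truth, candidate.top(k))
    mean_eff = _mean_topk_value(ground_truth, ground_truth.ranking.top(k))
    if mean_eff == 0:
        raise ZeroDivisionError("ground-truth top-k mean is zero")
    gap = 1.0 - mean_candidate / mean_eff
    # The true top-k maximizes the k-mean, so gap >= 0 up to rounding noise.
    return 0.0 if -1e-9 < gap < 0.0 else gap


def imprecision(
    ground_truth: GroundTruth, candidate: RankedList, spec: TopKSpec
) -> float:
    """ε(top-k) = 1 − M̄_C(top-k) / M̄_eff(top-k), for SIR efficiencies."""
    if ground_truth.kind != "sir_efficiency":
        raise ValueError("imprecision is defined on SIR efficiency ground truth")
    return _value_gap(ground_truth, candidate, spec)


def persistence_distance(
    ground_truth: GroundTruth, candidate: RankedList, spec: TopKSpec
) -> float:
    """δρ(top-k) = 1 − ρ̄_C(top-k) / ρ̄_eff(top-k), for SIS persistences."""
    if ground_truth.kind != "sis_persistence":
        raise ValueError(
            "persistence_distance is defined on SIS persistence ground truth"
        )
    return _value_gap(ground_truth, candidate, spec)


def osim(top_k_a: Iterable, top_k_b: Iterable, k: int) -> float:
    """OSim = |A ∩ B| / k for two top-k node sets (symmetric, order-blind)."""
    set_a, set_b = set(top_k_a), set(top_k_b)
    if len(set_a) != k or len(set_b) != k:
        raise ValueError(
            f"osim requires two sets of size k={k}, got {len(set_a)} and {len(set_b)}"
        )
    return len(set_a & set_b) / k


def kendall_top_k(
    candidate: RankedList,
    ground_truth: GroundTruth,
    spec: TopKSpec,
    variant: str = "b",
) -> float:
    """Kendall rank correlation over the candidate's own top-k node set.

    List A is the candidate's top-k nodes in candidate order; list B is the
    same k nodes ordered by their ground-truth values (wherever they sit in
    the full ground-truth ranking).  ``variant="b"`` (default) is the
    tie-adjusted coefficient; ``variant="a"`` counts concordant minus
    discordant pairs over k(k−1)/2.
    """
    k = spec.k
    nodes = candidate.top(k)
    values = []
    for node in nodes:
        if node not in ground_truth.values:
            raise KeyError(f"node {node!r} has no ground-truth value")
        values.append(ground_truth.values[node])
    if k == 1:
        return 1.0
    candidate_rank = np.arange(k, 0, -1)  # best-first positions, descending
    if variant == "b":
        tau = stats.kendalltau(candidate_rank, values, variant="b").statistic
        return float(tau) if not math.isnan(tau) else 0.0
    if variant == "a":
        concordant = discordant = 0
        for (xi, yi), (xj, yj) in itertools.combinations(
            zip(candidate_rank, values), 2
        ):
            product = (xi - xj) * (yi - yj)
            concordant += product > 0
            discordant += product < 0
        return (concordant - discordant) / (k * (k - 1) / 2)
    raise ValueError("variant must be 'a' or 'b'")


def _tie_fraction(values: Sequence[float]) -> float:
    """Fraction of tied pairs among the ground-truth values of a top-k set."""
    if len(values) < 2:
        return 0.0
    _, counts = np.unique(np.asarray(values), return_counts=True)
    tied = sum(c * (c - 1) / 2 for c in counts)
    return float(tied / (len(values) * (len(values) - 1) / 2))


@dataclass
class EvaluationReport:
    """Tidy per-cell records plus mean ± sd aggregation over samples.

    ``records`` has one row per (source, sample, measure, top-k, statistic);
    sample cells whose ranking is shorter than k carry value NaN and
    missing=True.  ``summary`` aggregates the sample rows (mean, sd, counts)
    and keeps the full-information rows verbatim.
    """

    records: pd.DataFrame
    ground_truth_kind: str
    n_samples: int
    provenance: dict = field(default_factory=dict)

    @property
    def n_missing_cells(self) -> int:
        return int(self.records["missing"].sum())

    @property
    def summary(self) -> pd.DataFrame:
        grouped = (
            self.records.groupby(["source", "measure", "topk_fraction", "statistic"])
            .agg(
                mean=("value", "mean"),
                sd=("value", "std"),
                n=("value", "count"),
                n_missing=("missing", "sum"),
            )
            .reset_index()
        )
        return grouped


def _statistics_for(
    ground_truth: GroundTruth,
    candidate: RankedList,
    spec: TopKSpec,
    kendall_variant: str,
) -> dict[str, float]:
    gap_name = (
        "imprecision" if ground_truth.kind == "sir_efficiency" else "persistence_distance"
    )
    gap_fn = imprecision if ground_truth.kind == "sir_efficiency" else persistence_distance
    k = spec.k
    out = {
        gap_name: gap_fn(ground_truth, candidate, spec),
        "osim": osim(ground_truth.ranking.top(k), candidate.top(k), k),
        "kendall": kendall_top_k(candidate, ground_truth, spec, variant=kendall_variant),
        "kendall_tie_fraction": _tie_fraction(
            [ground_truth.values[v] for v in candidate.top(k)]
        ),
    }
    return out


def run_experiment(
    graph: nx.Graph,
    *,
    algorithm: str,
    sampler_config: SamplerConfig,
    epidemic_config: SIRConfig | SISConfig | None = None,
    ground_truth: GroundTruth | None = None,
    measures: Sequence[str] = ("degree", "kcore"),
    topk_fractions: Sequence[float] = DEFAULT_TOPK_FRACTIONS,
    n_samples: int = 100,
    rng_seed: int = 0,
    kendall_variant: str = "b",
) -> EvaluationReport:
    """Run the four-step evaluation protocol and collect all statistics.

    1. Ground truth: simulate the epidemic model on ``graph`` (or reuse a
       precomputed :class:`GroundTruth`).
    2. Samples-ranking: draw ``n_samples`` samples with ``algorithm``, compute
       each centrality in the sample subgraph structure and rank the
       discovered nodes.
    3. Graph-ranking (full information): rank all nodes by centrality in the
       original graph.
    4. Evaluation: imprecision/persistence-distance, OSim and Kendall tau per
       top-k, for both sources.
    """
    if (epidemic_config is None) == (ground_truth is None):
        raise ValueError("provide exactly one of epidemic_config / ground_truth")
    if ground_truth is None:
        if isinstance(epidemic_config, SIRConfig):
            ground_truth = sir_ground_truth(graph, epidemic_config)
        elif isinstance(epidemic_config, SISConfig):
            ground_truth = sis_ground_truth(graph, epidemic_config)
        else:
            raise TypeError("epidemic_config must be SIRConfig or SISConfig")
    unknown = set(measures) - CENTRALITY_MEASURES.keys()
    if unknown:
        raise ValueError(f"unknown centrality measures: {sorted(unknown)}")
    sampler = SAMPLERS[algorithm]

    n = graph.number_of_nodes()
    specs = [TopKSpec(fraction, n) for fraction in topk_fractions]
    rng = np.random.default_rng(rng_seed)
    rows: list[dict] = []

    def evaluate(source: str, sample_id, ranked: RankedList, measure: str) -> None:
        for spec in specs:
            base = {
                "source": source,
                "sample_id": sample_id,
                "measure": measure,
                "topk_fraction": spec.fraction,
                "k": spec.k,
            }
            if len(ranked) < spec.k:
                for stat in _stat_names:
                    rows.append(
                        {**base, "statistic": stat, "value": np.nan, "missing": True}
                    )
                continue
            for stat, value in _statistics_for(
                ground_truth, ranked, spec, kendall_variant
            ).items():
                rows.append(
                    {**base, "statistic": stat, "value": value, "missing": False}
                )

    gap_name = (
        "imprecision" if ground_truth.kind == "sir_efficiency" else "persistence_distance"
    )
    _stat_names = (gap_name, "osim", "kendall", "kendall_tie_fraction")

    # Step 2: samples-ranking.
    for sample_id in range(n_samples):
        config = replace(sampler_config, rng_seed=int(rng.integers(2**31)))
        subgraph = sample_subgraph(sampler(graph, config))
        for measure in measures:
            scores = CENTRALITY_MEASURES[measure](subgraph)
            ranked = rank_nodes(scores, rng_seed=int(rng.integers(2**31)))
            evaluate("sample", sample_id, ranked, measure)

    # Step 3: graph-ranking (full information case).
    for measure in measures:
        scores = CENTRALITY_MEASURES[measure](graph)
        ranked = rank_nodes(scores, rng_seed=int(rng.integers(2**31)))
        evaluate("graph", None, ranked, measure)

    records = pd.DataFrame(rows)
    return EvaluationReport(
        records=records,
        ground_truth_kind=ground_truth.kind,
        n_samples=n_samples,
        provenance={
            "algorithm": algorithm,
            "sampler_config": sampler_config,
            "rng_seed": rng_seed,
            "measures": tuple(measures),
            "ground_truth": ground_truth.provenance,
        },
    )
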