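"""Synthetic benchmark harness: networks, truths, correlation replicates, metrics.

The benchmark emulates the validation design used for curated pathway-map
networks: an original network consisting of a connected "pathway core" plus
"expansion" interactions, three interaction mechanisms split into two
classes, true activity drawn by the 90/10 rule (class-1 pathway and class-2
expansion interactions active with probability 0.9, the complementary
assignments with probability 0.1), and correlation replicates sampled in
Fisher-z space (active mean 0.7, inactive mean 0, n = 5 time points,
N = 5 replicates per truth).

The published pathway-map topologies are proprietary, so topology here is
generator-defined: growth by preferential attachment around a connected
core, with hubs — which is what gives the line graph its dense
neighborhoods.  Presets match the published network sizes; each preset also
records the published active/inactive split, which desk-scale evaluations
of the topology-free ML baseline use directly as class sample sizes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .baseline import ml_classify
from .em import EmConfig, run_em
from .network import (
    CorrelationData,
    Interaction,
    InteractionNetwork,
    StateVector,
    canonical_mechanism,
)

__all__ = [
    "SimConfig",
    "SimulationTruth",
    "RecoveryMetrics",
    "BenchmarkResult",
    "PRESETS",
    "PUBLISHED_CLASS_SIZES",
    "generate_network",
    "apply_90_10_rule",
    "simulate_correlations",
    "evaluate_recovery",
    "consensus_network",
    "ml_desk_benchmark",
    "run_benchmark",
]


@dataclass
class SimConfig:
    """Benchmark generator settings.

    ``class1`` mechanisms dominate the pathway core (they stay active under
    the 90/10 rule); the complementary ``class2`` dominates the expansion
    region.  ``mix`` is the fraction of interactions in each region labeled
    with the *other* region's class — real pathway regions are largely, but
    not entirely, of one class.
    """

    n_interactions: int
    n_pathway: int
    mechanisms: tuple[str, ...] = ("M", "TR", "B")
    class1: tuple[str, ...] = ("M", "TR")
    p_keep: float = 0.9
    mean_active: float = 0.7
    mean_inactive: float = 0.0
    n_timepoints: int = 5
    n_sims: int = 5
    topology: str = "hub_attach"  # hub_attach | provided
    mix: float = 0.2
    new_node_prob: float = 0.6
    bridge_prob: float = 0.15
    minority_embed: float = 0.5
    mech_coherence: float = 0.85
    seed: int = 0

    def __post_init__(self) -> None:
        self.mechanisms = tuple(canonical_mechanism(m) for m in self.mechanisms)
        self.class1 = tuple(canonical_mechanism(m) for m in self.class1)
        if not set(self.class1) < set(self.mechanisms):
            raise ValueError("class1 must be a proper subset of mechanisms")
        if not 0.0 < self.p_keep < 1.0:
            raise ValueError("p_keep must be in (0, 1)")
        if not 1 <= self.n_pathway <= self.n_interactions:
            raise ValueError("need 1 <= n_pathway <= n_interactions")
        if self.n_timepoints < 4:
            raise ValueError("n_timepoints must be >= 4")

    @property
    def class2(self) -> tuple[str, ...]:
        return tuple(m for m in self.mechanisms if m not in self.class1)


#: Presets sized like the three published benchmark networks.
PRESETS: dict[str, SimConfig] = {
    "vegf": SimConfig(
        n_interactions=1065, n_pathway=426,
        mechanisms=("M", "TR", "B"), class1=("M", "TR"),
    ),
    "cell_adhesion": SimConfig(
        n_interactions=344, n_pathway=138,
        mechanisms=("+P", "-P", "TR"), class1=("+P", "-P"),
    ),
    "blood_coag": SimConfig(
        n_interactions=94, n_pathway=38,
        mechanisms=("C", "B", "+P"), class1=("C", "B"),
    ),
}

#: Published (active, inactive) interaction counts of the real benchmark
#: networks; used as class sample sizes for topology-free evaluations.
PUBLISHED_CLASS_SIZES: dict[str, tuple[int, int]] = {
    "vegf": (635, 430),
    "cell_adhesion": (200, 144),
    "blood_coag": (71, 23),
}


@dataclass
class SimulationTruth:
    """A generated original network with its true active set I*."""

    network: InteractionNetwork
    pathway_ids: frozenset[str]
    true_active: frozenset[str]
    rule: str = "90/10"

    def __post_init__(self) -> None:
        ids = set(self.network.interactions)
        if not self.pathway_ids <= ids or not self.true_active <= ids:
            raise ValueError("pathway/active ids must be network interaction ids")


def _segment_plan(
    config: SimConfig,
) -> list[tuple[str, tuple[str, ...], int, bool]]:
    """Four contiguous growth segments: each region is a majority-class patch
    plus an embedded minority-class patch holding exactly the ``mix``
    fraction (region, class pool, edge count, is_minority)."""
    n_exp = config.n_interactions - config.n_pathway
    minor_p = int(round(config.mix * config.n_pathway))
    minor_e = int(round(config.mix * n_exp))
    segments = [
        ("pathway", config.class1, config.n_pathway - minor_p, False),
        ("pathway", config.class2, minor_p, True),
        ("expansion", config.class2, n_exp - minor_e, False),
        ("expansion", config.class1, minor_e, True),
    ]
    return [s for s in segments if s[2] > 0]


def generate_network(
    config: SimConfig, seed: int | None = None
) -> tuple[InteractionNetwork, frozenset[str]]:
    """Grow a connected network of ``n_interactions`` edges with hub structure.

    Growth proceeds in four contiguous segments (see ``_segment_plan``): the
    pathway core's class-1 majority, an embedded class-2 minority patch of
    exactly the ``mix`` fraction, then the expansion region's class-2
    majority and its class-1 minority patch.  Edges anchor preferentially
    to high-degree nodes of their own segment; majority segments bridge to
    the wider network with probability ``bridge_prob``, and minority
    patches anchor into their own region with probability
    ``minority_embed`` (an off-class patch — say a binding complex inside a
    signaling map — neighbors the surrounding majority edges).  Those
    boundaries are where cross-class neighbor pairs arise; within segments,
    same-class pairs dominate, which is what makes the result "M-M-pair
    rich" once the 90/10 rule correlates state with region and class.

    Mechanism labels are *node-coherent*: every node carries a label from
    its segment's class, and an edge inherits its anchor node's label with
    probability ``mech_coherence``.  This reproduces the one-to-many
    structure of real maps (a transcription-factor hub whose edges are all
    TR, a microRNA hub whose edges are all M, a complex whose edges are all
    B) and makes mechanism-pair couplings informative.  Deterministic given
    the seed.
    """
    if config.topology != "hub_attach":
        raise ValueError(f"generate_network handles topology='hub_attach', got {config.topology!r}")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    nodes: list[str] = []
    degree: list[int] = []
    node_label: list[str] = []

    region_pools: dict[str, list[int]] = {"pathway": [], "expansion": []}

    def new_node(seg_pool: list[int], class_pool: tuple[str, ...], region: str) -> int:
        nodes.append(f"n{len(nodes)}")
        degree.append(0)
        node_label.append(class_pool[rng.integers(len(class_pool))])
        seg_pool.append(len(nodes) - 1)
        region_pools[region].append(len(nodes) - 1)
        return len(nodes) - 1

    def weighted_pick(pool: list[int], exclude: int | None = None) -> int:
        w = np.array([degree[i] + 1.0 for i in pool], dtype=float)
        if exclude is not None and exclude in pool:
            w[pool.index(exclude)] = 0.0
        if w.sum() <= 0:
            w[:] = 1.0
        return int(pool[rng.choice(len(pool), p=w / w.sum())])

    interactions: list[Interaction] = []
    ids_seen: set[str] = set()
    pathway_ids: set[str] = set()
    for region, class_pool, n_edges, is_minor in _segment_plan(config):
        seg_nodes: list[int] = []
        for _k in range(n_edges):
            for _attempt in range(20):
                if not nodes:
                    a = new_node(seg_nodes, class_pool, region)
                    b = new_node(seg_nodes, class_pool, region)
                else:
                    # anchor inside the segment; minority patches embed into
                    # their region (a complex inside a signaling map neighbors
                    # the signaling edges), majority segments occasionally
                    # bridge to the wider network — both produce the region
                    # boundaries where cross-class neighbor pairs arise
                    pool = seg_nodes
                    if is_minor:
                        if not pool or rng.random() < config.minority_embed:
                            pool = region_pools[region] or list(range(len(nodes)))
                    elif not pool or rng.random() < config.bridge_prob:
                        pool = list(range(len(nodes)))
                    a = weighted_pick(pool)
                    if rng.random() < config.new_node_prob or len(nodes) < 2:
                        b = new_node(seg_nodes, class_pool, region)
                    else:
                        b_pool = seg_nodes or list(range(len(nodes)))
                        if len([i for i in b_pool if i != a]) == 0:
                            b = new_node(seg_nodes, class_pool, region)
                        else:
                            b = weighted_pick(b_pool, exclude=a)
                if node_label[a] in class_pool and rng.random() < config.mech_coherence:
                    mech = node_label[a]  # hub-coherent labeling
                else:
                    mech = class_pool[rng.integers(len(class_pool))]
                iid = f"{nodes[a]}|{mech}|{nodes[b]}"
                if iid not in ids_seen and f"{nodes[b]}|{mech}|{nodes[a]}" not in ids_seen:
                    break
            else:
                a = weighted_pick(seg_nodes or list(range(len(nodes))))
                b = new_node(seg_nodes, class_pool, region)
                mech = class_pool[rng.integers(len(class_pool))]
                iid = f"{nodes[a]}|{mech}|{nodes[b]}"
            ids_seen.add(iid)
            degree[a] += 1
            degree[b] += 1
            interactions.append(Interaction(iid, nodes[a], nodes[b], mech))
            if region == "pathway":
                pathway_ids.add(iid)
    return InteractionNetwork(interactions), frozenset(pathway_ids)


def apply_90_10_rule(
    net: InteractionNetwork,
    pathway_ids: Iterable[str],
    class1: Sequence[str],
    class2: Sequence[str],
    p_keep: float = 0.9,
    seed: int = 0,
) -> SimulationTruth:
    """Draw the true active set I*.

    Pathway interactions of class 1 (and expansion interactions of class 2)
    are active with probability ``p_keep``; the complementary assignments
    with probability ``1 - p_keep``.
    """
    pathway = frozenset(pathway_ids)
    class1 = {canonical_mechanism(m) for m in class1}
    class2 = {canonical_mechanism(m) for m in class2}
    rng = np.random.default_rng(seed)
    active: set[str] = set()
    for iid, ia in net.interactions.items():
        favored = (iid in pathway and ia.mechanism in class1) or (
            iid not in pathway and ia.mechanism in class2
        )
        prob = p_keep if favored else 1.0 - p_keep
        if rng.random() < prob:
            active.add(iid)
    label = "90/10" if abs(p_keep - 0.9) < 1e-12 else f"{p_keep:.0%}/{1 - p_keep:.0%}"
    return SimulationTruth(
        network=net,
        pathway_ids=pathway,
        true_active=frozenset(active),
        rule=label,
    )


def simulate_correlations(
    truth: SimulationTruth,
    mean_active: float = 0.7,
    mean_inactive: float = 0.0,
    n_timepoints: int = 5,
    seed: int = 0,
) -> CorrelationData:
    """One correlation replicate sampled in Fisher-z space.

    Each interaction draws ``z ~ Normal(artanh(mean), 1/sqrt(n-3))`` with
    the mean chosen by its true state, then ``r = tanh(z)``.
    """
    if n_timepoints < 4:
        raise ValueError("n_timepoints must be >= 4")
    rng = np.random.default_rng(seed)
    se = 1.0 / math.sqrt(n_timepoints - 3)
    values: dict[str, float] = {}
    ids = list(truth.network.interactions)
    means = np.where(
        [i in truth.true_active for i in ids],
        np.arctanh(mean_active),
        np.arctanh(mean_inactive),
    )
    z = rng.normal(loc=means, scale=se)
    r = np.tanh(z)
    for i, v in zip(ids, r):
        values[i] = float(v)
    return CorrelationData(values=values, n=n_timepoints)


@dataclass
class RecoveryMetrics:
    """Confusion counts and the derived percentages (0-100 scale)."""

    tp: int
    fp: int
    tn: int
    fn: int

    @classmethod
    def from_prediction(
        cls, predicted: StateVector, true_active: Iterable[str]
    ) -> "RecoveryMetrics":
        truth = set(true_active)
        tp = fp = tn = fn = 0
        for i, s in predicted.states.items():
            if i in truth:
                tp += s
                fn += 1 - s
            else:
                fp += s
                tn += 1 - s
        return cls(tp=tp, fp=fp, tn=tn, fn=fn)

    @property
    def sensitivity(self) -> float:
        d = self.tp + self.fn
        return 100.0 * self.tp / d if d else float("nan")

    @property
    def specificity(self) -> float:
        d = self.tn + self.fp
        return 100.0 * self.tn / d if d else float("nan")

    @property
    def percent_correct(self) -> float:
        total = self.tp + self.fp + self.tn + self.fn
        return 100.0 * (self.tp + self.tn) / total if total else float("nan")


def evaluate_recovery(predicted: StateVector, truth: SimulationTruth) -> RecoveryMetrics:
    """Confusion of a predicted state vector against the true active set."""
    if set(predicted.states) != set(truth.network.interactions):
        raise ValueError("prediction does not cover the network's interactions")
    return RecoveryMetrics.from_prediction(predicted, truth.true_active)


def consensus_network(
    results: Sequence[StateVector], threshold: float = 0.8
) -> set[str]:
    """Interactions active in at least ``ceil(threshold * N)`` of N results
    (at least one), e.g. 4 of 5 replicates at the default threshold."""
    if not results:
        raise ValueError("need at least one state vector")
    ids = set(results[0].states)
    for sv in results[1:]:
        if set(sv.states) != ids:
            raise ValueError("state vectors cover different interaction sets")
    need = max(1, math.ceil(threshold * len(results)))
    counts: dict[str, int] = {i: 0 for i in ids}
    for sv in results:
        for i in sv.active_set():
            counts[i] += 1
    return {i for i, c in counts.items() if c >= need}


def ml_desk_benchmark(
    n_active: int,
    n_inactive: int,
    n_replicates: int = 5,
    r_alpha: float = 0.7,
    mean_active: float = 0.7,
    mean_inactive: float = 0.0,
    n_timepoints: int = 5,
    seed: int = 0,
) -> list[RecoveryMetrics]:
    """Topology-free evaluation of the ML baseline at fixed class sizes.

    The baseline classifies each edge independently, so its recovery
    metrics depend only on the noise model and the number of truly active
    and inactive edges — not on any network topology.  Draw ``n_active``
    correlations around ``mean_active`` and ``n_inactive`` around
    ``mean_inactive`` in Fisher-z space (standard error
    ``1/sqrt(n_timepoints - 3)``), classify, and repeat over seeded
    replicates.
    """
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_replicates)]
    se = 1.0 / math.sqrt(n_timepoints - 3)
    out: list[RecoveryMetrics] = []
    active_ids = [f"a{k}" for k in range(n_active)]
    inactive_ids = [f"i{k}" for k in range(n_inactive)]
    for rep_seed in seeds:
        rng = np.random.default_rng(rep_seed)
        values = {}
        for iid in active_ids:
            values[iid] = float(np.tanh(rng.normal(np.arctanh(mean_active), se)))
        for iid in inactive_ids:
            values[iid] = float(np.tanh(rng.normal(np.arctanh(mean_inactive), se)))
        corr = CorrelationData(values=values, n=n_timepoints)
        predicted = ml_classify(corr, r_alpha=r_alpha)
        out.append(RecoveryMetrics.from_prediction(predicted, set(active_ids)))
    return out


@dataclass
class BenchmarkResult:
    """Per-method recovery metrics over replicates, plus exclusions."""

    truth: SimulationTruth
    metrics: dict[str, list[RecoveryMetrics]]
    excluded: dict[str, int]
    states: dict[str, list[StateVector]]

    def summary(self) -> pd.DataFrame:
        rows = []
        for method, ms in self.metrics.items():
            def agg(attr: str) -> tuple[float, float]:
                vals = np.array([getattr(m, attr) for m in ms], dtype=float)
                sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
                return float(np.mean(vals)), sd

            sens = agg("sensitivity")
            spec = agg("specificity")
            pc = agg("percent_correct")
            rows.append(
                {
                    "method": method,
                    "n_replicates": len(ms),
                    "n_excluded": self.excluded.get(method, 0),
                    "sensitivity_mean": sens[0],
                    "sensitivity_sd": sens[1],
                    "specificity_mean": spec[0],
                    "specificity_sd": spec[1],
                    "percent_correct_mean": pc[0],
                    "percent_correct_sd": pc[1],
                }
            )
        return pd.DataFrame(rows)


def run_benchmark(
    sim_config: SimConfig,
    methods: Sequence[str] = ("full", "single", "ml"),
    em_config: EmConfig | None = None,
    ml_r_alpha: float | None = None,
    network: InteractionNetwork | None = None,
    pathway_ids: Iterable[str] | None = None,
) -> BenchmarkResult:
    """One truth, ``n_sims`` correlation replicates, each method per replicate.

    EM replicates that hit runaway reinforcement or fail to converge are
    excluded from the summary (the exclusion count is reported).  The ML
    baseline's r_alpha defaults to the generative active mean.  With
    ``topology='provided'`` pass the network and pathway partition
    explicitly.  Deterministic given ``sim_config.seed``.
    """
    unknown = set(methods) - {"full", "single", "ml"}
    if unknown:
        raise ValueError(f"unknown methods: {sorted(unknown)}")
    ss = np.random.SeedSequence(sim_config.seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2 + sim_config.n_sims)]
    if sim_config.topology == "provided":
        if network is None or pathway_ids is None:
            raise ValueError("topology='provided' requires network and pathway_ids")
        net, pathway = network, frozenset(pathway_ids)
    else:
        net, pathway = generate_network(sim_config, seed=seeds[0])
    truth = apply_90_10_rule(
        net, pathway, sim_config.class1, sim_config.class2,
        p_keep=sim_config.p_keep, seed=seeds[1],
    )
    base_em = em_config if em_config is not None else EmConfig()
    metrics: dict[str, list[RecoveryMetrics]] = {m: [] for m in methods}
    states: dict[str, list[StateVector]] = {m: [] for m in methods}
    excluded: dict[str, int] = {m: 0 for m in methods}
    for k in range(sim_config.n_sims):
        corr = simulate_correlations(
            truth,
            mean_active=sim_config.mean_active,
            mean_inactive=sim_config.mean_inactive,
            n_timepoints=sim_config.n_timepoints,
            seed=seeds[2 + k],
        )
        for method in methods:
            if method == "ml":
                predicted = ml_classify(
                    corr,
                    r_alpha=ml_r_alpha if ml_r_alpha is not None else sim_config.mean_active,
                )
            else:
                result = run_em(net, corr, replace(base_em, model=method))
                if result.runaway or not result.converged:
                    excluded[method] += 1
                    continue
                predicted = result.states
            metrics[method].append(evaluate_recovery(predicted, truth))
            states[method].append(predicted)
    empty = [m for m in methods if not metrics[m]]
    if empty:
        raise RuntimeError(
            f"all replicates excluded for method(s) {empty} "
            f"(runaway reinforcement or non-convergence)"
        )
    return BenchmarkResult(truth=truth, metrics=metrics, excluded=excluded, states=states)
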