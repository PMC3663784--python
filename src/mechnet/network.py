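"""Mechanism-annotated interaction networks and per-edge correlation scores.

The model in this package is *edge-centric*: the unit of inference is the
interaction (edge) of a molecular network, not the node.  Every interaction
carries a mechanism annotation from a 10-code controlled vocabulary
(binding, cleavage, phosphorylation, transcription regulation, microRNA
binding, ...), and two interactions are "neighbors" when they share a node
— i.e. downstream inference runs on the line graph of the physical network.

This module provides the domain types, readers/writers for the plain-text
exchange formats (SIF edge lists, edge-attribute tables, correlation and
expression TSVs), and the two data-preparation procedures that turn
expression or per-time-point significance data into per-interaction
correlation scores.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MECHANISMS",
    "UnknownMechanismError",
    "NetworkFormatError",
    "canonical_mechanism",
    "Interaction",
    "InteractionNetwork",
    "CorrelationData",
    "ExpressionMatrix",
    "StateVector",
    "read_network",
    "write_network",
    "interaction_neighbors",
    "read_correlation_table",
    "correlations_for_network",
    "read_expression_matrix",
    "edge_correlations",
    "aggregate_edge_correlation",
    "AggregationResult",
    "artificial_correlation_score",
]

#: The 10-code interaction-mechanism vocabulary (binding, cleavage, covalent
#: modification, phosphorylation, dephosphorylation, transformation,
#: transport, catalysis, transcription regulation, microRNA binding).
MECHANISMS: tuple[str, ...] = ("B", "C", "CM", "+P", "-P", "T", "Tn", "Z", "TR", "M")

# "Tr" appears in the wild as an alternate spelling of "TR"; the Unicode
# minus shows up in dephosphorylation codes copied from rich text.
_ALIASES: dict[str, str] = {m: m for m in MECHANISMS}
_ALIASES["Tr"] = "TR"


class UnknownMechanismError(ValueError):
    """A mechanism code outside the controlled vocabulary."""


class NetworkFormatError(ValueError):
    """Malformed SIF / attribute / correlation input."""


def canonical_mechanism(code: str) -> str:
    """Validate ``code`` against the mechanism vocabulary and canonicalize it.

    Accepts the alternate spelling ``Tr`` for transcription regulation and a
    Unicode minus in ``-P``; anything else outside the vocabulary raises
    :class:`UnknownMechanismError`.
    """
    cleaned = code.strip().replace("−", "-")
    try:
        return _ALIASES[cleaned]
    except KeyError:
        raise UnknownMechanismError(
            f"unknown mechanism code {code!r}; expected one of {MECHANISMS}"
        ) from None


@dataclass(frozen=True)
class Interaction:
    """A directed, mechanism-annotated interaction between two nodes."""

    id: str
    source: str
    target: str
    mechanism: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "mechanism", canonical_mechanism(self.mechanism))

    @property
    def endpoints(self) -> frozenset[str]:
        return frozenset((self.source, self.target))


def _default_id(source: str, mechanism: str, target: str) -> str:
    # Canonical edge identity: (source, mechanism, target), direction kept.
    return f"{source}|{canonical_mechanism(mechanism)}|{target}"


class InteractionNetwork:
    """A network of mechanism-annotated interactions with a line-graph view.

    Parameters
    ----------
    interactions
        Interactions with unique ids.  Parallel edges between the same node
        pair are allowed when their mechanisms differ; they are neighbors of
        each other (they share both endpoints).
    extra_nodes
        Isolated nodes not touched by any interaction.
    """

    def __init__(
        self,
        interactions: Iterable[Interaction],
        extra_nodes: Iterable[str] = (),
    ) -> None:
        self.interactions: dict[str, Interaction] = {}
        for ia in interactions:
            if ia.id in self.interactions:
                prev = self.interactions[ia.id]
                if prev != ia:
                    raise NetworkFormatError(
                        f"duplicate interaction id {ia.id!r} with conflicting records"
                    )
                continue
            self.interactions[ia.id] = ia
        self.nodes: set[str] = set(extra_nodes)
        incident: dict[str, set[str]] = {}
        for ia in self.interactions.values():
            self.nodes.add(ia.source)
            self.nodes.add(ia.target)
            incident.setdefault(ia.source, set()).add(ia.id)
            incident.setdefault(ia.target, set()).add(ia.id)
        # Two interactions are adjacent iff they share >= 1 node; never self.
        adjacency: dict[str, set[str]] = {i: set() for i in self.interactions}
        for members in incident.values():
            for i in members:
                adjacency[i].update(members)
        for i in adjacency:
            adjacency[i].discard(i)
        self.adjacency: dict[str, frozenset[str]] = {
            i: frozenset(nbrs) for i, nbrs in adjacency.items()
        }

    def __len__(self) -> int:
        return len(self.interactions)

    def __contains__(self, interaction_id: str) -> bool:
        return interaction_id in self.interactions

    @property
    def interaction_ids(self) -> list[str]:
        return list(self.interactions)

    def neighbors(self, interaction_id: str) -> frozenset[str]:
        if interaction_id not in self.adjacency:
            raise KeyError(f"unknown interaction id {interaction_id!r}")
        return self.adjacency[interaction_id]

    @property
    def mechanisms_present(self) -> tuple[str, ...]:
        return tuple(sorted({ia.mechanism for ia in self.interactions.values()}))


def interaction_neighbors(net: InteractionNetwork, interaction_id: str) -> frozenset[str]:
    """All interactions sharing a node with ``interaction_id`` (excluding itself)."""
    return net.neighbors(interaction_id)


@dataclass
class CorrelationData:
    """Per-interaction sample correlations with a common sample size.

    ``n`` is the number of paired observations behind each correlation; it
    must be at least 4 so the Fisher standard error ``1/sqrt(n-3)`` exists.
    ``missing`` lists interactions for which no correlation could be computed
    (e.g. a constant expression profile); they carry no value and downstream
    consumers exclude them with a warning.
    """

    values: dict[str, float]
    n: int
    missing: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.n < 4:
            raise ValueError(f"sample size n must be >= 4, got {self.n}")
        bad = {k: v for k, v in self.values.items() if not -1.0 <= v <= 1.0}
        if bad:
            raise ValueError(f"correlations outside [-1, 1]: {bad}")

    def require_network(self, net: InteractionNetwork) -> None:
        """Raise unless every network interaction has a value (or is flagged missing)."""
        gaps = [i for i in net.interactions if i not in self.values and i not in self.missing]
        if gaps:
            raise NetworkFormatError(
                f"no correlation for {len(gaps)} interaction(s): {sorted(gaps)[:10]}"
            )


@dataclass
class StateVector:
    """Binary activity assignment (1 = active) for every interaction."""

    states: dict[str, int]

    def __post_init__(self) -> None:
        bad = {k: v for k, v in self.states.items() if v not in (0, 1)}
        if bad:
            raise ValueError(f"states must be 0/1: {bad}")

    def active_set(self) -> set[str]:
        return {i for i, s in self.states.items() if s == 1}

    def __getitem__(self, interaction_id: str) -> int:
        return self.states[interaction_id]

    def __len__(self) -> int:
        return len(self.states)


@dataclass
class ExpressionMatrix:
    """Expression values for measured units (probes) over time points.

    ``data`` rows are measured units, columns are samples/time points.
    ``probe_map`` sends a measured unit to its gene id; ``object_map`` sends
    a network node id to the set of gene ids it represents.  Both maps may be
    many-to-many, which is resolved by :func:`aggregate_edge_correlation`.
    """

    data: pd.DataFrame
    probe_map: dict[str, str]
    object_map: dict[str, set[str]]

    def __post_init__(self) -> None:
        if self.data.columns.duplicated().any():
            raise ValueError("expression matrix has duplicated column labels")

    def probes_for_gene(self, gene: str) -> list[str]:
        return [p for p, g in self.probe_map.items() if g == gene and p in self.data.index]

    def genes_for_node(self, node: str) -> set[str]:
        return set(self.object_map.get(node, set()))


# ---------------------------------------------------------------------------
# SIF + edge-attribute I/O


def _parse_sif(path: str | Path) -> tuple[list[tuple[str, str, str]], set[str]]:
    edges: list[tuple[str, str, str]] = []
    isolated: set[str] = set()
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        tokens = raw.split()
        if not tokens:
            continue
        if len(tokens) == 1:
            isolated.add(tokens[0])
        elif len(tokens) == 3:
            edges.append((tokens[0], tokens[1], tokens[2]))
        else:
            raise NetworkFormatError(
                f"{path}:{lineno}: expected 'source relation target' (3 tokens) "
                f"or a single isolated-node token, got {len(tokens)}: {raw!r}"
            )
    return edges, isolated


def _parse_eda(path: str | Path) -> dict[tuple[str, str], str]:
    """Cytoscape .eda edge-attribute dialect: ``source (relation) target = VALUE``."""
    attrs: dict[tuple[str, str], str] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or "=" not in line:
            continue
        key, _, value = line.rpartition("=")
        left = key.strip()
        # "A (rel) B" -> A, B; the relation token is not part of edge identity
        if "(" not in left or ")" not in left:
            if lineno == 1:  # header line such as "Mechanism (class=String)"
                continue
            raise NetworkFormatError(f"{path}:{lineno}: not an .eda edge key: {raw!r}")
        src = left[: left.index("(")].strip()
        tgt = left[left.rindex(")") + 1 :].strip()
        mech = canonical_mechanism(value)
        prev = attrs.get((src, tgt))
        if prev is not None and prev != mech:
            raise NetworkFormatError(
                f"{path}:{lineno}: conflicting mechanisms for edge {src}->{tgt}: "
                f"{prev!r} vs {mech!r}"
            )
        attrs[(src, tgt)] = mech
    return attrs


def _parse_attr_table(path: str | Path) -> dict[tuple[str, str], list[str]]:
    """Tab-separated attribute table; duplicate (source, target) rows with
    distinct mechanisms denote parallel edges."""
    table = pd.read_csv(path, sep="\t", dtype=str)
    cols = {c.lower(): c for c in table.columns}
    try:
        s, t, m = cols["source"], cols["target"], cols["mechanism"]
    except KeyError:
        raise NetworkFormatError(
            f"{path}: attribute table needs columns (source, target, mechanism); "
            f"got {list(table.columns)}"
        ) from None
    attrs: dict[tuple[str, str], list[str]] = {}
    for _, row in table.iterrows():
        key = (row[s], row[t])
        mech = canonical_mechanism(row[m])
        attrs.setdefault(key, [])
        if mech not in attrs[key]:
            attrs[key].append(mech)
    return attrs


def read_network(sif_path: str | Path, mechanism_attr_path: str | Path) -> InteractionNetwork:
    """Read a SIF edge list plus a mechanism attribute table.

    The attribute file is either a tab-separated table with header columns
    ``source, target, mechanism`` or the Cytoscape ``.eda`` dialect
    (``source (relation) target = VALUE``, detected by extension or content).
    Every SIF edge must be annotated; unannotated edges raise an error that
    names the offending edge keys.
    """
    edges, isolated = _parse_sif(sif_path)
    attr_path = Path(mechanism_attr_path)
    text_head = attr_path.read_text().lstrip().splitlines()
    is_eda = attr_path.suffix == ".eda" or (
        bool(text_head) and "=" in text_head[min(1, len(text_head) - 1)] and "\t" not in text_head[0]
    )
    if is_eda:
        attrs = {key: [mech] for key, mech in _parse_eda(attr_path).items()}
    else:
        attrs = _parse_attr_table(attr_path)
    interactions: list[Interaction] = []
    unannotated: list[str] = []
    for src, rel, tgt in edges:
        mechs = attrs.get((src, tgt))
        if mechs is None:
            unannotated.append(f"{src}->{tgt}")
            continue
        if len(mechs) == 1:
            mech = mechs[0]
        else:
            # parallel edges: the SIF relation token must disambiguate
            try:
                rel_mech = canonical_mechanism(rel)
            except UnknownMechanismError:
                rel_mech = None
            if rel_mech in mechs:
                mech = rel_mech
            else:
                raise NetworkFormatError(
                    f"conflicting mechanisms {mechs} for edge {src}->{tgt} and the "
                    f"SIF relation {rel!r} does not disambiguate them"
                )
        interactions.append(Interaction(_default_id(src, mech, tgt), src, tgt, mech))
    if unannotated:
        raise NetworkFormatError(
            f"{len(unannotated)} SIF edge(s) missing from the mechanism attribute "
            f"file: {sorted(set(unannotated))}"
        )
    return InteractionNetwork(interactions, extra_nodes=isolated)


def write_network(
    net: InteractionNetwork, sif_path: str | Path, mechanism_attr_path: str | Path
) -> None:
    """Write a network back to SIF + mechanism attribute TSV (round-trippable)."""
    sif_lines = [
        f"{ia.source}\t{ia.mechanism}\t{ia.target}" for ia in net.interactions.values()
    ]
    touched = {n for ia in net.interactions.values() for n in (ia.source, ia.target)}
    sif_lines += sorted(net.nodes - touched)
    Path(sif_path).write_text("\n".join(sif_lines) + "\n")
    attr = pd.DataFrame(
        [(ia.source, ia.target, ia.mechanism) for ia in net.interactions.values()],
        columns=["source", "target", "mechanism"],
    )
    attr.to_csv(mechanism_attr_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Correlation and expression input


def read_correlation_table(path: str | Path) -> pd.DataFrame:
    """Read a TSV with columns (source, target, r)."""
    table = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in table.columns}
    if not {"source", "target", "r"} <= set(cols):
        raise NetworkFormatError(
            f"{path}: correlation table needs columns (source, target, r)"
        )
    return table.rename(columns={cols["source"]: "source", cols["target"]: "target", cols["r"]: "r"})


def correlations_for_network(
    table: pd.DataFrame, net: InteractionNetwork, n: int
) -> CorrelationData:
    """Match a (source, target, r) table to the network's interactions.

    Parallel interactions between the same node pair share the table row's
    value.  Every interaction must be covered.
    """
    lookup = {(row.source, row.target): float(row.r) for row in table.itertuples()}
    values: dict[str, float] = {}
    for ia in net.interactions.values():
        r = lookup.get((ia.source, ia.target))
        if r is None:
            raise NetworkFormatError(
                f"no correlation row for interaction {ia.id!r} ({ia.source}->{ia.target})"
            )
        values[ia.id] = r
    return CorrelationData(values=values, n=n)


def read_expression_matrix(
    expr_path: str | Path,
    probe_map_path: str | Path | None = None,
    object_map_path: str | Path | None = None,
) -> ExpressionMatrix:
    """Read an expression TSV (first column = row id) plus optional 2-column maps.

    Without a probe map, measured units are taken to be gene ids; without an
    object map, node ids are taken to be gene ids.
    """
    data = pd.read_csv(expr_path, sep="\t", index_col=0)
    if probe_map_path is not None:
        pm_table = pd.read_csv(probe_map_path, sep="\t", dtype=str)
        probe_map = dict(zip(pm_table.iloc[:, 0], pm_table.iloc[:, 1]))
    else:
        probe_map = {str(p): str(p) for p in data.index}
    if object_map_path is not None:
        om_table = pd.read_csv(object_map_path, sep="\t", dtype=str)
        object_map: dict[str, set[str]] = {}
        for node, gene in zip(om_table.iloc[:, 0], om_table.iloc[:, 1]):
            object_map.setdefault(node, set()).add(gene)
    else:
        object_map = {g: {g} for g in set(probe_map.values())}
    return ExpressionMatrix(data=data, probe_map=probe_map, object_map=object_map)


@dataclass
class AggregationResult:
    """Representative expression row per gene plus pairwise edge aggregation."""

    representatives: dict[str, str]
    corr_matrix: pd.DataFrame

    def edge_value(self, genes_a: Iterable[str], genes_b: Iterable[str]) -> float:
        """Mean correlation over all gene pairs across an interaction."""
        pairs = [
            (self.representatives[ga], self.representatives[gb])
            for ga in genes_a
            for gb in genes_b
        ]
        if not pairs:
            raise ValueError("empty candidate gene set for an interaction endpoint")
        return float(np.mean([self.corr_matrix.loc[pa, pb] for pa, pb in pairs]))


def aggregate_edge_correlation(
    candidate_rows: Mapping[str, Sequence[str]],
    corr_matrix: pd.DataFrame,
    absolute: bool = False,
) -> AggregationResult:
    """Resolve many-to-many probe/gene maps to per-edge correlations.

    For a gene measured by several rows, the representative row is the one
    with the largest mean correlation against all candidate rows of *other*
    genes (signed by default; ``absolute=True`` ranks by magnitude).  Edge
    values are then means over the gene-pair correlations of an interaction,
    via :meth:`AggregationResult.edge_value`.
    """
    all_rows = [r for rows in candidate_rows.values() for r in rows]
    if not all_rows:
        raise ValueError("no candidate rows supplied")
    reps: dict[str, str] = {}
    for gene, rows in candidate_rows.items():
        if len(rows) == 0:
            raise ValueError(f"empty candidate row set for {gene!r}")
        if len(rows) == 1:
            reps[gene] = rows[0]
            continue
        others = [r for g, rr in candidate_rows.items() if g != gene for r in rr]
        scores = {}
        for row in rows:
            vals = corr_matrix.loc[row, others].to_numpy(dtype=float)
            if absolute:
                vals = np.abs(vals)
            scores[row] = float(np.nanmean(vals)) if len(vals) else -np.inf
        reps[gene] = max(rows, key=lambda r: scores[r])
    return AggregationResult(representatives=reps, corr_matrix=corr_matrix)


def edge_correlations(
    expr: ExpressionMatrix, net: InteractionNetwork, absolute_selection: bool = False
) -> CorrelationData:
    """Spearman correlations between interaction endpoint expression profiles.

    Multi-probe genes and multi-gene network objects are resolved by
    :func:`aggregate_edge_correlation`.  Interactions whose endpoints have a
    constant profile (rank correlation undefined) are flagged ``missing``
    rather than assigned a value.
    """
    if expr.data.shape[1] < 4:
        raise ValueError("need at least 4 expression columns (time points)")
    genes_needed: set[str] = set()
    touched = {n for ia in net.interactions.values() for n in (ia.source, ia.target)}
    for node in touched:
        genes = expr.genes_for_node(node)
        if not genes:
            raise NetworkFormatError(f"network node {node!r} maps to no gene")
        genes_needed |= genes
    candidate_rows = {g: expr.probes_for_gene(g) for g in genes_needed}
    for g, rows in candidate_rows.items():
        if not rows:
            raise NetworkFormatError(f"gene {g!r} has no expression rows")
    all_rows = sorted({r for rows in candidate_rows.values() for r in rows})
    sub = expr.data.loc[all_rows]
    # rows with a constant profile get NaN entries (rank correlation undefined)
    corr_matrix = sub.T.corr(method="spearman", min_periods=2)
    constant = sub.std(axis=1) == 0
    corr_matrix.loc[constant, :] = np.nan
    corr_matrix.loc[:, constant] = np.nan
    agg = aggregate_edge_correlation(candidate_rows, corr_matrix, absolute=absolute_selection)
    values: dict[str, float] = {}
    missing: set[str] = set()
    for ia in net.interactions.values():
        r = agg.edge_value(expr.genes_for_node(ia.source), expr.genes_for_node(ia.target))
        if math.isnan(r):
            missing.add(ia.id)
        else:
            values[ia.id] = r
    return CorrelationData(values=values, n=expr.data.shape[1], missing=frozenset(missing))


# ---------------------------------------------------------------------------
# Artificial correlation scores from per-time-point significance calls


def artificial_correlation_score(
    sig_a: Sequence[int], sig_b: Sequence[int]
) -> float:
    """Score an interaction from two binary significance vectors.

    Each vector flags whether the endpoint gene was significantly expressed
    at each time point.  If neither gene is significant anywhere the score is
    0; otherwise the score is ``0.4 + (number of co-significant time
    points)/10``, an equally spaced ladder between 0.4 and 0.8 for four time
    points.
    """
    a = np.asarray(sig_a, dtype=int)
    b = np.asarray(sig_b, dtype=int)
    if a.shape != b.shape:
        raise ValueError(f"significance vectors differ in length: {a.shape} vs {b.shape}")
    if not (np.isin(a, (0, 1)).all() and np.isin(b, (0, 1)).all()):
        raise ValueError("significance vectors must be binary")
    if not a.any() and not b.any():
        return 0.0
    subscore = int(np.sum(a & b))
    return 0.4 + subscore / 10.0
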