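"""Synthetic networks with planted dense complexes and held-out edges.

The generator emulates the premise that proteins in a complex tend to
interact: it plants complexes as dense modules (each within-complex pair is
an edge with probability ``p_within``) on a sparse background (every other
pair with probability ``p_background``), optionally makes consecutive
complexes share nodes, and then removes a fraction of the within-complex
edges.  The removed edges are the recoverable ground truth — the "deficient
interactions" a link predictor should restore — and double as the core of a
synthetic gold-standard positive set.  The negative set is sampled from
cross-complex pairs that never carried an edge, the natural analogue of a
different-compartment negative gold standard.

Everything is reproducible from a single RNG seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional

import networkx as nx
import numpy as np

from .graph_io import ComplexSet, ReferenceSets
from .pairs import Pair, canonical_pair
from .prediction import PredictionSet

__all__ = [
    "PlantedModel",
    "GroundTruth",
    "generate",
    "recovery_metrics",
    "sample_random_predictions",
]


@dataclass
class PlantedModel:
    """Parameters of the planted-complex network model.

    Defaults describe the standard study condition: near-clique complexes of
    8–12 proteins (every within-complex pair present) on a sparse background
    (pair probability 0.02), with 10% of within-complex edges held out.

    Parameters
    ----------
    n_background : int
        Number of background proteins outside every planted complex.
    p_background : float
        Edge probability for every pair not inside a planted complex.
    complex_sizes : tuple of int
        Sizes of the planted complexes.
    p_within : float
        Edge probability for pairs inside a complex; must exceed
        ``p_background`` (planted modules are denser than background).
    holdout_fraction : float
        Fraction of generated within-complex edges removed from the network
        and recorded as ground truth, in [0, 1).
    overlap_fraction : float
        Each complex after the first shares ``ceil(overlap_fraction * size)``
        members with its predecessor, in [0, 1); overlapping complexes let
        the same pair be predicted repeatedly (h > 1).
    seed : int
        RNG seed; identical seeds give identical outputs.
    """

    n_background: int = 120
    p_background: float = 0.02
    complex_sizes: tuple[int, ...] = (8, 9, 10, 11, 12)
    p_within: float = 1.0
    holdout_fraction: float = 0.1
    overlap_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_background <= 1.0 and 0.0 <= self.p_within <= 1.0):
            raise ValueError("edge probabilities must be in [0, 1]")
        if self.p_within <= self.p_background:
            raise ValueError("planted complexes must be denser than background")
        if not (0.0 <= self.holdout_fraction < 1.0):
            raise ValueError("holdout_fraction must be in [0, 1)")
        if not (0.0 <= self.overlap_fraction < 1.0):
            raise ValueError("overlap_fraction must be in [0, 1)")
        if any(s < 2 for s in self.complex_sizes):
            raise ValueError("complex sizes must be >= 2")
        for size in self.complex_sizes:
            if math.ceil(self.overlap_fraction * size) >= size:
                raise ValueError(
                    f"overlap {self.overlap_fraction} leaves no fresh node for size {size}"
                )
        if self.n_background < 0:
            raise ValueError("n_background must be >= 0")


@dataclass
class GroundTruth:
    """Planted complexes and the held-out within-complex edges."""

    planted_complexes: ComplexSet
    held_out_edges: set[Pair] = field(default_factory=set)


def _plant_complexes(model: PlantedModel) -> tuple[list[str], ComplexSet]:
    """Lay out complex membership, sharing nodes between consecutive complexes."""
    nodes: list[str] = []

    def new_node() -> str:
        nodes.append(f"P{len(nodes) + 1:04d}")
        return nodes[-1]

    complexes: list[tuple[str, frozenset[str]]] = []
    previous: list[str] = []
    for i, size in enumerate(model.complex_sizes):
        n_shared = math.ceil(model.overlap_fraction * size) if previous else 0
        shared = previous[:min(n_shared, len(previous))]
        members = shared + [new_node() for _ in range(size - len(shared))]
        complexes.append((f"C{i + 1:04d}", frozenset(members)))
        previous = members
    for _ in range(model.n_background):
        new_node()
    return nodes, ComplexSet(complexes)


def generate(
    model: PlantedModel,
) -> tuple[nx.Graph, GroundTruth, ReferenceSets]:
    """Generate (network, ground truth, reference sets) from a planted model.

    Within-complex pairs get edges with probability ``p_within`` and all
    other pairs with ``p_background``; a ``holdout_fraction`` of the
    within-complex edges is then removed uniformly at random and recorded.
    The reference sets contain: gs_positive = held-out edges plus a sample
    of kept within-complex edges; gs_negative = a sample of cross-complex
    pairs that never carried an edge; reference_interactome = all network
    edges plus the held-out edges (an "experimental superset" of the
    network); and per-complex annotations whose term names contain the word
    "complex" for complex members.
    """
    rng = np.random.default_rng(model.seed)
    nodes, complex_set = _plant_complexes(model)
    graph = nx.Graph()
    graph.add_nodes_from(nodes)

    within_pairs: set[Pair] = set()
    for _, members in complex_set:
        for a, b in combinations(sorted(members), 2):
            within_pairs.add((a, b))

    within_edges = sorted(
        p for p in within_pairs if rng.random() < model.p_within
    )
    background_edges = []
    for a, b in combinations(nodes, 2):
        pair = canonical_pair(a, b)
        if pair in within_pairs:
            continue
        if rng.random() < model.p_background:
            background_edges.append(pair)

    n_hold = math.floor(model.holdout_fraction * len(within_edges))
    held_idx = rng.choice(len(within_edges), size=n_hold, replace=False) if n_hold else []
    held_out = {within_edges[i] for i in held_idx}
    kept_within = [p for p in within_edges if p not in held_out]

    graph.add_edges_from(kept_within)
    graph.add_edges_from(background_edges)

    # gold standard: held-out edges + a sample of kept within-complex edges
    n_extra = len(kept_within) // 4
    extra_idx = rng.choice(len(kept_within), size=n_extra, replace=False) if n_extra else []
    gs_positive = held_out | {kept_within[i] for i in extra_idx}

    membership: dict[str, set[str]] = {}
    for cid, members in complex_set:
        for p in members:
            membership.setdefault(p, set()).add(cid)
    complex_nodes = sorted(membership)
    cross_nonedges = [
        (a, b)
        for a, b in combinations(complex_nodes, 2)
        if not membership[a] & membership[b]
        and not graph.has_edge(a, b)
        and (a, b) not in held_out
    ]
    n_neg = min(len(cross_nonedges), 10 * max(len(gs_positive), 1))
    neg_idx = rng.choice(len(cross_nonedges), size=n_neg, replace=False) if n_neg else []
    gs_negative = {cross_nonedges[i] for i in neg_idx}

    annotations: dict[str, set[tuple[str, str]]] = {}
    for i, (cid, members) in enumerate(complex_set, start=1):
        term = (f"GO:{i:07d}", f"planted module {i} complex")
        for p in members:
            annotations.setdefault(p, set()).add(term)
    for p in nodes:
        annotations.setdefault(p, set()).add(("GO:0000000", "cytoplasm"))

    refs = ReferenceSets(
        gs_positive=gs_positive,
        gs_negative=gs_negative,
        reference_interactome={canonical_pair(*e) for e in graph.edges()} | held_out,
        annotations=annotations,
    )
    return graph, GroundTruth(planted_complexes=complex_set, held_out_edges=held_out), refs


def recovery_metrics(
    pred: PredictionSet, truth: GroundTruth
) -> tuple[float, float]:
    """Precision and recall of predictions against the held-out edges.

    Precision is the fraction of predicted pairs that are held-out edges
    (``nan`` for an empty prediction set); recall is the fraction of
    held-out edges that were predicted (1.0 when nothing was held out).
    """
    pairs = pred.pairs()
    hits = len(pairs & truth.held_out_edges)
    precision = hits / len(pairs) if pairs else math.nan
    recall = hits / len(truth.held_out_edges) if truth.held_out_edges else 1.0
    return precision, recall


def sample_random_predictions(
    network: nx.Graph, n_pairs: int, rng: Optional[np.random.Generator] = None
) -> PredictionSet:
    """A size-matched random baseline: uniform non-edges of the network.

    Draws ``n_pairs`` distinct node pairs uniformly among pairs that are not
    network edges — the null predictor against which topology-aware recall
    is judged.
    """
    from .prediction import PredictionEntry

    if rng is None:
        rng = np.random.default_rng()
    nodes = sorted(network.nodes())
    chosen: set[Pair] = set()
    n_possible = len(nodes) * (len(nodes) - 1) // 2 - network.number_of_edges()
    n_pairs = min(n_pairs, n_possible)
    while len(chosen) < n_pairs:
        i, j = rng.integers(len(nodes)), rng.integers(len(nodes))
        if i == j:
            continue
        pair = canonical_pair(nodes[int(i)], nodes[int(j)])
        if network.has_edge(*pair):
            continue
        chosen.add(pair)
    return PredictionSet(
        entries={pair: PredictionEntry(h=1, sources=[("random", 0)]) for pair in chosen}
    )
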