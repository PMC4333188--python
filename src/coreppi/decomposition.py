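"""Adaptive k-core decomposition of protein complexes into dense subnets.

Terminology note: in this method a "k-core" is a *complete* subnetwork on k
nodes — a k-clique — not the classical graph-theoretic k-core (maximal
subgraph of minimum degree k).  The implementation uses clique semantics
throughout; functions are named for cliques to avoid the clash.

A detected complex is decomposed by repeating three steps until no k-clique
remains among its unconsumed members:

1. find a k-clique among the remaining members (the seed);
2. greedily extend the seed inside the remaining members: repeatedly append
   the member with the most connections into the current set, as long as
   the density 2m/(n(n-1)) of the extended set stays strictly above the
   threshold λ;
3. prune the accepted subnet from the complex and continue on the residue.

Members left when no k-clique can be found are abandoned — loosely
connected parts of a complex contribute no predictions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional

import networkx as nx
import numpy as np

__all__ = [
    "DecompositionParams",
    "Subnet",
    "subnet_density",
    "find_k_clique",
    "greedy_extend",
    "decompose_complex",
]


@dataclass
class DecompositionParams:
    """Parameters of the adaptive k-clique decomposition.

    Parameters
    ----------
    k : int
        Seed clique size, at least 2.  The scale of the smallest dense unit
        worth extending; choose it below the typical size of the complexes
        being decomposed (4 is a common choice; larger, e.g. 7, suits
        detectors that emit big dense complexes).
    density_threshold : float
        λ — the subnet density a greedily extended seed must strictly exceed
        to keep growing, in (0, 1].  0.7 is the recommended trade-off between
        prediction quality and quantity.
    seed_mode : {"deterministic", "random"}
        How the seed clique is chosen among all k-cliques of the remaining
        members: "deterministic" takes the lexicographically smallest member
        tuple (reproducible without an RNG); "random" draws uniformly from
        the enumerated k-cliques using ``rng_seed``.
    rng_seed : int, optional
        Seed for the "random" mode RNG.
    """

    k: int
    density_threshold: float = 0.7
    seed_mode: str = "deterministic"
    rng_seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError(f"k must be >= 2, got {self.k}")
        if not (0.0 < self.density_threshold <= 1.0):
            raise ValueError(
                f"density threshold must be in (0, 1], got {self.density_threshold}"
            )
        if self.seed_mode not in ("deterministic", "random"):
            raise ValueError(f"unknown seed_mode {self.seed_mode!r}")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.rng_seed)


@dataclass(frozen=True)
class Subnet:
    """A retained dense subnet: member set, induced edge count and density."""

    members: frozenset[str]
    edge_count: int
    density: float

    @property
    def size(self) -> int:
        return len(self.members)


def subnet_density(network: nx.Graph, members) -> float:
    """Density 2m/(n(n-1)) of the subgraph induced by ``members``.

    ``m`` is the number of network edges with both endpoints in ``members``
    and ``n = |members|``; a clique has density 1.0.  Requires n >= 2.
    """
    members = set(members)
    n = len(members)
    if n < 2:
        raise ValueError(f"density undefined for {n} node(s)")
    m = _induced_edge_count(network, members)
    return 2.0 * m / (n * (n - 1))


def _induced_edge_count(network: nx.Graph, members: set) -> int:
    count = 0
    for u in members:
        if u not in network:
            continue
        for v in network.adj[u]:
            if v in members and u < v:
                count += 1
    return count


def _k_cliques(network: nx.Graph, candidates: set, k: int) -> Iterator[tuple]:
    """Enumerate k-cliques of the induced subgraph in lexicographic order.

    Backtracking over sorted node labels: a partial clique is only extended
    with common neighbours larger than its last member, so each clique is
    produced exactly once, smallest tuple first.
    """
    nodes = sorted(c for c in candidates if c in network)
    adj = {u: {v for v in network.adj[u] if v in candidates} for u in nodes}

    def extend(clique: list, pool: list) -> Iterator[tuple]:
        if len(clique) == k:
            yield tuple(clique)
            return
        # prune: not enough candidates left to complete the clique
        need = k - len(clique)
        for i, u in enumerate(pool):
            if len(pool) - i < need:
                break
            clique.append(u)
            yield from extend(clique, [v for v in pool[i + 1:] if v in adj[u]])
            clique.pop()

    yield from extend([], nodes)


def find_k_clique(
    network: nx.Graph,
    candidates,
    k: int,
    mode: str = "deterministic",
    rng: Optional[np.random.Generator] = None,
) -> Optional[frozenset]:
    """Find a clique of exactly ``k`` candidates, or None if none exists.

    ``mode="deterministic"`` returns the clique with the lexicographically
    smallest member tuple; ``mode="random"`` draws uniformly over all
    k-cliques of the induced subgraph using ``rng``.
    """
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    candidates = set(candidates)
    if mode == "deterministic":
        return next((frozenset(c) for c in _k_cliques(network, candidates, k)), None)
    if mode == "random":
        cliques = list(_k_cliques(network, candidates, k))
        if not cliques:
            return None
        if rng is None:
            rng = np.random.default_rng()
        return frozenset(cliques[int(rng.integers(len(cliques)))])
    raise ValueError(f"unknown seed mode {mode!r}")


def greedy_extend(
    network: nx.Graph,
    seed,
    candidates,
    density_threshold: float,
) -> Subnet:
    """Greedily extend a seed clique inside ``candidates`` under the λ test.

    At each step the candidate node with the most edges into the current set
    is considered (ties broken by lexicographically smallest identifier).  A
    node with zero connections stops the extension; otherwise the node is
    accepted only if the density of the extended set stays strictly above
    ``density_threshold`` — a rejection ends the extension, per the stopping
    rule of the method.  The seed itself is a clique (density 1.0), so the
    returned subnet always satisfies the threshold.
    """
    current = set(seed)
    pool = set(candidates) - current
    # connection count of each pool node into the current set
    links = {
        u: sum(1 for v in network.adj.get(u, ()) if v in current) for u in pool
    }
    m = _induced_edge_count(network, current)
    while pool:
        best = min(pool, key=lambda u: (-links[u], u))
        if links[best] == 0:
            break
        n_new = len(current) + 1
        m_new = m + links[best]
        density = 2.0 * m_new / (n_new * (n_new - 1))
        if not density > density_threshold:
            break
        current.add(best)
        pool.discard(best)
        m = m_new
        del links[best]
        for v in network.adj.get(best, ()):
            if v in pool:
                links[v] += 1
    n = len(current)
    return Subnet(
        members=frozenset(current),
        edge_count=m,
        density=2.0 * m / (n * (n - 1)) if n > 1 else 0.0,
    )


def decompose_complex(
    network: nx.Graph,
    complex_members,
    params: DecompositionParams,
    rng: Optional[np.random.Generator] = None,
) -> list[Subnet]:
    """Decompose one complex into node-disjoint dense subnets.

    Members absent from the network are dropped first.  The loop finds a
    k-clique among the remaining members, extends it greedily, prunes the
    accepted subnet from the remainder, and repeats; when no k-clique is
    left the remaining members are abandoned.  Every returned subnet has
    density > λ, at least k members, and shares no node with its siblings.
    """
    remaining = {p for p in complex_members if p in network}
    if rng is None and params.seed_mode == "random":
        rng = params.rng()
    subnets: list[Subnet] = []
    while True:
        seed = find_k_clique(network, remaining, params.k, params.seed_mode, rng)
        if seed is None:
            break
        subnet = greedy_extend(network, seed, remaining, params.density_threshold)
        subnets.append(subnet)
        remaining -= subnet.members
    return subnets
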