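"""Predict missing interactions inside dense subnets and aggregate them.

Every unordered pair of proteins inside a retained subnet that is not
already an edge of the network becomes a predicted interaction.  Because
complexes (and hence their subnets) from one or several detectors may
overlap, the same pair can be predicted repeatedly; the repetition count h
records how many (complex, subnet) sources emitted it.  A pair predicted by
several independent subnets is considered more reliable, and the h > 1
subset (``filter_by_repetition`` with ``min_h=2``) is the standard
high-confidence adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable

import networkx as nx

from .decomposition import Subnet
from .pairs import Pair, canonical_pair

__all__ = [
    "PredictionEntry",
    "PredictionSet",
    "predict_pairs_in_subnet",
    "aggregate_predictions",
    "filter_by_repetition",
]


@dataclass
class PredictionEntry:
    """Repetition count h and provenance of one predicted pair."""

    h: int
    sources: list[tuple[str, int]] = field(default_factory=list)


@dataclass
class PredictionSet:
    """Map from canonical pair to its repetition count and sources."""

    entries: dict[Pair, PredictionEntry] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, pair: Pair) -> bool:
        return pair in self.entries

    def pairs(self) -> set[Pair]:
        return set(self.entries)

    def h_histogram(self) -> dict[int, int]:
        """Number of predicted pairs at each repetition level h."""
        hist: dict[int, int] = {}
        for entry in self.entries.values():
            hist[entry.h] = hist.get(entry.h, 0) + 1
        return dict(sorted(hist.items()))

    def total_emitted(self) -> int:
        """Σ h over unique pairs = total pair-predictions emitted by subnets."""
        return sum(entry.h for entry in self.entries.values())


def predict_pairs_in_subnet(network: nx.Graph, subnet: Subnet) -> set[Pair]:
    """All unordered member pairs of a subnet absent from the network.

    For a subnet with n members and m induced edges this returns exactly
    n(n-1)/2 - m pairs; a complete subnet yields none.
    """
    members = sorted(subnet.members)
    return {
        (a, b)
        for a, b in combinations(members, 2)
        if not network.has_edge(a, b)
    }


def aggregate_predictions(
    per_subnet: Iterable[tuple[str, int, Iterable[Pair]]],
) -> PredictionSet:
    """Merge per-subnet pair sets, counting repetitions.

    ``per_subnet`` yields (complex id, subnet index, pair set) triples.  The
    repetition count h of a pair equals the number of subnets that predicted
    it; sources are recorded in input order.
    """
    entries: dict[Pair, PredictionEntry] = {}
    for complex_id, subnet_index, pairs in per_subnet:
        for a, b in pairs:
            pair = canonical_pair(a, b)
            entry = entries.get(pair)
            if entry is None:
                entries[pair] = PredictionEntry(h=1, sources=[(complex_id, subnet_index)])
            else:
                entry.h += 1
                entry.sources.append((complex_id, subnet_index))
    return PredictionSet(entries=entries)


def filter_by_repetition(pred: PredictionSet, min_h: int) -> PredictionSet:
    """Keep entries with h >= min_h (min_h=2 is the high-confidence subset)."""
    if min_h < 1:
        raise ValueError(f"min_h must be >= 1, got {min_h}")
    return PredictionSet(
        entries={
            pair: PredictionEntry(h=entry.h, sources=list(entry.sources))
            for pair, entry in pred.entries.items()
            if entry.h >= min_h
        }
    )
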