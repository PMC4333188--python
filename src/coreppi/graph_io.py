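"""Read and write networks, complex sets, predictions and reference sets.

All formats are plain whitespace-delimited text, mirroring what PPI
databases and complex detectors export:

* network — two-column edge list, one interaction per line, ``#`` comments;
* complexes — one complex per line, members whitespace-separated;
* predictions — TSV with columns protein_a, protein_b, h, sources;
* reference pair sets — two-column edge list;
* annotations — three-column TSV (protein, term_id, term_name).

Protein identifiers are opaque, case-sensitive strings; no identifier
mapping is attempted.  Networks are cleaned on read: self-interactions are
dropped and duplicate records (including reversed duplicates) collapse onto
one canonical edge.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import networkx as nx
import pandas as pd

from .pairs import Pair, canonical_pair

logger = logging.getLogger(__name__)

__all__ = [
    "ComplexSet",
    "ReferenceSets",
    "canonical_pair",
    "read_network",
    "write_network",
    "read_complexes",
    "write_complexes",
    "read_predictions",
    "write_predictions",
    "read_pair_set",
    "write_pair_set",
    "read_annotations",
    "write_annotations",
]


@dataclass
class ComplexSet:
    """An ordered collection of detected protein complexes.

    Each complex is a (complex id, member set) pair.  Complexes may overlap
    and members need not all occur in the network they are analysed against.
    """

    complexes: list[tuple[str, frozenset[str]]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.complexes)

    def __iter__(self) -> Iterator[tuple[str, frozenset[str]]]:
        return iter(self.complexes)

    def members(self, complex_id: str) -> frozenset[str]:
        for cid, mem in self.complexes:
            if cid == complex_id:
                return mem
        raise KeyError(complex_id)

    @property
    def ids(self) -> list[str]:
        return [cid for cid, _ in self.complexes]

    def all_members(self) -> set[str]:
        out: set[str] = set()
        for _, mem in self.complexes:
            out |= mem
        return out


@dataclass
class ReferenceSets:
    """Evaluation references: gold standard, reference interactome, annotations.

    ``gs_positive`` and ``gs_negative`` are the true-positive and true-negative
    gold-standard pair sets (they must be disjoint); ``reference_interactome``
    is an independent experimentally supported pair set used for direct hit
    counting; ``annotations`` maps each protein to its set of
    (term id, term name) annotation terms.
    """

    gs_positive: set[Pair] = field(default_factory=set)
    gs_negative: set[Pair] = field(default_factory=set)
    reference_interactome: set[Pair] = field(default_factory=set)
    annotations: dict[str, set[tuple[str, str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        overlap = self.gs_positive & self.gs_negative
        if overlap:
            raise ValueError(
                f"gold-standard positive and negative sets overlap on {len(overlap)} pairs"
            )


def _data_lines(path: str | Path) -> Iterator[tuple[int, str]]:
    """Yield (1-based line number, stripped line) skipping comments/blanks."""
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            yield lineno, line


def read_network(path: str | Path) -> nx.Graph:
    """Read a two-column edge list into a cleaned undirected network.

    Self-interactions are dropped and duplicate or reversed-duplicate records
    collapse to a single canonical edge; counts of dropped records are logged.

    Raises
    ------
    ValueError
        On a line with a column count other than two (the error names the
        line number), or if the file contains no interaction records.
    """
    graph = nx.Graph()
    n_self = n_dup = 0
    n_records = 0
    for lineno, line in _data_lines(path):
        fields = line.split()
        if len(fields) != 2:
            raise ValueError(
                f"{path}:{lineno}: expected 2 columns, got {len(fields)}: {line!r}"
            )
        n_records += 1
        a, b = fields
        if a == b:
            n_self += 1
            continue
        u, v = canonical_pair(a, b)
        if graph.has_edge(u, v):
            n_dup += 1
            continue
        graph.add_edge(u, v)
    if n_records == 0:
        raise ValueError(f"{path}: no interaction records found")
    if n_self or n_dup:
        logger.info(
            "read_network(%s): dropped %d self-interactions and %d duplicate records",
            path, n_self, n_dup,
        )
    logger.info(
        "read_network(%s): %d proteins, %d interactions",
        path, graph.number_of_nodes(), graph.number_of_edges(),
    )
    return graph


def write_network(network: nx.Graph, path: str | Path) -> None:
    """Write a network as a canonical, sorted two-column edge list."""
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("# protein_a\tprotein_b\n")
        for a, b in sorted(canonical_pair(u, v) for u, v in network.edges()):
            fh.write(f"{a}\t{b}\n")


def read_complexes(path: str | Path) -> ComplexSet:
    """Read a complex file: one complex per line, members whitespace-separated.

    Complexes are assigned ids ``C0001``, ``C0002``, ... in file order.
    Duplicate members within a line are collapsed; empty lines are skipped
    with a warning.
    """
    complexes: list[tuple[str, frozenset[str]]] = []
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if line.startswith("#"):
                continue
            if not line:
                logger.warning("%s:%d: empty complex line skipped", path, lineno)
                continue
            members = frozenset(line.split())
            complexes.append((f"C{len(complexes) + 1:04d}", members))
    return ComplexSet(complexes)


def write_complexes(complex_set: ComplexSet, path: str | Path) -> None:
    """Write one complex per line, members tab-separated and sorted."""
    with open(path, "wt", encoding="utf-8") as fh:
        for _, members in complex_set:
            fh.write("\t".join(sorted(members)) + "\n")


_PRED_COLUMNS = ["protein_a", "protein_b", "h", "sources"]


def write_predictions(pred, path: str | Path) -> None:
    """Write a prediction set as a TSV, one row per unique canonical pair.

    Columns are protein_a, protein_b, repetition count h, and the
    semicolon-joined sources (``complex_id/subnet_index``).  Rows sort by
    h descending, then pair ascending, and round-trip losslessly through
    :func:`read_predictions`.
    """
    rows = []
    for (a, b), entry in pred.entries.items():
        src = ";".join(f"{cid}/{idx}" for cid, idx in entry.sources)
        rows.append((a, b, entry.h, src))
    rows.sort(key=lambda r: (-r[2], r[0], r[1]))
    frame = pd.DataFrame(rows, columns=_PRED_COLUMNS)
    frame.to_csv(path, sep="\t", index=False)


def read_predictions(path: str | Path):
    """Read a prediction TSV written by :func:`write_predictions`."""
    from .prediction import PredictionEntry, PredictionSet

    frame = pd.read_csv(
        path, sep="\t", dtype={"protein_a": str, "protein_b": str, "sources": str},
        keep_default_na=False,
    )
    missing = [c for c in _PRED_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing prediction columns {missing}")
    entries = {}
    for row in frame.itertuples(index=False):
        pair = canonical_pair(row.protein_a, row.protein_b)
        sources = []
        if row.sources:
            for token in row.sources.split(";"):
                cid, _, idx = token.partition("/")
                sources.append((cid, int(idx) if idx else 0))
        entries[pair] = PredictionEntry(h=int(row.h), sources=sources)
    return PredictionSet(entries=entries)


def read_pair_set(path: str | Path) -> set[Pair]:
    """Read a two-column file into a set of canonical pairs (self pairs dropped)."""
    pairs: set[Pair] = set()
    for lineno, line in _data_lines(path):
        fields = line.split()
        if len(fields) != 2:
            raise ValueError(
                f"{path}:{lineno}: expected 2 columns, got {len(fields)}: {line!r}"
            )
        if fields[0] == fields[1]:
            continue
        pairs.add(canonical_pair(*fields))
    return pairs


def write_pair_set(pairs: Iterable[Pair], path: str | Path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("# protein_a\tprotein_b\n")
        for a, b in sorted(pairs):
            fh.write(f"{a}\t{b}\n")


def read_annotations(path: str | Path) -> dict[str, set[tuple[str, str]]]:
    """Read a protein→term table: three tab-separated columns.

    Columns are protein, term id, term name (the name may contain spaces, so
    the split is on tabs and limited to three fields).
    """
    annotations: dict[str, set[tuple[str, str]]] = {}
    for lineno, line in _data_lines(path):
        fields = line.split("\t", 2)
        if len(fields) != 3:
            raise ValueError(
                f"{path}:{lineno}: expected 3 tab-separated columns, got {len(fields)}"
            )
        protein, term_id, term_name = (f.strip() for f in fields)
        annotations.setdefault(protein, set()).add((term_id, term_name))
    return annotations


def write_annotations(annotations: dict[str, set[tuple[str, str]]], path: str | Path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("# protein\tterm_id\tterm_name\n")
        for protein in sorted(annotations):
            for term_id, term_name in sorted(annotations[protein]):
                fh.write(f"{protein}\t{term_id}\t{term_name}\n")
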