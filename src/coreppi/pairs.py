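"""Canonical representation of an undirected protein pair.

An interaction is an unordered pair of protein identifiers: the pair
``(a, b)`` and ``(b, a)`` denote the same interaction and only one record is
kept.  Throughout the package a pair is stored as a tuple sorted
lexicographically, so pair sets can be intersected and compared directly.
"""

from __future__ import annotations

Pair = tuple[str, str]


def canonical_pair(a: str, b: str) -> Pair:
    """Return the canonical (lexicographically sorted) form of a pair.

    Raises
    ------
    ValueError
        If ``a == b`` — self-interactions are not representable.
    """
    if a == b:
        raise ValueError(f"self-interaction not allowed: {a!r}")
    return (a, b) if a < b else (b, a)


def canonicalize_pairs(pairs) -> set[Pair]:
    """Canonicalize an iterable of 2-tuples into a set of pairs."""
    return {canonical_pair(a, b) for a, b in pairs}
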