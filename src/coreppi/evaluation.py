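"""Estimators for predicted interaction sets.

Three estimators are provided:

* a gold-standard likelihood ratio L = (P+/G+) / (P-/G-), where P+ and P-
  count predictions hitting the true-positive and true-negative gold
  standard sets of sizes G+ and G-; the ratio-of-proportions form corrects
  for the huge imbalance between positives and negatives (Jansen et al.'s
  yeast gold standard has G+ = 8250 and G- = 2705844, shipped here as
  default constants, with L >= 300 / >= 600 as the customary acceptance
  thresholds);
* a reference-interactome hit ratio — the percentage of predictions present
  in an independent experimental pair set (BioGRID-style);
* overlap statistics between two prediction sets — intersection, union and
  the Jaccard percentage 100·|A∩B|/|A∪B|;

plus an annotation-based complex hit ratio: the percentage of predicted
pairs whose two proteins share an annotation term whose name contains a
keyword ("complex" by default).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

from .graph_io import ReferenceSets
from .pairs import Pair
from .prediction import PredictionSet

__all__ = [
    "GS_POSITIVE_SIZE",
    "GS_NEGATIVE_SIZE",
    "LikelihoodInputs",
    "OverlapStats",
    "likelihood_ratio",
    "count_gs_hits",
    "reference_hit_ratio",
    "overlap_stats",
    "annotation_hit_ratio",
]

#: Size of the Jansen et al. yeast gold-standard true-positive set.
GS_POSITIVE_SIZE = 8250
#: Size of the Jansen et al. yeast gold-standard true-negative set.
GS_NEGATIVE_SIZE = 2705844


@dataclass
class LikelihoodInputs:
    """Hit counts and gold-standard sizes entering the likelihood ratio."""

    p_plus: int
    p_minus: int
    g_plus: int = GS_POSITIVE_SIZE
    g_minus: int = GS_NEGATIVE_SIZE

    def __post_init__(self) -> None:
        if self.p_plus < 0 or self.p_minus < 0:
            raise ValueError("hit counts must be non-negative")
        if self.g_plus <= 0 or self.g_minus <= 0:
            raise ValueError("gold-standard sizes must be positive")


@dataclass(frozen=True)
class OverlapStats:
    """Intersection/union bookkeeping for two prediction sets."""

    size_a: int
    size_b: int
    intersection: int
    union: int
    ratio_percent: float

    @property
    def ratio_percent_rounded(self) -> int:
        """Overlap percentage rounded half-up to an integer."""
        return int(math.floor(self.ratio_percent + 0.5))


def likelihood_ratio(inputs: LikelihoodInputs) -> float:
    """Gold-standard likelihood ratio L = (P+/G+) / (P-/G-).

    Returns ``inf`` when P- = 0 with P+ > 0 (no true-negative hits at all)
    and ``nan`` when both counts are zero (no gold-standard hits — L is
    undefined).
    """
    if inputs.p_minus == 0:
        return math.inf if inputs.p_plus > 0 else math.nan
    return (inputs.p_plus / inputs.g_plus) / (inputs.p_minus / inputs.g_minus)


def count_gs_hits(
    pred: PredictionSet,
    refs: ReferenceSets,
    use_standard_sizes: bool = False,
) -> LikelihoodInputs:
    """Count predictions hitting the gold-standard positive/negative sets.

    By default G+ and G- are the sizes of the supplied reference sets; pass
    ``use_standard_sizes=True`` to use the published yeast constants instead.
    """
    pairs = pred.pairs()
    p_plus = len(pairs & refs.gs_positive)
    p_minus = len(pairs & refs.gs_negative)
    if use_standard_sizes:
        return LikelihoodInputs(p_plus, p_minus)
    return LikelihoodInputs(
        p_plus, p_minus, g_plus=len(refs.gs_positive), g_minus=len(refs.gs_negative)
    )


def reference_hit_ratio(pred: PredictionSet, reference: set[Pair]) -> float:
    """Percentage of predicted pairs present in a reference interactome."""
    if len(pred) == 0:
        raise ValueError("hit ratio undefined for an empty prediction set")
    return 100.0 * len(pred.pairs() & reference) / len(pred)


def overlap_stats(set_a: Iterable[Pair], set_b: Iterable[Pair]) -> OverlapStats:
    """Overlap between two pair sets: |A∩B|, |A∪B| and 100·|A∩B|/|A∪B|.

    The union is computed by inclusion–exclusion and cross-checked against
    the directly computed set union.  Two empty sets give a 0% ratio.
    """
    a, b = set(set_a), set(set_b)
    inter = len(a & b)
    union = len(a) + len(b) - inter
    assert union == len(a | b)
    ratio = 100.0 * inter / union if union else 0.0
    return OverlapStats(
        size_a=len(a), size_b=len(b), intersection=inter, union=union,
        ratio_percent=ratio,
    )


def annotation_hit_ratio(
    pred: PredictionSet,
    annotations: Mapping[str, set[tuple[str, str]]],
    keyword: str = "complex",
) -> tuple[int, float]:
    """Fraction of predictions whose proteins share a keyword-matching term.

    A predicted pair hits if its two proteins are annotated with at least one
    common term whose name contains ``keyword`` (case-insensitive substring).
    Returns (hit count, percentage of predictions hitting).
    """
    if len(pred) == 0:
        raise ValueError("annotation hit ratio undefined for an empty prediction set")
    needle = keyword.lower()
    hits = 0
    for a, b in pred.pairs():
        shared = annotations.get(a, set()) & annotations.get(b, set())
        if any(needle in name.lower() for _, name in shared):
            hits += 1
    return hits, 100.0 * hits / len(pred)
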