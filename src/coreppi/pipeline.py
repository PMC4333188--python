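"""End-to-end prediction workflow: decompose every complex, predict, filter."""

from __future__ import annotations

from typing import Optional

import networkx as nx
import numpy as np

from .decomposition import DecompositionParams, decompose_complex
from .graph_io import ComplexSet
from .prediction import (
    PredictionSet,
    aggregate_predictions,
    filter_by_repetition,
    predict_pairs_in_subnet,
)

__all__ = ["predict_interactions"]


def predict_interactions(
    network: nx.Graph,
    complex_set: ComplexSet,
    params: DecompositionParams,
    min_h: int = 1,
) -> tuple[PredictionSet, dict]:
    """Run the full pipeline over a complex set.

    Each complex is decomposed into dense subnets; every non-adjacent member
    pair of each subnet is emitted as a prediction; predictions are merged
    with repetition counting and finally filtered to h >= ``min_h``.

    Returns the filtered prediction set and a run report with the complex
    and subnet counts, the number of abandoned members, the h histogram of
    the unfiltered set, and the parameters — enough to reproduce the run.
    """
    rng: Optional[np.random.Generator] = (
        params.rng() if params.seed_mode == "random" else None
    )
    per_subnet = []
    n_subnets = 0
    n_abandoned = 0
    for complex_id, members in complex_set:
        subnets = decompose_complex(network, members, params, rng=rng)
        in_network = {p for p in members if p in network}
        covered: set[str] = set()
        for index, subnet in enumerate(subnets):
            covered |= subnet.members
            per_subnet.append(
                (complex_id, index, predict_pairs_in_subnet(network, subnet))
            )
        n_subnets += len(subnets)
        n_abandoned += len(in_network - covered)
    aggregated = aggregate_predictions(per_subnet)
    filtered = filter_by_repetition(aggregated, min_h) if min_h > 1 else aggregated
    report = {
        "n_complexes": len(complex_set),
        "n_subnets": n_subnets,
        "n_abandoned_members": n_abandoned,
        "n_predictions_unfiltered": len(aggregated),
        "n_predictions": len(filtered),
        "h_histogram": aggregated.h_histogram(),
        "k": params.k,
        "density_threshold": params.density_threshold,
        "seed_mode": params.seed_mode,
        "rng_seed": params.rng_seed,
        "min_h": min_h,
    }
    return filtered, report
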