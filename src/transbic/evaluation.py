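"""Recovery / Relevance / Performance metrics for bicluster sets.

Recovery averages, over genuine biclusters, the best Jaccard agreement
with any detected bicluster; Relevance is the symmetric counterpart
averaged over detected biclusters; Performance is their geometric mean.
Agreement is computed over cells (gene, condition pairs) by default, or
over gene sets with ``match_on="genes"``.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

from .core import BTPBicluster
from .synthetic import GroundTruth

__all__ = [
    "recovery",
    "relevance",
    "performance",
    "truth_cell_sets",
    "detected_cell_sets",
]


def _jaccard(a: frozenset, b: frozenset) -> float:
    union = len(a | b)
    return len(a & b) / union if union else 0.0


def _as_sets(biclusters: Iterable) -> list:
    return [frozenset(b) for b in biclusters]


def recovery(genuine: Iterable, detected: Iterable) -> float:
    """Mean best-match Jaccard from each genuine to the detected set."""
    g = _as_sets(genuine)
    d = _as_sets(detected)
    if not g:
        raise ValueError("recovery needs a non-empty genuine set")
    if not d:
        return 0.0
    return sum(max(_jaccard(b1, b2) for b2 in d) for b1 in g) / len(g)


def relevance(genuine: Iterable, detected: Iterable) -> float:
    """Mean best-match Jaccard from each detected to the genuine set.

    An empty detected set scores 0 (failed runs score worst).
    """
    g = _as_sets(genuine)
    d = _as_sets(detected)
    if not d:
        return 0.0
    if not g:
        raise ValueError("relevance needs a non-empty genuine set")
    return sum(max(_jaccard(b2, b1) for b1 in g) for b2 in d) / len(d)


def performance(genuine: Iterable, detected: Iterable) -> float:
    """Geometric mean of recovery and relevance."""
    g = _as_sets(genuine)
    d = _as_sets(detected)
    return math.sqrt(recovery(g, d) * relevance(g, d))


def truth_cell_sets(truth: GroundTruth, match_on: str = "cells") -> list:
    """Genuine biclusters as cell (or gene) sets."""
    if match_on == "genes":
        return [frozenset(b.rows) for b in truth.biclusters]
    return [b.cells() for b in truth.biclusters]


def detected_cell_sets(
    biclusters: Sequence[BTPBicluster], match_on: str = "cells"
) -> list:
    """Detected biclusters as cell (or gene) sets."""
    if match_on == "genes":
        return [frozenset(b.gene_members) for b in biclusters]
    return [frozenset(b.cells()) for b in biclusters]
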