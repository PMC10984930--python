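"""Adaptive δ-neighborhoods and rough-set approximations.

The neighborhood of a query is the set of samples within an adaptively
chosen threshold

    δ = min_D + r · R_D

where ``min_D`` is the smallest query-to-training distance (local
information), ``R_D = max − min`` is the range of those distances (global
information), and ``r`` blends the two.  ``r = 0`` degenerates to
nearest-neighbor granules; ``r ≥ 1`` swallows the whole table.  The default
``r = 0.002`` follows the radius the method's evaluation selects.

Granulating a labeled table with each record's own neighborhood yields the
rough-set machinery: a record is in the *lower approximation* of class c
when its whole neighborhood is labeled c (certainly c), in the *upper
approximation* when its neighborhood touches class c (possibly c), and the
*boundary region* is the union of uppers minus the union of lowers — the
uncertain zone of the decision table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from .data_model import HybridRecord, HybridTable
from .distance import DistanceParams, distances_to_query, pairwise_distances
from .errors import ConfigurationError, ContractViolation

#: radius the method's evaluation settles on
DEFAULT_RADIUS = 0.002


@dataclass(frozen=True)
class Neighborhood:
    """A query's adaptive threshold and the samples that fall inside it."""

    delta: float
    min_d: float
    range_d: float
    members: tuple[int, ...]
    distances: Mapping[int, float]
    attribute_subset: Optional[tuple[str, ...]] = None

    def member_distances(self) -> np.ndarray:
        return np.array([self.distances[i] for i in self.members])


@dataclass(frozen=True)
class ApproximationResult:
    """Per-class lower/upper approximation index sets and the boundary region."""

    lower: Mapping[str, frozenset[int]]
    upper: Mapping[str, frozenset[int]]
    boundary: frozenset[int]

    @property
    def classes(self) -> tuple[str, ...]:
        return tuple(sorted(self.lower))


def adaptive_threshold(
    distances: Sequence[float], r: float
) -> tuple[float, float, float]:
    """Return ``(delta, min_d, range_d)`` with δ = min + r·(max − min)."""
    if len(distances) == 0:
        raise ContractViolation("adaptive threshold needs a non-empty distance list")
    if r < 0:
        raise ConfigurationError("radius r must be nonnegative")
    arr = np.asarray(distances, dtype=float)
    min_d = float(arr.min())
    range_d = float(arr.max()) - min_d
    return min_d + r * range_d, min_d, range_d


def build_neighborhood(
    query: HybridRecord,
    table: HybridTable,
    params: DistanceParams,
    r: float = DEFAULT_RADIUS,
    attribute_subset: Optional[Sequence[str]] = None,
) -> Neighborhood:
    """δ-neighborhood of ``query`` in ``table`` under the adaptive threshold.

    Membership uses ``distance ≤ δ`` (ties at the threshold are inside), so
    every argmin sample always qualifies and the neighborhood is never empty
    for a non-empty table.
    """
    if len(table) == 0:
        raise ContractViolation("cannot build a neighborhood over an empty table")
    dists = distances_to_query(table, query, params, attribute_subset)
    delta, min_d, range_d = adaptive_threshold(dists, r)
    members = tuple(int(i) for i in np.flatnonzero(dists <= delta))
    return Neighborhood(
        delta=delta,
        min_d=min_d,
        range_d=range_d,
        members=members,
        distances={int(i): float(dists[i]) for i in members},
        attribute_subset=None if attribute_subset is None else tuple(attribute_subset),
    )


def class_approximations(
    table: HybridTable,
    params: DistanceParams,
    r: float = DEFAULT_RADIUS,
    attribute_subset: Optional[Sequence[str]] = None,
) -> ApproximationResult:
    """Lower/upper approximations of every decision class and the boundary.

    Each record's granule is built against the full table — self included,
    so its own distance 0 makes ``min_d = 0`` and δ = r·range.  Record i
    enters ``lower(c)`` iff its granule is contained in class c, and
    ``upper(c)`` iff its granule intersects class c.
    """
    if not table.has_labels:
        raise ContractViolation("class approximations need a labeled table")
    labels = table.labels
    if any(lab is None or (isinstance(lab, float) and np.isnan(lab)) for lab in labels):
        raise ContractViolation("every record must be labeled")
    dmat = pairwise_distances(table, params, attribute_subset)
    n = len(table)
    classes = sorted(set(labels))
    class_idx: dict[str, np.ndarray] = {
        c: np.asarray(labels == np.asarray(c, dtype=object), dtype=bool) for c in classes
    }
    lower: dict[str, set[int]] = {c: set() for c in classes}
    upper: dict[str, set[int]] = {c: set() for c in classes}
    for i in range(n):
        row = dmat[i]
        delta, _, _ = adaptive_threshold(row, r)
        granule = row <= delta
        for c in classes:
            inside = class_idx[c]
            if np.all(inside[granule]):
                lower[c].add(i)
            if np.any(inside[granule]):
                upper[c].add(i)
    result = ApproximationResult(
        lower={c: frozenset(v) for c, v in lower.items()},
        upper={c: frozenset(v) for c, v in upper.items()},
        boundary=frozenset(),
    )
    return ApproximationResult(
        lower=result.lower, upper=result.upper, boundary=boundary_region(result)
    )


def boundary_region(approx: ApproximationResult) -> frozenset[int]:
    """Union of upper approximations minus union of lowers (the uncertain zone)."""
    all_upper: set[int] = set().union(*approx.upper.values()) if approx.upper else set()
    all_lower: set[int] = set().union(*approx.lower.values()) if approx.lower else set()
    return frozenset(all_upper - all_lower)
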