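"""Hybrid distance for mixed numeric/categorical records.

Numeric attributes contribute 4σ-normalized Euclidean terms
``(|Δ_i| / 4σ_i)²`` where σ_i is the per-attribute dispersion fitted on the
training partition; dividing by four standard deviations bounds the leverage
of outliers, so a one-unit term means a difference of four σ.  Categorical
attributes contribute squared Levenshtein edit distances, by default
length-normalized to ``[0, 1]`` so string terms stay commensurate with the
numeric ones.  Both kinds combine under a single radical:

    d(x, y) = sqrt( Σ_num w_i (|Δ_i|/4σ_i)²  +  Σ_cat w_i L_i² )

which reduces exactly to the weighted normalized Euclidean distance on
all-numeric data and to a weighted Levenshtein aggregate on all-categorical
data.  Attributes with σ_i = 0 (constant in training) carry no
discriminating information and contribute 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache
from typing import Mapping, Optional, Sequence

import numpy as np

from .data_model import CATEGORICAL, NUMERIC, HybridRecord, HybridSchema, HybridTable
from .errors import ConfigurationError, ContractViolation

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DistanceParams:
    """Fitted per-attribute normalizers and weights.

    sigmas
        Population standard deviation (divisor n) of each numeric condition
        attribute over the training records.
    weights
        Nonnegative per-condition-attribute weights (default 1 everywhere).
    normalize_lev
        When on (default), each Levenshtein term is divided by the longer
        string length of the pair, mapping it into [0, 1].
    """

    schema: HybridSchema
    sigmas: Mapping[str, float]
    weights: Mapping[str, float]
    normalize_lev: bool = True

    def __post_init__(self) -> None:
        for name in self.schema.numeric_names:
            if name not in self.sigmas:
                raise ContractViolation(f"no sigma fitted for numeric attribute {name!r}")
            if self.sigmas[name] < 0:
                raise ContractViolation(f"negative sigma for {name!r}")
        for name in self.schema.condition_names:
            if name not in self.weights:
                raise ContractViolation(f"no weight for attribute {name!r}")
            if self.weights[name] < 0:
                raise ContractViolation(f"negative weight for {name!r}")


def fit_distance_params(
    train: HybridTable,
    weights: Optional[Mapping[str, float]] = None,
    normalize_lev: bool = True,
) -> DistanceParams:
    """Fit σ_i on the training table and resolve attribute weights.

    σ is the only fitted quantity; weights default to 1 for every condition
    attribute.  Constant attributes get σ = 0 and are flagged in the log
    (they contribute nothing to distances).
    """
    if len(train) == 0:
        raise ContractViolation("cannot fit distance params on an empty table")
    schema = train.schema
    if weights:
        for key in weights:
            if key not in schema.condition_names:
                raise ConfigurationError(f"weight given for unknown attribute {key!r}")
            if weights[key] < 0:
                raise ConfigurationError(f"negative weight for attribute {key!r}")
    sigmas: dict[str, float] = {}
    for name in schema.numeric_names:
        sigma = float(np.std(train.df[name].to_numpy(dtype=float)))  # divisor n
        if sigma == 0.0:
            logger.warning("attribute %r is constant in training (sigma = 0)", name)
        sigmas[name] = sigma
    resolved = {name: 1.0 for name in schema.condition_names}
    if weights:
        resolved.update({k: float(v) for k, v in weights.items()})
    return DistanceParams(
        schema=schema, sigmas=sigmas, weights=resolved, normalize_lev=normalize_lev
    )


@lru_cache(maxsize=65536)
def levenshtein(a: str, b: str) -> int:
    """Minimum number of single-character edits transforming ``a`` into ``b``.

    Wagner–Fischer dynamic programming over insertions, deletions and
    substitutions; when either string is empty the distance is the other
    string's length.
    """
    if a == b:
        return 0
    if not a:
        return len(b)
    if not b:
        return len(a)
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, start=1):
        cur = [i]
        for j, cb in enumerate(b, start=1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def _lev_term(a: str, b: str, normalize: bool) -> float:
    d = levenshtein(a, b)
    if normalize and d:
        d = d / max(len(a), len(b))
    return float(d)


def numeric_part(
    x: HybridRecord, y: HybridRecord, params: DistanceParams
) -> float:
    """Weighted 4σ-normalized Euclidean distance over numeric attributes only."""
    total = 0.0
    for name in params.schema.numeric_names:
        sigma = params.sigmas[name]
        if sigma == 0.0:
            continue
        diff = abs(float(x.values[name]) - float(y.values[name])) / (4.0 * sigma)
        total += params.weights[name] * diff * diff
    return float(np.sqrt(total))


def hybrid_distance(
    x: HybridRecord,
    y: HybridRecord,
    params: DistanceParams,
    attribute_subset: Optional[Sequence[str]] = None,
) -> float:
    """Hybrid distance between two records under fitted parameters.

    The attribute kind selects the term at run time: numeric attributes use
    the 4σ Euclidean form, categorical ones the (optionally normalized)
    Levenshtein distance; all terms share one radical.
    """
    schema = params.schema
    names = schema.condition_names if attribute_subset is None else tuple(attribute_subset)
    for name in names:
        if name not in x.values or name not in y.values:
            raise ContractViolation(f"records do not share attribute {name!r}")
    total = 0.0
    for name in names:
        w = params.weights[name]
        if schema.kind_of(name) == NUMERIC:
            sigma = params.sigmas[name]
            if sigma == 0.0:
                continue
            diff = abs(float(x.values[name]) - float(y.values[name])) / (4.0 * sigma)
            total += w * diff * diff
        else:
            term = _lev_term(str(x.values[name]), str(y.values[name]), params.normalize_lev)
            total += w * term * term
    return float(np.sqrt(total))


def distances_to_query(
    table: HybridTable,
    query: HybridRecord,
    params: DistanceParams,
    attribute_subset: Optional[Sequence[str]] = None,
) -> np.ndarray:
    """Vector of hybrid distances from every table row to ``query``.

    Vectorized over rows: numeric columns via array arithmetic, categorical
    columns via Levenshtein against each distinct token (tokens repeat
    heavily in decision tables, so distinct-value caching dominates).
    """
    schema = params.schema
    names = schema.condition_names if attribute_subset is None else tuple(attribute_subset)
    if schema.decision in names:
        raise ConfigurationError("attribute subset must not contain the decision attribute")
    n = len(table)
    total = np.zeros(n)
    for name in names:
        w = params.weights[name]
        if w == 0.0:
            continue
        if schema.kind_of(name) == NUMERIC:
            sigma = params.sigmas[name]
            if sigma == 0.0:
                continue
            col = table.df[name].to_numpy(dtype=float)
            diff = np.abs(col - float(query.values[name])) / (4.0 * sigma)
            total += w * diff * diff
        else:
            col = table.df[name].to_numpy(dtype=object)
            qtok = str(query.values[name])
            uniq, inverse = np.unique(col.astype(str), return_inverse=True)
            terms = np.array(
                [_lev_term(qtok, tok, params.normalize_lev) for tok in uniq]
            )
            t = terms[inverse]
            total += w * t * t
    return np.sqrt(total)


def pairwise_distances(
    table: HybridTable,
    params: DistanceParams,
    attribute_subset: Optional[Sequence[str]] = None,
) -> np.ndarray:
    """Symmetric (n, n) matrix of hybrid distances among table rows."""
    schema = params.schema
    names = schema.condition_names if attribute_subset is None else tuple(attribute_subset)
    if schema.decision in names:
        raise ConfigurationError("attribute subset must not contain the decision attribute")
    n = len(table)
    total = np.zeros((n, n))
    for name in names:
        w = params.weights[name]
        if w == 0.0:
            continue
        if schema.kind_of(name) == NUMERIC:
            sigma = params.sigmas[name]
            if sigma == 0.0:
                continue
            col = table.df[name].to_numpy(dtype=float)
            diff = np.abs(col[:, None] - col[None, :]) / (4.0 * sigma)
            total += w * diff * diff
        else:
            col = table.df[name].to_numpy(dtype=object).astype(str)
            uniq, inverse = np.unique(col, return_inverse=True)
            k = len(uniq)
            lev_u = np.zeros((k, k))
            for i in range(k):
                for j in range(i + 1, k):
                    lev_u[i, j] = lev_u[j, i] = _lev_term(
                        uniq[i], uniq[j], params.normalize_lev
                    )
            t = lev_u[np.ix_(inverse, inverse)]
            total += w * t * t
    return np.sqrt(total)
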