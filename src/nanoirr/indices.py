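"""The 11 irregularity index forms and their evaluation.

Every index here is edge-additive: ``value = prefactor * sum over edges of
c(w_u, w_v)`` where ``c`` is a symmetric, non-negative per-edge contribution
with ``c(x, x) = 0``, and the weights are either vertex degrees or
neighborhood degree sums. Because the contribution depends only on the
unordered endpoint-weight pair, any index can be evaluated from an
:class:`~nanoirr.graphs.EdgePartition` alone; evaluating from a graph and
from its partition give identical results (same canonical summation order:
entries sorted by (w_hi, w_lo) descending).

The canonical index order is AL, IRL, IRRT, IRF, IRA, IRDIF, IRLF, LA,
IRDI, IRGA, IRB. Contributions (x = w_u, y = w_v):

========  ====================================  =========
name      contribution                          prefactor
========  ====================================  =========
AL        ``|x - y|``                           1
IRL       ``|ln x - ln y|``                     1
IRRT      ``|x - y|``                           1/2
IRF       ``(x - y)**2``                        1
IRA       ``(x**-0.5 - y**-0.5)**2``            1
IRDIF     ``|x/y - y/x|``                       1
IRLF      ``|x - y| / sqrt(x*y)``               1
LA        ``|x - y| / (x + y)``                 2
IRDI      ``ln(1 + |x - y|)``                   1
IRGA      ``ln((x + y) / (2*sqrt(x*y)))``       1
IRB       ``(sqrt(x) - sqrt(y))**2``            1
========  ====================================  =========

IRGA's contribution is non-negative by the AM-GM inequality. Weights must
be strictly positive for the log/ratio/root forms (IRL, IRA, IRDIF, IRLF,
IRGA, IRB); a zero weight raises :class:`IndexDomainError` naming the index.

Contributions are computed in double precision from exact integer weights;
for exact (symbolic) arithmetic see :mod:`nanoirr.closed_forms`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Callable, Optional, Union

import networkx as nx
import sympy as sp

from nanoirr.graphs import (
    EdgePartition,
    VertexWeighting,
    degree_weights,
    edge_partition,
    neighborhood_weights,
)

__all__ = [
    "IndexDomainError",
    "IndexDefinition",
    "IndexValue",
    "INDEX_ORDER",
    "INDICES",
    "evaluate_index",
    "evaluate_graph",
    "evaluate_all",
]


class IndexDomainError(ValueError):
    """A weight outside an index contribution's domain (e.g. log of 0)."""


@dataclass(frozen=True)
class IndexDefinition:
    """One irregularity form: a symmetric per-edge contribution and a
    rational prefactor (1 for all forms except IRRT = 1/2 and LA = 2)."""

    name: str
    contribution: Callable[[float, float], float]
    symbolic: Callable[[int, int], sp.Expr]
    prefactor: Fraction = Fraction(1)
    strict_positive: bool = False  # reject zero weights (log/ratio/root forms)

    def term(self, x: float, y: float) -> float:
        if self.strict_positive and (x <= 0 or y <= 0):
            raise IndexDomainError(
                f"{self.name}: weight pair ({x}, {y}) outside domain "
                "(weights must be strictly positive)"
            )
        if x < 0 or y < 0:
            raise IndexDomainError(f"{self.name}: negative weight in ({x}, {y})")
        return self.contribution(x, y)


def _sym(hi: int, lo: int) -> tuple[sp.Expr, sp.Expr]:
    return sp.Integer(hi), sp.Integer(lo)


INDICES: dict[str, IndexDefinition] = {
    "AL": IndexDefinition(
        "AL",
        lambda x, y: abs(x - y),
        lambda hi, lo: sp.Integer(hi - lo),
    ),
    "IRL": IndexDefinition(
        "IRL",
        lambda x, y: abs(math.log(x) - math.log(y)),
        lambda hi, lo: sp.log(sp.Rational(hi, lo)),
        strict_positive=True,
    ),
    "IRRT": IndexDefinition(
        "IRRT",
        lambda x, y: abs(x - y),
        lambda hi, lo: sp.Integer(hi - lo),
        prefactor=Fraction(1, 2),
    ),
    "IRF": IndexDefinition(
        "IRF",
        lambda x, y: (x - y) ** 2,
        lambda hi, lo: sp.Integer((hi - lo) ** 2),
    ),
    "IRA": IndexDefinition(
        "IRA",
        lambda x, y: (x ** -0.5 - y ** -0.5) ** 2,
        lambda hi, lo: (1 / sp.sqrt(sp.Integer(hi)) - 1 / sp.sqrt(sp.Integer(lo))) ** 2,
        strict_positive=True,
    ),
    "IRDIF": IndexDefinition(
        "IRDIF",
        lambda x, y: abs(x / y - y / x),
        lambda hi, lo: sp.Rational(hi, lo) - sp.Rational(lo, hi),
        strict_positive=True,
    ),
    "IRLF": IndexDefinition(
        "IRLF",
        lambda x, y: abs(x - y) / math.sqrt(x * y),
        lambda hi, lo: (hi - lo) / sp.sqrt(sp.Integer(hi * lo)),
        strict_positive=True,
    ),
    "LA": IndexDefinition(
        "LA",
        lambda x, y: abs(x - y) / (x + y),
        lambda hi, lo: sp.Rational(hi - lo, hi + lo),
        prefactor=Fraction(2),
    ),
    "IRDI": IndexDefinition(
        "IRDI",
        lambda x, y: math.log(1 + abs(x - y)),
        lambda hi, lo: sp.log(sp.Integer(1 + hi - lo)),
    ),
    "IRGA": IndexDefinition(
        "IRGA",
        lambda x, y: math.log((x + y) / (2.0 * math.sqrt(x * y))),
        lambda hi, lo: sp.log(sp.Rational(hi + lo, 2) / sp.sqrt(sp.Integer(hi * lo))),
        strict_positive=True,
    ),
    "IRB": IndexDefinition(
        "IRB",
        lambda x, y: (math.sqrt(x) - math.sqrt(y)) ** 2,
        lambda hi, lo: (sp.sqrt(sp.Integer(hi)) - sp.sqrt(sp.Integer(lo))) ** 2,
        strict_positive=True,
    ),
}

#: Canonical evaluation/reporting order.
INDEX_ORDER: tuple[str, ...] = (
    "AL", "IRL", "IRRT", "IRF", "IRA", "IRDIF", "IRLF", "LA", "IRDI", "IRGA", "IRB",
)


@dataclass(frozen=True)
class IndexValue:
    """Result of evaluating one index under one weighting.

    ``value`` is non-negative and is 0 whenever all edge endpoint weights
    are equal; ``error`` carries a domain-error message when the index
    could not be evaluated (then ``value`` is NaN).
    """

    name: str
    weighting: str
    value: float
    error: Optional[str] = None


def _resolve_index(idx: Union[str, IndexDefinition]) -> IndexDefinition:
    if isinstance(idx, IndexDefinition):
        return idx
    try:
        return INDICES[idx]
    except KeyError:
        raise KeyError(f"unknown index {idx!r}; expected one of {INDEX_ORDER}") from None


def evaluate_index(
    part: EdgePartition, idx: Union[str, IndexDefinition]
) -> IndexValue:
    """Evaluate one irregularity index from an edge partition.

    The value is ``prefactor * sum over classes of frequency * c(hi, lo)``,
    summed over entries sorted by (hi, lo) descending.
    """
    d = _resolve_index(idx)
    acc = 0.0
    for (hi, lo), freq in part.sorted_entries():
        if freq:
            acc += freq * d.term(hi, lo)
    return IndexValue(d.name, part.weighting, float(d.prefactor) * acc)


def _weights_for(g: nx.Graph, weighting: str) -> VertexWeighting:
    if weighting == "degree":
        return degree_weights(g)
    if weighting == "neighborhood":
        return neighborhood_weights(g)
    raise ValueError(
        f"unknown weighting {weighting!r}; expected 'degree' or 'neighborhood'"
    )


def evaluate_graph(
    g: nx.Graph,
    idx: Union[str, IndexDefinition],
    weighting: str = "neighborhood",
) -> IndexValue:
    """Evaluate one index on a graph (via its edge partition)."""
    return evaluate_index(edge_partition(g, _weights_for(g, weighting)), idx)


def evaluate_all(
    source: Union[nx.Graph, EdgePartition], weighting: str = "neighborhood"
) -> list[IndexValue]:
    """All 11 indices in canonical order.

    ``source`` may be a graph or a ready edge partition. Domain errors are
    captured per index (value NaN, message in ``error``) so the remaining
    indices are still computed.
    """
    if isinstance(source, EdgePartition):
        part = source
    else:
        part = edge_partition(source, _weights_for(source, weighting))
    out: list[IndexValue] = []
    for name in INDEX_ORDER:
        try:
            out.append(evaluate_index(part, name))
        except IndexDomainError as exc:
            out.append(IndexValue(name, part.weighting, float("nan"), str(exc)))
    return out
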