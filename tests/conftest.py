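"""Shared fixtures and the independent edge-loop oracle.

The oracle evaluates every index by looping over the graph's edges with the
formulas written out directly (no partition, no shared code with the engine
under test), so graph-vs-partition equivalence checks are a genuine
dual-route comparison.
"""

import math

import networkx as nx
import pytest

PREFACTOR = {name: 1.0 for name in
             ("AL", "IRL", "IRF", "IRA", "IRDIF", "IRLF", "IRDI", "IRGA", "IRB")}
PREFACTOR["IRRT"] = 0.5
PREFACTOR["LA"] = 2.0

_FORMULA = {
    "AL": lambda x, y: abs(x - y),
    "IRL": lambda x, y: abs(math.log(x) - math.log(y)),
    "IRRT": lambda x, y: abs(x - y),
    "IRF": lambda x, y: (x - y) ** 2,
    "IRA": lambda x, y: (1 / math.sqrt(x) - 1 / math.sqrt(y)) ** 2,
    "IRDIF": lambda x, y: abs(x / y - y / x),
    "IRLF": lambda x, y: abs(x - y) / math.sqrt(x * y),
    "LA": lambda x, y: abs(x - y) / (x + y),
    "IRDI": lambda x, y: math.log(1 + abs(x - y)),
    "IRGA": lambda x, y: math.log((x + y) / (2 * math.sqrt(x * y))),
    "IRB": lambda x, y: (math.sqrt(x) - math.sqrt(y)) ** 2,
}


def naive_index(g: nx.Graph, name: str, weighting: str = "neighborhood") -> float:
    """Direct edge-loop evaluation, independent of the package's engine."""
    if weighting == "degree":
        w = dict(g.degree())
    else:
        w = {v: sum(g.degree(u) for u in g[v]) for v in g}
    f = _FORMULA[name]
    return PREFACTOR[name] * sum(f(w[u], w[v]) for u, v in g.edges())


@pytest.fixture
def c5():
    return nx.cycle_graph(5)


@pytest.fixture
def p4():
    return nx.path_graph(4)


@pytest.fixture
def star3():
    return nx.star_graph(3)  # K1,3


@pytest.fixture(scope="session")
def hac5c7_22():
    from nanoirr import build_hac5c7

    return build_hac5c7(2, 2)


@pytest.fixture(scope="session")
def hac5c6c7_22():
    from nanoirr import build_hac5c6c7

    return build_hac5c6c7(2, 2)
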