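"""Comparison grids over (p, q) and printed-table matching.

`run_grid` reproduces the published comparison tables: one row per (p, q)
pair, the 11 neighborhood indices in canonical order. Provenance is either
``"closed-form"`` (exact coefficients from the published partition tables;
works for any p, q >= 1 including the tables' [1,1] row) or ``"graph"``
(build the nanotube and evaluate; requires p, q >= 2 and, for HAC5C6C7,
reflects the realizable partition rather than the unrealizable published
one). Values are full precision; rounding happens only at presentation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from nanoirr.closed_forms import derive_all
from nanoirr.indices import INDEX_ORDER, evaluate_all
from nanoirr.nanotubes import build_nanotube

__all__ = [
    "GridRow",
    "GridReport",
    "run_grid",
    "diagonal_pairs",
    "printed_cell_matches",
]


@dataclass(frozen=True)
class GridRow:
    p: int
    q: int
    values: dict[str, float]


@dataclass(frozen=True)
class GridReport:
    family: str
    provenance: str
    rows: tuple[GridRow, ...]

    def to_dataframe(self) -> pd.DataFrame:
        records = [
            {"family": self.family, "p": r.p, "q": r.q, **r.values}
            for r in self.rows
        ]
        return pd.DataFrame.from_records(
            records, columns=["family", "p", "q", *INDEX_ORDER]
        )

    def to_csv(self, path) -> None:
        # machine CSV always carries full precision (17 significant digits)
        self.to_dataframe().to_csv(path, index=False, float_format="%.17g")

    def format_table(self, decimals: int = 2) -> str:
        """Human table rounded for presentation, mirroring the published
        two-decimal layout."""
        df = self.to_dataframe().drop(columns="family")
        return df.round(decimals).to_string(index=False)

    def series_frame(self) -> pd.DataFrame:
        """Plot-data export: x = grid row index, one series per index."""
        df = self.to_dataframe()
        df.insert(0, "row", range(len(df)))
        return df.drop(columns="family")


def diagonal_pairs(pmax: int) -> list[tuple[int, int]]:
    """[1,1], [2,2], ..., [pmax,pmax] — the published grids' rows."""
    return [(k, k) for k in range(1, pmax + 1)]


def run_grid(
    family: str,
    pairs: Iterable[tuple[int, int]],
    provenance: str = "closed-form",
) -> GridReport:
    """Index values for a family over a list of (p, q) pairs.

    Invalid pairs (p or q < 1; < 2 for graph provenance) are skipped with a
    warning. Graph provenance and closed-form provenance agree to 1e-9
    wherever the family's published partition is graph-realizable (HAC5C7
    everywhere; HAC5C6C7 nowhere with 3 not dividing p — see
    :mod:`nanoirr.nanotubes`).
    """
    if provenance not in ("closed-form", "graph"):
        raise ValueError(f"unknown provenance {provenance!r}")
    rows: list[GridRow] = []
    for p, q in pairs:
        min_pq = 1 if provenance == "closed-form" else 2
        if p < min_pq or q < min_pq:
            warnings.warn(
                f"skipping (p, q) = ({p}, {q}): requires p, q >= {min_pq} "
                f"for {provenance} provenance",
                stacklevel=2,
            )
            continue
        if provenance == "closed-form":
            values = {
                cf.index: cf.pq_coefficient * p * q + cf.p_coefficient * p
                for cf in derive_all(family, "published")
            }
        else:
            g = build_nanotube(family, p, q)
            values = {iv.name: iv.value for iv in evaluate_all(g, "neighborhood")}
        rows.append(GridRow(p, q, values))
    return GridReport(family, provenance, tuple(rows))


def printed_cell_matches(value: float, printed: str, slack: float = 0.01) -> bool:
    """Does a computed value reproduce a printed table cell?

    The printed grids round inconsistently (round-half-up in some cells,
    truncation in others, occasionally a dropped final digit), so a cell is
    accepted when, at its own printed precision, the computed value either
    rounds to it, truncates to it, or lies within ``slack`` of it.
    """
    printed = printed.strip()
    target = float(printed)
    decimals = len(printed.split(".")[1]) if "." in printed else 0
    ulp = 10.0 ** -decimals
    rounded = math.floor(value / ulp + 0.5) * ulp
    truncated = math.floor(value / ulp) * ulp
    return (
        abs(rounded - target) < ulp / 2
        or abs(truncated - target) < ulp / 2
        or abs(value - target) <= slack + 1e-12
    )
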