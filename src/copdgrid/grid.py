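"""Bounded (a, b) grid enumeration, bijectivity verification, inversion.

Because the input domain is a finite integer lattice, the probability
mapping can be checked exhaustively: every cell's prediction is rounded
to a fixed number of decimal places (14 by default, round-half-even) and
injectivity means all rounded keys are distinct. "Surjectivity" is
coverage of the enumerated output set — the operational reading for a
finite domain — and reverse inference looks a probability up in that
set, exactly or to a tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_EVEN, Decimal

from .model import ModelCoefficients, predict_poor_control_probability
from .phenotype import GRID126, GRID21, DomainBounds

__all__ = [
    "RiskCell",
    "CombinationGrid",
    "BijectivityReport",
    "InversionResult",
    "NotInCodomainError",
    "enumerate_grid",
    "verify_bijectivity",
    "invert_probability",
    "grid_to_matrix_text",
    "grid_to_json",
]


class NotInCodomainError(KeyError):
    """The queried probability matches no grid cell (within tolerance)."""


def round_key(pr: float, precision: int) -> str:
    """Decimal string of ``pr`` with exactly ``precision`` fractional digits.

    Rounding is half-even on the decimal expansion of the float.
    """
    q = Decimal(1).scaleb(-precision)
    return str(Decimal(pr).quantize(q, rounding=ROUND_HALF_EVEN))


@dataclass(frozen=True)
class RiskCell:
    a: int
    b: int
    pr: float
    pr_key: str


@dataclass(frozen=True)
class BijectivityReport:
    injective: bool
    surjective_over_codomain: bool
    collisions: tuple[tuple[tuple[int, int], ...], ...]
    distinct_outputs: int
    n_cells: int


@dataclass(frozen=True)
class InversionResult:
    """A reverse lookup result: the matched cell plus match diagnostics."""

    cell: RiskCell
    distance: float
    tie_broken: bool = False

    @property
    def a(self) -> int:
        return self.cell.a

    @property
    def b(self) -> int:
        return self.cell.b


@dataclass(frozen=True)
class CombinationGrid:
    """All (a, b) cells of a bounded domain with their predicted risks.

    Cells are ordered row-major: ascending in ``a``, then in ``b``.
    """

    bounds: DomainBounds
    coeffs: ModelCoefficients
    precision: int
    cells: tuple[RiskCell, ...]
    _by_key: dict = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "_by_key", {c.pr_key: c for c in self.cells}
        )

    def cell(self, a: int, b: int) -> RiskCell:
        idx = a * (self.bounds.b_max + 1) + b
        c = self.cells[idx]
        assert (c.a, c.b) == (a, b)
        return c

    def to_matrix(self):
        """Probabilities as an array with rows = a, columns = b."""
        import numpy as np

        m = np.empty((self.bounds.a_max + 1, self.bounds.b_max + 1))
        for c in self.cells:
            m[c.a, c.b] = c.pr
        return m

    def __len__(self) -> int:
        return len(self.cells)


def enumerate_grid(
    coeffs: ModelCoefficients,
    bounds: DomainBounds = GRID126,
    precision: int = 14,
) -> CombinationGrid:
    """Evaluate the risk equation on every cell of the bounded domain.

    Produces exactly (a_max+1)*(b_max+1) cells — 126 for the
    high-resolution domain, 21 for the streamlined one — each carrying
    the raw probability and its rounded decimal key.
    """
    if not (1 <= precision <= 17):
        raise ValueError(f"precision must lie in [1, 17], got {precision}")
    cells = []
    for a in range(bounds.a_max + 1):
        for b in range(bounds.b_max + 1):
            est = predict_poor_control_probability(coeffs, a, b)
            cells.append(RiskCell(a=a, b=b, pr=est.pr, pr_key=round_key(est.pr, precision)))
    return CombinationGrid(
        bounds=bounds, coeffs=coeffs, precision=precision, cells=tuple(cells)
    )


def verify_bijectivity(grid: CombinationGrid) -> BijectivityReport:
    """Check injectivity of cell -> rounded probability over the grid.

    Collisions are groups of cells sharing a rounded key. Surjectivity is
    reported over the enumerated codomain (the set of outputs actually
    produced), which a finite enumeration covers by construction; the
    distinct-output count quantifies it.
    """
    groups: dict[str, list[tuple[int, int]]] = {}
    for c in grid.cells:
        groups.setdefault(c.pr_key, []).append((c.a, c.b))
    collisions = tuple(
        tuple(v) for v in groups.values() if len(v) > 1
    )
    distinct = len(groups)
    return BijectivityReport(
        injective=not collisions,
        surjective_over_codomain=True,
        collisions=collisions,
        distinct_outputs=distinct,
        n_cells=len(grid.cells),
    )


def invert_probability(
    grid: CombinationGrid, pr_query: float, tolerance: float = 0.0
) -> InversionResult:
    """Reverse inference: map a probability back to its unique (a, b) cell.

    With ``tolerance == 0`` the query is rounded to the grid's precision
    and must match a cell key exactly. With a positive tolerance the
    nearest cell within it is returned; an exact distance tie is broken
    toward the lexicographically smaller (a, b) and flagged.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be nonnegative")
    if tolerance == 0.0:
        key = round_key(pr_query, grid.precision)
        cell = grid._by_key.get(key)
        if cell is None:
            raise NotInCodomainError(
                f"probability {pr_query!r} (key {key}) is not in the "
                "enumerated codomain"
            )
        return InversionResult(cell=cell, distance=abs(cell.pr - pr_query))
    best: list[RiskCell] = []
    best_d = tolerance
    for c in grid.cells:
        d = abs(c.pr - pr_query)
        if d < best_d or (d == best_d and not best):
            best, best_d = [c], d
        elif d == best_d and best:
            best.append(c)
    if not best:
        raise NotInCodomainError(
            f"no cell within {tolerance} of probability {pr_query!r}"
        )
    tie = len(best) > 1
    cell = min(best, key=lambda c: (c.a, c.b))
    return InversionResult(cell=cell, distance=best_d, tie_broken=tie)


def grid_to_matrix_text(grid: CombinationGrid, sep: str = "\t") -> str:
    """Delimited text matrix (rows a, columns b) of rounded probabilities."""
    header = sep.join(["a\\b"] + [str(b) for b in range(grid.bounds.b_max + 1)])
    lines = [header]
    for a in range(grid.bounds.a_max + 1):
        row = [str(a)] + [
            grid.cell(a, b).pr_key for b in range(grid.bounds.b_max + 1)
        ]
        lines.append(sep.join(row))
    return "\n".join(lines) + "\n"


def grid_to_json(grid: CombinationGrid) -> str:
    import json

    return json.dumps(
        {
            "bounds": {"a_max": grid.bounds.a_max, "b_max": grid.bounds.b_max,
                       "name": grid.bounds.name},
            "precision": grid.precision,
            "coefficients_digest": grid.coeffs.digest(),
            "cells": [
                {"a": c.a, "b": c.b, "pr": c.pr, "pr_key": c.pr_key}
                for c in grid.cells
            ],
        },
        indent=2,
    )
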