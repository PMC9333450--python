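"""Normalized diagonal sampling (NDS) designs.

The NDS design tests every nonempty subset of a drug panel only along its
*diagonal*: all drugs in the subset at the same normalized concentration
ratio c_j, with x_i = c_j * N_i. A d-drug screen over a ladder of m - 1
nonzero ratios therefore needs (2^d - 1)(m - 1) drug-containing conditions
plus controls, instead of the m^d conditions of the full-factorial
checkerboard — the saving that makes eight-way screens feasible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from itertools import combinations
from typing import Iterator

import numpy as np

from .errors import InvalidParameterError
from .panel import DrugPanel


@dataclass(frozen=True)
class DilutionLadder:
    """Ordered ladder of normalized concentration ratios c_1 > c_2 > ... > 0.

    Ratios are unitless multiples of each drug's normalization N_i; the
    realized concentrations of drug i are {c_j * N_i}.
    """

    ratios: tuple[float, ...]
    dilution_factor: float = float("nan")

    def __post_init__(self):
        ratios = tuple(float(r) for r in self.ratios)
        if len(ratios) < 1:
            raise InvalidParameterError("ladder needs at least one ratio")
        if any(not (r > 0) for r in ratios):
            raise InvalidParameterError("ladder ratios must be positive")
        if any(a <= b for a, b in zip(ratios, ratios[1:])):
            raise InvalidParameterError("ladder ratios must be strictly decreasing")
        object.__setattr__(self, "ratios", ratios)

    def __len__(self) -> int:
        return len(self.ratios)

    def __iter__(self) -> Iterator[float]:
        return iter(self.ratios)

    def ratio(self, step_index: int) -> float:
        """Ratio c_j for 1-based step index j."""
        return self.ratios[step_index - 1]


@dataclass(frozen=True)
class DesignPoint:
    """One experimental condition: a drug subset at one diagonal step.

    ``subset`` is empty for drug-free controls (``step_index`` is then None).
    Concentrations are ug/mL, keyed by drug name; drugs absent from the
    subset are at 0.
    """

    subset: frozenset[str]
    step_index: int | None
    concentrations: dict[str, float]
    replicate: int = 1
    plate: str = ""
    well: str = ""

    @property
    def is_control(self) -> bool:
        return len(self.subset) == 0


@dataclass(frozen=True)
class NDSDesign:
    """A complete NDS design over a panel and a dilution ladder."""

    panel: DrugPanel
    ladder: DilutionLadder
    points: tuple[DesignPoint, ...]
    replicates: int = 1
    seed: int | None = None

    def __len__(self) -> int:
        return len(self.points)

    def drug_points(self) -> list[DesignPoint]:
        return [p for p in self.points if not p.is_control]

    def control_points(self) -> list[DesignPoint]:
        return [p for p in self.points if p.is_control]


def build_ladder(top_ratio: float, dilution_factor: float, steps: int) -> DilutionLadder:
    """Geometric dilution ladder: c_j = top_ratio * factor^-(j-1), j = 1..steps.

    >>> build_ladder(1, 2, 3).ratios
    (1.0, 0.5, 0.25)
    """
    if not (top_ratio > 0):
        raise InvalidParameterError(f"top_ratio must be > 0, got {top_ratio}")
    if not (dilution_factor > 1):
        raise InvalidParameterError(f"dilution_factor must be > 1, got {dilution_factor}")
    if steps < 1:
        raise InvalidParameterError(f"steps must be >= 1, got {steps}")
    ratios = tuple(top_ratio * dilution_factor ** -(j - 1) for j in range(1, steps + 1))
    return DilutionLadder(ratios, dilution_factor)


def enumerate_nds(panel: DrugPanel, ladder: DilutionLadder, replicates: int = 1) -> NDSDesign:
    """Enumerate the de-duplicated NDS design.

    Every nonempty subset of the panel appears at every ladder step with the
    configured replicate count, plus one drug-free control per replicate:
    (2^d - 1) * steps * replicates drug points + replicates controls.
    """
    if replicates < 1:
        raise InvalidParameterError(f"replicates must be >= 1, got {replicates}")
    names = panel.names
    norms = panel.normalizations()
    points: list[DesignPoint] = []
    for rep in range(1, replicates + 1):
        points.append(
            DesignPoint(
                subset=frozenset(),
                step_index=None,
                concentrations={n: 0.0 for n in names},
                replicate=rep,
            )
        )
    for size in range(1, len(names) + 1):
        for subset in combinations(names, size):
            for j, c in enumerate(ladder.ratios, start=1):
                conc = {n: (c * norms[n] if n in subset else 0.0) for n in names}
                for rep in range(1, replicates + 1):
                    points.append(
                        DesignPoint(
                            subset=frozenset(subset),
                            step_index=j,
                            concentrations=conc,
                            replicate=rep,
                        )
                    )
    return NDSDesign(panel=panel, ladder=ladder, points=tuple(points), replicates=replicates)


def design_size(d: int, m: int) -> tuple[int, int]:
    """Well counts for a d-drug NDS screen with m concentration levels per drug
    (m - 1 nonzero ladder steps; zero is the m-th level).

    Returns ``(formula_count, unique_condition_count)``: the headline
    m * 2^d accounting, which counts the empty subset at every step, and the
    de-duplicated count (m-1)(2^d - 1) + 1 in which those coincident
    drug-free wells collapse to a single control condition.
    """
    if d < 1:
        raise InvalidParameterError(f"d must be >= 1, got {d}")
    if m < 2:
        raise InvalidParameterError(f"m must be >= 2, got {m}")
    return m * 2**d, (m - 1) * (2**d - 1) + 1


def full_factorial_size(d: int, m: int) -> int:
    """Number of conditions m^d in the full-factorial checkerboard."""
    if d < 1:
        raise InvalidParameterError(f"d must be >= 1, got {d}")
    if m < 2:
        raise InvalidParameterError(f"m must be >= 2, got {m}")
    return m**d


def steps_between(a: float, b: float, factor: float = 2.0) -> float:
    """Number of dilution steps from concentration b up to a: log(a/b)/log(factor)."""
    if not (a > 0 and b > 0):
        raise InvalidParameterError("concentrations must be positive")
    if not (factor > 1):
        raise InvalidParameterError("factor must be > 1")
    return math.log(a / b) / math.log(factor)


_ROWS = "ABCDEFGH"


def _well_labels(wells_per_plate: int) -> list[str]:
    # standard 8x12 labels for 96-well plates; generic W1..Wn otherwise
    if wells_per_plate == 96:
        return [f"{r}{c}" for r in _ROWS for c in range(1, 13)]
    return [f"W{k}" for k in range(1, wells_per_plate + 1)]


def randomize_layout(design: NDSDesign, wells_per_plate: int = 96, seed: int = 0) -> NDSDesign:
    """Assign every design point a (plate, well) by uniform random permutation.

    Plates are filled row-major after permuting the points with a
    seed-determined generator, so a fixed seed reproduces the layout exactly.
    """
    if wells_per_plate < 1:
        raise InvalidParameterError("wells_per_plate must be >= 1")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(design.points))
    labels = _well_labels(wells_per_plate)
    placed = list(design.points)
    for slot, idx in enumerate(order):
        plate = f"P{slot // wells_per_plate + 1}"
        well = labels[slot % wells_per_plate]
        placed[idx] = replace(placed[idx], plate=plate, well=well)
    return NDSDesign(
        panel=design.panel,
        ladder=design.ladder,
        points=tuple(placed),
        replicates=design.replicates,
        seed=seed,
    )
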