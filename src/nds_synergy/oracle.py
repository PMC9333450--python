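"""Brute-force verification of the diagonal design's correctness.

The diagonal design's guarantee — that sampling each subset only along its
equal-normalized-concentration diagonal still finds the exact MECI — rests
on the *absence of paradoxical growth*: along any ray x0 + c*x in
concentration space, once the response has started to fall it may not rise
again (rise-then-fall hyperantagonism is allowed; fall-then-rise Eagle-type
recovery is not).

This module checks both halves empirically:

* :func:`full_factorial_meci` solves the MECI optimization by exhaustive
  enumeration over the full checkerboard grid, with no monotonicity
  assumption — the independent oracle.
* :func:`check_nonparadoxical` scans sampled rays for fall-then-rise
  violations.
* :func:`verify_theorem` computes every subset's MECI both ways (diagonal
  design vs full factorial) and reports agreement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations, product
from typing import Callable, Iterable, Iterator, Sequence

import numpy as np

from .design import DilutionLadder
from .errors import InvalidParameterError
from .panel import DrugPanel
from .scoring import (
    NOT_FOUND,
    ConcentrationVector,
    _NotFound,
    meci_from_nds,
    subset_key,
)
from .simulate import ResponseSurface, diagonal_effectiveness, response

GRID_WARN_SIZE = 10**6


@dataclass(frozen=True)
class FullFactorialGrid:
    """The checkerboard grid: per-drug nonzero level sets plus zero.

    Points are enumerated lazily; the grid over a subset S has
    (len(levels)+1)^|S| points (including the all-zero point).
    """

    panel: DrugPanel
    levels: dict[str, tuple[float, ...]]

    @classmethod
    def from_ladder(cls, panel: DrugPanel, ladder: DilutionLadder) -> "FullFactorialGrid":
        """Grid whose levels are the ladder ratios times each drug's N_i,
        so design and oracle optimize over comparable level sets."""
        norms = panel.normalizations()
        return cls(
            panel=panel,
            levels={n: tuple(c * norms[n] for c in ladder.ratios) for n in panel.names},
        )

    def size(self, subset: Iterable[str] | None = None) -> int:
        names = list(subset) if subset is not None else list(self.panel.names)
        out = 1
        for n in names:
            out *= len(self.levels[n]) + 1
        return out

    def iter_points(self, subset: Iterable[str] | None = None) -> Iterator[dict[str, float]]:
        names = [n for n in self.panel.names if subset is None or n in set(subset)]
        axes = [self.levels[n] + (0.0,) for n in names]
        zeros = {n: 0.0 for n in self.panel.names}
        for combo in product(*axes):
            point = dict(zeros)
            point.update(dict(zip(names, combo)))
            yield point


def full_factorial_meci(
    effectiveness_oracle: Callable[[dict[str, float]], bool],
    panel: DrugPanel,
    grid: FullFactorialGrid,
    subset: Iterable[str],
) -> float | _NotFound:
    """Exact MECI of ``subset`` by exhaustive enumeration of the grid.

    Minimizes max_i x_i/N_i over every effective grid point with support
    inside the subset; makes no monotonicity assumption. Returns NOT_FOUND
    when no point is effective.
    """
    target = set(subset)
    if not target:
        raise InvalidParameterError("subset must be nonempty")
    if grid.size(target) > GRID_WARN_SIZE:
        import warnings

        warnings.warn(
            f"full-factorial grid has {grid.size(target)} points; this may be slow",
            stacklevel=2,
        )
    norms = panel.normalizations()
    best: float | None = None
    for point in grid.iter_points(target):
        support = [n for n in target if point[n] > 0]
        if not support:
            continue
        m = max(point[n] / norms[n] for n in support)
        if best is not None and m >= best:
            continue  # cannot improve; skip the oracle call
        if effectiveness_oracle(point):
            best = m
    return NOT_FOUND if best is None else best


@dataclass
class RayCheckResult:
    """Outcome of a fall-then-rise scan along one ray x0 + c*x."""

    background: ConcentrationVector
    direction: ConcentrationVector
    scalars: tuple[float, ...]
    responses: tuple[float, ...]
    violations: list[tuple[int, int, int]]  # index triples i < j < k
    tolerance: float

    @property
    def ok(self) -> bool:
        return not self.violations


def check_nonparadoxical(
    scalars: Sequence[float],
    responses: Sequence[float],
    tolerance: float = 0.0,
    background: ConcentrationVector | None = None,
    direction: ConcentrationVector | None = None,
) -> RayCheckResult:
    """Flag paradoxical (fall-then-rise) behaviour along a sampled ray.

    A triple i < j < k is a violation when r_j < r_i - tolerance and
    r_k > r_j + tolerance: the response dropped and later recovered. An
    empty violation list means the samples are consistent with
    non-paradoxical growth at the given tolerance.
    """
    c = np.asarray(scalars, dtype=float)
    r = np.asarray(responses, dtype=float)
    if c.size != r.size:
        raise InvalidParameterError("scalars and responses must have equal length")
    if c.size < 3:
        raise InvalidParameterError("need at least 3 points along the ray")
    if np.any(np.diff(c) <= 0):
        raise InvalidParameterError("ray scalars must be strictly increasing")
    violations: list[tuple[int, int, int]] = []
    running_max = r[0]
    argmax = 0
    for j in range(1, c.size - 1):
        if running_max - r[j] > tolerance:
            after = r[j + 1 :]
            rises = np.nonzero(after - r[j] > tolerance)[0]
            if rises.size:
                violations.append((argmax, j, j + 1 + int(rises[0])))
        if r[j] > running_max:
            running_max = r[j]
            argmax = j
    zero = ConcentrationVector({})
    return RayCheckResult(
        background=background or zero,
        direction=direction or zero,
        scalars=tuple(c.tolist()),
        responses=tuple(r.tolist()),
        violations=violations,
        tolerance=tolerance,
    )


def ray_responses(
    surface: ResponseSurface,
    background: dict[str, float],
    direction: dict[str, float],
    scalars: Sequence[float],
) -> list[float]:
    """Responses of a surface along x0 + c*x for each scalar c."""
    names = surface.panel.names
    return [
        response(
            surface,
            {n: background.get(n, 0.0) + c * direction.get(n, 0.0) for n in names},
        )
        for c in scalars
    ]


def random_ray_checks(
    surface: ResponseSurface,
    n_rays: int = 100,
    n_points: int = 50,
    seed: int = 0,
    tolerance: float = 0.0,
) -> list[RayCheckResult]:
    """Scan random (background, direction) rays for paradoxical growth.

    Backgrounds are drawn up to one normalization unit of a random drug
    subset; directions are random nonnegative combinations; each ray is
    sampled at ``n_points`` scalars spanning several dilution ranges.
    """
    rng = np.random.default_rng(seed)
    panel = surface.panel
    names = panel.names
    norms = panel.normalizations()
    out = []
    scalars = np.linspace(0.0, 2.0, n_points)[1:]  # strictly increasing, c > 0
    scalars = np.concatenate([[0.0], scalars])
    for _ in range(n_rays):
        bg_mask = rng.random(len(names)) < 0.5
        x0 = {
            n: (rng.uniform(0.0, norms[n]) if keep else 0.0)
            for n, keep in zip(names, bg_mask)
        }
        dir_mask = rng.random(len(names)) < 0.7
        if not dir_mask.any():
            dir_mask[rng.integers(len(names))] = True
        x = {
            n: (rng.uniform(0.1, 2.0) * norms[n] if keep else 0.0)
            for n, keep in zip(names, dir_mask)
        }
        rs = ray_responses(surface, x0, x, scalars)
        out.append(
            check_nonparadoxical(
                scalars,
                rs,
                tolerance=tolerance,
                background=ConcentrationVector(x0),
                direction=ConcentrationVector(x),
            )
        )
    return out


def verify_theorem(
    surface: ResponseSurface,
    ladder: DilutionLadder,
    threshold: float,
    closure: str = "closure",
) -> dict:
    """Compare diagonal-design MECI with the brute-force MECI for every subset.

    The diagonal route scores noiseless effectiveness calls on the subset
    diagonals; the oracle enumerates the full checkerboard built from the
    same ladder levels. On a non-paradoxical (monotone-mode) surface the two
    must agree exactly on every subset; a paradoxical surface can hide its
    effective dip region from the diagonal design.
    """
    panel = surface.panel
    table = diagonal_effectiveness(surface, ladder, threshold)
    grid = FullFactorialGrid.from_ladder(panel, ladder)

    def oracle(point: dict[str, float]) -> bool:
        return response(surface, point) <= threshold

    report: dict = {"subsets": {}, "all_agree": True, "n_subsets": 0, "n_agree": 0}
    for k in range(1, len(panel) + 1):
        for subset in combinations(panel.names, k):
            nds_val = meci_from_nds(table, subset, panel, closure=closure).meci
            ff_val = full_factorial_meci(oracle, panel, grid, subset)
            if nds_val is NOT_FOUND or ff_val is NOT_FOUND:
                agree = nds_val is ff_val
            else:
                agree = math.isclose(float(nds_val), float(ff_val), rel_tol=1e-9)
            key = subset_key(subset, panel)
            report["subsets"][key] = {
                "nds": repr(NOT_FOUND) if nds_val is NOT_FOUND else float(nds_val),
                "full_factorial": repr(NOT_FOUND) if ff_val is NOT_FOUND else float(ff_val),
                "agree": bool(agree),
            }
            report["n_subsets"] += 1
            report["n_agree"] += int(agree)
            report["all_agree"] = report["all_agree"] and agree
    return report
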