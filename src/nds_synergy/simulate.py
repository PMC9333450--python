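"""Ground-truth dose-response surfaces and synthetic plate-reader data.

The generative family is a pooled-Hill surface. An *effective dose*

    E(x) = (sum_i (x_i / D_i)^p)^(1/p)  +  sum_S beta_S prod_{i in S} x_i / D_i

pools the per-drug dose fractions (p = 1 is Loewe-like additivity, large p
approaches highest-single-agent pooling) and the optional beta_S terms
inject *emergent* synergy for chosen drug subsets. The measured response is
a transform of E:

* ``monotone``          r = r0 / (1 + E^h) — nonincreasing along every ray
  from every background, so non-paradoxical by construction.
* ``hyperantagonistic`` r first rises (linearly to a peak at E = e0) and
  then declines by a Hill law — a unimodal transform of a coordinatewise
  nondecreasing E, so still non-paradoxical (rise-then-fall is allowed).
* ``paradoxical``       the monotone response times a Gaussian recovery
  bump 1 + a*exp(-((E - e0)/w)^2) centred beyond the initial decline —
  an Eagle-effect-like dip-then-rise that violates non-paradoxical growth.

Synthetic OD600 readings follow a fixed logistic shape over 24 h at 15-min
cadence whose carrying capacity above background scales with r(x)/r0, plus
additive Gaussian noise; the noiseless AUGC is therefore strictly
increasing in r(x).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .design import DilutionLadder, NDSDesign
from .errors import InvalidParameterError
from .growth import EffectivenessTable, EffectivenessThreshold, GrowthCurve
from .panel import DrugPanel
from .scoring import ConcentrationVector, subset_key

MODES = ("monotone", "hyperantagonistic", "paradoxical")


@dataclass(frozen=True)
class ResponseSurface:
    """A multi-drug dose-response surface with known ground truth.

    Parameters
    ----------
    panel : DrugPanel
    half_effect_doses : mapping drug name -> D_i (ug/mL, > 0)
        Dose at which a single drug alone reaches E = 1 (half the baseline
        response in monotone mode with any Hill slope).
    hill : float
        Hill steepness h > 0 of the response transform.
    pool_exponent : float
        p > 0; 1 = Loewe-like additive pooling, large = HSA-like max pooling.
    interaction_terms : mapping frozenset[str] -> float
        beta_S >= 0 per drug subset; positive values create emergent synergy
        for S (the subset becomes effective at lower doses than its parts
        predict).
    baseline : float
        r0 > 0, the uninhibited response in AUGC units (OD*hours).
    mode : {"monotone", "hyperantagonistic", "paradoxical"}
    bump_amplitude, bump_center, bump_width :
        Shape parameters shared by the non-monotone modes: the peak height
        a, its location e0 on the E axis, and (paradoxical mode only) the
        Gaussian width w.
    """

    panel: DrugPanel
    half_effect_doses: dict[str, float]
    hill: float = 2.0
    pool_exponent: float = 1.0
    interaction_terms: dict[frozenset, float] = field(default_factory=dict)
    baseline: float = 6.0
    mode: str = "monotone"
    bump_amplitude: float = 1.5
    bump_center: float = 3.0
    bump_width: float = 0.6

    def __post_init__(self):
        if self.mode not in MODES:
            raise InvalidParameterError(f"unknown mode {self.mode!r}")
        if not (self.hill > 0 and self.pool_exponent > 0 and self.baseline > 0):
            raise InvalidParameterError("hill, pool_exponent and baseline must be > 0")
        for n in self.panel.names:
            if n not in self.half_effect_doses:
                raise InvalidParameterError(f"missing half-effect dose for {n}")
            if not (self.half_effect_doses[n] > 0):
                raise InvalidParameterError(f"half-effect dose for {n} must be > 0")
        if any(b < 0 for b in self.interaction_terms.values()):
            raise InvalidParameterError("interaction coefficients must be >= 0")
        object.__setattr__(
            self,
            "interaction_terms",
            {frozenset(k): float(v) for k, v in self.interaction_terms.items()},
        )

    # -- effective dose -------------------------------------------------

    def effective_dose(self, x: ConcentrationVector | Mapping[str, float]) -> float:
        conc = x.concentrations if isinstance(x, ConcentrationVector) else x
        fracs = {n: conc.get(n, 0.0) / self.half_effect_doses[n] for n in self.panel.names}
        p = self.pool_exponent
        pooled = sum(f**p for f in fracs.values() if f > 0) ** (1.0 / p) if any(
            f > 0 for f in fracs.values()
        ) else 0.0
        inter = 0.0
        for s, beta in self.interaction_terms.items():
            prod = 1.0
            for n in s:
                prod *= fracs.get(n, 0.0)
            inter += beta * prod
        return pooled + inter


def response(surface: ResponseSurface, x: ConcentrationVector | Mapping[str, float]) -> float:
    """Response r(x) of the surface at concentration vector x."""
    conc = x.concentrations if isinstance(x, ConcentrationVector) else x
    if any(v < 0 for v in conc.values()):
        raise InvalidParameterError("concentrations must be >= 0")
    e = surface.effective_dose(x)
    r0, h = surface.baseline, surface.hill
    if surface.mode == "monotone":
        return r0 / (1.0 + e**h)
    if surface.mode == "hyperantagonistic":
        a, e0 = surface.bump_amplitude, surface.bump_center
        if e <= e0:
            return r0 * (1.0 + a * e / e0)
        return r0 * (1.0 + a) / (1.0 + (e - e0) ** h)
    # paradoxical (Eagle-effect-like recovery)
    a, e0, w = surface.bump_amplitude, surface.bump_center, surface.bump_width
    return r0 / (1.0 + e**h) * (1.0 + a * np.exp(-(((e - e0) / w) ** 2)))


def ground_truth_effectiveness(
    surface: ResponseSurface, x: ConcentrationVector | Mapping[str, float], t: float
) -> bool:
    """True when the noiseless response falls at or below the threshold t."""
    return response(surface, x) <= t


def diagonal_effectiveness(
    surface: ResponseSurface, ladder: DilutionLadder, t: float
) -> EffectivenessTable:
    """Noiseless NDS effectiveness calls for every subset diagonal.

    The measure recorded is the response itself; this is the table the
    brute-force theorem checks score, bypassing the growth-curve layer.
    """
    from itertools import combinations

    panel = surface.panel
    norms = panel.normalizations()
    rows = []
    for k in range(1, len(panel) + 1):
        for subset in combinations(panel.names, k):
            key = subset_key(subset, panel)
            for j, c in enumerate(ladder.ratios, start=1):
                x = {n: (c * norms[n] if n in subset else 0.0) for n in panel.names}
                r = response(surface, x)
                rows.append((key, j, c, r, r <= t, 1))
    df = pd.DataFrame(
        rows,
        columns=["subset", "step_index", "ratio", "measure_value", "effective", "n_replicates"],
    )
    return EffectivenessTable(df, EffectivenessThreshold("AUGC", t), "mean")


def random_monotone_surface(
    panel: DrugPanel,
    rng: np.random.Generator,
    interaction_probability: float = 0.5,
    max_interaction: float = 20.0,
) -> ResponseSurface:
    """Draw a random monotone pooled-Hill surface for property checks.

    Half-effect doses are placed between 2^-4 and 2^1 times each drug's
    normalization so singles cross effectiveness inside (or just outside) a
    typical two-fold ladder; Hill slope, pooling exponent and an optional
    random emergent-synergy term are drawn broadly.
    """
    norms = panel.normalizations()
    d_i = {n: norms[n] * 2.0 ** rng.uniform(-4.0, 1.0) for n in panel.names}
    inter: dict[frozenset, float] = {}
    if len(panel) >= 2 and rng.random() < interaction_probability:
        size = int(rng.integers(2, len(panel) + 1))
        subset = frozenset(rng.choice(panel.names, size=size, replace=False).tolist())
        inter[subset] = float(rng.uniform(0.0, max_interaction))
    return ResponseSurface(
        panel=panel,
        half_effect_doses=d_i,
        hill=float(rng.uniform(1.0, 4.0)),
        pool_exponent=float(rng.uniform(1.0, 8.0)),
        interaction_terms=inter,
        baseline=6.0,
        mode="monotone",
    )


@dataclass
class SimulatedDataset:
    """Synthetic plate-reader dataset with its noiseless ground truth."""

    design: NDSDesign
    readings: list[GrowthCurve]
    truth: pd.DataFrame  # subset, step_index, ratio, response, effective
    seed: int
    noise_sd: float


# fixed logistic shape shared by all wells: midpoint 8 h, timescale 1.5 h
_T_MID_H = 8.0
_TAU_H = 1.5
_K_MAX = 0.5  # OD span of an uninhibited well above background
_BACKGROUND = 0.05


def synthesize_readings(
    surface: ResponseSurface,
    design: NDSDesign,
    noise_sd: float = 0.01,
    seed: int = 0,
    threshold: float | None = None,
    window_hours: float = 24.0,
    cadence_min: float = 15.0,
) -> SimulatedDataset:
    """Generate OD600 growth curves for every point of a design.

    Each well follows ``od(t) = background + (r(x)/r0) * K * logistic(t)``
    with additive Gaussian noise of standard deviation ``noise_sd``; the
    noiseless AUGC is strictly increasing in the surface response r(x).
    ``threshold`` (response units) fills the truth table's effectiveness
    column; default is half the baseline.
    """
    if noise_sd < 0:
        raise InvalidParameterError("noise_sd must be >= 0")
    if threshold is None:
        threshold = surface.baseline / 2.0
    rng = np.random.default_rng(seed)
    times = np.arange(0.0, window_hours * 60.0 + 0.5 * cadence_min, cadence_min)
    hours = times / 60.0
    shape = 1.0 / (1.0 + np.exp(-(hours - _T_MID_H) / _TAU_H))
    shape = shape - shape[0]  # start exactly at background
    readings: list[GrowthCurve] = []
    truth_rows = {}
    for point in design.points:
        r = response(surface, point.concentrations)
        od = _BACKGROUND + (r / surface.baseline) * _K_MAX * shape
        if noise_sd > 0:
            od = od + rng.normal(0.0, noise_sd, size=od.shape)
        readings.append(
            GrowthCurve(
                times=times.copy(),
                od=od,
                plate=point.plate,
                well=point.well,
                background=_BACKGROUND,
            )
        )
        key = subset_key(point.subset, design.panel)
        ratio = design.ladder.ratio(point.step_index) if point.step_index else 0.0
        truth_rows[(key, point.step_index, ratio)] = (r, r <= threshold)
    truth = pd.DataFrame(
        [
            (k[0], k[1], k[2], v[0], v[1])
            for k, v in truth_rows.items()
        ],
        columns=["subset", "step_index", "ratio", "response", "effective"],
    )
    return SimulatedDataset(
        design=design, readings=readings, truth=truth, seed=seed, noise_sd=noise_sd
    )


def eagle_demo_surface(panel: DrugPanel) -> ResponseSurface:
    """A fixed paradoxical (Eagle-effect) surface that defeats the diagonal design.

    Half-effect doses sit at half each drug's normalization and a strong
    narrow recovery bump is centred at twice the half-effect dose, so every
    diagonal crosses an effective dip that recovers above threshold before
    the top tested ratio. The diagonal design's monotone reading then skips
    the dip that the full-factorial oracle finds, and paradox scans flag the
    fall-then-rise rays.
    """
    norms = panel.normalizations()
    return ResponseSurface(
        panel=panel,
        half_effect_doses={n: 0.5 * norms[n] for n in panel.names},
        hill=4.0,
        pool_exponent=1.0,
        mode="paradoxical",
        bump_amplitude=30.0,
        bump_center=2.0,
        bump_width=0.3,
    )


def injected_pair_synergy_surface(
    panel: DrugPanel,
    pair: tuple[str, str],
    threshold_frac: float = 0.1,
    hill: float = 4.0,
    pool_exponent: float = 6.0,
    margin: float = 1.1,
) -> ResponseSurface:
    """Monotone surface where exactly one drug pair is emergently synergistic.

    Singles cross the effectiveness threshold (a ``threshold_frac`` fraction
    of the uninhibited response) just below the top ladder ratio, and an
    interaction term makes the given pair's diagonal effective at one
    quarter of that ratio — a 4-fold emergent synergy (ESS = 0.25) with all
    other subsets inheriting, not improving on, their parts.
    """
    if not (0 < threshold_frac < 1):
        raise InvalidParameterError("threshold_frac must be in (0, 1)")
    a, b = pair
    norms = panel.normalizations()
    # E value at which r/r0 crosses threshold_frac
    e_t = (1.0 / threshold_frac - 1.0) ** (1.0 / hill)
    # singles reach e_t at 0.7x the top ratio (margin against noise)
    doses = {n: 0.7 * norms[n] / e_t for n in panel.names}
    frac_quarter = 0.25 * e_t / 0.7  # per-drug dose fraction at ratio 1/4
    pooled_quarter = frac_quarter * 2.0 ** (1.0 / pool_exponent)
    beta = (margin * e_t - pooled_quarter) / frac_quarter**2
    return ResponseSurface(
        panel=panel,
        half_effect_doses=doses,
        hill=hill,
        pool_exponent=pool_exponent,
        interaction_terms={frozenset({a, b}): beta},
        mode="monotone",
    )
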