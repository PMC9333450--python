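"""Minimax effective concentration indices and synergy scores.

The minimax concentration (MEC) of a condition x is max_i x_i / N_i over
the drugs present. The MECI of a drug set is the smallest MEC among
*effective* tested conditions with support inside the set; on NDS data this
reduces to the smallest effective diagonal ratio over all subsets. Two
interpretive ratios follow:

* TSS (total synergy score)    = MECI(set) / best singleton MECI,
* ESS (emergent synergy score) = MECI(set) / best proper-subset MECI,

with TSS <= ESS <= 1 whenever both are defined. ESS <= 0.25 is read as
synergy, 0.25 < ESS < 1 as weak synergy, ESS >= 1 as no synergy. A
diagonal-restricted upper bound on the Loewe FICI (sum of fractions of MIC
over effective sampled points) is reported alongside for comparability with
checkerboard studies; it is a bound, not the exact FICI, because NDS does
not sample off-diagonal points.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import IncompleteDesignError, InvalidParameterError
from .growth import EffectivenessTable
from .panel import DrugPanel

logger = logging.getLogger(__name__)


class _NotFound:
    """Sentinel: no tested condition was effective."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self):
        return "NOT_FOUND"

    def __bool__(self):
        return False


NOT_FOUND = _NotFound()

SYNERGY_CUTOFF = 0.25  # inclusive; matches a pairwise FICI cutoff of 0.5 on the diagonal


@dataclass(frozen=True)
class ConcentrationVector:
    """A point in concentration space: per-drug concentrations in ug/mL.

    The *support* is the set of drugs at nonzero concentration.
    """

    concentrations: dict[str, float]

    def __post_init__(self):
        if any(v < 0 for v in self.concentrations.values()):
            raise InvalidParameterError("concentrations must be >= 0")

    @property
    def support(self) -> frozenset[str]:
        return frozenset(n for n, v in self.concentrations.items() if v > 0)

    def __getitem__(self, name: str) -> float:
        return self.concentrations.get(name, 0.0)


@dataclass(frozen=True)
class SynergyScores:
    """All scores for one drug subset."""

    subset: frozenset[str]
    meci: float | _NotFound
    witness: ConcentrationVector | None
    tss: float | None
    ess: float | None
    fici_diagonal_bound: float | None
    classification: str
    normalization_label: str = ""

    @property
    def size(self) -> int:
        return len(self.subset)


def subset_key(subset: Iterable[str], panel: DrugPanel | None = None) -> str:
    """Canonical string key for a drug subset (semicolon-joined, panel order)."""
    names = set(subset)
    if panel is not None:
        ordered = [n for n in panel.names if n in names]
        extra = sorted(names - set(ordered))
        return ";".join(ordered + extra)
    return ";".join(sorted(names))


def parse_subset_key(key: str) -> frozenset[str]:
    return frozenset(s for s in key.split(";") if s)


def mec(x: ConcentrationVector, panel: DrugPanel) -> float:
    """Minimax concentration: max over the support of x_i / N_i."""
    support = x.support
    if not support:
        raise InvalidParameterError("MEC of the all-zero condition is undefined")
    norms = panel.normalizations()
    return max(x[n] / norms[n] for n in support)


def fic(x: ConcentrationVector, panel: DrugPanel) -> float:
    """Summed fraction of MIC, the Loewe FIC of a single condition."""
    mics = panel.mics()
    return sum(x[n] / mics[n] for n in x.support)


def bliss_expected(effects: Sequence[float]) -> float:
    """Bliss-independence expected fractional reduction: 1 - prod(1 - e_i)."""
    effects = list(effects)
    if not effects:
        raise InvalidParameterError("need at least one effect")
    if any(not (0 <= e <= 1) for e in effects):
        raise InvalidParameterError("effects must lie in [0, 1]")
    out = 1.0
    for e in effects:
        out *= 1.0 - e
    return 1.0 - out


def hsa_expected(effects: Sequence[float]) -> float:
    """Highest-single-agent expected reduction: max of the individual effects."""
    effects = list(effects)
    if not effects:
        raise InvalidParameterError("need at least one effect")
    if any(not (0 <= e <= 1) for e in effects):
        raise InvalidParameterError("effects must lie in [0, 1]")
    return max(effects)


def classify(ess_value: float | None) -> str:
    """Interpretive label from an ESS value (None -> indeterminate)."""
    if ess_value is None:
        return "indeterminate"
    if ess_value <= SYNERGY_CUTOFF:
        return "synergy"
    if ess_value < 1.0:
        return "weak synergy"
    return "none"


# ---------------------------------------------------------------------------
# diagonal extraction


def _diagonal_profiles(table: EffectivenessTable) -> dict[frozenset[str], list[tuple[float, bool]]]:
    """Per-subset (ratio, effective) pairs sorted by ascending ratio."""
    profiles: dict[frozenset[str], list[tuple[float, bool]]] = {}
    for subset, grp in table.data.groupby("subset", sort=False):
        names = parse_subset_key(subset)
        if not names:
            continue  # controls carry no diagonal
        pairs = sorted(zip(grp["ratio"].astype(float), grp["effective"].astype(bool)))
        profiles[names] = pairs
    return profiles


def _smallest_effective_ratio(
    pairs: list[tuple[float, bool]], closure: str
) -> tuple[float | None, bool]:
    """Smallest effective ratio along one diagonal and a non-monotone flag.

    ``closure`` (default elsewhere) takes the smallest ratio from which every
    larger tested ratio is also effective — the upward-closed reading implied
    by non-paradoxical growth. ``raw-min`` takes the smallest effective ratio
    regardless of what happens above it.
    """
    if closure not in ("closure", "raw-min"):
        raise InvalidParameterError(f"unknown closure rule {closure!r}")
    flags = [eff for _, eff in pairs]
    # non-monotone: an ineffective ratio above an effective one
    nonmono = any(
        e_lo and not e_hi for (_, e_lo), (_, e_hi) in zip(pairs, pairs[1:])
    ) or any(
        flags[i] and not flags[j] for i in range(len(flags)) for j in range(i + 1, len(flags))
    )
    if closure == "raw-min":
        for ratio, eff in pairs:
            if eff:
                return ratio, nonmono
        return None, nonmono
    best = None
    for ratio, eff in reversed(pairs):  # descending check of the effective suffix
        if not eff:
            break
        best = ratio
    return best, nonmono


def _require_coverage(
    profiles: Mapping[frozenset[str], list], target: frozenset[str]
) -> list[frozenset[str]]:
    subsets = [
        frozenset(c) for k in range(1, len(target) + 1) for c in combinations(sorted(target), k)
    ]
    missing = [s for s in subsets if s not in profiles]
    if missing:
        raise IncompleteDesignError(
            "effectiveness table is missing diagonals for subsets: "
            + ", ".join(";".join(sorted(s)) for s in missing),
            missing=missing,
        )
    return subsets


def meci_from_nds(
    table: EffectivenessTable,
    target_subset: Iterable[str],
    panel: DrugPanel,
    closure: str = "closure",
) -> SynergyScores:
    """MECI of a drug set from NDS effectiveness calls, with its witness.

    The MECI is the minimum, over every nonempty subset of the target, of
    that subset's smallest effective diagonal ratio. Returns a
    :class:`SynergyScores` carrying only ``meci`` and ``witness`` (TSS/ESS
    are filled by :func:`score_all_subsets`).
    """
    target = frozenset(target_subset)
    if not target:
        raise InvalidParameterError("target subset must be nonempty")
    profiles = _diagonal_profiles(table)
    subsets = _require_coverage(profiles, target)
    norms = panel.normalizations()
    best: float | None = None
    best_subset: frozenset[str] | None = None
    for s in subsets:
        ratio, nonmono = _smallest_effective_ratio(profiles[s], closure)
        if nonmono:
            logger.warning(
                "non-monotone effectiveness along diagonal of {%s}: "
                "possible paradoxical growth",
                ";".join(sorted(s)),
            )
        if ratio is not None and (best is None or ratio < best):
            best, best_subset = ratio, s
    if best is None:
        return SynergyScores(
            subset=target,
            meci=NOT_FOUND,
            witness=None,
            tss=None,
            ess=None,
            fici_diagonal_bound=None,
            classification="indeterminate",
            normalization_label=panel.normalization_label,
        )
    witness = ConcentrationVector(
        {n: (best * norms[n] if n in best_subset else 0.0) for n in panel.names}
    )
    return SynergyScores(
        subset=target,
        meci=best,
        witness=witness,
        tss=None,
        ess=None,
        fici_diagonal_bound=None,
        classification="",
        normalization_label=panel.normalization_label,
    )


def tss(meci_map: Mapping[frozenset[str], float | _NotFound], subset: Iterable[str]) -> float | None:
    """Total synergy score: MECI(set) / min singleton MECI.

    Singletons whose MECI is NOT_FOUND are skipped in the denominator; the
    result is undefined (None) if the set's MECI or every singleton MECI is
    NOT_FOUND.
    """
    target = frozenset(subset)
    numer = meci_map.get(target, NOT_FOUND)
    if numer is NOT_FOUND or numer is None:
        return None
    singles = [
        meci_map[frozenset({i})]
        for i in target
        if meci_map.get(frozenset({i}), NOT_FOUND) is not NOT_FOUND
    ]
    if not singles:
        return None
    return float(numer) / float(min(singles))


def ess(meci_map: Mapping[frozenset[str], float | _NotFound], subset: Iterable[str]) -> float | None:
    """Emergent synergy score: MECI(set) / best proper nonempty subset MECI."""
    target = frozenset(subset)
    numer = meci_map.get(target, NOT_FOUND)
    if numer is NOT_FOUND or numer is None:
        return None
    proper = []
    for k in range(1, len(target)):
        for c in combinations(sorted(target), k):
            v = meci_map.get(frozenset(c), NOT_FOUND)
            if v is not NOT_FOUND and v is not None:
                proper.append(v)
    if not proper:
        return None
    return float(numer) / float(min(proper))


def fici_diagonal_bound(
    table: EffectivenessTable, subset: Iterable[str], panel: DrugPanel
) -> float | None:
    """Upper bound on the Loewe FICI from the sampled diagonals.

    Minimum over effective tested points x (the diagonals of every subset of
    the target) of sum_i x_i / MIC_i. The exact FICI would need the full
    factorial; this is only the best value among NDS-sampled points and is
    labelled a bound everywhere it is reported.
    """
    target = frozenset(subset)
    if not target:
        raise InvalidParameterError("target subset must be nonempty")
    mics = panel.mics()
    norms = panel.normalizations()
    best = None
    for s_key, grp in table.data.groupby("subset", sort=False):
        names = parse_subset_key(s_key)
        if not names or not names <= target:
            continue
        weight = sum(norms[n] / mics[n] for n in names)
        for ratio, eff in zip(grp["ratio"].astype(float), grp["effective"].astype(bool)):
            if eff:
                val = ratio * weight
                if best is None or val < best:
                    best = val
    return best


def score_all_subsets(
    table: EffectivenessTable, panel: DrugPanel, closure: str = "closure"
) -> list[SynergyScores]:
    """Score every nonempty subset of the panel from NDS effectiveness calls.

    Computes each subset's MECI (minimum over its own and all contained
    diagonals), then TSS, ESS, the diagonal FICI bound and the interpretive
    classification. Deterministic given its inputs; one row per subset.
    """
    profiles = _diagonal_profiles(table)
    target = frozenset(panel.names)
    _require_coverage(profiles, target)
    names_ordered = [n for n in panel.names]
    norms = panel.normalizations()
    mics = panel.mics()

    # smallest effective ratio per diagonal
    diag: dict[frozenset[str], float | None] = {}
    for s, pairs in profiles.items():
        ratio, nonmono = _smallest_effective_ratio(pairs, closure)
        if nonmono:
            logger.warning(
                "non-monotone effectiveness along diagonal of {%s}: "
                "possible paradoxical growth",
                ";".join(sorted(s)),
            )
        diag[s] = ratio

    # MECI by dynamic programming over the subset lattice
    meci_map: dict[frozenset[str], float | _NotFound] = {}
    witness_map: dict[frozenset[str], frozenset[str] | None] = {}
    all_subsets: list[frozenset[str]] = [
        frozenset(c)
        for k in range(1, len(names_ordered) + 1)
        for c in combinations(names_ordered, k)
    ]
    for s in all_subsets:  # ordered by size, so sub-results exist
        best = diag.get(s)
        best_sub = s if best is not None else None
        for i in s:
            sub = s - {i}
            if not sub:
                continue
            v = meci_map[sub]
            if v is not NOT_FOUND and (best is None or v < best):
                best, best_sub = float(v), witness_map[sub]
        meci_map[s] = NOT_FOUND if best is None else best
        witness_map[s] = best_sub

    out: list[SynergyScores] = []
    for s in all_subsets:
        m = meci_map[s]
        if m is NOT_FOUND:
            out.append(
                SynergyScores(
                    subset=s,
                    meci=NOT_FOUND,
                    witness=None,
                    tss=None,
                    ess=None,
                    fici_diagonal_bound=None,
                    classification="indeterminate",
                    normalization_label=panel.normalization_label,
                )
            )
            continue
        w_sub = witness_map[s]
        witness = ConcentrationVector(
            {n: (m * norms[n] if n in w_sub else 0.0) for n in names_ordered}
        )
        t = tss(meci_map, s)
        e = ess(meci_map, s)
        # FICI bound from the precomputed diagonals (raw effective calls)
        best_fic = None
        for sub, pairs in profiles.items():
            if not sub <= s:
                continue
            weight = sum(norms[n] / mics[n] for n in sub)
            for ratio, eff in pairs:
                if eff:
                    val = ratio * weight
                    if best_fic is None or val < best_fic:
                        best_fic = val
        label = classify(e) if e is not None else ("none" if len(s) == 1 else "indeterminate")
        out.append(
            SynergyScores(
                subset=s,
                meci=m,
                witness=witness,
                tss=t,
                ess=e,
                fici_diagonal_bound=best_fic,
                classification=label,
                normalization_label=panel.normalization_label,
            )
        )
    return out


def scores_to_frame(scores: Sequence[SynergyScores], panel: DrugPanel) -> pd.DataFrame:
    """Tabulate scores: raw and log2 values, witness, classification."""

    def _log2(v):
        return math.log2(v) if isinstance(v, (int, float)) and v is not None and v > 0 else np.nan

    code = {d.name: d.asm_code for d in panel.drugs}
    rows = []
    for s in scores:
        m = None if s.meci is NOT_FOUND else s.meci
        witness_txt = (
            ";".join(
                f"{code[n]}={s.witness[n]:.10g}" for n in panel.names if s.witness[n] > 0
            )
            if s.witness is not None
            else ""
        )
        rows.append(
            {
                "subset": ";".join(code[n] for n in panel.names if n in s.subset),
                "size": s.size,
                "meci": np.nan if m is None else m,
                "log2_meci": _log2(m),
                "tss": np.nan if s.tss is None else s.tss,
                "log2_tss": _log2(s.tss),
                "ess": np.nan if s.ess is None else s.ess,
                "log2_ess": _log2(s.ess),
                "fici_diagonal_bound": (
                    np.nan if s.fici_diagonal_bound is None else s.fici_diagonal_bound
                ),
                "classification": s.classification,
                "witness": witness_txt,
                "normalization_label": s.normalization_label,
            }
        )
    return pd.DataFrame(rows)
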