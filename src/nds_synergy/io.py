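"""Delimited-text readers and writers for every pipeline artifact.

All files are comma-separated UTF-8 with a required header row and decimal
points; concentrations are serialized with up to 10 significant digits so
two-fold dilution chains survive a round trip to within matching tolerance.
Schema violations raise :class:`~nds_synergy.errors.SchemaError` naming the
offending column, and malformed rows are reported with their line numbers.
"""

from __future__ import annotations

import csv
import json
import math
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .design import DesignPoint, DilutionLadder, NDSDesign
from .errors import SchemaError
from .growth import EffectivenessTable, EffectivenessThreshold, GrowthCurve
from .panel import DrugPanel
from .scoring import parse_subset_key, subset_key
from .simulate import SimulatedDataset

_FMT = "%.10g"


def _fmt(x: float) -> str:
    return _FMT % x


def _require_columns(header: Sequence[str], required: Iterable[str], path) -> None:
    missing = [c for c in required if c not in header]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")


# ---------------------------------------------------------------------------
# design files


def write_design(design: NDSDesign, path: str | Path) -> None:
    """One row per design point: plate, well, replicate, subset (ASM codes),
    step_index, then one concentration column per drug (ug/mL)."""
    panel = design.panel
    code = {d.name: d.asm_code for d in panel.drugs}
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(
            ["plate", "well", "replicate", "subset", "step_index"]
            + [code[n] for n in panel.names]
        )
        for p in design.points:
            w.writerow(
                [
                    p.plate,
                    p.well,
                    p.replicate,
                    ";".join(code[n] for n in panel.names if n in p.subset),
                    "" if p.step_index is None else p.step_index,
                ]
                + [_fmt(p.concentrations[n]) for n in panel.names]
            )


def read_design(path: str | Path, panel: DrugPanel) -> NDSDesign:
    """Read a design file back against its panel; round-trip stable."""
    by_code = {d.asm_code: d.name for d in panel.drugs}
    points: list[DesignPoint] = []
    step_ratios: dict[int, float] = {}
    norms = panel.normalizations()
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise SchemaError(f"{path}: empty file")
        _require_columns(
            reader.fieldnames,
            ["plate", "well", "replicate", "subset", "step_index"] + list(panel.asm_codes),
            path,
        )
        for lineno, row in enumerate(reader, start=2):
            try:
                subset = frozenset(by_code[c] for c in row["subset"].split(";") if c)
                step = int(row["step_index"]) if row["step_index"] else None
                conc = {by_code[c]: float(row[c]) for c in panel.asm_codes}
                replicate = int(row["replicate"])
            except (KeyError, ValueError) as exc:
                raise SchemaError(f"{path}: malformed row at line {lineno}: {exc}") from exc
            points.append(
                DesignPoint(
                    subset=subset,
                    step_index=step,
                    concentrations=conc,
                    replicate=replicate,
                    plate=row["plate"],
                    well=row["well"],
                )
            )
            if step is not None and subset:
                any_drug = next(iter(subset))
                step_ratios.setdefault(step, conc[any_drug] / norms[any_drug])
    if not points:
        raise SchemaError(f"{path}: no design points")
    replicates = max(p.replicate for p in points)
    ratios = tuple(step_ratios[j] for j in sorted(step_ratios))
    ladder = DilutionLadder(ratios) if ratios else DilutionLadder((1.0,))
    return NDSDesign(panel=panel, ladder=ladder, points=tuple(points), replicates=replicates)


# ---------------------------------------------------------------------------
# plate-reader readings


def write_readings(curves: Iterable[GrowthCurve], path: str | Path) -> None:
    """Long format: plate, well, time_min, od600."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["plate", "well", "time_min", "od600"])
        for curve in curves:
            for t, od in zip(curve.times, curve.od):
                w.writerow([curve.plate, curve.well, _fmt(t), _fmt(od)])


def read_readings(
    path: str | Path,
    background: float | None = None,
    column_map: dict[str, str] | None = None,
) -> list[GrowthCurve]:
    """Group a long-format readings file into per-well growth curves.

    ``column_map`` renames nonstandard headers onto the expected schema,
    e.g. ``{"OD": "od600", "minutes": "time_min"}`` for external datasets.
    If ``background`` is None each well defaults to its first reading.
    """
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=column_map)
    _require_columns(df.columns, ["plate", "well", "time_min", "od600"], path)
    for col in ("time_min", "od600"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            raise SchemaError(
                f"{path}: non-numeric value in column '{col}' at line {bad[0] + 2}"
            )
        df[col] = coerced
    curves = []
    for (plate, well), grp in df.groupby(["plate", "well"], sort=False):
        grp = grp.sort_values("time_min")
        curves.append(
            GrowthCurve(
                times=grp["time_min"].to_numpy(),
                od=grp["od600"].to_numpy(),
                plate=str(plate),
                well=str(well),
                background=background,
            )
        )
    return curves


# ---------------------------------------------------------------------------
# effectiveness tables


def write_effectiveness(table: EffectivenessTable, path: str | Path, panel: DrugPanel) -> None:
    df = table.data.copy()
    code = {d.name: d.asm_code for d in panel.drugs}
    df["subset"] = [
        ";".join(code[n] for n in panel.names if n in parse_subset_key(s)) for s in df["subset"]
    ]
    df["measure"] = table.threshold.measure
    df["threshold_value"] = table.threshold.value
    df["replicate_rule"] = table.replicate_rule
    df["normalization_label"] = panel.normalization_label
    df.to_csv(path, index=False, float_format=_FMT)


def read_effectiveness(path: str | Path, panel: DrugPanel) -> EffectivenessTable:
    df = pd.read_csv(path, keep_default_na=False, na_values=[""])
    _require_columns(
        df.columns,
        ["subset", "step_index", "ratio", "measure_value", "effective", "n_replicates"],
        path,
    )
    by_code = {d.asm_code: d.name for d in panel.drugs}
    df["subset"] = [
        subset_key([by_code[c] for c in str(s).split(";") if c], panel)
        if not (isinstance(s, float) and math.isnan(s))
        else ""
        for s in df["subset"]
    ]
    if df["effective"].dtype == object:
        df["effective"] = df["effective"].astype(str).str.lower().isin(["true", "1", "yes"])
    measure = str(df["measure"].iloc[0]) if "measure" in df.columns else "AUGC"
    value = float(df["threshold_value"].iloc[0]) if "threshold_value" in df.columns else float("nan")
    rule = str(df["replicate_rule"].iloc[0]) if "replicate_rule" in df.columns else "mean"
    keep = ["subset", "step_index", "ratio", "measure_value", "effective", "n_replicates"]
    return EffectivenessTable(df[keep], EffectivenessThreshold(measure, value), rule)


# ---------------------------------------------------------------------------
# scores, truth, manifests


def write_scores(scores_frame: pd.DataFrame, path: str | Path) -> None:
    scores_frame.to_csv(path, index=False, float_format=_FMT)


def read_scores(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_truth(dataset: SimulatedDataset, path: str | Path, panel: DrugPanel) -> None:
    df = dataset.truth.copy()
    code = {d.name: d.asm_code for d in panel.drugs}
    df["subset"] = [
        ";".join(code[n] for n in panel.names if n in parse_subset_key(s)) for s in df["subset"]
    ]
    df["seed"] = dataset.seed
    df["noise_sd"] = dataset.noise_sd
    df["normalization_label"] = panel.normalization_label
    df.to_csv(path, index=False, float_format=_FMT)


def write_manifest(config: dict, path: str | Path) -> None:
    """Echo every run parameter into a JSON manifest next to the outputs."""
    with open(path, "w") as fh:
        json.dump(config, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")


def read_manifest(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)


# ---------------------------------------------------------------------------
# response-surface configs


def read_surface(path: str | Path, panel: DrugPanel):
    """Read a response-surface YAML (half-effect doses, hill, pooling,
    interaction terms, baseline, mode) against a panel."""
    import yaml

    from .simulate import ResponseSurface

    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "half_effect_doses" not in doc:
        raise SchemaError(f"{path}: surface config must contain 'half_effect_doses'")
    by_code = {d.asm_code: d.name for d in panel.drugs}
    doses = {}
    for key, val in doc["half_effect_doses"].items():
        name = by_code.get(key, key)
        doses[name] = float(val)
    inter = {}
    for key, val in (doc.get("interaction_terms") or {}).items():
        names = frozenset(by_code.get(c, c) for c in str(key).split(";") if c)
        inter[names] = float(val)
    kwargs = {}
    for opt in ("hill", "pool_exponent", "baseline", "bump_amplitude", "bump_center", "bump_width"):
        if opt in doc:
            kwargs[opt] = float(doc[opt])
    return ResponseSurface(
        panel=panel,
        half_effect_doses=doses,
        interaction_terms=inter,
        mode=doc.get("mode", "monotone"),
        **kwargs,
    )


def write_surface(surface, path: str | Path) -> None:
    import yaml

    code = {d.name: d.asm_code for d in surface.panel.drugs}
    doc = {
        "mode": surface.mode,
        "hill": surface.hill,
        "pool_exponent": surface.pool_exponent,
        "baseline": surface.baseline,
        "bump_amplitude": surface.bump_amplitude,
        "bump_center": surface.bump_center,
        "bump_width": surface.bump_width,
        "half_effect_doses": {code[n]: v for n, v in surface.half_effect_doses.items()},
        "interaction_terms": {
            ";".join(sorted(code[n] for n in s)): b for s, b in surface.interaction_terms.items()
        },
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
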