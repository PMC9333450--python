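"""Drug panels and per-drug normalization constants.

A screen is defined over a panel of ``d`` drugs. Each drug carries its
experimentally determined MIC (minimum inhibitory concentration), an
optional species-level susceptibility breakpoint (e.g. EUCAST), and the
normalization constant ``N_i`` (all in ug/mL) used to place all drugs on a
common concentration scale. The choice of normalization changes the
scientific meaning of a synergy call, so it is recorded as an explicit
label and echoed into every output file.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import yaml

from .errors import InvalidParameterError, SchemaError

_NORMALIZATION_LABELS = ("MIC", "breakpoint", "custom")


@dataclass(frozen=True)
class DrugSpec:
    """One drug: identity, MIC, optional breakpoint, and normalization N_i.

    Parameters
    ----------
    name : str
        Full drug name (unique within a panel).
    mic : float
        Minimum inhibitory concentration, ug/mL, > 0.
    asm_code : str
        ASM-style abbreviation used in file outputs; defaults to ``name``.
    breakpoint : float or None
        Susceptible breakpoint, ug/mL, > 0 if present.
    normalization : float or None
        The constant N_i, ug/mL. If omitted it is resolved from
        ``normalization_label`` (breakpoint if present, else MIC).
    normalization_label : str
        "MIC", "breakpoint" or "custom" — how N_i was chosen.
    """

    name: str
    mic: float
    asm_code: str = ""
    breakpoint: float | None = None
    normalization: float | None = None
    normalization_label: str = ""

    def __post_init__(self):
        if self.mic is None or not (self.mic > 0):
            raise InvalidParameterError(f"{self.name}: mic must be > 0, got {self.mic}")
        if self.breakpoint is not None and not (self.breakpoint > 0):
            raise InvalidParameterError(
                f"{self.name}: breakpoint must be > 0, got {self.breakpoint}"
            )
        if not self.asm_code:
            object.__setattr__(self, "asm_code", self.name)
        # resolve N_i: explicit value wins, else label, else breakpoint-or-MIC
        norm = self.normalization
        label = self.normalization_label
        if norm is None:
            if label == "MIC":
                norm = self.mic
            elif label == "breakpoint":
                if self.breakpoint is None:
                    raise InvalidParameterError(
                        f"{self.name}: breakpoint normalization requested but no breakpoint given"
                    )
                norm = self.breakpoint
            elif label in ("", "custom"):
                if label == "custom":
                    raise InvalidParameterError(
                        f"{self.name}: custom normalization requires an explicit value"
                    )
                norm = self.breakpoint if self.breakpoint is not None else self.mic
                label = "breakpoint" if self.breakpoint is not None else "MIC"
            else:
                raise InvalidParameterError(f"unknown normalization label {label!r}")
        elif not label:
            if math.isclose(norm, self.mic, rel_tol=1e-9):
                label = "MIC"
            elif self.breakpoint is not None and math.isclose(norm, self.breakpoint, rel_tol=1e-9):
                label = "breakpoint"
            else:
                label = "custom"
        if not (norm > 0):
            raise InvalidParameterError(f"{self.name}: normalization must be > 0, got {norm}")
        if label not in _NORMALIZATION_LABELS:
            raise InvalidParameterError(f"unknown normalization label {label!r}")
        object.__setattr__(self, "normalization", float(norm))
        object.__setattr__(self, "normalization_label", label)


@dataclass(frozen=True)
class DrugPanel:
    """An ordered collection of drugs with a common normalization choice."""

    drugs: tuple[DrugSpec, ...]
    normalization_label: str = ""

    def __post_init__(self):
        drugs = tuple(self.drugs)
        if len(drugs) < 1:
            raise InvalidParameterError("a panel needs at least one drug")
        names = [d.name for d in drugs]
        if len(set(names)) != len(names):
            raise InvalidParameterError("drug names must be unique")
        codes = [d.asm_code for d in drugs]
        if len(set(codes)) != len(codes):
            raise InvalidParameterError("ASM codes must be unique")
        label = self.normalization_label
        if not label:
            labels = {d.normalization_label for d in drugs}
            label = labels.pop() if len(labels) == 1 else "custom"
        object.__setattr__(self, "drugs", drugs)
        object.__setattr__(self, "normalization_label", label)

    @classmethod
    def from_specs(cls, specs: Iterable[DrugSpec], normalization_label: str = "") -> "DrugPanel":
        return cls(tuple(specs), normalization_label)

    def __len__(self) -> int:
        return len(self.drugs)

    def __iter__(self) -> Iterator[DrugSpec]:
        return iter(self.drugs)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(d.name for d in self.drugs)

    @property
    def asm_codes(self) -> tuple[str, ...]:
        return tuple(d.asm_code for d in self.drugs)

    def drug(self, key: str) -> DrugSpec:
        """Look a drug up by name or ASM code."""
        for d in self.drugs:
            if d.name == key or d.asm_code == key:
                return d
        raise KeyError(f"no drug named {key!r} in panel")

    def normalizations(self) -> dict[str, float]:
        return {d.name: d.normalization for d in self.drugs}

    def mics(self) -> dict[str, float]:
        return {d.name: d.mic for d in self.drugs}

    def rescaled(self, factor: float) -> "DrugPanel":
        """Return a panel with every N_i multiplied by ``factor`` (label becomes custom)."""
        if not (factor > 0):
            raise InvalidParameterError("rescale factor must be > 0")
        return DrugPanel(
            tuple(
                DrugSpec(
                    name=d.name,
                    asm_code=d.asm_code,
                    mic=d.mic,
                    breakpoint=d.breakpoint,
                    normalization=d.normalization * factor,
                    normalization_label="custom",
                )
                for d in self.drugs
            ),
            "custom",
        )

    # -- serialization -------------------------------------------------

    @classmethod
    def from_yaml(cls, path: str | Path) -> "DrugPanel":
        """Read a panel config (YAML or JSON; units fixed as ug/mL)."""
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        if not isinstance(doc, dict) or "drugs" not in doc:
            raise SchemaError(f"{path}: panel config must contain a 'drugs' list")
        default_label = doc.get("normalization", "")
        specs = []
        for i, entry in enumerate(doc["drugs"]):
            if "name" not in entry or "mic" not in entry:
                raise SchemaError(f"{path}: drug entry {i} missing 'name' or 'mic'")
            specs.append(
                DrugSpec(
                    name=entry["name"],
                    asm_code=entry.get("asm_code", ""),
                    mic=float(entry["mic"]),
                    breakpoint=(
                        float(entry["breakpoint"]) if entry.get("breakpoint") is not None else None
                    ),
                    normalization=(
                        float(entry["normalization"])
                        if entry.get("normalization") is not None
                        else None
                    ),
                    normalization_label=entry.get("normalization_label", default_label),
                )
            )
        return cls(tuple(specs), default_label)

    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "normalization": self.normalization_label,
            "units": "ug/mL",
            "drugs": [
                {
                    "name": d.name,
                    "asm_code": d.asm_code,
                    "mic": d.mic,
                    **({"breakpoint": d.breakpoint} if d.breakpoint is not None else {}),
                    "normalization": d.normalization,
                    "normalization_label": d.normalization_label,
                }
                for d in self.drugs
            ],
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)
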