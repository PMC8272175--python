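"""Tissue thermophysical constants and experiment parameter grids.

The five simulated tissues (skin, fat, muscle, thyroid, nodule) each carry the
coefficients of the Pennes bioheat equation: conductivity ``k``, density
``rho``, specific heat ``c``, blood perfusion ``wb``, blood density ``rho_b``
and blood specific heat ``c_b`` (taken equal to the tissue's own ``rho``/``c``),
arterial blood temperature ``Tb`` and metabolic heat ``Qm``.

Two perfusion-unit presets exist because the literature values for the gland
and the nodule (0.098 and 0.465 (mL/s)/mL) are internally inconsistent with
the reported nodule-core temperatures when taken literally as 1/s: at that
strength the perfusion sink clamps the gland to ~37.02 degC, whereas dividing
those two values by 60 (i.e. reading them as per-minute rates) yields a
nodule-core equilibrium of ~38.4 degC, matching the reported steady-state
results.  ``AS_PRINTED`` keeps the table literally; ``PER_MINUTE_GLAND``
divides only the thyroid and nodule perfusion by 60 at solve time.
"""

from __future__ import annotations

import dataclasses
import enum
import io
from dataclasses import dataclass
from typing import Mapping

import pandas as pd
import yaml

__all__ = [
    "PerfusionPreset",
    "TissueProperties",
    "TissueRegistry",
    "NoduleParamCombo",
    "CaseSpec",
    "make_tissue_registry",
    "nodule_parameter_grid",
    "NODULE_SIZE_PRESETS",
    "FAT_THICKNESS_GRID",
    "TISSUE_LABELS",
]

TISSUE_LABELS = ("skin", "fat", "muscle", "thyroid", "nodule")

#: Arterial blood temperature, degC (uniform across tissues).
T_BLOOD = 37.0

#: Default fat-layer thicknesses of the factorial study, m.
FAT_THICKNESS_GRID = (0.0, 0.003, 0.006, 0.012)

#: Nodule ellipse semi-axes (a, b) in metres for the three size presets.
#: The sizes are quoted as diameter pairs (1.2; 0.7), (2.2; 1.26) and
#: (3.14; 1.80) cm; semi-axes are half of those.
NODULE_SIZE_PRESETS: Mapping[str, tuple[float, float]] = {
    "small": (0.006, 0.0035),
    "medium": (0.011, 0.0063),
    "large": (0.0157, 0.0090),
}


class PerfusionPreset(enum.Enum):
    """Interpretation of the gland/nodule perfusion units (see module docs)."""

    AS_PRINTED = "as_printed"
    PER_MINUTE_GLAND = "per_minute_gland"


@dataclass(frozen=True)
class TissueProperties:
    """Thermophysical record of one tissue.

    Units: k W/(m K); rho kg/m^3; c J/(kg K); wb 1/s as printed;
    rho_b kg/m^3; c_b J/(kg K); Tb degC; Qm W/m^3.
    """

    name: str
    k: float
    rho: float
    c: float
    wb: float
    Qm: float
    rho_b: float = None  # type: ignore[assignment]
    c_b: float = None  # type: ignore[assignment]
    Tb: float = T_BLOOD

    def __post_init__(self) -> None:
        if self.rho_b is None:
            object.__setattr__(self, "rho_b", self.rho)
        if self.c_b is None:
            object.__setattr__(self, "c_b", self.c)
        for field in ("k", "rho", "c", "rho_b", "c_b"):
            if getattr(self, field) <= 0:
                raise ValueError(f"{self.name}: {field} must be > 0")
        if self.wb < 0 or self.Qm < 0:
            raise ValueError(f"{self.name}: wb and Qm must be >= 0")

    @property
    def perfusion_coefficient(self) -> float:
        """wb * rho_b * c_b, the Pennes sink strength in W/(m^3 K)."""
        return self.wb * self.rho_b * self.c_b


#: Default tissue table (the study's Table of thermophysical parameters).
_DEFAULT_TISSUES = {
    "skin": dict(k=0.37, rho=1109.0, c=3391.0, wb=0.00196, Qm=1829.85),
    "fat": dict(k=0.21, rho=911.0, c=2348.0, wb=0.000501, Qm=464.61),
    "muscle": dict(k=0.47, rho=1090.0, c=3421.0, wb=0.000708, Qm=1046.0),
    "thyroid": dict(k=0.52, rho=1050.0, c=3609.0, wb=0.098, Qm=4200.0),
    "nodule": dict(k=0.89, rho=1050.0, c=3770.0, wb=0.465, Qm=42000.0),
}

#: Tissues whose perfusion is rescaled under PER_MINUTE_GLAND.
_GLAND_TISSUES = ("thyroid", "nodule")


@dataclass(frozen=True)
class NoduleParamCombo:
    """One (Qm, wb) combination of the 2x2 nodule-parameter study.

    ``wb`` is on the as-printed scale; the registry preset decides whether it
    is used literally (1/s) or divided by 60.
    """

    Qm: float
    wb: float


def nodule_parameter_grid() -> list[NoduleParamCombo]:
    """The four (Qm, wb) combinations: {4200, 42000} x {0.098, 0.465}.

    Ordered with Qm as the slow index, matching the published table.
    """
    return [
        NoduleParamCombo(Qm=Qm, wb=wb)
        for Qm in (4200.0, 42000.0)
        for wb in (0.098, 0.465)
    ]


@dataclass(frozen=True)
class TissueRegistry:
    """Immutable mapping tissue label -> TissueProperties, plus the preset.

    ``effective(label)`` applies the perfusion preset; raw table values are
    preserved in ``entries`` so the registry round-trips losslessly.
    """

    entries: Mapping[str, TissueProperties]
    preset: PerfusionPreset = PerfusionPreset.AS_PRINTED

    def __post_init__(self) -> None:
        if set(self.entries) != set(TISSUE_LABELS):
            raise ValueError(
                f"registry must contain exactly {TISSUE_LABELS}, "
                f"got {sorted(self.entries)}"
            )

    def __getitem__(self, label: str) -> TissueProperties:
        return self.entries[label]

    def effective(self, label: str) -> TissueProperties:
        """Properties with the perfusion preset applied."""
        props = self.entries[label]
        if (
            self.preset is PerfusionPreset.PER_MINUTE_GLAND
            and label in _GLAND_TISSUES
        ):
            return dataclasses.replace(props, wb=props.wb / 60.0)
        return props

    def with_nodule_combo(self, combo: NoduleParamCombo) -> "TissueRegistry":
        """Registry with the nodule's (Qm, wb) replaced by ``combo``."""
        entries = dict(self.entries)
        entries["nodule"] = dataclasses.replace(
            entries["nodule"], Qm=combo.Qm, wb=combo.wb
        )
        return TissueRegistry(entries=entries, preset=self.preset)

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "preset": self.preset.value,
            "tissues": {
                name: dataclasses.asdict(props)
                for name, props in self.entries.items()
            },
        }

    @classmethod
    def from_dict(cls, data: dict) -> "TissueRegistry":
        entries = {
            name: TissueProperties(**props)
            for name, props in data["tissues"].items()
        }
        return cls(entries=entries, preset=PerfusionPreset(data["preset"]))

    def to_csv(self) -> str:
        """Table layout mirroring the published parameter table (one column
        per tissue, one row per parameter)."""
        rows = ["k", "rho", "c", "Tb", "wb", "Qm"]
        frame = pd.DataFrame(
            {
                name: [getattr(self.entries[name], r) for r in rows]
                for name in TISSUE_LABELS
            },
            index=rows,
        )
        return frame.to_csv()

    @classmethod
    def from_csv(cls, text: str, preset: PerfusionPreset = PerfusionPreset.AS_PRINTED) -> "TissueRegistry":
        frame = pd.read_csv(io.StringIO(text), index_col=0)
        entries = {
            name: TissueProperties(
                name=name,
                k=frame.at["k", name],
                rho=frame.at["rho", name],
                c=frame.at["c", name],
                wb=frame.at["wb", name],
                Qm=frame.at["Qm", name],
                Tb=frame.at["Tb", name],
            )
            for name in frame.columns
        }
        return cls(entries=entries, preset=preset)


def make_tissue_registry(
    preset: PerfusionPreset | str = PerfusionPreset.AS_PRINTED,
) -> TissueRegistry:
    """Registry populated with the default tissue table under ``preset``."""
    if isinstance(preset, str):
        try:
            preset = PerfusionPreset(preset)
        except ValueError as exc:
            raise ValueError(
                f"unknown perfusion preset {preset!r}; valid: "
                f"{[p.value for p in PerfusionPreset]}"
            ) from exc
    entries = {
        name: TissueProperties(name=name, **vals)
        for name, vals in _DEFAULT_TISSUES.items()
    }
    return TissueRegistry(entries=entries, preset=preset)


@dataclass
class CaseSpec:
    """One simulation case of the factorial study.

    ``nodule_size`` is a preset label ('small' | 'medium' | 'large') or an
    explicit (a, b) semi-axes pair in metres.  ``combo`` overrides the
    nodule's (Qm, wb); None keeps the registry defaults.  ``mesh_target`` is
    the triangle edge-length target in metres.
    """

    fat_thickness: float = 0.006
    nodule_size: str | tuple[float, float] = "large"
    combo: NoduleParamCombo | None = None
    mesh_target: float = 0.001
    label: str | None = None

    def __post_init__(self) -> None:
        if self.fat_thickness < 0:
            raise ValueError("fat_thickness must be >= 0")
        if self.mesh_target <= 0:
            raise ValueError("mesh_target must be > 0")

    @property
    def nodule_semi_axes(self) -> tuple[float, float]:
        if isinstance(self.nodule_size, str):
            try:
                return NODULE_SIZE_PRESETS[self.nodule_size]
            except KeyError as exc:
                raise ValueError(
                    f"unknown nodule size preset {self.nodule_size!r}"
                ) from exc
        a, b = self.nodule_size
        if a <= 0 or b <= 0:
            raise ValueError("nodule semi-axes must be > 0")
        return (float(a), float(b))

    @property
    def case_id(self) -> str:
        if self.label:
            return self.label
        size = (
            self.nodule_size
            if isinstance(self.nodule_size, str)
            else "x".join(f"{1e3 * s:g}mm" for s in self.nodule_size)
        )
        combo = (
            f"_Qm{self.combo.Qm:g}_wb{self.combo.wb:g}" if self.combo else ""
        )
        return f"fat{1e3 * self.fat_thickness:g}mm_{size}{combo}"

    def to_dict(self) -> dict:
        return {
            "fat_thickness": self.fat_thickness,
            "nodule_size": (
                self.nodule_size
                if isinstance(self.nodule_size, str)
                else list(self.nodule_size)
            ),
            "combo": dataclasses.asdict(self.combo) if self.combo else None,
            "mesh_target": self.mesh_target,
            "label": self.label,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "CaseSpec":
        data = dict(data)
        if data.get("combo"):
            data["combo"] = NoduleParamCombo(**data["combo"])
        if isinstance(data.get("nodule_size"), list):
            data["nodule_size"] = tuple(data["nodule_size"])
        return cls(**data)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "CaseSpec":
        return cls.from_dict(yaml.safe_load(text))
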