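"""Dynamic infrared thermography (DITI) exam simulation.

The protocol chains three phases: (1) steady state under natural convection
(h = 10 W/m^2K, room air 25 degC), used as the initial condition for (2) a
300 s forced-cooling phase (fan airflow modelled purely as h = 50 W/m^2K at
room temperature), whose final field initializes (3) a 300 s natural
reheating phase (h = 10 again).  Skin temperatures are sampled every 15 s,
matching the camera acquisition schedule (20 frames in 5 min).

Also provides the profile/series extraction used in the analysis: skin-arc
profiles along the anterior surface, radial line profiles from the skin
through the nodule centre to the trachea wall, and the factorial sweep
driver.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import fem
from .fem import BoundarySpec, TemperatureField
from .geometry import NeckGeometry, ProbePoints, build_neck_geometry, probe_points
from .meshing import GAMMA1, Mesh, generate_mesh
from .params import CaseSpec, TissueRegistry

__all__ = [
    "PhaseConfig",
    "ProtocolConfig",
    "ProtocolResult",
    "TemperatureSeries",
    "run_protocol",
    "extract_point_series",
    "extract_skin_profile",
    "extract_line_profile",
    "run_sweep",
]


@dataclass(frozen=True)
class PhaseConfig:
    h: float
    Tair: float
    duration: float


@dataclass(frozen=True)
class ProtocolConfig:
    """Exam protocol parameters (time in s, h in W/m^2K, T in degC)."""

    cooling: PhaseConfig = PhaseConfig(h=50.0, Tair=25.0, duration=300.0)
    reheating: PhaseConfig = PhaseConfig(h=10.0, Tair=25.0, duration=300.0)
    steady_h: float = 10.0
    steady_Tair: float = 25.0
    Tp: float = 37.0
    sample_every: float = 15.0
    dt: float = 1.0
    theta: float = 1.0
    cooling_stop: str = "fixed_duration"  # or "mean_skin_threshold"
    mean_skin_threshold: float = 30.0

    def __post_init__(self) -> None:
        for ph in (self.cooling, self.reheating):
            if ph.h < 0:
                raise ValueError("phase h must be >= 0")
            n = ph.duration / self.sample_every
            if abs(n - round(n)) > 1e-9:
                raise ValueError(
                    "phase durations must be multiples of sample_every"
                )
        if self.cooling_stop not in ("fixed_duration", "mean_skin_threshold"):
            raise ValueError(f"unknown cooling_stop {self.cooling_stop!r}")


@dataclass
class TemperatureSeries:
    """Uniformly sampled temperatures at one skin point (degC)."""

    times: np.ndarray
    values: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.times) != len(self.values):
            raise ValueError("times and values must have equal length")
        if len(self.times) > 1:
            steps = np.diff(self.times)
            if not np.allclose(steps, steps[0], rtol=0, atol=1e-9):
                raise ValueError("series must be uniformly sampled")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def spacing(self) -> float:
        return float(self.times[1] - self.times[0]) if len(self) > 1 else 0.0

    def to_csv(self) -> str:
        header = f"# label: {self.label}\n" if self.label else ""
        return header + pd.DataFrame(
            {"time_s": self.times, "T_degC": self.values}
        ).to_csv(index=False)


@dataclass
class ProtocolResult:
    steady_field: TemperatureField
    cooling_fields: list[TemperatureField]
    reheating_fields: list[TemperatureField]
    case: CaseSpec
    geometry: NeckGeometry
    mesh: Mesh
    config: ProtocolConfig
    registry: TissueRegistry
    probes: ProbePoints = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.probes is None:
            self.probes = probe_points(self.geometry)

    @property
    def sample_times(self) -> np.ndarray:
        cool = [f.time_tag for f in self.cooling_fields]
        heat = [f.time_tag for f in self.reheating_fields[1:]]
        return np.asarray(cool + heat)


def _mean_skin_temperature(field: TemperatureField) -> float:
    mesh = field.mesh
    g1 = np.unique(mesh.boundary_edges[mesh.boundary_tags == GAMMA1])
    return float(field.nodal_values[g1].mean())


def run_protocol(
    case: CaseSpec,
    cfg: ProtocolConfig | None = None,
    registry: TissueRegistry | None = None,
    *,
    mesh: Mesh | None = None,
    geometry: NeckGeometry | None = None,
) -> ProtocolResult:
    """Run steady -> cooling -> reheating for one case.

    A pre-built geometry/mesh pair may be passed to amortize meshing across
    parameter combinations on identical geometry.
    """
    cfg = cfg or ProtocolConfig()
    if registry is None:
        from .params import PerfusionPreset, make_tissue_registry

        registry = make_tissue_registry(PerfusionPreset.PER_MINUTE_GLAND)
    if case.combo is not None:
        registry = registry.with_nodule_combo(case.combo)

    stage = "geometry"
    try:
        if geometry is None:
            geometry = build_neck_geometry(
                case.fat_thickness, case.nodule_semi_axes
            )
        stage = "meshing"
        if mesh is None:
            mesh = generate_mesh(geometry, case.mesh_target)
        stage = "steady"
        bc_steady = BoundarySpec(h=cfg.steady_h, Tair=cfg.steady_Tair, Tp=cfg.Tp)
        steady = fem.solve_steady(mesh, registry, bc_steady)
        stage = "cooling"
        bc_cool = BoundarySpec(
            h=cfg.cooling.h, Tair=cfg.cooling.Tair, Tp=cfg.Tp
        )
        if cfg.cooling_stop == "mean_skin_threshold":
            # march one sampling interval at a time until the mean anterior
            # skin temperature reaches the threshold (or the time limit)
            cooling = [steady]
            n_max = int(round(cfg.cooling.duration / cfg.sample_every))
            for _ in range(n_max):
                step = fem.solve_transient(
                    mesh, registry, bc_cool, cooling[-1],
                    duration=cfg.sample_every, dt=cfg.dt,
                    sample_every=cfg.sample_every, theta=cfg.theta,
                )
                cooling.append(step[-1])
                if _mean_skin_temperature(step[-1]) <= cfg.mean_skin_threshold:
                    break
        else:
            cooling = fem.solve_transient(
                mesh, registry, bc_cool, steady,
                duration=cfg.cooling.duration, dt=cfg.dt,
                sample_every=cfg.sample_every, theta=cfg.theta,
            )
        stage = "reheating"
        bc_heat = BoundarySpec(
            h=cfg.reheating.h, Tair=cfg.reheating.Tair, Tp=cfg.Tp
        )
        reheating = fem.solve_transient(
            mesh, registry, bc_heat, cooling[-1],
            duration=cfg.reheating.duration, dt=cfg.dt,
            sample_every=cfg.sample_every, theta=cfg.theta,
        )
    except Exception as exc:
        raise RuntimeError(
            f"protocol stage '{stage}' failed for case {case.case_id}: {exc}"
        ) from exc
    return ProtocolResult(
        steady_field=steady,
        cooling_fields=cooling,
        reheating_fields=reheating,
        case=case,
        geometry=geometry,
        mesh=mesh,
        config=cfg,
        registry=registry,
    )


def extract_point_series(
    result: ProtocolResult, probe: tuple[float, float], label: str = ""
) -> TemperatureSeries:
    """Cooling + reheating samples at one skin point (junction sample kept
    once, attributed to the cooling phase)."""
    fields = result.cooling_fields + result.reheating_fields[1:]
    values = [fem.evaluate_field(f, probe) for f in fields]
    times = [f.time_tag for f in fields]
    return TemperatureSeries(times=np.asarray(times), values=np.asarray(values), label=label)


def extract_skin_profile(
    field: TemperatureField,
    geom: NeckGeometry,
    spacing: float = 1.0e-3,
) -> pd.DataFrame:
    """Skin temperatures along GAMMA1 vs arc coordinate.

    Arc 0 is the anterior midline; negative arcs are the nodule side.
    Columns: arc_cm, T_degC.
    """
    s_max = geom.gamma1_half_angle * geom.outer_radius
    s = np.arange(-s_max, s_max + spacing / 2, spacing)
    pts = geom.point_at_arc(s)
    T = fem.evaluate_field(field, pts)
    return pd.DataFrame({"arc_cm": 100.0 * s, "T_degC": T})


def extract_line_profile(
    field: TemperatureField,
    geom: NeckGeometry,
    side: str = "nodule",
    spacing: float = 2.5e-4,
) -> pd.DataFrame:
    """Temperatures along the radial line from the skin surface through the
    nodule centre (or its mirror) down to the trachea wall.

    Columns: depth_m (from the skin surface), x, y, T_degC, tissue.
    """
    if side not in ("nodule", "mirror"):
        raise ValueError("side must be 'nodule' or 'mirror'")
    cx, cy = geom.nodule.center
    if side == "mirror":
        cx = -cx
    d = math.hypot(cx, cy)
    ux, uy = cx / d, cy / d
    # the ray passes through the disc centre; it meets the (concentric)
    # trachea wall at radius r_t + |offset along the ray|
    r_end = geom.trachea.radius + abs(
        ux * geom.trachea.center[0] + uy * geom.trachea.center[1]
    )
    n = int(math.floor((geom.outer_radius - r_end) / spacing))
    rr = geom.outer_radius - spacing * np.arange(n + 1)
    if rr[-1] > r_end + 1e-12:
        rr = np.append(rr, r_end)
    pts = np.column_stack([rr * ux, rr * uy])
    T = fem.evaluate_field(field, pts)
    tissue = geom.classify(pts)
    return pd.DataFrame(
        {
            "depth_m": geom.outer_radius - rr,
            "x": pts[:, 0],
            "y": pts[:, 1],
            "T_degC": T,
            "tissue": tissue,
        }
    )


def run_sweep(
    cases: list[CaseSpec],
    cfg: ProtocolConfig | None = None,
    registry: TissueRegistry | None = None,
) -> pd.DataFrame:
    """One protocol run per case; returns the summary table.

    Per-case failures are recorded in the 'error' column and the sweep
    continues.  Columns include the steady contralateral skin difference
    (delta_TCL), the fat-layer drop (delta_TF) and the series limits.
    """
    from .series import summarize

    if not cases:
        raise ValueError("case list is empty")
    rows = []
    for case in cases:
        row: dict = {"case_id": case.case_id, "fat_cm": 100 * case.fat_thickness}
        size = case.nodule_size if isinstance(case.nodule_size, str) else "custom"
        a, b = case.nodule_semi_axes
        row.update(
            nodule_size=size,
            nodule_area_cm2=1e4 * math.pi * a * b,
        )
        try:
            res = run_protocol(case, cfg, registry)
            pp = res.probes
            front = extract_point_series(res, pp.front_of_nodule, "front")
            contra = extract_point_series(res, pp.contralateral, "contra")
            prof = extract_line_profile(res.steady_field, res.geometry)
            metrics = summarize(front, contra, prof, res.geometry)
            n_cool = len(res.cooling_fields) - 1
            row.update(
                start_degC=metrics.start,
                end_cooling_degC=front.values[n_cool],
                cooling_min_degC=metrics.cooling_min,
                end_degC=metrics.end,
                delta_TCL_degC=metrics.delta_TCL,
                delta_TF_degC=metrics.delta_TF,
                error="",
            )
        except Exception as exc:  # noqa: BLE001 - sweep must continue
            row.update(error=str(exc))
        rows.append(row)
    return pd.DataFrame(rows)
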