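"""Protocol chaining, sampling, profiles and the factorial sweep."""

import numpy as np
import pytest

from thyrotherm import fem
from thyrotherm.fem import BoundarySpec
from thyrotherm.geometry import probe_points
from thyrotherm.params import CaseSpec
from thyrotherm.protocol import (
    PhaseConfig,
    ProtocolConfig,
    TemperatureSeries,
    extract_line_profile,
    extract_point_series,
    extract_skin_profile,
    run_protocol,
    run_sweep,
)


def test_protocol_phase_structure(protocol_default):
    res = protocol_default
    # 300 s / 15 s = 20 samples plus the initial field in each phase
    assert len(res.cooling_fields) == 21
    assert len(res.reheating_fields) == 21
    # the reheating phase yields 20 sampled fields after t = 0
    assert len(res.reheating_fields[1:]) == 20
    times = res.sample_times
    assert np.all(np.diff(times) == 15.0)
    assert times[0] == 0.0 and times[-1] == 600.0


def test_initial_condition_chaining(protocol_default):
    res = protocol_default
    # first cooling sample is the steady field itself
    assert np.array_equal(
        res.cooling_fields[0].nodal_values, res.steady_field.nodal_values
    )
    # reheating starts from the last cooling field: no jump at the junction
    jump = np.abs(
        res.reheating_fields[0].nodal_values
        - res.cooling_fields[-1].nodal_values
    ).max()
    assert jump < 1e-9


def test_point_series_sampling(protocol_default):
    res = protocol_default
    ser = extract_point_series(res, res.probes.front_of_nodule)
    assert len(ser) == (300 + 300) // 15 + 1 == 41
    assert ser.spacing == 15.0
    # cooling is monotone non-increasing at the skin probe
    cooling = ser.values[:21]
    assert np.all(np.diff(cooling) <= 1e-9)
    # five minutes of reheating does not recover the steady temperature
    assert ser.values[-1] < ser.values[0]


def test_point_series_outside_probe_raises(protocol_default):
    with pytest.raises(fem.EvaluationError):
        extract_point_series(protocol_default, (0.5, 0.5))


def test_constant_fields_give_constant_series(protocol_default):
    res = protocol_default
    def const(t):
        return fem.TemperatureField(
            mesh=res.mesh,
            nodal_values=np.full(res.mesh.n_nodes, 30.0),
            time_tag=t,
        )

    import copy

    frozen = copy.copy(res)
    frozen.cooling_fields = [const(t) for t in (0.0, 15.0, 30.0)]
    frozen.reheating_fields = [const(t) for t in (30.0, 45.0, 60.0)]
    ser = extract_point_series(frozen, res.probes.front_of_nodule)
    assert np.allclose(ser.values, 30.0)
    assert len(ser) == 5


def test_skin_profile_symmetric_for_symmetric_tissue(
    mesh_default, geom_default, nodule_as_thyroid_registry
):
    field = fem.solve_steady(
        mesh_default, nodule_as_thyroid_registry, BoundarySpec()
    )
    prof = extract_skin_profile(field, geom_default)
    T = prof["T_degC"].to_numpy()
    assert np.abs(T - T[::-1]).max() < 1e-6


def test_skin_profile_bounds_and_extent(steady_default, geom_default):
    prof = extract_skin_profile(steady_default, geom_default)
    assert prof["T_degC"].between(25.0, steady_default.nodal_values.max()).all()
    s_max_cm = 100 * geom_default.gamma1_half_angle * geom_default.outer_radius
    assert prof["arc_cm"].iloc[0] == pytest.approx(-s_max_cm)
    assert prof["arc_cm"].iloc[-1] == pytest.approx(s_max_cm, abs=0.11)
    # nodule side of the profile is warmer than the mirror side around -3 cm
    at = lambda s: prof.iloc[(prof["arc_cm"] - s).abs().argmin()]["T_degC"]
    assert at(-3.0) > at(3.0)


def test_line_profile_annotation_and_endpoints(steady_default, geom_default):
    prof = extract_line_profile(steady_default, geom_default, side="nodule")
    # starts at the skin probe
    pp = probe_points(geom_default)
    first = prof.iloc[0]
    assert (first["x"], first["y"]) == pytest.approx(pp.front_of_nodule)
    assert first["T_degC"] == pytest.approx(
        fem.evaluate_field(steady_default, pp.front_of_nodule)
    )
    # tissue annotations match dense reclassification exactly
    pts = prof[["x", "y"]].to_numpy()
    assert list(prof["tissue"]) == list(geom_default.classify(pts))
    # crosses the expected tissue sequence on the nodule side
    seq = list(dict.fromkeys(prof["tissue"]))
    assert seq[:4] == ["skin", "fat", "muscle", "thyroid"]
    assert "nodule" in seq
    # ends at the trachea wall
    last = prof.iloc[-1]
    assert np.hypot(last["x"], last["y"]) == pytest.approx(
        geom_default.trachea.radius, abs=1e-9
    )


def test_line_profile_mirror_side_has_no_nodule(steady_default, geom_default):
    prof = extract_line_profile(steady_default, geom_default, side="mirror")
    assert "nodule" not in set(prof["tissue"])
    with pytest.raises(ValueError):
        extract_line_profile(steady_default, geom_default, side="left")


def test_protocol_config_validation():
    with pytest.raises(ValueError):
        ProtocolConfig(cooling=PhaseConfig(h=50.0, Tair=25.0, duration=100.0))
    with pytest.raises(ValueError):
        ProtocolConfig(cooling_stop="whenever")


def test_mean_skin_threshold_stop(registry_pm):
    # an aggressive threshold stops cooling before the full five minutes
    case = CaseSpec(fat_thickness=0.0, nodule_size="large", mesh_target=3e-3)
    cfg = ProtocolConfig(cooling_stop="mean_skin_threshold", mean_skin_threshold=33.0)
    res = run_protocol(case, cfg, registry_pm)
    assert len(res.cooling_fields) < 21
    cfg_off = ProtocolConfig(cooling_stop="mean_skin_threshold", mean_skin_threshold=5.0)
    res_off = run_protocol(case, cfg_off, registry_pm)
    assert len(res_off.cooling_fields) == 21


def test_sweep_table_and_error_recording(registry_pm):
    cases = [
        CaseSpec(fat_thickness=0.0, nodule_size="large", mesh_target=3e-3),
        # nodule too large for the lobe: per-case failure, sweep continues
        CaseSpec(fat_thickness=0.0, nodule_size=(0.05, 0.04), mesh_target=3e-3),
    ]
    table = run_sweep(cases, ProtocolConfig(), registry_pm)
    assert len(table) == 2
    ok, bad = table.iloc[0], table.iloc[1]
    assert ok["error"] == ""
    assert ok["delta_TCL_degC"] > 0
    assert ok["cooling_min_degC"] <= ok["start_degC"]
    assert "geometry" in bad["error"] or "contained" in bad["error"]
    with pytest.raises(ValueError):
        run_sweep([], ProtocolConfig(), registry_pm)


def test_temperature_series_validation():
    with pytest.raises(ValueError):
        TemperatureSeries(times=[0, 15], values=[30.0])
    with pytest.raises(ValueError):
        TemperatureSeries(times=[0, 15, 45], values=[30.0, 30.1, 30.2])
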