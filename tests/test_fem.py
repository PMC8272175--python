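"""Solver correctness: analytic slab oracle, invariants, time integration."""

import dataclasses
import math

import numpy as np
import pytest

from thyrotherm import fem
from thyrotherm.fem import BoundarySpec, EvaluationError, SolverError, TemperatureField
from thyrotherm.meshing import make_strip_mesh
from thyrotherm.params import TissueRegistry, make_tissue_registry


def zeroed_registry() -> TissueRegistry:
    """All metabolic heat and perfusion switched off (pure conduction)."""
    reg = make_tissue_registry()
    entries = {
        name: dataclasses.replace(props, wb=0.0, Qm=0.0)
        for name, props in reg.entries.items()
    }
    return TissueRegistry(entries=entries, preset=reg.preset)


def analytic_slab(props, L, h, Tair, Tp, xs):
    """Closed-form 1D bioheat slab: Dirichlet Tp at x=0, Robin (h, Tair) at
    x=L, insulated laterally.  T = Tinf + A cosh(x/Ld) + B sinh(x/Ld)."""
    pc = props.perfusion_coefficient
    Tinf = props.Tb + props.Qm / pc
    Ld = math.sqrt(props.k / pc)
    A = Tp - Tinf
    sh, ch = math.sinh(L / Ld), math.cosh(L / Ld)
    B = (h * (Tinf + A * ch - Tair) + props.k * A * sh / Ld) / (
        -props.k * ch / Ld - h * sh
    )
    return Tinf + A * np.cosh(xs / Ld) + B * np.sinh(xs / Ld)


def test_steady_matches_1d_pennes_slab_oracle():
    reg = make_tissue_registry()
    L, W = 0.05, 0.01
    mesh = make_strip_mesh(L, W, 0.0005, tissue="muscle")
    bc = BoundarySpec(h=10.0, Tair=25.0, Tp=37.0)
    field = fem.solve_steady(mesh, reg, bc)
    xs = np.linspace(0.0, L, 41)
    expected = analytic_slab(reg.effective("muscle"), L, bc.h, bc.Tair, bc.Tp, xs)
    got = fem.evaluate_field(field, np.column_stack([xs, np.full_like(xs, W / 2)]))
    assert np.abs(got - expected).max() < 0.01


def test_constant_boundary_data_gives_constant_solution(mesh_default):
    # pure conduction, insulated skin (h=0), Dirichlet 37 posteriorly:
    # the harmonic solution with constant boundary data is constant
    field = fem.solve_steady(
        mesh_default, zeroed_registry(), BoundarySpec(h=0.0, Tp=37.0)
    )
    assert np.abs(field.nodal_values - 37.0).max() < 1e-9


def test_discrete_maximum_principle_without_sources(mesh_default):
    bc = BoundarySpec(h=10.0, Tair=25.0, Tp=37.0)
    field = fem.solve_steady(mesh_default, zeroed_registry(), bc)
    eps = 1e-9
    assert field.nodal_values.min() >= min(bc.Tair, bc.Tp) - eps
    assert field.nodal_values.max() <= max(bc.Tair, bc.Tp) + eps


def test_perfused_interior_temperatures_bounded(steady_default, registry_pm):
    bc_Tp = 37.0
    cap = max(
        bc_Tp,
        max(
            props.Tb + props.Qm / props.perfusion_coefficient
            for props in (
                registry_pm.effective(n)
                for n in ("skin", "fat", "muscle", "thyroid", "nodule")
            )
        ),
    )
    assert steady_default.nodal_values.max() <= cap + 1e-6


def test_mirror_symmetry_when_nodule_equals_thyroid(
    mesh_default, nodule_as_thyroid_registry
):
    from scipy.spatial import cKDTree

    field = fem.solve_steady(
        mesh_default, nodule_as_thyroid_registry, BoundarySpec()
    )
    tree = cKDTree(mesh_default.nodes)
    d, idx = tree.query(mesh_default.nodes * [-1.0, 1.0])
    assert d.max() == 0.0
    assert np.abs(field.nodal_values - field.nodal_values[idx]).max() < 1e-6


def test_transient_preserves_equilibrium(registry_pm):
    mesh = make_strip_mesh(0.02, 0.01, 0.002)
    reg = zeroed_registry()
    T0 = TemperatureField(mesh=mesh, nodal_values=np.full(mesh.n_nodes, 37.0))
    out = fem.solve_transient(
        mesh, reg, BoundarySpec(h=0.0, Tp=37.0), T0, duration=60, dt=1.0,
        sample_every=15.0,
    )
    assert len(out) == 5
    assert out[0] is not out[-1]
    for f in out:
        assert np.abs(f.nodal_values - 37.0).max() < 1e-9


def test_backward_euler_matches_dense_time_step_oracle(
    mesh_default, registry_pm, steady_default
):
    bc = BoundarySpec(h=50.0)  # forced-cooling shock, the stiffest phase
    coarse = fem.solve_transient(
        mesh_default, registry_pm, bc, steady_default, 60, dt=1.0, sample_every=60
    )
    dense = fem.solve_transient(
        mesh_default, registry_pm, bc, steady_default, 60, dt=0.05, sample_every=60
    )
    diff = np.abs(coarse[-1].nodal_values - dense[-1].nodal_values).max()
    assert diff < 0.01


def test_transient_converges_to_steady_state(mesh_default, registry_pm):
    bc = BoundarySpec(h=10.0)
    steady = fem.solve_steady(mesh_default, registry_pm, bc)
    # perturb with a forced-cooling episode, then hold the steady boundary
    # conditions for an hour: the relaxed field must return to steady state
    cooled = fem.solve_transient(
        mesh_default, registry_pm, BoundarySpec(h=50.0), steady, 300,
        dt=5.0, sample_every=300,
    )[-1]
    out = fem.solve_transient(
        mesh_default, registry_pm, bc, cooled, duration=3600, dt=10.0,
        sample_every=3600,
    )
    assert np.abs(out[-1].nodal_values - steady.nodal_values).max() < 0.05


def test_first_returned_field_is_the_initial_condition(
    mesh_default, registry_pm, steady_default
):
    out = fem.solve_transient(
        mesh_default, registry_pm, BoundarySpec(h=50.0), steady_default,
        duration=15, dt=1.0, sample_every=15,
    )
    assert np.array_equal(out[0].nodal_values, steady_default.nodal_values)


def test_transient_configuration_errors(mesh_default, registry_pm, steady_default):
    bc = BoundarySpec()
    with pytest.raises(ValueError):
        fem.solve_transient(mesh_default, registry_pm, bc, steady_default, 60, dt=0.0)
    with pytest.raises(ValueError):
        fem.solve_transient(
            mesh_default, registry_pm, bc, steady_default, 60, dt=7.0,
            sample_every=15.0,
        )


def test_singular_system_raises():
    # no Dirichlet, no Robin, no perfusion sink, but nonzero metabolic heat:
    # a pure-Neumann problem with net heat input has no steady solution
    mesh = make_strip_mesh(0.02, 0.01, 0.002)
    mesh.boundary_tags[:] = "GAMMA2"
    reg = make_tissue_registry()
    entries = {
        name: dataclasses.replace(props, wb=0.0)
        for name, props in reg.entries.items()
    }
    with pytest.raises(SolverError):
        fem.solve_steady(
            mesh, TissueRegistry(entries=entries), BoundarySpec(h=0.0)
        )


def test_evaluate_field_at_nodes_and_constants(steady_default, mesh_default):
    for idx in (0, mesh_default.n_nodes // 2, mesh_default.n_nodes - 1):
        p = mesh_default.nodes[idx]
        assert fem.evaluate_field(steady_default, p) == pytest.approx(
            steady_default.nodal_values[idx], abs=1e-12
        )
    const = TemperatureField(
        mesh=mesh_default, nodal_values=np.full(mesh_default.n_nodes, 31.5)
    )
    assert fem.evaluate_field(const, (0.0, 0.02)) == pytest.approx(31.5)


def test_evaluate_field_reproduces_linear_fields_exactly(rng):
    # P1 interpolation is exact for T = alpha*x + beta*y + c
    mesh = make_strip_mesh(0.04, 0.02, 0.004)
    alpha, beta, c = 120.0, -45.0, 33.0
    field = TemperatureField(
        mesh=mesh,
        nodal_values=alpha * mesh.nodes[:, 0] + beta * mesh.nodes[:, 1] + c,
    )
    pts = rng.uniform([0.0, 0.0], [0.04, 0.02], size=(200, 2))
    got = fem.evaluate_field(field, pts)
    expected = alpha * pts[:, 0] + beta * pts[:, 1] + c
    assert np.abs(got - expected).max() < 1e-9


def test_evaluate_field_outside_domain_raises(steady_default):
    with pytest.raises(EvaluationError):
        fem.evaluate_field(steady_default, (0.2, 0.2))


def test_steady_residual_is_tiny(mesh_default, registry_pm):
    # the solver itself enforces relative residual < 1e-10; re-check here
    from thyrotherm.fem import _apply_dirichlet, _assemble

    bc = BoundarySpec()
    K, _, F, dir_nodes = _assemble(mesh_default, registry_pm, bc)
    A = _apply_dirichlet(K, dir_nodes)
    rhs = F.copy()
    rhs[dir_nodes] = bc.Tp
    field = fem.solve_steady(mesh_default, registry_pm, bc)
    res = np.linalg.norm(A @ field.nodal_values - rhs) / np.linalg.norm(rhs)
    assert res < 1e-10
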