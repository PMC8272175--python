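"""Shared fixtures: coarse meshes and solved cases reused across the suite.

FEM-backed fixtures are session-scoped so each expensive mesh/solve happens
once; h = 2 mm is enough for every qualitative property checked here (the
acceptance temperatures are recomputed separately at h = 1 mm).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest
from hypothesis import settings

from thyrotherm import fem
from thyrotherm.geometry import build_neck_geometry, probe_points
from thyrotherm.meshing import generate_mesh
from thyrotherm.params import (
    CaseSpec,
    NODULE_SIZE_PRESETS,
    PerfusionPreset,
    TissueRegistry,
    make_tissue_registry,
)
from thyrotherm.protocol import ProtocolConfig, run_protocol

settings.register_profile("suite", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("suite")

COARSE_H = 2.0e-3


@pytest.fixture(scope="session")
def registry_pm() -> TissueRegistry:
    return make_tissue_registry(PerfusionPreset.PER_MINUTE_GLAND)


@pytest.fixture(scope="session")
def registry_ap() -> TissueRegistry:
    return make_tissue_registry(PerfusionPreset.AS_PRINTED)


@pytest.fixture(scope="session")
def geom_default():
    """Reference geometry: fat 0.6 cm, large nodule."""
    return build_neck_geometry(0.006, NODULE_SIZE_PRESETS["large"])


@pytest.fixture(scope="session")
def mesh_default(geom_default):
    return generate_mesh(geom_default, COARSE_H)


@pytest.fixture(scope="session")
def steady_default(mesh_default, registry_pm):
    return fem.solve_steady(mesh_default, registry_pm, fem.BoundarySpec())


@pytest.fixture(scope="session")
def nodule_as_thyroid_registry(registry_pm) -> TissueRegistry:
    """Registry whose nodule is thermally identical to thyroid tissue."""
    entries = dict(registry_pm.entries)
    entries["nodule"] = dataclasses.replace(entries["thyroid"], name="nodule")
    return TissueRegistry(entries=entries, preset=registry_pm.preset)


@pytest.fixture(scope="session")
def fat_steady_cases(registry_pm):
    """Steady solves for the four fat thicknesses (large nodule)."""
    out = {}
    for fat in (0.0, 0.003, 0.006, 0.012):
        geom = build_neck_geometry(fat, NODULE_SIZE_PRESETS["large"])
        mesh = generate_mesh(geom, COARSE_H)
        field = fem.solve_steady(mesh, registry_pm, fem.BoundarySpec())
        out[fat] = (geom, mesh, field, probe_points(geom))
    return out


@pytest.fixture(scope="session")
def size_steady_cases(registry_pm):
    """Steady solves for the three nodule sizes at fat 0."""
    out = {}
    for size in ("small", "medium", "large"):
        geom = build_neck_geometry(0.0, NODULE_SIZE_PRESETS[size])
        mesh = generate_mesh(geom, COARSE_H)
        field = fem.solve_steady(mesh, registry_pm, fem.BoundarySpec())
        out[size] = (geom, mesh, field, probe_points(geom))
    return out


@pytest.fixture(scope="session")
def protocol_default(registry_pm):
    """Full default protocol run (fat 0.6 cm, large nodule, h = 2 mm)."""
    case = CaseSpec(fat_thickness=0.006, nodule_size="large", mesh_target=COARSE_H)
    return run_protocol(case, ProtocolConfig(), registry_pm)


@pytest.fixture(scope="session")
def protocol_by_fat(registry_pm):
    """Full protocol runs for the four fat thicknesses (large nodule)."""
    out = {}
    for fat in (0.0, 0.003, 0.006, 0.012):
        case = CaseSpec(fat_thickness=fat, nodule_size="large", mesh_target=COARSE_H)
        out[fat] = run_protocol(case, ProtocolConfig(), registry_pm)
    return out


@pytest.fixture(scope="session")
def acceptance_targets():
    """The full reference-target recomputation at production resolution."""
    from thyrotherm.reporting import compute_acceptance_targets

    return compute_acceptance_targets(h=1.0e-3, dt=1.0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
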