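"""P1 finite-element solver for the Pennes bioheat equation.

Steady state:  0 = div(k grad T) + wb*rho_b*c_b*(Tb - T) + Qm
Transient:     rho*c dT/dt = div(k grad T) + wb*rho_b*c_b*(Tb - T) + Qm

with a convective (Robin) condition -n.k grad T = h (T - Tair) on GAMMA1,
zero flux on GAMMA2 and prescribed temperature Tp on GAMMA3.  Temperatures
are carried in degC throughout (the model is linear in T).

Discretization: linear triangles, consistent mass matrix, exact edge-length
quadrature for the Robin boundary terms, strong (row-replacement) Dirichlet
imposition, and a theta time-stepping scheme (backward Euler by default)
with a single sparse LU factorization reused across all steps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.spatial import cKDTree

from .meshing import GAMMA1, GAMMA3, Mesh
from .params import TissueRegistry

__all__ = [
    "BoundarySpec",
    "TemperatureField",
    "SolverError",
    "EvaluationError",
    "solve_steady",
    "solve_transient",
    "evaluate_field",
]


class SolverError(RuntimeError):
    pass


class EvaluationError(ValueError):
    pass


@dataclass(frozen=True)
class BoundarySpec:
    """Boundary data: Robin (h, Tair) on GAMMA1, zero flux on GAMMA2,
    prescribed Tp on GAMMA3.  h = 0 turns GAMMA1 into an insulated surface."""

    h: float = 10.0
    Tair: float = 25.0
    Tp: float = 37.0

    def __post_init__(self) -> None:
        if self.h < 0:
            raise ValueError("convection coefficient h must be >= 0")


@dataclass
class TemperatureField:
    """Nodal temperatures (degC) on a mesh; ``time_tag`` is None for steady
    solutions and the solution time in seconds otherwise."""

    mesh: Mesh
    nodal_values: np.ndarray
    time_tag: float | None = None

    def __post_init__(self) -> None:
        self.nodal_values = np.asarray(self.nodal_values, dtype=float)
        if self.nodal_values.shape != (self.mesh.n_nodes,):
            raise ValueError("nodal_values length must match mesh nodes")
        if not np.isfinite(self.nodal_values).all():
            raise SolverError("temperature field contains non-finite values")

    def evaluate(self, p) -> float | np.ndarray:
        return evaluate_field(self, p)

    def to_csv(self) -> str:
        import pandas as pd

        return pd.DataFrame(
            {
                "x": self.mesh.nodes[:, 0],
                "y": self.mesh.nodes[:, 1],
                "T": self.nodal_values,
            }
        ).to_csv(index=False)


# ---------------------------------------------------------------------------
# assembly


def _element_geometry(mesh: Mesh):
    p = mesh.nodes[mesh.elements]  # (m, 3, 2)
    x, y = p[..., 0], p[..., 1]
    # P1 shape-function gradients: b_i = dphi_i/dx * 2A, c_i = dphi_i/dy * 2A
    b = np.stack([y[:, 1] - y[:, 2], y[:, 2] - y[:, 0], y[:, 0] - y[:, 1]], axis=1)
    c = np.stack([x[:, 2] - x[:, 1], x[:, 0] - x[:, 2], x[:, 1] - x[:, 0]], axis=1)
    return b, c, mesh.element_areas()


def _assemble(mesh: Mesh, registry: TissueRegistry, bc: BoundarySpec):
    """Returns (K, M, F, dirichlet_nodes): K includes conduction, perfusion
    and Robin terms; M is the rho*c consistent mass matrix; F the load."""
    n = mesh.n_nodes
    b, c, area = _element_geometry(mesh)
    if (area <= 0).any():
        raise SolverError("mesh contains non-positive element areas")

    labels = np.unique(mesh.element_region)
    k_e = np.empty(mesh.n_elements)
    pc_e = np.empty(mesh.n_elements)  # perfusion coefficient wb*rho_b*c_b
    rc_e = np.empty(mesh.n_elements)  # rho*c
    src_e = np.empty(mesh.n_elements)  # pc*Tb + Qm
    for lab in labels:
        props = registry.effective(str(lab))
        m = mesh.element_region == lab
        k_e[m] = props.k
        pc_e[m] = props.perfusion_coefficient
        rc_e[m] = props.rho * props.c
        src_e[m] = props.perfusion_coefficient * props.Tb + props.Qm

    rows = np.repeat(mesh.elements, 3, axis=1).ravel()  # i index
    cols = np.tile(mesh.elements, 3).ravel()  # j index

    # conduction: k/(4A) * (b_i b_j + c_i c_j)
    bb = b[:, :, None] * b[:, None, :] + c[:, :, None] * c[:, None, :]
    k_vals = (k_e / (4.0 * area))[:, None, None] * bb

    # consistent local mass: A/12 * (1 + delta_ij)
    m_loc = (np.ones((3, 3)) + np.eye(3)) / 12.0
    m_vals = area[:, None, None] * m_loc

    K = sp.coo_matrix(
        ((k_vals + pc_e[:, None, None] * m_vals).ravel(), (rows, cols)),
        shape=(n, n),
    ).tocsr()
    M = sp.coo_matrix(
        ((rc_e[:, None, None] * m_vals).ravel(), (rows, cols)), shape=(n, n)
    ).tocsr()

    F = np.zeros(n)
    np.add.at(F, mesh.elements.ravel(), np.repeat(src_e * area / 3.0, 3))

    # Robin terms on GAMMA1 (exact edge-length quadrature)
    g1 = mesh.boundary_edges[mesh.boundary_tags == GAMMA1]
    if len(g1) and bc.h > 0:
        e0, e1 = mesh.nodes[g1[:, 0]], mesh.nodes[g1[:, 1]]
        Le = np.linalg.norm(e1 - e0, axis=1)
        loc = np.array([[2.0, 1.0], [1.0, 2.0]]) / 6.0
        r_rows = np.repeat(g1, 2, axis=1).ravel()
        r_cols = np.tile(g1, 2).ravel()
        r_vals = (bc.h * Le)[:, None, None] * loc
        K = K + sp.coo_matrix(
            (r_vals.ravel(), (r_rows, r_cols)), shape=(n, n)
        ).tocsr()
        np.add.at(F, g1.ravel(), np.repeat(bc.h * bc.Tair * Le / 2.0, 2))

    dir_nodes = np.unique(mesh.boundary_edges[mesh.boundary_tags == GAMMA3])
    return K, M, F, dir_nodes


def _apply_dirichlet(A: sp.csr_matrix, nodes: np.ndarray) -> sp.csr_matrix:
    """Row replacement: zero the Dirichlet rows and put 1 on the diagonal."""
    n = A.shape[0]
    mask = np.ones(n)
    mask[nodes] = 0.0
    D = sp.diags(mask)
    I_dir = sp.coo_matrix(
        (np.ones(len(nodes)), (nodes, nodes)), shape=(n, n)
    ).tocsr()
    return (D @ A + I_dir).tocsc()


def solve_steady(
    mesh: Mesh, registry: TissueRegistry, bc: BoundarySpec
) -> TemperatureField:
    """Steady Pennes solution; relative linear residual is checked < 1e-10."""
    K, _, F, dir_nodes = _assemble(mesh, registry, bc)
    A = _apply_dirichlet(K, dir_nodes)
    rhs = F.copy()
    rhs[dir_nodes] = bc.Tp
    with np.errstate(all="ignore"):
        try:
            T = spla.spsolve(A, rhs)
        except RuntimeError as exc:
            raise SolverError(f"sparse solve failed: {exc}") from exc
    if not np.isfinite(T).all():
        raise SolverError(
            "singular system: no Dirichlet or Robin boundary constrains the "
            "temperature level"
        )
    res = np.linalg.norm(A @ T - rhs) / max(np.linalg.norm(rhs), 1e-300)
    if res > 1e-10:
        raise SolverError(f"linear solve residual {res:.2e} exceeds 1e-10")
    return TemperatureField(mesh=mesh, nodal_values=T, time_tag=None)


def solve_transient(
    mesh: Mesh,
    registry: TissueRegistry,
    bc: BoundarySpec,
    T0: TemperatureField,
    duration: float,
    dt: float = 1.0,
    sample_every: float = 15.0,
    theta: float = 1.0,
) -> list[TemperatureField]:
    """Theta-scheme time integration (theta = 1: backward Euler).

    Returns fields sampled at t = 0, sample_every, ..., duration; the first
    returned field is ``T0`` itself.  ``sample_every`` and ``duration`` must
    be integer multiples of ``dt``.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if T0.mesh is not mesh:
        raise ValueError("T0 must live on the same mesh")
    n_sub = sample_every / dt
    if abs(n_sub - round(n_sub)) > 1e-9:
        raise ValueError("sample_every must be an integer multiple of dt")
    n_samples = duration / sample_every
    if abs(n_samples - round(n_samples)) > 1e-9:
        raise ValueError("duration must be an integer multiple of sample_every")
    n_sub, n_samples = int(round(n_sub)), int(round(n_samples))
    if not 0.0 <= theta <= 1.0:
        raise ValueError("theta must lie in [0, 1]")

    K, M, F, dir_nodes = _assemble(mesh, registry, bc)
    A = _apply_dirichlet((M / dt + theta * K).tocsr(), dir_nodes)
    lu = spla.splu(A)
    B = (M / dt - (1.0 - theta) * K).tocsr()

    t0 = T0.time_tag or 0.0
    T = T0.nodal_values.copy()
    out = [TemperatureField(mesh=mesh, nodal_values=T.copy(), time_tag=t0)]
    for s in range(1, n_samples + 1):
        for _ in range(n_sub):
            rhs = B @ T + F
            rhs[dir_nodes] = bc.Tp
            T = lu.solve(rhs)
        out.append(
            TemperatureField(
                mesh=mesh, nodal_values=T.copy(), time_tag=t0 + s * sample_every
            )
        )
    return out


# ---------------------------------------------------------------------------
# point evaluation


def _mesh_eval_caches(mesh: Mesh):
    cache = getattr(mesh, "_eval_cache", None)
    if cache is None:
        finder = mesh.triangulation().get_trifinder()
        tree = cKDTree(mesh.nodes)
        # node -> incident elements
        incident: list[list[int]] = [[] for _ in range(mesh.n_nodes)]
        for ei, tri_nodes in enumerate(mesh.elements):
            for node in tri_nodes:
                incident[node].append(ei)
        cache = (finder, tree, incident)
        mesh._eval_cache = cache  # type: ignore[attr-defined]
    return cache


def _barycentric(mesh: Mesh, elem: np.ndarray, pts: np.ndarray) -> np.ndarray:
    p = mesh.nodes[mesh.elements[elem]]
    T = np.stack([p[:, 0] - p[:, 2], p[:, 1] - p[:, 2]], axis=2)
    rhs = pts - p[:, 2]
    det = T[:, 0, 0] * T[:, 1, 1] - T[:, 0, 1] * T[:, 1, 0]
    l0 = (rhs[:, 0] * T[:, 1, 1] - rhs[:, 1] * T[:, 0, 1]) / det
    l1 = (-rhs[:, 0] * T[:, 1, 0] + rhs[:, 1] * T[:, 0, 0]) / det
    return np.column_stack([l0, l1, 1.0 - l0 - l1])


def evaluate_field(field: TemperatureField, p) -> float | np.ndarray:
    """Barycentric linear interpolation at point(s) ``p``.

    Points that fall marginally outside the polygonal mesh boundary (e.g.
    exactly on the curved skin circle, beyond the chordal facets) are
    evaluated by linear extrapolation from the nearest boundary element;
    points clearly outside raise :class:`EvaluationError`.
    """
    mesh = field.mesh
    pts = np.atleast_2d(np.asarray(p, dtype=float))
    single = np.asarray(p).ndim == 1
    finder, tree, incident = _mesh_eval_caches(mesh)
    elem = np.asarray(finder(pts[:, 0], pts[:, 1]), dtype=int)
    missing = np.nonzero(elem < 0)[0]
    if len(missing):
        _, nearest = tree.query(pts[missing])
        for idx, node in zip(missing, np.atleast_1d(nearest)):
            cands = incident[int(node)]
            if not cands:
                raise EvaluationError(f"point {pts[idx]} outside the mesh")
            best, best_score = -1, -np.inf
            for ei in cands:
                lam = _barycentric(mesh, np.array([ei]), pts[idx][None, :])[0]
                score = lam.min()
                if score > best_score:
                    best, best_score = ei, score
            # tolerate the sagitta of polygonalized curved boundaries
            if best_score < -0.35:
                raise EvaluationError(
                    f"point {pts[idx]} outside the meshed domain"
                )
            elem[idx] = best
    lam = _barycentric(mesh, elem, pts)
    vals = (field.nodal_values[mesh.elements[elem]] * lam).sum(axis=1)
    return float(vals[0]) if single else vals
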