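"""Conforming triangulation of the neck cross-section.

The generator is a force-equilibrium Delaunay mesher (distmesh-style): points
on all boundary and tissue-interface curves are fixed, free interior points
relax under truss forces with repeated Delaunay retriangulation, and element
sizes follow a size field that refines the thin outer layers and small
nodules below the global target ``h_target``.

The neck mesh is built on the half-domain x >= 0 and mirrored across the
sagittal axis, so meshes are exactly mirror-symmetric point sets and
triangulations — the discrete solution of a symmetric problem is then
symmetric to solver precision, and left/right skin-temperature differences
carry no discretization asymmetry.

Element region labels come from centroid classification against the exact
geometry; boundary edges are tagged GAMMA1 (anterior skin), GAMMA2 (trachea
wall / insulated sides), GAMMA3 (posterior prescribed-temperature arc).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import Delaunay, cKDTree

from .geometry import Circle, NeckGeometry

__all__ = ["Mesh", "MeshingError", "generate_mesh", "make_strip_mesh", "convergence_report"]

GAMMA1 = "GAMMA1"
GAMMA2 = "GAMMA2"
GAMMA3 = "GAMMA3"

#: Edge-length cap inside the thin outer layers (skin is 1 mm thick).
_LAYER_CAP = 1.0e-3
#: Size-field grading rate away from refined features.
_GRADING = 0.3


class MeshingError(RuntimeError):
    pass


@dataclass
class Mesh:
    """P1 triangle mesh with region and boundary tags.

    ``nodes``: (n, 2) coordinates in metres; ``elements``: (m, 3) CCW node
    triples; ``element_region``: tissue label per element;
    ``boundary_edges``: (k, 2) node pairs; ``boundary_tags``: (k,) labels.
    """

    nodes: np.ndarray
    elements: np.ndarray
    element_region: np.ndarray
    boundary_edges: np.ndarray
    boundary_tags: np.ndarray
    h_target: float
    _tri_cache: object = field(default=None, repr=False, compare=False)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    def element_areas(self) -> np.ndarray:
        p = self.nodes[self.elements]
        d1 = p[:, 1] - p[:, 0]
        d2 = p[:, 2] - p[:, 0]
        return 0.5 * (d1[:, 0] * d2[:, 1] - d1[:, 1] * d2[:, 0])

    def min_angles_deg(self) -> np.ndarray:
        """Smallest interior angle of every element, degrees."""
        p = self.nodes[self.elements]
        angles = []
        for i in range(3):
            a = p[:, (i + 1) % 3] - p[:, i]
            b = p[:, (i + 2) % 3] - p[:, i]
            cosang = (a * b).sum(1) / (
                np.linalg.norm(a, axis=1) * np.linalg.norm(b, axis=1)
            )
            angles.append(np.degrees(np.arccos(np.clip(cosang, -1, 1))))
        return np.min(angles, axis=0)

    def triangulation(self):
        """matplotlib Triangulation (cached) for point location."""
        if self._tri_cache is None:
            from matplotlib.tri import Triangulation

            self._tri_cache = Triangulation(
                self.nodes[:, 0], self.nodes[:, 1], self.elements
            )
        return self._tri_cache

    def to_text(self) -> str:
        """Plain-text node/element export (CSV blocks)."""
        nodes = pd.DataFrame(self.nodes, columns=["x", "y"])
        elems = pd.DataFrame(self.elements, columns=["n0", "n1", "n2"])
        elems["region"] = self.element_region
        edges = pd.DataFrame(self.boundary_edges, columns=["n0", "n1"])
        edges["tag"] = self.boundary_tags
        return (
            "# nodes\n" + nodes.to_csv(index=False)
            + "# elements\n" + elems.to_csv(index=False)
            + "# boundary_edges\n" + edges.to_csv(index=False)
        )


# ---------------------------------------------------------------------------
# size field


def _make_size_field(geom: NeckGeometry, h_target: float):
    """Absolute local edge-length target h(p).

    Caps h inside the skin/fat band at 1 mm and near small nodules at ~2.5
    elements across the semi-minor axis, grading linearly back to h_target.
    """
    nod = geom.nodule
    cap_layer = min(h_target, _LAYER_CAP)
    cap_nod = max(min(h_target, nod.b / 2.5), 4.0e-4)
    band_inner = geom.r_fat_inner - 1.0e-3
    r_mi = geom.r_muscle_inner

    def h(p: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(p)
        r = np.hypot(p[:, 0], p[:, 1])
        # thin outer layers
        d_band = np.maximum(band_inner - r, 0.0)
        out = np.minimum(cap_layer + _GRADING * d_band, h_target)
        # nodule neighbourhood (and its mirror, to keep the field symmetric)
        ctr = geom.trachea.center
        d_tr = np.abs(
            np.hypot(p[:, 0] - ctr[0], p[:, 1] - ctr[1]) - geom.trachea.radius
        )
        for e in (nod, nod.mirrored()):
            loc = e._local(p)
            re = np.sqrt((loc[:, 0] / e.a) ** 2 + (loc[:, 1] / e.b) ** 2)
            d_out = np.maximum(re - 1.0, 0.0) * e.b
            out = np.minimum(out, cap_nod + _GRADING * d_out)
            # clearance between the nodule and the trachea wall
            d_abs = np.abs(re - 1.0) * e.b
            out = np.minimum(
                out, _LAYER_CAP + _GRADING * np.maximum(d_abs, d_tr)
            )
        # narrow clearance between the gland and the muscle-layer interface:
        # graded cap keyed to the distance from the pinch zone
        d_iface = np.abs(r - r_mi)
        for e in geom.lobes:
            loc = e._local(p)
            re = np.sqrt((loc[:, 0] / e.a) ** 2 + (loc[:, 1] / e.b) ** 2)
            d_lobe = np.abs(re - 1.0) * e.b
            d_pinch = np.maximum(d_lobe, d_iface)
            out = np.minimum(out, _LAYER_CAP + _GRADING * d_pinch)
        return np.maximum(out, 1e-12)

    return h


# ---------------------------------------------------------------------------
# fixed points on curves (half domain x >= 0)


def _dense_curve(curve) -> np.ndarray:
    if isinstance(curve, Circle):
        t = np.linspace(0, 2 * math.pi, 8193)
        return np.column_stack(
            [
                curve.center[0] + curve.radius * np.cos(t),
                curve.center[1] + curve.radius * np.sin(t),
            ]
        )
    t = np.linspace(0, 2 * math.pi, 8193)
    return curve.boundary(t)


def _axis_crossings(curve) -> list[float]:
    """y-values where the curve crosses the sagittal axis x = 0."""
    pts = _dense_curve(curve)
    x, y = pts[:, 0], pts[:, 1]
    ys = []
    sign = np.sign(x)
    idx = np.nonzero(sign[:-1] * sign[1:] < 0)[0]
    for i in idx:
        f = x[i] / (x[i] - x[i + 1])
        ys.append(y[i] + f * (y[i + 1] - y[i]))
    # points exactly on the axis
    for i in np.nonzero(x == 0.0)[0]:
        ys.append(y[i])
    return ys


def _resample_halfcurve(curve, hfun) -> np.ndarray:
    """Arc-length resampling of the x>=0 part of a closed curve at the local
    size field, dropping samples that crowd the axis crossings."""
    pts = _dense_curve(curve)
    # walk the closed polyline, splitting at axis crossings
    x = pts[:, 0]
    inside = x >= 0
    # rotate so the curve starts outside the half-plane if possible
    if inside.all():
        arcs = [pts]
    else:
        start = int(np.argmin(inside))
        order = np.r_[start : len(pts) - 1, 0:start]  # drop duplicate endpoint
        pts_r = pts[order]
        arcs = []
        current: list[np.ndarray] = []
        closed = np.vstack([pts_r, pts_r[:1]])
        for i in range(len(closed) - 1):
            p0, p1 = closed[i], closed[i + 1]
            in0, in1 = p0[0] >= 0, p1[0] >= 0
            if in0:
                current.append(p0)
            if in0 != in1:
                f = p0[0] / (p0[0] - p1[0])
                cross = p0 + f * (p1 - p0)
                cross[0] = 0.0
                current.append(cross)
                if in0:  # leaving: close the arc
                    arcs.append(np.array(current))
                    current = []
        if current:
            arcs.append(np.array(current))
    out = []
    for arc in arcs:
        if len(arc) < 2:
            continue
        seg = np.linalg.norm(np.diff(arc, axis=0), axis=1)
        s = np.r_[0.0, np.cumsum(seg)]
        total = s[-1]
        if total <= 0:
            continue
        # walk with local spacing
        samples = [arc[0]]
        pos = 0.0
        while True:
            hloc = float(hfun(samples[-1][None, :])[0])
            pos += hloc
            if pos >= total - 0.5 * hloc:
                break
            xi = np.interp(pos, s, arc[:, 0])
            yi = np.interp(pos, s, arc[:, 1])
            samples.append(np.array([xi, yi]))
        samples.append(arc[-1])
        out.append(np.array(samples))
    if not out:
        return np.empty((0, 2))
    allpts = np.vstack(out)
    # samples too close to the axis (their crossing anchors are kept exactly)
    hloc = hfun(allpts)
    keep = (allpts[:, 0] <= 0.0) | (allpts[:, 0] > 0.35 * hloc)
    allpts = allpts[keep]
    allpts[np.abs(allpts[:, 0]) < 1e-12, 0] = 0.0
    return allpts


def _half_circle_arc(radius: float, hfun, center_y: float = 0.0) -> np.ndarray:
    """x>=0 half of a circle centred on the axis, endpoints exactly on the
    axis and a node exactly at the equatorial point (radius, center_y)."""
    quarter = radius * math.pi / 2
    hloc = float(hfun(np.array([[radius, center_y]]))[0])
    n = max(4, int(round(quarter / hloc)))
    t = np.linspace(math.pi / 2, -math.pi / 2, 2 * n + 1)
    pts = np.column_stack(
        [radius * np.cos(t), center_y + radius * np.sin(t)]
    )
    pts[0] = (0.0, center_y + radius)
    pts[-1] = (0.0, center_y - radius)
    return pts


def _fixed_points(geom: NeckGeometry, hfun) -> np.ndarray:
    pts = [
        _half_circle_arc(geom.outer_radius, hfun),
        _resample_halfcurve(
            Circle(geom.trachea.center, geom.trachea.radius), hfun
        ),
    ]
    crossings: list[float] = []
    for r in geom.layer_radii:
        # adaptive sampling: the size field varies along these circles near
        # the gland pinch zone
        pts.append(_resample_halfcurve(Circle((0.0, 0.0), r), hfun))
        crossings.extend([r, -r])
    fd = _signed_distance(geom)
    ellipses = [*geom.lobes, geom.nodule, geom.nodule.mirrored()]
    for e in ellipses:
        ep = _resample_halfcurve(e, hfun)
        if len(ep):
            # interface points must stay clearly inside the domain
            ep = ep[fd(ep) < -0.3 * hfun(ep)]
        pts.append(ep)
        crossings.extend(_axis_crossings(e))
    # axis segments between the trachea hole and the outer circle,
    # subdivided at every curve crossing
    ctr_y = geom.trachea.center[1]
    r_tr = geom.trachea.radius
    for lo, hi in ((ctr_y + r_tr, geom.outer_radius), (-geom.outer_radius, ctr_y - r_tr)):
        marks = sorted(
            {lo, hi, *[c for c in crossings if lo + 1e-12 < c < hi - 1e-12]}
        )
        for y0, y1 in zip(marks[:-1], marks[1:]):
            length = y1 - y0
            hloc = float(hfun(np.array([[0.0, 0.5 * (y0 + y1)]]))[0])
            n = max(1, int(round(length / hloc)))
            y = np.linspace(y0, y1, n + 1)[1:-1]
            pts.append(np.column_stack([np.zeros(len(y)), y]))
        pts.append(np.column_stack([np.zeros(len(marks)), marks]))
    allpts = np.vstack([p for p in pts if len(p)])
    # dedupe: greedy removal of crowded points (crossing interface curves
    # otherwise leave fixed-point pairs too close to fit free points between)
    hloc = hfun(allpts)
    tree = cKDTree(allpts)
    pairs = tree.query_pairs(float(0.55 * hloc.max()), output_type="ndarray")
    drop = np.zeros(len(allpts), bool)
    # axis points are anchors: prefer dropping off-axis members of a pair
    on_axis = allpts[:, 0] == 0.0
    for i, j in pairs:
        d = np.linalg.norm(allpts[i] - allpts[j])
        if d < 0.55 * min(hloc[i], hloc[j]) and not (drop[i] or drop[j]):
            if on_axis[i] and not on_axis[j]:
                victim = j
            elif on_axis[j] and not on_axis[i]:
                victim = i
            else:
                victim = max(i, j)
            drop[victim] = True
    return allpts[~drop]


# ---------------------------------------------------------------------------
# distmesh core (half domain)


def _signed_distance(geom: NeckGeometry):
    R = geom.outer_radius
    cx, cy = geom.trachea.center
    rt = geom.trachea.radius

    def fd(p: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(p)
        d_out = np.hypot(p[:, 0], p[:, 1]) - R
        d_tr = rt - np.hypot(p[:, 0] - cx, p[:, 1] - cy)
        return np.maximum(np.maximum(d_out, d_tr), -p[:, 0])

    return fd


def _distmesh_half(geom: NeckGeometry, hfun, h_target: float, maxiter: int = 120):
    fd = _signed_distance(geom)
    pfix = _fixed_points(geom, hfun)
    nfix = len(pfix)
    h0 = float(min(hfun(pfix).min(), h_target))
    geps = 1e-3 * h0
    deps = math.sqrt(np.finfo(float).eps) * h0

    # initial free points: hex lattice, density ~ 1/h^2, cleared around pfix
    R = geom.outer_radius
    x = np.arange(0.0, R + h0, h0)
    y = np.arange(-R, R + h0 * math.sqrt(3) / 2, h0 * math.sqrt(3) / 2)
    xx, yy = np.meshgrid(x, y)
    xx[1::2] += h0 / 2
    p = np.column_stack([xx.ravel(), yy.ravel()])
    p = p[fd(p) < -geps]
    hp = hfun(p)
    rng = np.random.default_rng(0)
    p = p[rng.random(len(p)) < (hp.min() / hp) ** 2]
    tree = cKDTree(pfix)
    d, _ = tree.query(p)
    p = p[d > 0.55 * hfun(p)]
    p = np.vstack([pfix, p])

    pold = np.full_like(p, np.inf)
    bars = None
    for it in range(maxiter):
        if np.max(np.linalg.norm(p - pold, axis=1)) > 0.1 * h0:
            pold = p.copy()
            tri = Delaunay(p)
            cent = p[tri.simplices].mean(axis=1)
            keep = fd(cent) < -geps
            simplices = tri.simplices[keep]
            bars = np.unique(
                np.sort(
                    np.vstack(
                        [simplices[:, [0, 1]], simplices[:, [1, 2]], simplices[:, [0, 2]]]
                    ),
                    axis=1,
                ),
                axis=0,
            )
        barvec = p[bars[:, 0]] - p[bars[:, 1]]
        L = np.linalg.norm(barvec, axis=1)
        hbars = hfun(0.5 * (p[bars[:, 0]] + p[bars[:, 1]]))
        L0 = hbars * 1.2 * math.sqrt((L**2).sum() / (hbars**2).sum())
        F = np.maximum(L0 - L, 0.0)
        Fvec = (F / np.maximum(L, 1e-30))[:, None] * barvec
        Ftot = np.zeros_like(p)
        np.add.at(Ftot, bars[:, 0], Fvec)
        np.add.at(Ftot, bars[:, 1], -Fvec)
        Ftot[:nfix] = 0.0
        p = p + 0.2 * Ftot
        # project escaped free points back onto the boundary
        d = fd(p)
        out = d > 0
        out[:nfix] = False
        if out.any():
            pe = p[out]
            dgx = (fd(pe + [deps, 0]) - fd(pe)) / deps
            dgy = (fd(pe + [0, deps]) - fd(pe)) / deps
            norm2 = dgx**2 + dgy**2
            norm2[norm2 == 0] = 1.0
            pe = pe - np.column_stack(
                [fd(pe) * dgx / norm2, fd(pe) * dgy / norm2]
            )
            p[out] = pe
        interior = fd(p) < -geps
        interior[:nfix] = False
        if interior.any():
            move = np.linalg.norm(0.2 * Ftot[interior], axis=1)
            if move.max() < 1e-3 * h0:
                break
    return p, nfix


# ---------------------------------------------------------------------------
# assembly of the mirrored mesh


def _mirror_mesh(p: np.ndarray, simplices: np.ndarray):
    p = p.copy()
    p[np.abs(p[:, 0]) < 1e-9, 0] = 0.0
    n = len(p)
    right = p[:, 0] > 0.0
    mirror_index = np.full(n, -1, dtype=int)
    mirror_index[~right] = np.nonzero(~right)[0]  # axis nodes map to themselves
    new_nodes = p[right] * [-1.0, 1.0]
    mirror_index[right] = n + np.arange(len(new_nodes))
    nodes = np.vstack([p, new_nodes])
    mirrored = mirror_index[simplices][:, ::-1]  # reverse to keep CCW
    elements = np.vstack([simplices, mirrored])
    return nodes, elements


def _orient_ccw(nodes: np.ndarray, elements: np.ndarray) -> np.ndarray:
    p = nodes[elements]
    area2 = (p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1]) - (
        p[:, 1, 1] - p[:, 0, 1]
    ) * (p[:, 2, 0] - p[:, 0, 0])
    flip = area2 < 0
    elements = elements.copy()
    elements[flip] = elements[flip][:, ::-1]
    return elements


def _boundary_edges(elements: np.ndarray):
    edges = np.vstack(
        [elements[:, [0, 1]], elements[:, [1, 2]], elements[:, [2, 0]]]
    )
    key = np.sort(edges, axis=1)
    _, idx, counts = np.unique(key, axis=0, return_index=True, return_counts=True)
    return key[idx[counts == 1]]


def generate_mesh(geom: NeckGeometry, h_target: float = 1.0e-3) -> Mesh:
    """Mirror-symmetric conforming triangulation of the neck geometry.

    Raises :class:`MeshingError` for a non-positive target or a degenerate
    (unmeshable) configuration.
    """
    if h_target <= 0:
        raise MeshingError("h_target must be > 0")
    hfun = _make_size_field(geom, h_target)
    p, nfix = _distmesh_half(geom, hfun, h_target)
    fd = _signed_distance(geom)
    tri = Delaunay(p)
    cent = p[tri.simplices].mean(axis=1)
    keep = fd(cent) < -1e-3 * h_target * 0.5
    simplices = tri.simplices[keep]
    if len(simplices) == 0:
        raise MeshingError("meshing produced no interior elements")

    nodes, elements = _mirror_mesh(p, simplices)
    elements = _orient_ccw(nodes, elements)

    region = geom.classify(nodes[elements].mean(axis=1))
    bad = (region == "outside") | (region == "trachea")
    if bad.any():  # centroid leaked across the polygonal boundary
        elements = elements[~bad]
        region = region[~bad]

    bedges = _boundary_edges(elements)
    mids = nodes[bedges].mean(axis=1)
    r_mid = np.hypot(mids[:, 0], mids[:, 1])
    outer = r_mid > 0.5 * (geom.outer_radius + geom.trachea.radius)
    ang = np.abs(np.arctan2(mids[:, 0], mids[:, 1]))
    tags = np.where(
        outer, np.where(ang <= geom.gamma1_half_angle, GAMMA1, GAMMA3), GAMMA2
    )
    return Mesh(
        nodes=nodes,
        elements=elements,
        element_region=region,
        boundary_edges=bedges,
        boundary_tags=tags,
        h_target=h_target,
    )


def make_strip_mesh(
    length: float,
    width: float,
    h: float,
    tissue: str = "muscle",
) -> Mesh:
    """Structured triangulation of the rectangle [0, L] x [0, W].

    Boundary tags: x = 0 -> GAMMA3 (prescribed temperature), x = L -> GAMMA1
    (convective), lateral sides -> GAMMA2 (insulated).  Used for validation
    against the one-dimensional bioheat slab solution.
    """
    nx = max(1, int(round(length / h)))
    ny = max(1, int(round(width / h)))
    xs = np.linspace(0.0, length, nx + 1)
    ys = np.linspace(0.0, width, ny + 1)
    xx, yy = np.meshgrid(xs, ys, indexing="ij")
    nodes = np.column_stack([xx.ravel(), yy.ravel()])

    def nid(i, j):
        return i * (ny + 1) + j

    tris = []
    for i in range(nx):
        for j in range(ny):
            a, b, c, d = nid(i, j), nid(i + 1, j), nid(i + 1, j + 1), nid(i, j + 1)
            if (i + j) % 2 == 0:
                tris += [[a, b, c], [a, c, d]]
            else:
                tris += [[a, b, d], [b, c, d]]
    elements = np.asarray(tris, dtype=int)
    region = np.full(len(elements), tissue, dtype=object)
    bedges = _boundary_edges(elements)
    mids = nodes[bedges].mean(axis=1)
    tags = np.where(
        np.isclose(mids[:, 0], 0.0),
        GAMMA3,
        np.where(np.isclose(mids[:, 0], length), GAMMA1, GAMMA2),
    )
    return Mesh(
        nodes=nodes,
        elements=elements,
        element_region=region,
        boundary_edges=bedges,
        boundary_tags=tags,
        h_target=h,
    )


def convergence_report(
    geom: NeckGeometry,
    h_list: list[float],
    registry=None,
    bc=None,
    probe: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Self-convergence table: steady probe temperature vs mesh size.

    ``h_list`` must be sorted descending with at least two entries.  The
    probe defaults to the front-of-nodule skin point.  Columns: h,
    probe_temperature, delta (change from the previous row).
    """
    if len(h_list) < 2:
        raise ValueError("h_list needs at least two entries")
    if list(h_list) != sorted(h_list, reverse=True):
        raise ValueError("h_list must be sorted descending")
    from . import fem
    from .geometry import probe_points
    from .params import PerfusionPreset, make_tissue_registry

    if registry is None:
        registry = make_tissue_registry(PerfusionPreset.PER_MINUTE_GLAND)
    if bc is None:
        bc = fem.BoundarySpec()
    if probe is None:
        probe = probe_points(geom).front_of_nodule

    rows = []
    prev = None
    for h in h_list:
        try:
            mesh = generate_mesh(geom, h)
            field = fem.solve_steady(mesh, registry, bc)
        except Exception as exc:
            raise MeshingError(f"solve failed at h={h}: {exc}") from exc
        temp = fem.evaluate_field(field, probe)
        rows.append(
            {"h": h, "probe_temperature": temp, "delta": np.nan if prev is None else temp - prev}
        )
        prev = temp
    return pd.DataFrame(rows)
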