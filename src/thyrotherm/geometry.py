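"""Parametric 2D neck cross-section with tagged tissue regions.

The neck is a disc whose perimeter (36 cm) fixes the outer radius.  Skin,
fat and muscle are concentric annuli (skin 0.1 cm, muscle 1.0 cm, fat
configurable, possibly zero); the remaining interior is muscle-equivalent
tissue containing a circular trachea hole on the sagittal axis and two
mirror-image elliptic thyroid lobes, with an elliptic nodule concentric in
the left lobe.

Coordinates: metres, origin at the disc centre, sagittal axis x = 0,
anterior direction +y.  The patient's left (the nodule side) is x < 0.
Arc coordinates on the skin are measured from the anterior midline,
negative on the nodule side.  Boundary arcs: GAMMA1 = anterior half of the
outer circle (convective), GAMMA3 = posterior half (prescribed temperature),
GAMMA2 = trachea wall (insulated).

The lobes are not dimensioned in the source study; defaults here put the
lobe centres at polar distance 2.2 cm, +/-30 deg off the anterior midline
(which places the skin point in front of the nodule at arc -3 cm), sized as
the largest nodule preset plus a 2 mm shell and oriented with the major axis
tangential.  With those defaults the gland abuts the muscle layer under the
thickest (1.2 cm) fat preset.  All of this is configurable and serialized
with the geometry.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "GeometryError",
    "Circle",
    "Ellipse",
    "NeckGeometry",
    "ProbePoints",
    "build_neck_geometry",
    "classify_point",
    "probe_points",
    "NECK_PERIMETER",
    "OUTER_RADIUS",
]

NECK_PERIMETER = 0.36
OUTER_RADIUS = NECK_PERIMETER / (2.0 * math.pi)

SKIN_THICKNESS = 0.001
MUSCLE_THICKNESS = 0.010

#: Default lobe placement: angular offset from the anterior midline; the
#: polar distance defaults to "gland applied to the deep face of the muscle
#: layer" (see build_neck_geometry), leaving this clearance below it.
LOBE_ANGLE = math.radians(30.0)
LOBE_MUSCLE_CLEARANCE = 0.002
#: Shell added around the largest nodule to form the lobe semi-axes.
LOBE_SHELL = 0.002
#: Largest nodule semi-axes (see params.NODULE_SIZE_PRESETS).
_LARGEST_NODULE = (0.0157, 0.0090)

TRACHEA_RADIUS = 0.008
TRACHEA_CENTER = (0.0, 0.0)


class GeometryError(ValueError):
    """A geometric containment or validity constraint is violated."""


def _as_points(p) -> np.ndarray:
    pts = np.atleast_2d(np.asarray(p, dtype=float))
    if pts.shape[-1] != 2:
        raise ValueError("points must have shape (..., 2)")
    return pts


@dataclass(frozen=True)
class Circle:
    center: tuple[float, float]
    radius: float

    def contains(self, p) -> np.ndarray:
        pts = _as_points(p)
        d = np.hypot(pts[:, 0] - self.center[0], pts[:, 1] - self.center[1])
        return d <= self.radius

    def sample(self, spacing: float) -> np.ndarray:
        n = max(16, int(math.ceil(2 * math.pi * self.radius / spacing)))
        t = np.linspace(0.0, 2 * math.pi, n, endpoint=False)
        return np.column_stack(
            [
                self.center[0] + self.radius * np.cos(t),
                self.center[1] + self.radius * np.sin(t),
            ]
        )

    def to_dict(self) -> dict:
        return {"type": "circle", "center": list(self.center), "radius": self.radius}


@dataclass(frozen=True)
class Ellipse:
    """Ellipse with semi-axes (a, b); ``angle`` rotates the a-axis from +x."""

    center: tuple[float, float]
    a: float
    b: float
    angle: float = 0.0

    @property
    def area(self) -> float:
        return math.pi * self.a * self.b

    def _local(self, pts: np.ndarray) -> np.ndarray:
        c, s = math.cos(self.angle), math.sin(self.angle)
        dx = pts[:, 0] - self.center[0]
        dy = pts[:, 1] - self.center[1]
        return np.column_stack([c * dx + s * dy, -s * dx + c * dy])

    def contains(self, p, scale: float = 1.0) -> np.ndarray:
        loc = self._local(_as_points(p))
        return (loc[:, 0] / (scale * self.a)) ** 2 + (
            loc[:, 1] / (scale * self.b)
        ) ** 2 <= 1.0

    def boundary(self, t: np.ndarray) -> np.ndarray:
        c, s = math.cos(self.angle), math.sin(self.angle)
        x = self.a * np.cos(t)
        y = self.b * np.sin(t)
        return np.column_stack(
            [self.center[0] + c * x - s * y, self.center[1] + s * x + c * y]
        )

    def perimeter(self) -> float:
        # Ramanujan's approximation
        h = ((self.a - self.b) / (self.a + self.b)) ** 2
        return math.pi * (self.a + self.b) * (
            1 + 3 * h / (10 + math.sqrt(4 - 3 * h))
        )

    def sample(self, spacing: float) -> np.ndarray:
        n = max(24, int(math.ceil(self.perimeter() / spacing)))
        t = np.linspace(0.0, 2 * math.pi, n, endpoint=False)
        return self.boundary(t)

    def mirrored(self) -> "Ellipse":
        """Reflection across the sagittal axis x = 0."""
        return Ellipse(
            center=(-self.center[0], self.center[1]),
            a=self.a,
            b=self.b,
            angle=-self.angle,
        )

    def to_dict(self) -> dict:
        return {
            "type": "ellipse",
            "center": list(self.center),
            "semi_axes": [self.a, self.b],
            "angle": self.angle,
        }


@dataclass(frozen=True)
class ProbePoints:
    """Named measurement points of a geometry (metres).

    ``front_of_nodule``: skin point radially outward of the nodule centre;
    ``contralateral``: its mirror across the sagittal axis;
    ``nodule_center`` and ``lobe_mirror``: the nodule centre and its mirror
    inside the healthy lobe.  ``front_arc`` is the arc coordinate of the
    front probe (negative = nodule side).
    """

    front_of_nodule: tuple[float, float]
    contralateral: tuple[float, float]
    nodule_center: tuple[float, float]
    lobe_mirror: tuple[float, float]
    front_arc: float


@dataclass(frozen=True)
class NeckGeometry:
    outer_radius: float
    skin_thickness: float
    fat_thickness: float
    muscle_thickness: float
    trachea: Circle
    lobes: tuple[Ellipse, Ellipse]  # (left/nodule side, right)
    nodule: Ellipse
    gamma1_half_angle: float = math.pi / 2  # angular half-extent of GAMMA1

    # interface radii ------------------------------------------------------

    @property
    def r_skin_inner(self) -> float:
        return self.outer_radius - self.skin_thickness

    @property
    def r_fat_inner(self) -> float:
        return self.r_skin_inner - self.fat_thickness

    @property
    def r_muscle_inner(self) -> float:
        return self.r_fat_inner - self.muscle_thickness

    @property
    def layer_radii(self) -> list[float]:
        """Distinct internal layer-interface radii (fat interface collapses
        onto the skin one when fat_thickness = 0)."""
        radii = [self.r_skin_inner, self.r_fat_inner, self.r_muscle_inner]
        out: list[float] = []
        for r in radii:
            if not out or abs(out[-1] - r) > 1e-12:
                out.append(r)
        return out

    # region queries -------------------------------------------------------

    def classify(self, p) -> np.ndarray:
        """Vectorized tissue label per point.

        Precedence: outside the disc -> 'outside'; inside the trachea hole ->
        'trachea'; then nodule > thyroid > annular layer by radius, with the
        deep interior counting as muscle.
        """
        pts = _as_points(p)
        r = np.hypot(pts[:, 0], pts[:, 1])
        labels = np.full(len(pts), "muscle", dtype=object)
        labels[r > self.r_fat_inner] = "fat"
        labels[r > self.r_skin_inner] = "skin"
        inner = r <= self.r_muscle_inner
        for lobe in self.lobes:
            labels[inner & lobe.contains(pts)] = "thyroid"
        labels[inner & self.nodule.contains(pts)] = "nodule"
        labels[self.trachea.contains(pts)] = "trachea"
        labels[r > self.outer_radius + 1e-12] = "outside"
        return labels

    def classify_one(self, p) -> str:
        return str(self.classify(p)[0])

    def point_at_arc(self, s: float | np.ndarray) -> np.ndarray:
        """Skin-surface point at arc coordinate ``s`` (m, negative = nodule
        side), measured from the anterior midline (0, R)."""
        alpha = np.asarray(s, dtype=float) / self.outer_radius
        return np.stack(
            [
                self.outer_radius * np.sin(alpha),
                self.outer_radius * np.cos(alpha),
            ],
            axis=-1,
        )

    def mirrored(self) -> "NeckGeometry":
        """Whole geometry reflected across the sagittal axis."""
        return NeckGeometry(
            outer_radius=self.outer_radius,
            skin_thickness=self.skin_thickness,
            fat_thickness=self.fat_thickness,
            muscle_thickness=self.muscle_thickness,
            trachea=Circle(
                (-self.trachea.center[0], self.trachea.center[1]),
                self.trachea.radius,
            ),
            lobes=(self.lobes[1].mirrored(), self.lobes[0].mirrored()),
            nodule=self.nodule.mirrored(),
            gamma1_half_angle=self.gamma1_half_angle,
        )

    def interface_curves(self) -> list[Circle | Ellipse]:
        """All internal interface curves that the mesh must resolve.

        Includes the mirror image of the nodule ellipse so that meshes built
        from these curves are exactly mirror-symmetric point sets (the
        phantom curve only adds resolution; region tags come from
        ``classify``).
        """
        curves: list[Circle | Ellipse] = [
            Circle((0.0, 0.0), r) for r in self.layer_radii
        ]
        curves.extend(self.lobes)
        curves.append(self.nodule)
        curves.append(self.nodule.mirrored())
        return curves

    def to_json(self) -> str:
        return json.dumps(
            {
                "outer_radius": self.outer_radius,
                "skin_thickness": self.skin_thickness,
                "fat_thickness": self.fat_thickness,
                "muscle_thickness": self.muscle_thickness,
                "trachea": self.trachea.to_dict(),
                "lobes": [lb.to_dict() for lb in self.lobes],
                "nodule": self.nodule.to_dict(),
                "gamma1_half_angle": self.gamma1_half_angle,
            },
            indent=2,
        )


def _require_inside_ellipse(
    inner: Ellipse, outer: Ellipse, what: str, n: int = 512
) -> None:
    t = np.linspace(0, 2 * math.pi, n, endpoint=False)
    pts = inner.boundary(t)
    if not outer.contains(pts).all():
        raise GeometryError(f"{what}: not contained in {outer}")


def _require_clear_of_circle(e: Ellipse, c: Circle, what: str, n: int = 1024) -> None:
    t = np.linspace(0, 2 * math.pi, n, endpoint=False)
    pts = e.boundary(t)
    d = np.hypot(pts[:, 0] - c.center[0], pts[:, 1] - c.center[1])
    inside_center = bool(
        e.contains(np.asarray([c.center]))[0]
    )
    if (d < c.radius).any() or inside_center:
        raise GeometryError(f"{what}: overlaps the trachea circle {c}")


def build_neck_geometry(
    fat_thickness: float = 0.006,
    nodule_semi_axes: tuple[float, float] = _LARGEST_NODULE,
    *,
    lobe_distance: float | None = None,
    lobe_angle: float = LOBE_ANGLE,
    lobe_semi_axes: tuple[float, float] | None = None,
    trachea_radius: float = TRACHEA_RADIUS,
    trachea_center: tuple[float, float] = TRACHEA_CENTER,
) -> NeckGeometry:
    """Build the default parametric neck geometry.

    ``lobe_distance`` (polar distance of the lobe centres) defaults to
    placing the gland directly against the deep face of the muscle layer
    with a small meshing clearance — anatomically, the thyroid lies under
    the strap muscles, so a thicker fat layer pushes it deeper.

    Raises :class:`GeometryError` naming the violated containment when the
    nodule does not fit inside the lobe, the lobe inside the interior disc,
    or either overlaps the trachea hole.
    """
    if fat_thickness < 0:
        raise GeometryError("fat_thickness must be >= 0")
    a_n, b_n = nodule_semi_axes
    if a_n <= 0 or b_n <= 0:
        raise GeometryError("nodule semi-axes must be > 0")
    if lobe_semi_axes is None:
        lobe_semi_axes = (
            max(a_n, _LARGEST_NODULE[0]) + LOBE_SHELL,
            max(b_n, _LARGEST_NODULE[1]) + LOBE_SHELL,
        )
    if lobe_distance is None:
        r_muscle_inner = (
            OUTER_RADIUS - SKIN_THICKNESS - fat_thickness - MUSCLE_THICKNESS
        )
        lobe_distance = r_muscle_inner - lobe_semi_axes[1] - LOBE_MUSCLE_CLEARANCE

    # Left lobe centre at polar distance, lobe_angle off the +y axis toward -x;
    # major axis tangential (perpendicular to the radial direction).
    cx = -lobe_distance * math.sin(lobe_angle)
    cy = lobe_distance * math.cos(lobe_angle)
    left = Ellipse((cx, cy), *lobe_semi_axes, angle=lobe_angle)
    right = left.mirrored()
    nodule = Ellipse((cx, cy), a_n, b_n, angle=lobe_angle)
    trachea = Circle(tuple(trachea_center), trachea_radius)

    geom = NeckGeometry(
        outer_radius=OUTER_RADIUS,
        skin_thickness=SKIN_THICKNESS,
        fat_thickness=float(fat_thickness),
        muscle_thickness=MUSCLE_THICKNESS,
        trachea=trachea,
        lobes=(left, right),
        nodule=nodule,
    )

    _require_inside_ellipse(nodule, left, "nodule")
    # Lobes must stay inside the interior disc (below the muscle layer).
    t = np.linspace(0, 2 * math.pi, 512, endpoint=False)
    for name, lobe in (("left lobe", left), ("right lobe", right)):
        r = np.hypot(*lobe.boundary(t).T)
        if (r > geom.r_muscle_inner + 1e-12).any():
            raise GeometryError(
                f"{name}: extends beyond the interior disc "
                f"(radius {geom.r_muscle_inner:.4f} m) for "
                f"fat_thickness={fat_thickness}"
            )
    _require_clear_of_circle(nodule, trachea, "nodule")
    return geom


def classify_point(geom: NeckGeometry, p) -> str | np.ndarray:
    """Tissue label at ``p`` ('outside' beyond the disc, 'trachea' in the
    hole).  Accepts a single point or an (n, 2) array."""
    pts = np.asarray(p, dtype=float)
    if pts.ndim == 1:
        return geom.classify_one(pts)
    return geom.classify(pts)


def probe_points(geom: NeckGeometry) -> ProbePoints:
    """The four named probes used throughout the study."""
    cx, cy = geom.nodule.center
    d = math.hypot(cx, cy)
    if d == 0:
        raise GeometryError("nodule centred at the origin has no radial probe")
    ux, uy = cx / d, cy / d
    front = (geom.outer_radius * ux, geom.outer_radius * uy)
    # signed arc from the anterior midline; nodule side (x<0) is negative
    alpha = math.atan2(ux, uy)
    front_arc = geom.outer_radius * alpha
    return ProbePoints(
        front_of_nodule=front,
        contralateral=(-front[0], front[1]),
        nodule_center=(cx, cy),
        lobe_mirror=(-cx, cy),
        front_arc=front_arc,
    )
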