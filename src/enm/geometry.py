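"""Nerve cross-section geometry: outlines, fascicles, perineurium layering.

A cross-section is a 2D description (units: mm) that is conceptually extruded
along z to form the 3D volume-conductor domain.  Two synthetic anatomies are
built in: a *proximal* sciatic section (37 fascicles in an ~18.7 x 8.8 mm
ellipse) and a *distal* one (31 fascicles in an ~11.5 x 6.4 mm ellipse,
~58.2 mm^2).  Each fascicle carries a perineurium sheath whose thickness is
3% of the fascicle's equivalent diameter; the interior is endoneurium.

Custom anatomies can be loaded from a plain-text contour file (one polygon
per block, ``NERVE`` / ``FASCICLE <id>`` headers, ``x y`` vertex pairs in mm).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Point, Polygon
from shapely.prepared import prep

PERINEURIUM_FRACTION = 0.03  # sheath thickness as a fraction of equivalent diameter

# Fascicle size classes (equivalent diameter, mm)
SMALL_MAX = 0.4
BIG_MIN = 0.8

#: Published envelope statistics per synthetic anatomy.
#: full axes (mm), fascicle count, target total fascicular area (mm^2).
#: The proximal fascicular area follows from the reported whole-nerve fiber
#: population (13.5 k fibers at 240 /mm^2 -> 56.25 mm^2); the distal target
#: uses the same areal fill fraction of its envelope.
ANATOMIES = {
    "proximal": {"axes": (18.7, 8.8), "n_fascicles": 37, "fascicular_area": 56.25},
    "distal": {"axes": (11.5, 6.4), "n_fascicles": 31, "fascicular_area": 25.2},
}

DEFAULT_EXTRUSION_MM = 30.8  # solver domain length (2 x 15.4 mm)


class GeometryError(ValueError):
    """Invalid or inconsistent cross-section geometry."""


@dataclass(frozen=True)
class Fascicle:
    """One fascicle: closed contour plus derived scalar descriptors (mm)."""

    id: int
    contour: np.ndarray  # (N, 2) vertices, open ring

    def __post_init__(self):
        poly = Polygon(self.contour)
        if not poly.is_valid or poly.area <= 0:
            raise GeometryError(f"fascicle {self.id}: contour is self-intersecting or degenerate")
        object.__setattr__(self, "_polygon", poly)

    @property
    def polygon(self) -> Polygon:
        return self._polygon

    @property
    def area(self) -> float:
        return self._polygon.area

    @property
    def centroid(self) -> np.ndarray:
        c = self._polygon.centroid
        return np.array([c.x, c.y])

    @property
    def equivalent_diameter(self) -> float:
        """Diameter of the circle with the same area, mm."""
        return 2.0 * np.sqrt(self.area / np.pi)

    @property
    def perineurium_thickness(self) -> float:
        return PERINEURIUM_FRACTION * self.equivalent_diameter

    def endoneurium_polygon(self) -> Polygon:
        """Fascicle lumen: contour shrunk inward by the perineurium thickness."""
        inner = self._polygon.buffer(-self.perineurium_thickness)
        if inner.is_empty:
            # Degenerate only for absurdly thin fascicles; keep a nonempty core.
            inner = self._polygon.buffer(-0.25 * self.equivalent_diameter)
        return inner


def classify_fascicle_size(fascicle) -> str:
    """Size class by equivalent diameter: ``small`` (<0.4 mm), ``medium`` or ``big`` (>0.8 mm).

    Accepts a :class:`Fascicle` or a plain diameter in mm.
    """
    d = fascicle.equivalent_diameter if hasattr(fascicle, "equivalent_diameter") else float(fascicle)
    if d <= 0:
        raise GeometryError("equivalent diameter must be positive")
    if d < SMALL_MAX:
        return "small"
    if d > BIG_MIN:
        return "big"
    return "medium"


@dataclass
class NerveCrossSection:
    """Nerve outline with its fascicles; extruded along z for the solver."""

    outline: np.ndarray  # (N, 2)
    fascicles: list[Fascicle]
    anatomy_label: str = "custom"
    extrusion_length: float = DEFAULT_EXTRUSION_MM

    outline_polygon: Polygon = field(init=False, repr=False)

    def __post_init__(self):
        self.outline_polygon = Polygon(self.outline)
        if not self.outline_polygon.is_valid or self.outline_polygon.area <= 0:
            raise GeometryError("nerve outline is self-intersecting or degenerate")
        self.validate()

    def validate(self) -> None:
        outline = prep(self.outline_polygon)
        for f in self.fascicles:
            if not outline.contains(f.polygon):
                raise GeometryError(f"fascicle {f.id} is not strictly inside the nerve outline")
        for i, a in enumerate(self.fascicles):
            for b in self.fascicles[i + 1 :]:
                if a.polygon.intersects(b.polygon):
                    raise GeometryError(f"fascicles {a.id} and {b.id} overlap")
        if self.total_fascicular_area >= self.outline_polygon.area:
            raise GeometryError("total fascicular area exceeds nerve outline area")

    @property
    def total_fascicular_area(self) -> float:
        return float(sum(f.area for f in self.fascicles))

    @property
    def n_fascicles(self) -> int:
        return len(self.fascicles)

    @property
    def major_axis(self) -> float:
        xmin, ymin, xmax, ymax = self.outline_polygon.bounds
        return max(xmax - xmin, ymax - ymin)

    @property
    def minor_axis(self) -> float:
        xmin, ymin, xmax, ymax = self.outline_polygon.bounds
        return min(xmax - xmin, ymax - ymin)

    def fascicle_index(self) -> dict[int, Fascicle]:
        return {f.id: f for f in self.fascicles}


# ---------------------------------------------------------------------------
# Synthetic anatomy generator
# ---------------------------------------------------------------------------

def _ellipse_ring(a: float, b: float, n: int = 128) -> np.ndarray:
    th = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
    return np.column_stack([a * np.cos(th), b * np.sin(th)])


def _draw_diameters(rng: np.random.Generator, n: int, target_area: float) -> np.ndarray:
    """Equivalent diameters: truncated log-normal, all three size classes present,
    big-class diameters rescaled to land on the target total area."""
    sigma = 0.5
    mean_sq = target_area / n / (np.pi / 4.0)  # E[d^2] needed without truncation
    mu = 0.5 * (np.log(mean_sq) - 2 * sigma**2)
    d = np.exp(rng.normal(mu, sigma, size=n))
    d = np.clip(d, 0.15, 2.0)
    order = np.argsort(d)
    # make sure each size class holds at least two fascicles
    small = d < SMALL_MAX
    if small.sum() < 2:
        d[order[:2]] = rng.uniform(0.2, 0.38, size=2)
    medium = (d >= SMALL_MAX) & (d <= BIG_MIN)
    if medium.sum() < 2:
        mid = order[n // 3 : n // 3 + 2]
        d[mid] = rng.uniform(0.45, 0.75, size=2)
    if (d > BIG_MIN).sum() < 2:
        d[order[-2:]] = rng.uniform(0.9, 1.3, size=2)
    # rescale only the big class toward the area target (it dominates the area)
    for _ in range(8):
        areas = np.pi * d**2 / 4.0
        big = d > BIG_MIN
        deficit = target_area - areas[~big].sum()
        if deficit <= 0 or not big.any():
            break
        s = np.sqrt(deficit / areas[big].sum())
        d[big] = np.clip(d[big] * s, 0.82, 2.0)
        if abs(np.pi * (d**2).sum() / 4.0 - target_area) / target_area < 0.01:
            break
    return d


def _wavy_circle(rng: np.random.Generator, center: np.ndarray, r: float, n: int = 64) -> np.ndarray:
    """Gently perturbed circle; perturbation stays within the placement envelope."""
    th = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
    a1, a2 = rng.uniform(0.0, 0.04, size=2)
    p1, p2 = rng.uniform(0.0, 2 * np.pi, size=2)
    rr = r * (1.0 + a1 * np.cos(2 * th + p1) + a2 * np.cos(3 * th + p2))
    return center + np.column_stack([rr * np.cos(th), rr * np.sin(th)])


_MIN_GAP = 0.05  # mm, minimum inter-fascicle clearance
_BOUNDARY_MARGIN = 0.15  # mm, clearance between fascicle and nerve outline


def synthesize_cross_section(
    anatomy_label: str,
    seed: int,
    extrusion_length: float = DEFAULT_EXTRUSION_MM,
) -> NerveCrossSection:
    """Generate a synthetic sciatic cross-section matching published statistics.

    Parameters
    ----------
    anatomy_label : {"proximal", "distal"}
        Which published section to emulate (fascicle count, envelope,
        total fascicular area).
    seed : int
        Non-negative seed; identical seeds give bitwise-identical geometry.
    """
    if anatomy_label not in ANATOMIES:
        raise GeometryError(
            f"unknown anatomy label {anatomy_label!r}; valid labels: {sorted(ANATOMIES)}"
        )
    if seed < 0:
        raise GeometryError("seed must be a non-negative integer")
    spec = ANATOMIES[anatomy_label]
    a, b = spec["axes"][0] / 2.0, spec["axes"][1] / 2.0
    n = spec["n_fascicles"]
    outline_ring = _ellipse_ring(a, b)
    outline = Polygon(outline_ring)
    label_code = zlib.crc32(anatomy_label.encode()) % (2**31)
    rng = np.random.default_rng([int(seed), label_code])

    diam = _draw_diameters(rng, n, spec["fascicular_area"])
    order = np.argsort(diam)[::-1]  # place the big ones first

    scale = 1.0
    for restart in range(60):
        if restart and restart % 10 == 0:
            scale *= 0.97
        placed_c: list[np.ndarray] = []
        placed_r: list[float] = []
        ok = True
        for idx in order:
            r = diam[idx] * scale / 2.0
            r_env = 1.05 * r + _MIN_GAP / 2.0  # envelope covers contour waviness + half gap
            for _ in range(4000):
                x = rng.uniform(-a + r_env, a - r_env)
                y = rng.uniform(-b + r_env, b - r_env)
                m = _BOUNDARY_MARGIN + r_env
                if (x / (a - m)) ** 2 + (y / (b - m)) ** 2 > 1.0:
                    continue
                c = np.array([x, y])
                if placed_c:
                    dd = np.linalg.norm(np.asarray(placed_c) - c, axis=1)
                    if np.any(dd < np.asarray(placed_r) + r_env):
                        continue
                placed_c.append(c)
                placed_r.append(r_env)
                break
            else:
                ok = False
                break
        if ok:
            break
    else:
        raise GeometryError(f"could not pack {n} fascicles for anatomy {anatomy_label!r}")

    fascicles = []
    for fid, (idx, c, r_env) in enumerate(zip(order, placed_c, placed_r)):
        r = diam[idx] * scale / 2.0
        fascicles.append(Fascicle(id=fid, contour=_wavy_circle(rng, c, r)))
    return NerveCrossSection(
        outline=outline_ring,
        fascicles=fascicles,
        anatomy_label=anatomy_label,
        extrusion_length=extrusion_length,
    )


def cross_section_from_circles(
    outline_axes: tuple[float, float],
    circles: list[tuple[float, float, float]],
    anatomy_label: str = "custom",
) -> NerveCrossSection:
    """Build a simple cross-section from (cx, cy, diameter) circular fascicles.

    Convenience for toy anatomies in examples and tests; the outline is an
    ellipse with the given full axes (mm).
    """
    outline = _ellipse_ring(outline_axes[0] / 2.0, outline_axes[1] / 2.0)
    th = np.linspace(0.0, 2 * np.pi, 64, endpoint=False)
    fascicles = [
        Fascicle(id=i, contour=np.column_stack([cx + d / 2 * np.cos(th), cy + d / 2 * np.sin(th)]))
        for i, (cx, cy, d) in enumerate(circles)
    ]
    return NerveCrossSection(outline=outline, fascicles=fascicles, anatomy_label=anatomy_label)


# ---------------------------------------------------------------------------
# Contour file dialect
# ---------------------------------------------------------------------------

def save_cross_section(section: NerveCrossSection, path) -> None:
    """Write the plain-text contour dialect (``NERVE`` / ``FASCICLE <id>`` blocks)."""
    with open(path, "w") as fh:
        fh.write("NERVE\n")
        for x, y in section.outline:
            fh.write(f"{x:.9f} {y:.9f}\n")
        for f in section.fascicles:
            fh.write(f"FASCICLE {f.id}\n")
            for x, y in f.contour:
                fh.write(f"{x:.9f} {y:.9f}\n")


def load_cross_section(path, extrusion_length: float = DEFAULT_EXTRUSION_MM) -> NerveCrossSection:
    """Read a contour file and return a validated :class:`NerveCrossSection`.

    The file lists one ``NERVE`` outline polygon and at least one
    ``FASCICLE <id>`` polygon; vertices are ``x y`` pairs in mm.
    """
    outline = None
    fascicles: list[tuple[int, list[list[float]]]] = []
    current: list[list[float]] | None = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line.upper().startswith("NERVE"):
                current = []
                outline = current
            elif line.upper().startswith("FASCICLE"):
                parts = line.split()
                if len(parts) != 2:
                    raise GeometryError(f"line {lineno}: expected 'FASCICLE <id>'")
                current = []
                fascicles.append((int(parts[1]), current))
            else:
                if current is None:
                    raise GeometryError(f"line {lineno}: vertex before any polygon header")
                xy = line.split()
                if len(xy) != 2:
                    raise GeometryError(f"line {lineno}: expected 'x y' vertex pair")
                current.append([float(xy[0]), float(xy[1])])
    if outline is None or len(outline) < 3:
        raise GeometryError("contour file has no valid NERVE outline")
    if not fascicles:
        raise GeometryError("contour file lists no fascicles")
    fas = [Fascicle(id=fid, contour=np.asarray(verts)) for fid, verts in fascicles]
    return NerveCrossSection(
        outline=np.asarray(outline),
        fascicles=fas,
        anatomy_label="custom",
        extrusion_length=extrusion_length,
    )
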