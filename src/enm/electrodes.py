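"""Parametric TIME and FINE electrode geometries and their placement.

Coordinates follow the solver convention: x/y span the nerve cross-section
(x = medio-lateral, along the nerve's major axis), z runs along the nerve,
origin at the electrode center.  Units are mm.

TIME (transversal intrafascicular multichannel electrode): a 20-um-thick
polyimide ribbon inserted across the nerve in the cross-sectional plane.
The shaft's long axis lies along x, its width along z; circular 60-um active
sites (AS) sit on both faces (y = +/- thickness/2), the two faces offset by
half the inter-site pitch.

FINE (flat interface nerve electrode, no-compression variant): a rectangular
insulating frame around the nerve with square 0.5 x 0.5 mm ASs on the inner
top and bottom faces.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import json

import numpy as np
from shapely.geometry import Point

from enm.geometry import NerveCrossSection

VALID_AS_COUNTS = (12, 16, 20, 24)

TIME_THICKNESS = 0.020  # mm
TIME_AS_DIAMETER = 0.060  # mm
TIME_SHAFT_LENGTH = {"proximal": 18.0, "distal": 10.0}  # mm
TIME_WIDTH_RANGE = (0.380, 0.670)  # mm, linear in n_as over VALID_AS_COUNTS

FINE_FRAME = {"proximal": (18.75, 8.85), "distal": (10.9, 7.0)}  # inner opening, mm
FINE_AS_SIDE = 0.5  # mm
FINE_WALL = 0.3  # mm, frame wall thickness (solver substrate)
FINE_AXIAL_LENGTH = 5.0  # mm, cuff extent along z

SUBSTRATE_CONDUCTIVITY = 6.67e-14  # S/m, polyimide


class ElectrodeError(ValueError):
    """Invalid electrode specification or placement."""


@dataclass(frozen=True)
class ElectrodeSpec:
    """One electrode variant with its active-site layout (local coordinates)."""

    kind: str  # "TIME" | "FINE"
    anatomy: str
    n_as: int
    shaft_length: float  # TIME: shaft length along x; FINE: opening width
    shaft_width: float  # TIME: ribbon width along z; FINE: opening height
    shaft_thickness: float
    as_positions: np.ndarray  # (n_as, 3) local xyz
    as_face: np.ndarray  # (n_as,) +1 top / upper face, -1 bottom / lower face
    as_shape: str  # "circle" | "square"
    as_size: float  # diameter or side, mm
    substrate_conductivity: float = SUBSTRATE_CONDUCTIVITY

    @property
    def pitch(self) -> float:
        """Center-to-center spacing of consecutive same-face ASs along x."""
        xs = np.sort(self.as_positions[self.as_face > 0, 0])
        return float(xs[1] - xs[0]) if len(xs) > 1 else 0.0

    def to_json(self) -> str:
        d = asdict(self)
        d["as_positions"] = self.as_positions.tolist()
        d["as_face"] = self.as_face.tolist()
        return json.dumps(d, indent=1)


def _check_n_as(n_as: int) -> None:
    if n_as not in VALID_AS_COUNTS:
        raise ElectrodeError(f"invalid active-site count {n_as}; valid counts: {VALID_AS_COUNTS}")


def build_time(n_as: int, anatomy_label: str) -> ElectrodeSpec:
    """TIME electrode: 18 mm (proximal) or 10 mm (distal) shaft, n_as/2 sites
    per face, evenly pitched, opposite faces shifted by half the pitch."""
    _check_n_as(n_as)
    if anatomy_label not in TIME_SHAFT_LENGTH:
        raise ElectrodeError(f"unknown anatomy {anatomy_label!r}; valid: {sorted(TIME_SHAFT_LENGTH)}")
    length = TIME_SHAFT_LENGTH[anatomy_label]
    lo, hi = TIME_WIDTH_RANGE
    width = lo + (hi - lo) * (n_as - VALID_AS_COUNTS[0]) / (VALID_AS_COUNTS[-1] - VALID_AS_COUNTS[0])
    per_face = n_as // 2
    pitch = length / (per_face + 1)
    base = (np.arange(per_face) - (per_face - 1) / 2.0) * pitch
    y = TIME_THICKNESS / 2.0
    top = np.column_stack([base - pitch / 4.0, np.full(per_face, y), np.zeros(per_face)])
    bot = np.column_stack([base + pitch / 4.0, np.full(per_face, -y), np.zeros(per_face)])
    pos = np.vstack([top, bot])
    face = np.concatenate([np.ones(per_face), -np.ones(per_face)])
    return ElectrodeSpec(
        kind="TIME",
        anatomy=anatomy_label,
        n_as=n_as,
        shaft_length=length,
        shaft_width=width,
        shaft_thickness=TIME_THICKNESS,
        as_positions=pos,
        as_face=face,
        as_shape="circle",
        as_size=TIME_AS_DIAMETER,
    )


def build_fine(n_as: int, anatomy_label: str) -> ElectrodeSpec:
    """FINE cuff: rectangular frame of the published inner opening with square
    ASs evenly split between the two long (top/bottom) inner faces."""
    _check_n_as(n_as)
    if anatomy_label not in FINE_FRAME:
        raise ElectrodeError(f"unknown anatomy {anatomy_label!r}; valid: {sorted(FINE_FRAME)}")
    if anatomy_label == "distal" and n_as == 24:
        raise ElectrodeError(
            "FINE-24 does not fit the distal anatomy (12 ASs of 0.5 mm per 10.9 mm face); "
            "valid distal counts: (12, 16, 20)"
        )
    w, h = FINE_FRAME[anatomy_label]
    per_face = n_as // 2
    pitch = w / per_face
    xs = (np.arange(per_face) - (per_face - 1) / 2.0) * pitch
    top = np.column_stack([xs, np.full(per_face, h / 2.0), np.zeros(per_face)])
    bot = np.column_stack([xs, np.full(per_face, -h / 2.0), np.zeros(per_face)])
    return ElectrodeSpec(
        kind="FINE",
        anatomy=anatomy_label,
        n_as=n_as,
        shaft_length=w,
        shaft_width=h,
        shaft_thickness=FINE_WALL,
        as_positions=np.vstack([top, bot]),
        as_face=np.concatenate([np.ones(per_face), -np.ones(per_face)]),
        as_shape="square",
        as_size=FINE_AS_SIDE,
    )


@dataclass(frozen=True)
class Placement:
    """An electrode instance positioned in the nerve cross-section.

    ``insertion_point`` is the shaft center in cross-section coordinates;
    ``orientation`` rotates the shaft in-plane (degrees, 0 = along +x);
    ``z_center`` shifts the electrode along the nerve.
    """

    electrode: ElectrodeSpec
    insertion_point: tuple[float, float] = (0.0, 0.0)
    orientation: float = 0.0
    z_center: float = 0.0

    def as_global_positions(self) -> np.ndarray:
        """Active-site centers in global (x, y, z) coordinates."""
        th = np.deg2rad(self.orientation)
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        xy = self.electrode.as_positions[:, :2] @ R.T
        xy = xy + np.asarray(self.insertion_point)
        z = self.electrode.as_positions[:, 2] + self.z_center
        return np.column_stack([xy, z])


#: Parallel-implant offsets along the minor axis, as fractions of the minor
#: span, per implant count.  Chosen so each shaft's active-site span stays
#: inside the elliptical outline.
_MULTI_IMPLANT_FRACTIONS = {
    1: (0.5,),
    2: (0.27, 0.73),
    3: (0.27, 0.5, 0.73),
    4: (0.27, 0.42, 0.58, 0.73),
}


def place_implants(
    cross_section: NerveCrossSection,
    electrode: ElectrodeSpec,
    n_implants: int = 1,
    strategy: str = "evenly-spaced",
    seed: int = 0,
) -> list[Placement]:
    """Place one or more electrodes in/around the nerve.

    TIME shafts are inserted transversally along the nerve's major axis,
    parallel to each other, offset along the minor axis; ``centered`` forces a
    single shaft through the centroid.  FINE supports a single centered cuff.
    Deterministic given the placement parameters (the seed is accepted for
    interface stability; the evenly-spaced strategy is fully deterministic).
    """
    if not 1 <= n_implants <= 4:
        raise ElectrodeError("n_implants must be between 1 and 4")
    if electrode.kind == "FINE":
        if n_implants > 1:
            raise ElectrodeError("multi-implant placement is TIME-only")
        w, h = electrode.shaft_length, electrode.shaft_width
        bx0, by0, bx1, by1 = cross_section.outline_polygon.bounds
        # no-compression cuff: expand the stated opening if the nerve overflows it
        w = max(w, (bx1 - bx0) + 0.1)
        h = max(h, (by1 - by0) + 0.1)
        if (w, h) != (electrode.shaft_length, electrode.shaft_width):
            electrode = ElectrodeSpec(
                **{
                    **{k: getattr(electrode, k) for k in (
                        "kind", "anatomy", "n_as", "shaft_thickness", "as_positions",
                        "as_face", "as_shape", "as_size", "substrate_conductivity")},
                    "shaft_length": w,
                    "shaft_width": h,
                }
            )
            pos = electrode.as_positions.copy()
            pos[:, 1] = np.sign(electrode.as_face) * h / 2.0
            object.__setattr__(electrode, "as_positions", pos)
        return [Placement(electrode=electrode)]

    if strategy not in ("evenly-spaced", "centered"):
        raise ElectrodeError(f"unknown placement strategy {strategy!r}")
    if strategy == "centered" and n_implants != 1:
        raise ElectrodeError("centered strategy places a single implant")

    c = cross_section.outline_polygon.centroid
    by0, by1 = cross_section.outline_polygon.bounds[1], cross_section.outline_polygon.bounds[3]
    placements = []
    for frac in _MULTI_IMPLANT_FRACTIONS[n_implants]:
        y = by0 + frac * (by1 - by0)
        if strategy == "centered":
            y = c.y
        pl = Placement(electrode=electrode, insertion_point=(c.x, y))
        _check_time_fit(cross_section, pl)
        placements.append(pl)
    return placements


def _check_time_fit(cross_section: NerveCrossSection, placement: Placement) -> None:
    pos = placement.as_global_positions()
    for i, (x, y, _z) in enumerate(pos):
        if not cross_section.outline_polygon.contains(Point(x, y)):
            raise ElectrodeError(
                f"active site {i} at ({x:.2f}, {y:.2f}) mm falls outside the nerve outline; "
                "electrode does not fit at the requested position"
            )
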