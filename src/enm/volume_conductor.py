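"""Quasi-static extracellular potential (lead field) solver.

Solves the volume-conduction problem ``div(sigma grad V) = 0`` with a unit
current injected at one electrode active site and the outer boundary of a
saline cylinder grounded, on a nonuniform tensor-product grid with a
cell-centered finite-volume discretization.

Tissue handling:

* epineurium, saline: isotropic conductivities;
* endoneurium: anisotropic tensor (transverse, transverse, longitudinal);
* perineurium: a 9-60 um sheath, far below any practical grid spacing, is
  treated as a thin-film series resistance ``t / sigma_p`` added to grid
  faces that cross a fascicle boundary;
* TIME polyimide ribbon (20 um): a set of zero-conductance grid faces
  (an internal insulating sheet), with the active site's current injected
  into the cell adjacent to the correct face;
* FINE frame walls: substrate cells excluded from the system (no-flux).

Potentials scale linearly with the injected current, so each lead field is
stored per unit ampere and rescaled on evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.interpolate import RegularGridInterpolator
from scipy.sparse.linalg import LinearOperator, gmres, spilu, spsolve
from shapely import contains_xy
from shapely.geometry import Point

from enm.electrodes import FINE_AXIAL_LENGTH, FINE_WALL, Placement
from enm.geometry import NerveCrossSection

# Tissue conductivities, S/m
SIGMA = {
    "saline": 2.0,
    "epineurium": 0.0826,
    "endoneurium_t": 0.0826,  # transverse (x, y)
    "endoneurium_l": 0.571,  # longitudinal (z)
    "perineurium": 0.00088,
    "substrate": 6.67e-14,
}

# cell labels
OUTSIDE = -1  # grounded exterior (Dirichlet)
SALINE = 0
EPINEURIUM = 1
ENDONEURIUM = 2  # fascicle id stored separately
SUBSTRATE = 3

BOUNDARY_HALF_LENGTH = 15.4  # mm, domain extent along z in each direction
MIN_CYLINDER_DIAMETER = 16.0  # mm
CYLINDER_MARGIN = 4.0  # mm added around the nerve bounding box when larger


class SolverError(RuntimeError):
    pass


@dataclass
class GridSpec:
    """Grid resolution profile (mm)."""

    h_plane: float = 0.15  # in-plane spacing inside the nerve
    h_axial: float = 0.25  # axial spacing near the electrode
    h_max: float = 1.6  # far-field cap
    growth: float = 0.35  # grading slope away from fine windows

    @classmethod
    def coarse(cls) -> "GridSpec":
        return cls(h_plane=0.22, h_axial=0.35, h_max=2.2, growth=0.45)

    @classmethod
    def fine(cls) -> "GridSpec":
        return cls(h_plane=0.10, h_axial=0.15, h_max=1.2, growth=0.3)


def _graded_faces(lo, hi, windows, mandatory, h_max, growth):
    """Face positions from ``lo`` to ``hi``: spacing h(x) = min over fine
    windows of (h_w + growth * distance), capped at h_max; mandatory
    coordinates are hit exactly."""
    mand = sorted({float(m) for m in mandatory if lo < m < hi} | {lo, hi})

    def h_at(x):
        h = h_max
        for a, b, hw in windows:
            d = max(a - x, x - b, 0.0)
            h = min(h, hw + growth * d)
        return h

    faces = [lo]
    mi = 1
    x = lo
    h_prev = None
    while x < hi - 1e-9:
        h = h_at(x)
        if h_prev is not None:
            h = min(h, 1.35 * h_prev)  # cap neighbour size-ratio jumps
        h_prev = h
        nxt = x + h
        if mi < len(mand):
            if nxt >= mand[mi] - 0.35 * h:
                nxt = mand[mi]
                mi += 1
            else:
                nxt = min(nxt, mand[mi])
        faces.append(nxt)
        x = nxt
    faces[-1] = hi
    f = np.array(faces)
    keep = np.concatenate([[True], np.diff(f) > 1e-9])
    return f[keep]


@dataclass
class ConductivityMap:
    """Discrete tissue model: grid axes, per-cell labels, blocked faces,
    per-face perineurium films, and active-site source cells."""

    faces_x: np.ndarray
    faces_y: np.ndarray
    faces_z: np.ndarray
    label: np.ndarray  # (nx, ny, nz) int8
    fascicle_id: np.ndarray  # (nx, ny) int32, -1 where not endoneurium
    film_x: np.ndarray  # (nx+1, ny) perineurium thickness crossed at x-faces, mm
    film_y: np.ndarray  # (nx, ny+1)
    blocked_x: np.ndarray  # (nx+1, ny, nz) bool, zero-conductance faces
    blocked_y: np.ndarray  # (nx, ny+1, nz) bool
    sources: dict  # as_key -> list[(i, j, k, fraction)]
    cross_section: NerveCrossSection = field(repr=False, default=None)
    placements: list = field(repr=False, default=None)
    signature: tuple = ()
    symmetric_z: bool = False

    @property
    def centers(self):
        cx = 0.5 * (self.faces_x[1:] + self.faces_x[:-1])
        cy = 0.5 * (self.faces_y[1:] + self.faces_y[:-1])
        cz = 0.5 * (self.faces_z[1:] + self.faces_z[:-1])
        return cx, cy, cz

    @property
    def shape(self):
        return self.label.shape

    def classify_point(self, x, y, z=0.0) -> str:
        """Tissue name at a physical point.  Cell-level resolution except that
        the sub-grid structures (TIME ribbon, perineurium sheath) are resolved
        from the exact geometry."""
        cs = self.cross_section
        for pl in self.placements or []:
            el = pl.electrode
            if el.kind == "TIME":
                cx0, cy0 = pl.insertion_point
                if (
                    abs(y - cy0) <= el.shaft_thickness / 2
                    and abs(x - cx0) <= el.shaft_length / 2
                    and abs(z - pl.z_center) <= el.shaft_width / 2
                ):
                    return "substrate"
        cx, cy, cz = self.centers
        i = int(np.clip(np.searchsorted(cx, x), 0, len(cx) - 1))
        j = int(np.clip(np.searchsorted(cy, y), 0, len(cy) - 1))
        k = int(np.clip(np.searchsorted(cz, z), 0, len(cz) - 1))
        lab = int(self.label[i, j, k])
        if lab == ENDONEURIUM and cs is not None:
            fas = cs.fascicle_index().get(int(self.fascicle_id[i, j]))
            if fas is not None and not fas.endoneurium_polygon().contains(Point(x, y)):
                return "perineurium"
        return {OUTSIDE: "outside", SALINE: "saline", EPINEURIUM: "epineurium",
                ENDONEURIUM: "endoneurium", SUBSTRATE: "substrate"}[lab]

    def tissue_tensor(self, x, y, z=0.0) -> tuple[float, float, float]:
        """Conductivity tensor diagonal (S/m) at a physical point."""
        name = self.classify_point(x, y, z)
        if name == "outside":
            raise SolverError(f"point ({x}, {y}, {z}) is outside the domain")
        if name == "endoneurium":
            return (SIGMA["endoneurium_t"], SIGMA["endoneurium_t"], SIGMA["endoneurium_l"])
        return (SIGMA[name],) * 3


def build_conductivity_map(
    cross_section: NerveCrossSection,
    placements: list[Placement] | None = None,
    grid: GridSpec | None = None,
    symmetric_z: bool | None = None,
    extra_fine: tuple | None = None,
) -> ConductivityMap:
    """Rasterize the nerve + electrode geometry onto the solver grid.

    When every placement is centered at ``z = 0`` (the usual case) the domain
    is mirror-symmetric about the electrode plane and only the ``z >= 0``
    half is discretized; the lead field is mirrored on reconstruction.
    """
    grid = grid or GridSpec()
    placements = list(placements or [])
    bx0, by0, bx1, by1 = cross_section.outline_polygon.bounds
    diam = max(MIN_CYLINDER_DIAMETER, (bx1 - bx0) + CYLINDER_MARGIN, (by1 - by0) + CYLINDER_MARGIN)
    R = diam / 2.0
    Lz = cross_section.extrusion_length / 2.0
    if symmetric_z is None:
        symmetric_z = all(abs(pl.z_center) < 1e-12 for pl in placements)

    # --- axes: fine windows follow the electrode, not the whole nerve --------
    xw = [(bx0 - 0.4, bx1 + 0.4, 2.2 * grid.h_plane)]
    yw = [(by0 - 0.4, by1 + 0.4, 2.2 * grid.h_plane)]
    zw = [(0.0, 0.35, min(grid.h_axial, 0.12))]  # thin source cells at the AS plane
    mand_x, mand_y, mand_z = [], [], [0.0]
    for pl in placements:
        el = pl.electrode
        if el.kind == "TIME":
            x0, y0 = pl.insertion_point
            mand_y.append(y0)
            yw.append((y0 - 2.6, y0 + 2.6, grid.h_plane))
            yw.append((y0 - 0.45, y0 + 0.45, min(grid.h_plane, 0.12)))
            xw.append((x0 - el.shaft_length / 2 - 0.6, x0 + el.shaft_length / 2 + 0.6, grid.h_plane))
            zw.append((0.0, el.shaft_width / 2 + 0.6, grid.h_axial))
            mand_z.append(el.shaft_width / 2)
        else:
            h2, w2 = el.shaft_width / 2.0, el.shaft_length / 2.0
            mand_y += [-h2 - FINE_WALL, -h2, h2, h2 + FINE_WALL]
            mand_x += [-w2 - FINE_WALL, -w2, w2, w2 + FINE_WALL]
            yw.append((-h2 - 0.5, -h2 + 2.6, grid.h_plane))
            yw.append((h2 - 2.6, h2 + 0.5, grid.h_plane))
            xw.append((-w2 - 0.5, w2 + 0.5, grid.h_plane))
            zw.append((0.0, FINE_AXIAL_LENGTH / 2 + 0.6, grid.h_axial))
            mand_z.append(FINE_AXIAL_LENGTH / 2)
    if extra_fine is not None:
        # ad-hoc refinement box, e.g. around a manually placed source
        (ex, ey, ez), half, h = extra_fine
        xw.append((ex - half, ex + half, h))
        yw.append((ey - half, ey + half, h))
        zw.append((ez - half, ez + half, h))
    z_lo = 0.0 if symmetric_z else -Lz
    if not symmetric_z:
        zw = zw + [(-b, -a, h) for a, b, h in zw]
        mand_z += [-m for m in mand_z]
    fx = _graded_faces(-R, R, xw, mand_x, grid.h_max, grid.growth)
    fy = _graded_faces(-R, R, yw, mand_y, grid.h_max, grid.growth)
    fz = _graded_faces(z_lo, Lz, zw, mand_z, grid.h_max, grid.growth)
    cx = 0.5 * (fx[1:] + fx[:-1])
    cy = 0.5 * (fy[1:] + fy[:-1])
    cz = 0.5 * (fz[1:] + fz[:-1])
    nx, ny, nz = len(cx), len(cy), len(cz)

    # --- in-plane tissue classification --------------------------------------
    XX, YY = np.meshgrid(cx, cy, indexing="ij")
    plane = np.full((nx, ny), SALINE, dtype=np.int8)
    plane[XX**2 + YY**2 > R**2] = OUTSIDE
    inside_nerve = contains_xy(cross_section.outline_polygon, XX.ravel(), YY.ravel()).reshape(nx, ny)
    plane[inside_nerve & (plane == SALINE)] = EPINEURIUM
    fid = np.full((nx, ny), -1, dtype=np.int32)
    for f in cross_section.fascicles:
        m = contains_xy(f.polygon, XX.ravel(), YY.ravel()).reshape(nx, ny)
        plane[m] = ENDONEURIUM
        fid[m] = f.id

    # perineurium films on faces where fascicle membership changes
    thick = {f.id: f.perineurium_thickness for f in cross_section.fascicles}
    tmap = np.zeros(max(thick) + 1)
    for fk, tv in thick.items():
        tmap[fk] = tv
    film_x = np.zeros((nx + 1, ny))
    film_y = np.zeros((nx, ny + 1))
    fa, fb = fid[:-1, :], fid[1:, :]
    crossx = fa != fb
    film_x[1:nx][crossx] = (
        np.where(fa[crossx] >= 0, tmap[np.maximum(fa[crossx], 0)], 0.0)
        + np.where(fb[crossx] >= 0, tmap[np.maximum(fb[crossx], 0)], 0.0)
    )
    ga, gb = fid[:, :-1], fid[:, 1:]
    crossy = ga != gb
    film_y[:, 1:ny][crossy] = (
        np.where(ga[crossy] >= 0, tmap[np.maximum(ga[crossy], 0)], 0.0)
        + np.where(gb[crossy] >= 0, tmap[np.maximum(gb[crossy], 0)], 0.0)
    )

    label = np.repeat(plane[:, :, None], nz, axis=2)
    blocked_x = np.zeros((nx + 1, ny, nz), dtype=bool)
    blocked_y = np.zeros((nx, ny + 1, nz), dtype=bool)
    sources: dict = {}
    sig = [round(float(v), 6) for v in (R, Lz, grid.h_plane, grid.h_axial)] + [symmetric_z]

    for pi, pl in enumerate(placements):
        el = pl.electrode
        gpos = pl.as_global_positions()
        if el.kind == "TIME":
            x0, y0 = pl.insertion_point
            jf = int(np.argmin(np.abs(fy - y0)))  # ribbon plane face index
            xi = (cx >= x0 - el.shaft_length / 2) & (cx <= x0 + el.shaft_length / 2)
            zi = (cz >= pl.z_center - el.shaft_width / 2) & (cz <= pl.z_center + el.shaft_width / 2)
            blocked_y[np.ix_(np.nonzero(xi)[0], [jf], np.nonzero(zi)[0])] = True
            sig.append(("TIME", round(y0, 4), int(xi.sum()), int(zi.sum()), jf))
            for a, (px, _py, pz) in enumerate(gpos):
                i = int(np.argmin(np.abs(cx - px)))
                k = int(np.argmin(np.abs(cz - pz)))
                j = jf if el.as_face[a] > 0 else jf - 1  # cell above / below the ribbon
                sources[(pi, a)] = [(i, j, k, 1.0)]
        else:  # FINE frame: substrate wall cells + patch sources on inner faces
            w2, h2 = el.shaft_length / 2.0, el.shaft_width / 2.0
            zi = np.nonzero(np.abs(cz) <= FINE_AXIAL_LENGTH / 2)[0]
            in_wall_y = (np.abs(YY) > h2) & (np.abs(YY) < h2 + FINE_WALL) & (np.abs(XX) < w2 + FINE_WALL)
            in_wall_x = (np.abs(XX) > w2) & (np.abs(XX) < w2 + FINE_WALL) & (np.abs(YY) < h2 + FINE_WALL)
            wall = (in_wall_y | in_wall_x) & (plane != OUTSIDE)
            wi, wj = np.nonzero(wall)
            # in the no-compression cuff the nerve and the frame share their
            # dimensions: the opening left free by the idealized elliptical
            # outline is connective tissue, not a free saline shunt ring
            gap = (plane == SALINE) & (np.abs(XX) < w2) & (np.abs(YY) < h2)
            gi, gj = np.nonzero(gap)
            for k in zi:
                label[wi, wj, k] = SUBSTRATE
                label[gi, gj, k] = EPINEURIUM
            sig.append(("FINE", round(w2, 3), round(h2, 3), int(len(zi))))
            half = el.as_size / 2.0
            for a, (px, py, pz) in enumerate(gpos):
                i0 = int(np.argmin(np.abs(cx - px)))
                k0 = int(np.argmin(np.abs(cz - pz)))
                jtop = int(np.argmin(np.abs(cy - py)))
                step = -1 if el.as_face[a] > 0 else 1
                ii = np.nonzero((cx >= px - half) & (cx <= px + half))[0]
                kk = np.nonzero((cz >= pz - half) & (cz <= pz + half))[0]
                if len(ii) == 0:
                    ii = np.array([i0])
                if len(kk) == 0:
                    kk = np.array([k0])
                frac = 1.0 / (len(ii) * len(kk))
                cells = []
                for i in ii:
                    j = jtop
                    while 0 <= j < ny - 1 and label[i, j, k0] == SUBSTRATE:
                        j += step
                    for k in kk:
                        cells.append((int(i), int(j), int(k), frac))
                sources[(pi, a)] = cells

    return ConductivityMap(
        faces_x=fx, faces_y=fy, faces_z=fz, label=label, fascicle_id=fid,
        film_x=film_x, film_y=film_y, blocked_x=blocked_x, blocked_y=blocked_y,
        sources=sources, cross_section=cross_section, placements=placements,
        signature=tuple(map(str, sig)), symmetric_z=symmetric_z,
    )


# ---------------------------------------------------------------------------
# Assembly & solve
# ---------------------------------------------------------------------------

def _cell_sigma(label):
    st = np.empty(label.shape)
    sz = np.empty(label.shape)
    for lab, key_t, key_z in (
        (SALINE, "saline", "saline"),
        (EPINEURIUM, "epineurium", "epineurium"),
        (ENDONEURIUM, "endoneurium_t", "endoneurium_l"),
        (SUBSTRATE, "substrate", "substrate"),
        (OUTSIDE, "saline", "saline"),
    ):
        m = label == lab
        st[m] = SIGMA[key_t]
        sz[m] = SIGMA[key_z]
    return st, sz


class LinearSystem:
    """Assembled finite-volume system for one conductivity map.

    Shared by all active sites of the map: only the right-hand side changes
    per source, so the sparse matrix and its incomplete-LU preconditioner are
    built once.  Optional ``boundary_values`` (callable of x, y, z in mm)
    imposes inhomogeneous Dirichlet data on the grounded exterior, used by
    verification against closed-form solutions.
    """

    def __init__(self, cmap: ConductivityMap, sigma_override=None, boundary_values=None):
        fx, fy, fz = cmap.faces_x * 1e-3, cmap.faces_y * 1e-3, cmap.faces_z * 1e-3  # meters
        hx, hy, hz = np.diff(fx), np.diff(fy), np.diff(fz)
        label = cmap.label
        nx, ny, nz = label.shape
        if sigma_override is None:
            st, sz = _cell_sigma(label)
            film_x = cmap.film_x
            film_y = cmap.film_y
        else:
            # overriding conductivities means a bare medium: drop the
            # perineurium films along with the tissue map
            st, sz = sigma_override
            film_x = np.zeros_like(cmap.film_x)
            film_y = np.zeros_like(cmap.film_y)
        active = (label != OUTSIDE) & (label != SUBSTRATE)
        idx = -np.ones(label.shape, dtype=np.int64)
        idx[active] = np.arange(active.sum())
        self.n = int(active.sum())
        self.active = active
        self.idx = idx
        self.cmap = cmap

        if boundary_values is None:
            bvals = np.zeros(label.shape)
        else:
            ccx, ccy, ccz = cmap.centers
            XX, YY, ZZ = np.meshgrid(ccx, ccy, ccz, indexing="ij")
            bvals = boundary_values(XX, YY, ZZ)
        self._end_ghost = boundary_values is None or True

        rows, cols, vals = [], [], []
        diag = np.zeros(self.n)
        rhs0 = np.zeros(self.n)
        s_p = SIGMA["perineurium"]

        def add_axis(axis):
            if axis == 0:
                sa, sb = st[:-1], st[1:]
                ha, hb = hx[:-1, None, None] / 2, hx[1:, None, None] / 2
                A = hy[None, :, None] * hz[None, None, :]
                film = film_x[1:-1, :, None] * 1e-3
                blocked = cmap.blocked_x[1:-1]
                ia, ib = idx[:-1], idx[1:]
                act_a, act_b = active[:-1], active[1:]
                lab_a, lab_b = label[:-1], label[1:]
                bv_a, bv_b = bvals[:-1], bvals[1:]
            elif axis == 1:
                sa, sb = st[:, :-1], st[:, 1:]
                ha, hb = hy[None, :-1, None] / 2, hy[None, 1:, None] / 2
                A = hx[:, None, None] * hz[None, None, :]
                film = film_y[:, 1:-1, None] * 1e-3
                blocked = cmap.blocked_y[:, 1:-1]
                ia, ib = idx[:, :-1], idx[:, 1:]
                act_a, act_b = active[:, :-1], active[:, 1:]
                lab_a, lab_b = label[:, :-1], label[:, 1:]
                bv_a, bv_b = bvals[:, :-1], bvals[:, 1:]
            else:
                sa, sb = sz[:, :, :-1], sz[:, :, 1:]
                ha, hb = hz[None, None, :-1] / 2, hz[None, None, 1:] / 2
                A = hx[:, None, None] * hy[None, :, None]
                film = np.zeros(1)
                blocked = np.zeros(sa.shape, dtype=bool)
                ia, ib = idx[:, :, :-1], idx[:, :, 1:]
                act_a, act_b = active[:, :, :-1], active[:, :, 1:]
                lab_a, lab_b = label[:, :, :-1], label[:, :, 1:]
                bv_a, bv_b = bvals[:, :, :-1], bvals[:, :, 1:]
            R = ha / sa + hb / sb + (film / s_p if film.size > 1 else 0.0)
            G = np.where(blocked, 0.0, A / R)
            both = act_a & act_b
            g = G[both]
            rows.append(ia[both]); cols.append(ib[both]); vals.append(-g)
            rows.append(ib[both]); cols.append(ia[both]); vals.append(-g)
            np.add.at(diag, ia[both], g)
            np.add.at(diag, ib[both], g)
            # Dirichlet neighbors (outside the cylinder): V fixed at boundary value.
            dir_a = act_a & (lab_b == OUTSIDE)
            dir_b = act_b & (lab_a == OUTSIDE)
            np.add.at(diag, ia[dir_a], G[dir_a])
            np.add.at(rhs0, ia[dir_a], G[dir_a] * bv_b[dir_a])
            np.add.at(diag, ib[dir_b], G[dir_b])
            np.add.at(rhs0, ib[dir_b], G[dir_b] * bv_a[dir_b])
            # substrate neighbors: no-flux (face dropped entirely)

        add_axis(0)
        add_axis(1)
        add_axis(2)
        # grounded (or valued) ghost faces on the outer box walls; with a
        # symmetric half-domain the z = 0 end is a natural (Neumann) mirror
        ccx, ccy, ccz = cmap.centers

        def ghost_vals(axis, index, offset_mm):
            if boundary_values is None:
                return 0.0
            if axis == 2:
                Xg, Yg = np.meshgrid(ccx, ccy, indexing="ij")
                return boundary_values(Xg, Yg, np.full(Xg.shape, ccz[index] + offset_mm))
            if axis == 0:
                Yg, Zg = np.meshgrid(ccy, ccz, indexing="ij")
                return boundary_values(np.full(Yg.shape, ccx[index] + offset_mm), Yg, Zg)
            Xg, Zg = np.meshgrid(ccx, ccz, indexing="ij")
            return boundary_values(Xg, np.full(Xg.shape, ccy[index] + offset_mm), Zg)

        Aend = hx[:, None] * hy[None, :]
        ends = ((nz - 1, hz[-1]),) if cmap.symmetric_z else ((0, hz[0]), (nz - 1, hz[-1]))
        for kk, hzi in ends:
            m = active[:, :, kk]
            g = (Aend * (2 * sz[:, :, kk] / hzi))[m]
            gv = ghost_vals(2, kk, (hzi if kk else -hzi) * 1e3)
            np.add.at(diag, idx[:, :, kk][m], g)
            if boundary_values is not None:
                np.add.at(rhs0, idx[:, :, kk][m], g * gv[m])
        Ax = hy[:, None] * hz[None, :]
        for ii, hxi in ((0, hx[0]), (nx - 1, hx[-1])):
            m = active[ii, :, :]
            g = (Ax * (2 * st[ii, :, :] / hxi))[m]
            gv = ghost_vals(0, ii, (hxi if ii else -hxi) * 1e3)
            np.add.at(diag, idx[ii, :, :][m], g)
            if boundary_values is not None:
                np.add.at(rhs0, idx[ii, :, :][m], g * gv[m])
        Ay = hx[:, None] * hz[None, :]
        for jj, hyi in ((0, hy[0]), (ny - 1, hy[-1])):
            m = active[:, jj, :]
            g = (Ay * (2 * st[:, jj, :] / hyi))[m]
            gv = ghost_vals(1, jj, (hyi if jj else -hyi) * 1e3)
            np.add.at(diag, idx[:, jj, :][m], g)
            if boundary_values is not None:
                np.add.at(rhs0, idx[:, jj, :][m], g * gv[m])

        rows.append(np.arange(self.n)); cols.append(np.arange(self.n)); vals.append(diag)
        self.A = sparse.csr_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(self.n, self.n),
        )
        self.rhs0 = rhs0
        self._pre = None
        self._lu = None

    def preconditioner(self):
        if self._pre is None:
            ilu = spilu(self.A.tocsc(), drop_tol=1e-4, fill_factor=8)
            self._pre = LinearOperator(self.A.shape, ilu.solve)
        return self._pre

    def factorize(self):
        """Full sparse LU, worthwhile when many right-hand sides share the
        matrix (all active sites of an electrode)."""
        if self._lu is None:
            from scipy.sparse.linalg import splu

            self._lu = splu(self.A.tocsc(), permc_spec="MMD_AT_PLUS_A")
        return self._lu

    def solve(self, rhs, tol=1e-8, direct=None):
        b = rhs + self.rhs0
        if self._lu is not None:
            return self._lu.solve(b)
        if direct or (direct is None and self.n < 20000):
            return spsolve(self.A.tocsc(), b)
        x, info = gmres(self.A, b, rtol=tol, maxiter=400, restart=80, M=self.preconditioner())
        res = np.linalg.norm(self.A @ x - b) / max(np.linalg.norm(b), 1e-300)
        if info != 0 or res > 1e-5:
            raise SolverError(f"lead-field solve did not converge (info={info}, residual={res:.2e})")
        return x


@dataclass
class LeadField:
    """Extracellular potential per unit injected current for one active site."""

    as_key: tuple
    faces_x: np.ndarray
    faces_y: np.ndarray
    faces_z: np.ndarray
    values: np.ndarray  # (nx, ny, nz) volts per ampere
    reference_current: float = 1.0
    signature: tuple = ()

    def __post_init__(self):
        cx = 0.5 * (self.faces_x[1:] + self.faces_x[:-1])
        cy = 0.5 * (self.faces_y[1:] + self.faces_y[:-1])
        cz = 0.5 * (self.faces_z[1:] + self.faces_z[:-1])
        self._interp = RegularGridInterpolator(
            (cx, cy, cz), self.values, method="linear", bounds_error=False, fill_value=None
        )

    def at(self, points: np.ndarray, current: float = 1.0) -> np.ndarray:
        """Potential (volts) at (N, 3) points in mm for the given current (A)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        out = (
            (pts[:, 0] < self.faces_x[0]) | (pts[:, 0] > self.faces_x[-1])
            | (pts[:, 1] < self.faces_y[0]) | (pts[:, 1] > self.faces_y[-1])
            | (pts[:, 2] < self.faces_z[0]) | (pts[:, 2] > self.faces_z[-1])
        )
        if out.any():
            raise SolverError(
                f"query point index {int(np.nonzero(out)[0][0])} lies outside the solver domain"
            )
        return current * self._interp(pts)


class SuperposedField:
    """Signed-weight combination of lead fields (bipolar and multipolar modes)."""

    def __init__(self, lead_fields: list[LeadField], weights):
        if not lead_fields:
            raise SolverError("superposition needs at least one lead field")
        sig = lead_fields[0].signature
        if any(lf.signature != sig for lf in lead_fields):
            raise SolverError("superposition requires lead fields from the same conductivity map")
        if len(lead_fields) != len(list(weights)):
            raise SolverError("one weight per lead field required")
        self.lead_fields = list(lead_fields)
        self.weights = np.asarray(weights, dtype=float)

    def at(self, points: np.ndarray, current: float = 1.0) -> np.ndarray:
        acc = 0.0
        for lf, w in zip(self.lead_fields, self.weights):
            acc = acc + lf.at(points, current=current * w)
        return acc


def superpose(lead_fields: list[LeadField], weights) -> SuperposedField:
    """Pointwise weighted sum of lead fields; signs of weights set polarity."""
    return SuperposedField(lead_fields, weights)


def sample_at_nodes(potential, node_positions: np.ndarray, current: float = 1.0) -> np.ndarray:
    """Interpolate a (superposed) lead field at fiber compartment positions."""
    return potential.at(np.asarray(node_positions, dtype=float), current=current)


def _fill_masked(values, active):
    """Propagate neighboring active values into masked cells so interpolation
    adjacent to substrate or the stair-step boundary stays finite."""
    v = values.copy()
    if active.all():
        return v
    v[~active] = np.nan
    for _ in range(3):
        if not np.isnan(v).any():
            break
        for axis in (0, 1, 2):
            for sh in (1, -1):
                shifted = np.roll(v, sh, axis=axis)
                edge = [slice(None)] * 3
                edge[axis] = 0 if sh == 1 else -1
                shifted[tuple(edge)] = np.nan
                m = np.isnan(v) & ~np.isnan(shifted)
                v[m] = shifted[m]
    v[np.isnan(v)] = 0.0
    return v


class LeadFieldSolver:
    """Solves lead fields for the active sites of one conductivity map,
    reusing the assembled matrix and preconditioner across sites."""

    def __init__(self, cmap: ConductivityMap, tol: float = 1e-7, system: LinearSystem | None = None):
        self.cmap = cmap
        self.tol = tol
        if system is not None and system.cmap.signature != cmap.signature:
            raise SolverError("shared linear system was assembled for a different map")
        # electrode variants that rasterize to the same blocked-face pattern
        # share one assembled (and factorized) system; only sources differ
        self.system = system if system is not None else LinearSystem(cmap)

    def solve_as(self, as_key) -> LeadField:
        cmap = self.cmap
        if as_key not in cmap.sources:
            raise SolverError(f"unknown active site {as_key}")
        rhs = np.zeros(self.system.n)
        half = 0.5 if cmap.symmetric_z else 1.0
        for (i, j, k, frac) in cmap.sources[as_key]:
            if not self.system.active[i, j, k]:
                raise SolverError(f"active-site source cell {(i, j, k)} is not a conducting cell")
            rhs[self.system.idx[i, j, k]] += frac * half  # 1 A reference
        x = self.system.solve(rhs, tol=self.tol)
        vals = np.zeros(cmap.shape)
        vals[self.system.active] = x
        vals = _fill_masked(vals, self.system.active)
        fz = cmap.faces_z
        if cmap.symmetric_z:
            fz = np.concatenate([-fz[:0:-1], fz])
            vals = np.concatenate([vals[:, :, ::-1], vals], axis=2)
        return LeadField(
            as_key=as_key, faces_x=cmap.faces_x, faces_y=cmap.faces_y, faces_z=fz,
            values=vals, signature=cmap.signature,
        )

    def solve_all(self) -> dict:
        # a full factorization beats repeated Krylov solves once the matrix
        # is shared by enough sites (memory stays modest below ~100k cells)
        if len(self.cmap.sources) >= 12 and 20000 <= self.system.n <= 100000:
            self.system.factorize()
        return {k: self.solve_as(k) for k in sorted(self.cmap.sources)}


def solve_lead_field(cmap: ConductivityMap, as_key, tol: float = 1e-8) -> LeadField:
    """Solve the lead field for one active site key ``(placement_index, as_index)``."""
    return LeadFieldSolver(cmap, tol=tol).solve_as(as_key)


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------

def save_lead_fields(lead_fields: dict, path) -> None:
    """Store solved lead fields (grid axes + per-ampere potentials) in HDF5."""
    import h5py

    with h5py.File(path, "w") as h5:
        for (pi, a), lf in lead_fields.items():
            g = h5.create_group(f"placement{pi}/as{a}")
            g.create_dataset("faces_x", data=lf.faces_x)
            g.create_dataset("faces_y", data=lf.faces_y)
            g.create_dataset("faces_z", data=lf.faces_z)
            g.create_dataset("values", data=lf.values, compression="gzip", compression_opts=4)
            g.attrs["reference_current"] = lf.reference_current
            g.attrs["signature"] = "|".join(map(str, lf.signature))


def load_lead_fields(path) -> dict:
    import h5py

    out = {}
    with h5py.File(path, "r") as h5:
        for pname, pgrp in h5.items():
            pi = int(pname.removeprefix("placement"))
            for aname, g in pgrp.items():
                a = int(aname.removeprefix("as"))
                out[(pi, a)] = LeadField(
                    as_key=(pi, a),
                    faces_x=g["faces_x"][()],
                    faces_y=g["faces_y"][()],
                    faces_z=g["faces_z"][()],
                    values=g["values"][()],
                    reference_current=float(g.attrs["reference_current"]),
                    signature=tuple(str(g.attrs["signature"]).split("|")),
                )
    return out
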