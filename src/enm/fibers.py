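"""Myelinated sensory-fiber populations inside fascicles.

Fibers are Abeta-range myelinated axons placed in the endoneurium at a
configurable areal density (default 240 fibers/mm^2, a 50x reduction of the
anatomical density that preserves the diameter distribution).  Depending on
fascicle size, fibers are grouped into 1 (small), 3 (medium) or 5 (big)
spatially clustered populations, mimicking the somatotopic grouping of
fibers that innervate different skin regions.

Each fiber has 21 nodes of Ranvier and 20 internodes of length
``L = 100 * D`` (D = fiber diameter); the node ladder is shifted along z by
a per-fiber uniform offset in [0, L).  Diameters are drawn from a
configurable two-component Gaussian mixture over [5.7, 16.0] um and snapped
to the nearest tabulated MRG diameter, since the compartmental model is
parameterized only at those discrete values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely import contains_xy

from enm.biophysics import MRG_DIAMETERS_UM
from enm.geometry import Fascicle, NerveCrossSection, classify_fascicle_size

DEFAULT_DENSITY = 240.0  # fibers per mm^2 of endoneurial area
N_NODES = 21
INTERNODE_FACTOR = 100.0  # L = 100 * D

POPULATIONS_BY_CLASS = {"small": 1, "medium": 3, "big": 5}

#: Two-component Gaussian mixture over fiber diameter (um): modes near 7 and
#: 12 um with equal weights, truncated to the Abeta support [5.7, 16.0].
DEFAULT_DIAMETER_MIXTURE = ((7.0, 1.3, 0.5), (12.0, 2.0, 0.5))
DIAMETER_SUPPORT = (5.7, 16.0)


@dataclass(frozen=True)
class Fiber:
    """One myelinated fiber: cross-section position plus node ladder geometry."""

    id: int
    fascicle_id: int
    population_id: int
    x: float  # mm
    y: float  # mm
    diameter_um: float
    z_offset: float  # mm, node ladder shift in [0, L)

    @property
    def internode_mm(self) -> float:
        return INTERNODE_FACTOR * self.diameter_um * 1e-3

    def node_z(self) -> np.ndarray:
        """z of the 21 nodes of Ranvier (mm), ladder centered near z = 0."""
        L = self.internode_mm
        k = np.arange(N_NODES) - (N_NODES - 1) / 2.0
        return self.z_offset + k * L

    def node_positions(self) -> np.ndarray:
        z = self.node_z()
        return np.column_stack([np.full(N_NODES, self.x), np.full(N_NODES, self.y), z])


@dataclass
class FiberPopulation:
    """Clustered group of fibers within one fascicle."""

    fascicle_id: int
    population_id: int
    seed_point: tuple[float, float]
    fibers: list[Fiber] = field(default_factory=list)


def _sample_in_polygon(rng, poly, n, max_tries=200):
    """Uniform points inside a shapely polygon by rejection from its bbox."""
    x0, y0, x1, y1 = poly.bounds
    out = np.empty((0, 2))
    for _ in range(max_tries):
        need = n - len(out)
        if need <= 0:
            break
        pts = np.column_stack(
            [rng.uniform(x0, x1, 2 * need + 8), rng.uniform(y0, y1, 2 * need + 8)]
        )
        keep = contains_xy(poly, pts[:, 0], pts[:, 1])
        out = np.vstack([out, pts[keep]])
    if len(out) < n:
        # extremely thin polygon: fall back to the representative point
        rp = poly.representative_point()
        out = np.vstack([out, np.tile([[rp.x, rp.y]], (n - len(out), 1))])
    return out[:n]


def assign_populations(fascicle: Fascicle, seed: int) -> list[tuple[int, tuple[float, float]]]:
    """Population cluster centers for a fascicle: 1 (small), 3 (medium) or
    5 (big) points in the endoneurium.  Fibers later join the nearest center,
    which partitions the lumen into disjoint Voronoi cells."""
    k = POPULATIONS_BY_CLASS[classify_fascicle_size(fascicle)]
    rng = np.random.default_rng([int(seed), 7919, int(fascicle.id)])
    endo = fascicle.endoneurium_polygon()
    pts = _sample_in_polygon(rng, endo, k)
    return [(i, (float(px), float(py))) for i, (px, py) in enumerate(pts)]


def _draw_diameters(rng, n, mixture, support):
    comps = np.asarray([c[:2] for c in mixture])
    w = np.asarray([c[2] for c in mixture], dtype=float)
    w = w / w.sum()
    out = np.empty(0)
    while len(out) < n:
        which = rng.choice(len(comps), size=2 * n + 8, p=w)
        d = rng.normal(comps[which, 0], comps[which, 1])
        d = d[(d >= support[0]) & (d <= support[1])]
        out = np.concatenate([out, d])
    d = out[:n]
    tab = np.asarray(MRG_DIAMETERS_UM)
    return tab[np.argmin(np.abs(d[:, None] - tab[None, :]), axis=1)]


def populate_fibers(
    cross_section: NerveCrossSection,
    seed: int,
    density: float = DEFAULT_DENSITY,
    diameter_mixture=DEFAULT_DIAMETER_MIXTURE,
) -> list[FiberPopulation]:
    """Fill every fascicle with fibers at the requested endoneurial density.

    Per fascicle the fiber count is Poisson(density x endoneurial area) with
    a minimum of one fiber, positions are uniform in the endoneurium,
    population membership is by nearest cluster center, and node ladders get
    independent uniform z-offsets in [0, L).  Deterministic per
    (seed, fascicle id), so adding fascicles does not reshuffle others.
    """
    populations: list[FiberPopulation] = []
    fid_counter = 0
    for fas in cross_section.fascicles:
        rng = np.random.default_rng([int(seed), 104729, int(fas.id)])
        endo = fas.endoneurium_polygon()
        n = max(1, int(rng.poisson(density * endo.area)))
        pts = _sample_in_polygon(rng, endo, n)
        diam = _draw_diameters(rng, n, diameter_mixture, DIAMETER_SUPPORT)
        seeds = assign_populations(fas, seed)
        centers = np.asarray([c for _, c in seeds])
        which = np.argmin(((pts[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2), axis=1)
        pops = {
            pid: FiberPopulation(fascicle_id=fas.id, population_id=pid, seed_point=c)
            for pid, c in seeds
        }
        L = INTERNODE_FACTOR * diam * 1e-3
        zoff = rng.uniform(0.0, 1.0, size=n) * L
        for i in range(n):
            pops[int(which[i])].fibers.append(
                Fiber(
                    id=fid_counter,
                    fascicle_id=fas.id,
                    population_id=int(which[i]),
                    x=float(pts[i, 0]),
                    y=float(pts[i, 1]),
                    diameter_um=float(diam[i]),
                    z_offset=float(zoff[i]),
                )
            )
            fid_counter += 1
        populations.extend(pops.values())
    return populations


def all_fibers(populations: list[FiberPopulation]) -> list[Fiber]:
    return [f for p in populations for f in p.fibers]


def fibers_frame(populations: list[FiberPopulation]) -> pd.DataFrame:
    """Tabular export: one row per fiber (CSV-friendly)."""
    rows = [
        (f.id, f.fascicle_id, f.population_id, f.x, f.y, f.diameter_um, f.z_offset)
        for p in populations
        for f in p.fibers
    ]
    return pd.DataFrame(rows, columns=["id", "fascicle", "population", "x", "y", "D", "z_offset"])
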