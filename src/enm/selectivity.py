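"""Recruitment analysis: selectivity indexes, thresholds, policies, scores.

For every stimulation configuration (one cathodic active site, or a signed
pair of sites under the bipolar policy) the per-fiber recruitment thresholds
on the charge sweep yield per-fascicle recruitment counts ``n_i`` and
fractions ``mu_i``.  Two indexes grade a configuration at a given charge:

* spatial selectivity   ``Sel_i   = mu_i - (1/(m-1)) * sum_{j != i} mu_j``
* functional selectivity ``Sel_s_i = n_i / sum_j n_j``

A fascicle is *selectively recruited* by a configuration if at any sweep
amplitude ``Sel_i > 0.6`` and ``Sel_s_i > 0.9`` (strict) with at least one
fiber recruited.  An electrode's score is the percentage of fascicles
selectively recruited by at least one of its configurations.

To prune simulations, fibers farther from the driving site than the
electrode's effective stimulation range are skipped; a fascicle with at
least one fiber inside the range is *implicated* and keeps all its fibers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from enm.biophysics import (
    IntegrationSettings,
    StimulusSweep,
    compartment_z,
    diameter_class,
    find_threshold_indices,
)
from enm.electrodes import Placement, build_time, place_implants
from enm.fibers import Fiber, FiberPopulation, all_fibers, populate_fibers
from enm.geometry import NerveCrossSection
from enm.volume_conductor import GridSpec, LeadFieldSolver, build_conductivity_map

#: Effective stimulation range (mm) per electrode kind and anatomy: beyond it
#: no fiber is recruited at the sweep cap, so simulation is pointless.
EFFECTIVE_RANGE_MM = {
    ("TIME", "proximal"): 2.0,
    ("TIME", "distal"): 2.0,
    ("FINE", "proximal"): 4.0,
    ("FINE", "distal"): 3.0,
}

SEL_SPATIAL_MIN = 0.6  # strict inequality
SEL_FUNCTIONAL_MIN = 0.9

THRESHOLD_FRACTION = 0.10  # fascicle "perceptual" threshold: 10% of fibers


class SelectivityError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Index formulas
# ---------------------------------------------------------------------------

def spatial_selectivity(mu, i: int) -> float:
    """``Sel_i``: recruitment of fascicle i minus the mean of all others."""
    mu = np.asarray(mu, dtype=float)
    m = len(mu)
    if m < 2:
        raise SelectivityError("spatial selectivity needs at least two fascicles")
    if np.any((mu < 0) | (mu > 1)):
        raise SelectivityError("recruitment fractions must lie in [0, 1]")
    others = mu.sum() - mu[i]
    return float(mu[i] - others / (m - 1))


def functional_selectivity(n, i: int) -> float:
    """``Sel_s_i``: share of all recruited fibers that lie in fascicle i."""
    n = np.asarray(n, dtype=float)
    total = n.sum()
    if total <= 0:
        raise SelectivityError("functional selectivity undefined with zero recruited fibers")
    return float(n[i] / total)


def is_selective(sel_spatial: float, sel_functional: float, n_recruited: int) -> bool:
    """Strict selectivity criterion for one fascicle at one amplitude:
    ``Sel_i > 0.6`` and ``Sel_s_i > 0.9`` with at least one fiber recruited
    (equality does not qualify)."""
    return (
        sel_spatial > SEL_SPATIAL_MIN
        and sel_functional > SEL_FUNCTIONAL_MIN
        and n_recruited >= 1
    )


def fascicle_threshold_charge(mu_per_amplitude, charges_nc, fraction: float = THRESHOLD_FRACTION):
    """Smallest sweep charge at which the recruitment fraction reaches
    ``fraction`` (default 10%); None if never reached."""
    mu = np.asarray(mu_per_amplitude, dtype=float)
    hit = np.nonzero(mu >= fraction)[0]
    return None if len(hit) == 0 else float(np.asarray(charges_nc)[hit[0]])


# ---------------------------------------------------------------------------
# Effective-range filter
# ---------------------------------------------------------------------------

def effective_range_filter(
    fibers: list[Fiber],
    as_position,
    electrode_kind: str,
    anatomy: str,
    range_mm: float | None = None,
):
    """Apply the effective stimulation range around one active site.

    Returns ``(retained_fibers, implicated_fascicle_ids)``: every fiber of a
    fascicle with at least one fiber within the range is retained; other
    fascicles are excluded entirely.
    """
    if range_mm is None:
        range_mm = EFFECTIVE_RANGE_MM[(electrode_kind, anatomy)]
    pos = np.asarray(as_position, dtype=float)[:2]
    xy = np.array([[f.x, f.y] for f in fibers])
    fas = np.array([f.fascicle_id for f in fibers])
    dist = np.linalg.norm(xy - pos, axis=1)
    implicated = set(fas[dist <= range_mm].tolist())
    retained = [f for f in fibers if f.fascicle_id in implicated]
    return retained, implicated


# ---------------------------------------------------------------------------
# Stimulation configurations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StimConfig:
    """One stimulation configuration: signed unit currents on active sites."""

    name: str
    as_keys: tuple  # ((placement_idx, as_idx), ...)
    weights: tuple  # signed unit weights, same length

    @property
    def anchor(self):
        return self.as_keys[0]


def monopolar_configs(placements: list[Placement]) -> list[StimConfig]:
    """Single-site cathodic configurations, one per active site."""
    out = []
    for pi, pl in enumerate(placements):
        for a in range(pl.electrode.n_as):
            out.append(StimConfig(f"mono[{pi}:{a}]", ((pi, a),), (-1.0,)))
    return out


def enumerate_bipolar_configs(
    electrode, placement_index: int = 0, dedup: bool = False
) -> list[StimConfig]:
    """Anchored bipolar pairs for one electrode.

    For every anchor site A: the nearest opposite-face site (B) and the
    nearest same-face site (C), each in two polarity patterns — opposed
    (anchor cathodic, partner anodic; the reverse assignment arises from the
    partner's own anchored pair) and matched anodic (+/+), with equal current
    magnitude on both sites.  ``dedup`` collapses configurations whose signed
    weight maps coincide (e.g. the matched pattern of a reciprocal pair).
    """
    pos = electrode.as_positions
    face = electrode.as_face
    n = electrode.n_as
    if n < 2:
        return []
    configs = []
    seen = set()
    for a in range(n):
        d = np.linalg.norm(pos - pos[a], axis=1)
        d[a] = np.inf
        partners = []
        opp = np.nonzero(face != face[a])[0]
        if len(opp):
            partners.append(("B", int(opp[np.argmin(d[opp])])))
        same = np.nonzero(face == face[a])[0]
        same = same[same != a]
        if len(same):
            partners.append(("C", int(same[np.argmin(d[same])])))
        for tag, b in partners:
            for pat, wa, wb in (("-+", -1.0, +1.0), ("++", +1.0, +1.0)):
                cfg = StimConfig(
                    f"bi[{placement_index}:{a}{tag}{b}]{pat}",
                    ((placement_index, a), (placement_index, b)),
                    (wa, wb),
                )
                if dedup:
                    key = frozenset(zip(cfg.as_keys, cfg.weights))
                    if key in seen:
                        continue
                    seen.add(key)
                configs.append(cfg)
    return configs


# ---------------------------------------------------------------------------
# Evaluation engine
# ---------------------------------------------------------------------------

@dataclass
class SelectivityReport:
    """Outcome of evaluating a set of configurations on one fiber realization."""

    policy: str
    m: int
    selective_by_config: dict = field(default_factory=dict)  # name -> set of fascicle ids
    selective_union: set = field(default_factory=set)
    per_config_rows: list = field(default_factory=list)
    improvement: float | None = None  # percentage points over monopolar, if applicable

    @property
    def score(self) -> float:
        """Percentage of fascicles selectively recruited by any configuration."""
        return 100.0 * len(self.selective_union) / self.m

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.per_config_rows,
            columns=[
                "configuration", "fascicle", "n_fibers", "best_sel_spatial",
                "best_sel_functional", "selective", "threshold_charge_nc",
            ],
        )


class SelectivityEvaluator:
    """Caches per-configuration recruitment thresholds for one nerve + implant
    + fiber-population realization, and aggregates them into reports."""

    def __init__(
        self,
        cross_section: NerveCrossSection,
        placements: list[Placement],
        lead_fields: dict,
        populations: list[FiberPopulation],
        sweep: StimulusSweep | None = None,
        settings: IntegrationSettings | None = None,
        anatomy: str | None = None,
    ):
        self.cross_section = cross_section
        self.placements = placements
        self.lead_fields = lead_fields
        self.populations = populations
        self.sweep = sweep or StimulusSweep()
        self.settings = settings
        self.anatomy = anatomy or cross_section.anatomy_label
        self.fibers = all_fibers(populations)
        if cross_section.n_fascicles < 2:
            raise SelectivityError("selectivity indexes need at least two fascicles")
        self.m = cross_section.n_fascicles
        self.fascicle_ids = sorted(f.id for f in cross_section.fascicles)
        self.totals = {fid: 0 for fid in self.fascicle_ids}
        for f in self.fibers:
            self.totals[f.fascicle_id] += 1
        self._thresholds: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        self._as_xy = {}
        for pi, pl in enumerate(placements):
            gpos = pl.as_global_positions()
            for a in range(pl.electrode.n_as):
                self._as_xy[(pi, a)] = gpos[a]

    # -- thresholds ---------------------------------------------------------

    def config_thresholds(self, cfg: StimConfig):
        """(fiber index array, threshold sweep-index array) for a configuration."""
        if cfg.name in self._thresholds:
            return self._thresholds[cfg.name]
        kind = self.placements[cfg.anchor[0]].electrode.kind
        retained, _ = effective_range_filter(
            self.fibers, self._as_xy[cfg.anchor], kind, self.anatomy
        )
        idx = np.array([f.id for f in retained], dtype=np.int64)
        profs = self._profiles(retained, cfg)
        cls = np.array([diameter_class(f.diameter_um) for f in retained], dtype=np.int64)
        thr = (
            find_threshold_indices(cls, profs, self.sweep, settings=self.settings)
            if len(retained)
            else np.empty(0, dtype=np.int64)
        )
        self._thresholds[cfg.name] = (idx, thr)
        return self._thresholds[cfg.name]

    def _profiles(self, fibers: list[Fiber], cfg: StimConfig) -> np.ndarray:
        if not fibers:
            return np.empty((0, 0))
        pts = []
        for f in fibers:
            z = compartment_z(f.diameter_um, f.z_offset)
            pts.append(np.column_stack([np.full(len(z), f.x), np.full(len(z), f.y), z]))
        pts = np.concatenate(pts)
        # the longest ladders (D = 16 um spans 32 mm) poke past the solver
        # domain ends, where the grounded-boundary potential is negligible;
        # clamp those samples to the last axial plane
        anyf = next(iter(self.lead_fields.values()))
        pts[:, 2] = np.clip(pts[:, 2], anyf.faces_z[0] + 1e-9, anyf.faces_z[-1] - 1e-9)
        acc = 0.0
        for key, w in zip(cfg.as_keys, cfg.weights):
            acc = acc + w * self.lead_fields[key].at(pts)
        return acc.reshape(len(fibers), -1)

    # -- per-configuration selectivity --------------------------------------

    def config_selective_set(self, cfg: StimConfig, collect_rows: list | None = None) -> set:
        fiber_ids, thr = self.config_thresholds(cfg)
        fid_of = {f.id: f.fascicle_id for f in self.fibers}
        fas = np.array([fid_of[i] for i in fiber_ids], dtype=np.int64) if len(fiber_ids) else np.empty(0, int)
        nA = self.sweep.n
        counts = {}
        for fasc in np.unique(fas):
            t = np.sort(thr[(fas == fasc) & (thr >= 0)])
            counts[int(fasc)] = np.searchsorted(t, np.arange(nA), side="right")
        if not counts:
            return set()
        imp = sorted(counts)
        cmat = np.vstack([counts[i] for i in imp])  # (n_implicated, nA)
        tot = np.array([self.totals[i] for i in imp], dtype=float)
        mu = cmat / tot[:, None]
        N = cmat.sum(axis=0)
        mu_sum = mu.sum(axis=0)
        sel_spatial = mu - (mu_sum[None, :] - mu) / (self.m - 1)
        with np.errstate(invalid="ignore", divide="ignore"):
            sel_func = np.where(N[None, :] > 0, cmat / np.maximum(N[None, :], 1), 0.0)
        ok = (sel_spatial > SEL_SPATIAL_MIN) & (sel_func > SEL_FUNCTIONAL_MIN) & (cmat >= 1)
        selective = {imp[i] for i in range(len(imp)) if ok[i].any()}
        if collect_rows is not None:
            charges = self.sweep.charges_nc
            for i, fasc in enumerate(imp):
                thr_q = fascicle_threshold_charge(mu[i], charges)
                collect_rows.append(
                    (cfg.name, fasc, int(self.totals[fasc]), float(sel_spatial[i].max()),
                     float(sel_func[i].max()), fasc in selective, thr_q)
                )
        return selective

    # -- policies ------------------------------------------------------------

    def policy_configs(self, policy: str) -> list[StimConfig]:
        mono = monopolar_configs(self.placements)
        if policy == "monopolar":
            return mono
        if policy in ("bipolar", "combined"):
            bi = []
            for pi, pl in enumerate(self.placements):
                # identical signed weight maps evaluate identically; skip them
                bi.extend(enumerate_bipolar_configs(pl.electrode, pi, dedup=True))
            return mono + bi
        raise SelectivityError(f"unknown policy {policy!r}")

    def evaluate(self, policy: str) -> SelectivityReport:
        rows: list = []
        report = SelectivityReport(policy=policy, m=self.m)
        for cfg in self.policy_configs(policy):
            s = self.config_selective_set(cfg, collect_rows=rows)
            report.selective_by_config[cfg.name] = s
            report.selective_union |= s
        report.per_config_rows = rows
        return report

    # -- fascicle thresholds (validation figure) ------------------------------

    def nearest_fascicle_thresholds(self) -> dict:
        """Per monopolar configuration: charge at which the fascicle nearest
        the driving site reaches 10% recruitment (None if never)."""
        fid_of = {f.id: f.fascicle_id for f in self.fibers}
        fas_index = self.cross_section.fascicle_index()
        out = {}
        from shapely.geometry import Point

        for cfg in monopolar_configs(self.placements):
            ax, ay = self._as_xy[cfg.anchor][:2]
            p = Point(ax, ay)
            nearest = min(self.fascicle_ids, key=lambda i: fas_index[i].polygon.distance(p))
            fiber_ids, thr = self.config_thresholds(cfg)
            sel = [t for i, t in zip(fiber_ids, thr) if fid_of[i] == nearest and t >= 0]
            tot = self.totals[nearest]
            t_sorted = np.sort(np.array(sel))
            counts = np.searchsorted(t_sorted, np.arange(self.sweep.n), side="right")
            out[cfg.name] = fascicle_threshold_charge(counts / tot, self.sweep.charges_nc)
        return out


# ---------------------------------------------------------------------------
# Spec-level convenience entry points
# ---------------------------------------------------------------------------

def selective_fascicles(evaluator: SelectivityEvaluator, configs: list[StimConfig]):
    """Selective sets per configuration plus the electrode score (percent)."""
    per = {c.name: evaluator.config_selective_set(c) for c in configs}
    union = set().union(*per.values()) if per else set()
    return per, 100.0 * len(union) / evaluator.m


def evaluate_policy(
    cross_section: NerveCrossSection,
    placements: list[Placement],
    policy: str,
    lead_fields: dict,
    populations: list[FiberPopulation],
    sweep: StimulusSweep | None = None,
    settings: IntegrationSettings | None = None,
) -> SelectivityReport:
    """Evaluate a stimulation policy; ``bipolar`` includes the monopolar
    configurations (superset), so its score is never below monopolar's."""
    ev = SelectivityEvaluator(cross_section, placements, lead_fields, populations,
                              sweep=sweep, settings=settings)
    rep = ev.evaluate(policy)
    if policy in ("bipolar", "combined"):
        mono = SelectivityReport(policy="monopolar", m=ev.m)
        for cfg in ev.policy_configs("monopolar"):
            s = ev.config_selective_set(cfg)
            mono.selective_by_config[cfg.name] = s
            mono.selective_union |= s
        rep.improvement = rep.score - mono.score
    return rep


def evaluate_multi_implant(
    cross_section: NerveCrossSection,
    electrode,
    n_implants_list,
    seed: int,
    grid: GridSpec | None = None,
    density: float | None = None,
    sweep: StimulusSweep | None = None,
    settings: IntegrationSettings | None = None,
    populations: list[FiberPopulation] | None = None,
    shaft_cache: dict | None = None,
) -> dict:
    """Monopolar selectivity score for 1..4 parallel TIME implants.

    Each implant is evaluated with its own lead fields (one shaft per solve;
    neighbouring shafts are geometrically thin and ignored as obstacles) and
    the selective fascicle sets are united across implants.  ``shaft_cache``
    (keyed by shaft offset) lets nested calls reuse solved shafts.
    """
    if electrode.kind != "TIME":
        raise SelectivityError("multi-implant evaluation is TIME-only")
    from enm.fibers import DEFAULT_DENSITY

    density = density or DEFAULT_DENSITY
    if populations is None:
        populations = populate_fibers(cross_section, seed, density=density)
    cache = shaft_cache if shaft_cache is not None else {}
    scores = {}
    sets_by_n = {}
    for n in sorted(n_implants_list):
        placements = place_implants(cross_section, electrode, n)
        union = set()
        for pl in placements:
            key = round(pl.insertion_point[1], 6)
            if key not in cache:
                cmap = build_conductivity_map(cross_section, [pl], grid)
                lfs = LeadFieldSolver(cmap).solve_all()
                ev = SelectivityEvaluator(
                    cross_section, [pl], lfs, populations, sweep=sweep, settings=settings
                )
                rep = ev.evaluate("monopolar")
                cache[key] = rep.selective_union
            union |= cache[key]
        sets_by_n[n] = union
        scores[n] = 100.0 * len(union) / cross_section.n_fascicles
    return {"scores": scores, "selective_sets": sets_by_n}
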