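"""Seeded synthetic coronary cohort: trees, perfusion maps, ground truth.

Each synthetic patient consists of a left-coronary tree (LAD and LCX
trunks with one diagonal and one obtuse-marginal branch, radii obeying
Murray's law exactly at every bifurcation), brachial cuff pressures, a
voxelised hyperemic MBF map over a half-shell LV-myocardium mask (the
right-coronary territory is omitted, as the thin RV wall defeats automated
contouring), and per-vessel invasive-FFR ground truth.

The generative model is self-consistent with the analysis the package
performs.  Hyperemic microvascular resistance per outlet is tied to the
perfusion its Voronoi territory receives through the monotone coupling

    MBF = M0 * g(FFR),   g(f) = 1 for f > 0.8, f / 0.8 otherwise,

and the per-patient state is the fixed point of: resistances from
territory flows -> network solve -> outlet FFRs -> territory flows.
Stenosis severity per evaluable vessel is chosen by root-finding the
percent-diameter stenosis whose fixed-point FFR hits a target drawn from
the cohort's FFR-band mixture, so prevalence and severity strata arise
from the hemodynamics rather than being pasted on.

All randomness flows through one seeded generator per patient,
stream-split per stage; identical config + seed reproduces the cohort
byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .bc import HemodynamicState
from .perfusion import MBFMap, assign_territories
from .solver import SolverSettings, build_vessel_graph, ffr_at, solve_network
from .tree import CoronaryTree, Node, Segment, Stenosis

FFR_THRESHOLD = 0.8

#: FFR-band mixture for ground-truth targets: (lo, hi, weight within class)
_POSITIVE_BANDS = (((0.45, 0.70), 22.0), ((0.70, 0.80), 25.0))
_NEGATIVE_BANDS = (((0.80, 0.90), 44.0), ((0.90, 1.00), 12.0))

#: cohort composition (synthetic choices emulating the target population)
P_TWO_VESSELS = 0.11
P_LAD_IF_SINGLE = 0.9
P_CAC_GE_400 = 0.233
LESION_LOCATION_PROBS = {"proximal": 0.573, "middle": 0.369, "distal": 0.058}

_SHELL_INNER_MM = 3.0
_SHELL_OUTER_MM = 12.0


def ischemic_coupling(ffr):
    """Monotone MBF attenuation g(FFR): unity above the 0.8 threshold,
    proportional below it."""
    f = np.asarray(ffr, dtype=float)
    g = np.where(f > FFR_THRESHOLD, 1.0, f / FFR_THRESHOLD)
    return g if g.ndim else float(g)


@dataclass
class CohortConfig:
    n_patients: int = 50
    vessels_per_patient: dict[int, float] = field(
        default_factory=lambda: {1: 1.0 - P_TWO_VESSELS, 2: P_TWO_VESSELS})
    stenosis_severity_range: tuple[float, float] = (30.0, 90.0)
    ischemic_fraction: float = 0.46
    mbf_normal_mean: float = 2.0  # hyperemic MBF, mL/min/mL
    mbf_normal_sd: float = 0.25  # patient-to-patient spread of the normal level
    mbf_noise_sd: float = 0.2  # voxel noise, mL/min/mL
    ffr_measurement_noise_sd: float = 0.01  # pressure-wire read noise
    voxel_spacing: tuple[float, float, float] = (0.625, 0.625, 1.25)
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.stenosis_severity_range
        if not (30.0 <= lo <= hi <= 90.0):
            raise ValueError("stenosis severity range must lie within [30, 90]")
        if not (0.0 <= self.ischemic_fraction <= 1.0):
            raise ValueError("ischemic_fraction must be in [0, 1]")
        for name in ("mbf_normal_mean", "mbf_normal_sd", "mbf_noise_sd",
                     "ffr_measurement_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.mbf_normal_mean <= 0:
            raise ValueError("mbf_normal_mean must be > 0")
        if any(s <= 0 for s in self.voxel_spacing):
            raise ValueError("voxel spacing must be positive")
        if abs(sum(self.vessels_per_patient.values()) - 1.0) > 1e-9:
            raise ValueError("vessels_per_patient probabilities must sum to 1")


@dataclass
class VesselTruth:
    vessel_id: str
    vessel_name: str  # LAD | LCX
    stenosis_id: int
    invasive_ffr: float
    qca_percent: float
    cac_class: str  # "<400" | ">=400"
    lesion_location: str  # proximal | middle | distal
    readout_truncated: bool = False


@dataclass
class GroundTruth:
    vessels: list[VesselTruth]
    outlet_ffr: dict[int, float]  # noise-free fixed-point FFR per outlet

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([vars(v) for v in self.vessels])


@dataclass
class Patient:
    patient_id: str
    tree: CoronaryTree
    hemo: HemodynamicState
    mbf_map: MBFMap
    truth: GroundTruth
    mbf_normal: float  # patient-level M0, mL/min/mL


# ---------------------------------------------------------------------------
# geometry

def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


@dataclass
class _VesselPlan:
    name: str  # LAD | LCX
    trunk_segments: tuple[int, int]  # proximal, distal segment ids
    stenosis_id: int
    location: str


def _build_geometry(config: CohortConfig, rng: np.random.Generator,
                    vessel_names: list[str],
                    locations: dict[str, str],
                    lesion_lengths: dict[str, float],
                    initial_severity: dict[str, float],
                    ) -> tuple[CoronaryTree, list[_VesselPlan]]:
    """Left-coronary template with jittered lengths/radii/directions.

    Terminal leaf radii are drawn first and parent radii propagated upward
    by Murray's law, so every bifurcation satisfies r_p^3 = sum r_c^3
    exactly.
    """
    jit = lambda base: base * rng.uniform(0.9, 1.1)

    r_lad_leaf = 1.5 * rng.uniform(0.92, 1.08)
    r_diag_leaf = 1.2 * rng.uniform(0.92, 1.08)
    r_lcx_leaf = 1.3 * rng.uniform(0.92, 1.08)
    r_marg_leaf = 1.0 * rng.uniform(0.92, 1.08)
    # proximal radii of the tapered terminal segments
    taper = 0.8
    r_lad_p, r_diag_p = r_lad_leaf / taper, r_diag_leaf / taper
    r_lcx_p, r_marg_p = r_lcx_leaf / taper, r_marg_leaf / taper
    r_lad_trunk = (r_lad_p ** 3 + r_diag_p ** 3) ** (1.0 / 3.0)
    r_lcx_trunk = (r_lcx_p ** 3 + r_marg_p ** 3) ** (1.0 / 3.0)
    r_lm = (r_lad_trunk ** 3 + r_lcx_trunk ** 3) ** (1.0 / 3.0)

    d_lm = _unit([0.6, 0.0, -0.8] + rng.normal(0.0, 0.05, 3))
    d_lad = _unit([0.60, 0.35, -0.70] + rng.normal(0.0, 0.07, 3))
    d_lad2 = _unit(d_lad + rng.normal(0.0, 0.08, 3))
    d_diag = _unit(d_lad + [0.0, 0.45, 0.15] + rng.normal(0.0, 0.07, 3))
    d_lcx = _unit([0.35, -0.80, -0.45] + rng.normal(0.0, 0.07, 3))
    d_lcx2 = _unit(d_lcx + [0.2, 0.0, -0.3] + rng.normal(0.0, 0.08, 3))
    d_marg = _unit(d_lcx + [0.25, 0.1, -0.45] + rng.normal(0.0, 0.07, 3))

    L = {"lm": jit(8.0), "lad_p": jit(28.0), "lad_d": jit(45.0),
         "diag": jit(30.0), "lcx_p": jit(25.0), "lcx_d": jit(38.0),
         "marg": jit(28.0)}

    p0 = np.zeros(3)
    p1 = p0 + d_lm * L["lm"]
    p2 = p1 + d_lad * L["lad_p"]
    p3 = p2 + d_lad2 * L["lad_d"]
    p4 = p2 + d_diag * L["diag"]
    p5 = p1 + d_lcx * L["lcx_p"]
    p6 = p5 + d_lcx2 * L["lcx_d"]
    p7 = p5 + d_marg * L["marg"]

    nodes = {
        0: Node(0, p0, r_lm), 1: Node(1, p1, r_lm),
        2: Node(2, p2, r_lad_trunk), 3: Node(3, p3, r_lad_leaf),
        4: Node(4, p4, r_diag_leaf), 5: Node(5, p5, r_lcx_trunk),
        6: Node(6, p6, r_lcx_leaf), 7: Node(7, p7, r_marg_leaf),
    }
    segments = [
        Segment(0, 0, 1, L["lm"], r_lm, r_lm),
        Segment(1, 1, 2, L["lad_p"], r_lad_trunk, r_lad_trunk),
        Segment(2, 2, 3, L["lad_d"], r_lad_p, r_lad_leaf),
        Segment(3, 2, 4, L["diag"], r_diag_p, r_diag_leaf),
        Segment(4, 1, 5, L["lcx_p"], r_lcx_trunk, r_lcx_trunk),
        Segment(5, 5, 6, L["lcx_d"], r_lcx_p, r_lcx_leaf),
        Segment(6, 5, 7, L["marg"], r_marg_p, r_marg_leaf),
    ]
    outlets = {3: "LAD", 4: "diagonal", 6: "LCX", 7: "marginal"}

    trunk = {"LAD": (1, 2), "LCX": (4, 5)}
    seg_by_id = {s.id: s for s in segments}
    stenoses: list[Stenosis] = []
    plans: list[_VesselPlan] = []
    for k, name in enumerate(vessel_names):
        prox_id, dist_id = trunk[name]
        loc = locations[name]
        if loc == "proximal":
            seg = seg_by_id[prox_id]
            frac = rng.uniform(0.40, 0.60)
        elif loc == "middle":
            seg = seg_by_id[dist_id]
            frac = rng.uniform(0.20, 0.42)
        else:  # distal
            seg = seg_by_id[dist_id]
            frac = rng.uniform(0.55, 0.78)
        length = lesion_lengths[name]
        center = float(np.clip(frac * seg.length,
                               length / 2 + 0.5, seg.length - length / 2 - 0.5))
        stenoses.append(Stenosis(k, seg.id, center, length, initial_severity[name]))
        plans.append(_VesselPlan(name, trunk[name], k, loc))

    tree = CoronaryTree(nodes, segments, stenoses, outlets, inlet=0)
    return tree, plans


def generate_tree(config: CohortConfig, patient_seed: int) -> CoronaryTree:
    """Standalone tree generator (geometry + stenoses with severities drawn
    uniformly from the configured range)."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, patient_seed]))
    names = _draw_vessel_names(rng)
    lo, hi = config.stenosis_severity_range
    locations = {n: _draw_location(rng) for n in names}
    lengths = {n: rng.uniform(8.0, 16.0) for n in names}
    sev = {n: float(rng.uniform(lo, hi)) for n in names}
    tree, _ = _build_geometry(config, rng, names, locations, lengths, sev)
    return tree


def _draw_vessel_names(rng: np.random.Generator) -> list[str]:
    if rng.random() < P_TWO_VESSELS:
        return ["LAD", "LCX"]
    return ["LAD" if rng.random() < P_LAD_IF_SINGLE else "LCX"]


def _draw_location(rng: np.random.Generator) -> str:
    names = list(LESION_LOCATION_PROBS)
    probs = np.array([LESION_LOCATION_PROBS[n] for n in names])
    return str(rng.choice(names, p=probs / probs.sum()))


# ---------------------------------------------------------------------------
# LV mask

def build_lv_mask(tree: CoronaryTree, config: CohortConfig) -> MBFMap:
    """Perfusion-bed myocardium mask for the left-coronary outlets.

    The mask is the union of spherical shells (inner/outer radii 3/12 mm)
    around the outlet terminal nodes -- the subepicardial tissue each
    outlet perfuses -- cut by a plane through the outlet centroid so the
    proximal (right-coronary) side is absent, mirroring the exclusion of
    RCA territories.  The cut is relaxed if it would strip any outlet of
    its whole Voronoi cell.  Returned as an MBFMap with zero values.
    """
    _, seeds = tree.outlet_positions()
    center = seeds.mean(axis=0)
    normal = _unit(center - tree.nodes[tree.inlet].position)

    spacing = np.asarray(config.voxel_spacing)
    lo = seeds.min(axis=0) - (_SHELL_OUTER_MM + 2.0)
    hi = seeds.max(axis=0) + (_SHELL_OUTER_MM + 2.0)
    all_pts = np.vstack([n.position for n in tree.nodes.values()])
    lo = np.minimum(lo, all_pts.min(axis=0) - 2.0)
    hi = np.maximum(hi, all_pts.max(axis=0) + 2.0)
    shape = tuple(int(np.ceil((hi[i] - lo[i]) / spacing[i])) for i in range(3))
    origin = tuple(float(x) for x in lo)

    ii, jj, kk = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    centers = lo + (np.stack([ii, jj, kk], axis=-1) + 0.5) * spacing
    d_out = np.linalg.norm(centers[..., None, :] - seeds[None, None, None, :, :],
                           axis=-1)  # (nx, ny, nz, n_outlets)
    shell = ((d_out >= _SHELL_INNER_MM) & (d_out <= _SHELL_OUTER_MM)).any(axis=-1)
    side = (centers - center) @ normal
    for margin in (-4.0, -8.0, -_SHELL_OUTER_MM, -np.inf):
        mask = shell & (side >= margin)
        if not mask.any():
            continue
        nearest = np.argmin(d_out[mask], axis=-1)
        if np.all(np.bincount(nearest, minlength=seeds.shape[0]) > 0):
            break
    if not mask.any():
        raise ValueError("degenerate LV mask: no voxels")
    return MBFMap(np.zeros(shape), mask, tuple(float(s) for s in spacing), origin)


# ---------------------------------------------------------------------------
# coupled ground-truth hemodynamics

def _fixed_point_outlet_ffr(tree: CoronaryTree, hemo: HemodynamicState,
                            m0: float, outlet_vol_ml: dict[int, float],
                            step: float, damping: float = 0.5,
                            tol: float = 1.0e-11, max_iter: int = 200):
    """Self-consistent outlet FFRs under the MBF--FFR coupling.

    Iterates R_i = (MAP - Pv)/(M0 * g(FFR_i) * V_i) against the network
    solve until the outlet FFRs are stationary.  Returns (ffr_by_outlet,
    graph, solution).
    """
    outlet_ids = sorted(tree.outlets)
    ffr = {o: 1.0 for o in outlet_ids}
    settings = SolverSettings(step=step)
    dp_drive = hemo.map_pressure - hemo.pv

    def resistances():
        return {o: dp_drive / (m0 * ischemic_coupling(ffr[o]) * outlet_vol_ml[o])
                for o in outlet_ids}

    # graph topology depends only on the geometry; resistance updates are
    # applied in place and the Newton solve warm-started between passes
    graph = build_vessel_graph(tree, hemo, resistances(), step=step)
    sol = None
    p_init = None
    for _ in range(max_iter):
        res = resistances()
        graph.outlet_r = np.asarray([res[o] for o in outlet_ids])
        sol = solve_network(graph, hemo.map_pressure, settings, p_init=p_init)
        p_init = sol.pressures
        new = {o: float(sol.pressures[graph.tree_node_index[o]]) / hemo.map_pressure
               for o in outlet_ids}
        delta = max(abs(new[o] - ffr[o]) for o in outlet_ids)
        ffr = {o: damping * ffr[o] + (1.0 - damping) * new[o] for o in outlet_ids}
        if delta < tol:
            break
    return ffr, graph, sol


def _vessel_ffr(tree: CoronaryTree, hemo: HemodynamicState, m0: float,
                outlet_vol_ml: dict[int, float], stenosis_id: int,
                step: float, offset: float = 20.0) -> tuple[float, bool]:
    _, graph, sol = _fixed_point_outlet_ffr(tree, hemo, m0, outlet_vol_ml, step)
    return ffr_at(sol, graph, stenosis_id, offset)


def _draw_target_ffr(rng: np.random.Generator, ischemic: bool) -> float:
    bands = _POSITIVE_BANDS if ischemic else _NEGATIVE_BANDS
    w = np.array([b[1] for b in bands])
    (lo, hi), _ = bands[rng.choice(len(bands), p=w / w.sum())]
    return float(rng.uniform(lo, hi))


def _invert_severity(tree: CoronaryTree, hemo: HemodynamicState, m0: float,
                     outlet_vol_ml: dict[int, float], stenosis_id: int,
                     target_ffr: float, severity_range: tuple[float, float],
                     step: float = 4.0) -> float:
    """Percent-diameter severity whose fixed-point vessel FFR hits the target.

    FFR is strictly decreasing in severity; targets outside the achievable
    range clamp to the nearest bound of ``severity_range``.
    """
    st = tree.stenosis_by_id(stenosis_id)
    lo, hi = severity_range

    def f(sev: float) -> float:
        st.severity = sev
        return _vessel_ffr(tree, hemo, m0, outlet_vol_ml, stenosis_id, step)[0] - target_ffr

    if lo == hi:
        st.severity = lo
        return lo
    f_lo = f(lo)
    if f_lo <= 0.0:  # even the mildest stenosis undershoots the target
        st.severity = lo
        return lo
    f_hi = f(hi)
    if f_hi >= 0.0:  # max severity cannot reach the target
        st.severity = hi
        return hi
    sev = float(brentq(f, lo, hi, xtol=1.0e-2))
    st.severity = sev
    return sev


# ---------------------------------------------------------------------------
# patient assembly

def generate_mbf_map(tree: CoronaryTree, outlet_ffr: dict[int, float],
                     config: CohortConfig, rng: np.random.Generator,
                     mbf_normal: float | None = None,
                     mask_map: MBFMap | None = None) -> MBFMap:
    """Voxelised hyperemic MBF consistent with the ground-truth outlet FFRs.

    Territory voxels get Normal(M0 * g(FFR), mbf_noise_sd) truncated at
    zero; the territory rule is the same Voronoi assignment the analysis
    stage uses, which keeps parameter recovery well-posed.
    """
    if mask_map is None:
        mask_map = build_lv_mask(tree, config)
    if mask_map.n_masked == 0:
        raise ValueError("degenerate mask: zero voxels")
    m0 = config.mbf_normal_mean if mbf_normal is None else mbf_normal
    terr = assign_territories(mask_map, tree)
    values = np.zeros(mask_map.mask.shape)
    sel = mask_map.mask
    labels = terr.labels[sel]
    mean = np.zeros(labels.shape)
    for oid in terr.outlet_ids:
        mean[labels == oid] = m0 * ischemic_coupling(outlet_ffr[oid])
    noise = rng.normal(0.0, config.mbf_noise_sd, size=mean.shape) \
        if config.mbf_noise_sd > 0 else 0.0
    values[sel] = np.maximum(mean + noise, 0.0)
    return MBFMap(values, mask_map.mask, mask_map.spacing, mask_map.origin)


def simulate_invasive_ffr(tree: CoronaryTree, hemo: HemodynamicState,
                          config: CohortConfig, m0: float,
                          outlet_vol_ml: dict[int, float],
                          stenosis_ids: list[int],
                          rng: np.random.Generator | None = None,
                          step: float = 1.0,
                          ) -> tuple[dict[int, float], dict[int, tuple[float, bool]]]:
    """Pressure-wire ground truth at fine discretisation (step <= 1 mm).

    Returns (outlet_ffr, {stenosis_id: (vessel_ffr, truncated)}); vessel
    FFRs are read 20 mm distal to each stenosis and perturbed by the
    configured measurement noise, clipped to (0, 1].
    """
    if step > 1.0:
        raise ValueError("invasive simulation requires step <= 1 mm")
    outlet_ffr, graph, sol = _fixed_point_outlet_ffr(tree, hemo, m0,
                                                     outlet_vol_ml, step)
    readings: dict[int, tuple[float, bool]] = {}
    for sid in stenosis_ids:
        f, trunc = ffr_at(sol, graph, sid, offset=20.0)
        if rng is not None and config.ffr_measurement_noise_sd > 0:
            f += float(rng.normal(0.0, config.ffr_measurement_noise_sd))
        readings[sid] = (float(np.clip(f, 1.0e-6, 1.0)), trunc)
    return outlet_ffr, readings


def generate_patient(config: CohortConfig, patient_index: int) -> Patient:
    """One fully simulated patient; deterministic in (config.seed, patient_index)."""
    ss = np.random.SeedSequence([config.seed, patient_index])
    rng_geom, rng_truth, rng_map, rng_meas = [
        np.random.default_rng(s) for s in ss.spawn(4)]

    sbp = float(np.clip(rng_geom.normal(130.0, 15.0), 95.0, 185.0))
    dbp = float(np.clip(rng_geom.normal(78.0, 10.0), 55.0, sbp - 20.0))
    hemo = HemodynamicState(sbp=sbp, dbp=dbp)

    names = _draw_vessel_names(rng_geom)
    locations = {n: _draw_location(rng_geom) for n in names}
    lengths = {n: float(rng_geom.uniform(8.0, 16.0)) for n in names}
    lo, hi = config.stenosis_severity_range
    init_sev = {n: float(rng_geom.uniform(lo, hi)) for n in names}
    tree, plans = _build_geometry(config, rng_geom, names, locations,
                                  lengths, init_sev)

    mask_map = build_lv_mask(tree, config)
    terr = assign_territories(mask_map, tree)
    vol_ml = {o: terr.voxel_count(o) * mask_map.voxel_volume_mm3 * 1.0e-3
              for o in terr.outlet_ids}
    if any(v == 0.0 for v in vol_ml.values()):
        raise ValueError("empty Voronoi territory in synthetic mask")

    m0 = float(max(0.2, rng_truth.normal(config.mbf_normal_mean,
                                         config.mbf_normal_sd)))

    cac = ">=400" if rng_truth.random() < P_CAC_GE_400 else "<400"
    targets = {}
    for plan in plans:
        ischemic = rng_truth.random() < config.ischemic_fraction
        targets[plan.stenosis_id] = _draw_target_ffr(rng_truth, ischemic)

    severities = {}
    for plan in plans:
        # invert each lesion with the companion vessel temporarily healthy
        others = [tree.stenosis_by_id(p.stenosis_id) for p in plans
                  if p.stenosis_id != plan.stenosis_id]
        saved = [(o, o.severity) for o in others]
        for o, _ in saved:
            o.severity = 1.0e-6
        severities[plan.stenosis_id] = _invert_severity(
            tree, hemo, m0, vol_ml, plan.stenosis_id,
            targets[plan.stenosis_id], (lo, hi))
        for o, s in saved:
            o.severity = s
    for sid, sev in severities.items():
        tree.stenosis_by_id(sid).severity = sev

    outlet_ffr, readings = simulate_invasive_ffr(
        tree, hemo, config, m0, vol_ml, [p.stenosis_id for p in plans],
        rng=rng_meas, step=1.0)

    mbf_map = generate_mbf_map(tree, outlet_ffr, config, rng_map,
                               mbf_normal=m0, mask_map=mask_map)

    pid = f"P{patient_index:04d}"
    vessels = []
    for plan in plans:
        f, trunc = readings[plan.stenosis_id]
        vessels.append(VesselTruth(
            vessel_id=f"{pid}-{plan.name}", vessel_name=plan.name,
            stenosis_id=plan.stenosis_id, invasive_ffr=f,
            qca_percent=severities[plan.stenosis_id], cac_class=cac,
            lesion_location=plan.location, readout_truncated=trunc))
    truth = GroundTruth(vessels, outlet_ffr)
    return Patient(pid, tree, hemo, mbf_map, truth, m0)


def generate_cohort(config: CohortConfig) -> list[Patient]:
    return [generate_patient(config, i) for i in range(config.n_patients)]
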