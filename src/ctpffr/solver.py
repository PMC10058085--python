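"""Reduced-order steady hemodynamics on the coronary tree.

The 3-D incompressible-flow problem is collapsed to a nonlinear resistor
network: mass conservation is enforced at every network node and momentum
along each edge through a pressure-drop law

    dP(Q) = a*Q + b*Q*|Q|

where ``a`` is the Poiseuille resistance integrated analytically through
the local (tapered or stenosed) radius profile and ``b`` is an empirical
quadratic separation loss of Young-Tsai form, present only across a
stenosis:

    b = (K_t * rho / 2) * (1/A_throat - 1/A_ref)^2,   K_t = 1.52.

The inlet is held at the mean aortic pressure; every outlet discharges
through its lumped microvascular resistance to the venous pressure.  The
nodal system is solved by damped Newton iteration on pressures.  Walls are
rigid, blood Newtonian.

FFR at a point is the ratio of local pressure to inlet pressure; the
per-vessel readout is taken at a fixed arc-length offset (20 mm by
convention, mirroring pressure-wire placement) distal to the stenosis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.linalg import spsolve

from .bc import MLMIN_TO_M3S, MMHG_TO_PA, HemodynamicState
from .tree import CoronaryTree, Segment, Stenosis

K_T = 1.52  # empirical stenosis expansion-loss coefficient
_G_MAX = 1.0e9  # conductance ceiling for (near-)zero-resistance edges, mL/min/mmHg


@dataclass
class SolverSettings:
    residual_tol: float = 1.0e-10  # max nodal mass imbalance, mL/min
    max_iter: int = 200
    relaxation: float = 0.7  # Newton under-relaxation factor in (0, 1]
    step: float = 1.0  # discretisation step along segments, mm

    def __post_init__(self) -> None:
        if self.residual_tol <= 0:
            raise ValueError("residual tolerance must be > 0")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if not (0.0 < self.relaxation <= 1.0):
            raise ValueError("relaxation must be in (0, 1]")
        if self.step <= 0:
            raise ValueError("discretisation step must be > 0")


def poiseuille_resistance(length_mm: float, radius_mm: float,
                          viscosity: float = 0.0035) -> float:
    """Poiseuille resistance 8*mu*L/(pi*r^4) in SI units (Pa*s/m^3)."""
    if length_mm <= 0 or radius_mm <= 0:
        raise ValueError("length and radius must be > 0")
    L = length_mm * 1.0e-3
    r = radius_mm * 1.0e-3
    return 8.0 * viscosity * L / (np.pi * r ** 4)


def _si_to_clinical_a(a_si: float) -> float:
    return a_si * MLMIN_TO_M3S / MMHG_TO_PA


def _si_to_clinical_b(b_si: float) -> float:
    return b_si * MLMIN_TO_M3S ** 2 / MMHG_TO_PA


def stenosis_loss_coefficient(throat_radius_mm: float, ref_radius_mm: float,
                              density: float = 1050.0) -> float:
    """Quadratic loss coefficient b (SI, Pa*s^2/m^6) for a focal stenosis."""
    a_t = np.pi * (throat_radius_mm * 1.0e-3) ** 2
    a_0 = np.pi * (ref_radius_mm * 1.0e-3) ** 2
    return (K_T * density / 2.0) * (1.0 / a_t - 1.0 / a_0) ** 2


def segment_coefficients(length_mm: float, radius_mm: float,
                         stenosis_severity: float | None = None,
                         blood: HemodynamicState | None = None,
                         ) -> tuple[float, float]:
    """Edge coefficients (a, b) in clinical units (mmHg*min/mL, mmHg*min^2/mL^2)
    for a uniform segment, optionally carrying a stenosis of the given
    percent-diameter severity over its whole length.
    """
    mu = blood.blood_viscosity if blood is not None else 0.0035
    rho = blood.blood_density if blood is not None else 1050.0
    if stenosis_severity is None or stenosis_severity == 0.0:
        a_si = poiseuille_resistance(length_mm, radius_mm, mu)
        return _si_to_clinical_a(a_si), 0.0
    if not (0.0 <= stenosis_severity < 100.0):
        raise ValueError("severity must be in [0, 100)")
    throat = radius_mm * (1.0 - stenosis_severity / 100.0)
    a_si = poiseuille_resistance(length_mm, throat, mu)
    b_si = stenosis_loss_coefficient(throat, radius_mm, rho)
    return _si_to_clinical_a(a_si), _si_to_clinical_b(b_si)


def _taper_integral(r0: float, r1: float, x0: float, x1: float, L: float) -> float:
    """integral of r(x)^-4 dx (mm^-3) over [x0, x1] for a linear taper r0 -> r1 on [0, L]."""
    k = (r1 - r0) / L
    if abs(k) < 1.0e-12:
        return (x1 - x0) / r0 ** 4
    ra = r0 + k * x0
    rb = r0 + k * x1
    return (ra ** -3 - rb ** -3) / (3.0 * k)


@dataclass
class VesselGraph:
    """Discretised network: nodes indexed 0..n-1, directed tree edges with
    (a, b) pressure-drop coefficients, one inlet, resistive outlets."""

    n_nodes: int
    edge_src: np.ndarray
    edge_dst: np.ndarray
    edge_a: np.ndarray  # mmHg*min/mL
    edge_b: np.ndarray  # mmHg*min^2/mL^2
    inlet: int
    outlet_nodes: np.ndarray  # graph indices
    outlet_r: np.ndarray  # mmHg*min/mL, aligned with outlet_nodes
    pv: float  # mmHg
    # readout support: per tree segment, arc positions and graph node ids
    seg_arcs: dict[int, np.ndarray] = field(default_factory=dict, repr=False)
    seg_nodes: dict[int, np.ndarray] = field(default_factory=dict, repr=False)
    tree: CoronaryTree | None = field(default=None, repr=False)
    tree_node_index: dict[int, int] = field(default_factory=dict, repr=False)


def build_vessel_graph(tree: CoronaryTree, hemo: HemodynamicState,
                       resistances: dict[int, float],
                       step: float = 1.0) -> VesselGraph:
    """Discretise the tree into a resistor network.

    ``resistances`` maps each outlet node id to its lumped R (mmHg*min/mL).
    Segments are subdivided at ``step`` (mm) intervals plus exact stenosis
    boundaries; Poiseuille coefficients use the analytic taper integral so
    the series resistance is independent of the subdivision.
    """
    missing = set(tree.outlets) - set(resistances)
    if missing:
        raise ValueError(f"outlet resistances missing for nodes {sorted(missing)}")
    mu = hemo.blood_viscosity
    rho = hemo.blood_density

    node_index: dict[int, int] = {}
    n = 0
    for nid in sorted(tree.nodes):
        node_index[nid] = n
        n += 1

    src, dst, e_a, e_b = [], [], [], []
    seg_arcs: dict[int, np.ndarray] = {}
    seg_nodes: dict[int, np.ndarray] = {}

    for seg in tree.segments:
        stens = tree.stenoses_on(seg.id)
        for i, st in enumerate(stens):
            if st.start < 0 or st.end > seg.length:
                raise ValueError(f"stenosis {st.id} outside segment {seg.id}")
            if i > 0 and st.start < stens[i - 1].end:
                raise ValueError(f"overlapping stenoses on segment {seg.id}")
        # equal subdivisions <= step; stenosis boundaries inserted exactly,
        # displacing any base point close enough to leave a sliver edge
        base = np.linspace(0.0, seg.length, int(np.ceil(seg.length / step)) + 1)
        bounds = [x for st in stens for x in (st.start, st.end)
                  if 1.0e-9 < x < seg.length - 1.0e-9]
        if bounds:
            bounds_arr = np.asarray(bounds)
            keep = np.abs(base[:, None] - bounds_arr[None, :]).min(axis=1) > 0.25 * step
            keep[0] = keep[-1] = True
            base = base[keep]
        arcs = np.unique(np.concatenate([base, bounds]))

        ids = np.empty(arcs.size, dtype=int)
        ids[0] = node_index[seg.parent]
        ids[-1] = node_index[seg.child]
        for j in range(1, arcs.size - 1):
            ids[j] = n
            n += 1
        seg_arcs[seg.id] = arcs
        seg_nodes[seg.id] = ids

        def stenosis_at(x: float) -> Stenosis | None:
            for st in stens:
                if st.start - 1.0e-9 <= x <= st.end + 1.0e-9:
                    return st
            return None

        for j in range(arcs.size - 1):
            x0, x1 = arcs[j], arcs[j + 1]
            xm = 0.5 * (x0 + x1)
            st = stenosis_at(xm)
            if st is None:
                integ = _taper_integral(seg.radius_prox, seg.radius_dist,
                                        x0, x1, seg.length)  # mm^-3
                a_si = 8.0 * mu * integ * 1.0e9 / np.pi  # Pa*s/m^3
                b_clin = 0.0
            else:
                r_ref = seg.radius_at(st.center)
                throat = r_ref * (1.0 - st.severity / 100.0)
                a_si = poiseuille_resistance(x1 - x0, throat, mu)
                # lumped expansion loss applied once, on the exit edge
                if abs(x1 - st.end) < 1.0e-9:
                    b_clin = _si_to_clinical_b(
                        stenosis_loss_coefficient(throat, r_ref, rho))
                else:
                    b_clin = 0.0
            src.append(ids[j])
            dst.append(ids[j + 1])
            e_a.append(_si_to_clinical_a(a_si))
            e_b.append(b_clin)

    outlet_ids = sorted(tree.outlets)
    return VesselGraph(
        n_nodes=n,
        edge_src=np.asarray(src), edge_dst=np.asarray(dst),
        edge_a=np.asarray(e_a), edge_b=np.asarray(e_b),
        inlet=node_index[tree.inlet],
        outlet_nodes=np.asarray([node_index[o] for o in outlet_ids]),
        outlet_r=np.asarray([float(resistances[o]) for o in outlet_ids]),
        pv=hemo.pv,
        seg_arcs=seg_arcs, seg_nodes=seg_nodes,
        tree=tree, tree_node_index=dict(node_index),
    )


@dataclass
class FFRSolution:
    pressures: np.ndarray  # mmHg, per graph node
    edge_flows: np.ndarray  # mL/min, aligned with graph edges
    converged: bool
    iterations: int
    final_residual: float  # mL/min, max nodal mass imbalance
    residual_history: np.ndarray
    inlet_flow: float  # mL/min
    flagged_retrograde: bool = False


class SolverError(RuntimeError):
    def __init__(self, msg: str, residual_history: np.ndarray):
        super().__init__(msg)
        self.residual_history = residual_history


def _edge_flows(dp: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Invert dP = a*Q + b*Q|Q| edge-wise (sign-symmetric).

    Uses the rationalised root 2*dP / (a + sqrt(a^2 + 4*b*|dP|)), which is
    cancellation-free as b -> 0 and reduces to dP/a on linear edges.
    """
    denom = a + np.sqrt(a ** 2 + 4.0 * b * np.abs(dp))
    return 2.0 * dp / np.maximum(denom, 2.0 / _G_MAX)


def solve_network(graph: VesselGraph, inlet_pressure: float,
                  settings: SolverSettings = SolverSettings(),
                  p_init: np.ndarray | None = None) -> FFRSolution:
    """Damped Newton solve of nodal mass conservation.

    The inlet pressure is fixed; every other nodal pressure is an unknown,
    initialised at uniform inlet pressure (or ``p_init`` to warm-start).
    Convergence: max nodal mass imbalance <= ``settings.residual_tol``
    (mL/min), floored by the roundoff level of stiff edges.  Raises
    ``SolverError`` on non-convergence, carrying the residual history.
    """
    n = graph.n_nodes
    free = np.ones(n, dtype=bool)
    free[graph.inlet] = False
    fidx = np.full(n, -1, dtype=int)
    fidx[free] = np.arange(free.sum())
    nf = int(free.sum())

    if p_init is not None:
        p = np.array(p_init, dtype=float)
        p[graph.inlet] = float(inlet_pressure)
    else:
        p = np.full(n, float(inlet_pressure))
    src, dst = graph.edge_src, graph.edge_dst
    a, b = graph.edge_a, graph.edge_b
    onodes, orr = graph.outlet_nodes, graph.outlet_r

    history = []
    converged = False
    it = 0
    eps = np.finfo(float).eps
    best_res = np.inf
    best_p = p.copy()
    stall = 0
    floor = 0.0
    for it in range(1, settings.max_iter + 1):
        dp = p[src] - p[dst]
        q = _edge_flows(dp, a, b)
        # nodal residual: net outflow minus inflow must vanish at free nodes
        resid = np.zeros(n)
        np.subtract.at(resid, src, q)
        np.add.at(resid, dst, q)
        resid[onodes] -= (p[onodes] - graph.pv) / orr
        maxres = float(np.abs(resid[free]).max()) if nf else 0.0
        history.append(maxres)
        if maxres < best_res * (1.0 - 1.0e-3):
            best_res, best_p, stall = maxres, p.copy(), 0
        else:
            stall += 1
        with np.errstate(divide="ignore"):
            g = np.minimum(1.0 / (a + 2.0 * b * np.abs(q)), _G_MAX)  # dQ/d(dP)
        # roundoff floor: pressure differences carry ~eps*|P| noise which a
        # stiff edge amplifies by its conductance
        floor = 8.0 * eps * float(g.max()) * abs(inlet_pressure) if g.size else 0.0
        if maxres <= max(settings.residual_tol, floor):
            converged = True
            break
        if stall >= 10 and best_res <= 100.0 * max(settings.residual_tol, floor):
            # stagnating at the machine floor: accept the best iterate
            p = best_p
            converged = True
            break
        rows, cols, vals = [], [], []
        for u_arr, v_arr, sign in ((src, src, 1.0), (dst, dst, 1.0),
                                   (src, dst, -1.0), (dst, src, -1.0)):
            sel = free[u_arr] & free[v_arr]
            rows.append(fidx[u_arr[sel]])
            cols.append(fidx[v_arr[sel]])
            vals.append(sign * g[sel])
        sel = free[onodes]
        rows.append(fidx[onodes[sel]])
        cols.append(fidx[onodes[sel]])
        vals.append(1.0 / orr[sel])
        J = csr_matrix((np.concatenate(vals),
                        (np.concatenate(rows), np.concatenate(cols))),
                       shape=(nf, nf))
        # residual is d(net inflow); Newton step on pressures
        delta = spsolve(J, resid[free])
        p[free] += settings.relaxation * delta

    history = np.asarray(history)
    if not converged:
        raise SolverError(
            f"no convergence after {settings.max_iter} iterations "
            f"(residual {history[-1]:.3e} mL/min)", history)

    dp = p[src] - p[dst]
    q = _edge_flows(dp, a, b)
    resid = np.zeros(n)
    np.subtract.at(resid, src, q)
    np.add.at(resid, dst, q)
    resid[onodes] -= (p[onodes] - graph.pv) / orr
    final_res = float(np.abs(resid[free]).max()) if nf else 0.0
    retro = bool(np.any(q < -settings.residual_tol))
    if retro:
        warnings.warn("retrograde edge flow detected; the network model "
                      "assumes root-to-leaf flow")
    inlet_flow = float(q[src == graph.inlet].sum() - q[dst == graph.inlet].sum())
    return FFRSolution(p, q, converged, it, final_res, history, inlet_flow,
                       flagged_retrograde=retro)


def pressure_at(solution: FFRSolution, graph: VesselGraph,
                seg_id: int, arc: float) -> float:
    """Nodal-linear interpolation of pressure at an arc-length on a segment."""
    arcs = graph.seg_arcs[seg_id]
    ids = graph.seg_nodes[seg_id]
    arc = float(np.clip(arc, 0.0, arcs[-1]))
    return float(np.interp(arc, arcs, solution.pressures[ids]))


def ffr_at(solution: FFRSolution, graph: VesselGraph, stenosis_id: int,
           offset: float = 20.0) -> tuple[float, bool]:
    """CTP-FFR read ``offset`` mm distal to a stenosis along the main flow path.

    Returns (ffr, truncated): if the tree ends before the requested offset
    the most distal point is used and flagged.
    """
    tree = graph.tree
    if tree is None:
        raise ValueError("graph carries no tree reference")
    st = tree.stenosis_by_id(stenosis_id)  # KeyError if unknown
    seg = tree.segment_by_id(st.segment)
    path = tree.main_continuation(seg)
    inlet_p = float(solution.pressures[graph.inlet])

    remaining = st.end + offset
    truncated = False
    for k, s in enumerate(path):
        if remaining <= s.length or k == len(path) - 1:
            if remaining > s.length:
                truncated = True
                remaining = s.length
            return pressure_at(solution, graph, s.id, remaining) / inlet_p, truncated
        remaining -= s.length
    raise AssertionError("unreachable")


def solve_tree(tree: CoronaryTree, hemo: HemodynamicState,
               resistances: dict[int, float],
               settings: SolverSettings = SolverSettings(),
               ) -> tuple[VesselGraph, FFRSolution]:
    """Convenience wrapper: discretise and solve in one call."""
    graph = build_vessel_graph(tree, hemo, resistances, step=settings.step)
    sol = solve_network(graph, hemo.map_pressure, settings)
    return graph, sol
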