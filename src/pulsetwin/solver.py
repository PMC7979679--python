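"""1-D pulse-wave solver on an arterial network.

Mass and momentum balance in each tapered segment (flat velocity profile
for the convective term, boundary-layer friction ``-2*pi*gamma*nu*Q/A``)
close with a power-law viscoelastic tube law.  Junctions conserve mass
and total pressure; terminal segments drain into three-element
Windkessel models; the aortic root couples to a lumped two-chamber
heart through conservation of mass and static pressure.

The time stepper (two-step MacCormack, CFL-limited) lives in
:mod:`pulsetwin._kernel`; this module flattens a
:class:`~pulsetwin.network.NetworkTopology`, drives the run to a
periodic cardiac cycle and packages waveform records.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _kernel
from .network import (FluidProperties, HeartModel, NetworkTopology,
                      VesselSegment, WindkesselOutlet)
from .units import MMHG
from .waveforms import WaveformRecord


class SolverDivergenceError(RuntimeError):
    """The explicit scheme blew up (non-positive area or NaN)."""


@dataclass
class SolverConfig:
    """Time-step control and convergence protocol.

    The run stops once the maximum node-wise pressure difference between
    consecutive cycles drops below ``periodicity_tol_mmhg`` or after
    ``max_cycles`` cycles.
    """

    cfl: float = 0.8
    max_cycles: int = 12
    periodicity_tol_mmhg: float = 0.1
    scheme: str = "maccormack2"
    wave_speed_margin: float = 1.45   # safety factor on c0 for the CFL bound
    advective_margin: float = 3.0     # m/s allowance for |u| in the CFL bound

    def __post_init__(self):
        if not (0.0 < self.cfl <= 1.0):
            raise ValueError("CFL number must be in (0, 1]")
        if self.periodicity_tol_mmhg <= 0:
            raise ValueError("periodicity tolerance must be positive")


@dataclass
class MeasurementSite:
    """A named sampling node: fractional position along a segment, or a
    fixed distance upstream of its distal end."""

    name: str
    segment: str
    frac: float | None = 0.5
    from_distal_m: float | None = None


#: measurement sites used throughout the pipeline; peripheral inputs are
#: sampled midway along their vessels and the abdominal target close to
#: the distal end of the abdominal aorta.
DEFAULT_SITES = (
    MeasurementSite("aortic_root", "aortic_root", frac=0.0),
    MeasurementSite("carotid", "left_common_carotid", frac=0.5),
    MeasurementSite("brachial", "left_brachial", frac=0.5),
    MeasurementSite("femoral", "left_femoral", frac=0.5),
    MeasurementSite("abdominal_aorta", "abdominal_aorta",
                    frac=None, from_distal_m=0.03),
    MeasurementSite("left_cerebral", "left_cerebral", frac=0.5),
    MeasurementSite("left_iliac", "left_iliac", frac=0.5),
)

INPUT_SITES = ("carotid", "brachial", "femoral")
TARGET_SITES = ("aortic_root", "abdominal_aorta", "left_cerebral", "left_iliac")


def tube_law_pressure(A, dA_dt, seg: VesselSegment, fluid: FluidProperties,
                      node: int = 0):
    """Wall pressure from the viscoelastic tube law.

    ``P = P0 + Pext + (2*rho*c0^2/b) * ((A/A0)^(b/2) - 1)
    + Gamma/(A0*sqrt(A)) * dA/dt`` evaluated with the reference
    area/wave speed of grid node ``node``.
    """
    A = np.asarray(A, dtype=float)
    if np.any(A <= 0):
        raise ValueError("lumen area must be positive")
    A0 = seg.node_A0()[node]
    c0 = seg.node_c0()[node]
    elastic = (2.0 * fluid.density * c0 ** 2 / seg.b) * (
        (A / A0) ** (seg.b / 2.0) - 1.0)
    viscous = seg.Gamma / (A0 * np.sqrt(A)) * np.asarray(dA_dt, dtype=float)
    return seg.P0 + seg.Pext + elastic + viscous


def windkessel_outlet_update(Q_in: float, outlet: WindkesselOutlet, dt: float,
                             stored_pressure: float):
    """Advance the lumped R-C compartment one step (semi-implicit).

    ``stored_pressure`` is the compartment pressure above ``Pout``.
    Returns ``(boundary_pressure, new_stored_pressure)`` with the
    boundary pressure ``Pout + stored + Zc*Q_in``.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    rc = outlet.R * outlet.C
    new_stored = (stored_pressure + dt / outlet.C * Q_in) / (1.0 + dt / rc)
    return outlet.Pout + new_stored + outlet.Zc * Q_in, new_stored


def junction_coupling(parent, children, fluid: FluidProperties,
                      P0: float = 80.0 * MMHG, Pext: float = 0.0):
    """Solve one junction given characteristic information.

    ``parent`` is ``(A_guess, A0, c0, b, W_plus)`` for the parent's
    distal end; ``children`` a list of ``(A_guess, A0, c0, b, W_minus)``
    for each child's proximal end.  Returns ``(A, u)`` arrays ordered
    parent-first, satisfying mass and total-pressure conservation.
    """
    m = len(children)
    if not 1 <= m <= 3:
        raise ValueError("junction must couple 1-3 children")
    cAg = np.array([c[0] for c in children])
    cA0 = np.array([c[1] for c in children])
    cC0 = np.array([c[2] for c in children])
    cB = np.array([float(c[3]) for c in children])
    cWm = np.array([c[4] for c in children])
    out_A = np.empty(4)
    out_u = np.empty(4)
    res = _kernel._junction_solve(
        parent[0], parent[1], parent[2], float(parent[3]), parent[4],
        cAg, cA0, cC0, cB, cWm, m, fluid.density, P0, Pext, out_A, out_u)
    if res > 1e-6:
        raise RuntimeError(f"junction solve failed to converge (residual {res:.2e})")
    return out_A[:m + 1].copy(), out_u[:m + 1].copy()


def chamber_elastance(E_min, E_max, phase, t_rise, t_fall, onset=0.0):
    """Time-varying elastance at cycle phase ``phase`` in [0, 1)."""
    ph = (phase - onset) % 1.0
    return E_min + (E_max - E_min) * _kernel._activation(ph, t_rise, t_fall)


@dataclass
class FlatNetwork:
    """Node-flattened view of a topology, ready for the kernel."""

    seg_ids: list[int]
    seg_index: dict[int, int]
    seg_off: np.ndarray
    seg_nn: np.ndarray
    seg_dx: np.ndarray
    A0: np.ndarray
    c0: np.ndarray
    seg_b: np.ndarray
    seg_gamma: np.ndarray
    seg_Gamma: np.ndarray
    seg_P0: np.ndarray
    seg_Pext: np.ndarray
    jparent: np.ndarray
    jnchild: np.ndarray
    jchild: np.ndarray
    out_seg: np.ndarray
    out_kind: np.ndarray
    out_Zc: np.ndarray
    out_R: np.ndarray
    out_C: np.ndarray
    out_Pout: np.ndarray
    inlet_seg: int
    ncell: int


def flatten_network(net: NetworkTopology,
                    outlet_kind_overrides: dict[int, int] | None = None
                    ) -> FlatNetwork:
    seg_ids = sorted(net.segments)
    seg_index = {sid: i for i, sid in enumerate(seg_ids)}
    offs, nns, dxs, bs, gs, Gs, P0s, Pexts = [], [], [], [], [], [], [], []
    A0_parts, c0_parts = [], []
    off = 0
    for sid in seg_ids:
        seg = net.segments[sid]
        offs.append(off)
        nns.append(seg.n_nodes)
        dxs.append(seg.dx)
        bs.append(seg.b)
        gs.append(seg.gamma)
        Gs.append(seg.Gamma)
        P0s.append(seg.P0)
        Pexts.append(seg.Pext)
        A0_parts.append(seg.node_A0())
        c0_parts.append(seg.node_c0())
        off += seg.n_nodes

    jparent, jnchild, jchild = [], [], []
    for pid, kids in net.junctions:
        jparent.append(seg_index[pid])
        jnchild.append(len(kids))
        row = [seg_index[k] for k in kids] + [0] * (3 - len(kids))
        jchild.append(row[:3])

    overrides = outlet_kind_overrides or {}
    oseg, okind, oZc, oR, oC, oPout = [], [], [], [], [], []
    for sid in net.terminal_ids():
        out = net.outlets[sid]
        oseg.append(seg_index[sid])
        okind.append(overrides.get(sid, _kernel.OUT_WK3))
        oZc.append(out.Zc)
        oR.append(out.R)
        oC.append(out.C)
        oPout.append(out.Pout)

    return FlatNetwork(
        seg_ids=seg_ids, seg_index=seg_index,
        seg_off=np.array(offs, dtype=np.int64),
        seg_nn=np.array(nns, dtype=np.int64),
        seg_dx=np.array(dxs, dtype=np.float64),
        A0=np.concatenate(A0_parts), c0=np.concatenate(c0_parts),
        seg_b=np.array(bs), seg_gamma=np.array(gs), seg_Gamma=np.array(Gs),
        seg_P0=np.array(P0s), seg_Pext=np.array(Pexts),
        jparent=np.array(jparent, dtype=np.int64),
        jnchild=np.array(jnchild, dtype=np.int64),
        jchild=np.array(jchild, dtype=np.int64).reshape(-1, 3),
        out_seg=np.array(oseg, dtype=np.int64),
        out_kind=np.array(okind, dtype=np.int64),
        out_Zc=np.array(oZc), out_R=np.array(oR), out_C=np.array(oC),
        out_Pout=np.array(oPout),
        inlet_seg=seg_index[net.inlet_segment_id],
        ncell=off,
    )


def site_node_index(net: NetworkTopology, flat: FlatNetwork,
                    site: MeasurementSite) -> int:
    seg = net.by_name(site.segment)
    si = flat.seg_index[seg.id]
    nn = int(flat.seg_nn[si])
    if site.from_distal_m is not None:
        frac = max(0.0, 1.0 - site.from_distal_m / seg.length)
    else:
        frac = site.frac
    node = int(round(frac * (nn - 1)))
    return int(flat.seg_off[si]) + min(max(node, 0), nn - 1)


def stable_dt(net: NetworkTopology, config: SolverConfig) -> float:
    """CFL bound (the viscoelastic split step is implicit and imposes
    no constraint of its own)."""
    dt = math.inf
    for seg in net.segments.values():
        c0 = seg.node_c0()
        cmax = float(np.max(c0)) * config.wave_speed_margin \
            + config.advective_margin
        dt = min(dt, config.cfl * seg.dx / cmax)
    return dt


@dataclass
class SolverResult:
    """One converged (or flagged) cardiac cycle plus heart summaries."""

    records: dict[str, WaveformRecord]
    time: np.ndarray
    converged: bool
    cycles_run: int
    cycle_diff_mmhg: float
    junction_mass_residual: float
    stroke_volume: float       # m^3 (aortic valve flow integral)
    ejection_fraction: float
    cardiac_output: float      # m^3/s
    end_diastolic_volume: float
    end_systolic_volume: float
    dt: float
    pressure_all_nodes: np.ndarray = field(repr=False, default=None)
    flow_all_nodes: np.ndarray = field(repr=False, default=None)
    flat: FlatNetwork = field(repr=False, default=None)


def _heart_param_array(h: HeartModel) -> np.ndarray:
    v, a = h.ventricle, h.atrium
    return np.array([
        h.period,
        v.E_min, v.E_max, v.V0, v.t_rise, v.t_fall, v.onset,
        a.E_min, a.E_max, a.V0, a.t_rise, a.t_fall, a.onset,
        h.R_mitral, h.R_aortic, h.R_venous, h.P_venous,
    ])


def _initial_state(net: NetworkTopology, flat: FlatNetwork,
                   init_compartment_mmhg: float):
    A = flat.A0.copy()
    Q = np.zeros(flat.ncell)
    pc0 = init_compartment_mmhg * MMHG
    out_Pc = np.maximum(flat.out_Pout, pc0) * np.ones_like(flat.out_Pout)
    h = net.heart
    V_la = h.atrium.V0 + h.P_venous / h.atrium.E_min
    V_lv = h.ventricle.V0 + h.P_venous / h.ventricle.E_min
    heart_state = np.array([V_la, V_lv])
    return A, Q, out_Pc, heart_state


def run_to_periodic(net: NetworkTopology,
                    config: SolverConfig | None = None,
                    sites: tuple[MeasurementSite, ...] = DEFAULT_SITES,
                    init_compartment_mmhg: float = 85.0,
                    patient_id: str = "",
                    keep_fields: bool = False) -> SolverResult:
    """Integrate the network to a periodic cardiac cycle.

    Returns the last full cycle sampled at the named measurement sites.
    Raises :class:`SolverDivergenceError` on blow-up; a run that merely
    fails to reach the periodicity tolerance is returned flagged
    (``converged=False``).
    """
    config = config or SolverConfig()
    flat = flatten_network(net)
    dt = stable_dt(net, config)
    T = net.heart.period
    steps = int(math.ceil(T / dt))
    dt = T / steps

    A, Q, out_Pc, heart_state = _initial_state(net, flat, init_compartment_mmhg)
    P_prev = np.zeros((steps, flat.ncell))
    P_curr = np.zeros((steps, flat.ncell))
    Q_curr = np.zeros((steps, flat.ncell))
    q_valve = np.zeros(steps)
    v_lv = np.zeros(steps)
    v_la = np.zeros(steps)

    cycles, diff, mass_res, diverged = _kernel.run_simulation(
        flat.seg_off, flat.seg_nn, flat.seg_dx, flat.A0, flat.c0,
        flat.seg_b, flat.seg_gamma, flat.seg_Gamma, flat.seg_P0, flat.seg_Pext,
        flat.jparent, flat.jnchild, flat.jchild,
        flat.out_seg, flat.out_kind, flat.out_Zc, flat.out_R, flat.out_C,
        flat.out_Pout, out_Pc,
        flat.inlet_seg, _kernel.INLET_HEART, np.zeros(1),
        _heart_param_array(net.heart), heart_state,
        net.fluid.density, net.fluid.kinematic_viscosity,
        dt, steps, config.max_cycles, config.periodicity_tol_mmhg * MMHG,
        A, Q, P_prev, P_curr, Q_curr, q_valve, v_lv, v_la)

    if diverged:
        raise SolverDivergenceError(
            f"solver diverged during cycle {cycles + 1} (dt={dt:.3e})")

    t = np.arange(steps) * dt
    records = {}
    for site in sites:
        node = site_node_index(net, flat, site)
        records[site.name] = WaveformRecord(
            site=site.name, time=t.copy(),
            pressure_mmhg=P_curr[:, node] / MMHG,
            flow_ml_s=Q_curr[:, node] * 1e6,
            patient_id=patient_id)

    sv = float(np.sum(q_valve) * dt)
    edv = float(np.max(v_lv))
    esv = float(np.min(v_lv))
    ef = (edv - esv) / edv if edv > 0 else float("nan")
    co = sv * net.heart.heart_rate / 60.0
    net.heart.stroke_volume = sv
    net.heart.ejection_fraction = ef
    net.heart.cardiac_output = co

    return SolverResult(
        records=records, time=t,
        converged=bool(diff < config.periodicity_tol_mmhg * MMHG),
        cycles_run=int(cycles), cycle_diff_mmhg=float(diff / MMHG),
        junction_mass_residual=float(mass_res),
        stroke_volume=sv, ejection_fraction=ef, cardiac_output=co,
        end_diastolic_volume=edv, end_systolic_volume=esv, dt=dt,
        pressure_all_nodes=P_curr if keep_fields else None,
        flow_all_nodes=Q_curr if keep_fields else None,
        flat=flat if keep_fields else None)


def run_prescribed_inflow(net: NetworkTopology, qin: np.ndarray,
                          config: SolverConfig | None = None,
                          outlet_kinds: dict[int, int] | None = None,
                          n_passes: int = 1,
                          sites: tuple[MeasurementSite, ...] = (),
                          init_compartment_mmhg: float = 0.0):
    """Drive the network with a prescribed inflow sequence (one pass =
    one "cycle" of ``len(qin)`` steps at the stable dt).

    Used for wave-propagation diagnostics: ``outlet_kinds`` may map
    terminal segment ids to CLOSED (perfect reflector) or ABSORBING
    (non-reflecting) ends.  Returns ``(t, P, Q, flat)`` with the full
    node fields of the final pass.
    """
    config = config or SolverConfig()
    flat = flatten_network(net, outlet_kind_overrides=outlet_kinds)
    dt = stable_dt(net, config)
    steps = len(qin)

    A, Q, out_Pc, heart_state = _initial_state(net, flat, init_compartment_mmhg)
    P_prev = np.zeros((steps, flat.ncell))
    P_curr = np.zeros((steps, flat.ncell))
    Q_curr = np.zeros((steps, flat.ncell))
    q_valve = np.zeros(steps)
    v_lv = np.zeros(steps)
    v_la = np.zeros(steps)

    cycles, diff, mass_res, diverged = _kernel.run_simulation(
        flat.seg_off, flat.seg_nn, flat.seg_dx, flat.A0, flat.c0,
        flat.seg_b, flat.seg_gamma, flat.seg_Gamma, flat.seg_P0, flat.seg_Pext,
        flat.jparent, flat.jnchild, flat.jchild,
        flat.out_seg, flat.out_kind, flat.out_Zc, flat.out_R, flat.out_C,
        flat.out_Pout, out_Pc,
        flat.inlet_seg, _kernel.INLET_PRESCRIBED, np.asarray(qin, dtype=float),
        _heart_param_array(net.heart), heart_state,
        net.fluid.density, net.fluid.kinematic_viscosity,
        dt, steps, n_passes, -1.0,
        A, Q, P_prev, P_curr, Q_curr, q_valve, v_lv, v_la)

    if diverged:
        raise SolverDivergenceError("prescribed-inflow run diverged")
    t = np.arange(steps) * dt
    return t, P_curr, Q_curr, flat, mass_res
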