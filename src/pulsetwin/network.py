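"""Arterial-tree data model and I/O.

A systemic arterial network is a rooted tree of tapered 1-D vessel
segments.  The root (aortic root) couples to a lumped two-chamber heart;
every terminal segment drains into a three-element Windkessel model
standing in for its downstream vascular bed.

On disk a network is a CSV table of segments (clinical units: cm) plus a
YAML sidecar holding fluid properties, heart parameters and the
Windkessel outlet map (mmHg.s/mL, mL/mmHg).  In memory everything is SI.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .units import MMHG, ML, area_from_diameter, diameter_from_area

CSV_COLUMNS = [
    "id", "name", "length_cm", "D0_prox_cm", "D0_dist_cm",
    "c0_prox_m_s", "c0_dist_m_s", "b", "gamma", "Gamma_visc",
    "parent_id", "n_elements",
]

#: resistance unit on disk (mmHg.s/mL) expressed in Pa.s/m^3
R_UNIT = MMHG / ML
#: compliance unit on disk (mL/mmHg) expressed in m^3/Pa
C_UNIT = ML / MMHG


class NetworkError(ValueError):
    """Malformed network description (schema or topology)."""


@dataclass
class FluidProperties:
    """Blood density (kg/m^3) and kinematic viscosity (m^2/s)."""

    density: float = 1060.0
    kinematic_viscosity: float = 3.3e-6

    def __post_init__(self):
        if self.density <= 0 or self.kinematic_viscosity <= 0:
            raise NetworkError("fluid properties must be strictly positive")


@dataclass
class VesselSegment:
    """One tapered 1-D vessel.

    Reference area ``A0`` and intrinsic wave speed ``c0`` vary linearly
    between proximal and distal values over ``n_elements`` equal cells
    (``n_elements + 1`` grid nodes).  Nodewise overrides (``A0_nodes``,
    ``c0_nodes``) support aneurysm insertion and stiffness degradation.
    """

    id: int
    name: str
    length: float              # m
    A0_prox: float             # m^2
    A0_dist: float             # m^2
    c0_prox: float             # m/s
    c0_dist: float             # m/s
    b: float = 2.0             # stiffness exponent
    gamma: float = 9.0         # boundary-layer friction profile parameter
    Gamma: float = 0.8         # wall viscoelastic coefficient (Pa.s.m)
    P0: float = 80.0 * MMHG    # reference (stress-free) pressure, Pa
    Pext: float = 0.0          # external pressure, Pa
    n_elements: int = 8
    A0_nodes: np.ndarray | None = None
    c0_nodes: np.ndarray | None = None

    @property
    def n_nodes(self) -> int:
        return self.n_elements + 1

    @property
    def dx(self) -> float:
        return self.length / self.n_elements

    def node_positions(self) -> np.ndarray:
        return np.linspace(0.0, self.length, self.n_nodes)

    def node_A0(self) -> np.ndarray:
        if self.A0_nodes is not None:
            return np.asarray(self.A0_nodes, dtype=float)
        return np.linspace(self.A0_prox, self.A0_dist, self.n_nodes)

    def node_c0(self) -> np.ndarray:
        if self.c0_nodes is not None:
            return np.asarray(self.c0_nodes, dtype=float)
        return np.linspace(self.c0_prox, self.c0_dist, self.n_nodes)


@dataclass
class WindkesselOutlet:
    """Three-element Windkessel: Zc in series with a parallel R-C pair."""

    segment_id: int
    Zc: float          # characteristic impedance, Pa.s/m^3
    R: float           # distal (vascular-bed) resistance, Pa.s/m^3
    C: float           # compliance, m^3/Pa
    Pout: float = 10.0 * MMHG  # outflow (venous) pressure, Pa


@dataclass
class ChamberParams:
    """Time-varying elastance chamber."""

    E_min: float       # Pa/m^3
    E_max: float       # Pa/m^3
    V0: float          # unstressed volume, m^3
    t_rise: float      # activation rise end, fraction of period
    t_fall: float      # activation fall end, fraction of period
    onset: float = 0.0  # activation onset, fraction of period


@dataclass
class HeartModel:
    """Two-chamber (left atrium + left ventricle) lumped heart.

    Valves are pressure-gated resistances; venous return enters the
    atrium from a constant-pressure reservoir through ``R_ven``.
    """

    heart_rate: float = 60.0          # beats/min
    ventricle: ChamberParams = field(default_factory=lambda: ChamberParams(
        E_min=0.10 * MMHG / ML, E_max=2.8 * MMHG / ML, V0=15e-6,
        t_rise=0.30, t_fall=0.45, onset=0.0))
    atrium: ChamberParams = field(default_factory=lambda: ChamberParams(
        E_min=0.15 * MMHG / ML, E_max=0.35 * MMHG / ML, V0=3e-6,
        t_rise=0.09, t_fall=0.17, onset=0.85))
    R_mitral: float = 0.04 * MMHG / ML   # Pa.s/m^3
    R_aortic: float = 0.025 * MMHG / ML
    R_venous: float = 0.045 * MMHG / ML
    P_venous: float = 10.0 * MMHG
    # filled in after a converged simulation
    stroke_volume: float | None = None   # m^3
    ejection_fraction: float | None = None
    cardiac_output: float | None = None  # m^3/s

    def __post_init__(self):
        if self.heart_rate <= 0:
            raise NetworkError("heart_rate must be positive")

    @property
    def period(self) -> float:
        return 60.0 / self.heart_rate


@dataclass
class NetworkTopology:
    """Rooted tree of vessel segments with outlet models and fluid."""

    segments: dict[int, VesselSegment]
    junctions: list[tuple[int, list[int]]]
    inlet_segment_id: int
    outlets: dict[int, WindkesselOutlet]
    fluid: FluidProperties = field(default_factory=FluidProperties)
    heart: HeartModel = field(default_factory=HeartModel)

    def children_of(self, seg_id: int) -> list[int]:
        for pid, kids in self.junctions:
            if pid == seg_id:
                return list(kids)
        return []

    def parent_of(self, seg_id: int) -> int | None:
        for pid, kids in self.junctions:
            if seg_id in kids:
                return pid
        return None

    def terminal_ids(self) -> list[int]:
        parents = {pid for pid, _ in self.junctions}
        return [sid for sid in self.segments if sid not in parents]

    def by_name(self, name: str) -> VesselSegment:
        for seg in self.segments.values():
            if seg.name == name:
                return seg
        raise KeyError(f"no segment named {name!r}")

    def path_to(self, seg_id: int) -> list[int]:
        """Segment ids from the inlet down to (and including) seg_id."""
        path = [seg_id]
        while path[0] != self.inlet_segment_id:
            parent = self.parent_of(path[0])
            if parent is None:
                raise NetworkError(f"segment {path[0]} is not reachable from inlet")
            path.insert(0, parent)
        return path

    def copy(self) -> "NetworkTopology":
        return copy.deepcopy(self)


def characteristic_impedance(seg: VesselSegment, fluid: FluidProperties) -> float:
    """Characteristic impedance Z = rho*c0/A0 at the proximal reference
    cross-section (Pa.s/m^3).

    At fixed wall stiffness E*h this scales as D0^(-5/2), which is the
    impedance drop an aneurysmal dilation produces.
    """
    return fluid.density * seg.c0_prox / seg.A0_prox


def wave_speed_from_stiffness(Eh43: float, D0: float, density: float) -> float:
    """Intrinsic wave speed from wall stiffness k = (4/3)*E*h.

    Inverts Z = rho*c0/A0 = (4/pi)*sqrt(2*rho*k)/D0^(5/2) for c0.
    """
    A0 = area_from_diameter(D0)
    Z = (4.0 / math.pi) * math.sqrt(2.0 * density * Eh43) / D0 ** 2.5
    return Z * A0 / density


def validate_network(net: NetworkTopology) -> list[str]:
    """Return a list of invariant violations (empty when valid)."""
    v: list[str] = []
    if net.fluid.density <= 0:
        v.append("fluid: density must be positive")
    if net.fluid.kinematic_viscosity <= 0:
        v.append("fluid: kinematic viscosity must be positive")
    for sid, seg in net.segments.items():
        tag = f"segment {sid} ({seg.name})"
        if seg.length <= 0:
            v.append(f"{tag}: length must be positive")
        if min(seg.A0_prox, seg.A0_dist) <= 0 or (
                seg.A0_nodes is not None and np.min(seg.A0_nodes) <= 0):
            v.append(f"{tag}: reference area A0 must be positive everywhere")
        if min(seg.c0_prox, seg.c0_dist) <= 0 or (
                seg.c0_nodes is not None and np.min(seg.c0_nodes) <= 0):
            v.append(f"{tag}: wave speed c0 must be positive")
        if seg.n_elements < 2:
            v.append(f"{tag}: n_elements must be >= 2")
        if seg.gamma < 0:
            v.append(f"{tag}: gamma must be >= 0")
        if seg.Gamma < 0:
            v.append(f"{tag}: Gamma must be >= 0")
    if net.inlet_segment_id not in net.segments:
        v.append(f"inlet segment {net.inlet_segment_id} not in network")
    seen_children: set[int] = set()
    for pid, kids in net.junctions:
        if pid not in net.segments:
            v.append(f"junction parent {pid} not in network")
        if len(kids) < 1:
            v.append(f"junction at {pid}: must have at least one child")
        for k in kids:
            if k not in net.segments:
                v.append(f"junction child {k} not in network")
            if k in seen_children:
                v.append(f"segment {k}: has more than one parent")
            seen_children.add(k)
    if net.inlet_segment_id in seen_children:
        v.append("inlet segment cannot be a junction child")
    # reachability / acyclicity: tree must reach every segment from inlet
    reached = {net.inlet_segment_id}
    frontier = [net.inlet_segment_id]
    while frontier:
        nxt = []
        for pid in frontier:
            for k in net.children_of(pid):
                if k not in reached:
                    reached.add(k)
                    nxt.append(k)
        frontier = nxt
    for sid in net.segments:
        if sid not in reached:
            v.append(f"segment {sid}: unreachable from inlet (cycle or orphan)")
    for tid in net.terminal_ids():
        if tid not in net.outlets:
            v.append(f"segment {tid}: terminal segment missing outlet model")
    for oid, out in net.outlets.items():
        if oid not in net.segments:
            v.append(f"outlet references unknown segment {oid}")
        if out.Zc <= 0 or out.R <= 0 or out.C <= 0:
            v.append(f"outlet {oid}: Zc, R, C must be positive")
    hr = net.heart
    for label, ch in (("ventricle", hr.ventricle), ("atrium", hr.atrium)):
        if not (0 < ch.E_min < ch.E_max):
            v.append(f"heart {label}: need 0 < E_min < E_max")
    return v


def _heart_to_dict(h: HeartModel) -> dict:
    def chamber(c: ChamberParams) -> dict:
        return {
            "E_min_mmHg_per_mL": c.E_min / (MMHG / ML),
            "E_max_mmHg_per_mL": c.E_max / (MMHG / ML),
            "V0_mL": c.V0 / ML,
            "t_rise": c.t_rise, "t_fall": c.t_fall, "onset": c.onset,
        }
    return {
        "heart_rate_bpm": h.heart_rate,
        "ventricle": chamber(h.ventricle),
        "atrium": chamber(h.atrium),
        "R_mitral_mmHg_s_per_mL": h.R_mitral / R_UNIT,
        "R_aortic_mmHg_s_per_mL": h.R_aortic / R_UNIT,
        "R_venous_mmHg_s_per_mL": h.R_venous / R_UNIT,
        "P_venous_mmHg": h.P_venous / MMHG,
    }


def _heart_from_dict(d: dict) -> HeartModel:
    def chamber(c: dict) -> ChamberParams:
        return ChamberParams(
            E_min=c["E_min_mmHg_per_mL"] * MMHG / ML,
            E_max=c["E_max_mmHg_per_mL"] * MMHG / ML,
            V0=c["V0_mL"] * ML,
            t_rise=c["t_rise"], t_fall=c["t_fall"], onset=c.get("onset", 0.0),
        )
    return HeartModel(
        heart_rate=d["heart_rate_bpm"],
        ventricle=chamber(d["ventricle"]),
        atrium=chamber(d["atrium"]),
        R_mitral=d["R_mitral_mmHg_s_per_mL"] * R_UNIT,
        R_aortic=d["R_aortic_mmHg_s_per_mL"] * R_UNIT,
        R_venous=d["R_venous_mmHg_s_per_mL"] * R_UNIT,
        P_venous=d["P_venous_mmHg"] * MMHG,
    )


def sidecar_path(csv_path: str | Path) -> Path:
    return Path(csv_path).with_suffix(".yaml")


def load_network(path: str | Path) -> NetworkTopology:
    """Load a network from a segment CSV and its YAML sidecar.

    Raises :class:`NetworkError` naming the offending field on schema
    violations, and on cyclic or disconnected topologies.
    """
    path = Path(path)
    if not path.exists():
        raise NetworkError(f"network file not found: {path}")
    df = pd.read_csv(path, comment="#")
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise NetworkError(f"network CSV missing columns: {missing}")
    side = sidecar_path(path)
    if not side.exists():
        raise NetworkError(f"sidecar file not found: {side}")
    meta = yaml.safe_load(side.read_text())

    fluid = FluidProperties(
        density=float(meta["fluid"]["density_kg_m3"]),
        kinematic_viscosity=float(meta["fluid"]["kinematic_viscosity_m2_s"]),
    )
    P0 = float(meta.get("reference_pressure_mmHg", 80.0)) * MMHG
    Pext = float(meta.get("external_pressure_mmHg", 0.0)) * MMHG

    segments: dict[int, VesselSegment] = {}
    parent_map: dict[int, int] = {}
    for row in df.itertuples(index=False):
        sid = int(row.id)
        if sid in segments:
            raise NetworkError(f"duplicate segment id {sid}")
        segments[sid] = VesselSegment(
            id=sid, name=str(row.name),
            length=float(row.length_cm) * 1e-2,
            A0_prox=area_from_diameter(float(row.D0_prox_cm) * 1e-2),
            A0_dist=area_from_diameter(float(row.D0_dist_cm) * 1e-2),
            c0_prox=float(row.c0_prox_m_s), c0_dist=float(row.c0_dist_m_s),
            b=float(row.b), gamma=float(row.gamma), Gamma=float(row.Gamma_visc),
            P0=P0, Pext=Pext, n_elements=int(row.n_elements),
        )
        pid = int(row.parent_id)
        if pid >= 0:
            parent_map[sid] = pid

    junctions: dict[int, list[int]] = {}
    for sid, pid in parent_map.items():
        junctions.setdefault(pid, []).append(sid)
    junction_list = [(pid, sorted(kids)) for pid, kids in sorted(junctions.items())]

    roots = [sid for sid in segments if sid not in parent_map]
    if len(roots) != 1:
        raise NetworkError(f"network must have exactly one root, found {roots}")

    outlets: dict[int, WindkesselOutlet] = {}
    name_to_id = {seg.name: sid for sid, seg in segments.items()}
    for key, o in (meta.get("outlets") or {}).items():
        sid = name_to_id.get(key, None)
        if sid is None:
            try:
                sid = int(key)
            except (TypeError, ValueError):
                raise NetworkError(f"outlet key {key!r} matches no segment")
        outlets[sid] = WindkesselOutlet(
            segment_id=sid,
            Zc=float(o["Zc_mmHg_s_per_mL"]) * R_UNIT,
            R=float(o["R_mmHg_s_per_mL"]) * R_UNIT,
            C=float(o["C_mL_per_mmHg"]) * C_UNIT,
            Pout=float(o.get("Pout_mmHg", 10.0)) * MMHG,
        )

    heart = _heart_from_dict(meta["heart"]) if "heart" in meta else HeartModel()
    net = NetworkTopology(segments=segments, junctions=junction_list,
                          inlet_segment_id=roots[0], outlets=outlets,
                          fluid=fluid, heart=heart)
    violations = validate_network(net)
    if violations:
        raise NetworkError("invalid network: " + "; ".join(violations))
    return net


def save_network(net: NetworkTopology, path: str | Path) -> None:
    """Write the CSV + YAML pair; inverse of :func:`load_network`."""
    path = Path(path)
    rows = []
    parent = {k: pid for pid, kids in net.junctions for k in kids}
    for sid in sorted(net.segments):
        seg = net.segments[sid]
        rows.append({
            "id": sid, "name": seg.name,
            "length_cm": seg.length * 1e2,
            "D0_prox_cm": diameter_from_area(seg.A0_prox) * 1e2,
            "D0_dist_cm": diameter_from_area(seg.A0_dist) * 1e2,
            "c0_prox_m_s": seg.c0_prox, "c0_dist_m_s": seg.c0_dist,
            "b": seg.b, "gamma": seg.gamma, "Gamma_visc": seg.Gamma,
            "parent_id": parent.get(sid, -1), "n_elements": seg.n_elements,
        })
    pd.DataFrame(rows, columns=CSV_COLUMNS).to_csv(path, index=False)

    any_seg = next(iter(net.segments.values()))
    meta = {
        "fluid": {
            "density_kg_m3": net.fluid.density,
            "kinematic_viscosity_m2_s": net.fluid.kinematic_viscosity,
        },
        "reference_pressure_mmHg": any_seg.P0 / MMHG,
        "external_pressure_mmHg": any_seg.Pext / MMHG,
        "heart": _heart_to_dict(net.heart),
        "outlets": {
            net.segments[sid].name: {
                "Zc_mmHg_s_per_mL": float(out.Zc / R_UNIT),
                "R_mmHg_s_per_mL": float(out.R / R_UNIT),
                "C_mL_per_mmHg": float(out.C / C_UNIT),
                "Pout_mmHg": float(out.Pout / MMHG),
            } for sid, out in sorted(net.outlets.items())
        },
    }
    sidecar_path(path).write_text(yaml.safe_dump(meta, sort_keys=False))


def single_vessel_network(length=0.4, diameter=0.02, c0=6.0, b=2.0,
                          gamma=9.0, Gamma=0.0, n_elements=40,
                          Zc=None, R=1.2e8, C=1.2e-8,
                          Pout=10.0 * MMHG, P0=80.0 * MMHG,
                          heart: HeartModel | None = None) -> NetworkTopology:
    """A uniform single vessel with one Windkessel outlet — the minimal
    configuration for analytic solver checks."""
    fluid = FluidProperties()
    A0 = area_from_diameter(diameter)
    seg = VesselSegment(id=1, name="vessel", length=length,
                        A0_prox=A0, A0_dist=A0, c0_prox=c0, c0_dist=c0,
                        b=b, gamma=gamma, Gamma=Gamma, P0=P0,
                        n_elements=n_elements)
    if Zc is None:
        Zc = fluid.density * c0 / A0
    outlet = WindkesselOutlet(segment_id=1, Zc=Zc, R=R, C=C, Pout=Pout)
    return NetworkTopology(segments={1: seg}, junctions=[],
                           inlet_segment_id=1, outlets={1: outlet},
                           fluid=fluid, heart=heart or HeartModel())


def default_network_path() -> Path:
    """Path of the systemic tree shipped with the package."""
    return Path(__file__).parent / "data" / "systemic_tree.csv"


def load_default_network() -> NetworkTopology:
    return load_network(default_network_path())
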