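"""Virtual-patient generation.

A patient profile (age, weight, height, gender, pressures, cardiac
parameters) is drawn uniformly within cohort bounds; the base arterial
tree is then scaled to the profile through empirical anthropometric
relations, vessel stiffness is adjusted for age, Windkessel outlets are
distributed to meet the target mean arterial pressure at the target
cardiac output, and the heart model is calibrated so the converged
simulation reproduces the sampled ejection fraction and cardiac output
within 5 %.  Patients whose converged haemodynamics fall outside
physiological screening bounds are rejected and redrawn, preserving the
uniform marginals of the retained cohort within bounds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .aneurysm import AneurysmSpec, SeverityClass, insert_aneurysm
from .network import NetworkTopology, WindkesselOutlet
from .solver import (SolverConfig, SolverResult, run_to_periodic)
from .units import MMHG, L_MIN, ML, area_from_diameter, diameter_from_area
from .waveforms import (DEFAULT_SAMPLES_PER_CYCLE, ResampledCycle,
                        heart_femoral_pwv, resample_cycle)

#: reference anatomy of the shipped tree
H_REF_CM = 175.0
W_REF_KG = 75.0
AGE_ANCHOR = 50.0
#: fractional wave-speed increase per year of age away from the anchor
AGE_STIFFNESS_SLOPE = 0.0105

#: heart-model calibration contract (fraction of target)
CARDIAC_TOLERANCE = 0.05

#: physiological screening bounds for retained patients (mmHg)
MAP_BOUNDS_MMHG = (50.0, 150.0)


def compute_bsa(weight_kg: float, height_cm: float) -> float:
    """Du Bois body surface area (m^2)."""
    if weight_kg < 0 or height_cm < 0:
        raise ValueError("weight and height must be non-negative")
    return 0.007184 * weight_kg ** 0.425 * height_cm ** 0.725


@dataclass
class SamplerRanges:
    """Uniform sampling bounds for each profile field."""

    age_years: tuple[float, float] = (30.0, 89.0)
    weight_kg: tuple[float, float] = (40.0, 120.0)
    height_cm: tuple[float, float] = (150.0, 200.0)
    ejection_fraction: tuple[float, float] = (0.57, 0.6699)
    cardiac_output_l_min: tuple[float, float] = (4.5, 7.0)
    heart_rate_bpm: tuple[float, float] = (55.0, 90.0)
    map_mmhg: tuple[float, float] = (75.0, 105.0)

    def __post_init__(self):
        for name, (lo, hi) in asdict(self).items():
            if not lo < hi:
                raise ValueError(f"{name}: lower bound must be below upper")


@dataclass
class PatientProfile:
    age_years: float
    weight_kg: float
    height_cm: float
    gender: int                    # 1 male, 0 female
    bsa_m2: float
    map_mmhg: float
    ejection_fraction: float
    cardiac_output_l_min: float
    heart_rate_bpm: float
    pulse_pressure_mmhg: float | None = None   # recorded after simulation
    condition: str = "healthy"

    def to_dict(self) -> dict:
        return asdict(self)


def sample_profile(rng: np.random.Generator,
                   ranges: SamplerRanges | None = None) -> PatientProfile:
    """Draw each field independently and uniformly; BSA is computed,
    never sampled."""
    r = ranges or SamplerRanges()
    age = float(rng.uniform(*r.age_years))
    weight = float(rng.uniform(*r.weight_kg))
    height = float(rng.uniform(*r.height_cm))
    gender = int(rng.integers(0, 2))
    return PatientProfile(
        age_years=age, weight_kg=weight, height_cm=height, gender=gender,
        bsa_m2=compute_bsa(weight, height),
        map_mmhg=float(rng.uniform(*r.map_mmhg)),
        ejection_fraction=float(rng.uniform(*r.ejection_fraction)),
        cardiac_output_l_min=float(rng.uniform(*r.cardiac_output_l_min)),
        heart_rate_bpm=float(rng.uniform(*r.heart_rate_bpm)),
    )


def femoral_length_cm(height_cm: float) -> float:
    return 0.245 * height_cm


def descending_aorta_length_cm(height_cm: float) -> float:
    return -2.6235 + 0.1507 * height_cm


def abdominal_aorta_diameter_mm(age_years: float, gender: int,
                                bsa_m2: float) -> float:
    """Proximal abdominal-aorta diameter (mm) from age, gender and BSA."""
    return (14.10 + 0.13 * age_years
            + (-1.09 + 0.04 * age_years) * gender + 5.8 * bsa_m2)


class GenerationError(RuntimeError):
    """A profile produced an unusable scaled network."""


def scale_geometry(profile: PatientProfile,
                   base_net: NetworkTopology) -> NetworkTopology:
    """Scale the base anatomy to the profile.

    Named relations set both femoral lengths, the descending
    (thoracic) aorta length and the proximal abdominal-aorta diameter;
    every other segment scales isometrically: lengths with the height
    ratio, diameters with the square root of the BSA ratio.
    """
    net = base_net.copy()
    h_ratio = profile.height_cm / H_REF_CM
    d_ratio = math.sqrt(profile.bsa_m2 / compute_bsa(W_REF_KG, H_REF_CM))
    for seg in net.segments.values():
        seg.length *= h_ratio
        seg.A0_prox *= d_ratio ** 2
        seg.A0_dist *= d_ratio ** 2

    for name in ("left_femoral", "right_femoral"):
        net.by_name(name).length = femoral_length_cm(profile.height_cm) / 100.0
    net.by_name("thoracic_aorta").length = \
        descending_aorta_length_cm(profile.height_cm) / 100.0

    abd = net.by_name("abdominal_aorta")
    d_prox_cm = abdominal_aorta_diameter_mm(
        profile.age_years, profile.gender, profile.bsa_m2) / 10.0
    taper = math.sqrt(abd.A0_dist / abd.A0_prox)
    abd.A0_prox = area_from_diameter(d_prox_cm / 100.0)
    abd.A0_dist = area_from_diameter(d_prox_cm * taper / 100.0)

    for seg in net.segments.values():
        if seg.length <= 0 or seg.A0_prox <= 0 or seg.A0_dist <= 0:
            raise GenerationError(f"non-positive scaled value in {seg.name}")
    return net


def age_stiffness_multiplier(age_years: float) -> float:
    """Monotone wave-speed multiplier; 1 at the anchor age."""
    return 1.0 + AGE_STIFFNESS_SLOPE * (age_years - AGE_ANCHOR)


def adjust_stiffness_for_age(profile: PatientProfile,
                             net: NetworkTopology) -> NetworkTopology:
    """Rescale intrinsic wave speeds for ageing-related stiffening,
    calibrated so the cohort heart-femoral pulse wave velocity spans the
    target range (roughly 6.8-12 m/s)."""
    m = age_stiffness_multiplier(profile.age_years)
    for seg in net.segments.values():
        seg.c0_prox *= m
        seg.c0_dist *= m
        if seg.c0_nodes is not None:
            seg.c0_nodes = np.asarray(seg.c0_nodes) * m
    return net


def assign_windkessel(net: NetworkTopology, map_mmhg: float,
                      cardiac_output_l_min: float,
                      pout_mmhg: float = 10.0,
                      time_constant_s: float = 1.8) -> NetworkTopology:
    """Distribute outlet Windkessel elements.

    Total effective resistance meets the target mean arterial pressure
    at the target cardiac output; conductances and compliances are
    apportioned in proportion to outlet area; each characteristic
    impedance follows Z = rho*c0/A0 at the terminal cross-section.
    """
    co = cardiac_output_l_min * L_MIN
    r_eff = (map_mmhg - pout_mmhg) * MMHG / co
    c_tot = time_constant_s / r_eff
    rho = net.fluid.density
    terms = net.terminal_ids()
    areas = {tid: net.segments[tid].node_A0()[-1] for tid in terms}
    a_sum = sum(areas.values())
    outlets = {}
    for tid in terms:
        seg = net.segments[tid]
        frac = areas[tid] / a_sum
        zc = rho * seg.node_c0()[-1] / areas[tid]
        r_total_branch = r_eff / frac
        r_distal = max(r_total_branch - zc, 0.1 * r_total_branch)
        outlets[tid] = WindkesselOutlet(
            segment_id=tid, Zc=zc, R=r_distal, C=c_tot * frac,
            Pout=pout_mmhg * MMHG)
    net.outlets = outlets
    return net


class CalibrationError(RuntimeError):
    """Heart tuning failed to reach the EF/CO contract."""


def sample_cardiac_parameters(profile: PatientProfile, net: NetworkTopology,
                              solver_config: SolverConfig | None = None,
                              max_iter: int = 8) -> SolverResult:
    """Tune heart elastance and preload so the converged simulation
    reproduces the profile's EF and CO within 5 %.

    Mutates ``net.heart`` in place and returns the final converged run.
    Raises :class:`CalibrationError` when the bounded iteration fails.
    """
    cfg = solver_config or SolverConfig()
    coarse = SolverConfig(cfl=cfg.cfl, max_cycles=5,
                          periodicity_tol_mmhg=max(
                              1.0, cfg.periodicity_tol_mmhg))
    h = net.heart
    h.heart_rate = profile.heart_rate_bpm
    co_t = profile.cardiac_output_l_min * L_MIN
    sv_t = co_t / (h.heart_rate / 60.0)
    edv_t = sv_t / profile.ejection_fraction
    esv_t = edv_t - sv_t

    # analytic first guess: diastolic filling against E_min, systolic
    # emptying against E_max at roughly the target MAP
    h.P_venous = max(0.3 * MMHG, (edv_t - h.ventricle.V0) * h.ventricle.E_min)
    h.ventricle.E_max = (profile.map_mmhg + 25.0) * MMHG \
        / max(esv_t - h.ventricle.V0, 5e-6)

    result = None
    for it in range(max_iter):
        result = run_to_periodic(net, coarse,
                                 init_compartment_mmhg=profile.map_mmhg)
        sv = result.stroke_volume
        edv = result.end_diastolic_volume
        esv = result.end_systolic_volume
        ef = result.ejection_fraction
        co = result.cardiac_output
        if (abs(ef - profile.ejection_fraction) / profile.ejection_fraction
                < 0.6 * CARDIAC_TOLERANCE
                and abs(co - co_t) / co_t < 0.6 * CARDIAC_TOLERANCE):
            break
        fill = (edv_t - h.ventricle.V0) / max(edv - h.ventricle.V0, 1e-6)
        h.P_venous = float(np.clip(h.P_venous * fill, 0.2 * MMHG, 40 * MMHG))
        empty = (esv - h.ventricle.V0) / max(esv_t - h.ventricle.V0, 1e-6)
        h.ventricle.E_max = float(np.clip(
            h.ventricle.E_max * np.clip(empty, 0.4, 2.5),
            0.3 * MMHG / ML, 12.0 * MMHG / ML))
    final = run_to_periodic(net, cfg, init_compartment_mmhg=profile.map_mmhg)
    ef_err = abs(final.ejection_fraction - profile.ejection_fraction) \
        / profile.ejection_fraction
    co_err = abs(final.cardiac_output - co_t) / co_t
    if ef_err > CARDIAC_TOLERANCE or co_err > CARDIAC_TOLERANCE:
        raise CalibrationError(
            f"EF error {ef_err:.1%}, CO error {co_err:.1%} after "
            f"{max_iter} iterations")
    return final


@dataclass
class VirtualPatient:
    """One simulated subject: profile, anatomy summary and waveforms."""

    patient_id: str
    profile: PatientProfile
    label: SeverityClass
    aneurysm: AneurysmSpec | None
    cycles: dict[str, ResampledCycle]
    abdominal_diameter_cm: float
    pwv_m_s: float
    converged: bool
    ef_simulated: float = float("nan")
    co_simulated_l_min: float = float("nan")
    rejected_reason: str | None = None


def heart_femoral_path_length(net: NetworkTopology) -> float:
    """Aortic root to mid-femoral distance along the tree (m)."""
    femoral = net.by_name("left_femoral")
    path = net.path_to(femoral.id)
    length = sum(net.segments[sid].length for sid in path[:-1])
    return length + 0.5 * femoral.length


def build_patient(profile: PatientProfile, base_net: NetworkTopology,
                  severity: SeverityClass, rng: np.random.Generator,
                  solver_config: SolverConfig | None = None,
                  n_samples: int = DEFAULT_SAMPLES_PER_CYCLE,
                  patient_id: str = "",
                  critical_fraction: float = 0.25) -> VirtualPatient:
    """Scale, (optionally) insert an aneurysm, calibrate and simulate
    one subject.  Raises GenerationError/CalibrationError/
    SolverDivergenceError on rejection paths."""
    from .aneurysm import sample_aneurysm_spec

    profile.condition = severity.value
    net = scale_geometry(profile, base_net)
    net = adjust_stiffness_for_age(profile, net)

    spec = None
    if severity != SeverityClass.healthy:
        spec = sample_aneurysm_spec(severity, rng,
                                    critical_fraction=critical_fraction)
        try:
            net = insert_aneurysm(net, spec, rng)
        except ValueError as exc:
            raise GenerationError(str(exc)) from exc
        if spec.critical:
            # locally floppy wall segments need a shorter stable step
            base = solver_config or SolverConfig()
            solver_config = SolverConfig(
                cfl=min(base.cfl, 0.45), max_cycles=base.max_cycles,
                periodicity_tol_mmhg=base.periodicity_tol_mmhg)
    assign_windkessel(net, profile.map_mmhg, profile.cardiac_output_l_min)
    result = sample_cardiac_parameters(profile, net,
                                       solver_config=solver_config)

    root = result.records["aortic_root"]
    map_sim = float(np.mean(root.pressure_mmhg))
    if not MAP_BOUNDS_MMHG[0] < map_sim < MAP_BOUNDS_MMHG[1]:
        raise GenerationError(f"simulated MAP {map_sim:.0f} mmHg out of bounds")
    profile.pulse_pressure_mmhg = float(
        np.max(root.pressure_mmhg) - np.min(root.pressure_mmhg))

    cycles = {name: resample_cycle(rec, n_samples)
              for name, rec in result.records.items()}
    try:
        pwv = heart_femoral_pwv(result.records["aortic_root"],
                                result.records["femoral"],
                                heart_femoral_path_length(net))
    except ValueError:
        # foot detection can fail on strongly distorted aneurysmal beats
        pwv = float("nan")
    if spec is not None:
        diameter = spec.max_diameter_cm
    else:
        abd = net.by_name("abdominal_aorta")
        diameter = diameter_from_area(abd.A0_prox) * 100.0
    return VirtualPatient(
        patient_id=patient_id, profile=profile, label=severity,
        aneurysm=spec, cycles=cycles, abdominal_diameter_cm=diameter,
        pwv_m_s=float(pwv), converged=result.converged,
        ef_simulated=result.ejection_fraction,
        co_simulated_l_min=result.cardiac_output / L_MIN)
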