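"""Fusiform abdominal aortic aneurysms and severity grading.

An aneurysm dilates the abdominal aorta with a sinusoidal axial
diameter profile, widest at mid-length.  Severity is graded from the
maximum diameter: healthy < 3 cm, small 3-4.4 cm, medium 4.5-5.4 cm,
large >= 5.5 cm.  "Critical" large aneurysms additionally lose wall
stiffness over 5 contiguous grid elements (local pulse wave velocity
reduced to 14-30 % of its original value), mimicking imminent rupture;
small and medium aneurysms keep their original stiffness.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np

from .network import NetworkTopology
from .units import area_from_diameter, diameter_from_area

ABDOMINAL_SEGMENT = "abdominal_aorta"

#: class edges in cm; half-open decimal-aligned bins
SMALL_MIN, MEDIUM_MIN, LARGE_MIN = 3.0, 4.5, 5.5
#: largest diameter generated (every one-decimal diameter in [3.0, 6.9]
#: is attainable)
D_MAX_CM = 6.9

#: critical stiffness degradation: fraction of original wave speed
CRITICAL_PWV_FACTOR_RANGE = (0.14, 0.30)
N_DEGRADED_ELEMENTS = 5

#: aneurysm length ranges per class (cm); weakly increasing with class
LENGTH_RANGES_CM = {
    "small": (4.0, 6.6),
    "medium": (4.5, 7.1),
    "large": (5.5, 10.0),
}


class SeverityClass(str, enum.Enum):
    healthy = "healthy"
    small = "small"
    medium = "medium"
    large = "large"

    @property
    def index(self) -> int:
        return list(SeverityClass).index(self)


def classify_severity(d_max_cm: float) -> SeverityClass:
    """Grade an abdominal aortic diameter (cm)."""
    if d_max_cm <= 0:
        raise ValueError("diameter must be positive")
    if d_max_cm < SMALL_MIN:
        return SeverityClass.healthy
    if d_max_cm < MEDIUM_MIN:
        return SeverityClass.small
    if d_max_cm < LARGE_MIN:
        return SeverityClass.medium
    return SeverityClass.large


@dataclass
class AneurysmSpec:
    """Geometry and wall state of one fusiform AAA."""

    max_diameter_cm: float
    length_cm: float
    proximal_offset_cm: float
    severity: SeverityClass
    critical: bool = False
    degraded_elements: list[int] = field(default_factory=list)
    pwv_reduction_factors: list[float] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "max_diameter_cm": self.max_diameter_cm,
            "length_cm": self.length_cm,
            "proximal_offset_cm": self.proximal_offset_cm,
            "severity": self.severity.value,
            "critical": self.critical,
            "degraded_elements": list(self.degraded_elements),
            "pwv_reduction_factors": list(self.pwv_reduction_factors),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AneurysmSpec":
        return cls(max_diameter_cm=d["max_diameter_cm"],
                   length_cm=d["length_cm"],
                   proximal_offset_cm=d["proximal_offset_cm"],
                   severity=SeverityClass(d["severity"]),
                   critical=d.get("critical", False),
                   degraded_elements=list(d.get("degraded_elements", [])),
                   pwv_reduction_factors=list(d.get("pwv_reduction_factors", [])))


def aneurysm_diameter_profile(xi_cm: float, baseline_d_cm: float,
                              spec: AneurysmSpec) -> float:
    """Local diameter (cm) at axial position ``xi_cm`` in [0, L].

    ``D(xi) = D_base + (D_max - D_base) * sin(pi*xi/L)``: continuous
    with the baseline at both ends, maximal at mid-length.
    """
    if not 0.0 <= xi_cm <= spec.length_cm:
        raise ValueError("axial coordinate outside the aneurysm extent")
    bulge = spec.max_diameter_cm - baseline_d_cm
    return baseline_d_cm + bulge * math.sin(math.pi * xi_cm / spec.length_cm)


def sample_aneurysm_spec(severity: SeverityClass, rng: np.random.Generator,
                         critical_fraction: float = 0.25) -> AneurysmSpec:
    """Draw a random aneurysm of the given class.

    Diameter is uniform within the class interval (large capped at
    6.9 cm); length uniform within the class length range; only large
    aneurysms may be critical.  The axial placement and any stiffness
    degradation are resolved at insertion time.
    """
    if severity == SeverityClass.healthy:
        raise ValueError("healthy patients carry no aneurysm")
    bounds = {
        SeverityClass.small: (SMALL_MIN, MEDIUM_MIN),
        SeverityClass.medium: (MEDIUM_MIN, LARGE_MIN),
        SeverityClass.large: (LARGE_MIN, D_MAX_CM),
    }[severity]
    d = float(rng.uniform(*bounds))
    length = float(rng.uniform(*LENGTH_RANGES_CM[severity.value]))
    critical = bool(severity == SeverityClass.large
                    and rng.random() < critical_fraction)
    return AneurysmSpec(max_diameter_cm=d, length_cm=length,
                        proximal_offset_cm=-1.0,  # placed at insertion
                        severity=severity, critical=critical)


def insert_aneurysm(net: NetworkTopology, spec: AneurysmSpec,
                    rng: np.random.Generator) -> NetworkTopology:
    """Return a copy of ``net`` with the aneurysm written into the
    abdominal aorta's nodewise reference area (and, for critical cases,
    its nodewise wave speed).

    The proximal offset is drawn uniformly over feasible placements
    when the spec does not fix one.  Raises when the aneurysm does not
    fit within the vessel.
    """
    net = net.copy()
    seg = net.by_name(ABDOMINAL_SEGMENT)
    L_cm = seg.length * 100.0
    if spec.length_cm > L_cm:
        raise ValueError(
            f"aneurysm ({spec.length_cm:.1f} cm) longer than the abdominal "
            f"aorta ({L_cm:.1f} cm)")
    if spec.proximal_offset_cm < 0:
        spec.proximal_offset_cm = float(rng.uniform(0.0, L_cm - spec.length_cm))
    elif spec.proximal_offset_cm + spec.length_cm > L_cm + 1e-9:
        raise ValueError("aneurysm extends past the distal end")

    x_cm = seg.node_positions() * 100.0
    A0 = seg.node_A0().copy()
    c0 = seg.node_c0().copy()
    x0 = spec.proximal_offset_cm
    in_an = (x_cm >= x0) & (x_cm <= x0 + spec.length_cm)
    d_base_max = diameter_from_area(np.max(A0[in_an])) * 100.0
    if spec.max_diameter_cm < d_base_max - 1e-9:
        raise ValueError(
            f"aneurysm D_max {spec.max_diameter_cm:.2f} cm does not exceed "
            f"the local baseline diameter {d_base_max:.2f} cm")
    for i in np.flatnonzero(in_an):
        d_base = diameter_from_area(A0[i]) * 100.0
        d_local = aneurysm_diameter_profile(x_cm[i] - x0, d_base, spec)
        A0[i] = area_from_diameter(d_local / 100.0)
    seg.A0_nodes = A0

    if spec.critical:
        idx = np.flatnonzero(in_an)
        if idx.size < N_DEGRADED_ELEMENTS:
            raise ValueError("aneurysm too short for critical degradation")
        start = int(rng.integers(0, idx.size - N_DEGRADED_ELEMENTS + 1))
        chosen = idx[start:start + N_DEGRADED_ELEMENTS]
        factors = rng.uniform(*CRITICAL_PWV_FACTOR_RANGE,
                              size=N_DEGRADED_ELEMENTS)
        c0[chosen] *= factors
        seg.c0_nodes = c0
        spec.degraded_elements = [int(i) for i in chosen]
        spec.pwv_reduction_factors = [float(f) for f in factors]
    return net
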