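import numpy as np
import pytest

from pulsetwin.aneurysm import (AneurysmSpec, SeverityClass,
                                aneurysm_diameter_profile, classify_severity,
                                insert_aneurysm, sample_aneurysm_spec)
from pulsetwin.patients import (build_patient, compute_bsa, PatientProfile)
from pulsetwin.units import diameter_from_area


class TestSeverity:
    @pytest.mark.parametrize("d,expected", [
        (2.5, SeverityClass.healthy),
        (2.99, SeverityClass.healthy),
        (3.0, SeverityClass.small),
        (4.4, SeverityClass.small),
        (4.5, SeverityClass.medium),
        (5.4, SeverityClass.medium),
        (5.0, SeverityClass.medium),
        (5.5, SeverityClass.large),
        (6.2, SeverityClass.large),
    ])
    def test_diameter_bins(self, d, expected):
        assert classify_severity(d) is expected

    def test_nonpositive_diameter_rejected(self):
        with pytest.raises(ValueError):
            classify_severity(0.0)


class TestDiameterProfile:
    SPEC = AneurysmSpec(max_diameter_cm=5.0, length_cm=8.0,
                        proximal_offset_cm=0.0,
                        severity=SeverityClass.medium)

    def test_endpoints_continuous_with_baseline(self):
        assert aneurysm_diameter_profile(0.0, 2.0, self.SPEC) == 2.0
        assert aneurysm_diameter_profile(8.0, 2.0, self.SPEC) \
            == pytest.approx(2.0, abs=1e-12)

    def test_maximum_at_mid_length(self):
        assert aneurysm_diameter_profile(4.0, 2.0, self.SPEC) \
            == pytest.approx(5.0)

    def test_quarter_length_hand_value(self):
        # 2 + 3*sin(pi/4) = 4.1213...
        spec = AneurysmSpec(max_diameter_cm=5.0, length_cm=4.0,
                            proximal_offset_cm=0.0,
                            severity=SeverityClass.medium)
        assert aneurysm_diameter_profile(1.0, 2.0, spec) \
            == pytest.approx(2.0 + 3.0 * np.sin(np.pi / 4), rel=1e-12)

    def test_outside_extent_rejected(self):
        with pytest.raises(ValueError, match="extent"):
            aneurysm_diameter_profile(9.0, 2.0, self.SPEC)


class TestSampleSpec:
    @pytest.mark.parametrize("severity,lo,hi", [
        (SeverityClass.small, 3.0, 4.5),
        (SeverityClass.medium, 4.5, 5.5),
        (SeverityClass.large, 5.5, 6.9),
    ])
    def test_diameters_within_class_interval(self, severity, lo, hi):
        rng = np.random.default_rng(11)
        draws = [sample_aneurysm_spec(severity, rng).max_diameter_cm
                 for _ in range(1000)]
        assert min(draws) >= lo
        assert max(draws) <= hi

    def test_only_large_can_be_critical(self):
        rng = np.random.default_rng(3)
        for severity in (SeverityClass.small, SeverityClass.medium):
            for _ in range(50):
                assert not sample_aneurysm_spec(severity, rng,
                                                critical_fraction=1.0).critical
        crit = [sample_aneurysm_spec(SeverityClass.large, rng,
                                     critical_fraction=1.0).critical
                for _ in range(10)]
        assert all(crit)

    def test_healthy_has_no_aneurysm(self):
        with pytest.raises(ValueError):
            sample_aneurysm_spec(SeverityClass.healthy,
                                 np.random.default_rng(0))

    def test_fixed_seed_reproducibility(self):
        a = sample_aneurysm_spec(SeverityClass.large, np.random.default_rng(5))
        b = sample_aneurysm_spec(SeverityClass.large, np.random.default_rng(5))
        assert a.max_diameter_cm == b.max_diameter_cm
        assert a.length_cm == b.length_cm


class TestInsertion:
    def _spec(self, d_max, critical=False, length=8.0, offset=2.0):
        return AneurysmSpec(max_diameter_cm=d_max, length_cm=length,
                            proximal_offset_cm=offset,
                            severity=classify_severity(max(d_max, 3.0)),
                            critical=critical)

    def test_null_aneurysm_leaves_network_unchanged(self, default_net):
        abd = default_net.by_name("abdominal_aorta")
        d_base = diameter_from_area(abd.A0_prox) * 100
        spec = self._spec(d_base, offset=0.0, length=abd.length * 100)
        net = insert_aneurysm(default_net, spec, np.random.default_rng(0))
        abd2 = net.by_name("abdominal_aorta")
        # prox node diameter equals the untouched baseline
        assert abd2.node_A0()[0] == pytest.approx(abd.A0_prox, rel=1e-12)

    def test_critical_degrades_exactly_five_elements(self, default_net):
        spec = self._spec(6.5, critical=True)
        net = insert_aneurysm(default_net, spec, np.random.default_rng(1))
        abd = net.by_name("abdominal_aorta")
        base_c0 = default_net.by_name("abdominal_aorta").node_c0()
        changed = np.flatnonzero(~np.isclose(abd.node_c0(), base_c0))
        assert changed.size == 5
        factors = abd.node_c0()[changed] / base_c0[changed]
        assert np.all((factors >= 0.14) & (factors <= 0.30))
        assert spec.degraded_elements == list(changed)

    def test_medium_keeps_original_stiffness(self, default_net):
        spec = self._spec(5.0)
        net = insert_aneurysm(default_net, spec, np.random.default_rng(2))
        abd = net.by_name("abdominal_aorta")
        assert np.allclose(abd.node_c0(),
                           default_net.by_name("abdominal_aorta").node_c0())

    def test_sinusoidal_area_profile_written(self, default_net):
        spec = self._spec(6.0, offset=3.0, length=6.0)
        net = insert_aneurysm(default_net, spec, np.random.default_rng(3))
        abd = net.by_name("abdominal_aorta")
        x_cm = abd.node_positions() * 100
        d = diameter_from_area(abd.node_A0()) * 100
        mid = np.argmin(np.abs(x_cm - 6.0))   # offset + L/2
        assert d[mid] == pytest.approx(6.0, abs=0.25)

    def test_impedance_drops_in_every_aneurysm_element(self, default_net):
        """Enlarged diameter at fixed wall stiffness lowers Z=rho*c0/A0."""
        spec = self._spec(6.5, offset=3.0, length=6.0)
        net = insert_aneurysm(default_net, spec, np.random.default_rng(4))
        abd = net.by_name("abdominal_aorta")
        base = default_net.by_name("abdominal_aorta")
        z_new = abd.node_c0() / abd.node_A0()
        z_old = base.node_c0() / base.node_A0()
        inside = abd.node_A0() > base.node_A0() * (1 + 1e-9)
        assert inside.any()
        assert np.all(z_new[inside] < z_old[inside])

    def test_too_long_aneurysm_rejected(self, default_net):
        spec = self._spec(6.0, length=40.0, offset=0.0)
        with pytest.raises(ValueError, match="longer"):
            insert_aneurysm(default_net, spec, np.random.default_rng(0))

    def test_dmax_below_baseline_rejected(self, default_net):
        spec = self._spec(1.0, offset=2.0)
        with pytest.raises(ValueError, match="baseline"):
            insert_aneurysm(default_net, spec, np.random.default_rng(0))


class TestHaemodynamicEffect:
    def test_large_critical_aaa_changes_distal_waveform(self, default_net):
        """A large critical AAA leaves a >1% relative L2 signature on
        the distal abdominal pressure cycle of a matched patient."""
        def profile():
            return PatientProfile(
                age_years=70.0, weight_kg=80.0, height_cm=175.0, gender=1,
                bsa_m2=compute_bsa(80, 175), map_mmhg=95.0,
                ejection_fraction=0.60, cardiac_output_l_min=5.5,
                heart_rate_bpm=65.0)

        healthy = build_patient(profile(), default_net,
                                SeverityClass.healthy,
                                np.random.default_rng(10), patient_id="h")
        aaa = build_patient(profile(), default_net, SeverityClass.large,
                            np.random.default_rng(10), patient_id="a",
                            critical_fraction=1.0)
        p_h = healthy.cycles["abdominal_aorta"].pressure_mmhg
        p_a = aaa.cycles["abdominal_aorta"].pressure_mmhg
        rel = np.linalg.norm(p_a - p_h) / np.linalg.norm(p_h)
        assert rel > 0.01
        assert aaa.aneurysm.critical
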