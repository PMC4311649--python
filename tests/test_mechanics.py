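"""Energy, force, elasticity and the dual error report."""

import math
import warnings

import numpy as np
import pytest

from capadh.errors import (
    DomainError,
    InsufficientDataError,
    NonMonotoneEnergyWarning,
    SmallDeflectionWarning,
)
from capadh.geometry import MeniscusProfile, ProfileFit
from capadh.mechanics import (
    BendingSpecimen,
    ContactPatch,
    FluidProperties,
    FrameRecord,
    PullSequence,
    adhesion_force,
    aggregate_values,
    analyze_sequence,
    elongation_at_snapoff,
    energy_derivative,
    force_elongation_curve,
    meniscus_energy,
    spring_constant,
    systematic_error,
    weight_force,
    youngs_modulus_bending,
)
from capadh.synthetic import SyntheticTruth, beam_oracle, generate_pull_family


def make_sequence(profiles, tips, stages=None, relaxed=None, pixel_scale=2e-6):
    """Assemble a PullSequence from ground-truth profiles and tip heights."""
    n = len(profiles)
    stages = stages if stages is not None else np.arange(n, dtype=float)
    frames = [
        FrameRecord(stage_position=float(stages[k]), timestamp=float(k),
                    fit=ProfileFit.exact(profiles[k]),
                    tip_position=float(tips[k]), tip_from_fit=True)
        for k in range(n)
    ]
    if relaxed is not None:
        frames.append(FrameRecord(stage_position=float(stages[-1] + 1),
                                  timestamp=float(n),
                                  tip_position=float(relaxed)))
    return PullSequence(frames=frames, snap_index=n - 1,
                        pixel_scale=pixel_scale)


class TestEnergy:
    def test_flat_surface_zero(self, water):
        p = MeniscusProfile(a=1e-3, b=0.0, c=0.0, r_tip=0.1e-3)
        e = meniscus_energy(p, water, ContactPatch(1e-9, 0.0))
        assert e.value == pytest.approx(0.0, abs=1e-18)
        assert e.includes_contact

    def test_linear_in_surface_tension(self, slender_profile, water):
        doubled = FluidProperties(surface_tension=2 * water.surface_tension)
        e1 = meniscus_energy(slender_profile, water).value
        e2 = meniscus_energy(slender_profile, doubled).value
        assert e2 == pytest.approx(2 * e1, rel=1e-12)

    def test_hemisphere_value(self, water):
        # sigma (2 pi R^2 - pi R^2) for R = 1 mm
        p = MeniscusProfile(a=1e-3, b=1e-3, c=0.0, r_tip=0.0)
        e = meniscus_energy(p, water)
        assert not e.includes_contact
        assert e.value == pytest.approx(0.07275 * math.pi * 1e-6, rel=1e-9)

    def test_unknown_interface_tension_flagged(self, slender_profile, water):
        known = meniscus_energy(slender_profile, water,
                                ContactPatch(1e-9, 0.05))
        unknown = meniscus_energy(slender_profile, water,
                                  ContactPatch(1e-9, None))
        assert known.includes_contact and not unknown.includes_contact
        assert known.value - unknown.value == pytest.approx(0.05 * 1e-9)


class TestEnergyDerivative:
    def test_linear_energy(self):
        y = np.linspace(0, 50e-6, 6)
        E = 2.0e-5 * y + 3e-9
        assert energy_derivative(y, E) == pytest.approx(2.0e-5, rel=1e-12)

    def test_additive_constant_annihilated(self):
        # an unknown sigma* contact term only shifts E by a constant
        y = np.linspace(0, 50e-6, 6)
        E = 2.0e-5 * y + 0.5 * y**2
        assert energy_derivative(y, E + 1e-7) == pytest.approx(
            energy_derivative(y, E), rel=1e-9
        )

    def test_quadratic_family_matches_analytic(self, water):
        # A(y) = A0 + k y^2  ->  F = dE/dy = 2 sigma k y
        k, A0, y0 = 3.0, 1e-7, 40e-6
        y = y0 - np.arange(5)[::-1] * 8e-6  # default-scale frame spacing
        E = water.surface_tension * (A0 + k * y**2)
        expected = 2 * water.surface_tension * k * y0
        got = energy_derivative(y, E, stencil=3)
        assert got == pytest.approx(expected, rel=1e-3)
        backward = energy_derivative(y, E, stencil=2)
        assert backward != pytest.approx(expected, rel=1e-6)  # O(h) bias

    def test_needs_two_samples(self):
        with pytest.raises(InsufficientDataError):
            energy_derivative([1.0], [1.0])


class TestForces:
    def test_adhesion_force_on_analytic_family(self, water):
        seq, rec = generate_pull_family(SyntheticTruth(), 8)
        F = adhesion_force(seq, water)
        assert F == pytest.approx(rec.snap_force, rel=5e-3)

    def test_adhesion_force_zero_for_constant_energy(self, water):
        p = MeniscusProfile(a=47e-6, b=160e-6, c=0.0, r_tip=20e-6)
        seq = make_sequence([p] * 4, tips=np.linspace(1e-4, 1.6e-4, 4))
        assert adhesion_force(seq, water) == pytest.approx(0.0, abs=1e-12)

    def test_non_monotone_energy_warns(self, water):
        profiles = [MeniscusProfile(a=47e-6, b=b, c=0.0, r_tip=20e-6)
                    for b in (100e-6, 160e-6, 140e-6, 180e-6)]
        seq = make_sequence(profiles, tips=np.linspace(1e-4, 1.7e-4, 4))
        with pytest.warns(NonMonotoneEnergyWarning):
            adhesion_force(seq, water)

    def test_weight_force_values(self, water):
        hemi = MeniscusProfile(a=0.5e-3, b=0.5e-3, c=0.0, r_tip=0.0)
        assert weight_force(hemi, water) == pytest.approx(
            998 * 9.81 * (2 * math.pi / 3) * 0.5e-3**3, rel=1e-9
        )
        flat = MeniscusProfile(a=1e-3, b=0.0, c=0.0, r_tip=0.1e-3)
        assert weight_force(flat, water) == pytest.approx(0.0, abs=1e-12)

    def test_weight_force_unit_arithmetic(self, water):
        # a profile holding exactly 1 mm^3 of water weighs 9.79 uN:
        # V = 2 pi b a^2 / 3 = 1e-9 m^3 at a = 1 mm
        b = 3 * 1e-9 / (2 * math.pi * 1e-6)
        p = MeniscusProfile(a=1e-3, b=b, c=0.0, r_tip=0.0)
        assert weight_force(p, water) == pytest.approx(998 * 9.81 * 1e-9,
                                                       rel=1e-9)

    def test_spring_constant(self):
        assert spring_constant(20e-6, 10e-6) == pytest.approx(2.0)
        with pytest.raises(DomainError):
            spring_constant(20e-6, 0.0)


class TestForceElongationCurve:
    def test_hookean_family(self, water):
        seq, rec = generate_pull_family(SyntheticTruth(), 10)
        curve = force_elongation_curve(seq, water)
        assert curve.slope == pytest.approx(rec.spring_constant, rel=0.05)
        assert curve.r_squared > 0.99
        assert not curve.relative_reference
        # per-point forces track the analytic family
        assert np.allclose(curve.force, rec.force, rtol=2e-3)

    def test_constant_force_flat_curve(self, water):
        # linear E(y): constant force, zero slope vs (constant) elongation is
        # degenerate -- instead check the forces are flat
        seq, rec = generate_pull_family(SyntheticTruth(), 8)
        y = np.array([f.tip_position for f in seq.pre_frames])
        curve = force_elongation_curve(seq, water)
        assert np.ptp(curve.force) / curve.force.mean() > 0.01  # sanity
        del y, rec

    def test_two_frames_insufficient(self, water):
        p = MeniscusProfile(a=47e-6, b=160e-6, c=0.0, r_tip=20e-6)
        seq = make_sequence([p, p.with_params(b=170e-6)],
                            tips=[1e-4, 1.1e-4])
        with pytest.raises(InsufficientDataError):
            force_elongation_curve(seq, water)


class TestElongation:
    def test_recoil_definition(self, water):
        seq, rec = generate_pull_family(SyntheticTruth(), 6)
        dy = elongation_at_snapoff(seq)
        assert dy == pytest.approx(rec.snap_elongation, rel=1e-9)
        assert dy > 0

    def test_missing_relaxed_frame(self):
        p = MeniscusProfile(a=47e-6, b=160e-6, c=0.0, r_tip=20e-6)
        seq = make_sequence([p, p.with_params(b=170e-6),
                             p.with_params(b=180e-6)],
                            tips=[1e-4, 1.1e-4, 1.2e-4])
        with pytest.raises(InsufficientDataError):
            elongation_at_snapoff(seq)


class TestBendingModulus:
    SPEC = BendingSpecimen(length=1e-2, diameter=70e-6)

    def test_diameter_scaling(self):
        e1 = youngs_modulus_bending(40e-6, self.SPEC, 0.1)
        big = BendingSpecimen(length=1e-2, diameter=140e-6)
        e2 = youngs_modulus_bending(40e-6, big, 0.1)
        assert e2 == pytest.approx(e1 / 16, rel=1e-12)

    def test_guards(self):
        with pytest.raises(DomainError):
            youngs_modulus_bending(0.0, self.SPEC, 0.1)
        with pytest.raises(DomainError):
            youngs_modulus_bending(1e-6, self.SPEC, 0.0)

    def test_beam_oracle_inversion(self):
        """The end-slope inversion recovers the beam modulus within 2% for
        angles up to 10 degrees, degrading monotonically with angle."""
        E_truth = 3.0e9
        rel_errs = []
        for alpha_target in np.radians([2, 5, 8, 10, 14]):
            # pick F giving roughly this end slope in linear theory
            I = math.pi * (70e-6)**4 / 64
            F = alpha_target * 2 * E_truth * I / 1e-2**2
            sol = beam_oracle(E_truth, 1e-2, 70e-6, F)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", SmallDeflectionWarning)
                E_est = youngs_modulus_bending(F, self.SPEC, sol.alpha)
            rel_errs.append(abs(E_est / E_truth - 1))
        assert all(e < 0.02 for e in rel_errs[:4])
        assert np.all(np.diff(rel_errs) > 0)  # degrades with alpha

    def test_warns_beyond_validity(self):
        with pytest.warns(SmallDeflectionWarning):
            youngs_modulus_bending(40e-6, self.SPEC, math.radians(14))


class TestErrorPropagation:
    def test_perfect_camera_limit(self, water):
        seq, _ = generate_pull_family(SyntheticTruth(), 6)
        seq.pixel_scale = 0.0
        worst, mc = systematic_error(seq, water)
        assert worst["F"] == pytest.approx(0.0, abs=1e-18)
        assert mc["F"] == pytest.approx(0.0, abs=1e-18)

    def test_linear_in_pixel_scale(self, water):
        seq, _ = generate_pull_family(SyntheticTruth(), 6)
        w1, _ = systematic_error(seq, water)
        seq.pixel_scale = seq.pixel_scale / 2
        w2, _ = systematic_error(seq, water)
        assert w2["F"] == pytest.approx(w1["F"] / 2, rel=0.2)
        assert w2["dy"] == pytest.approx(w1["dy"] / 2, rel=0.2)

    def test_invariant_to_time_relabeling(self, water):
        seq, _ = generate_pull_family(SyntheticTruth(), 6)
        w1, _ = systematic_error(seq, water)
        for f in seq.frames:
            f.timestamp += 17.0
        w2, _ = systematic_error(seq, water)
        assert w1 == w2

    def test_analyze_sequence_full_report(self, water):
        seq, rec = generate_pull_family(SyntheticTruth(), 8)
        res = analyze_sequence(seq, water, seed=1)
        assert res.adhesion_force == pytest.approx(rec.snap_force, rel=5e-3)
        assert res.spring_constant == pytest.approx(rec.spring_constant,
                                                    rel=5e-3)
        assert res.weight_force < 0.01 * res.adhesion_force
        for key in ("F", "dy", "D"):
            assert res.systematic[key] >= 0
            assert res.systematic_mc[key] >= 0
            assert res.systematic[key] >= res.systematic_mc[key]


class TestAggregation:
    def test_textbook_sem(self):
        s = aggregate_values([1.0, 2.0, 3.0])
        assert s.mean == pytest.approx(2.0)
        assert s.sem == pytest.approx(0.5774, abs=1e-4)

    def test_identical_replicates(self):
        s = aggregate_values([2.0] * 5, systematics=[0.3] * 5)
        assert s.sem == 0.0
        assert s.systematic == pytest.approx(0.3)

    def test_needs_two(self):
        with pytest.raises(InsufficientDataError):
            aggregate_values([1.0])

    def test_sem_calibration_75_replicates(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(19.5, 2.6, size=75)
        s = aggregate_values(vals)
        assert s.sem == pytest.approx(2.6 / math.sqrt(75), rel=0.35)
        assert s.n == 75
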