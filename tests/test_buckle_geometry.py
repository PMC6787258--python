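"""Elastica profile: elliptic-parameter inversion and curvature identities."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import ellipe, ellipk

from bucklesense import (
    BuckleProfile,
    elliptic_parameter_exact,
    elliptic_parameter_series,
    local_curvature,
    oriented_curvature,
    profile_xz,
    tangent_angle,
)
from bucklesense.buckle_geometry import signed_curvature
from bucklesense.errors import DomainError


class TestEllipticParameter:
    def test_series_value_at_ten_percent_compression(self):
        # four printed series terms evaluated by hand:
        # 0.1 - 0.00125 - 3.125e-5 - 1.07421875e-6
        assert elliptic_parameter_series(0.1) == pytest.approx(0.09871767578125, abs=1e-12)

    def test_series_vanishes_in_flat_limit(self):
        assert elliptic_parameter_series(1e-9) == pytest.approx(0.0, abs=2e-9)

    def test_series_domain_error_mentions_validity(self):
        with pytest.raises(DomainError, match="series"):
            elliptic_parameter_series(0.3)
        with pytest.raises(DomainError):
            elliptic_parameter_series(-0.1)

    def test_exact_inversion_satisfies_defining_relation(self):
        m = elliptic_parameter_exact(0.9)
        assert 2 * ellipe(m) / ellipk(m) - 1 == pytest.approx(0.9, abs=1e-10)

    def test_exact_agrees_with_series_in_weak_compression(self):
        # independent oracle: bisection on the complete-elliptic relation
        assert abs(elliptic_parameter_series(0.1) - elliptic_parameter_exact(0.9)) < 1e-5

    def test_flat_membrane_limit(self):
        assert elliptic_parameter_exact(1 - 1e-8) < 1e-6

    @pytest.mark.parametrize("m_true", [0.01, 0.05, 0.098718, 0.2])
    def test_round_trip_through_projection_ratio(self, m_true):
        ratio = 2 * ellipe(m_true) / ellipk(m_true) - 1
        assert elliptic_parameter_exact(ratio) == pytest.approx(m_true, abs=1e-9)


class TestProfileShape:
    def test_endpoints_and_peak(self, profile):
        x, z = profile_xz(profile, np.array([0.0, profile.L / 2, profile.L]))
        assert x[0] == pytest.approx(0.0, abs=1e-6 * profile.L)
        assert z[0] == pytest.approx(0.0, abs=1e-6 * profile.L)
        assert x[2] == pytest.approx(profile.Lx, abs=1e-6 * profile.L)
        assert z[2] == pytest.approx(0.0, abs=1e-6 * profile.L)
        # crest height z(L/2) = 4 lam sqrt(m)
        assert z[1] == pytest.approx(4 * profile.lam * np.sqrt(profile.m), rel=1e-9)

    def test_x_is_monotone_and_z_nonnegative(self, profile):
        s = np.linspace(0, profile.L, 2001)
        x, z = profile_xz(profile, s)
        assert np.all(np.diff(x) > 0)
        assert np.all(z >= -1e-12)

    def test_x_end_matches_integrated_tangent(self, profile):
        # oracle: numerically integrate cos(psi) ds over one period
        s = np.linspace(0, profile.L, 20001)
        x_int = np.trapezoid(np.cos(tangent_angle(profile, s)), s)
        x_end, _ = profile_xz(profile, profile.L)
        assert x_end == pytest.approx(x_int, abs=1e-6 * profile.L)

    def test_arc_length_consistency(self, profile):
        s = np.linspace(0, profile.L, 200001)
        x, z = profile_xz(profile, s)
        length = np.sum(np.hypot(np.diff(x), np.diff(z)))
        assert length == pytest.approx(profile.L, rel=1e-4)

    def test_profile_symmetry_about_crest(self, profile):
        s = np.linspace(0, profile.L, 501)
        _, z = profile_xz(profile, s)
        _, z_mirror = profile_xz(profile, profile.L - s)
        np.testing.assert_allclose(z, z_mirror, atol=1e-9)

    def test_domain_error_outside_period(self, profile):
        with pytest.raises(DomainError, match="wrap"):
            profile_xz(profile, -0.5)
        with pytest.raises(DomainError):
            profile_xz(profile, profile.L + 0.5)

    def test_flat_limit_tends_to_straight_segment(self):
        # total bend max C * L decays like sqrt(gamma) toward the flat limit
        bend = []
        for gamma in (1e-2, 1e-3, 1e-4, 1e-6):
            p = BuckleProfile.from_gamma(gamma, 37.8)
            s = np.linspace(0, p.L, 101)
            bend.append(np.max(local_curvature(p, s)) * p.L)
        assert np.all(np.diff(bend) < 0)
        assert bend[-1] < 0.02
        p = BuckleProfile.from_gamma(1e-4, 37.8)
        _, z = profile_xz(p, np.linspace(0, p.L, 101))
        assert np.max(z) < 0.3


class TestCurvature:
    def test_tangent_angle_values(self, profile):
        assert tangent_angle(profile, 0.0) == pytest.approx(0.0, abs=1e-12)
        # sn(K) = 1 so psi(L/4) = 2 arcsin(sqrt(m)) ~ 0.6392 rad at 10% compression
        psi_q = tangent_angle(profile, profile.L / 4)
        assert psi_q == pytest.approx(2 * np.arcsin(np.sqrt(profile.m)), rel=1e-12)
        assert psi_q == pytest.approx(0.63921, abs=1e-4)

    def test_curvature_is_tangent_angle_derivative(self, profile):
        h = 1e-3
        s = np.linspace(h, profile.L - h, 1000)
        fd = (tangent_angle(profile, s + h) - tangent_angle(profile, s - h)) / (2 * h)
        np.testing.assert_allclose(np.abs(fd), local_curvature(profile, s), atol=1e-6)

    def test_inflection_and_crest(self, profile):
        assert local_curvature(profile, profile.L / 4) == pytest.approx(0.0, abs=1e-7)
        assert local_curvature(profile, profile.L / 2) == pytest.approx(
            2 * np.sqrt(profile.m) / profile.lam, rel=1e-9
        )

    def test_curvature_symmetry(self, profile):
        s = np.linspace(0, profile.L, 401)
        np.testing.assert_allclose(
            local_curvature(profile, s), local_curvature(profile, profile.L - s), atol=1e-9
        )

    def test_signed_curvature_closes_the_tangent_loop(self, profile):
        s = np.linspace(0, profile.L, 40001)
        integral = np.trapezoid(signed_curvature(profile, s), s)
        assert integral == pytest.approx(0.0, abs=1e-8)

    def test_oriented_curvature_limits(self, profile):
        C90, R90 = oriented_curvature(profile, profile.L / 2, 90.0)
        assert C90 == pytest.approx(0.0, abs=1e-12)
        assert np.isinf(R90)
        C0, R0 = oriented_curvature(profile, profile.L / 2, 0.0)
        assert C0 == pytest.approx(profile.max_curvature, rel=1e-9)
        assert R0 == pytest.approx(1 / profile.max_curvature, rel=1e-9)
        C45, _ = oriented_curvature(profile, profile.L / 2, 45.0)
        assert C45 == pytest.approx(C0 / 2, rel=1e-9)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(gamma=st.floats(min_value=0.01, max_value=0.19))
def test_profile_invariants_across_compression(gamma):
    """Defining relation, endpoints, and psi-derivative hold for any gamma."""
    p = BuckleProfile.from_gamma(gamma, 30.0)
    assert p.Lx / p.L == pytest.approx(2 * ellipe(p.m) / ellipk(p.m) - 1, abs=1e-6)
    x_end, z_end = profile_xz(p, p.L)
    assert x_end == pytest.approx(p.Lx, abs=1e-6 * p.L)
    assert z_end == pytest.approx(0.0, abs=1e-6 * p.L)
    s = np.linspace(0.01, p.L - 0.01, 50)
    h = 1e-4
    fd = (tangent_angle(p, s + h) - tangent_angle(p, s - h)) / (2 * h)
    np.testing.assert_allclose(np.abs(fd), local_curvature(p, s), atol=1e-6)
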