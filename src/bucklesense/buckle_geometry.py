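"""Analytic geometry of a laterally compressed (Euler-buckled) membrane.

A tensionless bilayer compressed by a ratio ``gamma = (L - Lx)/L`` along x
adopts the classical elastica shape, expressible with Jacobi elliptic
functions of the arc length ``s``::

    x(s) = 2 lam E[am(s/lam, m), m] - s
    z(s) = 2 lam sqrt(m) (1 - cn(s/lam, m))

where ``m`` is the elliptic *parameter* (the square of the elliptic
modulus), ``lam = L / 4K[m]`` the characteristic length, and ``K``/``E``
complete elliptic integrals of the first/second kind.  ``m`` is fixed by
the projection ratio through ``Lx/L = 2 E[m]/K[m] - 1``.

All elliptic-function calls in this module use the *parameter* convention
(scipy's ``m``), never the modulus ``k = sqrt(m)``.  Lengths are nm, angles
at the public surface are degrees, curvature is nm^-1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.special import ellipe, ellipj, ellipk, elliprd, elliprf

from .errors import DomainError

__all__ = [
    "C_FLOOR",
    "BuckleProfile",
    "elliptic_parameter_series",
    "elliptic_parameter_exact",
    "profile_xz",
    "tangent_angle",
    "local_curvature",
    "signed_curvature",
    "oriented_curvature",
]

#: Curvature below which the radius of curvature is reported as infinite.
C_FLOOR = 1e-6


def elliptic_parameter_series(gamma: float) -> float:
    """Elliptic parameter from the four-term series in the compression ratio.

    m = gamma - gamma^2/8 - gamma^3/32 - 11 gamma^4/1024, truncated exactly
    at these four terms.  Valid only in the weak-compression regime.

    Parameters
    ----------
    gamma : float
        Compression ratio (L - Lx)/L, must lie in (0, 0.2].
    """
    if not 0.0 < gamma <= 0.2:
        raise DomainError(
            f"gamma={gamma!r} outside the series-validity range (0, 0.2]; "
            "the truncated expansion is only trusted for weak compression — "
            "use elliptic_parameter_exact for stronger buckling"
        )
    return gamma - gamma**2 / 8.0 - gamma**3 / 32.0 - 11.0 * gamma**4 / 1024.0


def elliptic_parameter_exact(Lx_over_L: float) -> float:
    """Invert ``Lx/L = 2E[m]/K[m] - 1`` for the elliptic parameter ``m``.

    Bracketed root finding on m in (1e-12, 1 - 1e-12); the left-hand side is
    strictly decreasing in m (from 1 at m=0 to -1 as m->1), so a unique root
    exists for any ratio in (0, 1) — the physically buckled regime.
    """
    if not 0.0 < Lx_over_L < 1.0:
        raise DomainError(f"Lx_over_L={Lx_over_L!r} must lie in (0, 1)")

    def residual(m: float) -> float:
        return 2.0 * ellipe(m) / ellipk(m) - 1.0 - Lx_over_L

    m = brentq(residual, 1e-12, 1.0 - 1e-12, xtol=1e-15, rtol=8.9e-16)
    if abs(residual(m)) > 1e-10:
        raise RuntimeError("elliptic parameter inversion did not converge")
    return m


@dataclass(frozen=True)
class BuckleProfile:
    """Shape parameters of one buckle period.

    Attributes
    ----------
    gamma : float
        Compression ratio (L - Lx)/L.
    L : float
        Total arc length of one period, nm.
    m : float
        Elliptic parameter (modulus squared).
    lam : float
        Characteristic length L / 4K[m], nm.
    Lx : float
        Projected box length along the buckling direction, nm.
    """

    gamma: float
    L: float
    m: float
    lam: float
    Lx: float

    def __post_init__(self) -> None:
        if not (0.0 < self.gamma < 1.0 and 0.0 < self.m < 1.0 and self.lam > 0.0):
            raise DomainError(
                f"invalid BuckleProfile: gamma={self.gamma}, m={self.m}, lam={self.lam}"
            )

    @classmethod
    def from_gamma(cls, gamma: float, L: float, *, method: str = "exact") -> "BuckleProfile":
        """Build a profile from the compression ratio and period arc length.

        ``method='exact'`` (default) inverts the complete-elliptic-integral
        relation; ``method='series'`` uses the truncated expansion, kept for
        cross-checks against the series route.
        """
        if L <= 0:
            raise DomainError("L must be positive")
        if not 0.0 < gamma < 1.0:
            raise DomainError("gamma must lie in (0, 1)")
        if method == "exact":
            m = elliptic_parameter_exact(1.0 - gamma)
        elif method == "series":
            m = elliptic_parameter_series(gamma)
        else:
            raise ValueError(f"unknown method {method!r}")
        lam = L / (4.0 * ellipk(m))
        return cls(gamma=gamma, L=L, m=m, lam=lam, Lx=(1.0 - gamma) * L)

    @classmethod
    def from_projection(cls, Lx_over_L: float, L: float) -> "BuckleProfile":
        """Build a profile from the projection ratio Lx/L and arc length L."""
        return cls.from_gamma(1.0 - Lx_over_L, L, method="exact")

    # Convenience method mirrors of the module-level operations.
    def xz(self, s):
        return profile_xz(self, s)

    def psi(self, s):
        return tangent_angle(self, s)

    def curvature(self, s):
        return local_curvature(self, s)

    @property
    def peak_height(self) -> float:
        """Crest height z(L/2) = 4 lam sqrt(m), nm."""
        return 4.0 * self.lam * np.sqrt(self.m)

    @property
    def max_curvature(self) -> float:
        """Largest curvature along the buckle, at the crest: 2 sqrt(m)/lam."""
        return 2.0 * np.sqrt(self.m) / self.lam


def _ellipeinc(phi, m: float):
    """Incomplete elliptic integral of the second kind E(phi | m).

    Evaluated through the Carlson symmetric forms R_F and R_D after
    reducing phi modulo pi (E(phi + pi) = E(phi) + 2E[m]).  The cephes
    routine behind scipy's ellipeinc has isolated one-ULP argument values
    where it returns results off by ~0.2, which breaks root finding on
    x(s); the Carlson route is uniformly accurate.
    """
    phi = np.asarray(phi, dtype=float)
    n = np.round(phi / np.pi)
    phi_r = phi - n * np.pi  # in [-pi/2, pi/2]
    s = np.sin(phi_r)
    c2 = np.cos(phi_r) ** 2
    q = 1.0 - m * s**2
    E_r = s * elliprf(c2, q, 1.0) - (m / 3.0) * s**3 * elliprd(c2, q, 1.0)
    return 2.0 * n * ellipe(m) + E_r


def _check_s(profile: BuckleProfile, s) -> np.ndarray:
    s = np.asarray(s, dtype=float)
    tol = 1e-9 * profile.L
    if s.min() < -tol or s.max() > profile.L + tol:
        raise DomainError(
            f"arc length outside [0, L={profile.L}]; wrap s periodically before calling"
        )
    return np.clip(s, 0.0, profile.L)


def xz_psi(profile: BuckleProfile, s):
    """(x, z, psi) at arc length ``s`` from a single elliptic evaluation.

    Equivalent to ``profile_xz`` + ``tangent_angle``; used on hot paths.
    """
    s = _check_s(profile, s)
    sn, cn, _, ph = ellipj(s / profile.lam, profile.m)
    sqm = np.sqrt(profile.m)
    x = 2.0 * profile.lam * _ellipeinc(ph, profile.m) - s
    z = 2.0 * profile.lam * sqm * (1.0 - cn)
    psi = 2.0 * np.arcsin(sqm * sn)
    return x, z, psi


def profile_xz(profile: BuckleProfile, s):
    """Point (x, z) on the buckle at arc length ``s`` (vectorized).

    x(s) = 2 lam E[am(s/lam, m), m] - s ;  z(s) = 2 lam sqrt(m)(1 - cn(s/lam, m)).
    """
    s = _check_s(profile, s)
    u = s / profile.lam
    _, cn, _, ph = ellipj(u, profile.m)
    x = 2.0 * profile.lam * _ellipeinc(ph, profile.m) - s
    z = 2.0 * profile.lam * np.sqrt(profile.m) * (1.0 - cn)
    return x, z


def tangent_angle(profile: BuckleProfile, s):
    """Tangent angle psi(s) = 2 arcsin(sqrt(m) sn(s/lam, m)), radians, signed."""
    s = _check_s(profile, s)
    sn, _, _, _ = ellipj(s / profile.lam, profile.m)
    return 2.0 * np.arcsin(np.sqrt(profile.m) * sn)


def local_curvature(profile: BuckleProfile, s):
    """Unsigned local curvature C(s) = sqrt(2(cos psi - (1 - 2m)))/lam, nm^-1.

    Vanishes at the inflection points s = L/4 and 3L/4 and peaks at the
    crest s = L/2 where C = 2 sqrt(m)/lam.  Round-off can drive the radicand
    slightly negative near the inflections; it is clamped at zero.
    """
    s = _check_s(profile, s)
    psi = tangent_angle(profile, s)
    radicand = 2.0 * (np.cos(psi) - (1.0 - 2.0 * profile.m))
    radicand = np.where(radicand > -1e-12, np.maximum(radicand, 0.0), radicand)
    if np.any(np.asarray(radicand) < 0):
        raise DomainError("curvature radicand negative beyond round-off tolerance")
    return np.sqrt(radicand) / profile.lam


def signed_curvature(profile: BuckleProfile, s):
    """Signed curvature dpsi/ds = 2 sqrt(m) cn(s/lam, m)/lam, nm^-1.

    Equal to ``local_curvature`` in magnitude; the sign follows cn, negative
    between the inflection points' far side (L/4 < s < 3L/4 has cn < 0 only
    past the quarter period).  Integrates to zero over a full period.
    """
    s = _check_s(profile, s)
    _, cn, _, _ = ellipj(s / profile.lam, profile.m)
    return 2.0 * np.sqrt(profile.m) * cn / profile.lam


def oriented_curvature(profile: BuckleProfile, s, theta_deg):
    """Curvature felt by an elongated inclusion at (s, theta).

    The buckle's principal curvatures are c1 = C(s) along x and c2 = 0 along
    y, so a protein whose long axis makes an in-plane angle ``theta`` (degrees)
    with the buckling direction samples ``C(s, theta) = C(s) cos^2 theta``.

    Returns ``(C, R)`` with R = 1/C; where C falls below :data:`C_FLOOR`
    (e.g. theta = 90 deg) R is reported as ``inf``.
    """
    theta = np.asarray(theta_deg, dtype=float)
    if np.any(theta < 0.0) or np.any(theta > 90.0):
        raise DomainError("theta must lie in [0, 90] degrees")
    C = local_curvature(profile, s) * np.cos(np.radians(theta)) ** 2
    with np.errstate(divide="ignore"):
        R = np.where(C < C_FLOOR, np.inf, 1.0 / np.where(C < C_FLOOR, 1.0, C))
    if np.isscalar(theta_deg) and np.isscalar(s):
        return float(C), float(R)
    return C, R
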