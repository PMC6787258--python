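"""Occupancy maps and Boltzmann-inversion free energy over membrane curvature.

From an ensemble of protein placements (s_norm, theta) on a buckled
membrane, build:

* a 2D occupancy histogram over (s_norm, theta), alongside the analytic
  radius-of-curvature map R(s, theta) at the bin centres;
* a 1D free-energy profile over the radius of curvature,
  F(R) = -ln[ P_obs(R) / P_geom(R) ]  (k_BT units),
  where P_geom is the geometric density of states: the distribution of
  R(s, theta) under a uniform measure on the (s, theta) surface.  Dividing
  by it is essential — without the correction a non-interacting (uniform)
  ensemble would show spurious structure simply because different
  curvatures occupy different amounts of surface;
* the curvature-dependent binding free energy dG_bind = F(R_bind) relative
  to the flat-membrane reference (negative = favourable).

The flat reference is the most weakly curved populated bin: samples whose
radius exceeds the last finite bin edge (including the infinite-radius
sentinel at theta = 90 deg) are collected in an overflow bin, and the
profile is shifted so the largest-R populated bin is zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence
import warnings

import numpy as np

from .buckle_geometry import BuckleProfile, oriented_curvature
from .errors import DomainError
from .trajectory_mapping import SurfacePlacement

__all__ = [
    "CurvatureLandscape",
    "default_R_edges",
    "occupancy_map",
    "free_energy_profile",
    "binding_free_energy",
]

#: Fine-grid resolution (n_s, n_theta) for the geometric density of states.
DOS_GRID = (2000, 900)


def default_R_edges(n_bins: int = 24, R_min: float = 10.0, R_max: float = 200.0) -> np.ndarray:
    """Log-spaced radius bin edges in nm (an overflow bin is added on use)."""
    return np.geomspace(R_min, R_max, n_bins + 1)


@dataclass
class CurvatureLandscape:
    """Binned view of a placement ensemble on the buckle surface."""

    s_edges: np.ndarray  # s_norm bin edges, dimensionless
    theta_edges: np.ndarray  # degrees
    occupancy: np.ndarray  # (n_s, n_theta) counts
    curvature_map: np.ndarray  # (n_s, n_theta) analytic R at bin centres, nm
    R_edges: np.ndarray | None = None  # finite radius bin edges, nm
    free_energy: np.ndarray | None = None  # per R-bin incl. overflow, k_BT; nan = unpopulated
    reference_bin: int | None = None  # index of the zero-energy bin

    @property
    def n_frames(self) -> int:
        return int(self.occupancy.sum())


def occupancy_map(
    placements: Sequence[SurfacePlacement],
    s_bins: int = 50,
    theta_bins: int = 45,
    profile: BuckleProfile | None = None,
) -> CurvatureLandscape:
    """2D occupancy over (s_norm, theta) with the companion analytic R map.

    ``profile`` is required to evaluate R(s, theta) at the bin centres.
    """
    if len(placements) == 0:
        raise DomainError("cannot histogram an empty placement ensemble")
    if profile is None:
        raise DomainError("a BuckleProfile is required for the curvature map")
    s = np.array([p.s_norm for p in placements])
    th = np.array([p.theta for p in placements])
    s_edges = np.linspace(0.0, 1.0, s_bins + 1)
    theta_edges = np.linspace(0.0, 90.0, theta_bins + 1)
    occ, _, _ = np.histogram2d(s, th, bins=[s_edges, theta_edges])

    s_centres = 0.5 * (s_edges[:-1] + s_edges[1:]) * profile.L
    th_centres = 0.5 * (theta_edges[:-1] + theta_edges[1:])
    S, TH = np.meshgrid(s_centres, th_centres, indexing="ij")
    _, R = oriented_curvature(profile, S.ravel(), TH.ravel())
    return CurvatureLandscape(
        s_edges=s_edges,
        theta_edges=theta_edges,
        occupancy=occ,
        curvature_map=np.asarray(R).reshape(S.shape),
    )


def _bin_radii(R: np.ndarray, R_edges: np.ndarray) -> np.ndarray:
    """Counts per radius bin; bin 0 absorbs R below the first edge and the
    last (overflow) bin absorbs R beyond the last edge, including inf."""
    n_finite = len(R_edges) - 1
    idx = np.searchsorted(R_edges, R, side="right") - 1
    idx = np.clip(idx, 0, n_finite)  # index n_finite = overflow
    return np.bincount(idx, minlength=n_finite + 1).astype(float)


def geometric_density(
    profile: BuckleProfile, R_edges: np.ndarray, grid: tuple[int, int] = DOS_GRID
) -> np.ndarray:
    """Geometric density of states: R(s, theta) histogrammed over a uniform
    (s, theta) grid, normalized to unit total."""
    n_s, n_theta = grid
    s = (np.arange(n_s) + 0.5) * profile.L / n_s
    theta = (np.arange(n_theta) + 0.5) * 90.0 / n_theta
    S, TH = np.meshgrid(s, theta, indexing="ij")
    _, R = oriented_curvature(profile, S.ravel(), TH.ravel())
    counts = _bin_radii(np.asarray(R), R_edges)
    return counts / counts.sum()


def free_energy_profile(
    placements: Sequence[SurfacePlacement],
    profile: BuckleProfile,
    R_edges: np.ndarray | None = None,
    correct_dos: bool = True,
    grid: tuple[int, int] = DOS_GRID,
) -> CurvatureLandscape:
    """Free-energy profile F(R) in k_BT by Boltzmann inversion.

    With ``correct_dos`` (default) the observed radius histogram is divided
    by the geometric density of states so that a uniformly distributed
    ensemble yields a flat profile; with ``correct_dos=False`` the raw
    -ln P_obs is returned (kept for comparison with analyses that skip the
    correction).  Unpopulated bins are NaN, never zero.  The profile is
    shifted so the largest-R populated bin (the flat-membrane stand-in,
    usually the overflow bin) is exactly zero.
    """
    if len(placements) == 0:
        raise DomainError("cannot invert an empty placement ensemble")
    if len(placements) < 100:
        warnings.warn(
            f"only {len(placements)} placements; free-energy profile will be noisy",
            stacklevel=2,
        )
    if R_edges is None:
        R_edges = default_R_edges()
    R_edges = np.asarray(R_edges, dtype=float)

    R_obs = np.array([p.R for p in placements])
    counts = _bin_radii(R_obs, R_edges)
    p_obs = counts / counts.sum()

    if correct_dos:
        p_geom = geometric_density(profile, R_edges, grid)
    else:
        p_geom = np.ones_like(p_obs) / len(p_obs)

    with np.errstate(divide="ignore", invalid="ignore"):
        F = -np.log(p_obs / p_geom)
    F[(counts == 0) | (p_geom == 0)] = np.nan

    populated = np.flatnonzero(~np.isnan(F))
    reference = int(populated[-1])  # largest-R populated bin
    F -= F[reference]

    landscape = occupancy_map(placements, profile=profile)
    landscape.R_edges = R_edges
    landscape.free_energy = F
    landscape.reference_bin = reference
    return landscape


def binding_free_energy(landscape: CurvatureLandscape, R_bind: float) -> float:
    """dG_bind (k_BT): F at R_bind relative to the flat reference.

    Linear interpolation between the centres (geometric means, matching the
    log-spaced bins) of the populated finite-radius bins; negative values
    mean binding to that curvature is favourable relative to flat.
    """
    if landscape.free_energy is None or landscape.R_edges is None:
        raise DomainError("landscape has no free-energy profile; run free_energy_profile first")
    F = landscape.free_energy
    edges = landscape.R_edges
    centres = np.sqrt(edges[:-1] * edges[1:])  # finite bins only
    ok = ~np.isnan(F[: len(centres)])
    if not ok.any():
        raise DomainError("no populated finite-radius bins")
    c, f = centres[ok], F[: len(centres)][ok]
    if not c[0] <= R_bind <= c[-1]:
        raise DomainError(
            f"R_bind={R_bind} nm outside the populated radius range "
            f"[{c[0]:.1f}, {c[-1]:.1f}] nm"
        )
    # Refuse to bridge masked gaps: R_bind must fall in/next to a populated bin.
    containing = np.searchsorted(edges, R_bind, side="right") - 1
    if 0 <= containing < len(centres) and np.isnan(F[containing]):
        raise DomainError(
            f"R_bind={R_bind} nm falls in an unpopulated bin; populated range "
            f"is [{c[0]:.1f}, {c[-1]:.1f}] nm with gaps"
        )
    return float(np.interp(R_bind, c, f))
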