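"""Map snapshots of a buckled membrane + protein onto the analytic elastica.

The observables are the protein centre-of-mass position on the normalized
arc length, ``s_norm = s/L in [0, 1)``, and its in-plane orientation
``theta in [0, 90]`` degrees — the angle between the first principal axis
of the protein bead cloud (projected on x–y) and the buckling direction x.
Together they fix the membrane curvature the protein sits on,
``C(s, theta) = C(s) cos^2 theta``.

Alignment follows the operational recipe: wrap x into one period, bin the
membrane head beads in x, locate the crest as the smoothed mode of the
bin-mean height, and shift the frame so the crest coincides with the
analytic crest at s = L/2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np

from .buckle_geometry import BuckleProfile, oriented_curvature, profile_xz, xz_psi
from .errors import AlignmentError, MappingError, OrientationError, PipelineError
from .frames import LabeledFrame

__all__ = [
    "SurfacePlacement",
    "align_to_profile",
    "protein_arclength",
    "protein_orientation",
    "arclength_from_x",
    "map_trajectory",
]

log = logging.getLogger(__name__)

#: Number of x-bins used for crest detection (bin width Lx / N_ALIGN_BINS).
N_ALIGN_BINS = 50


@dataclass(frozen=True)
class SurfacePlacement:
    """Protein placement on the buckle for one frame."""

    s_norm: float  # normalized arc length in [0, 1)
    theta: float  # degrees in [0, 90]
    C: float  # curvature at (s, theta), nm^-1
    R: float  # radius of curvature, nm (inf when C below floor)
    shift_applied: float  # x-shift used during alignment, nm
    time: float = 0.0  # ps


def _binned_height(x: np.ndarray, z: np.ndarray, Lx: float, n_bins: int):
    """Mean z per x-bin (period-wrapped), with occupancy counts."""
    idx = np.floor((x % Lx) / (Lx / n_bins)).astype(int)
    idx = np.clip(idx, 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    sums = np.bincount(idx, weights=z, minlength=n_bins)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return means, counts


def _circular_smooth3(values: np.ndarray) -> np.ndarray:
    """3-bin moving average with periodic wrap, nan-aware."""
    stacked = np.vstack([np.roll(values, 1), values, np.roll(values, -1)])
    with np.errstate(invalid="ignore"):
        return np.nanmean(stacked, axis=0)


def align_to_profile(
    frame: LabeledFrame,
    profile: BuckleProfile,
    n_bins: int = N_ALIGN_BINS,
) -> tuple[LabeledFrame, float]:
    """Centre the membrane crest on the analytic crest at s = L/2.

    Returns the aligned frame (x shifted with periodic wrapping, z offset so
    the lowest bin-mean height is zero) and the applied x-shift in nm.
    """
    heads = frame.membrane
    if len(heads) < 3:
        raise AlignmentError("need at least 3 membrane head beads")
    if abs(frame.box[0] - profile.Lx) > 0.05 * profile.Lx:
        raise AlignmentError(
            f"box x-length {frame.box[0]:.3f} nm inconsistent with profile "
            f"Lx {profile.Lx:.3f} nm (>5% off)"
        )
    Lx = profile.Lx
    means, counts = _binned_height(heads[:, 0], heads[:, 2], Lx, n_bins)
    occupied = counts > 0
    if occupied.sum() < 10:
        raise AlignmentError(
            f"only {int(occupied.sum())} occupied x-bins; membrane too sparse to align"
        )
    smooth = _circular_smooth3(means)
    peak = int(np.nanargmax(smooth))
    # Ambiguous crest: another bin ties the smoothed maximum.  Break the tie
    # with the larger raw bin-mean height.
    ties = np.flatnonzero(np.isclose(smooth, smooth[peak], rtol=0, atol=1e-12))
    if len(ties) > 1:
        peak = int(ties[np.nanargmax(means[ties])])
        log.debug("ambiguous crest bins (%d tied); refining from bin %d", len(ties), peak)

    # Refine the crest as the height-weighted circular centroid of the head
    # beads: the bin mode alone aliases between the two leaflets (their beads
    # are displaced in x by +-offset*sin(psi)), while the centroid is exact
    # for any x-symmetric height profile.
    ang = 2.0 * np.pi * (heads[:, 0] % Lx) / Lx
    w = np.maximum(heads[:, 2] - np.nanmin(means), 0.0) ** 2
    if w.sum() <= 0:
        raise AlignmentError("membrane height profile is flat; no crest to align")
    peak_x = (np.arctan2((w * np.sin(ang)).sum(), (w * np.cos(ang)).sum()) / (2.0 * np.pi) * Lx) % Lx

    crest_x, _ = profile_xz(profile, profile.L / 2.0)  # = Lx/2 by symmetry
    shift = float(crest_x) - peak_x
    shift = (shift + Lx / 2.0) % Lx - Lx / 2.0  # minimal representative

    z_offset = float(np.nanmin(means))
    aligned = frame.shifted(np.array([shift, 0.0, -z_offset]), wrap_xy=False)
    coords = aligned.coords.copy()
    coords[:, 0] %= Lx
    aligned = LabeledFrame(coords, aligned.roles, aligned.box, aligned.time)
    return aligned, shift


@lru_cache(maxsize=8)
def _inversion_table(gamma: float, L: float):
    """Dense monotone (x, s) table of one buckle period for seeding Newton."""
    profile = BuckleProfile.from_gamma(gamma, L)
    s = np.linspace(0.0, L, 4097)
    x, _ = profile_xz(profile, s)
    return x, s


def arclength_from_x(profile: BuckleProfile, x, tol_factor: float = 1e-6):
    """Invert the monotone map x(s) on [0, L].

    A dense precomputed table seeds the root, and two Newton steps on the
    exact profile (x'(s) = cos psi > 0 everywhere in the buckled regime)
    polish it to well below ``tol_factor * L``.  ``x`` may be scalar or
    array.
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    if x.min() < -1e-9 or x.max() > profile.Lx + 1e-9:
        raise MappingError("x outside [0, Lx]; wrap into the box first")
    x_tab, s_tab = _inversion_table(profile.gamma, profile.L)
    s = np.interp(x, x_tab, s_tab)
    for _ in range(2):
        xs, _, psi = xz_psi(profile, s)
        s = np.clip(s - (xs - x) / np.maximum(np.cos(psi), 0.5), 0.0, profile.L)
    return s


def _unwrap(points: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Contiguous copy of a molecule split by x/y periodic boundaries.

    For each periodic axis the wrapped coordinates are sorted and the
    largest cyclic gap located: the molecule occupies the complement of
    that gap, so shifting the origin to the gap's end reconstructs a
    contiguous molecule exactly — for any molecule smaller than one box
    period.  (Min-imaging around a reference bead fails beyond half a
    period, which an elongated protein in a shallow box easily exceeds.)
    """
    pts = points.copy()
    for axis in (0, 1):
        B = box[axis]
        wrapped = pts[:, axis] % B
        order = np.sort(wrapped)
        gaps = np.diff(np.concatenate([order, order[:1] + B]))
        # molecule starts at the point just past the largest empty gap
        start = order[(np.argmax(gaps) + 1) % len(order)]
        pts[:, axis] = np.where(wrapped < start, wrapped + B, wrapped)
    return pts


def _unwrapped_com(points: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Centre of mass of a possibly boundary-split molecule (min-image)."""
    return _unwrap(points, box).mean(axis=0)


def protein_arclength(aligned_frame: LabeledFrame, profile: BuckleProfile) -> float:
    """Normalized arc-length coordinate of the protein centre of mass.

    The COM is the unweighted mean of the backbone bead positions (CG
    backbone beads are near-uniform in mass); ``s`` is found by inverting
    the monotone x(s) at the COM's x, and s_norm = s/L.
    """
    protein = aligned_frame.protein
    if len(protein) < 3:
        raise MappingError("need at least 3 protein backbone beads")
    com = _unwrapped_com(protein.copy(), aligned_frame.box)
    x_com = com[0] % profile.Lx
    heads_x = aligned_frame.membrane[:, 0]
    spans_period = heads_x.max() - heads_x.min() > 0.95 * profile.Lx
    if not spans_period and not (heads_x.min() - 1e-9 <= x_com <= heads_x.max() + 1e-9):
        # A full periodic sheet covers every x; this guards partial sheets.
        raise MappingError(
            f"protein COM x={x_com:.3f} nm outside membrane x-range "
            f"[{heads_x.min():.3f}, {heads_x.max():.3f}]"
        )
    s = float(arclength_from_x(profile, x_com)[0])
    return (s / profile.L) % 1.0


def protein_orientation(aligned_frame: LabeledFrame) -> float:
    """In-plane angle (degrees, folded into [0, 90]) of the protein long axis.

    The long axis is the eigenvector of the 3x3 positional covariance of the
    backbone beads with the largest eigenvalue, computed after minimum-image
    unwrapping; its x–y projection is compared with the buckling direction x.
    Folding uses the axis' sign ambiguity and the reflection symmetry of the
    buckle, so the result never exceeds 90 degrees.
    """
    protein = aligned_frame.protein
    if len(protein) < 3:
        raise OrientationError("need at least 3 protein backbone beads")
    pts = _unwrap(protein, aligned_frame.box)
    centred = pts - pts.mean(axis=0)
    cov = centred.T @ centred / len(pts)
    evals, evecs = np.linalg.eigh(cov)  # ascending
    if evals[-1] <= 0 or (evals[-1] - evals[-2]) / evals[-1] < 1e-9:
        raise OrientationError("degenerate covariance: first principal axis undefined")
    axis_vec = evecs[:, -1]
    proj = np.hypot(axis_vec[0], axis_vec[1])
    if proj < 1e-12:
        raise OrientationError("principal axis perpendicular to the membrane plane")
    return float(np.degrees(np.arctan2(abs(axis_vec[1]), abs(axis_vec[0]))))


def map_frame(frame: LabeledFrame, profile: BuckleProfile) -> SurfacePlacement:
    """Alignment + arc-length + orientation for a single frame."""
    aligned, shift = align_to_profile(frame, profile)
    s_norm = protein_arclength(aligned, profile)
    theta = protein_orientation(aligned)
    C, R = oriented_curvature(profile, s_norm * profile.L, theta)
    return SurfacePlacement(
        s_norm=s_norm, theta=theta, C=C, R=R, shift_applied=shift, time=frame.time
    )


def map_trajectory(
    frames: Iterable[LabeledFrame],
    profile: BuckleProfile,
    max_skip_fraction: float = 0.2,
) -> list[SurfacePlacement]:
    """Per-frame placement for a whole trajectory.

    Frames that fail alignment/mapping are logged and skipped; if more than
    ``max_skip_fraction`` of the frames fail, the whole run is rejected.
    Accepts any iterable (including generators, so large synthetic
    trajectories can be streamed without materializing every frame).
    """
    placements: list[SurfacePlacement] = []
    n_total = 0
    n_failed = 0
    for i, frame in enumerate(frames):
        n_total += 1
        try:
            placements.append(map_frame(frame, profile))
        except (AlignmentError, MappingError, OrientationError) as exc:
            n_failed += 1
            log.warning("frame %d skipped: %s", i, exc)
    if n_total == 0:
        raise PipelineError("empty frame sequence")
    if n_failed / n_total > max_skip_fraction:
        raise PipelineError(
            f"{n_failed}/{n_total} frames failed mapping (> {max_skip_fraction:.0%})"
        )
    return placements


def placements_to_table(placements: Sequence[SurfacePlacement]):
    """Tidy per-frame table (time, s_norm, theta, C, R, shift) as a DataFrame."""
    import pandas as pd

    return pd.DataFrame(
        {
            "time": [p.time for p in placements],
            "s_norm": [p.s_norm for p in placements],
            "theta": [p.theta for p in placements],
            "C": [p.C for p in placements],
            "R": [p.R for p in placements],
            "shift_applied": [p.shift_applied for p in placements],
        }
    )
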