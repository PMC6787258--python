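"""Ground-truth synthetic inputs for every stage of the pipeline.

Generates the study system the analysis assumes, with known truth:

* buckled bilayer sheets whose head beads lie exactly on the analytic
  elastica profile (two leaflets offset along the local normal, optional
  Gaussian positional noise mimicking thermal roughness);
* a banana-shaped protein — a circular-arc bead chain with a realistic
  lateral width, like an F-BAR dimer cross-section — placed at a chosen
  (s_norm, theta) on the buckle;
* Metropolis Monte-Carlo (s, theta) ensembles drawn from a
  curvature-dependent binding energy (step well or harmonic in C), rendered
  into full coordinate frames;
* cylindrically bent and flat open sheets for circle-fit validation;
* protein conformer ensembles with per-frame radius and per-bead jitter.

Defaults mirror the coarse-grained buckled system at 10% lateral
compression: gamma = 0.1 with a projected box of ~34 nm (the period is an
assumption — see docs), a 17 nm deep sheet, ~0.8 nm head-bead spacing, and
a protein arc of 25 nm radius.  Every generator is a pure function of
(config, seed).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterator

import numpy as np

from .buckle_geometry import BuckleProfile, local_curvature, profile_xz, tangent_angle, xz_psi
from .errors import ConfigError
from .frames import ROLE_MEMBRANE, ROLE_PROTEIN, LabeledFrame

__all__ = [
    "EnergyModel",
    "GeneratorConfig",
    "make_buckled_sheet",
    "place_protein",
    "sample_boltzmann_trajectory",
    "make_bent_sheet",
    "make_flat_sheet",
    "make_conformer_ensemble",
]


@dataclass(frozen=True)
class EnergyModel:
    """Curvature-dependent binding energy U(C) in k_BT.

    ``model='step'``: U = -well_depth where R = 1/C lies inside ``window``
    (default 17–33 nm, a broad preferred-curvature band), 0 elsewhere —
    the flat membrane is exactly the zero of energy.

    ``model='harmonic'``: U = 1/2 k (C - 1/preferred_R)^2 with the stiffness
    scaled so that the flat membrane sits ``well_depth`` above the minimum:
    k = 2 well_depth preferred_R^2.
    """

    preferred_R: float = 25.0  # nm
    well_depth: float = 2.0  # k_BT
    model: str = "step"
    window: tuple[float, float] = (17.0, 33.0)  # nm, step model only

    def __post_init__(self):
        if self.model not in ("step", "harmonic"):
            raise ConfigError(f"unknown energy model {self.model!r}")
        if self.well_depth < 0:
            raise ConfigError("well_depth must be >= 0")
        if self.model == "step" and not 0 < self.window[0] < self.window[1]:
            raise ConfigError("step window must satisfy 0 < R_lo < R_hi")

    def energy(self, C) -> np.ndarray:
        """U(C) in k_BT, vectorized over curvature C (nm^-1, >= 0)."""
        C = np.asarray(C, dtype=float)
        if self.model == "step":
            lo, hi = 1.0 / self.window[1], 1.0 / self.window[0]
            return np.where((C >= lo) & (C <= hi), -self.well_depth, 0.0)
        k = 2.0 * self.well_depth * self.preferred_R**2
        return 0.5 * k * (C - 1.0 / self.preferred_R) ** 2


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-condition parameters of the synthetic buckled system."""

    seed: int = 0
    gamma: float = 0.1  # 10% lateral compression
    L: float = 37.8  # buckle period arc length, nm (assumed; Lx ~ 34 nm)
    Ly: float = 17.0  # sheet depth, nm (leaves a clear periodic seam around the protein)
    lipid_spacing: float = 0.8  # head-bead grid spacing, nm
    leaflet_offset: float = 2.0  # half bilayer thickness, nm
    noise_sigma: float = 0.3  # positional noise, nm
    protein_arc_radius: float = 25.0  # nm
    protein_length: float = 14.0  # chord length, nm
    protein_width: float = 3.0  # lateral (dimer) width, nm
    n_protein_beads: int = 15  # beads per row (two rows)
    protein_standoff: float = 0.5  # surface-to-protein gap, nm
    energy_model: EnergyModel = field(default_factory=EnergyModel)
    n_frames: int = 100

    def __post_init__(self):
        if not 0.0 < self.gamma < 0.2:
            raise ConfigError("gamma must lie in (0, 0.2) for the buckled regime")
        for name in ("L", "Ly", "lipid_spacing", "leaflet_offset", "protein_arc_radius",
                     "protein_length", "protein_width"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.noise_sigma < 0:
            raise ConfigError("noise_sigma must be >= 0")
        if self.n_frames < 1:
            raise ConfigError("n_frames must be >= 1")
        if self.protein_length > self.L / 2.0:
            raise ConfigError(
                f"protein chord {self.protein_length} nm exceeds half the buckle "
                f"period L/2 = {self.L / 2.0} nm"
            )
        if self.protein_length > 2.0 * self.protein_arc_radius:
            raise ConfigError("protein chord cannot exceed the arc diameter")

    def profile(self) -> BuckleProfile:
        return BuckleProfile.from_gamma(self.gamma, self.L)


@lru_cache(maxsize=8)
def _base_sheet(gamma: float, L: float, Ly: float, spacing: float, offset: float):
    """Noiseless head-bead coordinates of one buckled sheet (cached)."""
    profile = BuckleProfile.from_gamma(gamma, L)
    n_s = math.ceil(L / spacing)
    n_y = math.ceil(Ly / spacing)
    s = (np.arange(n_s) + 0.5) * L / n_s
    y = (np.arange(n_y) + 0.5) * Ly / n_y
    x, z = profile_xz(profile, s)
    psi = tangent_angle(profile, s)
    normal = np.column_stack([-np.sin(psi), np.zeros_like(psi), np.cos(psi)])
    surf = np.column_stack([x, np.zeros_like(x), z])
    coords = []
    for sign in (+1.0, -1.0):
        pts = surf + sign * offset * normal  # (n_s, 3)
        tiled = np.repeat(pts, n_y, axis=0)
        tiled[:, 1] = np.tile(y, n_s)
        coords.append(tiled)
    coords = np.vstack(coords)
    z_top = coords[:, 2].max()
    return coords, z_top


def make_buckled_sheet(cfg: GeneratorConfig, rng: np.random.Generator | None = None) -> LabeledFrame:
    """Buckled bilayer sheet: head beads on the elastica profile.

    Beads sit on an (s, y) grid with ``lipid_spacing``, two leaflets offset
    by ±``leaflet_offset`` along the local surface normal, plus isotropic
    Gaussian noise of ``noise_sigma``.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    base, z_top = _base_sheet(cfg.gamma, cfg.L, cfg.Ly, cfg.lipid_spacing, cfg.leaflet_offset)
    coords = base.copy()
    if cfg.noise_sigma > 0:
        coords = coords + rng.normal(0.0, cfg.noise_sigma, coords.shape)
    profile = cfg.profile()
    box_z = z_top + 6.0 * cfg.noise_sigma + cfg.protein_arc_radius / 2.0 + 5.0
    roles = np.array([ROLE_MEMBRANE] * len(coords), dtype=object)
    return LabeledFrame(coords, roles, np.array([profile.Lx, cfg.Ly, box_z]))


def _anchor_arclength(cfg: GeneratorConfig, profile: BuckleProfile, s_target: float) -> float:
    """Anchor point such that the protein COM maps back to ``s_target``.

    The protein COM sits a fixed lift above the surface along the local
    normal, which displaces its x relative to the anchor on sloped parts of
    the buckle.  A few fixed-point iterations compensate, so the generator's
    ground truth is expressed in the same operational (COM-mapped)
    coordinate the measurement uses.
    """
    alpha = math.asin(cfg.protein_length / (2.0 * cfg.protein_arc_radius))
    phi = np.linspace(-alpha, alpha, cfg.n_protein_beads)
    lift = cfg.protein_standoff + cfg.protein_arc_radius * (1.0 - float(np.mean(np.cos(phi))))
    x_target, _ = profile_xz(profile, s_target)
    s_a = s_target
    for _ in range(5):
        x_a, _, psi = xz_psi(profile, s_a % profile.L)
        psi = float(psi)
        x_com = float(x_a) - lift * math.sin(psi)
        # minimal periodic x-difference (the anchor may cross the seam)
        dx = (float(x_target) - x_com + profile.Lx / 2.0) % profile.Lx - profile.Lx / 2.0
        s_a += dx / max(math.cos(psi), 0.3)
    return s_a % profile.L


def place_protein(
    cfg: GeneratorConfig,
    s_norm: float,
    theta: float,
    frame: LabeledFrame | None = None,
    rng: np.random.Generator | None = None,
) -> LabeledFrame:
    """Add a banana-protein bead arc at (s_norm, theta) on the buckle.

    The protein is a circular arc (radius ``protein_arc_radius``, chord
    ``protein_length``, ``n_protein_beads`` beads) in two parallel rows
    ``protein_width`` apart, lying tangent to the membrane at the arc
    position with its concave face toward the surface, lifted by
    ``protein_standoff``.  ``theta`` is the in-plane angle of the long axis
    from the buckling direction, exactly as the orientation measurement
    defines it.
    """
    if not 0.0 <= s_norm < 1.0:
        raise ConfigError("s_norm must lie in [0, 1)")
    if not 0.0 <= theta <= 90.0:
        raise ConfigError("theta must lie in [0, 90] degrees")
    if frame is None:
        frame = make_buckled_sheet(cfg, rng)
    profile = cfg.profile()

    s_a = _anchor_arclength(cfg, profile, s_norm * profile.L)
    x0, z0, psi = xz_psi(profile, s_a)
    psi = float(psi)
    p0 = np.array([float(x0), cfg.Ly / 2.0, float(z0)])
    n = np.array([-math.sin(psi), 0.0, math.cos(psi)])

    # Long-axis direction in the tangent plane whose x-y projection makes
    # exactly ``theta`` with x: w = (cos t, sin t, tan(psi) cos t).
    t_r = math.radians(theta)
    w = np.array([math.cos(t_r), math.sin(t_r), math.tan(psi) * math.cos(t_r)])
    u = w / np.linalg.norm(w)
    b = np.cross(n, u)
    b /= np.linalg.norm(b)

    R = cfg.protein_arc_radius
    alpha = math.asin(cfg.protein_length / (2.0 * R))
    phi = np.linspace(-alpha, alpha, cfg.n_protein_beads)
    centre = p0 + (cfg.protein_standoff + R) * n
    arc = centre[None, :] - R * np.cos(phi)[:, None] * n[None, :] + R * np.sin(phi)[:, None] * u[None, :]
    beads = np.vstack([arc + 0.5 * cfg.protein_width * b, arc - 0.5 * cfg.protein_width * b])
    beads[:, 0] %= frame.box[0]
    beads[:, 1] %= frame.box[1]

    coords = np.vstack([frame.coords, beads])
    roles = np.concatenate([frame.roles, np.array([ROLE_PROTEIN] * len(beads), dtype=object)])
    return LabeledFrame(coords, roles, frame.box, frame.time)


def _tune_widths(
    energy, L: float, rng: np.random.Generator, ds: float, dth: float
) -> tuple[float, float]:
    """Adjust proposal widths toward a 30–50% acceptance rate."""
    s, th = rng.uniform(0, L), rng.uniform(0, 90)
    for _ in range(20):
        acc = 0
        for _ in range(400):
            s2 = (s + rng.uniform(-ds, ds)) % L
            th2 = th + rng.uniform(-dth, dth)
            th2 = abs(th2)
            if th2 > 90:
                th2 = 180 - th2
            dU = energy(s2, th2) - energy(s, th)
            if dU <= 0 or rng.random() < math.exp(-dU):
                s, th = s2, th2
                acc += 1
        rate = acc / 400
        if 0.3 <= rate <= 0.5:
            return ds, dth
        factor = 1.5 if rate > 0.5 else 1 / 1.5
        ds = min(ds * factor, L / 2)
        dth = min(dth * factor, 45.0)
    return ds, dth


def sample_boltzmann_trajectory(
    cfg: GeneratorConfig,
    stream: bool = False,
    thin: int = 10,
):
    """Metropolis Monte-Carlo (s, theta) ensemble under the binding energy.

    Samples (s, theta) with U(s, theta) = U(C(s) cos^2 theta) from
    ``cfg.energy_model``, with uniform local proposals (auto-tuned widths,
    starting at 0.02 L and 5 deg) and ``thin``-fold thinning, then renders
    each kept sample into a full coordinate frame (buckled sheet + placed
    protein, fresh noise per frame).

    With ``well_depth = 0`` the energy surface is flat and full-domain
    (independence) proposals are used, so the kept samples are exactly
    i.i.d. uniform — the null ensemble.

    Returns ``(frames, truth)`` where truth is an (n_frames, 2) array of
    ground-truth (s_norm, theta) and ``frames`` is a list, or a lazy
    generator when ``stream=True`` (identical bytes either way for a fixed
    seed).
    """
    profile = cfg.profile()
    L = profile.L
    model = cfg.energy_model

    # Dense curvature table: U evaluation is the hot loop.
    s_grid = np.linspace(0.0, L, 4097)
    C_grid = local_curvature(profile, s_grid)

    def U(s: float, th: float) -> float:
        pos = s / L * 4096.0
        i = int(pos)
        frac = pos - i
        C_s = C_grid[i] + frac * (C_grid[min(i + 1, 4096)] - C_grid[i])
        return float(model.energy(C_s * math.cos(math.radians(th)) ** 2))

    ss = np.random.SeedSequence(cfg.seed)
    ss_mc, ss_frames = ss.spawn(2)
    rng = np.random.default_rng(ss_mc)

    n_keep = cfg.n_frames
    truth = np.empty((n_keep, 2))
    if model.well_depth == 0:
        truth[:, 0] = rng.uniform(0, L, n_keep) / L
        truth[:, 1] = rng.uniform(0, 90, n_keep)
        accept_rate = 1.0
    else:
        ds, dth = _tune_widths(U, L, rng, 0.02 * L, 5.0)
        s, th = rng.uniform(0, L), rng.uniform(0, 90)
        accepted = 0
        total = 1000 + n_keep * thin
        kept = 0
        for step in range(total):
            s2 = (s + rng.uniform(-ds, ds)) % L
            th2 = th + rng.uniform(-dth, dth)
            th2 = abs(th2)
            if th2 > 90:
                th2 = 180 - th2
            dU = U(s2, th2) - U(s, th)
            if dU <= 0 or rng.random() < math.exp(-dU):
                s, th = s2, th2
                accepted += 1
            if step >= 1000 and (step - 1000) % thin == thin - 1:
                truth[kept] = (s / L, th)
                kept += 1
        accept_rate = accepted / total
        if not 0.1 <= accept_rate <= 0.9:
            warnings.warn(
                f"Metropolis acceptance rate {accept_rate:.2f} outside [0.1, 0.9] "
                f"even after width auto-tuning (ds={ds:.3f} nm, dtheta={dth:.2f} deg)",
                stacklevel=2,
            )

    frame_seeds = ss_frames.spawn(n_keep)

    def render() -> Iterator[LabeledFrame]:
        for k in range(n_keep):
            frng = np.random.default_rng(frame_seeds[k])
            sheet = make_buckled_sheet(cfg, frng)
            frame = place_protein(cfg, truth[k, 0], truth[k, 1], frame=sheet)
            frame.time = float(k)
            yield frame

    if stream:
        return render(), truth
    return list(render()), truth


def make_bent_sheet(
    radius: float,
    arc_span: float = 60.0,
    Ly: float = 15.0,
    spacing: float = 0.8,
    noise_sigma: float = 0.3,
    seed: int = 0,
    leaflet_offset: float = 2.0,
) -> LabeledFrame:
    """Cylindrically bent open-edged sheet of known radius.

    ``radius`` is the radius of the *innermost* (concave-side) leaflet — the
    quantity the circle-fit measurement estimates; the outer leaflet sits
    ``2 * leaflet_offset`` further out.  ``arc_span`` is the angular extent
    in degrees.  The sheet arches upward, concave side down.
    """
    if radius <= 0:
        raise ConfigError("radius must be positive")
    rng = np.random.default_rng(seed)
    span = math.radians(arc_span)
    r_in, r_out = radius, radius + 2.0 * leaflet_offset
    n_arc = max(math.ceil(r_out * span / spacing), 4)
    n_y = max(math.ceil(Ly / spacing), 2)
    phi = np.linspace(-span / 2.0, span / 2.0, n_arc)
    y = (np.arange(n_y) + 0.5) * Ly / n_y
    zc = -r_in * math.cos(span / 2.0)
    coords = []
    for r in (r_in, r_out):
        x = r * np.sin(phi)
        z = zc + r * np.cos(phi)
        pts = np.repeat(np.column_stack([x, np.zeros_like(x), z]), n_y, axis=0)
        pts[:, 1] = np.tile(y, n_arc)
        coords.append(pts)
    coords = np.vstack(coords)
    if noise_sigma > 0:
        coords = coords + rng.normal(0.0, noise_sigma, coords.shape)
    x_span = 2.0 * r_out * math.sin(span / 2.0)
    coords[:, 0] += x_span / 2.0 + 2.0  # keep coordinates positive
    box = np.array([x_span + 4.0, Ly, coords[:, 2].max() + 5.0])
    roles = np.array([ROLE_MEMBRANE] * len(coords), dtype=object)
    return LabeledFrame(coords, roles, box)


def make_flat_sheet(
    Lx: float = 34.0,
    Ly: float = 15.0,
    spacing: float = 0.8,
    noise_sigma: float = 0.3,
    seed: int = 0,
    leaflet_offset: float = 2.0,
) -> LabeledFrame:
    """Flat bilayer sheet (degenerate, infinite-radius case)."""
    rng = np.random.default_rng(seed)
    n_x = math.ceil(Lx / spacing)
    n_y = math.ceil(Ly / spacing)
    x = (np.arange(n_x) + 0.5) * Lx / n_x
    y = (np.arange(n_y) + 0.5) * Ly / n_y
    X, Y = np.meshgrid(x, y, indexing="ij")
    coords = []
    for z in (leaflet_offset, -leaflet_offset):
        coords.append(np.column_stack([X.ravel(), Y.ravel(), np.full(X.size, z + leaflet_offset)]))
    coords = np.vstack(coords)
    if noise_sigma > 0:
        coords = coords + rng.normal(0.0, noise_sigma, coords.shape)
    roles = np.array([ROLE_MEMBRANE] * len(coords), dtype=object)
    return LabeledFrame(coords, roles, np.array([Lx, Ly, 4.0 * leaflet_offset + 5.0]))


def make_conformer_ensemble(
    n_frames: int,
    base_radius: float,
    radius_sigma: float = 0.0,
    jitter_sigma: float = 0.0,
    seed: int = 0,
    chord: float = 14.0,
    width: float = 3.0,
    n_beads: int = 15,
):
    """Banana-protein conformer ensemble with known per-frame radii.

    Per-frame arc radius is lognormal with median ``base_radius`` and
    linear-scale spread ~``radius_sigma``; each bead additionally gets
    isotropic Gaussian jitter.  Returns ``(coords, radii)`` with coords of
    shape (n_frames, 2 * n_beads, 3): the canonical arc lies in the x–z
    plane (chord along x, bending in z) with two rows ``width`` apart in y.
    """
    if base_radius <= 0:
        raise ConfigError("base_radius must be positive")
    if chord > 2.0 * base_radius:
        raise ConfigError("chord cannot exceed the arc diameter")
    rng = np.random.default_rng(seed)
    sigma_log = radius_sigma / base_radius
    radii = base_radius * np.exp(rng.normal(0.0, sigma_log, n_frames)) if sigma_log > 0 else np.full(
        n_frames, base_radius
    )
    frames = np.empty((n_frames, 2 * n_beads, 3))
    for f, R in enumerate(radii):
        alpha = math.asin(min(chord / (2.0 * R), 1.0))
        phi = np.linspace(-alpha, alpha, n_beads)
        arc = np.column_stack([R * np.sin(phi), np.zeros(n_beads), R * (1.0 - np.cos(phi))])
        beads = np.vstack([arc + [0, width / 2, 0], arc - [0, width / 2, 0]])
        if jitter_sigma > 0:
            beads = beads + rng.normal(0.0, jitter_sigma, beads.shape)
        frames[f] = beads
    return frames, radii
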