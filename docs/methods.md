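# Methods

## The buckled-membrane assay

A bilayer patch compressed laterally by γ = (L − L_x)/L buckles into the
zero-temperature Euler elastica.  We use the closed form in Jacobi elliptic
functions with the *parameter* convention throughout (m = k², matching
scipy's `m` argument):

- x(s) = 2λ E[am(s/λ, m), m] − s,  z(s) = 2λ√m (1 − cn(s/λ, m))
- ψ(s) = 2 arcsin(√m sn(s/λ, m)),  C(s) = dψ/ds = √(2(cos ψ − (1 − 2m)))/λ
- m solves L_x/L = 2E[m]/K[m] − 1;  λ = L/4K[m]

The exact inversion of the projection relation is the default route to m
(bracketed Brent on m ∈ (10⁻¹², 1 − 10⁻¹²), residual < 10⁻¹⁰); the
four-term weak-compression series is retained as an independent cross-check
and agrees to 4×10⁻⁸ at γ = 0.1.  C(s) vanishes at the inflections
s = L/4, 3L/4 and peaks at the crest, C_max = 2√m/λ.  An inclusion whose
long axis makes an in-plane angle θ with the buckling direction feels
C(s, θ) = C(s) cos²θ (the transverse principal curvature is zero); its
radius of curvature R = 1/C is reported as infinite below a floor of
10⁻⁶ nm⁻¹ (e.g. exactly at θ = 90°).

**Choice of scale.** The compression ratio fixes only the *shape*; the
absolute scale requires the period arc length L, which is not derivable
from γ.  All defaults assume L = 37.8 nm (projected box L_x ≈ 34 nm,
a typical coarse-grained buckled-patch size); with it the tightest radius
on the surface is 9.3 nm and the crest height 7.4 nm.  Quantities quoted in
nm therefore inherit this assumption; dimensionless results (s_norm, θ,
free-energy differences in k_BT) do not, apart from the binning of R.

A numerical note: scipy's `ellipeinc` (cephes) returns results off by
O(0.1) at isolated, one-ULP-specific arguments, which is fatal for root
finding on x(s).  The incomplete integral is therefore evaluated through
the Carlson symmetric forms `elliprf`/`elliprd` after reduction modulo π.

## Mapping snapshots to (s_norm, θ)

Alignment follows the operational recipe of centering the buckle crest:
x is wrapped into one period, membrane head beads are binned in x
(50 bins), and the crest is located from the bin-mean height profile —
refined as the height-weighted circular centroid of the beads, which is
exact for the x-symmetric elastica and immune to the two-leaflet grid
aliasing that makes the raw binned mode jitter by 2–3 bins.  The frame is
shifted so the crest sits at the analytic crest (s = L/2) and the height
offset is removed.

The protein's position is the unweighted mean of its backbone beads
(coarse-grained backbone beads are near-uniform in mass), computed after
reconstructing a contiguous molecule across periodic boundaries.
Unwrapping uses the largest-cyclic-gap rule per periodic axis — valid for
any molecule smaller than one box period, whereas min-imaging around a
reference bead fails once a molecule spans half the box (a 14-nm protein
in a 17-nm-deep box does, at θ near 90°).  s is obtained by inverting the
monotone x(s) — a dense precomputed table seeds two Newton steps on the
exact profile (x′ = cos ψ > 0), accurate to ~10⁻¹⁵ L.  Orientation is the
first principal axis of the backbone covariance, projected on x–y and
folded into [0°, 90°] (the axis is orientationless and C depends on
cos²θ).  Per-frame failures are skipped with a warning; a run with more
than 20% failures is rejected.

## Free energy over curvature

The placement ensemble is histogrammed over R(s, θ) into log-spaced bins
(24 bins, 10–200 nm) plus an overflow bin that also collects the
infinite-R sentinel; samples tighter than the first edge (possible because
the surface reaches R ≈ 9.3 nm) are clipped into the first bin.  The
profile is

F(R) = −ln[ P_obs(R) / P_geom(R) ]   (k_BT),

where P_geom is the geometric density of states — the same histogram taken
over a uniform 2000 × 900 (s, θ) grid.  Without this correction a
non-interacting ensemble is *not* flat (different curvatures occupy very
different amounts of surface), so the correction is the default and the
uniform-ensemble null test is the first gate of any analysis; the raw
−ln P_obs mode is available behind a flag for comparison with analyses
that skip it.  Empty bins are masked (NaN), never zero.  The zero of
energy is the largest-R populated bin — the flat-membrane stand-in —
and ΔG_bind(R_bind) interpolates linearly between the geometric bin
centres.  Only counting statistics are propagated; no reweighting.

## Synthetic data and what it does (not) establish

Every input is generated with known ground truth:

- **Buckled sheets**: head beads on an (s, y) grid (0.8 nm spacing, a
  lipid-headgroup scale), two leaflets offset ±2 nm along the local
  normal, isotropic Gaussian noise of σ = 0.3 nm emulating thermal
  roughness.  Sheet depth defaults to 17 nm — deep enough that the
  protein's periodic images never touch and period-unwrapping stays
  well-posed, while keeping frames cheap.
- **Protein**: a circular-arc bead chain (radius 25 nm, chord 14 nm, 15
  beads) in two rows 3 nm apart — an F-BAR-dimer-like footprint.  The
  lateral width matters: it makes the bending plane the (1st, 3rd)
  principal-axes plane, as the side-view projection assumes.  Placement
  targets are *operational*: θ is the in-plane angle the orientation
  measurement returns, and the anchor point is fixed-point-adjusted so the
  measured (COM-mapped) s_norm equals the target despite the COM riding
  ~0.8 nm above the surface.
- **Boltzmann ensembles**: Metropolis over (s, θ) with U(C(s, θ)); either
  a step well (−w over an R window, default 17–33 nm — the flat membrane
  is exactly the energy zero) or a harmonic well in C scaled so flat sits
  w above the minimum.  Local uniform proposals (Δs = 0.02 L, Δθ = 5°)
  auto-tune to 30–50% acceptance; 10× thinning; with w = 0 an
  independence proposal makes the null ensemble exactly i.i.d. uniform.
- **Bent/flat sheets and conformer ensembles** with stored truth for the
  circle-fit and RMSD/RMSF metrics; the bent sheet's `radius` refers to
  the innermost (concave-side) leaflet, the quantity the fit estimates.

Passing tests therefore establish that the *analysis machinery* is
unbiased under its own assumptions — a static analytic buckle, rigid
protein, isotropic noise.  They do not establish robustness to membrane
shape fluctuations, protein flexibility, lipid-specific effects, or
membrane deformation by the bound protein, none of which the generator
emulates.

## Circle fits and shape metrics

The circle fit is the algebraic Kåsa solution (linear normal equations —
deterministic, no initial guess) refined by a short Gauss–Newton descent
on the radial residuals.  The refinement matters: plain Kåsa
underestimates a 30°, R = 100 nm arc at σ = 0.3 nm noise by ~8%, while the
refined estimator is unbiased to well under 1% (per-fit scatter is then
information-limited, ~2 nm for that arc).  Fits with radius > 10⁴ nm, or
whose residual is not decisively below that of a straight line through
the bilayer midsurface, report a "flat" sentinel rather than a number.
The innermost leaflet is selected per frame as the beads radially inside
the midsurface circle (bin-mean height profile).  RMSD uses Kabsch
superposition; RMSF superposes all frames to the iteratively converged
mean structure (5 iterations) — note superposition absorbs 6 rigid-body
degrees of freedom, so an all-site isotropic jitter σ appears as
σ√3·√(1 − 6/3N), not σ√3 exactly.  The protein's side-view radius projects
the backbone onto its (1st, 3rd) principal-axes plane before fitting.

## Tube coverage

f_tube(R) = k_c/(2R²) is the Helfrich bending cost per area of a cylinder
(no spontaneous curvature, no tension); ρ = f_tube(R_bind)/|ΔG_bind| is
the areal protein density whose binding free energy pays that cost, and
1/ρ the area claimed per protein.  Everything is in k_BT, so temperature
never appears explicitly; k_c defaults to 20 k_BT, typical of fluid
bilayers.  With R_bind = 25 nm and ΔG_bind = −2 k_BT this gives
ρ = 0.008 nm⁻² (125 nm² per protein).  The estimate ignores
protein–protein interactions and treats ΔG_bind as coverage-independent.

## Problem sizes

The null test and each well-depth recovery use 10⁵ Monte-Carlo samples
(every sample rendered to a ~2500-bead frame and mapped back); the
occupancy-mode check uses 3×10⁴; circle-fit recovery uses 50 noise seeds
per radius.  The analysis drivers default to 2×10⁴ samples, which already
pins ΔG_bind to a few times 10⁻² k_BT.

## Known limitations

- The buckle is the zero-temperature elastica; thermally fluctuating
  shapes (and any feedback of the protein on the membrane) are out of
  scope.
- ΔG_bind from a step-well ensemble is exact by construction; for smooth
  wells the overflow (flat-reference) bin averages over residual curvature
  between R = 200 nm and flat, which can bias the reference by ~0.1 w for
  a harmonic well — one reason the depth-recovery conditions use the step
  model.
- File formats cover fixed-column GRO/PDB and a role-labelled XYZ table;
  binary trajectories (XTC/TRR/DCD) are a documented extension point.
- s_norm and θ are well-defined only while the protein stays on the
  membrane; desorbed frames fail mapping and are skipped.
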