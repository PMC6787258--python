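# bucklesense

Analysis pipeline for **membrane-curvature sensing and induction by
banana-shaped (F-BAR) proteins**, built around the buckled-membrane assay:
a laterally compressed bilayer adopts the Euler-elastica arch, presenting a
continuum of curvatures on a single surface, and where a curved protein
chooses to sit — and how it orients — reads out its curvature preference.

## The model

A tensionless bilayer compressed by a ratio γ = (L − L<sub>x</sub>)/L along
x buckles into the elastica

```
x(s) = 2λ E[am(s/λ, m), m] − s
z(s) = 2λ √m (1 − cn(s/λ, m))
```

with arc length s, elliptic parameter m fixed by
L<sub>x</sub>/L = 2E[m]/K[m] − 1 (or the weak-compression series
m = γ − γ²/8 − γ³/32 − 11γ⁴/1024), and characteristic length λ = L/4K[m].
The local curvature is C(s) = dψ/ds = √(2(cos ψ − (1 − 2m)))/λ, where
ψ(s) = 2 sin⁻¹(√m · sn(s/λ, m)) is the tangent angle.  An elongated protein
at normalized arc position s_norm = s/L whose long axis makes an in-plane
angle θ with the buckling direction feels

```
C(s, θ) = C(s) cos²θ           R(s, θ) = 1 / C(s, θ)
```

The pipeline maps bead-coordinate snapshots (membrane head beads + protein
backbone beads) to (s_norm, θ), histograms the ensemble, and inverts it by
Boltzmann inversion with a density-of-states correction into a free-energy
profile F(R) in k<sub>B</sub>T.  The binding free energy ΔG_bind = F(R_bind)
relative to a flat membrane feeds the elastic tube-coverage estimate

```
f_tube(R) = k_c / (2R²)        ρ = f_tube(R_bind) / |ΔG_bind|
```

A Kåsa + Gauss–Newton circle fit measures induced curvature of bent sheets
and the side-view radius of curvature of the protein itself; RMSD/RMSF
round out the model-validation metrics.

## Worked example

Everything runs on synthetic data with known ground truth — no simulation
output is required.  The numbered drivers under `analysis/` run the whole
study and write tables under `results/`:

```bash
python analysis/01_buckle_geometry.py
python analysis/02_curvature_sensing.py
python analysis/03_membrane_bending.py
python analysis/04_protein_shape.py
python analysis/05_tube_coverage.py
```

`01` prints the buckle parameters at 10% compression (period L = 37.8 nm
assumed):

```
m (exact inversion)      : 0.09871763
m (four-term series)     : 0.09871768  (diff +4.33e-08)
Lx/L from series m       : 0.900000  (target 0.9)
characteristic length    : 5.863 nm
crest height             : 7.368 nm
tightest surface radius  : 9.33 nm (crest, theta=0)
```

`02` draws 20 000 Monte-Carlo placements from a step binding well of
2 k<sub>B</sub>T over the 17–33 nm radius band, renders every sample into a
full bead frame, maps the frames back, and recovers the imposed well:

```
mapped 20000 frames; mean |s_norm error| 0.0006
recovered dG_bind(25 nm) = -1.986 k_BT (imposed -2.0)
occupancy mode sits at R = 22.9 nm
```

`05` then turns that measured ΔG_bind into the coverage needed to
stabilize a 25-nm tube against a bending rigidity of 20 k<sub>B</sub>T:

```
bending cost f_tube = 0.0160 k_BT/nm^2
required density rho = 0.0081 nm^-2 -> one protein per 124 nm^2
```

i.e. roughly one protein per 125 nm² of tube surface — dense coverage.

The same machinery is exposed as a CLI (`bucklesense generate / sense /
bend / theory`), e.g.

```bash
bucklesense theory --kc 20 --r-bind 25 --dg -2
```

prints the closed-form record with ρ = 0.008 nm⁻² and 125 nm² per protein.

## Layout

- `src/bucklesense/` — library: `buckle_geometry`, `trajectory_mapping`,
  `curvature_stats`, `shape_fitting`, `tube_theory`, `synthetic_data`,
  `cli_io`, `cli`.
- `analysis/` — numbered drivers reproducing the study, one stage each.
- `docs/methods.md` — model, assumptions, parameter choices, limitations.
- `tests/` — unit, property and end-to-end acceptance tests.
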