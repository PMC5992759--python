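# Methods

This note records the physical model behind `alphamicro`, the defaults
and why they were chosen, what the synthetic generators do and do not
emulate, and the numerical choices that matter. Every number quoted here
is produced by the package's own tests or scripts.

## Transport physics

Alpha particles are transported in the continuous-slowing-down
approximation (CSDA): the particle follows a straight line and loses
energy at the local linear energy transfer (LET), with no energy-loss
straggling, angular scattering, delta-ray escape or nuclear recoil. For
chord-times-LET dosimetry in micrometre targets these omissions are
second-order: straggling blurs the end of the ~40 µm Am-241 track by a
fraction of a micrometre, and delta-ray ranges at these energies are
well below the nucleus size.

The embedded LET table (`alphamicro/data/alpha_water_let.tsv`,
10 keV – 25 MeV) is generated once from an ICRU-49-style proton
electronic-stopping table for liquid water, joined to Bethe theory above
~1 MeV/u and scaled to helium with the ZBL effective-charge
parametrization; its header documents the construction. Spot checks in
the test suite hold it within 2% of published tabulated values
(e.g. ~85 keV/µm at 5486 keV), and the CSDA range at 5486 keV comes out
at 42.1 µm. Interpolation between knots is log-log linear. Residual
energies are evaluated through a pre-integrated range–energy relation
`E_out = R⁻¹(R(E_in) − s)` on a 6000-point log grid, which makes the
composition law `residual(E, a+b) = residual(residual(E, a), b)` and the
energy-balance identity hold to interpolation accuracy (~1e-6 relative;
the fine-step oracle in the tests agrees to 0.1%). Below a 10 keV cutoff
the particle deposits its remaining energy locally; the residual range
there is far below one voxel.

Mylar is modelled as scaled water: a path `t` of foil slows the particle
like `1.2 t` of water (density 1400 kg/m³ recorded but unused beyond the
record). The foil is only 1.4 µm thick, so the water-equivalence factor —
configurable on `MaterialModel` — moves entry energies by tens of keV at
most. Cytoplasm, nucleus and culture medium are all water at 1000 kg/m³.

## Track fields and the synthetic collimated source

A track is stored as entry point at the top of the mylar foil, unit
direction (+z into the cells) and energy on arrival. The synthetic
generator emulates a collimated Am-241 irradiation: entries uniform over
a square field, azimuth uniform, polar angle uniform in solid angle
within a 45° cone, and energies from a truncated normal with mean
4500 keV and SD 200 keV. The mean reflects the degradation of the
5486 keV emission over a ~5 mm air gap plus source self-absorption; the
SD stands in for the combination of spectrum width and ~100–200 keV
detector energy resolution. The true post-air spectrum of such a setup
is measured, not published, so both numbers are explicit `EnergyLaw`
parameters. What the generator does *not* emulate: spatial correlations
from collimator walls, fluence non-uniformity at the field edge, and
track-reconstruction failures (the rim filter exists for real data,
where tracks ending within 1 µm of the read-out volume boundary carry
unreliable energies).

`total_dose` defines the field's absorbed dose `D_total` as the energy
deposited by all tracks in an 8 µm water layer (a typical adherent-cell
height) above the foil, divided by the layer mass. For one vertical
5486 keV track on 100×100 µm² this reproduces the closed single-chord
computation in the tests to 0.2%.

## Cell geometries and ray traversal

Label volumes are 8-bit stacks with values 0/182/201 for
background/cytoplasm/nucleus, voxel sizes given as (x, y, z) in nm, and
a world origin in µm; the world position of a voxel's centre is
`origin + (index + 0.5)·voxel_size`. Traversal is an exact
boundary-crossing walk (all plane crossings of the ray with the three
axis grids, sorted), handling anisotropic voxels without resampling;
100 random rays per test run agree with a 1 nm point-sampling oracle to
within one voxel diagonal. Deposits in the nucleus are accumulated
segment by segment with the range–energy relation, so interleaved
cytoplasm/background gaps slow the particle correctly.

The synthetic cell is an ellipsoidal nucleus inside an ellipsoidal
cytoplasm margin on a 96×96×430 nm grid. The default monolayer nucleus
(semi-axes 7×7×3.6 µm, 739 µm³) matches the measured mean U87 nucleus
volume of 740 µm³ while staying inside the 8 µm cell height — adherent
glioblastoma cells are flattened, and the flattening matters: it sets
the chord-length distribution of near-vertical tracks. Voxelization
recovers analytic ellipsoid volumes within the one-voxel surface-shell
bound (≲2%).

The one-voxel segmentation-uncertainty estimate reduces the nucleus to
an equal-volume sphere whose radius r is measured in
isotropic-equivalent voxels (edge = cube root of the voxel volume) and
returns the shell fraction `3/r + 3/r² + 1/r³`. For a 1.87e5-voxel
nucleus this gives r ≈ 35.5 and ≈ 8.7%. A published account of the same
estimate quotes r = 39 and 5.1%, which is not reproducible from any
closed form we know (at r = 39 the shell formula gives 7.7%); the
package keeps the standard closed form.

## Dose distributions

`DoseDistribution` is a uniform-grid density with an explicit point mass
at z = 0. Convolution arithmetic treats bin centres as a lattice; sums
of i centres sit at `(m + i/2)Δz`, so i-fold convolutions are re-aligned
to the centre lattice exactly for odd i and by a mean-preserving
half/half split for even i. `analytic_ndd` accumulates
`Σ p(i, λ) f^i` in the frequency domain with the Poisson truncation
order chosen so the neglected tail is < 1e-9; normalization holds to
1e-6 and the mean to 0.1% (property-tested over random spectra). For
λ beyond ~400 expected hits it switches to the closed-form
characteristic function `exp(λ(F−1))` on a point lattice — the regime
where the order-by-order sum is pointless and the half-bin smoothing of
the lattice split is far below the distribution's width.

`mc_ndd` implements field resampling: per repetition the cell sits at
one of `placements` (default 64) random lateral offsets and
`N = round(z̄/D_total · N_total)` tracks are drawn with replacement
(a flag switches N to Poisson resampling). Two facts matter when
comparing it with `analytic_ndd`:

* the layer dose and the nucleus mean dose differ by a few percent for a
  flattened cell, so the two routes' λ differ by the same factor at
  equal nominal z̄ — the self-consistency test therefore compares at matched
  hit intensity, where the Kolmogorov distance at 50,000 repetitions is
  ~0.004;
* with a *finite* measured field the per-placement hit rate varies
  (relative SD ≈ `sqrt((1−h)/(n_tracks·h))`), and because all N draws of
  a repetition share one placement this correlation survives averaging
  over placements. It is a real property of dose-scaled track resampling,
  visible as a slightly inflated zero-dose mass for sparse fields.

## Survival and the α_z calibration

Survival is exponential only; the quadratic term is deliberately
omitted, appropriate for high-LET radiation at ≤1 Gy. `fit_alpha_d` is
the least-squares slope of `ln S` through the origin. `fit_alpha_z`
minimizes the calibration objective by bounded scalar search on
`[α_D, 20 α_D]` (xatol 1e-10), with NDDs cached per dose since they do
not depend on α_z; survival is floored at 1e-300 before the log. The
uncertainty propagates σ(α_D) through a central-difference
`dα_z/dα_D`. Degenerate (point-mass) spectra recover the closed-form
fixed point `(1 − e^{−α_z q})/q = α_D` to 1e-6, round trips recover a
generating α_z to 0.1%, and α_z ≥ α_D holds on randomized spectra.

## The virtual spheroid

Cells are spheres on an HCP lattice (ABAB layering, nearest-neighbour
distance `2 R_eff`); shrinking the geometric radius to
`R_eff = η^(1/3) R_cell` with η = 0.740 removes the packing voids, so
the medium is water everywhere and the nuclei are disjoint spheres of
radius r_n at the lattice sites. Emissions start at the full emission
energy (default 5486 keV) from scenario-defined origins — uniform inside
a random nucleus, uniform in the inter-nucleus space, on a random
nucleus surface, or on a random sphere of radius R_eff — with isotropic
directions, drawn only within a ball of radius `range + 2 R_eff` around
the centre (farther decays cannot reach the centre cell; the truncation
is exact, not approximate). Scoring uses analytic line–sphere chords for
the centre nucleus and the centre cytoplasm shell (between r_n and
R_eff); cytoplasm dose is scored for *every* emission, while the run
length is set by nucleus hits (20,000 by default, giving a relative
standard error of the mean nucleus dose below 1%). A `uniform` control
scenario (decays everywhere) must and does give a dose ratio of 1.

**Cell size.** The nucleus volume is a measured 740 µm³; the whole-cell
volume is not directly measured. The default nucleus-to-cell volume
fraction of 0.10 (R_cell ≈ 12.1 µm) is fixed from the stated
correspondence between particle ranges of 10–20 cell radii and emission
energies of 10–16 MeV, which brackets R_cell between 11.1 and 12.3 µm
given the range table. The fraction is an explicit config parameter; the
test suite sweeps 0.08–0.14 and verifies that the scenario
ordering (in-nucleus > nuclear-membrane > 1 > cytoplasm ≈ cell-membrane)
is invariant across it.

**LET bookkeeping.** Two averages are reported. `avg_let` is the
per-particle mean: the LET of each hitting particle at nucleus entry,
averaged over hits — the natural "average LET of the particles in the
nucleus" and the quantity comparable to published per-scenario LET
tables (~103/129/112/131 keV/µm for
in-nucleus/cytoplasm/nuclear-membrane/cell-membrane at the defaults).
`avg_let_deposit_weighted` weights the LET along each chord by the
energy deposited (computed exactly via `∫LET dE` lookups); track-end
deposits pull it ~25 keV/µm higher. Both are exact under CSDA, they
simply answer different questions.

**Relative effectiveness.** The scenario's expected survival versus
absorbed dose D uses the scenario's own single-hit spectrum with mean
nucleus dose `D × dose_ratio`, i.e. the absorbed dose is referenced to
the cytoplasm/medium dose; the fitted slope is divided by the external
reference slope (α_D = 1.66 Gy⁻¹, with α_z = 1.92 Gy⁻¹ in the
exponent — both consumed as constants, since the underlying survival
data points are not available to re-derive them). Because compound-
Poisson survival is exactly exponential in D, the fitted slope is
independent of the dose grid. With spherical 740 µm³ nuclei the
nuclear-membrane scenario's slope ratio converges to ~1.19, about 10%
below the published 1.33: the published effectiveness row implies
single-hit means of ~0.09 Gy, smaller than an isotropic-flux chord
through a 740 µm³ sphere can produce (mean chord 7.5 µm × ~95 keV/µm ≈
0.15 Gy), suggesting it was computed with the measured, flattened
monolayer cell spectra rather than the virtual spherical ones. The
package reports what its own geometry gives.

## Problem sizes

Defaults were sized so a full test run stays comfortably interactive on
one CPU: single-hit matrices use 1,200–8,000 tracks × 8–64 placements,
the resampling comparison 50,000 repetitions, Am-241 scenarios 20,000
centre-nucleus hits (a few seconds each, fully vectorized), the energy
sweep 1,500 hits per (scenario, energy) pair up to 20 MeV, and the
acceptance script 150,000 hits per reported quantity (~15 s total).

## Known limitations

* No straggling, scattering, delta rays or recoiling daughter nuclides;
  dose is deterministic along each chord.
* The stopping table is a reconstructed tabulation, accurate to a few
  percent in absolute LET; all derived quantities inherit that scale.
* Spheroid cells are perfect spheres with concentric nuclei; real U87
  nuclei are neither spherical nor concentric, which mostly affects the
  single-hit spectrum width and the effectiveness slopes (see above).
* The synthetic energy spectrum and cell-height parameters stand in for
  unpublished measured distributions; conclusions that hinge on the
  exact spectrum shape should be re-run with measured track lists.
* Segmentation and refractive-index corrections are upstream concerns:
  label volumes are consumed as given.
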