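# Methods

This note records the models, conventions and numerical choices behind
`cryocdi`, and what the synthetic-data tests do and do not demonstrate.

## Geometry and conventions

The experiment is parameterized by photon energy E (keV; wavelength
λ[Å] = 12.398/E), camera length r (m), pixel pitch p (µm) and an even
detector side N. The real-space sampling of any reconstruction is
Δx = λr/(Np) — 28.9 nm for the production values (8 keV, 5.29 m, 55 µm,
516 px) — and the field of view is NΔx. Axes are (X, Y) in the detector
plane and Z along the beam at 0° tilt; the tilt axis is Y; all cubic grids
are 0-indexed with the zero-frequency / rotation-centre voxel at index N/2.
Fourier arrays are kept in this centered frame everywhere; conversion to
wrap-around order happens only inside FFT calls.

Physical constants: r_e = 2.8179×10⁻¹⁵ m, 1 keV = 1.602177×10⁻¹⁶ J,
u = 1.66054×10⁻²⁴ g, M/N_e = 1.88 u per electron for protein-like
composition. Four-digit values are deliberate: the published quantities are
printed to 3 significant digits and reproduce within 1–2%.

## Phantom generator

The phantom emulates a tachyzoite-like cell: a prolate ellipsoid (semi-axes
a ≥ b ≥ c, long axis X) sheared so its centerline follows a parabolic arc —
the bend parameter is sagitta/length, default 0.15. The shear is volume
preserving, so organelle volume fractions equal the ratios of the analytic
ellipsoid volumes exactly. The default organelle set spans 1.7%–13.1% of
the cell volume (nucleus mid-posterior, an elongated dense bundle and
smaller tubular bodies toward the apical +X end, an apical tip), with
density contrasts 0.6–1.0 over the cytoplasm. Optional extras:

- `texture_amplitude` — seeded, Gaussian-correlated (σ = 2 voxels)
  multiplicative density texture inside the cell, default 5% RMS in the
  pipeline config;
- `edge_sigma_um` — Gaussian softening of all boundaries. Real membranes
  are not voxel-sharp, and a band-limited phantom is required wherever a
  Fourier-interpolation oracle is evaluated; the pipeline default is one
  voxel (30 nm).

`generate_phantom` refuses any cell whose bounding box (including the bend
excursion) leaves less than a quarter-grid margin per axis: this is the
linear-oversampling ≥ 2 condition that makes the simulated phase problem
well-posed. Generation is bit-reproducible for a fixed seed.

## Forward model

Projections are line integrals along Z after rotating the volume about Y.
The rotation uses the three-pass Fourier shear decomposition
R(θ) = S_x(−tan θ/2)·S_z(sin θ)·S_x(−tan θ/2), each shear applied as a 1D
FFT phase ramp: exact for periodic band-limited volumes and
mass-conserving to machine precision (valid for |θ| < 80° with the support
in the central half of the grid). Spline resampling
(`rotate_volume_y(..., method="spline")`) is retained for nonnegative
workflows; its ~10⁻³–10⁻² amplitude error at high tilt is what ruled it out
as the default.

Expected counts follow the absolute far-field scale
E[counts(q)] = I₀ r_e² ΔA/r² · |DFT(projection)|²(q), so the central pixel
obeys I(0) = I₀ r_e² N_e² ΔA/r². Poisson sampling, a circular beamstop
(default radius 6 px, scaled down for small grids), and a dead cross
(default 4 px) between the 2×2 detector modules are applied on top. The
Ewald sphere is treated as flat: at 8 keV and these scattering angles its
sagitta across the detector is far below one pixel, so each pattern is a
central plane of the 3D transform. Tilt angles follow equal-slope
tomography (equal increments of tan θ), with independent positive/negative
branch counts and maxima (37/+50.9°, 34/−60.6° by default, 72 angles with
0° included).

The oversampling guard on each simulated pattern measures the support
extent as the smallest interval containing 99.9% of the projection's
absolute mass, which ignores interpolation ringing tails while remaining
exact for compact nonnegative projections.

## Preprocessing

Background frames (beam only) are subtracted after an optional per-pixel
gain map, with a scalar scale (default the exposure ratio, 1 for equal
exposures); negative residuals are clipped to zero as pure noise.
Friedel symmetrization maps every pixel (i, j) to its mate
((N−i) mod N, (N−j) mod N): pairs both known are averaged, half-known pairs
are completed, unknown pairs stay unknown — idempotent, and the known set
only grows. Repeat 0° frames are compared with
R = Σ|√I₁ − γ√I₂| / Σ√I₁ (γ least-squares), which is ≈ 1/(2√N̄) for pure
Poisson noise at mean count N̄ and grows with genuine structural change.

## Fourier assembly

Known pattern pixels at centered detector coordinates (u, v) are deposited
at q = R(−θ)·(u, v, 0). Each Fourier voxel within the capture radius
(default 0.71 voxels) of one or more samples receives the inverse-distance
weighted mean (power 2); a sample within 10⁻⁶ voxels of a voxel centre
determines that voxel exactly (coincident hits are averaged). Voxels with
no sample in range are unknown: the missing wedge (tilt range < ±90°), the
beamstop cone and the module-gap shadows all live in this unknown set, and
are never invented by the gridder. Intensities, not amplitudes, are
interpolated; no density-compensation kernel is applied.

Accuracy: with the full 72-angle series the gridded volume matches the
direct 3D DFT intensity of a band-limited phantom to <5% relative L2 when
the linear oversampling is ~8 (speckle ≈ 8 voxels); the residual error is
the plain-IDW interpolation across speckles and is insensitive to adding
angles beyond ~36.

## Phase retrieval

One OSS iteration: (1) modulus projection — replace |F| by √I on known
voxels, keep phases, let unknown voxels float at their calculated values
(this float is what later *retrieves* the central-speckle intensity behind
the beamstop); (2) HIO — keep ρ′ inside the support, ρ − βρ′ outside
(β = 0.9); with positivity on (default), negative-ρ′ voxels inside the
support are treated like outside ones; (3) the out-of-support region is
replaced by its Gaussian-filtered version, W(k) = exp(−k²/2α²) with k the
centered frequency index in voxels. α steps down linearly over 10 equal
stages from N to N/10; at each stage boundary the lowest-R_rec iterate so
far is restored. Initial iterates are the inverse transform of the measured
moduli with uniform random phases, seeded per ensemble member through
`numpy` SeedSequence spawning (fully deterministic given one seed).

R_rec uses the least-squares scale γ = Σ|F_e||F_c| / Σ|F_c|², making the
residual invariant to the global density scale. Each member returns its
best-R iterate; members are sorted by final R, the best `keep_best` aligned
to the lowest-R member by integer-shift cross-correlation with the
centro-inversion (twin) ambiguity resolved by trying both orientations, and
averaged voxel-wise. Densities are reported clipped at zero (HIO leaves
small negative residue outside the support).

The two-stage protocol runs the ensemble with a centered half-grid cube,
thresholds the stage-1 average at 10% of its peak *within that cube* (so
the tight support is contained in the dilated cube by construction), keeps
the largest connected component, dilates by a 2-voxel ball, and repeats the
ensemble with this tight support. The reported `final_r` is the residual of
the averaged density itself against the data.

A property worth knowing: a single HIO/OSS step *raises* R_rec from a
modulus-consistent random start (whose R is low by construction) — the
residual drops only over tens-to-hundreds of iterations. Convergence is
therefore asserted on full runs, not single steps.

## Quantification

- **Dose**: D_p = (µ/ρ)·(P_t/A)·E with explicit unit conversions
  (cm²/g → 0.1 m²/kg, µm⁻² → 10¹² m⁻², keV → J). µ/ρ is a user input
  (9.9 cm²/g at 8 keV for cellular material by default). D_t = n·D_p.
- **Electron count**: N_e = √(I(0)·r² / (I₀·r_e²·ΔA)), the exact inverse of
  the forward model's central pixel. In a real (or simulated) reconstruction
  I(0) is taken from the γ-scaled calculated modulus at q = 0, since the
  measured centre is behind the beamstop. This extrapolated DC term is the
  least-constrained quantity in the pipeline: at desk scale (small grids,
  generous tight support) it can overshoot by tens of percent, which the
  worked example in the README shows honestly.
- **Mass density**: ρ_m = 1.88·N_e·u / V, with V from the 10%-of-peak
  threshold segmentation (largest connected component).
- **Oversampling ratios**: O_axis = λr/(p·D_axis); a warning is emitted
  below 2.
- **PRTF**: |⟨F_k⟩|/√I_meas per voxel, capped at 1, averaged over integer
  radius shells; shells with no measured voxel (beamstop) are excluded from
  the threshold scan. Resolution is the full period at the outermost shell
  before the curve first drops below the threshold (default 0.5), flagged
  when the curve never drops (band edge). With only two averaged members
  the PRTF is an optimistic estimator; it sharpens as the ensemble grows.
- **Line scans**: the 10–90% rise distance of the steepest edge of a 1D
  profile, with sub-voxel crossings by linear interpolation and a floor of
  one voxel; an edge is rejected when its contrast is under 3× the
  profile's high-frequency noise estimate.

## What the synthetic tests show — and what they do not

The generator reproduces the acquisition's statistical structure: compact
positive density, polarized organelles, absolute photon scale, Poisson
noise, asymmetric EST tilt range, beamstop and module gaps. It does not
model substrate/ice background texture beyond a flat level, detector
nonlinearity, partial coherence, drift, or radiation damage. Passing tests
therefore validate the *algorithms* under the stated physics, not
performance on any particular beamline's systematics.

Desk-scale problem sizes are used throughout: 16³–32³ grids for phase
retrieval (500 iterations × 5 seeds for the noiseless recovery check —
Pearson r ≥ 0.95 over the support, R_rec < 0.05), 64³ for the
Fourier-slice gridding oracle, 32³ with experiment-like counting noise
(landing at R_rec ≈ 0.22–0.25, the regime the production data reported) for
the missing-wedge anisotropy check. The production 601³ array runs through
the identical code path; it is simply a larger grid.

Known limitations: the missing-wedge anisotropy is largely *repaired* by
support+positivity constraints on noiseless compact objects — the Z/X
resolution gap becomes measurable only in the noisy regime; the DC
extrapolation bias discussed above; and plain IDW gridding saturates at a
few percent intensity error regardless of angular sampling (a
density-compensated kernel would fix this but is deliberately out of
scope — the method under study used plain inverse-distance weighting).
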