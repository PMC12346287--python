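# Methods

This note records the physical models, numerical choices and known
limitations behind `fsodt`, in the spirit of a methods supplement.

## Coordinate and Fourier conventions

All 2-vectors are `(y, x)` ordered to match numpy array axes; DMD mirror
indices are 0-based `(row, col)`. Lengths are in µm, spatial frequencies in
cycles/µm, time in s. Fields are sampled on even-sized grids; spatial
frequencies use `fftfreq` ordering internally. The axial wavenumber of a
transverse frequency `f` in a medium of index `n₀` is
`k_z = 2π·sqrt((n₀/λ)² − |f|²)`; components beyond the propagating band are
evanescent.

Plane waves are phase-referenced so that the axial phase vanishes in the
plane through the volume center (`z = 0`); measured fields are taken in
that plane (the focal plane) and refocused to the volume exit plane for
the iterative solver with the homogeneous angular-spectrum transfer.

## DMD pattern synthesis

The spot→beam map is `δr = (fl·λ/M)(f_p − f_c)`,
`f = (M/(fl·λ))(r_p − r_c)`. The printed form of this relation is
typographically ambiguous about the fraction placement; the form above is
fixed by dimensional analysis (`fl·λ/M` has units of µm², turning a DMD
frequency shift into a sample-plane offset) and is exactly invertible,
which the tests verify by round trip.

Mirrors are ON where the spot disc contains them and the thresholded
carrier `cos(2π f_p·r + φ) ≥ 0`. The DMD is modelled as an ideal binary
amplitude mask on a square grid; mirror-tilt/diamond-lattice diffraction
physics is out of scope. Overlapping spot discs are rejected by default
(they corrupt carrier purity); an OR-union mode exists for dense multiplex
rendering. Rendering full frames is opt-in (`render_frames=True`) since
most workflows only need the beam bookkeeping.

Angle sets use a sunflower (Fermat-spiral) layout, radius
`f_max·sqrt((i+½)/n)` at azimuth `i`·golden-angle: deterministic,
quasi-uniform (minimum pairwise spacing ≈ 0.8 of the hexagonal-packing
ideal), on-axis for `n = 1`.

Multiplex partitioning seeds each frame by farthest-point selection
(lowest index on ties), duplicates angles only to fill the last frame, and
refines with 5 sweeps of 300 random pairwise swaps, keeping a swap iff it
increases the mean within-frame pairwise DMD-plane distance capped at a
maximum value (distances are measured on the DMD face, where spot
separation is what limits demultiplexing). The cap defaults to 0.3× the
pupil radius: with a cap at the full pupil radius the capped average is
almost insensitive to a single near-coincident pair, and the optimizer
tolerates beam spacings far below the uniform ideal, which directly
collapses the demultiplexing region radius; a tighter cap saturates the
already-good pairs and concentrates the objective on the close ones
(measured minimum inter-carrier spacing at 19× improves from ≈ 0.15/µm to
≈ 0.30/µm against a 0.56/µm uniform ideal). The RNG is an explicit seeded
generator; accepted-swap loss is monotone by construction.

## Forward models

*Angular spectrum*: diagonal in the Fourier basis, `exp(i k_z d)` on
propagating components; evanescent components decay as `exp(−|k_z|·|d|)`
for either sign of `d`, so refocusing never amplifies noise.

*BPM*: symmetric split-step — half-step free-space propagation, phase
screen `exp(i k₀ (n − n₀) dz / cosθ)`, half-step — placing screens at
slice centers. `cosθ = 1` in plain mode; in obliquity mode it is the axial
direction cosine of the single dominant plane-wave component, and the
model refuses multiplexed input (the beams share no common obliquity
factor), directing users to the SSNP.

*SSNP*: evolves `(E, ∂E/∂z)` with the exact homogeneous 2×2 Fourier-domain
propagator `[[cos k_z dz, sin k_z dz / k_z], [−k_z sin k_z dz, cos k_z dz]]`
and a scattering kick `∂E/∂z ← ∂E/∂z − k₀²(n² − n₀²) dz E` at slice
centers (same symmetric splitting). The entrance state assumes a purely
forward-travelling incident field (`∂E/∂z = i k_z E`), consistent with
transmission geometry; the exit state is projected onto the forward
component `E₊ = (E + (i k_z)⁻¹ ∂E/∂z)/2`. For evanescent modes the exact
propagator contains divergent cosh/sinh terms; those modes are instead
damped exponentially on both state components, which leaves the
pupil-filtered observables unchanged (evanescent content never reaches the
detector) while keeping the scheme unconditionally stable.

Default slice thickness is the voxel pitch; a log warning fires when
`dz > λ/(4·Δn_max)`. Boundaries are periodic by default in this package's
reconstructions: synthetic illumination frequencies are snapped to the FFT
grid so plane waves are exactly periodic, and phantoms are kept away from
the lateral edges. A padded mode with raised-cosine apodization of the
scattering potential is available for scenes that approach the boundary;
it suppresses wrap-around scattering sources at the cost of edge fidelity
of the incident wave.

*Scalar Mie oracle*: the forward models are scalar, so the independent
sphere oracle solves the scalar Helmholtz problem exactly: partial-wave
coefficients `b_l = −(m j_l'(mx) j_l(x) − j_l(mx) j_l'(x)) /
(m j_l'(mx) h_l(x) − j_l(mx) h_l'(x))` from continuity of the field and
its radial derivative at the surface, series truncated at
`⌈x + 4x^{1/3} + 2⌉`. Bessel tables are built by stable vectorized
recurrences (upward for `y_l`; Miller's downward recurrence for `j_l`,
started above both `l_max` and the largest argument and anchored to
whichever of `j₀`, `j₁` is larger to avoid the zeros of `sin z / z`).
Internal consistency is checked against the optical theorem and the
weak-contrast (Born) limit. Multi-sphere scenes superpose single-scattering
fields — the oracle is for validation phantoms; dense media go through the
SSNP. Polarization is out of scope throughout.

## Holography

Synthetic holograms use a clean tilted plane-wave reference
`R = exp(−i2π f_ref·r)`, putting the signal sideband at `+f_ref`;
demodulation shifts that sideband to baseband and low-passes with a hard
disc window softened by a raised-cosine edge over 10 % of its radius to
limit ringing. Reference frequencies are chosen on the FFT grid with
`|f_ref| ≥ 3·f_b` (band separation) while keeping the conjugate sideband's
alias outside the signal band. When the camera grid is finer than the
reconstruction grid, demodulated fields are resampled by exact Fourier
cropping.

For dynamic samples the incident field is estimated as the complex time
average of the demodulated series (RI inhomogeneities of moving objects
average out); the residual temporal variance is logged, and a variance
near zero flags a static object contaminating the background.

Weighted phase unwrapping solves the weighted least-squares problem of
Ghiglia–Romero type with conjugate gradients preconditioned by the DCT
Poisson solver (Neumann boundaries), weights defaulting to the normalized
squared field amplitude, tolerance 1e−6, ≤ 50 iterations. The smooth LS
surface is then snapped back onto the input modulo 2π (global offset
removed by a weighted circular mean of the fractional residuals, so the
rounding never sits on a tie): the output is everywhere the input plus an
integer multiple of 2π, and smooth in-range inputs return unchanged.

## Linear reconstruction and demultiplexing

The Rytov datum of a view is `U = E₀,canon · ψ` with
`ψ = ln|E/E₀| + i·unwrap(arg E/E₀)` and `E₀,canon` the unit incident wave
phase-referenced at the volume center (the actual beam's amplitude, offset
and phase cancel in the ratio). The Fourier diffraction theorem then gives
`V̂(f − f_inc, f_z(f) − f_z(f_inc)) = −4πi f_z(f) Û(f)` on the Ewald cap,
gridded by nearest-voxel deposition with multiplicity counts; overlapping
cap contributions are averaged, missing-cone voxels stay at background (no
inpainting). A Born variant (`U = E₀,canon (E/E₀ − 1)`) is available;
Rytov is the default because it tolerates thick phantoms.

For an `M`-fold multiplexed frame, each beam's region is the set of
Fourier pixels nearer its carrier than any other (ties to the lowest
index), additionally capped by a disc of radius
`min(half minimum inter-carrier distance, detection band)` so regions are
isotropic. At `M = 1` the region is the whole band and the result is
*bitwise* classical Rytov ODT (tested against an independently coded
classical route). Beams closer than two frequency bins raise a
degenerate-partition error. Because the disc radius shrinks as `M` grows,
initializer resolution degrades monotonically with multiplexing — the
expected failure mode at extreme multiplexing.

## Iterative reconstruction

Data term `w_ps Σ|E_model − E_meas|² + w_pi Σ(|E_model| − |E_meas|)²`
summed per frame and averaged over frames; defaults `w_ps = 1, w_pi = 0`,
with `w_pi > 0` recommended when phase unwrapping of the initializer is
unreliable (the phase-insensitive term is invariant to global phase).
Gradients with respect to the complex index follow from a reverse slice
sweep applying the conjugate transpose of every linear step of the chosen
multislice model (orthonormal FFTs make every adjoint explicit); the SSNP
path differentiates through `V = k₀²(n² − n₀²)` by the chain rule. The
returned gradient `G` satisfies `dL = Re⟨G, dn⟩` and is validated against
central finite differences at 1e−4 and an inner-product adjoint identity.

The proximal step applies, in order: the isotropic 3D TV proximal operator
(delegated to `skimage.restoration.denoise_tv_chambolle`, applied to the
real and imaginary parts of `n − n₀` separately), complex soft
thresholding of `n − n₀`, then projection `Re(n) ← max(Re(n), n₀)`,
`Im(n) ← max(Im(n), 0)`. The composition approximates the joint prox of
the summed regularizers; the constraints hold exactly on every returned
iterate.

FISTA uses `t_{k+1} = (1 + sqrt(1 + 4t_k²))/2` momentum, a step size from
10 power iterations on the finite-difference Hessian at the initializer
(backtracking halves it if needed), adaptive restart whenever the
monitored composite objective (data term + TV/ℓ1 value) increases, and a
divergence abort at 10× the initial objective. The recorded history is
non-increasing by construction. Defaults: 50 iterations, relative-change
tolerance 1e−5, full-batch gradients.

## Synthetic data

The generators emulate the experimental regimes the analysis targets:
1-µm polystyrene beads (`n = 1.57`) in water (`n₀ = 1.333`) or
water–glycerol (≈ 1.41), chambers of 10–120 µm, 785-nm illumination.
Brownian dynamics use Euler–Maruyama steps with per-axis variance
`2 D(h) dt`. The wall-hindrance law `D(h) = D₀(1 − (9/16) R/h)` is the
leading-order parallel result; the same form is applied axially as a
documented simplification (the true perpendicular correction is stronger).
With hindrance on, the axial update includes the Itô spurious-drift term
`dD/dh·dt` so the stationary distribution remains Boltzmann. Sedimentation
adds drift `−D/l_g` with `l_g = k_B T/(m g)` and
`m = (4/3)πR³(ρ_bead − ρ_solvent)`; walls reflect at one radius from the
coverslip and chamber top, and gravity-on scenes start from the stationary
truncated-exponential height distribution (a settled sample). Swimmers are
rods (cylinders with hemispherical caps) translating along a smoothly
wandering velocity direction while the body axis precesses about it at the
prescribed wobble angle.

Hologram rendering superposes each frame's beams, scatters them with the
Mie superposition (sparse sphere scenes) or the SSNP through the
rasterized volume, applies the detection pupil, refocuses to the volume
center, interferes with the tilted reference, and adds Poisson shot noise
at a stated photon budget per unit-intensity pixel plus Gaussian read
noise. Everything is bit-reproducible from the integer seed.

What the generators do *not* emulate: speckle and DMD diffraction
artifacts, aberrations and index mismatch at the coverslip,
inter-particle hydrodynamic coupling, flagellar dynamics, camera fixed
-pattern noise. Passing tests therefore demonstrate algorithmic
correctness and statistical calibration on idealized data, not robustness
to those instrument effects.

## Tracking and statistics

Localization: DoG filter with sigmas (0.5×, 1.5×) the expected radius,
maximum filter, threshold, then a 3D Gaussian least-squares fit in a
4 × 2 × 2 µm ROI; fits are kept when widths lie within (0.3, 3)× the
expected per-axis sigma, with the axial expectation inflated 3× for the
missing-cone elongation. Linking is greedy globally-nearest-neighbour per
frame pair with a displacement gate and gap memory; it matches the
exhaustive optimal assignment on well-separated scenes (tested against
`scipy.optimize.linear_sum_assignment`). MSD uses time- and
ensemble-averaged non-overlapping windows by default (overlapping
optional), lags capped at 32 strides, and fits a line with free intercept
(absorbing static localization error); `D = slope/(2·dim)`. The
hindrance fit is weighted linear regression of per-height-bin lateral
`D` on `1/h` — exact on noiseless law-generated data. The Boltzmann mass
fit uses the truncated-exponential maximum likelihood on excess heights
(decaying from the bottom for dense particles, from the top for buoyant
ones). Wobble analysis segments rods by RI threshold + connected
components (replacing a trained-classifier step whose training data is
not reproducible here), takes the first principal axis per component,
links centroids, drops tracks shorter than 50 frames or with smoothed
path length under 4 µm, smooths centroids with a centered 15-frame
rolling mean (edges truncated), differentiates with second-order stencils
(central inside, one-sided at the ends), and reports the mean per-frame
angle between velocity and body axis with the axis sign chosen to
minimize it.

## Problem sizes used in the shipped studies

The validation-sphere study reconstructs the 10-µm sphere on a 128² × 64
grid (0.15 µm lateral, 0.25 µm axial) from 49 directions with 40 FISTA
iterations, holograms synthesized on a 2× oversampled camera grid; a
full-scale experiment uses 147 directions and much larger camera grids,
which this study scales down while keeping every algorithmic step. The
end-to-end
tracking loop uses 10 beads over 64 frames on 64² × 32 volumes with a
linear (Rytov-only) per-frame reconstruction. These sizes are the
package's default desk-scale choices; all are parameters.

## Known limitations

Scalar fields only; transmission geometry only; nearest-voxel gridding in
the initializer (no NUFFT); the prox composition is not the exact joint
proximal operator; periodic boundaries assume the scene stays away from
the lateral edges; the axial hindrance law is a leading-order
approximation; greedy linking is not globally optimal in dense crowds.
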