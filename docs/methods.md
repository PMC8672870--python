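# Methods

This note documents the models, numerical choices and limitations of the
package, in the order the pipeline runs them.

## Voxel models and materials

Media are isotropic voxel lattices of speed of sound `c` (m/s), amplitude
attenuation `α` (Np/m at the operating frequency) and density `ρ` (kg/m³);
impedance `Z = ρc` is derived. Attenuation is stored in the material table
as Np/cm at 1.0 MHz and scaled linearly in frequency (exponent fixed at 1)
at model-assignment time — absorption is treated as purely absorptive,
with scattering neglected. The default table holds measured mean
properties of milk-based ballistics-gelatin mixes (30/50/70% evaporated
milk), canola oil, and degassed water; the 30% and 50% mixes carry no
thermal constants and are acoustic-only. Users can override any entry via
a YAML material table (phantom-specific property measurements are the
norm in validation work).

Synthetic phantoms are rasterized by a **center-point membership test**
(no partial-volume averaging): a voxel takes the label of the shape
containing its center, inclusions over host over surround. This keeps
label counts deterministic and converges to the analytic solid volume as
the voxel shrinks (O(Δx); verified at two resolutions in the tests). The
preset cylinders are 102 × 30 mm (pressure type) and 102 × 150 mm
(thermal type); inclusion number, sizes and positions in the
heterogeneous presets are seeded pseudo-random ellipsoids of 8–20 mm
extent — illustrative configurations, not replicas of any physical
phantom.

Coordinates are right-handed with z the beam axis, origin at the
transducer face center, voxel positions at voxel centers, lengths in mm,
pressures in Pa, all phasors under the `e^{+jωt}` convention with forward
phase `e^{−jkz}`.

## Transducer source

The 940-kHz array preset (256 elements, 100-mm focal length,
144 × 98 mm aperture) packs equal-area circular elements pseudo-randomly
(seeded, non-overlapping) on the focal sphere, because the physical
element layout of such arrays is proprietary. Consequently absolute focal
dimensions of the preset will not exactly match any specific physical
array, and no quantitative validation target depends on them.

The Rayleigh–Sommerfeld integral is evaluated once onto the model front
plane: `p(r) = Σ (jωρ u ΔA / 2π) e^{−jkd} e^{−αd} / d` over sub-sources no
farther apart than λ/4, with sub-source areas weighted by the local shell
surface element (`1/cosγ`, `cosγ = √(F² − ρ²)/F`). The λ/4 default is
converged at the focus (halving it changes the focal value by < 0.5%);
near-field points within a third of the focal length need finer spacing.
Focusing phases are `+k(d − F)` per element, which puts all contributions
in phase at the target under the sign conventions above. Power scaling
multiplies the plane by one real factor so `Σ |p|²/(2Z) ΔA` equals the
target acoustic power; the plane must capture the beam (edge |p| below
1% of the peak by default; planes near the array carry a low-power
near-field skirt, so the pipeline relaxes this to 5% — configurable).

## Hybrid angular spectrum propagation

Per z-slab of thickness Δz:

* space domain: multiply by
  `exp(−j (k(x,y) − k̄) Δz) · exp(−α(x,y) Δz)` where `k = 2πf/c` and `k̄`
  is the **arithmetic mean over the unpadded plane**;
* spectral domain: lossless angular-spectrum advance by Δz at `k̄`.

Attenuation is applied wholly in the space-domain step; the spectral step
is lossless. Output plane `iz` holds the field at the *back face* of slab
`iz` (the returned volume's origin records the half-voxel z offset), so a
plane wave through an `L`-mm uniform slab exits with amplitude
`e^{−αL}` exactly.

Numerical dressing: transverse zero-padding of 25% per side with a
raised-cosine roll-off over 16 voxels applied once to the field edge on
entry (both cropped/removed on output) suppresses FFT wrap-around.
Evanescent components decay by default (imaginary `k_z`, sign forced
dissipative for either propagation direction); a `zero` mode removes them
instead, making the lossless propagator unitary on the propagating
subspace — that mode is what the round-trip and power-conservation tests
use. With padding and taper disabled, the homogeneous-model result equals
the plain angular spectrum to round-off (~1e-13 over hundreds of planes).

**Reflections.** At every z-interface the normal-incidence Fresnel
coefficient `R = (Z₂ − Z₁)/(Z₂ + Z₁)` is applied per voxel column to the
incident field to seed a counter-propagating wave; a marching pass
propagates all seeds with the same split-step scheme, and the next pass
re-reflects them in the opposite direction (`−R` for the reverse
crossing). Passes are summed coherently (default: two). Each pass keeps
the field that *arrived* at a plane separate from the locally seeded
reflection, so a wave never re-reflects at the interface that created it.
The forward field is not transmission-corrected (no `T` factor), i.e. the
scheme is first-order in interface contrast; for the gelatin/oil contrast
here (|R| ≈ 0.11) the neglected terms are O(R²) ≈ 1%.

## Full-wave reference solver

An independent brute-force route used only for cross-validation: the
first-order linear acoustics system solved by a k-space pseudospectral
time-domain method — spectral derivatives on half-voxel staggered grids,
`sinc(c_ref |k| Δt/2)` k-space correction (`c_ref` = max model speed),
split-field quartic-profile absorbing layers on all faces, and absorption
as a pressure-proportional damping `γ = 2αc` which reproduces `e^{−αz}`
exactly at the single drive frequency. The monochromatic source plane is
injected as an additive mass source with two analytic corrections so the
launched forward wave reproduces the requested complex plane: an
obliquity pre-filter (`cosθ = k_z/k` on the drive spectrum; a plane mass
source otherwise over-drives oblique components by `1/cosθ`) and a
`cos(ωΔt/2)` factor for the leapfrog time staggering. The solver runs in
float32 (accuracy is grid-limited, ≥ 6 points per wavelength here, not
precision-limited), marches until the slowest wave has crossed the
domain plus ramp/settle margins, and extracts the steady-state |p| and
phase by exact quadrature demodulation over the final two drive cycles —
for a settled monochromatic field this equals the per-voxel maximum
pressure over those cycles, without the phase-sampling noise of a
discrete max. In homogeneous water the two routes agree to ~0.2% in
amplitude (focal RMSDn ~0.1%), which bounds the calibration error the
cross-validation inherits.

## Cross-validation benchmark

The seeded benchmark (`fusim.validation`) is a 30 × 30 × 40 mm domain at
0.25 mm: water, a 30-mm 70%-milk gelatin slab (5–35 mm), and one oil
sphere of seeded 8–10 mm diameter jittered ±1.5 mm around the beam axis
at 15 mm depth. The source is a Gaussian-apodized (8-mm waist)
spherically-converging plane focused 28 mm past the model face — chosen
so the full cone fits the transverse domain with a clean edge roll-off;
a large therapy-array footprint would not fit a desk-scale domain at its
front plane, and both solvers receive literally the same tapered plane.
The figure of merit is the normalized RMS difference of |p| over the
41³-voxel region centered on the geometric focus, normalized by the
global maximum of the full-wave (reference) pattern, with neither
pattern self-normalized. Typical values are ~2% across seeds; the
residual is dominated by genuine split-step approximation error
(refraction and multiple scattering through the inclusion), not solver
calibration.

## Thermal solver

`Q = α|p|²/Z` per voxel, with |p| the peak phasor amplitude. Q computed
on the 0.25-mm acoustic grid is moved to the coarser thermal grid by
volume-weighted block averaging (integer spacing ratio enforced), which
conserves total deposited power. The Pennes equation is integrated by
forward Euler with flux-form conduction, harmonic-mean face
conductivities at material interfaces, zero-flux (adiabatic) boundaries,
uniform initial condition, and perfusion carried but defaulted to zero
(phantoms are not perfused). Defaults match standard practice: 0.1-s
step, 0.5-mm grid; the solver refuses any `Δt` above the explicit bound
`min ρc_p Δx²/(6k)` (0.283 s for the 70% gelatin at 0.5 mm; the bound is
capped at 1e6 s with a warning if conductivity is degenerate). The final
heating step is weighted fractionally so deposited energy equals
`∫Q dV × heat_duration` exactly; with adiabatic boundaries the flux-form
update conserves that energy to round-off, which the tests verify along
with the uniform-heating rise `Q t/(ρc_p)` and heat-kernel variance
growth `2Dt`, `D = k/(ρc_p)`.

## Comparison metrics

* **RMSDn (pressure):** RMS of `(|p_sim| − |p_ref|)/p_max,ref` over a
  `(2h+1)³` region (default h = 20, i.e. 41³ ≈ the 1-cm scan extent at
  0.25 mm), ×100. The normalizer is the reference pattern's *global*
  maximum; no self-normalization of either pattern.
* **RMSD / RMSDn (temperature):** non-normalized RMS in °C; the
  normalized variant divides residuals by the reference frame's peak
  temperature rise. The comparison region defaults to the whole frame
  (configurable slices), as no canonical thermal region exists.
* **FWHM:** per-axis half-maximum crossings through the global peak by
  linear interpolation, walking outward from the main lobe; unbounded
  lobes raise, single-voxel impulses warn.
* **EMD:** both 2D patterns normalized to unit mass; exact optimal
  transport (Euclidean ground distance, reported in original pixel
  lengths) solved as a linear program over the nonzero support points
  with HiGHS. Patterns whose support product exceeds a cap are first
  binned 2×2 mass-conservingly. The test oracle is an independent
  brute-force enumeration of integer transport plans.
* **Center of thermal mass:** ΔT-weighted centroid over voxels with
  ΔT ≥ 1.0 °C (threshold configurable and reported); ΔCOTM is the
  Euclidean distance between two centroids.
* **Temperature curves:** per-frame spatial max, and the mean over a
  5×5×5-voxel cube (15.6 mm³ at 0.5 mm — the nearest integer cube to a
  16 mm³ region) centered on the spatiotemporal peak voxel; ties break
  to the lowest linear index for determinism.

## What the synthetic phantoms do and do not show

The generator reproduces the geometry and measured mean properties of
gelatin/oil phantoms, so passing tests demonstrate correctness of the
numerics and internal consistency of the acoustic–thermal chain. It does
not emulate measurement physics: hydrophone calibration, MR thermometry
noise and partial-volume effects, segmentation error from real images,
property uncertainty (±SD in the table), or temperature-dependent
property drift between repeated sonications. Agreement numbers against
the in-repo full-wave solver therefore isolate *algorithmic* error of
the split-step scheme and are expected to be smaller than
simulation-vs-experiment differences, which fold in all of the above.

## Known limitations

Linear propagation only (no KZK/Westervelt nonlinearity); no shear
waves, dispersion, or angled-interface refraction beyond the split-step
scheme; thermal properties constant in time and temperature; no
perfused-tissue validation (the perfusion term is implemented but
untested against reference solutions); the EMD solver is exact but
dense — patterns with very large supports are binned before solving.
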