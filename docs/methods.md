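# Methods

## Photon propagation model

Both the excitation and the emission process are modelled by the
steady-state diffusion equation with the Robin boundary condition
`2qD ∂Φ/∂n + Φ = 0`, valid in highly scattering media (`μs′ ≫ μa`) a few
transport lengths away from sources and boundaries. All coefficients are
homogeneous; `D = 1/[3(μa + μs′)]` and `μeff = sqrt(μa/D)`.

- **Free-space kernel.** `G(ρ) = exp(-μeff ρ)/(4πDρ)` is the unique
  free-space Green's function of the diffusion operator above.
- **Slab boundaries.** The two planes normal to the detection axis
  (detector at `x = 0`, illuminated surface at `x = thickness`) are
  treated with the extrapolated-boundary method: zero-density planes at
  `x = -z_b` and `x = thickness + z_b`, `z_b = 2qD`, and an
  alternating-sign image-source series across them. The series is summed
  in shells of increasing order and truncated when a shell's relative
  contribution drops below a tolerance (default 1e-14 inside an imaging
  setup, so that scalar and vectorized evaluations of the same weight
  agree to ~1e-13; convergence is geometric with ratio
  `exp(-2 μeff (thickness + 2 z_b))` — a handful of shells for the 3 cm
  phantom, a few dozen for sub-centimetre slabs).
- **Lateral walls are ignored.** In the reference phantom every source,
  target, and detector position of interest is ≥ 1 cm (≈ 10 transport
  lengths) from the lateral walls, where their influence is negligible.
  For laterally small objects this assumption degrades gracefully but is
  not controlled.
- **Boundary mismatch `q`.** Unknown for the Intralipid/perspex phantom;
  default `q = 1` (index matched), configurable. Results depend on it only
  through `z_b = 2qD ≈ 0.07 cm`.
- **Collimated sources** are replaced by an isotropic point source one
  transport length `1/μs′` beneath the illuminated surface.
- **Detected quantity.** The boundary photon density `Φ` at the detector
  node. Exitance is proportional to `Φ` under the Robin condition, so
  this choice only fixes a global scale.
- **Singularity handling.** Distances are clamped to `Δx/2` (half a depth
  voxel) wherever a kernel is evaluated between coincident or adjacent
  points — the node containing the source, and detector pixels paired
  with boundary nodes. This is standard voxelized-kernel practice and
  affects only those voxels.

## Forward model and system matrix

The Born weights `C_{n,i}^{(m)} = G_em · Φ_ex` couple every voxel to every
detector pixel. The full weight tensor (`Npix² · Nx` entries) is never
materialized; the two factor fields are cached (the excitation field once
per setup, emission fields per requested pixel) and the system-matrix
assembly evaluates exactly the reference row and focal column of each
depth conversion matrix — `Npix·Nx + Npix·(Npix−1)` kernel products per
focal depth, the count reported by `count_green_evaluations`. Because the
detector pixel lattice coincides with the lateral grid-node lattice, the
focal column over all pixel pairs reduces to a `(2Ny−1)×(2Nz−1)`
lateral-offset table, making assembly O(Npix²) lookups.

Conventions fixed by this package (the physics does not prefer any):

- Pixel linearization is y-fastest, `m = iz·Ny + iy`, 0-based.
- The voxel grid is node-centered with nodes on both boundaries
  (a 3 cm axis at 0.05 cm spacing has exactly 61 nodes).
- `ΔV` is absorbed into `R`, so `B = R F` holds with `F` in yield units.
- Focal-plane index: nearest depth node; exact midpoints round toward the
  detector.
- **Reference pixel: the central detector pixel** (configurable). The
  anchoring pixel of the proportional relation is mathematically
  arbitrary, but it skews the column scaling
  `C_n^{(ref)}/C_{n,k}^{(ref)}` of the assembled operator. A corner
  reference breaks the lateral symmetry of a symmetric phantom and drags
  the regularized restoration toward the far corner (measured: 0.25 cm
  center deviation at desk scale versus 0.002 cm for the central
  reference). The central pixel is the unique symmetry-preserving choice
  on an odd lattice.
- The system-matrix error between two focal depths is reported as the
  squared Frobenius norm by default (squared spectral norm available);
  the shallow/deep asymmetry conclusions are norm-robust.

## Inversion

The fixed-λ Levenberg–Marquardt update is a preconditioned Richardson
iteration on the normal equations. `(RᵀR + λαI)` with `α = trace(RᵀR)` is
factorized once by Cholesky and reused across iterations; no explicit
inverse is formed, and `α` is cached with the matrix. Defaults: zero
initial image, λ = 1e-4, 200 iterations, λ constant across iterations, no
early stopping. For the bare update the residual norm is provably
non-increasing (the residual propagator `I − R(RᵀR+λαI)⁻¹Rᵀ` has spectrum
in (0, 1]); mode `j` of the data is recovered at rate
`1 − (1 + σj²/λα)^{-T}` after `T` iterations, so the effective spectral
cutoff sits near `σ² ≈ λα/T`, well below the single-step Tikhonov cutoff.

An optional **nonnegativity projection** zeroes negative values after each
update. Fluorescent yield is physically non-negative; on the desk-scale
phantom the projection roughly halves the restored lobe width (0.33 cm vs
0.75 cm FWHM) by suppressing the ringing that the truncated spectrum
otherwise produces. The phantom pipeline and the depth-estimation sweep
use it; studies that probe the bare update (regularization ordering,
residual monotonicity, solver oracles) leave it off.

Depth estimation restores the image over a set of candidate focal depths
and returns the candidate whose restored-target center is closest to the
blurry image's maximum location (ties to the shallower candidate) — the
restored target sits at its true lateral position only when the focal
plane matches the true depth.

## Synthetic phantom

`PhantomSpec` reproduces a classic validation setup: a 3×3×3 cm diffusive
cube with μa = 0.02 cm⁻¹ and μs′ = 10 cm⁻¹ (5% Intralipid-like), a 0.3 cm
diameter fluorescent tube at 2 cm depth from the detector surface, offset
1 cm laterally from one wall and spanning the tank along z, and a
collimated source entering the center of the opposite face. Yield is
proportional to dye concentration with the proportionality constant folded
into `yield_amplitude`; the glass capillary and tank walls are not
modelled (optically thin or outside the diffusive domain). Voxelization is
a binary node-center-in-cylinder mask (surface nodes count as inside, with
a 1e-9 relative tolerance on r² so lattice points at exactly the radius
are not lost to roundoff). The default voxel size is 0.05 cm; all shipped
studies run at 0.1 cm (31³ nodes, 961-pixel images), chosen as the
package's desk scale — assembly plus 200 iterations completes in about a
second, and the qualitative behaviour matches the 0.05 cm grid.

What the fixture does *not* emulate about real camera data: measurement
noise is off by default (optional gaussian/poisson models are provided),
and there is no lens/filter model, no excitation bleed-through, and no
autofluorescence. One consequence is worth spelling out: the simulated
halo from 2 cm depth is ~2.7 cm wide — diffusion theory at these
coefficients is *wider* than typical camera measurements of the same
phantom (reported around 1.9 cm), because a real camera's angular
acceptance and optics narrow the detected spot. Two downstream effects:

1. The 3 cm detector window cannot bracket both half-maximum crossings of
   the simulated halo when the target sits 1 cm from a wall. `fwhm()`
   therefore exposes an explicit `symmetric_fallback` that measures a
   singly-clipped profile as twice the peak-to-crossing distance on the
   intact side (exact for symmetric profiles, an error otherwise).
2. Passing the inverse-crime studies here does not certify the
   camera-data regime. In particular, restoring *measured* images under
   mismatched assumed optical coefficients is reported to be insensitive
   to the coefficients — that happens because measured data is sharper
   than every candidate model kernel, so all restorations sit at the
   regularization floor. A clean inverse crime is structurally outside
   that regime (its data is exactly as wide as the true kernel, and an
   assumed kernel sharper than the true one visibly under-deconvolves),
   so the shipped coefficient study varies the *medium* — simulating and
   restoring at each coefficient pair — and finds the achievable
   resolution insensitive to the coefficients (≈7% spread across
   ±50–100% changes), the simulation-side analogue of the reported
   flatness.

## Numerical choices and degenerate inputs

- Kernel series truncation and the `Δx/2` clamp as above; coincident
  points without a clamp raise.
- `fwhm` uses a zero baseline (profiles are background-free in
  simulation) and linear interpolation between bracketing samples;
  a profile with no positive maximum, or clipped on both sides, raises.
- Target centers are intensity-weighted centroids over the connected
  component (at ≥ half maximum) containing the global maximum, so
  multi-blob restorations are judged by their dominant blob.
- Degenerate configurations raise early: sources outside the slab or less
  than one transport length from both faces, tubes that do not fit the
  tank, focal depths outside the slab, non-positive λ.

## Known limitations

- Geometry is limited to infinite media and slabs; arbitrary surfaces
  (e.g. an animal torso from CT) are out of scope.
- Single point source, single view; no multi-projection tomography.
- Homogeneous optical coefficients only.
- The desk-scale (0.1 cm) studies inherit a coarser resolution floor than
  the 0.05 cm reference grid; the 61³ configuration is supported
  (≈ 106 MB system matrix) but not exercised by the default test run.
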