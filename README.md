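# fpirestore

Diffusion-model image restoration for transillumination **fluorescence
planar imaging (FPI)**.

Planar fluorescence imaging photographs the light that fluorescent probes
emit through centimetres of biological tissue. Because near-infrared
photons scatter elastically every fraction of a millimetre, the image of a
fluorochrome sitting 2 cm deep is not a picture of the fluorochrome but a
broad diffusion halo — centimetres wide for a millimetre-scale target —
which makes it hard to judge the size or position of, say, an in-situ
tumour from a camera image alone. `fpirestore` deblurs such images with a
physical model of photon diffusion instead of an optical point-spread
function, and ships a synthetic phantom generator so the whole method can
be exercised, tested, and benchmarked without any camera data.

## The model

Photon transport in the turbid medium is described by the steady-state
diffusion equation with a Robin boundary condition,

```
-∇·D∇Φ(r) + μa Φ(r) = Q(r),      2qD ∂Φ/∂n + Φ = 0 on ∂Ω,
```

with `D = 1/[3(μa + μs′)]` and homogeneous coefficients. Its free-space
Green's function is `G(ρ) = exp(-μeff ρ)/(4πDρ)` with
`μeff = sqrt(μa/D)`; slab boundaries are handled by extrapolated-boundary
image sources. Under the Born approximation the blurry pixel values are

```
B_m = ΔV Σ_n Σ_i C_{n,i}^{(m)} f(x_i, y_n, z_n),
C_{n,i}^{(m)} = G_em(r_dm, x_i, y_n, z_n) · Φ_ex(x_i, y_n, z_n, r_s),
```

where `f` is the fluorescent yield, `i` indexes depth, and `n` the lateral
pixel lattice. The restoration target is the *expected image*
`F_n = Σ_i C_{n,i}^{(m)} f / Σ_i C_{n,i}^{(m)}` — by the first mean value
theorem, a weighted average of the yield along the detection axis. Since
`F` depends on the anchoring pixel `m`, a single linear system only exists
after assuming all signal originates from a chosen constant-depth *focal
plane* (depth index `k`), which yields the square system matrix

```
R_mn = ΔV · C_n^{(ref)} · C_{n,k}^{(m)} / C_{n,k}^{(ref)},      B = R F.
```

The inverse problem is solved by the fixed-λ Levenberg–Marquardt iteration

```
F ← F + (RᵀR + λαI)⁻¹ Rᵀ (B − RF),      α = trace(RᵀR),
```

optionally with a nonnegativity projection after each step. Restoration is
sharp when the depth of focal plane (DFP) matches the true target depth;
sweeping the DFP and comparing restored-target centers against the blurry
maximum estimates the target depth.

## Worked example

Simulate the reference phantom — a 3×3×3 cm diffusive cube
(μa = 0.02 cm⁻¹, μs′ = 10 cm⁻¹) holding a 0.3 cm fluorescent tube at 2 cm
depth, trans-illuminated by a collimated point source — then restore the
blurred image at the matched focal depth:

```python
from fpirestore import PhantomSpec, PlanarRestoration, make_fixture

spec = PhantomSpec(yield_amplitude=8.0)          # 8 umol/L-equivalent dye
fixture = make_fixture(spec, spacing=0.1)        # 31^3 nodes, 961 pixels
model = PlanarRestoration(fixture["blurry"], fixture["setup"], dfp=2.0)
results = model.fit(lam=1e-4, iterations=200, nonnegativity_clamp=True)
print(results.summary())
report = results.evaluate(true_center=spec.true_center)
print(f"center deviation: {report.center_deviation_cm:.4f} cm")
```

which prints

```
Planar fluorescence restoration (Levenberg-Marquardt)
========================================================
grid nodes (Nx,Ny,Nz):   (31, 31, 31)
voxel size (cm):         (0.1, 0.1, 0.1)
mu_a / mu_s' (1/cm):     0.02 / 10.0
slab thickness (cm):     3.0
depth of focal plane:    2.0 cm (node index 20)
lambda / iterations:     0.0001 / 200
residual first -> last:  4.876262e-02 -> 1.123778e-02
restored max:            8.666376e-01
restored center (y,z):   (1.002, 1.500) cm
restored FWHM:           0.334 cm
center deviation: 0.0021 cm
```

The blurred camera image of this phantom is a halo more than 2.5 cm wide;
the restored projection localizes the 0.3 cm tube to 0.33 cm FWHM with its
center 0.002 cm from the truth. `results.plot()` displays the restored
image; `fpirestore.estimate_depth` sweeps the DFP to recover the target
depth when it is unknown.

The same pipeline is available from the shell:

```bash
fpirestore simulate --config phantom.yaml --seed 7 --out fixture/
fpirestore build-matrix --config phantom.yaml --dfp 2.0 --out R.bin --report
fpirestore restore --matrix R.bin --image fixture/blurry.tif --lam 1e-4 \
    --iters 200 --out restored.tif
fpirestore evaluate --image restored.tif --spacing 0.1 --true-center 1.0 1.5
```

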