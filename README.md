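# sai — scattering-assisted imaging

`sai` reconstructs fluorescence images at a resolution finer than the
diffraction limit of the collection optics by exploiting speckle
illumination *embedded in a scattering medium*.  It is aimed at microscopists
and method developers who want to study or apply speckle-based
super-resolution when long working distances (hence low collection NA)
make conventional high-NA imaging impossible.

## The idea

Coherent light inside a strongly scattering mounting medium forms speckle
grains of size ~λ/2n — set by the medium's refractive index *n*, not by the
numerical aperture of any lens.  A sequence of N frames is acquired, each
under an independent speckle pattern I_n:

    M_n = (I_n ρ) ⋆ h + ε

with ρ the fixed fluorophore density, h the collection PSF (FWHM
R = c λ/NA), and ε detector noise.  Because fully developed speckle has an
exponential intensity PDF, grains brighter than average are rare and sparse.
Subtracting the mean frame and keeping the positive part,

    HM_n = (M_n − M̄)⁺,

isolates those high-intensity grains.  Each HM_n is then fitted with a sum
of Gaussian grains of known FWHM S,

    S_n = Σ_k A_k exp(−(r − R_k)² / 2σ_S²),   G_n = S_n ⋆ h,

by a greedy stochastic descent on F = |HM_n − G_n|²: random perturbations of
one grain's amplitude/centre are accepted only if F decreases, and during
the first quarter of the run (thermalization) grains may be created at the
largest residual or destroyed, starting from K = A/A_speckle grains with
A_speckle = π(S/2)².  Averaging the fitted S_n over frames — rendered
*without* the PSF — yields the final image S̄, whose intrinsic resolution is
the grain size S rather than the PSF width R.

Reliability is quantified by the degree of similitude between two
independent fits, Q = Σab / √(Σa² Σb²) ∈ [0, 1]; fitting the sparse HM_n
gives a far higher Q than fitting the raw frames.

## Worked example

Simulate a thin fluorescent line (FWHM 120 nm) under the low-NA reference
optics — collection PSF FWHM 1.1 µm, embedded grains of FWHM 240 nm, 60 nm
pixels, Poisson noise at peak per-frame SNR ≈ 10 — and reconstruct it:

```python
from sai import (FitConfig, average_reconstruction, enhancement_factor,
                 fit_stack, line_profile_fwhm)
from sai.scenes import line_scene

scene = line_scene(seed=1, n_frames=100)
fits = fit_stack(scene.hm, scene.psf, scene.optics, FitConfig(seed=2),
                 scene.k_start)
sai_img = average_reconstruction(fits, scene.stack.frames.shape[1:])

px = scene.optics.pixel_size_nm
wf = line_profile_fwhm(scene.mean.values, px)   # wide-field = mean frame
sr = line_profile_fwhm(sai_img, px)
print(f"wide-field FWHM : {wf:.0f} nm")
print(f"SAI FWHM        : {sr:.0f} nm")
print(f"enhancement     : {enhancement_factor(wf, sr):.2f}x")
```

Output:

```
wide-field FWHM : 1106 nm
SAI FWHM        : 278 nm
enhancement     : 3.98x
```

The wide-field width is the 1.1 µm PSF (the 120 nm line is unresolved); the
reconstruction recovers the line at ~0.28 µm — roughly the 240 nm grain
size broadened by the line width and residual localization error — a ~4×
resolution gain from the same low-NA objective.

## Command line

Every stage is also a subcommand of the `sai` console script:

```sh
sai make-phantom rho.tif --kind filaments --size 128 --pixel 60
sai simulate rho.tif stack.tif --frames 600 --photon-scale 300 --seed 1
sai extract stack.tif out/                 # M̄, HM stack, A, K_start
sai fit out/hm_stack.tif out/ 600          # per-frame grain sets (JSONL)
sai reconstruct out/grains.jsonl out/sai.tif 128 128
sai evaluate out/sai.tif out/mean.tif --pixel 60
sai run config.yaml                        # the whole pipeline from YAML
```

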