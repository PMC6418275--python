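# Methods

This note documents the models, numerical choices and limitations behind
`sai`, in the spirit of a methods appendix.

## Optical model

The collection arm is a single 2-D Gaussian PSF with FWHM equal to the
nominal resolution R = c·λ/NA.  The coefficient c defaults to 0.51 (the
FWHM of an Airy disc); it is configurable and absorbs both the
Airy-vs-Gaussian approximation and the excitation/emission wavelength
ambiguity.  A Gaussian PSF makes the grain-model convolution analytic
(variances add), which the test suite uses as an independent closed-form
oracle for the FFT-convolution rendering path.  Vector diffraction,
aberrations, polarization and 3-D sectioning are out of scope.

The PSF kernel is sampled on an odd grid holding ±4.5σ and normalized to
unit sum; construction fails if more than 1% of the Gaussian mass would be
truncated.  Unit sum guarantees that convolution conserves total intensity.

## Speckle generation

*Aperture-limited regime.*  A uniform-amplitude, uniform-random-phase pupil
disc of spatial-frequency radius NA/λ is inverse-Fourier-transformed; the
intensity autocovariance FWHM is then ≈ λ/2NA and shrinks as the aperture
opens.

*Embedded regime.*  The field inside a scattering medium of index n is a
sum of random plane waves.  We draw each wave's transverse wavevector
uniformly from the disc |k⊥| ≤ 2πn/λ (the full transverse spectrum the
medium supports) with an independent uniform phase.  Three candidate
spectra were considered for this simulation: a ring spectrum (all waves at
|k⊥| = 2πn/λ) gives an autocovariance FWHM of ≈ 0.72·λ/2n (J₀² closed
form); isotropic 3-D directions give ≈ 0.89·λ/2n (sinc²); the filled disc
gives ≈ 1.03·λ/2n (jinc², the classic "λ/2NA with NA = n" result).  The
filled disc is the choice consistent with the known λ/2n grain size of
embedded speckle, so it is the default.  Either way the grain size is
independent of the illumination NA — the property that motivates the whole
method.  Patterns are normalized to unit mean, playing the role of
illumination-power control.

The generator does not model the microstructure of any particular
scattering material, wavefront shaping, or the memory effect; it emulates
only the two statistical properties downstream stages rely on: grain size
and fully developed (exponential-intensity) statistics.  An experimentally
measured grain size S is treated as an input: for the reference scenes we
set n = λ/2S (n ≈ 1.11 for S = 240 nm at 532 nm), i.e. the *effective*
index that reproduces the measured grain.

*Grain-size metrology.*  Grain size is the FWHM of the radially averaged
autocovariance of the intensity (mean removed, FFT-based, asymptotic
baseline from the outer 25% of radii subtracted, half-crossing refined by
linear interpolation).  Note the autocovariance of a Gaussian feature of
FWHM w has FWHM w√2; the statistic is a property of the *pattern*, not of a
single grain, and matches how grain sizes are quoted experimentally.
Because a single realization is noisy, tests and figures always average ≥ 5
independent realizations.

## Forward model and noise

Frames are (I_n·ρ) ⋆ h computed with zero-padded FFT convolution (no
wrap-around), with noise applied after the convolution — detector noise —
and clipped at zero, as camera counts are.  The default noise model is
Poisson shot noise at a configurable photon budget, optionally plus
additive Gaussian read noise.  `photon_scale_for_peak_snr` calibrates the
photon budget so the median per-frame peak has a chosen shot-noise SNR
(peak SNR 10 ⇒ ~100 counts at the peak), the regime in which the reference
benchmarks run.  Whether noise enters before or after the convolution is
not observable at this SNR; post-convolution was chosen as the physically
natural camera model.

## High-intensity extraction

M̄ is the plain per-pixel mean (≥ 2 frames required); HM_n = (M_n − M̄)⁺.
No denoising precedes the subtraction.  The signal area A is the *count* of
mean-frame pixels above background mean + 2σ — a count, not a fraction,
since K = A/A_speckle must be a grain number.  Background statistics come
from the low-intensity part of M̄ by quantile matching: the 10th and 40th
percentiles of the pixel values are fitted to a Gaussian background
(σ = (q₄₀−q₁₀)/(z₄₀−z₁₀), µ = q₄₀−z₄₀σ).  Both quantiles lie inside the
background population whenever the background covers at least about half
the field, and unlike a plain mean/std over the dimmest pixels the estimate
carries no truncation bias; for an exactly-zero background it degenerates
to µ = σ = 0 and the threshold reduces to "any recorded intensity".  A
warning is raised when the measured signal area reaches half the field,
where this assumption breaks.  An overestimated A only inflates the
initial grain count — harmless, because thermalization death moves prune
aggressively (see below).  K_start is computed once from the mean frame
and shared by all frames.

## Grain fitting

The per-frame model is S_n = Σ A_k exp(−(r−R_k)²/2σ_S²) with one shared
width.  S is measured as an autocorrelation FWHM, so by default
σ_S = S_px/√(8 ln 2); the literal σ_S = S_px reading is available via
`FitConfig.grain_sigma_mode = "literal"`.

Optimization is strict greedy descent: a proposal is accepted iff F
strictly decreases (ties rejected); there is no temperature and no uphill
moves.  Proposals perturb one grain at a time — position by a Gaussian step
of s.d. 0.5·S_px, amplitude multiplicatively by (1 + N(0, 0.1)) — with
amplitude projected to ≥ 0 and position to the field (the proximal step).
Both scales anneal linearly to 20% of their initial value over the run
(default 200 sweeps; one sweep = K single-grain proposals).  Initial
centres are drawn from the above-threshold support of HM_n with the local
frame value as the starting amplitude.

Because grain ⋆ PSF is again a Gaussian (σ_c² = σ_S² + σ_h², peak scaled by
σ_S²/σ_c²), the optimizer evaluates model changes in closed form on a local
window truncated at 3σ_c, making one proposal O(window) instead of
O(image); the incremental cost bookkeeping is exact for the truncated
model, so the accepted-move cost trace is monotone by construction and is
asserted on every run.  The inner loop is compiled with numba (a
pure-Python fallback keeps the package functional, if slow, without it).

During the first quarter of the run (thermalization) the grain count
adapts.  Birth: a candidate at the largest positive residual with its
least-squares amplitude, accepted iff F decreases.  Death: removal gains
for all grains are scanned once per round, candidates are tried
most-harmful-first (each re-evaluated against the current model before
removal), and rounds repeat while any removal strictly lowers F.  This
reaches the same fixed point as removing the single best candidate and
rescanning — no improving removal remains — at a fraction of the cost.
After thermalization the count is frozen; only amplitudes and centres move.

*Model-order behaviour.*  With K_start from the area formula the model is
deliberately over-parameterized: a PSF-sized blob is many A_speckle in
area.  Death moves prune most of the surplus (a typical reference frame
ends with ~5% of K_start), and grains that survive pile onto blob centres,
because any symmetric spread of equal-width Gaussians widens the model and
raises F.  Per-grain parameters are therefore only identifiable at true
model order; what the averaged image relies on — and what the tests check —
is that the amplitude-weighted centroid of the grains fitting a blob
localizes its centre well below the PSF width (≲ 0.2·S at high SNR,
verified against an exhaustive grid-search oracle at fixed model order).

## Reconstruction and metrics

S̄ is the pixel mean over frames of the rendered S_n *without* PSF
convolution; this is the only reading under which the reconstruction's
intrinsic width is the grain size S, and it is what makes a ~0.4 µm line
measurable through a 1.1 µm objective.  No smoothing or gamma is applied.

Q between two reconstructions is Σab/√(Σa²Σb²) (discrete integrals as
pixel sums; the per-image normalization α folded in).  For stacks Q is the
mean of per-frame values; frame pairs that are both empty are skipped, and
a pair with exactly one empty member contributes 0.

Resolution is measured as the FWHM of an intensity profile: either along an
arbitrary segment (cubic interpolation, 8× oversampling) or, for straight
line phantoms, of the profile averaged along the line direction — the
standard pooling of many parallel cuts.  Half-maximum crossings are refined
by linear interpolation.  The enhancement factor is the ratio of wide-field
to reconstructed FWHM.  Fourier ring correlation is not implemented.

## Reference scenes and problem sizes

The benchmark scenes (in `sai.scenes`) use the low-NA configuration:
λ = 532 nm, NA = 0.25, c chosen so R = 1.1 µm, S = 240 nm (grain
FWHM = 0.22·R), 60 nm pixels, 128² fields, peak per-frame SNR 10.  The
resolution benchmark uses a single 120 nm line and N = 600 frames; the
reliability benchmark uses a two-filament phantom and N = 60 frames — Q is
a mean over frames and is stable well below N = 100.  On these scenes two
independent HM-mode fits agree at Q ≈ 0.95 while raw-mode fits reach only
Q ≈ 0.5–0.6, and the reconstructed line measures ≈ 0.28 µm against the
1.1 µm wide-field width (enhancement ≈ 4).  128² at 60 nm pixels leaves
~19 grain FWHMs across the field, enough for line-profile statistics; the
field size is a speed/statistics trade-off, and all quantitative claims are
re-derived at run time by the test suite and `scripts/acceptance.py`, never
hard-coded.

## Known limitations

- Synthetic speckle is ideal: unit contrast, perfect frame-to-frame
  independence, no drift, no photobleaching, no background
  autofluorescence.  Passing benchmarks here bounds algorithmic error, not
  experimental robustness; in real tissue, background and reduced SNR
  degrade localization first.
- The grain width is assumed known and global.  A miscalibrated S biases
  both K_start and the reconstructed feature widths.
- Greedy descent with birth/death is a heuristic global optimizer; on dense
  (raw-frame) targets it lands in configuration-dependent minima — that is
  precisely the behaviour the Q contrast quantifies.
- The forward model is 2-D; out-of-focus light is not modelled.
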