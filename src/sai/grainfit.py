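"""Per-frame Gaussian grain fitting by greedy stochastic descent.

Each high-intensity frame ``HM_n`` is modelled as a sum of ``K_n`` isotropic
Gaussian grains ``S_n = sum_k A_k exp(-(r - R_k)^2 / (2 sigma_S^2))`` seen
through the collection PSF, ``G_n = S_n conv h``.  The fit minimizes the
squared distance ``F = sum |HM_n - G_n|^2`` by proposing random perturbations
of one grain's amplitude and centre at a time and accepting a proposal only
when ``F`` strictly decreases (amplitudes are projected to >= 0 and centres
to the field, a proximal step).  During the first *thermalization* fraction
of the run the grain count itself may change: birth proposals place a grain
at the largest positive residual with its least-squares amplitude, and death
proposals remove the grain whose removal lowers ``F`` the most; both are
accepted under the same strict-descent rule.

Because both the grain and the PSF are Gaussian, the model image is a sum of
Gaussians of variance ``sigma_S^2 + sigma_h^2`` with peak amplitude scaled by
``sigma_S^2 / (sigma_S^2 + sigma_h^2)``; the optimizer works directly in this
closed form, updating only a local window (3 sigma) around a perturbed grain,
which keeps one proposal O(window) instead of O(image).

The grain width is fixed by the measured speckle size ``S``.  ``S`` is an
autocorrelation FWHM, so by default ``sigma_S = S_px / sqrt(8 ln 2)``; the
literal reading ``sigma_S = S_px`` is available via
``FitConfig.grain_sigma_mode = "literal"``.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve

from .optics import FWHM_PER_SIGMA, OpticalConfig, PsfKernel
from .render import gaussian_spots

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(fn):
            return fn

        return wrap

__all__ = ["SpeckleGrain", "GrainSet", "FitConfig", "FitResult",
           "render_grainset", "render_guess", "cost", "fit_frame", "fit_stack"]


@dataclass(frozen=True)
class SpeckleGrain:
    """One fitted grain: peak amplitude and continuous centre (row, col)."""

    amplitude: float
    row: float
    col: float


@dataclass(frozen=True)
class GrainSet:
    """All grains of one frame; a single width ``sigma_S`` is shared."""

    amplitudes: np.ndarray
    rows: np.ndarray
    cols: np.ndarray
    grain_sigma_px: float
    frame_index: int = 0

    def __post_init__(self) -> None:
        a = np.atleast_1d(np.asarray(self.amplitudes, dtype=float))
        r = np.atleast_1d(np.asarray(self.rows, dtype=float))
        c = np.atleast_1d(np.asarray(self.cols, dtype=float))
        if not (len(a) == len(r) == len(c)):
            raise ValueError("amplitudes, rows, cols must have equal length")
        if np.any(a < 0):
            raise ValueError("amplitudes must be >= 0")
        object.__setattr__(self, "amplitudes", a)
        object.__setattr__(self, "rows", r)
        object.__setattr__(self, "cols", c)

    @property
    def k(self) -> int:
        return int(len(self.amplitudes))

    @property
    def grains(self) -> list[SpeckleGrain]:
        return [SpeckleGrain(float(a), float(r), float(c))
                for a, r, c in zip(self.amplitudes, self.rows, self.cols)]


@dataclass(frozen=True)
class FitConfig:
    """Optimizer settings.

    ``n_iterations`` counts sweeps; one sweep makes ``K`` single-grain
    proposals.  Proposal scales anneal linearly from their initial value to
    ``anneal_floor`` times it over the run, so coarse placement precedes
    refinement.  ``position_step_px`` defaults to half the grain FWHM.
    """

    n_iterations: int = 200
    thermalization_fraction: float = 0.25
    position_step_px: float | None = None
    amplitude_step_frac: float = 0.1
    birth_death_rate: int = 1
    anneal_floor: float = 0.2
    grain_sigma_mode: str = "fwhm"          # "fwhm" | "literal"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_iterations <= 0:
            raise ValueError("n_iterations must be > 0")
        if not 0.0 < self.thermalization_fraction < 1.0:
            raise ValueError("thermalization_fraction must lie in (0, 1)")
        if self.position_step_px is not None and self.position_step_px <= 0:
            raise ValueError("position_step_px must be > 0")
        if self.amplitude_step_frac <= 0:
            raise ValueError("amplitude_step_frac must be > 0")
        if self.grain_sigma_mode not in ("fwhm", "literal"):
            raise ValueError("grain_sigma_mode must be 'fwhm' or 'literal'")


@dataclass(frozen=True)
class FitResult:
    """Outcome of one frame fit."""

    grain_set: GrainSet
    cost_trace: np.ndarray        # F after initialization and after each sweep
    accepted_moves: int
    n_births: int = 0
    n_deaths: int = 0


def grain_sigma_px(cfg: OpticalConfig, fit_cfg: FitConfig | None = None) -> float:
    """Rendered grain sigma from the measured speckle FWHM ``S``."""
    mode = fit_cfg.grain_sigma_mode if fit_cfg is not None else "fwhm"
    s_px = cfg.speckle_size_px
    return s_px / FWHM_PER_SIGMA if mode == "fwhm" else s_px


def render_grainset(gs: GrainSet, shape_px: tuple[int, int]) -> np.ndarray:
    """Sum of grain Gaussians (peak-normalized amplitudes), no PSF."""
    return gaussian_spots(shape_px, gs.rows, gs.cols, gs.amplitudes,
                          gs.grain_sigma_px)


def render_guess(gs: GrainSet, psf: PsfKernel,
                 shape_px: tuple[int, int]) -> np.ndarray:
    """Model frame ``G_n``: the rendered grain set seen through the PSF."""
    return fftconvolve(render_grainset(gs, shape_px), psf.values, mode="same")


def cost(hm: np.ndarray, g: np.ndarray) -> float:
    """Squared distance ``F = sum |HM - G|^2``."""
    hm = np.asarray(hm, dtype=float)
    g = np.asarray(g, dtype=float)
    if hm.shape != g.shape:
        raise ValueError("images must share a shape")
    d = hm - g
    return float(np.dot(d.ravel(), d.ravel()))


# ---------------------------------------------------------------------------
# descent kernel (operates on *effective* amplitudes: peak values of G)
# ---------------------------------------------------------------------------

@njit(cache=True)
def _add_patch(g, row, col, amp, inv2s2, w):
    h, wd = g.shape
    ic = int(row + 0.5)
    jc = int(col + 0.5)
    r0 = max(0, ic - w)
    r1 = min(h - 1, ic + w)
    c0 = max(0, jc - w)
    c1 = min(wd - 1, jc + w)
    for i in range(r0, r1 + 1):
        d = i - row
        fr = amp * np.exp(-d * d * inv2s2)
        for j in range(c0, c1 + 1):
            e = j - col
            g[i, j] += fr * np.exp(-e * e * inv2s2)


@njit(cache=True)
def _delta_replace(hm, g, ro, co, ao, rn, cn, an, inv2s2, w):
    """Change in F when grain (ro,co,ao) becomes (rn,cn,an); O(window)."""
    h, wd = hm.shape
    io = int(ro + 0.5)
    jo = int(co + 0.5)
    i_n = int(rn + 0.5)
    j_n = int(cn + 0.5)
    r0 = max(0, min(io, i_n) - w)
    r1 = min(h - 1, max(io, i_n) + w)
    c0 = max(0, min(jo, j_n) - w)
    c1 = min(wd - 1, max(jo, j_n) + w)
    nr = r1 - r0 + 1
    nc = c1 - c0 + 1
    if nr <= 0 or nc <= 0:
        return 0.0
    vco = np.zeros(nc)
    vcn = np.zeros(nc)
    for j in range(nc):
        jj = c0 + j
        if jo - w <= jj <= jo + w:
            e = jj - co
            vco[j] = np.exp(-e * e * inv2s2)
        if j_n - w <= jj <= j_n + w:
            e = jj - cn
            vcn[j] = np.exp(-e * e * inv2s2)
    df = 0.0
    for i in range(r0, r1 + 1):
        fo = 0.0
        fn = 0.0
        if io - w <= i <= io + w:
            d = i - ro
            fo = ao * np.exp(-d * d * inv2s2)
        if i_n - w <= i <= i_n + w:
            d = i - rn
            fn = an * np.exp(-d * d * inv2s2)
        for j in range(nc):
            res = hm[i, c0 + j] - g[i, c0 + j]
            res_new = res + fo * vco[j] - fn * vcn[j]
            df += res_new * res_new - res * res
    return df


@njit(cache=True)
def _best_birth(hm, g, row, col, inv2s2, w):
    """Least-squares amplitude and resulting dF for a grain at (row, col)."""
    h, wd = hm.shape
    ic = int(row + 0.5)
    jc = int(col + 0.5)
    r0 = max(0, ic - w)
    r1 = min(h - 1, ic + w)
    c0 = max(0, jc - w)
    c1 = min(wd - 1, jc + w)
    num = 0.0
    den = 0.0
    for i in range(r0, r1 + 1):
        d = i - row
        fr = np.exp(-d * d * inv2s2)
        for j in range(c0, c1 + 1):
            e = j - col
            u = fr * np.exp(-e * e * inv2s2)
            num += (hm[i, j] - g[i, j]) * u
            den += u * u
    if den <= 0.0 or num <= 0.0:
        return 0.0, 0.0
    amp = num / den
    return amp, -num * num / den


@njit(cache=True)
def _fit_kernel(hm, amps, rows, cols, k0, n_sweeps, therm_sweeps,
                bd_per_sweep, sigma_c, pos0, amp0, anneal_floor, seed):
    np.random.seed(seed)
    h, wd = hm.shape
    w = int(np.ceil(3.0 * sigma_c))
    inv2s2 = 1.0 / (2.0 * sigma_c * sigma_c)
    max_k = amps.shape[0]
    k = k0
    g = np.zeros_like(hm)
    for m in range(k):
        _add_patch(g, rows[m], cols[m], amps[m], inv2s2, w)
    f = 0.0
    for i in range(h):
        for j in range(wd):
            d = hm[i, j] - g[i, j]
            f += d * d
    trace = np.empty(n_sweeps + 1)
    trace[0] = f
    accepted = 0
    births = 0
    deaths = 0
    for sweep in range(n_sweeps):
        t = sweep / max(1, n_sweeps - 1)
        sp = pos0 * (1.0 - (1.0 - anneal_floor) * t)
        sa = amp0 * (1.0 - (1.0 - anneal_floor) * t)
        for _ in range(k):
            m = np.random.randint(k)
            rn = rows[m] + np.random.normal() * sp
            cn = cols[m] + np.random.normal() * sp
            if rn < 0.0:
                rn = 0.0
            elif rn > h - 1.0:
                rn = h - 1.0
            if cn < 0.0:
                cn = 0.0
            elif cn > wd - 1.0:
                cn = wd - 1.0
            an = amps[m] * (1.0 + np.random.normal() * sa)
            if an < 0.0:
                an = 0.0
            df = _delta_replace(hm, g, rows[m], cols[m], amps[m],
                                rn, cn, an, inv2s2, w)
            if df < 0.0:
                _add_patch(g, rows[m], cols[m], -amps[m], inv2s2, w)
                _add_patch(g, rn, cn, an, inv2s2, w)
                rows[m] = rn
                cols[m] = cn
                amps[m] = an
                f += df
                accepted += 1
        if sweep < therm_sweeps:
            for _ in range(bd_per_sweep):
                # birth at the largest positive residual
                best = 0.0
                bi = 0
                bj = 0
                for i in range(h):
                    for j in range(wd):
                        r = hm[i, j] - g[i, j]
                        if r > best:
                            best = r
                            bi = i
                            bj = j
                if best > 0.0 and k < max_k:
                    amp, df = _best_birth(hm, g, float(bi), float(bj),
                                          inv2s2, w)
                    if df < 0.0 and amp > 0.0:
                        _add_patch(g, float(bi), float(bj), amp, inv2s2, w)
                        rows[k] = float(bi)
                        cols[k] = float(bj)
                        amps[k] = amp
                        k += 1
                        f += df
                        births += 1
                # deaths: scan all removal candidates once, then try them in
                # most-harmful-first order (re-evaluating each against the
                # updated model); repeat while any removal strictly lowers F
                improved = True
                while improved and k > 0:
                    improved = False
                    dfs = np.empty(k)
                    for m in range(k):
                        dfs[m] = _delta_replace(hm, g, rows[m], cols[m],
                                                amps[m], rows[m], cols[m],
                                                0.0, inv2s2, w)
                    order = np.argsort(dfs)
                    for oi in range(k):
                        m = order[oi]
                        if dfs[m] >= 0.0:
                            break
                        if amps[m] == 0.0:
                            continue
                        df = _delta_replace(hm, g, rows[m], cols[m], amps[m],
                                            rows[m], cols[m], 0.0, inv2s2, w)
                        if df < 0.0:
                            _add_patch(g, rows[m], cols[m], -amps[m],
                                       inv2s2, w)
                            amps[m] = 0.0
                            f += df
                            deaths += 1
                            improved = True
                    if improved:  # compact out the removed grains
                        keep = 0
                        for m in range(k):
                            if amps[m] > 0.0:
                                amps[keep] = amps[m]
                                rows[keep] = rows[m]
                                cols[keep] = cols[m]
                                keep += 1
                        k = keep
        trace[sweep + 1] = f
    return k, trace, accepted, births, deaths


# ---------------------------------------------------------------------------
# public fitting interface
# ---------------------------------------------------------------------------

def fit_frame(hm: np.ndarray, psf: PsfKernel, cfg_optics: OpticalConfig,
              fit_cfg: FitConfig, k_start: int, seed: int | None = None,
              frame_index: int = 0,
              support_threshold: float = 0.0) -> FitResult:
    """Fit one high-intensity frame with a sum of Gaussian grains.

    ``k_start`` grains are initialized at random positions drawn from the
    above-threshold support of ``hm`` with the local frame value as starting
    amplitude, then refined by strict greedy descent with birth/death moves
    during thermalization.  The returned cost trace is non-increasing.
    """
    hm = np.ascontiguousarray(np.asarray(hm, dtype=np.float64))
    if hm.ndim != 2:
        raise ValueError("hm must be 2-D")
    if not np.all(np.isfinite(hm)):
        raise ValueError("hm contains non-finite pixels")
    if k_start < 0:
        raise ValueError("k_start must be >= 0")
    if seed is None:
        seed = fit_cfg.seed
    sigma_s = grain_sigma_px(cfg_optics, fit_cfg)
    sigma_h = psf.sigma_px
    sigma_c = float(np.hypot(sigma_s, sigma_h))
    famp = sigma_s ** 2 / sigma_c ** 2   # grain peak -> model peak
    h, w = hm.shape

    support = np.flatnonzero(hm > support_threshold)
    rng = np.random.default_rng(seed)
    therm_sweeps = int(round(fit_cfg.n_iterations *
                             fit_cfg.thermalization_fraction))
    max_k = k_start + therm_sweeps * fit_cfg.birth_death_rate + 8
    amps = np.zeros(max_k)
    rows = np.zeros(max_k)
    cols = np.zeros(max_k)
    k0 = 0
    if support.size and k_start > 0:
        idx = rng.choice(support, size=k_start, replace=True)
        rows[:k_start] = idx // w + rng.uniform(-0.5, 0.5, k_start)
        cols[:k_start] = idx % w + rng.uniform(-0.5, 0.5, k_start)
        np.clip(rows[:k_start], 0, h - 1, out=rows[:k_start])
        np.clip(cols[:k_start], 0, w - 1, out=cols[:k_start])
        amps[:k_start] = hm.ravel()[idx]     # effective (model-peak) amplitude
        k0 = k_start

    pos0 = fit_cfg.position_step_px
    if pos0 is None:
        pos0 = 0.5 * cfg_optics.speckle_size_px
    kernel_seed = int(np.uint32(seed if seed >= 0 else -seed) % np.uint32(2**31 - 1))
    k_final, trace, accepted, births, deaths = _fit_kernel(
        hm, amps, rows, cols, k0, int(fit_cfg.n_iterations), therm_sweeps,
        int(fit_cfg.birth_death_rate), sigma_c, float(pos0),
        float(fit_cfg.amplitude_step_frac), float(fit_cfg.anneal_floor),
        kernel_seed)
    if np.any(np.diff(trace) > 1e-6 * max(1.0, abs(trace[0]))):
        raise RuntimeError("cost trace increased: descent invariant violated")
    keep = amps[:k_final] > 0
    gs = GrainSet(amplitudes=amps[:k_final][keep] / famp,
                  rows=rows[:k_final][keep], cols=cols[:k_final][keep],
                  grain_sigma_px=sigma_s, frame_index=frame_index)
    return FitResult(grain_set=gs, cost_trace=trace, accepted_moves=int(accepted),
                     n_births=int(births), n_deaths=int(deaths))


def frame_seed(master_seed: int, frame_index: int) -> int:
    """Deterministic, order-independent per-frame seed."""
    return int(np.random.SeedSequence((master_seed, frame_index))
               .generate_state(1)[0] % (2**31 - 1))


def fit_stack(hm_stack, psf: PsfKernel, cfg_optics: OpticalConfig,
              fit_cfg: FitConfig, k_start: int,
              support_threshold: float = 0.0) -> list[FitResult]:
    """Fit every frame independently with per-frame deterministic seeds."""
    frames = hm_stack.frames if hasattr(hm_stack, "frames") \
        else np.asarray(hm_stack, dtype=float)
    results = []
    for n in range(frames.shape[0]):
        results.append(fit_frame(frames[n], psf, cfg_optics, fit_cfg, k_start,
                                 seed=frame_seed(fit_cfg.seed, n),
                                 frame_index=n,
                                 support_threshold=support_threshold))
    return results
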