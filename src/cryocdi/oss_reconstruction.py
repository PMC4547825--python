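"""Iterative phase retrieval with oversampling smoothness (OSS).

The measured quantity is the Fourier modulus |F| on the known voxels of the
assembled 3D intensity volume; the phases are lost.  Each iteration projects
onto the data (replace moduli by sqrt(intensity) on known voxels, keep the
current phases; unknown voxels — beamstop cone, missing wedge, gaps — float
at their calculated values) and then applies the hybrid input-output (HIO)
real-space update: keep the projected density inside the support, drive it
down with feedback beta outside.  OSS augments HIO by replacing the
out-of-support region with its Gaussian low-pass-filtered version,
W(k) = exp(-k^2 / (2 alpha^2)), with the filter width alpha stepped down
over a fixed number of stages from ~N (no filtering) to ~N/10; at each stage
boundary the lowest-residual iterate seen so far is restored.

Progress is monitored by the modulus residual

    R_rec = sum_known | |F_exp| - gamma |F_calc| | / sum_known |F_exp|,

with gamma the least-squares amplitude scale.  An ensemble of independently
seeded reconstructions is run, the lowest-R members aligned (integer shift +
centro-inversion ambiguity) and averaged; a tight support is derived from a
first-pass average and the ensemble repeated — the two-stage protocol.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .fourier_assembly import FourierIntensityVolume
from .geometry_phantom import DensityVolume

__all__ = [
    "OSSConfig",
    "SupportMask",
    "ReconstructionResult",
    "rfactor",
    "oss_step",
    "run_ensemble",
    "derive_support",
    "cubic_support",
    "two_stage_reconstruct",
    "align_volumes",
]


def _cfftn(x: np.ndarray) -> np.ndarray:
    """FFT with the zero-frequency voxel at index N//2 on both sides."""
    return np.fft.fftshift(np.fft.fftn(np.fft.ifftshift(x)))


def _cifftn(x: np.ndarray) -> np.ndarray:
    return np.fft.fftshift(np.fft.ifftn(np.fft.ifftshift(x)))


@dataclass
class OSSConfig:
    """Ensemble phase-retrieval settings.

    Defaults mirror a full production run: 100 seeds of 1000 iterations, the
    best 10 averaged, HIO feedback 0.9, ten filter stages.  ``alpha_start`` /
    ``alpha_end`` default to N and N/10 (in Fourier voxels) when left None.
    """

    n_iterations: int = 1000
    beta: float = 0.9
    n_filter_stages: int = 10
    alpha_start: float | None = None
    alpha_end: float | None = None
    n_seeds: int = 100
    keep_best: int = 10
    positivity: bool = True
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_iterations <= 0 or self.n_iterations % self.n_filter_stages:
            raise ValueError("n_iterations must be a positive multiple of n_filter_stages")
        if self.keep_best <= 0 or self.keep_best > self.n_seeds:
            raise ValueError("keep_best must lie in [1, n_seeds]")
        if self.alpha_start is not None and self.alpha_end is not None:
            if not (self.alpha_start >= self.alpha_end > 0):
                raise ValueError("require alpha_start >= alpha_end > 0")

    def alphas(self, grid_side: int) -> np.ndarray:
        start = grid_side if self.alpha_start is None else self.alpha_start
        end = grid_side / 10.0 if self.alpha_end is None else self.alpha_end
        return np.linspace(start, end, self.n_filter_stages)


@dataclass
class SupportMask:
    """Boolean real-space support; nonempty and at most half the grid."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise ValueError("support mask is empty")
        if self.mask.mean() > 0.5:
            raise ValueError("support exceeds half the grid: modulus constraint unsolvable")


@dataclass
class ReconstructionResult:
    density: DensityVolume
    support: SupportMask
    r_trace: np.ndarray
    final_r: float
    seed: int


def rfactor(modulus_exp: np.ndarray, modulus_calc: np.ndarray,
            known_mask: np.ndarray) -> tuple[float, float]:
    """Modulus residual R_rec and its fitted scale gamma.

    gamma is the least-squares scale sum(|Fe||Fc|)/sum(|Fc|^2) over known
    voxels; R = sum | |Fe| - gamma |Fc| | / sum |Fe|.
    """
    fe = np.abs(modulus_exp[known_mask])
    fc = np.abs(modulus_calc[known_mask])
    se = float(fe.sum())
    if fe.size == 0 or se == 0.0:
        raise ValueError("experimental modulus is empty or all-zero on known voxels")
    denom = float((fc * fc).sum())
    gamma = float((fe * fc).sum()) / denom if denom > 0 else 0.0
    r = float(np.abs(fe - gamma * fc).sum() / se)
    return r, gamma


def _modulus_project(f: np.ndarray, modulus: np.ndarray,
                     known: np.ndarray) -> np.ndarray:
    """Replace |F| by the measured modulus on known voxels, keeping phases."""
    mag = np.abs(f)
    phase = np.where(mag > 0, f / np.where(mag > 0, mag, 1.0), 1.0)
    return np.where(known, modulus * phase, f)


def _gaussian_filter_kernel(n: int, alpha: float) -> np.ndarray:
    """Centered W(k) = exp(-|k|^2 / (2 alpha^2)), k in Fourier voxels."""
    k = np.arange(n) - n // 2
    kx, ky, kz = np.meshgrid(k, k, k, indexing="ij")
    return np.exp(-(kx ** 2 + ky ** 2 + kz ** 2) / (2.0 * alpha ** 2))


def _real_space_update(rho: np.ndarray, rho_proj: np.ndarray, support: np.ndarray,
                       alpha: float, beta: float, positivity: bool) -> np.ndarray:
    """HIO feedback plus the OSS out-of-support smoothing at width alpha."""
    keep = support & (rho_proj >= 0 if positivity else np.ones_like(support))
    new = np.where(keep, rho_proj, rho - beta * rho_proj)
    outside = ~support
    if np.isfinite(alpha):
        w = _gaussian_filter_kernel(rho.shape[0], alpha)
        smoothed = _cifftn(_cfftn(np.where(outside, new, 0.0)) * w).real
        new = np.where(outside, smoothed, new)
    return new


def oss_step(current: np.ndarray, modulus: np.ndarray, known_mask: np.ndarray,
             support: np.ndarray, alpha: float, beta: float = 0.9,
             positivity: bool = True) -> np.ndarray:
    """One OSS iteration on a centered real-space iterate.

    With ``alpha = inf`` the smoothing is skipped and the step is plain HIO.
    """
    f = _cfftn(current)
    rho_proj = _cifftn(_modulus_project(f, modulus, known_mask)).real
    return _real_space_update(current, rho_proj, support, alpha, beta, positivity)


def _run_single(modulus: np.ndarray, known: np.ndarray, support: np.ndarray,
                config: OSSConfig, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """One seeded OSS reconstruction; returns (best density, R trace)."""
    n = modulus.shape[0]
    phases = rng.uniform(-np.pi, np.pi, size=modulus.shape)
    f0 = np.where(known, modulus, 0.0) * np.exp(1j * phases)
    rho = _cifftn(f0).real

    alphas = config.alphas(n)
    per_stage = config.n_iterations // config.n_filter_stages
    best_rho = rho.copy()
    best_r = np.inf
    trace = np.empty(config.n_iterations + 1)
    it = 0
    for alpha in alphas:
        for _ in range(per_stage):
            f = _cfftn(rho)
            r, _ = rfactor(modulus, np.abs(f), known)
            trace[it] = r
            it += 1
            if r < best_r:
                best_r, best_rho = r, rho.copy()
            rho_proj = _cifftn(_modulus_project(f, modulus, known)).real
            rho = _real_space_update(rho, rho_proj, support, alpha,
                                     config.beta, config.positivity)
        rho = best_rho.copy()  # restart each stage from the best iterate so far
    trace[it] = best_r
    return best_rho, trace


def _invert(vol: np.ndarray) -> np.ndarray:
    """Centro-inversion about the grid centre N//2 (the twin image)."""
    return np.roll(vol[::-1, ::-1, ::-1], shift=(1, 1, 1), axis=(0, 1, 2))


def align_volumes(reference: np.ndarray, vol: np.ndarray) -> np.ndarray:
    """Align ``vol`` to ``reference`` by integer shift, resolving the
    conjugate-inversion (twin) ambiguity by trying both orientations."""
    fr = np.fft.fftn(reference)
    best = None
    best_score = -np.inf
    for cand in (vol, _invert(vol)):
        cc = np.fft.ifftn(fr * np.conj(np.fft.fftn(cand))).real
        shift = np.unravel_index(np.argmax(cc), cc.shape)
        score = cc[shift]
        if score > best_score:
            best_score = score
            best = np.roll(cand, shift, axis=(0, 1, 2))
    return best


def run_ensemble(intensity: FourierIntensityVolume, support: SupportMask,
                 config: OSSConfig,
                 voxel_size_nm: float = 1.0) -> tuple[list[ReconstructionResult], DensityVolume]:
    """Run ``n_seeds`` independent reconstructions and average the best.

    Members are sorted by final R_rec; the ``keep_best`` lowest are aligned to
    the first of them and averaged voxel-wise.  Deterministic for a fixed
    ``config.rng_seed``.
    """
    modulus = np.sqrt(np.clip(intensity.intensities, 0.0, None))
    known = intensity.known_mask
    if support.mask.shape != modulus.shape:
        raise ValueError("support and intensity grids differ")

    ss = np.random.SeedSequence(config.rng_seed)
    children = ss.spawn(config.n_seeds)
    results = []
    for i, child in enumerate(children):
        rho, trace = _run_single(modulus, known, support.mask, config,
                                 np.random.default_rng(child))
        dens = DensityVolume(np.clip(rho, 0.0, None), voxel_size_nm)
        results.append(ReconstructionResult(density=dens, support=support,
                                            r_trace=trace, final_r=float(trace[-1]),
                                            seed=i))
    results.sort(key=lambda r: r.final_r)

    best = results[: config.keep_best]
    ref = best[0].density.values
    stack = [ref] + [align_volumes(ref, r.density.values) for r in best[1:]]
    avg = np.mean(stack, axis=0)
    return results, DensityVolume(np.clip(avg, 0.0, None), voxel_size_nm)


def cubic_support(grid_side: int, side: int | None = None) -> SupportMask:
    """A centered cube, defaulting to half the grid per axis."""
    side = grid_side // 2 if side is None else side
    lo = grid_side // 2 - side // 2
    mask = np.zeros((grid_side,) * 3, dtype=bool)
    mask[lo:lo + side, lo:lo + side, lo:lo + side] = True
    return SupportMask(mask)


def derive_support(average: DensityVolume, threshold_frac: float = 0.1,
                   dilation: int = 2,
                   within: np.ndarray | None = None) -> SupportMask:
    """Tight support: largest connected component above a density threshold,
    dilated by ``dilation`` voxels.

    ``within`` optionally restricts the thresholded region (e.g. to the
    previous stage's support) before labelling, so the derived support is
    contained in the dilation of the prior one by construction.
    """
    if not 0.0 < threshold_frac < 1.0:
        raise ValueError("threshold_frac must lie in (0, 1)")
    vals = average.values
    above = vals >= threshold_frac * vals.max()
    if within is not None:
        above &= within
    if not above.any():
        raise ValueError("no voxels above threshold")
    labels, nlab = ndimage.label(above)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, nlab + 1))
    mask = labels == (1 + int(np.argmax(sizes)))
    if dilation > 0:
        zz, yy, xx = np.mgrid[-dilation:dilation + 1, -dilation:dilation + 1,
                              -dilation:dilation + 1]
        ball = zz ** 2 + yy ** 2 + xx ** 2 <= dilation ** 2
        mask = ndimage.binary_dilation(mask, structure=ball)
    return SupportMask(mask)


def two_stage_reconstruct(intensity: FourierIntensityVolume, config: OSSConfig,
                          voxel_size_nm: float = 1.0,
                          support_threshold: float = 0.1,
                          support_dilation: int = 2,
                          return_members: bool = False):
    """Loose-support ensemble -> tight support -> final ensemble average.

    Stage 1 uses a centered cubic support of half the grid per axis.  The
    stage-1 average is thresholded (within that cube) and dilated to give the
    tight support for stage 2.  The returned density is the aligned average
    of the best stage-2 members; ``final_r`` is its own modulus residual
    against the data.
    """
    n = intensity.grid_side
    sup1 = cubic_support(n)
    _, avg1 = run_ensemble(intensity, sup1, config, voxel_size_nm)
    sup2 = derive_support(avg1, support_threshold, support_dilation,
                          within=sup1.mask)

    stage2_cfg = OSSConfig(n_iterations=config.n_iterations, beta=config.beta,
                           n_filter_stages=config.n_filter_stages,
                           alpha_start=config.alpha_start,
                           alpha_end=config.alpha_end, n_seeds=config.n_seeds,
                           keep_best=config.keep_best,
                           positivity=config.positivity,
                           rng_seed=config.rng_seed + 1)
    results2, avg2 = run_ensemble(intensity, sup2, stage2_cfg, voxel_size_nm)

    modulus = np.sqrt(np.clip(intensity.intensities, 0.0, None))
    final_r, _ = rfactor(modulus, np.abs(_cfftn(avg2.values)), intensity.known_mask)
    trace = np.append(results2[0].r_trace, final_r)
    result = ReconstructionResult(density=avg2, support=sup2, r_trace=trace,
                                  final_r=float(final_r), seed=config.rng_seed)
    if return_members:
        return result, results2
    return result
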