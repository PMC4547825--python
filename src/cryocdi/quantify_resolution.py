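"""Quantitative post-analysis: dosimetry, electron count, mass density,
oversampling ratios, PRTF and line-scan resolution, threshold segmentation.

Dosimetry uses the thin-sample surface-dose estimate

    D_p = (mu/rho) * (P_t/A) * E_photon        [Gy per projection]

with the mass attenuation coefficient mu/rho in cm^2/g, the fluence P_t/A in
photons/um^2 and the photon energy converted to joules; the total dose is the
per-projection dose times the number of projections.

The absolute intensity of the central speckle ties the diffraction data to
the electron content of the specimen:

    I(0) = I0 * r_e^2 * N_e^2 * dA / r^2   =>   N_e = sqrt(I(0) r^2 / (I0 r_e^2 dA)),

and for biological material of typical protein composition the molecular
weight is M ~= 1.88 * N_e atomic mass units, which converts the electron
count into an average mass density given the segmented cell volume.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .forward_simulator import R_E_M
from .fourier_assembly import FourierIntensityVolume
from .geometry_phantom import DensityVolume, ExperimentGeometry

__all__ = [
    "DoseParams",
    "PRTFCurve",
    "dose_per_projection",
    "total_dose",
    "electrons_from_central_speckle",
    "mass_density",
    "oversampling_ratios",
    "compute_prtf",
    "linescan_resolution",
    "segment_threshold",
]

KEV_TO_J = 1.602177e-16   # joules per keV
AMU_G = 1.66054e-24       # atomic mass unit, g
PROTEIN_MASS_PER_ELECTRON = 1.88  # amu per electron for H50 C30 N9 O10 S composition


class OversamplingWarning(UserWarning):
    """Linear oversampling below 2 on some axis: phase problem ill-posed."""


@dataclass(frozen=True)
class DoseParams:
    """Inputs of the dose estimate (units in the field names' docs above)."""

    mass_attenuation_cm2_g: float
    fluence_per_um2: float
    photon_energy_kev: float
    n_projections: int = 1

    def __post_init__(self) -> None:
        if min(self.mass_attenuation_cm2_g, self.fluence_per_um2,
               self.photon_energy_kev) < 0 or self.n_projections < 1:
            raise ValueError("dose parameters must be nonnegative (n_projections >= 1)")


def dose_per_projection(params: DoseParams) -> float:
    """Absorbed dose of a single exposure, in Gy.

    Unit bookkeeping: (cm^2/g) -> 0.1 m^2/kg and (photons/um^2) -> 1e12
    photons/m^2, so the product with the photon energy in J is J/kg.
    """
    mu_rho_m2_kg = params.mass_attenuation_cm2_g * 0.1
    fluence_m2 = params.fluence_per_um2 * 1e12
    energy_j = params.photon_energy_kev * KEV_TO_J
    return mu_rho_m2_kg * fluence_m2 * energy_j


def total_dose(dose_p: float, n_projections: int) -> float:
    """Accumulated dose of the whole tilt series, in Gy."""
    if n_projections < 1:
        raise ValueError("n_projections must be >= 1")
    return dose_p * n_projections


def electrons_from_central_speckle(central_counts: float, fluence_per_um2: float,
                                   pixel_area_um2: float, distance_m: float) -> float:
    """Total electron count from the absolute central-speckle intensity.

    Inverts I(0) = I0 r_e^2 N_e^2 dA / r^2 for N_e.
    """
    if min(central_counts, fluence_per_um2, pixel_area_um2, distance_m) <= 0:
        raise ValueError("all inputs must be positive")
    return float(np.sqrt(central_counts * distance_m ** 2
                         / (fluence_per_um2 * R_E_M ** 2 * pixel_area_um2)))


def mass_density(n_electrons: float, volume_um3: float) -> float:
    """Average mass density in g/cm^3 from the electron count and cell volume."""
    if volume_um3 <= 0:
        raise ValueError("volume must be positive")
    mass_g = PROTEIN_MASS_PER_ELECTRON * n_electrons * AMU_G
    return mass_g / (volume_um3 * 1e-12)  # um^3 -> cm^3


def oversampling_ratios(geometry: ExperimentGeometry,
                        support_extent_um: tuple[float, float, float]) -> np.ndarray:
    """Linear oversampling per axis: field of view over support extent.

    Emits :class:`OversamplingWarning` when any ratio is below 2, the minimum
    for a solvable oversampled phase problem.
    """
    extents = np.asarray(support_extent_um, dtype=np.float64)
    if np.any(extents <= 0):
        raise ValueError("support extents must be positive")
    ratios = geometry.field_of_view_um / extents
    if np.any(ratios < 2.0):
        warnings.warn("linear oversampling < 2 on at least one axis",
                      OversamplingWarning, stacklevel=2)
    return ratios


@dataclass
class PRTFCurve:
    """Shell-averaged phase retrieval transfer function.

    ``shell_radius_vox`` are Fourier shell radii in voxels; ``values`` the
    PRTF in [0, 1]; ``voxel_size_nm`` fixes the frequency scale.
    """

    shell_radius_vox: np.ndarray
    values: np.ndarray
    voxel_size_nm: float
    grid_side: int
    n_valid: np.ndarray | None = None

    def frequency_per_nm(self) -> np.ndarray:
        return self.shell_radius_vox / (self.grid_side * self.voxel_size_nm)

    def resolution_nm(self, threshold: float = 0.5) -> tuple[float, bool]:
        """Full-period resolution at the given PRTF threshold.

        Scans outward from the centre over shells that contain measured
        voxels (a central beamstop leaves the innermost shells empty) and
        reports the last such shell before the curve first drops below the
        threshold.  Returns (resolution_nm, at_band_edge): when the curve
        never drops below the threshold, the band-edge resolution is returned
        with the flag set.
        """
        valid = (self.n_valid > 0 if self.n_valid is not None
                 else np.ones(len(self.values), bool))
        idx = np.nonzero(valid)[0]
        if idx.size == 0:
            raise ValueError("PRTF curve has no populated shells")
        vals = self.values[idx]
        radii = self.shell_radius_vox[idx]
        below = np.nonzero(vals < threshold)[0]
        if below.size == 0:
            return float(self.grid_side * self.voxel_size_nm / radii[-1]), True
        # floor at one voxel: a crossing at the innermost populated shell
        # means nothing beyond the very lowest frequencies is retrieved
        radius = max(radii[below[0] - 1] if below[0] > 0 else radii[0], 1.0)
        return float(self.grid_side * self.voxel_size_nm / radius), False


def compute_prtf(member_transforms: list[np.ndarray] | np.ndarray,
                 measured_intensity: FourierIntensityVolume,
                 voxel_size_nm: float = 1.0) -> PRTFCurve:
    """PRTF(q) = |mean_k F_k(q)| / sqrt(I_meas(q)), shell-averaged.

    Member transforms must be centered (zero frequency at N//2) and aligned in
    real space beforehand.  Voxels that are unknown or have zero measured
    intensity are excluded; values are capped at 1.
    """
    members = np.asarray(member_transforms)
    if members.ndim != 4 or members.shape[0] < 2:
        raise ValueError("need at least two aligned member transforms")
    n = measured_intensity.grid_side
    if members.shape[1:] != (n, n, n):
        raise ValueError("member transforms do not match the intensity grid")

    mean_f = np.abs(members.mean(axis=0))
    meas = measured_intensity.intensities
    valid = measured_intensity.known_mask & (meas > 0)
    ratio = np.zeros((n, n, n))
    ratio[valid] = np.minimum(mean_f[valid] / np.sqrt(meas[valid]), 1.0)

    k = np.arange(n) - n // 2
    kx, ky, kz = np.meshgrid(k, k, k, indexing="ij")
    shell = np.rint(np.sqrt(kx ** 2 + ky ** 2 + kz ** 2)).astype(int)
    nshell = n // 2 + 1
    radii = np.arange(nshell, dtype=np.float64)
    values = np.zeros(nshell)
    n_valid = np.zeros(nshell, dtype=np.int64)
    for s in range(nshell):
        sel = (shell == s) & valid
        n_valid[s] = sel.sum()
        if n_valid[s]:
            values[s] = ratio[sel].mean()
    return PRTFCurve(shell_radius_vox=radii, values=values,
                     voxel_size_nm=voxel_size_nm, grid_side=n,
                     n_valid=n_valid)


def _edge_rise_distance(profile: np.ndarray) -> float:
    """10-90% rise distance (in samples) of the steepest edge of a 1D profile."""
    grad = np.gradient(profile)
    edge = int(np.argmax(np.abs(grad)))
    sign = np.sign(grad[edge]) or 1.0
    p = profile if sign > 0 else profile[::-1]
    e = edge if sign > 0 else len(p) - 1 - edge

    # plateau levels on either side of the edge: local extrema bounding the rise
    lo_seg = p[: e + 1]
    hi_seg = p[e:]
    low = float(lo_seg.min())
    high = float(hi_seg.max())
    span = high - low
    if span <= 0:
        raise ValueError("no rising edge found")
    t10 = low + 0.10 * span
    t90 = low + 0.90 * span

    def crossing(level: float) -> float:
        # last upward crossing of `level` at or before the 90% point on the rise
        above = p >= level
        idx = np.nonzero(~above[:-1] & above[1:])[0]
        if idx.size == 0:
            return float(np.argmax(above))
        # pick the crossing nearest the steepest-gradient sample
        i = idx[np.argmin(np.abs(idx - e))]
        frac = (level - p[i]) / (p[i + 1] - p[i])
        return float(i + frac)

    x10 = crossing(t10)
    x90 = crossing(t90)
    if x90 <= x10:
        return 1.0  # sub-sample edge: floor of one sample
    return x90 - x10


def linescan_resolution(volume: DensityVolume, axis: str,
                        line_position: tuple[int, int] | None = None,
                        noise_sigma: float | None = None) -> float:
    """Resolution estimate from the 10-90% rise of the sharpest density edge
    along one primary axis, in nm.

    ``line_position`` gives the indices on the two remaining axes (defaults to
    the grid centre).  If the edge contrast is below 3x the profile noise
    (estimated from the line's high-frequency residual unless supplied), the
    edge is deemed unresolvable and an error is raised.
    """
    axes = {"X": 0, "Y": 1, "Z": 2}
    if axis.upper() not in axes:
        raise ValueError("axis must be one of X, Y, Z")
    ax = axes[axis.upper()]
    n = volume.grid_side
    i, j = (n // 2, n // 2) if line_position is None else line_position
    index: list[object] = [i, j]
    index.insert(ax, slice(None))
    profile = volume.values[tuple(index)].astype(np.float64)

    if noise_sigma is None:
        noise_sigma = float(np.abs(np.diff(profile, n=2)).mean() / np.sqrt(6))
    contrast = float(profile.max() - profile.min())
    if contrast < 3.0 * noise_sigma:
        raise ValueError("no edge with contrast >= 3x the profile noise")
    rise = _edge_rise_distance(profile)
    return rise * volume.voxel_size_nm


def segment_threshold(volume: DensityVolume,
                      threshold_frac: float = 0.10) -> tuple[np.ndarray, float]:
    """Cell-bound segmentation: voxels above a fraction of the peak density.

    Keeps the largest connected component and returns (mask, volume in um^3).
    """
    if not 0.0 < threshold_frac < 1.0:
        raise ValueError("threshold_frac must lie in (0, 1)")
    vals = volume.values
    above = vals >= threshold_frac * vals.max()
    if not above.any() or vals.max() <= 0:
        raise ValueError("no voxels above threshold")
    labels, nlab = ndimage.label(above)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels,
                               index=np.arange(1, nlab + 1))
    mask = labels == (1 + int(np.argmax(sizes)))
    vol_um3 = float(mask.sum()) * volume.voxel_volume_um3
    return mask, vol_um3
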