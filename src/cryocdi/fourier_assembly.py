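"""Assembly of the 3D diffraction volume from tilted 2D patterns.

Under the flat-Ewald-sphere approximation each pattern samples a central
plane of the object's 3D Fourier intensity, tilted by its acquisition angle
about the Y axis.  Gridding deposits every known pattern pixel at its rotated
plane coordinate and fills each Fourier voxel with the inverse-distance-
weighted mean of the samples within a capture radius:

    I(voxel) = sum_i w_i I_i / sum_i w_i,   w_i = d_i^(-p),

with an exact-hit cap so a sample landing on a voxel centre determines it.
Voxels with no sample in range stay unknown — this is where the missing wedge
(tilt range < +-90 deg) and the beamstop cone live.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .forward_simulator import TiltSeries, _rotation_matrix_y

__all__ = ["FourierIntensityVolume", "assemble_intensity"]

_EXACT_HIT_DIST = 1e-6


@dataclass
class FourierIntensityVolume:
    """Gridded 3D diffraction intensities with interpolation weights.

    ``intensities`` and ``weight_sum`` are N^3 arrays in the centered frame
    (zero frequency at index N//2); ``known_mask`` is True exactly where
    ``weight_sum > 0``.
    """

    intensities: np.ndarray
    weight_sum: np.ndarray
    known_mask: np.ndarray

    def __post_init__(self) -> None:
        if not (self.intensities.shape == self.weight_sum.shape == self.known_mask.shape):
            raise ValueError("component shapes differ")
        if np.any(self.known_mask != (self.weight_sum > 0)):
            raise ValueError("known_mask must equal weight_sum > 0")
        if np.any(self.intensities[self.known_mask] < 0):
            raise ValueError("known intensities must be nonnegative")

    @property
    def grid_side(self) -> int:
        return self.intensities.shape[0]

    @property
    def known_fraction(self) -> float:
        return float(self.known_mask.mean())


def _plane_coordinates(n_grid: int, detector_side: int, angle_deg: float,
                       known: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """3D Fourier coordinates (centered, voxel units) of known pattern pixels.

    A pattern pixel at centered detector coordinates (u, v) maps to
    q = R(-angle) @ (u, v, 0): the plane tilted with the sample.  Pixels whose
    in-plane coordinates fall outside the (possibly cropped) grid are dropped.
    Returns (coords 3xM, flat pixel indices M).
    """
    cd = detector_side // 2
    ii, jj = np.nonzero(known)
    u = ii - cd
    v = jj - cd
    half = n_grid // 2
    keep = (np.abs(u) <= half) & (np.abs(v) <= half)
    u, v = u[keep], v[keep]
    rot = _rotation_matrix_y(-angle_deg)
    coords = rot @ np.stack([u, v, np.zeros_like(u, dtype=np.float64)])
    flat = ii[keep] * detector_side + jj[keep]
    return coords, flat


def assemble_intensity(series: TiltSeries, grid_side: int | None = None,
                       idw_power: float = 2.0,
                       idw_radius: float = 0.71) -> FourierIntensityVolume:
    """Grid a Friedel-symmetrized tilt series onto an N^3 Fourier volume.

    ``grid_side`` defaults to the detector side; a smaller value is a centered
    crop (lower band limit).  ``idw_radius`` is the capture radius in voxels
    around each sample; the default 0.71 (half a voxel diagonal in 2D) keeps
    each plane local while leaving no holes along its own grid.
    """
    if not series.patterns:
        raise ValueError("empty tilt series")
    n = series.geometry.detector_side if grid_side is None else int(grid_side)
    if n <= 0 or n % 2:
        raise ValueError("grid_side must be a positive even integer")

    num = np.zeros(n ** 3)
    den = np.zeros(n ** 3)
    exact_num = np.zeros(n ** 3)
    exact_cnt = np.zeros(n ** 3)
    ctr = n // 2
    offsets = np.array(np.meshgrid([0, 1], [0, 1], [0, 1], indexing="ij")).reshape(3, -1).T

    for pat in series.patterns:
        coords, flat = _plane_coordinates(n, series.geometry.detector_side,
                                          pat.tilt_angle_deg, pat.known_mask)
        if coords.shape[1] == 0:
            continue
        vals = pat.counts.ravel()[flat]
        base = np.floor(coords).astype(np.int64)
        for off in offsets:
            vox = base + off[:, None]
            d = np.sqrt(((coords - vox) ** 2).sum(axis=0))
            idx = vox + ctr
            ok = ((d <= idw_radius)
                  & (idx >= 0).all(axis=0) & (idx < n).all(axis=0))
            if not ok.any():
                continue
            d_ok = d[ok]
            lin = (idx[0, ok] * n + idx[1, ok]) * n + idx[2, ok]
            hit = d_ok < _EXACT_HIT_DIST
            # a sample landing on a voxel centre determines it exactly;
            # coincident exact hits are averaged
            np.add.at(exact_num, lin[hit], vals[ok][hit])
            np.add.at(exact_cnt, lin[hit], 1.0)
            w = d_ok[~hit] ** (-idw_power)
            np.add.at(num, lin[~hit], w * vals[ok][~hit])
            np.add.at(den, lin[~hit], w)

    exact = exact_cnt > 0
    intensities = np.zeros(n ** 3)
    known_flat = exact | (den > 0)
    idw_only = ~exact & (den > 0)
    intensities[exact] = exact_num[exact] / exact_cnt[exact]
    intensities[idw_only] = num[idw_only] / den[idw_only]
    np.clip(intensities, 0.0, None, out=intensities)
    weight_sum = np.where(exact, exact_cnt, den)
    return FourierIntensityVolume(intensities=intensities.reshape(n, n, n),
                                  weight_sum=weight_sum.reshape(n, n, n),
                                  known_mask=known_flat.reshape(n, n, n))
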