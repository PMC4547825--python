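"""Experiment geometry and synthetic cell phantoms.

The geometry describes a lens-less diffraction setup: a coherent X-ray beam
illuminates a frozen-hydrated cell and a pixel-array detector far downstream
records the far-field intensity.  The real-space sampling interval of any
image reconstructed from such a pattern is fixed by the geometry,

    dx = lambda * r / (N * p),

with wavelength lambda, camera length r, detector side N pixels and pixel
pitch p.  The phantom generator produces a compact, nonnegative 3D electron
density shaped like an apicomplexan tachyzoite: a bent ("banana") prolate
ellipsoid with denser ellipsoidal organelles concentrated toward the apical
end.  Compact support with generous zero margin is what makes the phase
problem of the downstream reconstruction solvable (linear oversampling >= 2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "HC_KEV_ANGSTROM",
    "ExperimentGeometry",
    "DensityVolume",
    "Organelle",
    "PhantomSpec",
    "make_geometry",
    "generate_phantom",
    "default_phantom_spec",
]

# h*c in keV * Angstrom; wavelength[A] = HC / energy[keV]
HC_KEV_ANGSTROM = 12.398


class InvalidParameterError(ValueError):
    """An experiment parameter is out of its physical domain."""


class GeometryError(ValueError):
    """A phantom does not fit the grid with the required oversampling margin."""


@dataclass(frozen=True)
class ExperimentGeometry:
    """Beam, camera and detector description of one acquisition.

    Parameters
    ----------
    photon_energy_kev : float
        Photon energy E in keV.
    camera_length_m : float
        Sample-to-detector distance r in metres.
    pixel_pitch_um : float
        Detector pixel pitch p in micrometres.
    detector_side : int
        Detector side length N in pixels (even).
    beamstop_radius_px : float
        Radius of the central beamstop disk, in pixels.
    gap_width_px : int
        Width of the dead cross between the 2x2 detector modules, in pixels.
    fluence_per_um2 : float
        Incident fluence per exposure, photons / um^2.
    exposure_s : float
        Exposure time per pattern, seconds.
    """

    photon_energy_kev: float
    camera_length_m: float
    pixel_pitch_um: float
    detector_side: int
    beamstop_radius_px: float = 6.0
    gap_width_px: int = 4
    fluence_per_um2: float = 4.99e9
    exposure_s: float = 100.0

    def __post_init__(self) -> None:
        for name in ("photon_energy_kev", "camera_length_m", "pixel_pitch_um",
                     "fluence_per_um2", "exposure_s"):
            if not np.isfinite(getattr(self, name)) or getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be positive, got {getattr(self, name)!r}")
        if self.detector_side <= 0 or self.detector_side % 2 != 0:
            raise InvalidParameterError(
                f"detector_side must be a positive even integer, got {self.detector_side}")
        if self.beamstop_radius_px < 0 or self.gap_width_px < 0:
            raise InvalidParameterError("beamstop radius and gap width must be >= 0")

    @property
    def wavelength_angstrom(self) -> float:
        """Photon wavelength in Angstrom, lambda = 12.398 / E[keV]."""
        return HC_KEV_ANGSTROM / self.photon_energy_kev

    @property
    def pixel_size_nm(self) -> float:
        """Real-space sampling interval dx = lambda*r/(N*p), in nm."""
        lam_m = self.wavelength_angstrom * 1e-10
        return lam_m * self.camera_length_m / (self.detector_side * self.pixel_pitch_um * 1e-6) * 1e9

    @property
    def field_of_view_um(self) -> float:
        """Reconstructed field of view N*dx = lambda*r/p, in um."""
        return self.detector_side * self.pixel_size_nm * 1e-3

    @property
    def pixel_area_um2(self) -> float:
        return self.pixel_pitch_um ** 2

    def gap_layout(self) -> list[tuple[int, int]]:
        """Index ranges [lo, hi) of dead rows/columns between the 2x2 modules."""
        if self.gap_width_px == 0:
            return []
        c = self.detector_side // 2
        half = self.gap_width_px / 2.0
        lo = int(np.floor(c - half))
        hi = int(np.ceil(c + half))
        return [(lo, hi)]


def make_geometry(energy_kev: float,
                  camera_length_m: float,
                  pixel_pitch_um: float,
                  detector_side: int,
                  beamstop_radius_px: float = 6.0,
                  gap_width_px: int = 4,
                  fluence_per_um2: float = 4.99e9,
                  exposure_s: float = 100.0) -> ExperimentGeometry:
    """Build an :class:`ExperimentGeometry`, validating all parameters."""
    return ExperimentGeometry(
        photon_energy_kev=energy_kev,
        camera_length_m=camera_length_m,
        pixel_pitch_um=pixel_pitch_um,
        detector_side=detector_side,
        beamstop_radius_px=beamstop_radius_px,
        gap_width_px=gap_width_px,
        fluence_per_um2=fluence_per_um2,
        exposure_s=exposure_s,
    )


@dataclass
class DensityVolume:
    """3D electron density on a cubic voxel grid.

    ``values`` holds electrons per voxel; ``voxel_size_nm`` is the cubic voxel
    edge in nm.  The density is centered on the grid with the geometric centre
    at index N//2 along each axis.
    """

    values: np.ndarray
    voxel_size_nm: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3 or len(set(self.values.shape)) != 1:
            raise ValueError("values must be a cubic 3D array")
        if self.voxel_size_nm <= 0:
            raise ValueError("voxel_size_nm must be positive")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("density contains non-finite values")
        if np.any(self.values < 0):
            raise ValueError("electron density must be nonnegative")

    @property
    def grid_side(self) -> int:
        return self.values.shape[0]

    @property
    def total_electrons(self) -> float:
        return float(self.values.sum())

    @property
    def voxel_volume_um3(self) -> float:
        return (self.voxel_size_nm * 1e-3) ** 3


@dataclass(frozen=True)
class Organelle:
    """An ellipsoidal density excursion inside the cell.

    ``center_um`` is the offset of the organelle centre from the cell centre in
    the cell's own (straight) frame; ``semi_axes_um`` its semi-axes; ``contrast``
    the density added inside, as a multiple of the cell base density.
    """

    center_um: tuple[float, float, float]
    semi_axes_um: tuple[float, float, float]
    contrast: float = 0.5

    @property
    def volume_um3(self) -> float:
        a, b, c = self.semi_axes_um
        return 4.0 / 3.0 * np.pi * a * b * c


@dataclass
class PhantomSpec:
    """Parameters of a banana-shaped cell phantom.

    The cell is a prolate ellipsoid (semi-axes ``cell_semi_axes_um``, long axis
    first, along X) sheared so its centerline follows a circular arc;
    ``centerline_curvature`` is the sagitta of the arc divided by the cell
    length.  The shear is volume preserving, so organelle volume fractions are
    exactly the ratios of the ellipsoid volumes.  ``texture_amplitude`` adds a
    smooth seeded density texture inside the cell (relative RMS amplitude).
    """

    cell_semi_axes_um: tuple[float, float, float] = (2.0, 1.0, 0.75)
    centerline_curvature: float = 0.15
    organelles: list[Organelle] = field(default_factory=list)
    base_density: float = 1.0
    texture_amplitude: float = 0.0
    edge_sigma_um: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if any(a <= 0 for a in self.cell_semi_axes_um):
            raise InvalidParameterError("cell semi-axes must be positive")
        if self.base_density < 0:
            raise InvalidParameterError("base_density must be >= 0")
        vcell = self.cell_volume_um3
        for org in self.organelles:
            frac = org.volume_um3 / vcell
            if not 0.0 < frac < 0.5:
                raise InvalidParameterError(
                    f"organelle volume fraction {frac:.3f} outside (0, 0.5)")

    @property
    def cell_volume_um3(self) -> float:
        a, b, c = self.cell_semi_axes_um
        return 4.0 / 3.0 * np.pi * a * b * c


def default_phantom_spec(scale: float = 1.0) -> PhantomSpec:
    """A tachyzoite-like phantom: a ~1.5 x 2 x 4 um bent cell with denser
    organelles packed toward the apical (+X) end, optionally scaled by
    ``scale`` (volume fractions are scale-invariant).

    Organelle volume fractions span ~1.7% to 13.1% of the cell volume,
    mimicking the range of segmented sub-cellular regions (nucleus, rhoptry
    bundle, tubular networks, apical tip).
    """
    vcell = 4.0 / 3.0 * np.pi * 2.0 * 1.0 * 0.75  # ~6.28 um^3

    def axes(frac: float, elong: float = 1.0) -> tuple[float, float, float]:
        # ellipsoid with volume frac*vcell and aspect elong along X
        r = (frac * vcell * 3.0 / (4.0 * np.pi) / elong) ** (1.0 / 3.0)
        return (elong * r, r, r)

    s = float(scale)

    def sc(v: tuple[float, float, float]) -> tuple[float, float, float]:
        return (v[0] * s, v[1] * s, v[2] * s)

    organelles = [
        Organelle(sc((-0.7, 0.0, 0.0)), sc(axes(0.131)), contrast=0.6),            # nucleus, mid-posterior
        Organelle(sc((1.2, 0.1, 0.0)), sc(axes(0.060, elong=2.0)), contrast=0.9),  # rhoptry bundle
        Organelle(sc((0.5, -0.3, 0.1)), sc(axes(0.040, elong=1.5)), contrast=0.7),  # tubular network
        Organelle(sc((0.3, 0.4, -0.1)), sc(axes(0.030, elong=1.5)), contrast=0.7),  # tubular network
        Organelle(sc((1.7, 0.0, 0.0)), sc(axes(0.017)), contrast=1.0),             # apical tip / conoid
    ]
    return PhantomSpec(cell_semi_axes_um=sc((2.0, 1.0, 0.75)),
                       centerline_curvature=0.15,
                       organelles=organelles,
                       base_density=1.0,
                       texture_amplitude=0.05,
                       rng_seed=0)


def _cell_frame(spec: PhantomSpec, x_um: np.ndarray, y_um: np.ndarray,
                z_um: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Map lab coordinates (um, cell-centred) into the straightened cell frame.

    The bend is a pure shear: y -> y - y_c(x) with y_c a parabolic arc of
    sagitta ``curvature * length`` (zero at the cell centre for symmetry).
    """
    a = spec.cell_semi_axes_um[0]
    length = 2.0 * a
    sagitta = spec.centerline_curvature * length
    y_c = sagitta * ((x_um / a) ** 2 - 0.5)
    return x_um, y_um - y_c, z_um


def generate_phantom(spec: PhantomSpec, grid_side: int, voxel_size_nm: float) -> DensityVolume:
    """Rasterize a phantom spec onto a cubic grid.

    Raises :class:`GeometryError` if the cell (including the bend excursion)
    does not leave a margin of at least ``grid_side/4`` voxels on each side of
    every axis — the margin that guarantees linear oversampling >= 2 in the
    simulated diffraction downstream.

    Deterministic for a fixed ``spec.rng_seed``.
    """
    n = int(grid_side)
    vox_um = voxel_size_nm * 1e-3
    half_extent_um = n * vox_um / 2.0

    a, b, c = spec.cell_semi_axes_um
    sagitta = spec.centerline_curvature * 2.0 * a
    # conservative bounding half-extents of the bent cell per axis
    bounds = (a, b + sagitta, c)
    for ax, bound in zip("XYZ", bounds):
        if bound > half_extent_um / 2.0:  # support must fit in the central half
            raise GeometryError(
                f"phantom half-extent {bound:.3f} um on {ax} exceeds the "
                f"oversampling margin ({half_extent_um / 2.0:.3f} um) of the "
                f"{n}^3 grid at {voxel_size_nm} nm voxels")

    coords = (np.arange(n) - n // 2) * vox_um
    x, y, z = np.meshgrid(coords, coords, coords, indexing="ij")
    xf, yf, zf = _cell_frame(spec, x, y, z)
    inside = (xf / a) ** 2 + (yf / b) ** 2 + (zf / c) ** 2 <= 1.0

    values = np.where(inside, spec.base_density, 0.0)

    for org in spec.organelles:
        cx, cy, cz = org.center_um
        oa, ob, oc = org.semi_axes_um
        in_org = (((xf - cx) / oa) ** 2 + ((yf - cy) / ob) ** 2
                  + ((zf - cz) / oc) ** 2) <= 1.0
        values += np.where(in_org & inside, org.contrast * spec.base_density, 0.0)

    if spec.texture_amplitude > 0 and spec.base_density > 0:
        from scipy.ndimage import gaussian_filter
        rng = np.random.default_rng(spec.rng_seed)
        noise = gaussian_filter(rng.standard_normal((n, n, n)), sigma=2.0)
        rms = noise.std() or 1.0
        texture = 1.0 + spec.texture_amplitude * noise / rms
        values = np.where(inside, values * np.clip(texture, 0.0, None), values)

    if spec.edge_sigma_um > 0:
        # soften the membrane/organelle edges: real boundaries are not
        # voxel-sharp, and a band-limited phantom keeps interpolation honest
        from scipy.ndimage import gaussian_filter
        values = gaussian_filter(values, sigma=spec.edge_sigma_um / vox_um)
        values = np.clip(values, 0.0, None)

    return DensityVolume(values=values, voxel_size_nm=voxel_size_nm)
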