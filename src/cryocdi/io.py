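"""File formats: HDF5 tilt series, MRC density volumes, TIFF frames.

Tilt series live in a single HDF5 file (/patterns, /masks, /angles_deg plus
geometry attributes); densities are MRC/CCP4 mode-2 float maps with the voxel
size recorded in the cell header; assembled Fourier volumes are HDF5 with
/intensity, /weights and /known datasets.
"""

from __future__ import annotations

import json
from pathlib import Path

import gemmi
import h5py
import numpy as np
import tifffile

from .forward_simulator import DiffractionPattern, TiltSeries
from .fourier_assembly import FourierIntensityVolume
from .geometry_phantom import DensityVolume, ExperimentGeometry

__all__ = [
    "save_tilt_series", "load_tilt_series",
    "save_mrc", "load_mrc",
    "save_fourier_volume", "load_fourier_volume",
    "export_pattern_tiff",
]

_GEOMETRY_ATTRS = ("photon_energy_kev", "camera_length_m", "pixel_pitch_um",
                   "detector_side", "beamstop_radius_px", "gap_width_px",
                   "fluence_per_um2", "exposure_s")


def save_tilt_series(path: str | Path, series: TiltSeries,
                     provenance: dict | None = None) -> None:
    n = len(series.patterns)
    side = series.geometry.detector_side
    with h5py.File(path, "w") as f:
        pats = f.create_dataset("patterns", (n, side, side), dtype="f8")
        masks = f.create_dataset("masks", (n, side, side), dtype="u1")
        for k, p in enumerate(series.patterns):
            pats[k] = p.counts
            masks[k] = p.known_mask
        f.create_dataset("angles_deg", data=series.angles_deg)
        f.create_dataset("exposures_s",
                         data=[p.exposure_s for p in series.patterns])
        for name in _GEOMETRY_ATTRS:
            f.attrs[name] = getattr(series.geometry, name)
        if provenance:
            f.attrs["provenance"] = json.dumps(provenance)


def load_tilt_series(path: str | Path) -> TiltSeries:
    with h5py.File(path, "r") as f:
        geometry = ExperimentGeometry(**{
            name: (int(f.attrs[name]) if name in ("detector_side", "gap_width_px")
                   else float(f.attrs[name]))
            for name in _GEOMETRY_ATTRS})
        angles = f["angles_deg"][...]
        exposures = f["exposures_s"][...]
        patterns = [DiffractionPattern(counts=f["patterns"][k],
                                       known_mask=f["masks"][k].astype(bool),
                                       tilt_angle_deg=float(angles[k]),
                                       exposure_s=float(exposures[k]))
                    for k in range(len(angles))]
    return TiltSeries(patterns=patterns, geometry=geometry)


def load_tilt_series_provenance(path: str | Path) -> dict | None:
    with h5py.File(path, "r") as f:
        raw = f.attrs.get("provenance")
    return json.loads(raw) if raw else None


def save_mrc(path: str | Path, volume: DensityVolume) -> None:
    """Write a density as an MRC/CCP4 mode-2 (float32) map; the cell edge
    encodes grid_side * voxel_size (in Angstrom, 1 nm = 10 A)."""
    grid = gemmi.FloatGrid(np.ascontiguousarray(volume.values, dtype=np.float32))
    edge_a = volume.grid_side * volume.voxel_size_nm * 10.0
    grid.unit_cell = gemmi.UnitCell(edge_a, edge_a, edge_a, 90, 90, 90)
    grid.spacegroup = gemmi.SpaceGroup("P1")
    ccp4 = gemmi.Ccp4Map()
    ccp4.grid = grid
    ccp4.update_ccp4_header()
    ccp4.write_ccp4_map(str(path))


def load_mrc(path: str | Path) -> DensityVolume:
    ccp4 = gemmi.read_ccp4_map(str(path))
    values = np.array(ccp4.grid, copy=True).astype(np.float64)
    voxel_nm = ccp4.grid.unit_cell.a / ccp4.grid.nu / 10.0
    return DensityVolume(values=np.clip(values, 0.0, None), voxel_size_nm=voxel_nm)


def save_fourier_volume(path: str | Path, vol: FourierIntensityVolume) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("intensity", data=vol.intensities)
        f.create_dataset("weights", data=vol.weight_sum)
        f.create_dataset("known", data=vol.known_mask.astype(np.uint8))


def load_fourier_volume(path: str | Path) -> FourierIntensityVolume:
    with h5py.File(path, "r") as f:
        return FourierIntensityVolume(intensities=f["intensity"][...],
                                      weight_sum=f["weights"][...],
                                      known_mask=f["known"][...].astype(bool))


def export_pattern_tiff(path: str | Path, pattern: DiffractionPattern) -> None:
    """Export one frame as 32-bit float TIFF (unknown pixels set to -1)."""
    img = pattern.counts.astype(np.float32).copy()
    img[~pattern.known_mask] = -1.0
    tifffile.imwrite(str(path), img)
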