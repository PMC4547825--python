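"""Pattern correction: background subtraction, Friedel symmetrization, QC.

Raw frames come in sample/background pairs per tilt angle (the cell is moved
in and out of the beam).  Subtraction removes parasitic scattering; negative
residuals are noise and clipped to zero.  Because the object is real-valued,
the diffraction intensity is centro-symmetric (Friedel's law), which lets
pixels lost to the beamstop or module gaps be recovered from their mates and
symmetric pairs be averaged.  A simple amplitude R-value between two repeat
frames at the same angle serves as the radiation-damage / drift monitor.
"""

from __future__ import annotations

import numpy as np

from .forward_simulator import DiffractionPattern

__all__ = ["subtract_background", "symmetrize_friedel", "compare_repeats"]


def _conjugate_pixels(arr: np.ndarray) -> np.ndarray:
    """Map each pixel (i, j) to its Friedel mate ((N-i) % N, (N-j) % N)."""
    return np.roll(arr[::-1, ::-1], shift=(1, 1), axis=(0, 1))


def subtract_background(sample: DiffractionPattern,
                        background: DiffractionPattern,
                        scale: float = 1.0,
                        flatfield: np.ndarray | None = None) -> DiffractionPattern:
    """Gain-correct and subtract a beam-only frame from a sample frame.

    corrected = sample/flatfield - scale * background/flatfield on pixels known
    in both inputs; negatives are clipped to 0; everything else is unknown.
    ``scale`` defaults to 1 (equal exposures); pass the exposure-time ratio
    when they differ.
    """
    if sample.counts.shape != background.counts.shape:
        raise ValueError("sample and background shapes differ")
    if scale <= 0:
        raise ValueError("scale must be positive")
    if flatfield is None:
        gain = 1.0
    else:
        gain = np.asarray(flatfield, dtype=np.float64)
        if gain.shape != sample.counts.shape:
            raise ValueError("flatfield shape differs from pattern shape")
        if np.any(gain <= 0):
            raise ValueError("flatfield gains must be positive")
    joint = sample.known_mask & background.known_mask
    corrected = sample.counts / gain - scale * background.counts / gain
    corrected = np.clip(corrected, 0.0, None)
    corrected[~joint] = 0.0
    return DiffractionPattern(counts=corrected, known_mask=joint,
                              tilt_angle_deg=sample.tilt_angle_deg,
                              exposure_s=sample.exposure_s)


def symmetrize_friedel(pattern: DiffractionPattern) -> DiffractionPattern:
    """Enforce centro-symmetry and recover missing pixels from Friedel mates.

    For each pixel pair (q, -q): both known -> both set to their mean; exactly
    one known -> the unknown mate is filled and marked known; neither known ->
    both stay unknown.  Idempotent, and the known set never shrinks.
    """
    counts = pattern.counts.copy()
    known = pattern.known_mask.copy()
    mate_counts = _conjugate_pixels(counts)
    mate_known = _conjugate_pixels(known)

    both = known & mate_known
    counts[both] = 0.5 * (counts[both] + mate_counts[both])
    fill = ~known & mate_known
    counts[fill] = mate_counts[fill]
    known = known | mate_known
    counts[~known] = 0.0
    return DiffractionPattern(counts=counts, known_mask=known,
                              tilt_angle_deg=pattern.tilt_angle_deg,
                              exposure_s=pattern.exposure_s)


def compare_repeats(p1: DiffractionPattern, p2: DiffractionPattern) -> float:
    """Amplitude R-value between two frames of the same projection.

    R = sum |sqrt(I1) - gamma*sqrt(I2)| / sum sqrt(I1) over jointly known
    pixels, with gamma the least-squares amplitude scale.  0 for identical
    frames; insensitive to a global intensity scale.
    """
    if p1.counts.shape != p2.counts.shape:
        raise ValueError("patterns have different shapes")
    joint = p1.known_mask & p2.known_mask
    if not joint.any():
        raise ValueError("no jointly known pixels")
    a1 = np.sqrt(np.clip(p1.counts[joint], 0.0, None))
    a2 = np.sqrt(np.clip(p2.counts[joint], 0.0, None))
    denom = float((a2 * a2).sum())
    if denom == 0.0 or a1.sum() == 0.0:
        raise ValueError("degenerate (all-zero) amplitudes")
    gamma = float((a1 * a2).sum()) / denom
    return float(np.abs(a1 - gamma * a2).sum() / a1.sum())
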