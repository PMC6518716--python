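"""Shape deformation factor and millimetre wall-deformation summaries.

The core quantity is the per-frame shape deformation factor

    n_i = F_ic / F_c

where F_ic is the segmented silhouette area (px^2) of frame i from camera c
and F_c is the area of that camera's reference frame — the first frame of
the sequence, acquired with the vessel motionless.  Being a pure ratio, n_i
is independent of the pixel scale; the conversion to millimetres uses the
equivalent-circle radius of the reference silhouette:

    r_ref = sqrt(F_c / pi) * mm_per_pixel
    dr_i  = r_ref * (sqrt(n_i) - 1)

which is exact for concentric circular dilation and positive for expansion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .optics import PixelScale
from .segmentation import ObjectMeasure


class InvalidMeasurementError(ValueError):
    """Raised for non-positive areas, naming the offending frame."""


class InsufficientDataError(ValueError):
    """Raised when a series is too short for the requested reduction."""


class IncompleteTableError(ValueError):
    """Raised when a position x probe table has missing cells."""


POSITION_ANGLES_DEG = {"anterior": 0, "left": 90, "posterior": 180, "right": 270}


@dataclass
class DeformationSeries:
    """Per-camera area series and its deformation factors."""

    areas: np.ndarray            # F_ic, px^2
    factors: np.ndarray          # n_i = F_ic / F_ref
    reference_area: float        # F_c, px^2
    reference_index: int = 0
    camera_index: int = 1
    frame_rate: float = 30.0


@dataclass
class WallDeformationSummary:
    """Average wall deformation of one subject: mean ± sample SD over the
    4 positions x 4 probes amplitude table, reported in mm."""

    values_mm: np.ndarray        # (positions, probes)
    awd_mm: float                # mean of all cells
    sd_mm: float                 # sample SD (n - 1)
    positions: tuple = ("anterior", "posterior", "left", "right")

    @property
    def rounded(self) -> tuple[float, float]:
        return (round(self.awd_mm, 2), round(self.sd_mm, 2))


def deformation_factors(areas, reference_index: int = 0,
                        camera_index: int = 1,
                        frame_rate: float = 30.0) -> DeformationSeries:
    """Compute n_i = F_ic / F_reference for a per-frame area sequence."""
    a = np.asarray(areas, dtype=float)
    if a.ndim != 1 or len(a) < 2:
        raise InvalidMeasurementError("need a 1-D area sequence of length >= 2")
    bad = np.nonzero(a <= 0)[0]
    if len(bad):
        raise InvalidMeasurementError(f"non-positive area at frame {bad[0]}")
    ref = a[reference_index]
    return DeformationSeries(areas=a, factors=a / ref, reference_area=float(ref),
                             reference_index=reference_index,
                             camera_index=camera_index, frame_rate=frame_rate)


def factor_to_displacement(series: DeformationSeries, scale: PixelScale) -> np.ndarray:
    """Radial wall displacement (mm) from the deformation factors.

    Uses the equivalent-circle radius of the reference silhouette; the sign
    is positive for expansion.
    """
    if series.reference_area <= 0:
        raise InvalidMeasurementError("reference area must be positive")
    r_ref = math.sqrt(series.reference_area / math.pi) * scale.mm_per_pixel
    return r_ref * (np.sqrt(series.factors) - 1.0)


def cycle_amplitudes(displacements, frame_rate: float, pulse_rate: float) -> np.ndarray:
    """Per-cycle wall-deformation amplitude (mm): max - min per pulse window.

    The series is split into consecutive windows of one pulsation period
    (60 / pulse_rate seconds); a trailing partial cycle is discarded.
    """
    d = np.asarray(displacements, dtype=float)
    cycle_len = frame_rate * 60.0 / pulse_rate
    n_cycles = int(math.floor(len(d) / cycle_len))
    if n_cycles < 1:
        raise InsufficientDataError(
            f"series of {len(d)} frames covers less than one cycle "
            f"({cycle_len:.1f} frames)")
    amps = np.empty(n_cycles)
    for k in range(n_cycles):
        lo = int(round(k * cycle_len))
        hi = int(round((k + 1) * cycle_len))
        window = d[lo:hi]
        amps[k] = window.max() - window.min()
    return amps


def summarize_wall_deformation(values_mm, n_positions: int = 4,
                               n_probes: int = 4) -> WallDeformationSummary:
    """Average wall deformation (AWD): mean ± sample SD of the full table."""
    v = np.asarray(values_mm, dtype=float)
    if v.shape != (n_positions, n_probes) or np.any(~np.isfinite(v)):
        raise IncompleteTableError(
            f"need a complete {n_positions} x {n_probes} table without missing cells")
    flat = v.ravel()
    return WallDeformationSummary(values_mm=v, awd_mm=float(flat.mean()),
                                  sd_mm=float(flat.std(ddof=1)))


def static_diameter(measures, scale: PixelScale) -> float:
    """Static silhouette diameter (mm): caliper width x scale, averaged over cameras.

    ``measures`` is one :class:`ObjectMeasure` or a list of them (one per
    camera of the rig).
    """
    if isinstance(measures, ObjectMeasure):
        measures = [measures]
    if len(measures) < 1:
        raise ValueError("need at least one camera measurement")
    diam = [m.max_caliper_px * scale.mm_per_pixel for m in measures]
    return float(np.mean(diam))


def bin_positions(camera_angles_rad) -> list[str]:
    """Map camera/station angles to the nearest of the four anatomical
    positions (anterior 0, left 90, posterior 180, right 270 degrees)."""
    names = list(POSITION_ANGLES_DEG)
    anchors = np.deg2rad([POSITION_ANGLES_DEG[n] for n in names])
    out = []
    for ang in np.atleast_1d(np.asarray(camera_angles_rad, dtype=float)):
        diffs = np.abs((ang - anchors + math.pi) % (2 * math.pi) - math.pi)
        out.append(names[int(np.argmin(diffs))])
    return out
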