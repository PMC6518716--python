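"""Offline pipeline orchestration, file I/O, and the acquisition-queue model.

The measurement chain is batch ("offline") by design: frames are captured
first, then each camera's sequence runs through rectification, segmentation,
deformation factors and millimetre conversion, and finally per-position
summaries.  The capture side is honoured as a deterministic event-driven
simulation of its producer–consumer contract: a lossless saving queue
(bounded only by a declared memory budget) and a size-1 preview queue that
drops frames while the previewer is busy.  Preview drops can never affect
measurements, which consume the saving path only.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from .optics import CameraIntrinsics, PixelScale, rectify_image
from .phantom import FrameSequence, GroundTruth, RigGeometry
from .segmentation import segment_frame
from . import deformation as deform

logger = logging.getLogger("vesselcam")

#: frame filename dialect: camera is 1-based, frame index 0-based
FRAME_NAME = "cam{c:02d}_frame{i:06d}.png"


class SavingQueueOverflowError(RuntimeError):
    """Raised when the saving queue exceeds its declared memory budget."""


@dataclass
class FrameStreamStats:
    """Observable outcome of the producer–consumer acquisition contract."""

    frames_produced: int = 0
    frames_saved: int = 0
    frames_previewed: int = 0
    frames_dropped_from_preview: int = 0
    max_saving_queue: int = 0


def simulate_acquisition(n_frames: int, saving_capacity: int,
                         preview_consumer_period: int = 1,
                         saving_consumer_period: int | None = 1,
                         ) -> FrameStreamStats:
    """Deterministic replay of the capture architecture's queue semantics.

    Per producer tick: scheduled consumers pop first (the preview consumer
    every ``preview_consumer_period`` ticks, the saving consumer every
    ``saving_consumer_period`` ticks; ``None`` means it never runs during
    capture), then the producer appends the new frame to the saving queue —
    raising :class:`SavingQueueOverflowError` when the declared capacity
    would be exceeded — and offers it to the size-1 preview queue, dropping
    it if the slot is occupied.  After the last frame both queues are
    drained, modelling the offline completion of the run.
    """
    saving: list[int] = []
    preview: int | None = None
    stats = FrameStreamStats()
    for t in range(n_frames):
        if preview is not None and t % preview_consumer_period == 0:
            preview = None
            stats.frames_previewed += 1
        if saving and saving_consumer_period and t % saving_consumer_period == 0:
            saving.pop(0)
            stats.frames_saved += 1
        if len(saving) >= saving_capacity:
            raise SavingQueueOverflowError(
                f"saving queue exceeded capacity {saving_capacity} at frame {t + 1}")
        saving.append(t)
        stats.frames_produced += 1
        stats.max_saving_queue = max(stats.max_saving_queue, len(saving))
        if preview is None:
            preview = t
        else:
            stats.frames_dropped_from_preview += 1
    stats.frames_saved += len(saving)
    if preview is not None:
        stats.frames_previewed += 1
    return stats


# ---------------------------------------------------------------------------
# file I/O

def save_frames(seq: FrameSequence, directory) -> list[Path]:
    """Write a sequence as 8-bit grayscale PNG frames (zero-padded names)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, frame in enumerate(seq.frames):
        path = directory / FRAME_NAME.format(c=seq.camera_index, i=i)
        iio.imwrite(path, frame)
        paths.append(path)
    return paths


def load_frames(directory, camera_index: int, frame_rate: float = 30.0,
                view_angle: float = 0.0) -> FrameSequence:
    """Read one camera's PNG frames back in index order."""
    directory = Path(directory)
    pattern = f"cam{camera_index:02d}_frame*.png"
    paths = sorted(directory.glob(pattern))
    if not paths:
        raise FileNotFoundError(f"no frames matching {pattern} in {directory}")
    frames = np.stack([iio.imread(p) for p in paths])
    return FrameSequence(frames=frames, frame_rate=frame_rate,
                         camera_index=camera_index, view_angle=view_angle)


def save_ground_truth(gt: GroundTruth, path) -> None:
    pd.DataFrame({
        "camera": gt.camera_index,
        "frame": np.arange(len(gt.area_px2)),
        "area_px2": gt.area_px2,
        "n_true": gt.n_true,
        "displacement_mm_true": gt.displacement_mm_true,
    }).to_csv(path, index=False)


def save_rig(rig: RigGeometry, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump({"n_cameras": rig.n_cameras,
                        "angular_spacing": rig.angular_spacing,
                        "sweep_step": rig.sweep_step,
                        "sweep_range": rig.sweep_range,
                        "object_distance": rig.object_distance,
                        "image_size": list(rig.image_size)}, fh)


def load_rig(path) -> RigGeometry:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    d["image_size"] = tuple(d["image_size"])
    return RigGeometry(**d)


# ---------------------------------------------------------------------------
# pipeline

@dataclass
class PipelineConfig:
    """Everything one measurement run needs, resolvable at start."""

    rig: RigGeometry
    output_dir: Path
    frames_dir: Path | None = None          # on-disk source (PNG dialect)
    frames: dict[int, FrameSequence] | None = None   # in-memory source
    intrinsics: CameraIntrinsics | None = None
    cameras: tuple[int, ...] | None = None
    mm_per_pixel: float | None = None       # explicit scale ...
    scale_square_side: float | None = None  # ... or a reference square
    scale_square_area_px: float | None = None
    pulse_rate: float | None = 72.0         # per minute; None skips cycles
    min_object_px: int = 0
    area_jump_warn: float = 0.20            # warn on >20% frame-to-frame jumps
    seed: int = 0

    def resolve_scale(self) -> PixelScale:
        from .optics import pixel_scale_from_square
        if self.mm_per_pixel is not None:
            return PixelScale(mm_per_pixel=self.mm_per_pixel,
                              object_distance=self.rig.object_distance)
        if self.scale_square_side and self.scale_square_area_px:
            return pixel_scale_from_square(self.scale_square_area_px,
                                           self.scale_square_side)
        intr = self.intrinsics or self.rig.default_intrinsics()
        return PixelScale.from_camera(intr, self.rig.object_distance)


def _analyze_camera(seq: FrameSequence, intr: CameraIntrinsics,
                    scale: PixelScale, config: PipelineConfig) -> pd.DataFrame:
    areas = []
    for i, frame in enumerate(seq.frames):
        rectified = rectify_image(frame, intr)
        measure = segment_frame(rectified, min_object_px=config.min_object_px)
        if areas and abs(measure.area_px - areas[-1]) > config.area_jump_warn * areas[-1]:
            logger.warning("camera %d frame %d: area jump > %.0f%% (%d -> %d px)",
                           seq.camera_index, i, 100 * config.area_jump_warn,
                           areas[-1], measure.area_px)
        areas.append(measure.area_px)
    series = deform.deformation_factors(areas, camera_index=seq.camera_index,
                                        frame_rate=seq.frame_rate)
    disp = deform.factor_to_displacement(series, scale)
    return pd.DataFrame({"camera": seq.camera_index,
                         "frame": np.arange(len(areas)),
                         "area_px": areas,
                         "n_i": series.factors,
                         "displacement_mm": disp})


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute rectify → segment → measure → deformation for every camera.

    Per-camera CSVs (camera, frame, area_px, n_i, displacement_mm), a
    per-position amplitude summary and a JSON report are written under
    ``config.output_dir``; the seed is recorded in every output header.  A
    stage failure aborts only that camera's series.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    intr = config.intrinsics or config.rig.default_intrinsics()
    scale = config.resolve_scale()
    cameras = (config.cameras if config.cameras is not None
               else tuple(sorted(config.frames)) if config.frames is not None
               else tuple(range(1, config.rig.n_cameras + 1)))
    header = f"# seed={config.seed}\n"

    per_camera: dict[int, pd.DataFrame] = {}
    failures: dict[int, str] = {}
    for cam in cameras:
        try:
            if config.frames is not None:
                seq = config.frames[cam]
            else:
                seq = load_frames(config.frames_dir, cam,
                                  view_angle=config.rig.camera_angle(cam))
                seq.view_angle = config.rig.camera_angle(cam)
            if len(seq) < 2:
                raise ValueError("need at least 2 frames")
            df = _analyze_camera(seq, intr, scale, config)
            per_camera[cam] = df
            path = out / f"deformation_cam{cam:02d}.csv"
            with open(path, "w") as fh:
                fh.write(header)
                df.to_csv(fh, index=False)
        except Exception as exc:  # isolate per-camera failures
            logger.error("camera %d failed: %s", cam, exc)
            failures[cam] = str(exc)

    summary_rows = []
    for cam, df in per_camera.items():
        angle = config.rig.camera_angle(cam)
        position = deform.bin_positions([angle])[0]
        row = {"camera": cam, "position": position,
               "mean_n": float(df["n_i"].mean()),
               "max_displacement_mm": float(df["displacement_mm"].max())}
        if config.pulse_rate:
            try:
                amps = deform.cycle_amplitudes(df["displacement_mm"].to_numpy(),
                                               frame_rate=config.frames[cam].frame_rate
                                               if config.frames else 30.0,
                                               pulse_rate=config.pulse_rate)
                row["amplitude_mm"] = float(np.mean(amps))
                row["n_cycles"] = len(amps)
            except deform.InsufficientDataError:
                row["amplitude_mm"] = float(df["displacement_mm"].max()
                                            - df["displacement_mm"].min())
                row["n_cycles"] = 0
        summary_rows.append(row)
    summary = pd.DataFrame(summary_rows)
    with open(out / "summary.csv", "w") as fh:
        fh.write(header)
        summary.to_csv(fh, index=False)

    report = {"seed": config.seed, "mm_per_pixel": scale.mm_per_pixel,
              "cameras_analyzed": sorted(per_camera), "failures": failures,
              "positions": {r["position"]: r.get("amplitude_mm")
                            for r in summary_rows}}
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    return report
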