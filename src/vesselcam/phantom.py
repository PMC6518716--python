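"""Synthetic image sequences of a pulsating elastic-vessel phantom.

A ring of cameras observes the silhouette of an elastic vessel model from a
fixed working distance.  Each camera's view is emulated as the vessel
cross-section — a star-shaped boundary r(theta) with a Fourier-perturbed base
radius and a smoothly angle-dependent pulsation amplitude — rotated to that
camera's viewing angle, projected through the pinhole + distortion model,
and rasterised as a bright filled polygon on a dark background.  The analytic
(shoelace) area of the projected boundary, the per-frame area ratio against
the first (motionless) frame, and the true radial wall displacement are
recorded as ground truth, so every downstream stage can be verified exactly.

Rasterisation is deliberately aliased: a pixel is foreground iff its centre
lies inside the polygon.  That makes the pixel-count area an exact, seeded,
reproducible quantity that an independent point-in-polygon oracle can check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from matplotlib.path import Path

from .optics import CameraIntrinsics, project


class InvalidSpecError(ValueError):
    """Raised for physically impossible phantom specifications."""


class FieldOfViewError(ValueError):
    """Raised when a rendered object does not fit inside the frame."""


#: full-resolution default and the aspect-preserving test-scale default
FULL_RES = (1920, 1080)
TEST_RES = (480, 270)

#: default focal length as a fraction of the image width; at 480 px width
#: this gives fx = 420 px, under which the 0.05 m / 0.10 m verification
#: squares at 0.30 m rasterise to exact 70 px / 140 px sides
DEFAULT_FOCAL_FRACTION = 0.875


@dataclass
class RigGeometry:
    """Camera-ring geometry: nine cameras, 0.70 rad apart, sweepable ±0.70 rad."""

    n_cameras: int = 9
    angular_spacing: float = 0.70
    sweep_step: float = 0.17
    sweep_range: float = 0.70
    object_distance: float = 0.35
    image_size: tuple[int, int] = FULL_RES

    def __post_init__(self) -> None:
        if self.object_distance <= 0:
            raise ValueError("object_distance must be positive")
        if self.n_cameras < 1:
            raise ValueError("need at least one camera")
        gap = abs(self.n_cameras * self.angular_spacing - 2 * math.pi)
        if gap > self.angular_spacing:
            raise ValueError("cameras do not cover the full ring within one spacing")

    def camera_angle(self, camera_index: int) -> float:
        """Ring angle (rad) of camera ``camera_index`` (1-based, 1..n_cameras)."""
        if not 1 <= camera_index <= self.n_cameras:
            raise ValueError(f"camera_index must be in 1..{self.n_cameras}")
        return (camera_index - 1) * self.angular_spacing

    @property
    def n_stations(self) -> int:
        """Distinct angular stations of the sweep grid around the ring.

        The sweep moves in ``sweep_step`` increments, so the ring is
        discretised into floor(2*pi / sweep_step) cells (36 with defaults).
        """
        return int(2 * math.pi / self.sweep_step)

    def sweep_offsets(self) -> np.ndarray:
        k = int(round(self.sweep_range / self.sweep_step))
        return np.arange(-k, k + 1) * self.sweep_step

    def default_intrinsics(self) -> CameraIntrinsics:
        w, h = self.image_size
        return CameraIntrinsics.ideal(w, h, DEFAULT_FOCAL_FRACTION * w)

    def scaled(self, factor: int) -> "RigGeometry":
        """Same rig with the image resolution divided by ``factor``."""
        w, h = self.image_size
        return RigGeometry(self.n_cameras, self.angular_spacing, self.sweep_step,
                           self.sweep_range, self.object_distance,
                           (w // factor, h // factor))


def _amplitude_function(amplitude_mm) -> "callable":
    """Smooth per-angle amplitude through the four anchor positions.

    A dict {0: anterior, 90: left, 180: posterior, 270: right} (degrees) is
    interpolated with the low-order trigonometric polynomial
    a(t) = c0 + c1 cos t + s1 sin t + c2 cos 2t, which passes exactly through
    the four anchors.  A scalar means a uniform amplitude; a callable is used
    as-is (takes theta in radians).
    """
    if callable(amplitude_mm):
        return amplitude_mm
    if np.isscalar(amplitude_mm):
        a = float(amplitude_mm)
        return lambda theta: np.full_like(np.asarray(theta, dtype=float), a)
    anchors = dict(amplitude_mm)
    A, L, P, R = (anchors[0], anchors[90], anchors[180], anchors[270])
    c0 = (A + L + P + R) / 4.0
    c1 = (A - P) / 2.0
    s1 = (L - R) / 2.0
    c2 = (A + P - L - R) / 4.0
    return lambda theta: (c0 + c1 * np.cos(theta) + s1 * np.sin(theta)
                          + c2 * np.cos(2 * np.asarray(theta, dtype=float)))


def _radius_function(base_radius_mm, fourier) -> "callable":
    if callable(base_radius_mm):
        return base_radius_mm
    base = float(base_radius_mm)
    terms = list(fourier or [])

    def r(theta):
        theta = np.asarray(theta, dtype=float)
        out = np.full_like(theta, base)
        for order, amp, phase in terms:
            out = out + amp * np.cos(order * theta + phase)
        return out

    return r


@dataclass
class PhantomSpec:
    """Pulsating-vessel phantom: geometry, dynamics and photometry.

    The boundary radius at ring angle theta and time t is
    r(theta, t) = base(theta) + a(theta) * (1 - cos(2*pi*f*t)) / 2 with f the
    pulsation frequency in Hz, so frame 0 (t = 0) is the motionless reference
    and the peak outward wall displacement equals the amplitude a(theta).
    """

    base_radius_mm: float | object = 43.0
    radius_fourier: tuple = ((2, 1.5, 0.0), (3, 0.8, 1.0))
    pulsation_frequency: float = 72.0     # cycles per minute
    pulsation_amplitude_mm: float | dict | object = 4.0
    n_cycles: int = 10
    frame_rate: float = 30.0              # frames per second
    foreground_level: int = 200
    background_level: int = 30
    noise_sd: float = 2.0
    illumination_gradient: float = 0.1    # fractional left-right ramp
    n_boundary_points: int = 256

    def __post_init__(self) -> None:
        if self.foreground_level <= self.background_level:
            raise InvalidSpecError("foreground must be brighter than background")
        if self.noise_sd < 0:
            raise InvalidSpecError("noise_sd must be >= 0")
        theta = np.linspace(0, 2 * math.pi, 720, endpoint=False)
        amp = _amplitude_function(self.pulsation_amplitude_mm)(theta)
        if np.any(np.asarray(amp) < 0):
            raise InvalidSpecError("pulsation amplitude must be >= 0 at all angles")
        if np.any(self.radius(theta, 0.0) <= 0):
            raise InvalidSpecError("phantom radius must stay positive")

    @property
    def frequency_hz(self) -> float:
        return self.pulsation_frequency / 60.0

    @property
    def n_frames(self) -> int:
        return int(round(self.n_cycles * self.frame_rate * 60.0 / self.pulsation_frequency))

    def displacement(self, theta, t: float):
        """True outward wall displacement (mm) at angle theta and time t (s)."""
        amp = _amplitude_function(self.pulsation_amplitude_mm)(theta)
        return amp * (1.0 - math.cos(2 * math.pi * self.frequency_hz * t)) / 2.0

    def radius(self, theta, t: float):
        base = _radius_function(self.base_radius_mm, self.radius_fourier)(theta)
        return base + self.displacement(theta, t)


@dataclass
class FrameSequence:
    """Ordered frames from one camera with timing and angular metadata."""

    frames: np.ndarray                 # (n, H, W) uint8
    frame_rate: float
    camera_index: int = 1
    view_angle: float = 0.0            # rad on the ring

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def timestamps(self) -> np.ndarray:
        return np.arange(len(self.frames)) / self.frame_rate


@dataclass
class GroundTruth:
    """Exact per-frame truth for one rendered camera view."""

    camera_index: int
    area_px2: np.ndarray               # analytic shoelace area of the boundary
    n_true: np.ndarray                 # area ratio against frame 0
    displacement_mm_true: np.ndarray   # radial wall displacement at the view angle
    mm_per_pixel: float = field(default=float("nan"))


def shoelace_area(polygon: np.ndarray) -> float:
    """Signed-magnitude polygon area by the shoelace formula."""
    p = np.asarray(polygon, dtype=float)
    x, y = p[:, 0], p[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def rasterize_polygon(polygon: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Binary mask of pixels whose centres lie inside the polygon.

    ``shape`` is (height, width); polygon vertices are pixel coordinates.
    No anti-aliasing: the pixel-centre rule makes the foreground count exact.
    Centres exactly on the boundary count as outside (strict interior), so
    the degenerate edge-through-centre case is deterministic and symmetric.
    """
    h, w = shape
    poly = np.asarray(polygon, dtype=float)
    mask = np.zeros((h, w), dtype=bool)
    x0 = max(int(math.floor(poly[:, 0].min())), 0)
    x1 = min(int(math.ceil(poly[:, 0].max())) + 1, w)
    y0 = max(int(math.floor(poly[:, 1].min())), 0)
    y1 = min(int(math.ceil(poly[:, 1].max())) + 1, h)
    if x0 >= x1 or y0 >= y1:
        return mask
    xs, ys = np.meshgrid(np.arange(x0, x1), np.arange(y0, y1))
    pts = np.column_stack([xs.ravel(), ys.ravel()]).astype(float)
    inside = Path(poly).contains_points(pts, radius=-1e-9)
    mask[y0:y1, x0:x1] = inside.reshape(y1 - y0, x1 - x0)
    return mask


def _compose_frame(mask: np.ndarray, spec_fg: int, spec_bg: int,
                   gradient: float, noise_sd: float,
                   rng: np.random.Generator) -> np.ndarray:
    h, w = mask.shape
    img = np.where(mask, float(spec_fg), float(spec_bg))
    if gradient:
        ramp = 1.0 + gradient * (np.arange(w) / max(w - 1, 1) - 0.5)
        img = img * ramp[None, :]
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    return np.clip(np.floor(img + 0.5), 0, 255).astype(np.uint8)


def _project_boundary(points_mm: np.ndarray, distance_m: float,
                      intr: CameraIntrinsics) -> np.ndarray:
    pts3 = np.column_stack([points_mm / 1000.0,
                            np.full(len(points_mm), distance_m)])
    return project(pts3, intr)


def render_phantom_sequence(spec: PhantomSpec, rig: RigGeometry,
                            camera_index: int = 1, seed: int = 0,
                            intrinsics: CameraIntrinsics | None = None,
                            ) -> tuple[FrameSequence, GroundTruth]:
    """Render one camera's view of the pulsating phantom with ground truth.

    Frames are the filled projected cross-section at the camera's ring angle,
    drawn at ``foreground_level`` on ``background_level`` with the optional
    illumination ramp and seeded Gaussian noise, passed through the camera's
    distortion model.  Ground truth records the analytic (shoelace) area of
    the projected boundary before rasterisation, the area ratio against
    frame 0, and the true radial displacement at the viewing angle.
    """
    intr = intrinsics or rig.default_intrinsics()
    phi = rig.camera_angle(camera_index)
    n_frames = spec.n_frames
    if n_frames < 2:
        raise InvalidSpecError("sequence must contain at least 2 frames")
    theta = np.linspace(0, 2 * math.pi, spec.n_boundary_points, endpoint=False)
    h, w = intr.height, intr.width
    rng = np.random.default_rng(seed)
    frames = np.empty((n_frames, h, w), dtype=np.uint8)
    areas = np.empty(n_frames)
    disp = np.empty(n_frames)
    for i in range(n_frames):
        t = i / spec.frame_rate
        r = spec.radius(theta, t)
        if np.any(r <= 0):
            raise InvalidSpecError(f"phantom radius non-positive at frame {i}")
        # rotate the cross-section into this camera's viewing frame
        ang = theta - phi
        pts_mm = np.column_stack([r * np.cos(ang), r * np.sin(ang)])
        poly = _project_boundary(pts_mm, rig.object_distance, intr)
        areas[i] = shoelace_area(poly)
        disp[i] = float(spec.displacement(np.array([phi]), t)[0])
        mask = rasterize_polygon(poly, (h, w))
        frames[i] = _compose_frame(mask, spec.foreground_level, spec.background_level,
                                   spec.illumination_gradient, spec.noise_sd, rng)
    seq = FrameSequence(frames=frames, frame_rate=spec.frame_rate,
                        camera_index=camera_index, view_angle=phi)
    gt = GroundTruth(camera_index=camera_index, area_px2=areas,
                     n_true=areas / areas[0], displacement_mm_true=disp,
                     mm_per_pixel=1000.0 * rig.object_distance / intr.fx)
    return seq, gt


def _square_polygon(side_m: float, distance_m: float, intr: CameraIntrinsics,
                    points_per_edge: int = 64) -> np.ndarray:
    s = side_m * 1000.0 / 2.0  # half-side in mm
    corners = np.array([[-s, -s], [s, -s], [s, s], [-s, s]])
    edges = []
    for a, b in zip(corners, np.roll(corners, -1, axis=0)):
        lam = np.linspace(0, 1, points_per_edge, endpoint=False)[:, None]
        edges.append(a + lam * (b - a))
    boundary_mm = np.vstack(edges)
    return _project_boundary(boundary_mm, distance_m, intr)


def render_square_sequence(side_small: float, side_big: float, rig: RigGeometry,
                           order: str = "small_first", seed: int = 0,
                           intrinsics: CameraIntrinsics | None = None,
                           foreground_level: int = 200, background_level: int = 30,
                           noise_sd: float = 0.0, illumination_gradient: float = 0.0,
                           center_jitter_px: float = 0.0,
                           depth_jitter_rel: float = 0.0,
                           ) -> tuple[FrameSequence, GroundTruth]:
    """Render the two-square verification sequence (one frame per square).

    The squares are centred on the optical axis, perpendicular to it, at the
    rig's object distance.  With sides 0.05 m and 0.10 m the true area ratio
    is 4 — the protocol's reference value.  ``center_jitter_px`` (lateral,
    uniform per frame) and ``depth_jitter_rel`` (relative distance error per
    frame) emulate the repositioning variability between replicate
    acquisitions of a physical target: each square is placed independently,
    so its placement errors are independent.  Grey-level noise alone cannot
    move an aliased silhouette edge.
    """
    if not 0 < side_small <= side_big:
        raise ValueError("require 0 < side_small <= side_big")
    if order not in ("small_first", "big_first"):
        raise ValueError("order must be 'small_first' or 'big_first'")
    intr = intrinsics or rig.default_intrinsics()
    h, w = intr.height, intr.width
    sides = [side_small, side_big] if order == "small_first" else [side_big, side_small]
    rng = np.random.default_rng(seed)
    frames = np.empty((2, h, w), dtype=np.uint8)
    areas = np.empty(2)
    for i, side in enumerate(sides):
        dist = rig.object_distance
        if depth_jitter_rel:
            dist = dist * (1.0 + rng.uniform(-depth_jitter_rel, depth_jitter_rel))
        poly = _square_polygon(side, dist, intr)
        if center_jitter_px:
            poly = poly + rng.uniform(-center_jitter_px, center_jitter_px, 2)
        if (poly[:, 0].min() < 0 or poly[:, 0].max() > w - 1
                or poly[:, 1].min() < 0 or poly[:, 1].max() > h - 1):
            raise FieldOfViewError(
                f"square of side {side} m at {rig.object_distance} m "
                "projects outside the image bounds")
        areas[i] = shoelace_area(poly)
        mask = rasterize_polygon(poly, (h, w))
        frames[i] = _compose_frame(mask, foreground_level, background_level,
                                   illumination_gradient, noise_sd, rng)
    seq = FrameSequence(frames=frames, frame_rate=1.0, camera_index=1, view_angle=0.0)
    gt = GroundTruth(camera_index=1, area_px2=areas, n_true=areas / areas[0],
                     displacement_mm_true=np.zeros(2),
                     mm_per_pixel=1000.0 * rig.object_distance / intr.fx)
    return seq, gt
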