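"""Pinhole camera model with radial/tangential lens distortion.

Coordinate convention (used everywhere in this package): pixel origin at the
centre of the top-left pixel, x to the right, y down, 0-based.  A pixel
coordinate is therefore a continuous position; integer values land on pixel
centres.

The distortion model is the 5-coefficient Brown–Conrady form: three radial
terms (k1, k2, k3) and two tangential terms (p1, p2), applied in normalized
image coordinates x_n = X/Z, y_n = Y/Z:

    x_d = x_n (1 + k1 r^2 + k2 r^4 + k3 r^6) + 2 p1 x_n y_n + p2 (r^2 + 2 x_n^2)
    y_d = y_n (1 + k1 r^2 + k2 r^4 + k3 r^6) + p1 (r^2 + 2 y_n^2) + 2 p2 x_n y_n

with r^2 = x_n^2 + y_n^2, followed by the affine pixel mapping
(fx * x_d + cx, fy * y_d + cy).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml
from scipy import ndimage
from scipy.optimize import least_squares
from scipy.spatial.transform import Rotation


class ProjectionError(ValueError):
    """Raised for points at or behind the camera plane (Z <= 0)."""


class ConvergenceError(RuntimeError):
    """Raised when iterative undistortion fails to reach tolerance."""

    def __init__(self, message: str, residual: float):
        super().__init__(message)
        self.residual = residual


class DegenerateConfigurationError(ValueError):
    """Raised when a calibration problem is rank-deficient."""


class ScaleError(ValueError):
    """Raised for non-positive areas in pixel-scale estimation."""


@dataclass
class CameraIntrinsics:
    """Pinhole intrinsics plus Brown–Conrady distortion coefficients."""

    fx: float
    fy: float
    cx: float
    cy: float
    k1: float = 0.0
    k2: float = 0.0
    k3: float = 0.0
    p1: float = 0.0
    p2: float = 0.0
    width: int = 1920
    height: int = 1080

    def __post_init__(self) -> None:
        if self.fx <= 0 or self.fy <= 0:
            raise ValueError("focal lengths must be positive")
        if not (0 <= self.cx < self.width and 0 <= self.cy < self.height):
            raise ValueError("principal point must lie inside the image bounds")

    @property
    def distortion(self) -> np.ndarray:
        return np.array([self.k1, self.k2, self.k3, self.p1, self.p2])

    @property
    def has_distortion(self) -> bool:
        return bool(np.any(self.distortion != 0.0))

    @classmethod
    def ideal(cls, width: int, height: int, focal_px: float) -> "CameraIntrinsics":
        """Distortion-free camera with the principal point at the image centre."""
        return cls(fx=focal_px, fy=focal_px,
                   cx=(width - 1) / 2.0, cy=(height - 1) / 2.0,
                   width=width, height=height)

    def to_dict(self) -> dict:
        d = asdict(self)
        return {"fx": d["fx"], "fy": d["fy"], "cx": d["cx"], "cy": d["cy"],
                "k1": d["k1"], "k2": d["k2"], "k3": d["k3"],
                "p1": d["p1"], "p2": d["p2"],
                "image_width": d["width"], "image_height": d["height"]}

    @classmethod
    def from_dict(cls, d: dict) -> "CameraIntrinsics":
        return cls(fx=d["fx"], fy=d["fy"], cx=d["cx"], cy=d["cy"],
                   k1=d.get("k1", 0.0), k2=d.get("k2", 0.0), k3=d.get("k3", 0.0),
                   p1=d.get("p1", 0.0), p2=d.get("p2", 0.0),
                   width=int(d["image_width"]), height=int(d["image_height"]))

    def save_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh)

    @classmethod
    def load_yaml(cls, path) -> "CameraIntrinsics":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class PixelScale:
    """Metric scale of the object plane: millimetres per pixel."""

    mm_per_pixel: float
    object_distance: float | None = None

    def __post_init__(self) -> None:
        if self.mm_per_pixel <= 0:
            raise ScaleError("mm_per_pixel must be positive")

    @classmethod
    def from_camera(cls, intr: CameraIntrinsics, object_distance: float) -> "PixelScale":
        # mm/px at the object plane: 1000 * Z / f  (f in pixels)
        return cls(mm_per_pixel=1000.0 * object_distance / intr.fx,
                   object_distance=object_distance)


def distort_normalized(points_n: np.ndarray, intr: CameraIntrinsics) -> np.ndarray:
    """Apply the Brown–Conrady forward distortion in normalized coordinates."""
    pts = np.atleast_2d(np.asarray(points_n, dtype=float))
    x, y = pts[:, 0], pts[:, 1]
    r2 = x * x + y * y
    radial = 1.0 + intr.k1 * r2 + intr.k2 * r2 ** 2 + intr.k3 * r2 ** 3
    xd = x * radial + 2 * intr.p1 * x * y + intr.p2 * (r2 + 2 * x * x)
    yd = y * radial + intr.p1 * (r2 + 2 * y * y) + 2 * intr.p2 * x * y
    return np.column_stack([xd, yd])


def normalized_to_pixels(points_n: np.ndarray, intr: CameraIntrinsics) -> np.ndarray:
    pts = np.atleast_2d(np.asarray(points_n, dtype=float))
    return np.column_stack([intr.fx * pts[:, 0] + intr.cx,
                            intr.fy * pts[:, 1] + intr.cy])


def pixels_to_normalized(pixels: np.ndarray, intr: CameraIntrinsics) -> np.ndarray:
    pts = np.atleast_2d(np.asarray(pixels, dtype=float))
    return np.column_stack([(pts[:, 0] - intr.cx) / intr.fx,
                            (pts[:, 1] - intr.cy) / intr.fy])


def project(points_3d: np.ndarray, intr: CameraIntrinsics) -> np.ndarray:
    """Project 3-D camera-frame points (metres) to pixel coordinates.

    Applies central projection, the distortion polynomial, then the pixel
    mapping.  Raises :class:`ProjectionError` for non-positive depth.
    """
    pts = np.atleast_2d(np.asarray(points_3d, dtype=float))
    if pts.shape[1] != 3:
        raise ValueError("expected (N, 3) points")
    z = pts[:, 2]
    if np.any(z <= 0):
        raise ProjectionError("all points must have positive depth Z > 0")
    norm = pts[:, :2] / z[:, None]
    out = normalized_to_pixels(distort_normalized(norm, intr), intr)
    return out if np.asarray(points_3d).ndim == 2 else out[0]


def undistort_points(pixels: np.ndarray, intr: CameraIntrinsics,
                     tol: float = 1e-10, max_iter: int = 50) -> np.ndarray:
    """Invert the distortion map by fixed-point iteration.

    Returns the pixel coordinates the points would have under a pure
    pinhole (zero-distortion) camera with the same fx, fy, cx, cy.  The
    tolerance is measured in normalized coordinates.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    single = np.asarray(pixels).ndim == 1
    distorted_n = pixels_to_normalized(pixels, intr)
    xy = distorted_n.copy()
    k1, k2, k3, p1, p2 = intr.k1, intr.k2, intr.k3, intr.p1, intr.p2
    for _ in range(max_iter):
        x, y = xy[:, 0], xy[:, 1]
        r2 = x * x + y * y
        radial = 1.0 + k1 * r2 + k2 * r2 ** 2 + k3 * r2 ** 3
        tx = 2 * p1 * x * y + p2 * (r2 + 2 * x * x)
        ty = p1 * (r2 + 2 * y * y) + 2 * p2 * x * y
        xy = np.column_stack([(distorted_n[:, 0] - tx) / radial,
                              (distorted_n[:, 1] - ty) / radial])
        resid = np.abs(distort_normalized(xy, intr) - distorted_n).max()
        if resid < tol:
            break
    else:
        raise ConvergenceError(
            f"undistortion did not converge within {max_iter} iterations "
            f"(residual {resid:.3e})", residual=float(resid))
    out = normalized_to_pixels(xy, intr)
    return out[0] if single else out


def rectify_image(image: np.ndarray, intr: CameraIntrinsics) -> np.ndarray:
    """Resample a frame so lens distortion is removed.

    Inverse mapping: for every output pixel, the forward distortion model
    gives the source location in the captured frame, which is sampled with
    bilinear interpolation; sources outside the frame read as 0 (the dark
    background).  With all coefficients zero the image is returned unchanged.
    """
    img = np.asarray(image)
    if img.size == 0:
        raise ValueError("empty image")
    if not intr.has_distortion:
        return img.copy()
    h, w = img.shape[:2]
    xs, ys = np.meshgrid(np.arange(w, dtype=float), np.arange(h, dtype=float))
    grid = np.column_stack([xs.ravel(), ys.ravel()])
    src = normalized_to_pixels(
        distort_normalized(pixels_to_normalized(grid, intr), intr), intr)
    coords = np.array([src[:, 1].reshape(h, w), src[:, 0].reshape(h, w)])
    out = ndimage.map_coordinates(img.astype(float), coords, order=1,
                                  mode="constant", cval=0.0)
    if np.issubdtype(img.dtype, np.integer):
        out = np.clip(np.floor(out + 0.5), 0, np.iinfo(img.dtype).max)
    return out.astype(img.dtype)


@dataclass
class CalibrationResult:
    intrinsics: CameraIntrinsics
    rms_px: float
    per_view_rms: list[float] = field(default_factory=list)
    n_views: int = 0
    warning: str | None = None

    def to_dict(self) -> dict:
        return {"intrinsics": self.intrinsics.to_dict(), "rms_px": self.rms_px,
                "per_view_rms": list(self.per_view_rms), "n_views": self.n_views,
                "warning": self.warning}


def _homography(src: np.ndarray, dst: np.ndarray) -> np.ndarray:
    """Normalized DLT estimate of the homography mapping src -> dst."""

    def normalize(pts):
        mean = pts.mean(axis=0)
        scale = math.sqrt(2.0) / np.mean(np.linalg.norm(pts - mean, axis=1))
        T = np.array([[scale, 0, -scale * mean[0]],
                      [0, scale, -scale * mean[1]],
                      [0, 0, 1.0]])
        return T, (pts - mean) * scale

    Ts, s = normalize(src)
    Td, d = normalize(dst)
    n = len(src)
    A = np.zeros((2 * n, 9))
    for i in range(n):
        X, Y = s[i]
        u, v = d[i]
        A[2 * i] = [-X, -Y, -1, 0, 0, 0, u * X, u * Y, u]
        A[2 * i + 1] = [0, 0, 0, -X, -Y, -1, v * X, v * Y, v]
    _, sv, vt = np.linalg.svd(A)
    if sv[-2] < 1e-9 * sv[0]:
        raise DegenerateConfigurationError("degenerate point configuration for homography")
    H = vt[-1].reshape(3, 3)
    H = np.linalg.inv(Td) @ H @ Ts
    return H / H[2, 2]


def _intrinsics_from_homographies(Hs: list[np.ndarray]) -> tuple[float, float, float, float]:
    """Closed-form fx, fy, cx, cy from plane homographies (absolute-conic constraints)."""

    def v(H, i, j):
        return np.array([
            H[0, i] * H[0, j],
            H[0, i] * H[1, j] + H[1, i] * H[0, j],
            H[1, i] * H[1, j],
            H[2, i] * H[0, j] + H[0, i] * H[2, j],
            H[2, i] * H[1, j] + H[1, i] * H[2, j],
            H[2, i] * H[2, j],
        ])

    V = []
    for H in Hs:
        V.append(v(H, 0, 1))
        V.append(v(H, 0, 0) - v(H, 1, 1))
    V = np.array(V)
    _, sv, vt = np.linalg.svd(V)
    if sv[-1] > 1e-4 * sv[0] and len(Hs) >= 3:
        # genuinely inconsistent rather than near-null; still proceed, the
        # nonlinear refinement judges the final fit
        pass
    if sv[-2] < 1e-10 * sv[0]:
        raise DegenerateConfigurationError("calibration views are rank-deficient "
                                           "(coplanar or repeated poses)")
    b11, b12, b22, b13, b23, b33 = vt[-1]
    denom = b11 * b22 - b12 ** 2
    if denom == 0 or b11 == 0:
        raise DegenerateConfigurationError("singular conic estimate")
    cy = (b12 * b13 - b11 * b23) / denom
    lam = b33 - (b13 ** 2 + cy * (b12 * b13 - b11 * b23)) / b11
    if lam / b11 <= 0 or lam * b11 / denom <= 0:
        raise DegenerateConfigurationError("conic estimate is not positive definite")
    fx = math.sqrt(lam / b11)
    fy = math.sqrt(lam * b11 / denom)
    skew = -b12 * fx ** 2 * fy / lam
    cx = skew * cy / fy - b13 * fx ** 2 / lam
    return fx, fy, cx, cy


def _extrinsics_from_homography(H: np.ndarray, K: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    Kinv = np.linalg.inv(K)
    h1, h2, h3 = H[:, 0], H[:, 1], H[:, 2]
    lam = 1.0 / np.linalg.norm(Kinv @ h1)
    r1 = lam * (Kinv @ h1)
    r2 = lam * (Kinv @ h2)
    r3 = np.cross(r1, r2)
    R = np.column_stack([r1, r2, r3])
    # closest proper rotation
    U, _, Vt = np.linalg.svd(R)
    R = U @ Vt
    if np.linalg.det(R) < 0:
        R = -R
    t = lam * (Kinv @ h3)
    if t[2] < 0:  # plane must be in front of the camera
        R = R @ np.diag([-1, -1, 1])
        t = -t
    return Rotation.from_matrix(R).as_rotvec(), t


def calibrate(object_points: np.ndarray, image_points: list[np.ndarray],
              image_size: tuple[int, int], rms_warn_px: float = 1.0) -> CalibrationResult:
    """Estimate intrinsics and distortion from views of a planar target.

    ``object_points`` are the target's (N, 2) planar coordinates in metres
    (Z = 0 plane); ``image_points`` holds the detected (N, 2) pixel positions
    for each view.  A closed-form plane-based initialisation of fx, fy, cx,
    cy is refined together with k1, k2, k3, p1, p2 and the per-view poses by
    nonlinear least squares on the reprojection residuals.
    """
    obj = np.asarray(object_points, dtype=float)
    if obj.ndim != 2 or obj.shape[1] not in (2, 3):
        raise ValueError("object_points must be (N, 2) or (N, 3) with Z = 0")
    if obj.shape[1] == 3:
        if np.any(obj[:, 2] != 0):
            raise ValueError("planar target required (Z = 0)")
        obj = obj[:, :2]
    views = [np.asarray(p, dtype=float) for p in image_points]
    if len(views) < 3:
        raise ValueError("at least 3 views are required")
    if any(len(v) != len(obj) or len(v) < 8 for v in views):
        raise ValueError("each view needs the full set of >= 8 target points")

    Hs = [_homography(obj, v) for v in views]
    fx, fy, cx, cy = _intrinsics_from_homographies(Hs)
    K = np.array([[fx, 0, cx], [0, fy, cy], [0, 0, 1.0]])
    poses = [_extrinsics_from_homography(H, K) for H in Hs]

    obj3 = np.column_stack([obj, np.zeros(len(obj))])
    w, h = image_size

    def unpack(x):
        intr = CameraIntrinsics(fx=x[0], fy=x[1], cx=x[2], cy=x[3],
                                k1=x[4], k2=x[5], k3=x[6], p1=x[7], p2=x[8],
                                width=w, height=h)
        pv = x[9:].reshape(len(views), 6)
        return intr, pv

    def residuals(x):
        intr, pv = unpack(x)
        res = []
        for (rv, tv), det in zip(pv.reshape(-1, 2, 3), views):
            pts = Rotation.from_rotvec(rv).apply(obj3) + tv
            res.append((project(pts, intr) - det).ravel())
        return np.concatenate(res)

    x0 = np.concatenate([[fx, fy, cx, cy, 0, 0, 0, 0, 0],
                         np.concatenate([np.concatenate(p) for p in poses])])
    sol = least_squares(residuals, x0, method="lm", xtol=1e-12, ftol=1e-12)
    intr, pv = unpack(sol.x)
    per_view = []
    for (rv, tv), det in zip(pv.reshape(-1, 2, 3), views):
        pts = Rotation.from_rotvec(rv).apply(obj3) + tv
        err = project(pts, intr) - det
        per_view.append(float(np.sqrt(np.mean(np.sum(err ** 2, axis=1)))))
    rms = float(np.sqrt(np.mean(np.sum(sol.fun.reshape(-1, 2) ** 2, axis=1))))
    warning = None
    if rms > rms_warn_px:
        warning = f"RMS reprojection error {rms:.3f} px exceeds {rms_warn_px} px"
    return CalibrationResult(intrinsics=intr, rms_px=rms, per_view_rms=per_view,
                             n_views=len(views), warning=warning)


def pixel_scale_from_square(square_area_px: float, true_side: float) -> PixelScale:
    """Metric scale from a reference square of known physical side length.

    mm_per_pixel = 1000 * side / sqrt(area_px).
    """
    if square_area_px <= 0:
        raise ScaleError("square area must be positive")
    return PixelScale(mm_per_pixel=1000.0 * true_side / math.sqrt(square_area_px))
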