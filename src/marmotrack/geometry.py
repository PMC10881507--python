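"""Cage coordinate frame, pinhole cameras, fiducial calibration, triangulation.

The cage frame has its origin at the front-lower-left corner of the home
cage: x runs along the cage width, y along the depth (the acrylic front
face is the y = 0 plane, with the cameras standing at negative y), and z is
height.  All lengths are millimetres.

Cameras are standard pinhole models without lens distortion: a point X in
the cage frame maps to camera coordinates ``Xc = R @ X + t`` and then to
pixels ``u = fx * Xc[0]/Xc[2] + cx``, ``v = fy * Xc[1]/Xc[2] + cy``.
Camera pose is recovered from the four corner fiducials on the front face
via a planar homography, refined by nonlinear least squares; intrinsics
are supplied by configuration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial.transform import Rotation


class BehindCameraError(ValueError):
    """A point has non-positive depth in the camera frame."""


class CalibrationError(ValueError):
    """Fiducial configuration is degenerate or calibration failed."""


class InsufficientViewsError(ValueError):
    """Triangulation requires observations from at least two cameras."""


def _default_fiducials() -> np.ndarray:
    # four corners of the front face (y = 0 plane)
    return np.array(
        [
            [0.0, 0.0, 0.0],
            [820.0, 0.0, 0.0],
            [820.0, 0.0, 1578.0],
            [0.0, 0.0, 1578.0],
        ]
    )


@dataclass(frozen=True)
class CageModel:
    """Axis-aligned home-cage volume with front-face corner fiducials."""

    width: float = 820.0
    depth: float = 610.0
    height: float = 1578.0
    fiducial_points: np.ndarray = field(default_factory=_default_fiducials)

    def __post_init__(self) -> None:
        if min(self.width, self.depth, self.height) <= 0:
            raise ValueError("cage dimensions must be positive")
        fid = np.asarray(self.fiducial_points, dtype=float)
        if fid.shape != (4, 3):
            raise ValueError("expected four 3D fiducial points")
        if not np.allclose(fid[:, 1], 0.0):
            raise ValueError("fiducials must lie on the front face (y = 0)")
        object.__setattr__(self, "fiducial_points", fid)

    @property
    def box(self) -> np.ndarray:
        """(2, 3) array of (min, max) corners."""
        return np.array([[0.0, 0.0, 0.0], [self.width, self.depth, self.height]])

    def contains(self, points: np.ndarray, tol: float = 0.0) -> np.ndarray:
        """Boolean mask of points inside the cage box (with tolerance, mm)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        lo, hi = self.box
        ok = np.all((pts >= lo - tol) & (pts <= hi + tol), axis=1)
        return ok if np.asarray(points).ndim > 1 else bool(ok[0])

    @property
    def center(self) -> np.ndarray:
        return np.array([self.width / 2, self.depth / 2, self.height / 2])


@dataclass(frozen=True)
class PixelObservation:
    """One 2D observation of a target in one camera at one time."""

    camera_id: str
    pixel: tuple[float, float]
    timestamp: float = 0.0


@dataclass(frozen=True)
class CameraModel:
    """Calibrated pinhole camera: intrinsics plus cage-frame pose.

    ``rotation`` and ``translation`` map cage-frame mm to camera-frame mm,
    ``Xc = R @ X + t``; the optical axis is camera +z.
    """

    camera_id: str
    focal: tuple[float, float]
    principal_point: tuple[float, float]
    rotation: np.ndarray
    translation: np.ndarray
    image_size: tuple[int, int] = (1920, 1080)

    def __post_init__(self) -> None:
        fx, fy = self.focal
        if fx <= 0 or fy <= 0:
            raise ValueError("focal lengths must be positive")
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8) or np.linalg.det(R) < 0:
            raise ValueError("rotation must be orthonormal with det +1")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(
            self, "translation", np.asarray(self.translation, dtype=float).reshape(3)
        )

    @property
    def position(self) -> np.ndarray:
        """Camera centre in the cage frame."""
        return -self.rotation.T @ self.translation

    @classmethod
    def look_at(
        cls,
        camera_id: str,
        position,
        target,
        focal: tuple[float, float] = (620.0, 620.0),
        principal_point: tuple[float, float] | None = None,
        image_size: tuple[int, int] = (1920, 1080),
        up=(0.0, 0.0, 1.0),
    ) -> "CameraModel":
        """Build a camera at ``position`` whose optical axis points at ``target``."""
        position = np.asarray(position, dtype=float)
        forward = np.asarray(target, dtype=float) - position
        norm = np.linalg.norm(forward)
        if norm == 0:
            raise ValueError("camera position and target coincide")
        z = forward / norm
        x = np.cross(z, np.asarray(up, dtype=float))
        xn = np.linalg.norm(x)
        if xn < 1e-12:
            raise ValueError("viewing direction parallel to up vector")
        x /= xn
        y = np.cross(z, x)
        R = np.stack([x, y, z])
        if principal_point is None:
            principal_point = (image_size[0] / 2.0, image_size[1] / 2.0)
        return cls(
            camera_id=camera_id,
            focal=focal,
            principal_point=principal_point,
            rotation=R,
            translation=-R @ position,
            image_size=image_size,
        )

    # -- projection ---------------------------------------------------------

    def to_camera_frame(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return pts @ self.rotation.T + self.translation

    def project(self, points: np.ndarray) -> np.ndarray:
        """Project cage-frame points to pixels; raises behind the camera."""
        single = np.asarray(points).ndim == 1
        cam = self.to_camera_frame(points)
        if np.any(cam[:, 2] <= 0):
            raise BehindCameraError(
                f"point(s) behind camera {self.camera_id} (non-positive depth)"
            )
        fx, fy = self.focal
        cx, cy = self.principal_point
        uv = np.empty((cam.shape[0], 2))
        uv[:, 0] = fx * cam[:, 0] / cam[:, 2] + cx
        uv[:, 1] = fy * cam[:, 1] / cam[:, 2] + cy
        return uv[0] if single else uv

    def pixel_ray(self, pixel) -> tuple[np.ndarray, np.ndarray]:
        """Cage-frame ray (origin, unit direction) through a pixel."""
        u, v = pixel
        fx, fy = self.focal
        cx, cy = self.principal_point
        d_cam = np.array([(u - cx) / fx, (v - cy) / fy, 1.0])
        d = self.rotation.T @ d_cam
        return self.position, d / np.linalg.norm(d)

    def in_image(self, pixels: np.ndarray, margin: float = 0.0) -> np.ndarray:
        uv = np.atleast_2d(np.asarray(pixels, dtype=float))
        w, h = self.image_size
        ok = (
            (uv[:, 0] >= -margin)
            & (uv[:, 0] < w + margin)
            & (uv[:, 1] >= -margin)
            & (uv[:, 1] < h + margin)
        )
        return ok if np.asarray(pixels).ndim > 1 else bool(ok[0])


def project(camera: CameraModel, point) -> np.ndarray:
    """Functional alias for :meth:`CameraModel.project`."""
    return camera.project(point)


# ---------------------------------------------------------------------------
# Calibration from the four front-face corner fiducials
# ---------------------------------------------------------------------------


def _homography_from_points(plane_xy: np.ndarray, pixels: np.ndarray) -> np.ndarray:
    """DLT homography mapping plane coordinates to pixels (>= 4 points)."""
    n = plane_xy.shape[0]
    A = np.zeros((2 * n, 9))
    for i, ((X, Y), (u, v)) in enumerate(zip(plane_xy, pixels)):
        A[2 * i] = [X, Y, 1, 0, 0, 0, -u * X, -u * Y, -u]
        A[2 * i + 1] = [0, 0, 0, X, Y, 1, -v * X, -v * Y, -v]
    _, s, vt = np.linalg.svd(A)
    if s[-2] < 1e-9 * s[0]:
        raise CalibrationError("degenerate fiducial configuration")
    return vt[-1].reshape(3, 3)


@dataclass(frozen=True)
class CalibrationResult:
    camera: CameraModel
    residual_px: float


def calibrate_camera(
    marker_pixels: list[PixelObservation] | np.ndarray,
    cage: CageModel,
    focal: tuple[float, float],
    principal_point: tuple[float, float],
    image_size: tuple[int, int] = (1920, 1080),
    camera_id: str = "cam",
) -> CalibrationResult:
    """Recover camera pose from the four front-face corner markers.

    The fiducials are coplanar (y = 0), so the pose follows from a planar
    homography: with intrinsics K and world points (x, 0, z),
    ``H ~ K [c1 c3 t]`` where c1, c3 are the first and third columns of the
    rotation.  The decomposed pose is refined by least squares on the
    reprojection error of the four markers.
    """
    if isinstance(marker_pixels, (list, tuple)):
        pixels = np.array([obs.pixel for obs in marker_pixels], dtype=float)
    else:
        pixels = np.asarray(marker_pixels, dtype=float)
    world = np.asarray(cage.fiducial_points, dtype=float)
    if pixels.shape[0] != world.shape[0]:
        raise CalibrationError("need one pixel observation per fiducial")
    plane = world[:, [0, 2]]  # front face: (x, z) coordinates

    # collinearity check: area of the marker polygon in the plane
    centred = plane - plane.mean(axis=0)
    if np.linalg.svd(centred, compute_uv=False)[-1] < 1e-6:
        raise CalibrationError("fiducials are collinear")
    centred_px = pixels - pixels.mean(axis=0)
    if np.linalg.svd(centred_px, compute_uv=False)[-1] < 1e-6:
        raise CalibrationError("observed marker pixels are collinear")

    H = _homography_from_points(plane, pixels)
    fx, fy = focal
    cx, cy = principal_point
    K = np.array([[fx, 0, cx], [0, fy, cy], [0, 0, 1.0]])
    B = np.linalg.solve(K, H)
    lam = 2.0 / (np.linalg.norm(B[:, 0]) + np.linalg.norm(B[:, 1]))
    if B[2, 2] * lam < 0:  # markers must sit in front of the camera
        lam = -lam
    c1 = lam * B[:, 0]
    c3 = lam * B[:, 1]
    c2 = np.cross(c3, c1)
    R0 = np.column_stack([c1, c2, c3])
    # nearest proper rotation
    U, _, Vt = np.linalg.svd(R0)
    R0 = U @ np.diag([1.0, 1.0, np.sign(np.linalg.det(U @ Vt))]) @ Vt
    t0 = lam * B[:, 2]

    def residuals(params: np.ndarray) -> np.ndarray:
        R = Rotation.from_rotvec(params[:3]).as_matrix()
        t = params[3:]
        cam = world @ R.T + t
        uv = np.column_stack(
            [fx * cam[:, 0] / cam[:, 2] + cx, fy * cam[:, 1] / cam[:, 2] + cy]
        )
        return (uv - pixels).ravel()

    x0 = np.concatenate([Rotation.from_matrix(R0).as_rotvec(), t0])
    sol = least_squares(residuals, x0, method="lm", xtol=1e-15, ftol=1e-15)
    R = Rotation.from_rotvec(sol.x[:3]).as_matrix()
    t = sol.x[3:]
    per_point = sol.fun.reshape(-1, 2)
    resid = float(np.sqrt(np.mean(np.sum(per_point**2, axis=1))))
    camera = CameraModel(
        camera_id=camera_id,
        focal=focal,
        principal_point=principal_point,
        rotation=R,
        translation=t,
        image_size=image_size,
    )
    return CalibrationResult(camera=camera, residual_px=resid)


# ---------------------------------------------------------------------------
# Multi-view triangulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TriangulationResult:
    point: np.ndarray
    residual_px: float
    n_views: int
    low_confidence: bool = False


def _solve_linear(cameras: list[CameraModel], pixels: np.ndarray) -> np.ndarray:
    """Linear (DLT-style) least-squares intersection of viewing rays.

    Each view contributes the two equations ``(R0 - xn R2) X = xn t2 - t0``
    and ``(R1 - yn R2) X = yn t2 - t1`` in normalised pixel coordinates;
    the stacked system is solved via its 3x3 normal equations.
    """
    n = len(cameras)
    A = np.empty((2 * n, 3))
    b = np.empty(2 * n)
    for i, cam in enumerate(cameras):
        u, v = pixels[i]
        fx, fy = cam.focal
        cx, cy = cam.principal_point
        xn = (u - cx) / fx
        yn = (v - cy) / fy
        R, t = cam.rotation, cam.translation
        A[2 * i] = R[0] - xn * R[2]
        b[2 * i] = xn * t[2] - t[0]
        A[2 * i + 1] = R[1] - yn * R[2]
        b[2 * i + 1] = yn * t[2] - t[1]
    AtA = A.T @ A
    Atb = A.T @ b
    try:
        return np.linalg.solve(AtA, Atb)
    except np.linalg.LinAlgError:
        point, *_ = np.linalg.lstsq(A, b, rcond=None)
        return point


def _reproj_residuals(
    cameras: list[CameraModel], pixels: np.ndarray, point: np.ndarray
) -> np.ndarray:
    errs = np.empty(len(cameras))
    for i, cam in enumerate(cameras):
        camf = cam.rotation @ point + cam.translation
        if camf[2] <= 0:
            errs[i] = np.inf
            continue
        fx, fy = cam.focal
        cx, cy = cam.principal_point
        du = fx * camf[0] / camf[2] + cx - pixels[i, 0]
        dv = fy * camf[1] / camf[2] + cy - pixels[i, 1]
        errs[i] = math.hypot(du, dv)
    return errs


def _min_pairwise_cos(cameras: list[CameraModel], pixels: np.ndarray) -> float:
    """Smallest |cos| between viewing-ray pairs (1 means all parallel)."""
    dirs = np.empty((len(cameras), 3))
    for i, cam in enumerate(cameras):
        u, v = pixels[i]
        fx, fy = cam.focal
        cx, cy = cam.principal_point
        d = cam.rotation.T @ np.array([(u - cx) / fx, (v - cy) / fy, 1.0])
        dirs[i] = d / math.sqrt(d @ d)
    worst = 1.0
    for i in range(len(dirs)):
        for j in range(i + 1, len(dirs)):
            worst = min(worst, abs(float(dirs[i] @ dirs[j])))
    return worst


def triangulate_pixels(
    cams: list[CameraModel],
    pixels: np.ndarray,
    reject_outlier_views: bool = True,
    min_parallax_deg: float = 1.0,
) -> TriangulationResult:
    """Core triangulation on camera objects + an (n, 2) pixel array."""
    if len({c.camera_id for c in cams}) < 2:
        raise InsufficientViewsError("triangulation needs >= 2 distinct cameras")
    pixels = np.asarray(pixels, dtype=float)

    point = _solve_linear(cams, pixels)
    errs = _reproj_residuals(cams, pixels, point)

    if reject_outlier_views and len(cams) >= 3:
        order = np.argsort(errs)
        worst = order[-1]
        med_others = np.median(errs[order[:-1]])
        if med_others > 0 and errs[worst] > 3.0 * med_others:
            keep = [i for i in range(len(cams)) if i != worst]
            cams = [cams[i] for i in keep]
            pixels = pixels[keep]
            point = _solve_linear(cams, pixels)
            errs = _reproj_residuals(cams, pixels, point)

    low_conf = _min_pairwise_cos(cams, pixels) > math.cos(
        math.radians(min_parallax_deg)
    )
    residual = (
        float(np.sqrt(np.mean(errs**2))) if np.all(np.isfinite(errs)) else float("inf")
    )
    return TriangulationResult(
        point=point, residual_px=residual, n_views=len(cams), low_confidence=low_conf
    )


def triangulate(
    observations: list[PixelObservation],
    cameras: dict[str, CameraModel],
    reject_outlier_views: bool = True,
    min_parallax_deg: float = 1.0,
) -> TriangulationResult:
    """Triangulate one 3D point from >= 2 single-tick pixel observations.

    A view whose reprojection residual exceeds 3x the median of the other
    views is rejected (once, when at least three views are present).  Rays
    with maximal pairwise parallax below ``min_parallax_deg`` — e.g. a
    target sitting on the camera baseline — yield a low-confidence flag.
    """
    cams = []
    for obs in observations:
        if obs.camera_id not in cameras:
            raise KeyError(f"unknown camera {obs.camera_id!r}")
        cams.append(cameras[obs.camera_id])
    pixels = np.array([obs.pixel for obs in observations], dtype=float)
    return triangulate_pixels(cams, pixels, reject_outlier_views, min_parallax_deg)


def default_camera_rig(
    cage: CageModel,
    standoff: float = 1000.0,
    heights: tuple[float, float] = (900.0, 1900.0),
    spread: float = 600.0,
    focal: tuple[float, float] = (620.0, 620.0),
    image_size: tuple[int, int] = (1920, 1080),
) -> dict[str, CameraModel]:
    """Four-camera front rig: two columns at two mounting heights.

    Mirrors the recording geometry used for home-cage monitoring: cameras on
    poles ``standoff`` mm in front of the cage (negative y), left/right
    columns ``spread`` mm apart centred on the cage, aimed at the cage
    centre.
    """
    cx = cage.width / 2
    xs = (cx - spread / 2, cx + spread / 2)
    target = cage.center
    rig = {}
    for i, (x, name_x) in enumerate(zip(xs, ("left", "right"))):
        for z, name_z in zip(heights, ("lower", "upper")):
            cam_id = f"{name_x}_{name_z}"
            rig[cam_id] = CameraModel.look_at(
                cam_id,
                position=(x, -standoff, z),
                target=target,
                focal=focal,
                image_size=image_size,
            )
    return rig
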