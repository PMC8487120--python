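"""Simulated 2-D angiographic projection of a labelled 3-D scene.

The C-arm sweep is modelled as a single rotation about the patient's
superior-inferior axis (pure LAO, no cranial/caudal angulation), with a
parallel-beam (orthographic) geometry: the source is assumed far enough from
the aortic arch that ray divergence is negligible.  In the LPS frame the
projection direction at sweep angle ``theta`` (degrees) is::

    ray_dir(theta)    = (sin t, cos t, 0)      # theta = 0 is the AP view
    detector_u(theta) = (cos t, -sin t, 0)     # image-right
    detector_v        = (0, 0, -1)             # image-down (up = superior)

A detector pixel of a vessel silhouette is set iff the parallel ray through
its centre intersects at least one voxel carrying that vessel's label.  Rays
are sampled at half the minimum voxel spacing with nearest-neighbour lookup,
which is deterministic and cannot skip a voxel.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .vesselmodel import Centerline, VesselScene

__all__ = [
    "ProjectionGeometry",
    "ProjectionMask",
    "ProjectedCenterline",
    "geometry_for_angle",
    "geometry_for_scene",
    "project_label",
    "project_centerline",
    "render_view",
    "save_mask_png",
    "save_view_png",
]


@dataclass(frozen=True)
class ProjectionGeometry:
    """Parallel-beam C-arm geometry at one sweep angle.

    ``detector_shape`` is ``(rows, cols)``; rows run along ``detector_v``,
    columns along ``detector_u``.  ``det_center_uv`` places the detector
    centre in (u, v) millimetre coordinates, so a detector can be centred on
    an arbitrary scene without changing the angular convention.
    """

    theta: float
    ray_dir: np.ndarray
    detector_u: np.ndarray
    detector_v: np.ndarray
    pixel_size: float
    detector_shape: tuple[int, int]
    det_center_uv: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        for name in ("ray_dir", "detector_u", "detector_v"):
            v = np.asarray(getattr(self, name), dtype=float).reshape(3)
            object.__setattr__(self, name, v)
            if abs(np.linalg.norm(v) - 1.0) > 1e-9:
                raise ValueError(f"{name} must be a unit vector")
        if abs(self.ray_dir @ self.detector_u) > 1e-9 or \
           abs(self.ray_dir @ self.detector_v) > 1e-9 or \
           abs(self.detector_u @ self.detector_v) > 1e-9:
            raise ValueError("ray_dir, detector_u, detector_v must be orthogonal")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(u of each column, v of each row) in mm."""
        n_v, n_u = self.detector_shape
        cu, cv = self.det_center_uv
        u = cu + (np.arange(n_u) - (n_u - 1) / 2.0) * self.pixel_size
        v = cv + (np.arange(n_v) - (n_v - 1) / 2.0) * self.pixel_size
        return u, v

    def uv_to_pixel(self, points_uv: np.ndarray) -> np.ndarray:
        """Map (u, v) mm coordinates to fractional (row, col) pixel indices."""
        pts = np.atleast_2d(np.asarray(points_uv, dtype=float))
        n_v, n_u = self.detector_shape
        cu, cv = self.det_center_uv
        col = (pts[:, 0] - cu) / self.pixel_size + (n_u - 1) / 2.0
        row = (pts[:, 1] - cv) / self.pixel_size + (n_v - 1) / 2.0
        return np.column_stack([row, col])


@dataclass
class ProjectionMask:
    """Binary silhouette of one vessel label at one sweep angle."""

    mask: np.ndarray
    label: str
    theta: float
    pixel_size: float

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2-D")

    @property
    def pixel_count(self) -> int:
        return int(self.mask.sum())


@dataclass
class ProjectedCenterline:
    """A centerline mapped into detector (u, v) mm coordinates."""

    points2d: np.ndarray
    theta: float

    def __post_init__(self) -> None:
        self.points2d = np.asarray(self.points2d, dtype=float)
        if self.points2d.ndim != 2 or self.points2d.shape[1] != 2:
            raise ValueError("points2d must be (n, 2)")

    def length(self) -> float:
        """2-D arc length (mm) of the projected polyline."""
        return float(np.linalg.norm(np.diff(self.points2d, axis=0), axis=1).sum())


def geometry_for_angle(
    theta: float,
    pixel_size: float,
    detector_shape: tuple[int, int],
    det_center_uv: tuple[float, float] = (0.0, 0.0),
) -> ProjectionGeometry:
    """Build the parallel-beam frame for sweep angle ``theta`` in [0, 90]."""
    if not 0.0 <= theta <= 90.0:
        raise ValueError(f"theta must be within [0, 90] degrees, got {theta}")
    t = math.radians(theta)
    return ProjectionGeometry(
        theta=float(theta),
        ray_dir=np.array([math.sin(t), math.cos(t), 0.0]),
        detector_u=np.array([math.cos(t), -math.sin(t), 0.0]),
        detector_v=np.array([0.0, 0.0, -1.0]),
        pixel_size=float(pixel_size),
        detector_shape=(int(detector_shape[0]), int(detector_shape[1])),
        det_center_uv=(float(det_center_uv[0]), float(det_center_uv[1])),
    )


def geometry_for_scene(
    scene: VesselScene,
    theta: float,
    pixel_size: float | None = None,
    margin: int = 2,
) -> ProjectionGeometry:
    """Geometry whose detector covers the scene at every sweep angle.

    The detector is sized from the scene's bounding sphere (plus ``margin``
    pixels per side) and centred on the projection of the grid centre, so the
    detector shape is identical across the whole sweep.  ``pixel_size``
    defaults to the minimum voxel spacing.
    """
    if pixel_size is None:
        pixel_size = float(np.min(scene.spacing))
    lo, hi = scene.bounds
    radius = 0.5 * float(np.linalg.norm(hi - lo))
    n = int(math.ceil(2.0 * radius / pixel_size)) + 2 * margin
    geom = geometry_for_angle(theta, pixel_size, (n, n))
    c = scene.center
    return geometry_for_angle(
        theta, pixel_size, (n, n),
        det_center_uv=(float(c @ geom.detector_u), float(c @ geom.detector_v)),
    )


def project_centerline(cl: Centerline, geom: ProjectionGeometry) -> ProjectedCenterline:
    """Orthographically project a 3-D centerline onto the detector plane."""
    uv = np.column_stack([cl.points @ geom.detector_u, cl.points @ geom.detector_v])
    return ProjectedCenterline(points2d=uv, theta=geom.theta)


def _label_bbox(scene: VesselScene, value: int) -> tuple[np.ndarray, np.ndarray] | None:
    idx = np.nonzero(scene.volume == value)
    if idx[0].size == 0:
        return None
    lo = np.array([int(i.min()) for i in idx])
    hi = np.array([int(i.max()) for i in idx])
    return lo, hi


def _cast_rays(
    scene: VesselScene,
    geom: ProjectionGeometry,
    idx_lo: np.ndarray,
    idx_hi: np.ndarray,
    reduce_label: int | None,
) -> tuple[np.ndarray, slice, slice, float]:
    """Sample parallel rays through the index box [idx_lo, idx_hi].

    With ``reduce_label`` set, returns a boolean hit image (any sample equals
    the label); with ``None``, returns per-pixel foreground sample counts.
    The returned slices locate the computed sub-image on the full detector.
    """
    spacing, origin = scene.spacing, scene.origin
    step = 0.5 * float(np.min(spacing))
    # physical corners of the index box, padded by one voxel
    corners_idx = np.array(
        [[a, b, c]
         for a in (idx_lo[0] - 1, idx_hi[0] + 1)
         for b in (idx_lo[1] - 1, idx_hi[1] + 1)
         for c in (idx_lo[2] - 1, idx_hi[2] + 1)], dtype=float)
    corners = corners_idx * spacing + origin
    cu = corners @ geom.detector_u
    cv = corners @ geom.detector_v
    ct = corners @ geom.ray_dir
    u, v = geom.pixel_centers()
    j0 = int(np.clip(np.searchsorted(u, cu.min()) - 1, 0, len(u)))
    j1 = int(np.clip(np.searchsorted(u, cu.max()) + 1, 0, len(u)))
    i0 = int(np.clip(np.searchsorted(v, cv.min()) - 1, 0, len(v)))
    i1 = int(np.clip(np.searchsorted(v, cv.max()) + 1, 0, len(v)))
    rows, cols = slice(i0, i1), slice(j0, j1)
    if i1 <= i0 or j1 <= j0:
        return np.zeros((0, 0)), rows, cols, step
    base = (u[None, j0:j1, None] * geom.detector_u
            + v[i0:i1, None, None] * geom.detector_v)  # (r, c, 3)
    n_t = max(1, int(math.ceil((ct.max() - ct.min()) / step)) + 1)
    shape = np.array(scene.volume.shape)
    vol = scene.volume
    if reduce_label is not None:
        out = np.zeros(base.shape[:2], dtype=bool)
    else:
        out = np.zeros(base.shape[:2], dtype=np.int64)
    t0 = float(ct.min())
    for k in range(n_t):
        pts = base + (t0 + k * step) * geom.ray_dir
        idx = np.rint((pts - origin) / spacing).astype(np.int64)
        valid = np.all((idx >= 0) & (idx < shape), axis=-1)
        if not valid.any():
            continue
        ii = idx[valid]
        vals = vol[ii[:, 0], ii[:, 1], ii[:, 2]]
        if reduce_label is not None:
            hit = np.zeros(valid.shape, dtype=bool)
            hit[valid] = vals == reduce_label
            out |= hit
        else:
            cnt = np.zeros(valid.shape, dtype=np.int64)
            cnt[valid] = (vals != 0).astype(np.int64)
            out += cnt
    return out, rows, cols, step


def project_label(scene: VesselScene, label: str, geom: ProjectionGeometry) -> ProjectionMask:
    """Binary silhouette of ``label`` under the given geometry.

    A pixel is set iff the parallel ray through its centre passes within the
    labelled voxel region (nearest-neighbour sampling at half the minimum
    voxel spacing).
    """
    value = scene.label_value(label)
    mask = np.zeros(geom.detector_shape, dtype=bool)
    bbox = _label_bbox(scene, value)
    if bbox is not None:
        sub, rows, cols, _ = _cast_rays(scene, geom, bbox[0], bbox[1], value)
        if sub.size:
            mask[rows, cols] = sub
    return ProjectionMask(mask=mask, label=label, theta=geom.theta,
                          pixel_size=geom.pixel_size)


def render_view(scene: VesselScene, geom: ProjectionGeometry) -> np.ndarray:
    """Grayscale simulated angiogram: normalised ray-path thickness map.

    Each pixel holds the length of intersection of its ray with the
    foreground (any non-background label), rescaled to [0, 1].  Intended for
    qualitative views and absolute-difference images; not an attenuation
    model.
    """
    img = np.zeros(geom.detector_shape, dtype=float)
    fg = np.nonzero(scene.volume != 0)
    if fg[0].size == 0:
        return img
    lo = np.array([int(i.min()) for i in fg])
    hi = np.array([int(i.max()) for i in fg])
    counts, rows, cols, step = _cast_rays(scene, geom, lo, hi, None)
    if counts.size:
        img[rows, cols] = counts * step
    peak = img.max()
    if peak > 0:
        img /= peak
    return img


def save_mask_png(pm: ProjectionMask, directory: str | Path) -> Path:
    """Write a mask as 0/255 PNG named ``{label}_{theta:05.1f}.png`` plus a
    JSON sidecar echoing the geometry scalars."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    path = directory / f"{pm.label}_{pm.theta:05.1f}.png"
    iio.imwrite(path, (pm.mask.astype(np.uint8) * 255))
    sidecar = path.with_suffix(".json")
    sidecar.write_text(json.dumps(
        {"label": pm.label, "theta_deg": pm.theta, "pixel_size_mm": pm.pixel_size}
    ))
    return path


def save_view_png(image: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(path, np.clip(image * 255.0, 0, 255).astype(np.uint8))
    return path
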