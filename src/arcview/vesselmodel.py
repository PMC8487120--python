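"""Domain types for labelled vascular scenes and their on-disk bundle format.

A scene couples a labelled voxel volume (background / aorta / LCCA / LSA)
with one or more vessel centerlines, all expressed in a single physical
coordinate frame: LPS patient coordinates (+x patient-left, +y
patient-posterior, +z patient-superior), millimetres.  The voxel-index to
physical mapping is axis-aligned affine: ``x_mm = index * spacing + origin``.

On disk a scene is a *bundle*: a NIfTI label volume, one CSV (or JSON)
polyline per vessel with header ``x_mm,y_mm,z_mm`` ordered proximal to
distal, and a JSON sidecar holding the label mapping.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "Centerline",
    "VesselScene",
    "SceneBundleFiles",
    "SceneFormatError",
    "SceneValidationError",
    "arc_length",
    "read_scene",
    "write_scene",
    "read_centerline",
    "write_centerline",
    "CANONICAL_LABELS",
]

#: Default semantic label mapping.
CANONICAL_LABELS: dict[str, int] = {"background": 0, "aorta": 1, "LCCA": 2, "LSA": 3}


class SceneValidationError(ValueError):
    """A scene, centerline or bundle violates a structural invariant."""


class SceneFormatError(ValueError):
    """A file exists but is not in the expected format."""


@dataclass
class Centerline:
    """An ordered 3-D polyline in physical millimetres.

    Parameters
    ----------
    points
        ``(n, 3)`` array of positions in mm, ordered proximal to distal.
    label
        Name of the vessel the polyline traces (``"aorta"``, ``"LCCA"``,
        ``"LSA"``).
    """

    points: np.ndarray
    label: str

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise SceneValidationError(
                f"centerline '{self.label}': points must be (n, 3), got {pts.shape}"
            )
        if pts.shape[0] < 2:
            raise SceneValidationError(
                f"centerline '{self.label}': needs at least 2 points, got {pts.shape[0]}"
            )
        seg = np.diff(pts, axis=0)
        seg_len = np.linalg.norm(seg, axis=1)
        if np.any(seg_len <= 0.0):
            raise SceneValidationError(
                f"centerline '{self.label}': consecutive points must be distinct"
            )
        self.points = pts

    @property
    def segments(self) -> np.ndarray:
        """``(n-1, 3)`` array of consecutive difference vectors."""
        return np.diff(self.points, axis=0)

    def __eq__(self, other: object) -> bool:  # pragma: no cover - trivial
        if not isinstance(other, Centerline):
            return NotImplemented
        return self.label == other.label and np.array_equal(self.points, other.points)


def arc_length(cl: Centerline) -> float:
    """Total polyline length in mm (sum of Euclidean segment lengths).

    For the aorta centerline this is the 3-D reference length against which
    projected lengths are compared when quantifying foreshortening.
    """
    return float(np.linalg.norm(cl.segments, axis=1).sum())


@dataclass
class VesselScene:
    """A labelled voxel volume plus centerlines in one physical frame.

    Attributes
    ----------
    volume
        3-D integer label grid.
    spacing
        Per-axis voxel size, mm (all components > 0).
    origin
        Physical position (mm) of voxel ``(0, 0, 0)``'s centre.
    labels
        Mapping of semantic names to integer label values; must cover every
        value present in ``volume``.
    centerlines
        One :class:`Centerline` per vessel; ``"aorta"`` is required.
    """

    volume: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray
    labels: dict[str, int] = field(default_factory=lambda: dict(CANONICAL_LABELS))
    centerlines: dict[str, Centerline] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.volume = np.asarray(self.volume)
        if self.volume.ndim != 3:
            raise SceneValidationError(f"volume must be 3-D, got ndim={self.volume.ndim}")
        if self.volume.dtype.kind not in "iu":
            raise SceneFormatError(
                f"volume must be integer-valued, got dtype {self.volume.dtype}"
            )
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        if np.any(self.spacing <= 0):
            raise SceneValidationError(f"spacing must be > 0, got {self.spacing}")
        present = np.unique(self.volume)
        known = set(self.labels.values())
        unknown = sorted(int(v) for v in present if int(v) not in known)
        if unknown:
            raise SceneValidationError(
                f"volume contains label values {unknown} absent from mapping {self.labels}"
            )
        if "aorta" not in self.centerlines:
            raise SceneValidationError("scene requires an 'aorta' centerline")
        lo, hi = self.bounds
        for name, cl in self.centerlines.items():
            pts = cl.points
            if np.any(pts < lo - 1e-9) or np.any(pts > hi + 1e-9):
                raise SceneValidationError(
                    f"centerline '{name}' leaves the volume bounds "
                    f"[{lo}, {hi}] (mm)"
                )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.volume.shape  # type: ignore[return-value]

    @property
    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """Physical bounding box (mm) of the voxel grid, including half-voxel rims."""
        lo = self.origin - 0.5 * self.spacing
        hi = self.origin + (np.array(self.shape) - 0.5) * self.spacing
        return lo, hi

    @property
    def center(self) -> np.ndarray:
        """Physical centre (mm) of the voxel grid."""
        lo, hi = self.bounds
        return 0.5 * (lo + hi)

    def label_value(self, name: str) -> int:
        try:
            return self.labels[name]
        except KeyError:
            raise KeyError(
                f"label '{name}' not in scene; available: {sorted(self.labels)}"
            ) from None


@dataclass
class SceneBundleFiles:
    """Paths making up an on-disk scene bundle."""

    volume_path: Path
    centerline_paths: dict[str, Path]
    meta_path: Path

    @classmethod
    def for_dir(
        cls, directory: str | Path, vessels: tuple[str, ...] = ("aorta", "LCCA", "LSA")
    ) -> "SceneBundleFiles":
        """Conventional file layout inside ``directory``."""
        d = Path(directory)
        return cls(
            volume_path=d / "labels.nii",
            centerline_paths={v: d / f"centerline_{v}.csv" for v in vessels},
            meta_path=d / "meta.json",
        )


def write_centerline(cl: Centerline, path: str | Path) -> None:
    """Write a centerline as CSV (``x_mm,y_mm,z_mm``) or JSON, by extension."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(
            json.dumps({"label": cl.label, "points_mm": cl.points.tolist()})
        )
    else:
        pd.DataFrame(cl.points, columns=["x_mm", "y_mm", "z_mm"]).to_csv(
            path, index=False, float_format="%.9g"
        )


def read_centerline(path: str | Path, label: str) -> Centerline:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"centerline file not found: {path}")
    if path.suffix.lower() == ".json":
        payload = json.loads(path.read_text())
        pts = np.asarray(payload["points_mm"], dtype=float)
        label = payload.get("label", label)
    else:
        frame = pd.read_csv(path)
        missing = {"x_mm", "y_mm", "z_mm"} - set(frame.columns)
        if missing:
            raise SceneFormatError(
                f"{path}: centerline CSV missing columns {sorted(missing)}"
            )
        pts = frame[["x_mm", "y_mm", "z_mm"]].to_numpy(dtype=float)
    return Centerline(points=pts, label=label)


def _check_axis_aligned(affine: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    rot = affine[:3, :3]
    off = rot - np.diag(np.diag(rot))
    if np.max(np.abs(off)) > 1e-6 * max(1.0, np.max(np.abs(rot))):
        raise SceneFormatError(
            "oblique NIfTI affine not supported; the projector assumes an "
            "axis-aligned grid"
        )
    spacing = np.diag(rot).copy()
    if np.any(spacing <= 0):
        raise SceneFormatError(
            f"NIfTI affine has non-positive diagonal {spacing}; flipped axes "
            "are not supported"
        )
    return spacing, affine[:3, 3].copy()


def write_scene(scene: VesselScene, bundle: SceneBundleFiles) -> None:
    """Write a scene bundle such that :func:`read_scene` recovers the scene."""
    bundle.volume_path.parent.mkdir(parents=True, exist_ok=True)
    affine = np.eye(4)
    affine[:3, :3] = np.diag(scene.spacing)
    affine[:3, 3] = scene.origin
    nib.save(nib.Nifti1Image(scene.volume.astype(np.int16), affine), bundle.volume_path)
    for name, cl in scene.centerlines.items():
        if name not in bundle.centerline_paths:
            raise SceneValidationError(f"bundle has no path for centerline '{name}'")
        write_centerline(cl, bundle.centerline_paths[name])
    bundle.meta_path.write_text(json.dumps({"labels": scene.labels}, indent=2))


def read_scene(bundle: SceneBundleFiles) -> VesselScene:
    """Read and validate a scene bundle.

    Raises
    ------
    FileNotFoundError
        A referenced file is missing.
    SceneFormatError
        Volume is not integer-valued or the affine is oblique/flipped.
    SceneValidationError
        Label mapping or centerline invariants are violated.
    """
    if not Path(bundle.volume_path).exists():
        raise FileNotFoundError(f"volume file not found: {bundle.volume_path}")
    if not Path(bundle.meta_path).exists():
        raise FileNotFoundError(f"meta file not found: {bundle.meta_path}")
    img = nib.load(str(bundle.volume_path))
    data = np.asanyarray(img.dataobj)
    if data.dtype.kind not in "iu":
        if not np.allclose(data, np.round(data)):
            raise SceneFormatError(
                f"{bundle.volume_path}: volume is not integer-valued"
            )
        data = np.round(data).astype(np.int16)
    spacing, origin = _check_axis_aligned(np.asarray(img.affine))
    meta = json.loads(Path(bundle.meta_path).read_text())
    labels = {str(k): int(v) for k, v in meta["labels"].items()}
    centerlines = {
        name: read_centerline(path, name)
        for name, path in bundle.centerline_paths.items()
        if Path(path).exists()
    }
    missing = set(bundle.centerline_paths) - set(centerlines)
    if "aorta" in missing:
        raise FileNotFoundError(
            f"aorta centerline file not found: {bundle.centerline_paths['aorta']}"
        )
    return VesselScene(
        volume=data, spacing=spacing, origin=origin, labels=labels,
        centerlines=centerlines,
    )
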