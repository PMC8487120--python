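"""Per-angle view-quality metrics: branch overlap and arch foreshortening.

Two scalar metrics are evaluated at each C-arm sweep angle theta:

*Projection overlapping rate* (POR) of the two supra-aortic branches, by
exact pixel counting on the binary silhouettes::

    P_overlap(theta) = NP(S_LCCA ^ S_LSA) / (NP(S_LCCA) + NP(S_LSA))

where ``NP`` counts set pixels.  The rate lives in [0, 1/2]; it is 0 iff the
silhouettes are disjoint and 1/2 iff they are identical and non-empty.

*Projection foreshortening rate* (PFR) of the aortic centerline: the ratio
of the projected (detector-plane) centerline length at angle theta to the
3-D centerline length.  With the centerline delivered as a polyline, both
lengths are sums over segments; the projected length of a segment ``t`` with
unit ray direction ``P`` is ``||t - (t . P) P||``, so PFR = 1 means the view
is free of foreshortening.  The along-ray reading ``sum |t . P| / sum |t|``
(the literal integrand, which *grows* with foreshortening) is kept available
behind ``numerator="along_ray"`` for auditability.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .projection import (
    ProjectionGeometry,
    ProjectionMask,
    geometry_for_scene,
    project_label,
)
from .vesselmodel import Centerline, VesselScene, arc_length

__all__ = [
    "OverlapResult",
    "ForeshorteningResult",
    "AngleProfile",
    "overlap_rate",
    "foreshortening_rate",
    "sweep",
    "default_theta_grid",
    "random_profile",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class OverlapResult:
    """Branch-silhouette overlap at one angle (exact integer counting)."""

    p_overlap: float
    n_lcca: int
    n_lsa: int
    n_intersection: int
    theta: float


@dataclass(frozen=True)
class ForeshorteningResult:
    """Aortic-centerline foreshortening at one angle."""

    p_fs: float
    projected_length: float
    length_3d: float
    theta: float


@dataclass
class AngleProfile:
    """Per-angle table of the two metrics over a sweep grid."""

    thetas: np.ndarray
    p_overlap: np.ndarray
    p_fs: np.ndarray

    def __post_init__(self) -> None:
        self.thetas = np.asarray(self.thetas, dtype=float)
        self.p_overlap = np.asarray(self.p_overlap, dtype=float)
        self.p_fs = np.asarray(self.p_fs, dtype=float)
        n = len(self.thetas)
        if len(self.p_overlap) != n or len(self.p_fs) != n or n == 0:
            raise ValueError("profile columns must be non-empty and equal-length")
        if np.any(np.diff(self.thetas) <= 0):
            raise ValueError("thetas must be strictly increasing")
        if self.thetas[0] < 0.0 or self.thetas[-1] > 90.0:
            raise ValueError("thetas must lie within [0, 90] degrees")

    def __len__(self) -> int:
        return len(self.thetas)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"theta_deg": self.thetas, "p_overlap": self.p_overlap,
             "p_fs": self.p_fs}
        ).to_csv(path, index=False, float_format="%.12g")

    @classmethod
    def from_csv(cls, path: str | Path) -> "AngleProfile":
        frame = pd.read_csv(path)
        return cls(
            thetas=frame["theta_deg"].to_numpy(),
            p_overlap=frame["p_overlap"].to_numpy(),
            p_fs=frame["p_fs"].to_numpy(),
        )


def default_theta_grid(step: float = 1.0) -> np.ndarray:
    """0-90 degrees inclusive; the 1-degree default matches the granularity
    at which clinical C-arm angles are set."""
    n = int(round(90.0 / step))
    return np.linspace(0.0, 90.0, n + 1)


def overlap_rate(mask_lcca: ProjectionMask, mask_lsa: ProjectionMask) -> OverlapResult:
    """Projection overlapping rate from two same-angle silhouettes.

    If both silhouettes are empty the rate is undefined (0/0); by convention
    it is reported as 0 with a warning, since an empty silhouette cannot
    obscure anything.
    """
    if mask_lcca.mask.shape != mask_lsa.mask.shape:
        raise ValueError(
            f"mask shapes differ: {mask_lcca.mask.shape} vs {mask_lsa.mask.shape}"
        )
    if mask_lcca.theta != mask_lsa.theta:
        raise ValueError(
            f"masks are from different angles: {mask_lcca.theta} vs {mask_lsa.theta}"
        )
    n_a = mask_lcca.pixel_count
    n_b = mask_lsa.pixel_count
    n_inter = int(np.logical_and(mask_lcca.mask, mask_lsa.mask).sum())
    if n_a + n_b == 0:
        log.warning(
            "both branch silhouettes empty at theta=%.1f; overlap set to 0",
            mask_lcca.theta,
        )
        p = 0.0
    else:
        p = n_inter / (n_a + n_b)
    return OverlapResult(
        p_overlap=p, n_lcca=n_a, n_lsa=n_b, n_intersection=n_inter,
        theta=mask_lcca.theta,
    )


def foreshortening_rate(
    cl: Centerline,
    geom: ProjectionGeometry,
    numerator: str = "projected",
) -> ForeshorteningResult:
    """Projection foreshortening rate of a centerline at one angle.

    ``numerator="projected"`` (default) uses the detector-plane length, so a
    value of 1 means no foreshortening; ``"along_ray"`` uses the literal
    along-ray component sum instead.
    """
    seg = cl.segments
    seg_len = np.linalg.norm(seg, axis=1)
    length_3d = float(seg_len.sum())
    if length_3d <= 0.0:
        raise ValueError("centerline has zero length")
    along = seg @ geom.ray_dir
    if numerator == "projected":
        in_plane2 = np.maximum(seg_len**2 - along**2, 0.0)
        projected = float(np.sqrt(in_plane2).sum())
    elif numerator == "along_ray":
        projected = float(np.abs(along).sum())
    else:
        raise ValueError(f"unknown numerator variant '{numerator}'")
    return ForeshorteningResult(
        p_fs=projected / length_3d, projected_length=projected,
        length_3d=length_3d, theta=geom.theta,
    )


def sweep(
    scene: VesselScene,
    theta_grid: np.ndarray | None = None,
    *,
    pixel_size: float | None = None,
    numerator: str = "projected",
) -> AngleProfile:
    """Tabulate overlap and foreshortening over a sweep grid.

    For each angle, the LCCA and LSA labels are silhouette-projected to get
    the overlap rate and the aortic centerline is projected to get the
    foreshortening rate.  Deterministic: re-running yields identical values.
    """
    thetas = default_theta_grid() if theta_grid is None else np.asarray(
        theta_grid, dtype=float
    )
    for branch in ("LCCA", "LSA"):
        if branch not in scene.labels:
            raise ValueError(
                f"scene lacks the '{branch}' label needed for the overlap sweep"
            )
    aorta = scene.centerlines["aorta"]
    p_ov = np.empty(len(thetas))
    p_fs = np.empty(len(thetas))
    for i, theta in enumerate(thetas):
        geom = geometry_for_scene(scene, float(theta), pixel_size=pixel_size)
        m_lcca = project_label(scene, "LCCA", geom)
        m_lsa = project_label(scene, "LSA", geom)
        p_ov[i] = overlap_rate(m_lcca, m_lsa).p_overlap
        p_fs[i] = foreshortening_rate(aorta, geom, numerator=numerator).p_fs
    return AngleProfile(thetas=thetas, p_overlap=p_ov, p_fs=p_fs)


def random_profile(
    rng: np.random.Generator, thetas: np.ndarray | None = None
) -> AngleProfile:
    """Randomised synthetic :class:`AngleProfile` for selector stress tests.

    Draws a smooth unimodal foreshortening curve with its peak anywhere in
    [0, 90] (so every adaptive tier can fire) and an overlap pattern that is,
    with equal probability, zero everywhere, positive everywhere, zero on a
    random window, or zero on a random scattered subset.  Overlap zeros are
    exact, mirroring integer pixel counting.
    """
    thetas = default_theta_grid() if thetas is None else np.asarray(thetas, float)
    peak = rng.uniform(0.0, 90.0)
    width = rng.uniform(15.0, 60.0)
    base = rng.uniform(0.3, 0.7)
    p_fs = base + (1.0 - base) * np.cos(
        np.clip((thetas - peak) / width, -1.0, 1.0) * np.pi / 2.0
    ) ** 2
    p_fs = np.clip(p_fs + rng.normal(0.0, 0.003, size=len(thetas)), 0.01, 1.0)
    kind = rng.integers(0, 4)
    p_ov = rng.uniform(0.01, 0.5, size=len(thetas))
    if kind == 0:
        p_ov[:] = 0.0
    elif kind == 1:
        pass  # positive everywhere
    elif kind == 2:
        lo = rng.uniform(0.0, 90.0)
        hi = lo + rng.uniform(0.0, 90.0 - lo)
        p_ov[(thetas >= lo) & (thetas <= hi)] = 0.0
    else:
        p_ov[rng.random(len(thetas)) < rng.uniform(0.1, 0.9)] = 0.0
    return AngleProfile(thetas=thetas, p_overlap=p_ov, p_fs=p_fs)
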