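"""Parametric aortic-arch phantoms with analytically known geometry.

The phantom emulates the 3-D structure the view planner consumes: a curved
aortic arch carrying two adjacent supra-aortic branch vessels (LCCA and
LSA).  The arch midline is an exact semicircle of radius ``arch_radius``
lying in a plane that contains the patient's superior-inferior axis; the
plane's normal points along the LAO direction ``arch_plane_lao``, so the
sweep angle at which the X-ray is perpendicular to the arch plane — the
angle a foreshortening-free view should recover — is known by construction.
Straight ascending and descending segments extend the arch downwards, and
each branch is a straight cylinder leaving the arch midline.

The two branches are tilted out of the arch plane in *opposite* directions
by ``branch_axis_tilt`` (LCCA towards -normal, LSA towards +normal).  Viewed
perpendicular to the arch plane this out-of-plane divergence is invisible
and the branches appear maximally separated; sweeping below the arch-plane
angle makes the projected axes converge and eventually overlap.  Together
with the in-plane separation set by ``branch_angular_positions`` this gives
full control over which sweep angles show branch overlap, which is exactly
the regime the adaptive selector has to negotiate.

Generation is fully deterministic given a spec; cohorts add seeded uniform
jitter per field.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .vesselmodel import CANONICAL_LABELS, Centerline, SceneValidationError, VesselScene

__all__ = [
    "PhantomSpec",
    "generate_phantom",
    "sample_cohort",
    "DEFAULT_COHORT_JITTER",
]

#: analytic centerline sampling step, mm (below typical voxel spacing).
CENTERLINE_STEP_MM = 1.0

#: Default per-field jitter (additive uniform ranges) for synthetic cohorts.
#: The arch-plane range spans the LAO angles experts choose for TEVAR views
#: (roughly 35-55 deg); the remaining ranges vary the anatomy mildly while
#: keeping every draw inside the default grid.
DEFAULT_COHORT_JITTER: dict[str, tuple[float, float]] = {
    "arch_plane_lao": (-10.0, 10.0),
    "arch_radius": (-3.0, 3.0),
    "ascending_length": (-8.0, 8.0),
    "descending_length": (-8.0, 8.0),
    "branch_length": (-5.0, 5.0),
    "branch_angular_positions": (-3.0, 3.0),
}


@dataclass(frozen=True)
class PhantomSpec:
    """Complete parametric description of a synthetic arch + branches.

    Defaults approximate adult thoracic anatomy at CT-like resolution: a
    ~30 mm arch radius with a 22 mm-diameter lumen, 7 mm-diameter branches,
    and an arch plane at LAO 45 deg (the angle experts typically choose for
    TEVAR deployment views).
    """

    arch_radius: float = 30.0
    tube_radius_aorta: float = 11.0
    tube_radius_branch: float = 3.5
    arch_plane_lao: float = 45.0
    branch_angular_positions: tuple[float, float] = (81.0, 99.0)
    branch_length: float = 45.0
    branch_axis_tilt: float | tuple[float, float] = 65.0
    ascending_length: float = 60.0
    descending_length: float = 70.0
    grid_shape: tuple[int, int, int] = (96, 96, 96)
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)

    def __post_init__(self) -> None:
        if self.arch_radius <= 0 or self.tube_radius_aorta <= 0 \
                or self.tube_radius_branch <= 0:
            raise SceneValidationError("phantom radii must be > 0")
        if self.tube_radius_branch >= self.tube_radius_aorta:
            raise SceneValidationError(
                "branch tubes must be thinner than the aorta tube"
            )
        if self.branch_length <= 0 or self.ascending_length <= 0 \
                or self.descending_length <= 0:
            raise SceneValidationError("phantom lengths must be > 0")
        if not 0.0 <= self.arch_plane_lao <= 90.0:
            raise SceneValidationError("arch_plane_lao must lie in [0, 90] degrees")
        for phi in self.branch_angular_positions:
            if not 0.0 < phi < 180.0:
                raise SceneValidationError(
                    "branch angular positions must lie strictly inside (0, 180) deg"
                )
        if any(s <= 0 for s in self.spacing) or any(n < 8 for n in self.grid_shape):
            raise SceneValidationError("invalid grid_shape or spacing")
        if any(abs(t) > 90.0 for t in self.branch_tilts):
            raise SceneValidationError("branch tilts must lie within [-90, 90] deg")

    @property
    def branch_tilts(self) -> tuple[float, float]:
        """Signed out-of-plane tilts (LCCA, LSA) in degrees toward +normal.

        A scalar ``branch_axis_tilt`` t means opposite tilts (-t, +t): the
        LCCA leans to one side of the arch plane and the LSA to the other,
        which makes their projections converge when sweeping below the
        arch-plane angle.  A pair is taken literally.
        """
        t = self.branch_axis_tilt
        if isinstance(t, (int, float)):
            return (-float(t), float(t))
        return (float(t[0]), float(t[1]))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "PhantomSpec":
        d = json.loads(Path(path).read_text())
        for key in ("branch_angular_positions", "grid_shape", "spacing",
                    "branch_axis_tilt"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)


def _arch_frame(lao_deg: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(normal, in-plane horizontal e1, in-plane vertical e2) of the arch plane."""
    t = math.radians(lao_deg)
    normal = np.array([math.sin(t), math.cos(t), 0.0])
    e1 = np.array([math.cos(t), -math.sin(t), 0.0])
    e2 = np.array([0.0, 0.0, 1.0])
    return normal, e1, e2


def _analytic_centerlines(spec: PhantomSpec) -> dict[str, np.ndarray]:
    """Centerline polylines (mm) in an arch-centred frame (arch centre at 0)."""
    normal, e1, e2 = _arch_frame(spec.arch_plane_lao)
    R = spec.arch_radius
    step = CENTERLINE_STEP_MM

    def seg_points(a: np.ndarray, b: np.ndarray) -> np.ndarray:
        n = max(2, int(math.ceil(np.linalg.norm(b - a) / step)) + 1)
        return a + np.linspace(0.0, 1.0, n)[:, None] * (b - a)

    m0 = R * e1            # arch start (ascending side)
    m_pi = -R * e1         # arch end (descending side)
    asc = seg_points(m0 - spec.ascending_length * e2, m0)
    n_arc = max(2, int(math.ceil(math.pi * R / step)) + 1)
    phi = np.linspace(0.0, math.pi, n_arc)
    arc = R * (np.cos(phi)[:, None] * e1 + np.sin(phi)[:, None] * e2)
    desc = seg_points(m_pi, m_pi - spec.descending_length * e2)
    aorta = np.vstack([asc, arc[1:], desc[1:]])

    out = {"aorta": aorta}
    tilts = spec.branch_tilts
    for name, phi_deg, tilt_deg in (
        ("LCCA", spec.branch_angular_positions[0], tilts[0]),
        ("LSA", spec.branch_angular_positions[1], tilts[1]),
    ):
        p = math.radians(phi_deg)
        tilt = math.radians(tilt_deg)
        radial = math.cos(p) * e1 + math.sin(p) * e2
        direction = math.cos(tilt) * radial + math.sin(tilt) * normal
        origin = R * radial
        out[name] = seg_points(origin, origin + spec.branch_length * direction)
    return out


def _point_segment_dist2(
    pts: np.ndarray, a: np.ndarray, b: np.ndarray
) -> np.ndarray:
    ab = b - a
    denom = float(ab @ ab)
    t = np.clip(((pts - a) @ ab) / denom, 0.0, 1.0)
    diff = pts - (a + t[:, None] * ab)
    return np.einsum("ij,ij->i", diff, diff)


def generate_phantom(spec: PhantomSpec) -> VesselScene:
    """Voxelise a phantom spec into a labelled :class:`VesselScene`.

    Labelling rule: a voxel centre within ``tube_radius_aorta`` of the aorta
    midline (arc + straight limbs) is aorta; otherwise, within
    ``tube_radius_branch`` of a branch axis it takes that branch's label
    (nearest axis wins where both qualify, LCCA on an exact tie).  The
    analytic centerlines, sampled at 1 mm, are attached to the scene.

    Raises :class:`SceneValidationError` if the phantom (padded by its tube
    radii) does not fit inside the voxel grid.
    """
    curves = _analytic_centerlines(spec)
    pad = {
        "aorta": spec.tube_radius_aorta,
        "LCCA": spec.tube_radius_branch,
        "LSA": spec.tube_radius_branch,
    }
    all_lo = np.min([c.min(axis=0) - pad[k] for k, c in curves.items()], axis=0)
    all_hi = np.max([c.max(axis=0) + pad[k] for k, c in curves.items()], axis=0)

    shape = np.array(spec.grid_shape, dtype=int)
    spacing = np.array(spec.spacing, dtype=float)
    extent = shape * spacing
    size = all_hi - all_lo
    if np.any(size > extent):
        raise SceneValidationError(
            f"phantom extent {size} mm exceeds grid extent {extent} mm"
        )
    # centre the phantom in the grid; origin = physical position of voxel 0
    origin = 0.5 * (all_lo + all_hi) - 0.5 * (shape - 1) * spacing

    ax = [origin[i] + spacing[i] * np.arange(shape[i]) for i in range(3)]
    X, Y, Z = np.meshgrid(*ax, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])

    normal, e1, e2 = _arch_frame(spec.arch_plane_lao)
    R = spec.arch_radius
    a = pts @ e1
    b = pts @ e2
    w = pts @ normal
    rho = np.hypot(a, b)
    phi = np.arctan2(b, a)
    d2_arc = np.where(
        (phi >= 0.0) & (phi <= math.pi), (rho - R) ** 2 + w**2, np.inf
    )
    m0 = R * e1
    m_pi = -R * e1
    d2_asc = _point_segment_dist2(pts, m0 - spec.ascending_length * e2, m0)
    d2_desc = _point_segment_dist2(pts, m_pi, m_pi - spec.descending_length * e2)
    d2_aorta = np.minimum(d2_arc, np.minimum(d2_asc, d2_desc))

    branch_curves = {k: curves[k] for k in ("LCCA", "LSA")}
    d2_branch = {
        k: _point_segment_dist2(pts, c[0], c[-1]) for k, c in branch_curves.items()
    }

    labels = dict(CANONICAL_LABELS)
    vol = np.zeros(pts.shape[0], dtype=np.int16)
    r_b2 = spec.tube_radius_branch**2
    in_lcca = d2_branch["LCCA"] <= r_b2
    in_lsa = d2_branch["LSA"] <= r_b2
    vol[in_lsa] = labels["LSA"]
    vol[in_lcca & (~in_lsa | (d2_branch["LCCA"] <= d2_branch["LSA"]))] = labels["LCCA"]
    vol[d2_aorta <= spec.tube_radius_aorta**2] = labels["aorta"]  # aorta wins
    volume = vol.reshape(tuple(shape))

    centerlines = {
        name: Centerline(points=c, label=name) for name, c in curves.items()
    }
    return VesselScene(
        volume=volume, spacing=spacing, origin=origin, labels=labels,
        centerlines=centerlines,
    )


_JITTERABLE = {
    "arch_radius", "tube_radius_aorta", "tube_radius_branch", "arch_plane_lao",
    "branch_angular_positions", "branch_length", "branch_axis_tilt",
    "ascending_length", "descending_length",
}


def _fits(spec: PhantomSpec) -> bool:
    curves = _analytic_centerlines(spec)
    pad = {"aorta": spec.tube_radius_aorta,
           "LCCA": spec.tube_radius_branch, "LSA": spec.tube_radius_branch}
    lo = np.min([c.min(axis=0) - pad[k] for k, c in curves.items()], axis=0)
    hi = np.max([c.max(axis=0) + pad[k] for k, c in curves.items()], axis=0)
    return bool(np.all(hi - lo <= np.array(spec.grid_shape) * np.array(spec.spacing)))


def sample_cohort(
    base: PhantomSpec,
    n: int,
    seed: int,
    jitter: dict[str, tuple[float, float]] | None = None,
) -> list[PhantomSpec]:
    """Draw ``n`` specs around ``base`` with independent uniform jitter.

    ``jitter`` maps field names to additive ``(low, high)`` ranges; the key
    ``"branch_angular_positions"`` jitters each of the two positions
    independently.  Draws producing an invalid or non-fitting spec are
    rejected and redrawn (at most 100 retries each).  Reproducible given
    ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    jitter = dict(jitter or {})
    unknown = set(jitter) - _JITTERABLE
    if unknown:
        raise ValueError(f"cannot jitter fields {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    cohort: list[PhantomSpec] = []
    for _ in range(n):
        for attempt in range(100):
            changes: dict[str, object] = {}
            for name, (lo, hi) in jitter.items():
                if name == "branch_angular_positions":
                    p0, p1 = base.branch_angular_positions
                    changes[name] = (p0 + rng.uniform(lo, hi),
                                     p1 + rng.uniform(lo, hi))
                else:
                    changes[name] = getattr(base, name) + rng.uniform(lo, hi)
            try:
                cand = dataclasses.replace(base, **changes)
            except SceneValidationError:
                continue
            if _fits(cand):
                cohort.append(cand)
                break
        else:
            raise SceneValidationError(
                "could not draw a valid phantom spec within 100 retries; "
                "jitter ranges are too wide for the grid"
            )
    return cohort
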