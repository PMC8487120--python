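"""Optimal-view selection from an angle profile.

Two selectors are provided.

The *standard* selector jointly minimises overlap and foreshortening over
the sweep grid.  Because the foreshortening rate as implemented equals 1 in
a foreshortening-free view, the default objective is::

    theta_standard = argmin_theta  P_overlap(theta) + (1 - P_fs(theta))

(the ``literal`` variant minimises ``P_overlap + P_fs`` as sometimes
printed, which rewards foreshortening under the length-ratio reading and is
kept only for auditing).  Joint minimisation carries no guarantee that the
chosen angle is overlap-free.

The *adaptive* selector enforces overlap freedom as a hard clinical
constraint and then limits foreshortening adaptively:

1. ``theta_no_overlap``: grid angles with exactly zero branch overlap.
2. ``theta_fsmin``: the smallest grid angle attaining the maximal
   foreshortening rate ``p_fsmax``.
3. A candidate set keyed on how steep the best-foreshortening angle is:
   ``theta_fsmin <= 50`` keeps the singleton; ``50 < theta_fsmin <= 60``
   admits every angle with ``p_fs > 0.98 * p_fsmax``; ``theta_fsmin > 60``
   relaxes to ``p_fs > 0.95 * p_fsmax`` (strict inequalities).  Large gantry
   angles are clinically awkward, so a flatter tolerance buys smaller
   workable angles.
4. The optimal angle is the minimum of the intersection of the two sets.

The intersection can be empty (the published procedure assumes it is not);
a fallback ladder keeps the selector total, preferring overlap-free angles
throughout: first widen the tier tolerance (98%, then 95%, then any
overlap-free angle, taking the one with maximal ``p_fs``); only when no
angle is overlap-free at all fall back to the minimum-overlap angle (ties:
larger ``p_fs``, then smaller angle).  Every fallback is logged and recorded
on the result.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .vesselmodel import VesselScene
from .viewmetrics import AngleProfile, sweep

__all__ = [
    "AdaptiveSelection",
    "StandardSelection",
    "standard_select",
    "no_overlap_set",
    "adaptive_fs_set",
    "adaptive_select",
    "select_for_scene",
]

log = logging.getLogger(__name__)

#: Adaptive tier thresholds (fractions of p_fsmax) and angle cut-offs (deg).
TIER_SINGLETON_MAX_DEG = 50.0
TIER_98_MAX_DEG = 60.0
TIER_98 = 0.98
TIER_95 = 0.95


@dataclass
class StandardSelection:
    """Result of the joint-minimisation baseline."""

    theta_standard: float
    objective_value: float
    objective_variant: str


@dataclass
class AdaptiveSelection:
    """Result of the adaptive selector, with its intermediate sets."""

    theta_optimal: float
    theta_no_overlap: set[float]
    theta_fs_set: set[float]
    theta_fsmin: float
    p_fsmax: float
    branch: str
    fallback_used: str = "none"


def standard_select(profile: AngleProfile, variant: str = "corrected") -> StandardSelection:
    """Jointly minimise overlap and foreshortening over the grid.

    Ties are broken by the smallest angle.
    """
    if variant == "corrected":
        objective = profile.p_overlap + (1.0 - profile.p_fs)
    elif variant == "literal":
        objective = profile.p_overlap + profile.p_fs
    else:
        raise ValueError(f"unknown objective variant '{variant}'")
    i = int(np.argmin(objective))  # argmin returns the first (smallest) angle
    return StandardSelection(
        theta_standard=float(profile.thetas[i]),
        objective_value=float(objective[i]),
        objective_variant=variant,
    )


def no_overlap_set(profile: AngleProfile) -> set[float]:
    """Grid angles with exactly zero branch overlap.

    Exact comparison with 0 is meaningful because overlap rates come from
    integer pixel counting.  An empty set is a legal return.
    """
    return {float(t) for t in profile.thetas[profile.p_overlap == 0.0]}


def adaptive_fs_set(
    profile: AngleProfile,
) -> tuple[set[float], float, float, str]:
    """Foreshortening candidate set, tier keyed on ``theta_fsmin``.

    Returns ``(theta_fs_set, theta_fsmin, p_fsmax, branch)`` where branch is
    one of ``"<=50"``, ``"50-60"``, ``">60"``.
    """
    i_min = int(np.argmax(profile.p_fs))  # first max -> smallest angle on ties
    theta_fsmin = float(profile.thetas[i_min])
    p_fsmax = float(profile.p_fs[i_min])
    if theta_fsmin <= TIER_SINGLETON_MAX_DEG:
        return {theta_fsmin}, theta_fsmin, p_fsmax, "<=50"
    if theta_fsmin <= TIER_98_MAX_DEG:
        tier, branch = TIER_98, "50-60"
    else:
        tier, branch = TIER_95, ">60"
    members = profile.thetas[profile.p_fs > tier * p_fsmax]  # strict, as defined
    return {float(t) for t in members}, theta_fsmin, p_fsmax, branch


def _relaxation_ladder(branch: str) -> list[float | None]:
    # tiers still available below the one that already fired; None = any angle
    if branch == "<=50":
        return [TIER_98, TIER_95, None]
    if branch == "50-60":
        return [TIER_95, None]
    return [None]


def adaptive_select(profile: AngleProfile) -> AdaptiveSelection:
    """Adaptive optimal-view selection (total: always returns an angle)."""
    no_ov = no_overlap_set(profile)
    fs_set, theta_fsmin, p_fsmax, branch = adaptive_fs_set(profile)
    intersection = no_ov & fs_set
    if intersection:
        theta_opt = min(intersection)
        fallback = "none"
    elif not no_ov:
        # no overlap-free angle exists anywhere: least-overlap fallback,
        # ties by larger p_fs, then smaller angle
        order = np.lexsort(
            (profile.thetas, -profile.p_fs, profile.p_overlap)
        )
        theta_opt = float(profile.thetas[order[0]])
        fallback = "min-overlap"
        log.info(
            "no overlap-free angle on the grid; min-overlap fallback -> %.1f deg",
            theta_opt,
        )
    else:
        fallback = "tier-relaxation"
        theta_opt = None
        for tier in _relaxation_ladder(branch):
            if tier is None:
                # any overlap-free angle; prefer the best-displayed arch
                cands = sorted(no_ov)
                best = max(cands, key=lambda t: (
                    profile.p_fs[np.nonzero(profile.thetas == t)[0][0]], -t
                ))
                theta_opt = float(best)
                break
            cand = {
                float(t)
                for t in profile.thetas[profile.p_fs > tier * p_fsmax]
            } & no_ov
            if cand:
                theta_opt = min(cand)
                break
        assert theta_opt is not None
        log.info(
            "empty intersection for tier branch %s; relaxed -> %.1f deg",
            branch, theta_opt,
        )
    return AdaptiveSelection(
        theta_optimal=float(theta_opt),
        theta_no_overlap=no_ov,
        theta_fs_set=fs_set,
        theta_fsmin=theta_fsmin,
        p_fsmax=p_fsmax,
        branch=branch,
        fallback_used=fallback,
    )


def select_for_scene(
    scene: VesselScene,
    *,
    theta_grid: np.ndarray | None = None,
    pixel_size: float | None = None,
    objective: str = "corrected",
    numerator: str = "projected",
) -> tuple[AdaptiveSelection, StandardSelection, AngleProfile]:
    """Full per-case pipeline: sweep the grid, then run both selectors."""
    log.info("sweeping scene over the C-arm grid")
    profile = sweep(scene, theta_grid, pixel_size=pixel_size, numerator=numerator)
    log.info("running adaptive and standard selectors")
    adaptive = adaptive_select(profile)
    standard = standard_select(profile, variant=objective)
    log.info(
        "adaptive=%.1f deg (fallback=%s), standard=%.1f deg",
        adaptive.theta_optimal, adaptive.fallback_used, standard.theta_standard,
    )
    return adaptive, standard, profile
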