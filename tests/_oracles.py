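"""Independent brute-force re-implementations used as test oracles.

Deliberately written with plain Python loops and dicts, not shared with the
package code, so they can disagree with it.
"""

from __future__ import annotations


def bruteforce_adaptive(thetas, p_overlap, p_fs):
    """Literal set-logic optimal-view selection over an explicit angle table.

    Returns ``(theta_optimal, fallback, branch)``.
    """
    angles = [float(t) for t in thetas]
    table = {t: (float(po), float(pf))
             for t, po, pf in zip(angles, p_overlap, p_fs)}
    no_overlap = [t for t in angles if table[t][0] == 0.0]
    p_fsmax = max(pf for _, pf in table.values())
    theta_fsmin = min(t for t in angles if table[t][1] == p_fsmax)

    if theta_fsmin <= 50.0:
        fs_set = [theta_fsmin]
        branch, ladder = "<=50", [0.98, 0.95, None]
    elif theta_fsmin <= 60.0:
        fs_set = [t for t in angles if table[t][1] > 0.98 * p_fsmax]
        branch, ladder = "50-60", [0.95, None]
    else:
        fs_set = [t for t in angles if table[t][1] > 0.95 * p_fsmax]
        branch, ladder = ">60", [None]

    both = [t for t in no_overlap if t in fs_set]
    if both:
        return min(both), "none", branch
    if not no_overlap:
        best = min(angles, key=lambda t: (table[t][0], -table[t][1], t))
        return best, "min-overlap", branch
    for tier in ladder:
        if tier is None:
            best = max(no_overlap, key=lambda t: (table[t][1], -t))
            return best, "tier-relaxation", branch
        cand = [t for t in no_overlap if table[t][1] > tier * p_fsmax]
        if cand:
            return min(cand), "tier-relaxation", branch
    raise AssertionError("unreachable")
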