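"""Compiled inner loops for the per-step neighbourhood work.

Pure-python/numpy equivalents live in ``agents`` and are used both as a
fallback (when numba is unavailable) and as the independent reference the
test suite checks these kernels against.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return wrap


@njit(cache=True)
def epithelial_hood_kernel(pos, start, is_aec1, is_h2, reach, eps):
    """Per-alveolus epithelial neighbourhood pass.

    ``pos`` (N, 3) epithelial positions sorted by alveolus, ``start`` the
    per-alveolus offsets (len n_alv + 1).  For AEC1 actors the inverse-square
    weighted centre of mass runs over AEC1 neighbours; for healthy AEC2
    actors over all epithelial neighbours.  Returns the away-from-COM
    displacement per actor (zero when empty or symmetric) and the local AEC1
    tally per agent, both within ``reach``.
    """
    n = pos.shape[0]
    disp = np.zeros((n, 3))
    cnt = np.zeros(n, np.int64)
    r2 = reach * reach
    for a in range(start.size - 1):
        s, e = start[a], start[a + 1]
        for i in range(s, e):
            sense_all = is_h2[i]
            sense_a1 = is_aec1[i]
            wsum = 0.0
            cx = 0.0
            cy = 0.0
            cz = 0.0
            c1 = 0
            for j in range(s, e):
                if j == i:
                    continue
                dx = pos[i, 0] - pos[j, 0]
                dy = pos[i, 1] - pos[j, 1]
                dz = pos[i, 2] - pos[j, 2]
                d2 = dx * dx + dy * dy + dz * dz
                if d2 <= r2:
                    if is_aec1[j]:
                        c1 += 1
                    if sense_all or (sense_a1 and is_aec1[j]):
                        w = r2 / max(d2, 1e-6)
                        wsum += w
                        cx += w * pos[j, 0]
                        cy += w * pos[j, 1]
                        cz += w * pos[j, 2]
            cnt[i] = c1
            if wsum > 0.0 and (sense_all or sense_a1):
                dx = pos[i, 0] - cx / wsum
                dy = pos[i, 1] - cy / wsum
                dz = pos[i, 2] - cz / wsum
                if dx * dx + dy * dy + dz * dz >= eps * eps:
                    disp[i, 0] = dx
                    disp[i, 1] = dy
                    disp[i, 2] = dz
    return disp, cnt


@njit(cache=True)
def separation_push_kernel(pos, radius, start):
    """Accumulated push vectors resolving same-group overlaps.

    ``start`` delimits contiguous (alveolus, shell) groups in ``pos``.  Each
    agent of a violating pair (distance < half the summed radii) receives
    half the missing separation plus a small margin, summed over partners.
    Returns (push (N, 3), any_violation flag).
    """
    n = pos.shape[0]
    push = np.zeros((n, 3))
    hit = False
    for g in range(start.size - 1):
        s, e = start[g], start[g + 1]
        for i in range(s, e):
            for j in range(i + 1, e):
                lim = 0.5 * (radius[i] + radius[j])
                dx = pos[i, 0] - pos[j, 0]
                dy = pos[i, 1] - pos[j, 1]
                dz = pos[i, 2] - pos[j, 2]
                d2 = dx * dx + dy * dy + dz * dz
                if d2 < lim * lim:
                    hit = True
                    d = np.sqrt(d2)
                    if d < 1e-9:
                        dx, dy, dz = 1.0, 0.0, 0.0
                        d = 1.0
                    f = (0.5 * (lim - d) + 0.25) / d
                    push[i, 0] += dx * f
                    push[i, 1] += dy * f
                    push[i, 2] += dz * f
                    push[j, 0] -= dx * f
                    push[j, 1] -= dy * f
                    push[j, 2] -= dz * f
    return push, hit
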