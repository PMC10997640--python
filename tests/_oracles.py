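"""Independent brute-force reference implementations used as test oracles.

Everything here is deliberately naive (explicit loops, exhaustive scans)
and shares no code with the package under test.
"""

from __future__ import annotations

import numpy as np


def neighbor_offsets(connectivity: int):
    offs = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if (dx, dy, dz) == (0, 0, 0):
                    continue
                order = abs(dx) + abs(dy) + abs(dz)
                if connectivity == 6 and order > 1:
                    continue
                if connectivity == 18 and order > 2:
                    continue
                offs.append((dx, dy, dz))
    return offs


def flood_fill_labels(binary: np.ndarray, connectivity: int = 26) -> tuple[np.ndarray, int]:
    """Connected-component labeling by breadth-first flood fill."""
    binary = np.asarray(binary, dtype=bool)
    labels = np.zeros(binary.shape, dtype=int)
    offs = neighbor_offsets(connectivity)
    current = 0
    for start in map(tuple, np.argwhere(binary)):
        if labels[start]:
            continue
        current += 1
        stack = [start]
        labels[start] = current
        while stack:
            p = stack.pop()
            for off in offs:
                q = tuple(p[i] + off[i] for i in range(3))
                if any(c < 0 or c >= binary.shape[i] for i, c in enumerate(q)):
                    continue
                if binary[q] and not labels[q]:
                    labels[q] = current
                    stack.append(q)
    return labels, current


def flood_fill_region(values: np.ndarray, seed, threshold: float, connectivity: int = 26) -> np.ndarray:
    """Connected region containing the seed within {values >= threshold}."""
    above = values >= threshold
    labels, _ = flood_fill_labels(above, connectivity)
    return labels == labels[tuple(seed)]


def brute_max_pairwise(points_mm: np.ndarray) -> float:
    best = 0.0
    pts = np.asarray(points_mm, dtype=float)
    for i in range(len(pts)):
        for j in range(i + 1, len(pts)):
            best = max(best, float(np.linalg.norm(pts[i] - pts[j])))
    return best


def brute_surface_voxels(voxels: np.ndarray) -> np.ndarray:
    """Voxels with at least one 6-neighbor not in the set."""
    vox = {tuple(v) for v in voxels}
    surf = []
    for v in voxels:
        for off in neighbor_offsets(6):
            if tuple(v + np.array(off)) not in vox:
                surf.append(v)
                break
    return np.array(surf)


def brute_voxel_face_area(voxels: np.ndarray, spacing) -> float:
    vox = {tuple(v) for v in voxels}
    sx, sy, sz = spacing
    areas = {0: sy * sz, 1: sx * sz, 2: sx * sy}
    total = 0.0
    for v in voxels:
        for off in neighbor_offsets(6):
            if tuple(v + np.array(off)) not in vox:
                axis = int(np.argmax(np.abs(off)))
                total += areas[axis]
    return total


def brute_erosion_count(voxels: np.ndarray, connectivity: int = 26) -> int:
    """Iterations of binary erosion (given structuring element) to empty the set."""
    vox = {tuple(v) for v in voxels}
    offs = neighbor_offsets(connectivity)
    count = 0
    while vox:
        vox = {v for v in vox if all(tuple(np.add(v, off)) in vox for off in offs)}
        count += 1
    return count


def exhaustive_roc_cutoff(values: np.ndarray, labels: np.ndarray):
    """Scan midpoints between consecutive sorted unique values for max sens*spec.

    Ties in the product go to the lower cut-off. Returns (cutoff, sens, spec).
    """
    values = np.asarray(values, float)
    labels = np.asarray(labels, int)
    uniq = np.unique(values)
    cands = (uniq[:-1] + uniq[1:]) / 2.0 if len(uniq) > 1 else uniq
    best = None
    for c in cands:
        sens = np.mean(values[labels == 1] >= c)
        spec = np.mean(values[labels == 0] < c)
        if best is None or sens * spec > best[0] + 1e-15:
            best = (sens * spec, c, sens, spec)
    return best[1], best[2], best[3]


def mann_whitney_auc(values: np.ndarray, labels: np.ndarray) -> float:
    pos = values[labels == 1]
    neg = values[labels == 0]
    wins = 0.0
    for x in pos:
        for y in neg:
            wins += 1.0 if x > y else (0.5 if x == y else 0.0)
    return wins / (len(pos) * len(neg))


def logrank_statistic(times, events, groups) -> float:
    """Two-group log-rank chi-square: (Σ(O−E))² / ΣV over distinct event times."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    groups = np.asarray(groups)
    g1 = np.unique(groups)[0]
    O_minus_E = 0.0
    V = 0.0
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & (groups == g1)).sum()
        d = ((times == t) & (events == 1)).sum()
        d1 = ((times == t) & (events == 1) & (groups == g1)).sum()
        O_minus_E += d1 - d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return float(O_minus_E**2 / V)


def cox_partial_loglik(beta: float, times, events, x) -> float:
    """Partial log-likelihood for a single covariate, no tied event times."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    x = np.asarray(x, float)
    ll = 0.0
    for i in np.flatnonzero(events == 1):
        risk = times >= times[i]
        ll += beta * x[i] - np.log(np.sum(np.exp(beta * x[risk])))
    return float(ll)


def km_survival_steps(times, events):
    """Product-limit estimate by hand: list of (time, S(t)) after each event time."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    s = 1.0
    out = []
    for t in np.unique(times[events == 1]):
        n = (times >= t).sum()
        d = ((times == t) & (events == 1)).sum()
        s *= 1 - d / n
        out.append((float(t), float(s)))
    return out
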