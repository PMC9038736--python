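"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written for clarity over speed (plain Python loops,
exhaustive enumeration) and deliberately shares no code with the package.
"""

from __future__ import annotations

import itertools

import numpy as np

ALL_26 = [d for d in itertools.product((-1, 0, 1), repeat=3) if d != (0, 0, 0)]
HALF_13 = [d for d in ALL_26 if d > (0, 0, 0)]


def glcm_bruteforce(levels, mask, n_levels):
    """Direction-averaged symmetric co-occurrence probabilities via explicit
    voxel-pair enumeration."""
    levels = np.asarray(levels)
    mask = np.asarray(mask, dtype=bool)
    shape = levels.shape
    acc = np.zeros((n_levels, n_levels))
    used = 0
    for d in HALF_13:
        m = np.zeros((n_levels, n_levels))
        for idx in np.ndindex(shape):
            if not mask[idx]:
                continue
            j = tuple(idx[k] + d[k] for k in range(3))
            if all(0 <= j[k] < shape[k] for k in range(3)) and mask[j]:
                a, b = levels[idx] - 1, levels[j] - 1
                m[a, b] += 1
                m[b, a] += 1
        if m.sum() > 0:
            acc += m / m.sum()
            used += 1
    if used == 0:
        for idx in np.ndindex(shape):
            if mask[idx]:
                g = levels[idx] - 1
                acc[g, g] = 1.0
                return acc
    return acc / used


def zones_bruteforce(levels, mask):
    """(level, size) of every 26-connected constant-level zone via flood fill."""
    levels = np.asarray(levels)
    mask = np.asarray(mask, dtype=bool)
    shape = levels.shape
    seen = np.zeros(shape, dtype=bool)
    zones = []
    for start in np.ndindex(shape):
        if not mask[start] or seen[start]:
            continue
        g = levels[start]
        stack = [start]
        seen[start] = True
        size = 0
        while stack:
            cur = stack.pop()
            size += 1
            for d in ALL_26:
                nb = tuple(cur[k] + d[k] for k in range(3))
                if (
                    all(0 <= nb[k] < shape[k] for k in range(3))
                    and mask[nb]
                    and not seen[nb]
                    and levels[nb] == g
                ):
                    seen[nb] = True
                    stack.append(nb)
        zones.append((int(g), size))
    return sorted(zones)


def ngldm_bruteforce(levels, mask, n_levels):
    """Dependence-count matrix s(level, j), j = 1 + equal-level 26-neighbours."""
    levels = np.asarray(levels)
    mask = np.asarray(mask, dtype=bool)
    shape = levels.shape
    m = np.zeros((n_levels, 27))
    for idx in np.ndindex(shape):
        if not mask[idx]:
            continue
        k = 0
        for d in ALL_26:
            nb = tuple(idx[a] + d[a] for a in range(3))
            if (
                all(0 <= nb[a] < shape[a] for a in range(3))
                and mask[nb]
                and levels[nb] == levels[idx]
            ):
                k += 1
        m[levels[idx] - 1, k] += 1
    return m


def runs_bruteforce(levels, mask):
    """(level, length) of every maximal run along the 13 directions."""
    levels = np.asarray(levels)
    mask = np.asarray(mask, dtype=bool)
    shape = levels.shape
    runs = []
    for d in HALF_13:
        for idx in np.ndindex(shape):
            if not mask[idx]:
                continue
            prev = tuple(idx[k] - d[k] for k in range(3))
            if (
                all(0 <= prev[k] < shape[k] for k in range(3))
                and mask[prev]
                and levels[prev] == levels[idx]
            ):
                continue  # not a run start
            length = 1
            cur = tuple(idx[k] + d[k] for k in range(3))
            while (
                all(0 <= cur[k] < shape[k] for k in range(3))
                and mask[cur]
                and levels[cur] == levels[idx]
            ):
                length += 1
                cur = tuple(cur[k] + d[k] for k in range(3))
            runs.append((int(levels[idx]), length))
    return sorted(runs)


def auc_bruteforce(scores, labels):
    """All-pairs concordance probability with half credit for ties."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for a in pos:
        for b in neg:
            total += 1.0 if a > b else (0.5 if a == b else 0.0)
    return total / (len(pos) * len(neg))


def youden_bruteforce(scores, labels):
    """Best J over an exhaustive fine grid of cutoffs."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    lo, hi = scores.min() - 1.0, scores.max() + 1.0
    best = -np.inf
    for cut in np.linspace(lo, hi, 4001):
        pred = scores >= cut
        sens = (pred & (labels == 1)).sum() / (labels == 1).sum()
        spec = (~pred & (labels == 0)).sum() / (labels == 0).sum()
        best = max(best, sens + spec - 1.0)
    return best


def surface_distances_bruteforce(mask_a, mask_b, spacing):
    """All nearest distances from A's surface voxels to B's surface voxels."""

    def surface(m):
        m = np.asarray(m, dtype=bool)
        out = []
        for idx in np.ndindex(m.shape):
            if not m[idx]:
                continue
            for ax in range(3):
                for step in (-1, 1):
                    nb = list(idx)
                    nb[ax] += step
                    if not (0 <= nb[ax] < m.shape[ax]) or not m[tuple(nb)]:
                        out.append(idx)
                        break
                else:
                    continue
                break
        return np.array(out, dtype=float)

    sa = surface(mask_a) * np.asarray(spacing)
    sb = surface(mask_b) * np.asarray(spacing)
    dists = []
    for p in sa:
        dists.append(np.sqrt(((sb - p) ** 2).sum(axis=1)).min())
    return np.array(dists)
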