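"""Texture-matrix families on discretized volumes: GLCM, GLRLM, GLSZM,
NGLDM and NGTDM.

Conventions (fixed for reproducibility):

* input is an integer level array with 0 outside the mask, 1..n_levels inside;
* 3-D neighbourhoods are 26-connected; co-occurrence/run directions are the
  13 unique offsets at Chebyshev distance 1;
* GLCM: symmetrized per direction, each direction's matrix normalized to a
  probability matrix, then averaged over directions;
* GLRLM: run counts merged (summed) over the 13 directions;
* GLSZM zones are 26-connected components of constant level;
* NGLDM coarseness alpha = 0 (a neighbour is dependent iff its level is equal),
  dependence count j = 1 + number of dependent neighbours.

Ratios with vanishing denominators on degenerate inputs are defined as 0
(coarseness is capped instead, following common practice) so that every
feature is finite.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy import ndimage

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)

# 13 unique direction offsets (first nonzero component positive)
DIRECTIONS = [
    d
    for d in itertools.product((0, 1, -1), repeat=3)
    if d != (0, 0, 0) and d > (0, 0, 0)
]
assert len(DIRECTIONS) == 13


def _check_levels(levels: np.ndarray, mask: np.ndarray) -> int:
    levels = np.asarray(levels)
    if levels[mask].size == 0:
        raise ValueError("empty mask")
    if levels[mask].min() < 1:
        raise ValueError("levels must be >= 1 inside the mask")
    return int(levels[mask].max())


# ---------------------------------------------------------------------------
# GLCM


def glcm_matrix(levels: np.ndarray, mask: np.ndarray, n_levels: int | None = None) -> np.ndarray:
    """Direction-averaged symmetric co-occurrence probability matrix."""
    mask = np.asarray(mask, dtype=bool)
    ng = n_levels or _check_levels(levels, mask)
    acc = np.zeros((ng, ng))
    n_used = 0
    for d in DIRECTIONS:
        sl_a, sl_b = [], []
        for ax, step in enumerate(d):
            n = levels.shape[ax]
            if step == 0:
                sl_a.append(slice(None))
                sl_b.append(slice(None))
            elif step == 1:
                sl_a.append(slice(0, n - 1))
                sl_b.append(slice(1, n))
            else:
                sl_a.append(slice(1, n))
                sl_b.append(slice(0, n - 1))
        a = levels[tuple(sl_a)]
        b = levels[tuple(sl_b)]
        valid = mask[tuple(sl_a)] & mask[tuple(sl_b)]
        if not valid.any():
            continue
        av, bv = a[valid] - 1, b[valid] - 1
        counts = np.bincount(av * ng + bv, minlength=ng * ng).reshape(ng, ng).astype(float)
        counts = counts + counts.T  # symmetrize
        acc += counts / counts.sum()
        n_used += 1
    if n_used == 0:
        # no in-mask voxel pairs exist (e.g. single voxel): degenerate
        # one-cell distribution at the voxel's own level
        g = int(levels[mask][0]) - 1
        acc[g, g] = 1.0
        return acc
    return acc / n_used


def glcm_features(levels: np.ndarray, mask: np.ndarray, n_levels: int | None = None) -> dict[str, float]:
    p = glcm_matrix(levels, mask, n_levels)
    ng = p.shape[0]
    i = np.arange(1, ng + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = float((i * px).sum())
    mu_y = float((i * py).sum())
    sd_x = float(np.sqrt(((i - mu_x) ** 2 * px).sum()))
    sd_y = float(np.sqrt(((i - mu_y) ** 2 * py).sum()))

    # difference |i-j| and sum i+j marginal distributions
    k_diff = np.arange(ng)
    p_diff = np.array([p[np.abs(ii - jj) == k].sum() for k in k_diff])
    k_sum = np.arange(2, 2 * ng + 1)
    p_sum = np.array([p[(ii + jj) == k].sum() for k in k_sum])

    def entropy(q):
        q = q[q > 0]
        return float(-(q * np.log2(q)).sum())

    mu_diff = float((k_diff * p_diff).sum())
    mu_sum = float((k_sum * p_sum).sum())
    joint_avg = float((ii * p).sum())
    joint_var = float(((ii - joint_avg) ** 2 * p).sum())

    hxy = entropy(p.ravel())
    with np.errstate(divide="ignore", invalid="ignore"):
        outer = np.outer(px, py)
    pos = p > 0  # wherever p > 0 both marginals are positive
    hxy1 = float(-(p[pos] * np.log2(outer[pos])).sum()) if pos.any() else 0.0
    pos2 = outer > 0
    hxy2 = float(-(outer[pos2] * np.log2(outer[pos2])).sum())
    hx, hy = entropy(px), entropy(py)

    inv_var_mask = ii != jj
    feats = {
        "joint_maximum": float(p.max()),
        "joint_average": joint_avg,
        "joint_variance": joint_var,
        "joint_entropy": hxy,
        "difference_average": mu_diff,
        "difference_variance": float(((k_diff - mu_diff) ** 2 * p_diff).sum()),
        "difference_entropy": entropy(p_diff),
        "sum_average": mu_sum,
        "sum_variance": float(((k_sum - mu_sum) ** 2 * p_sum).sum()),
        "sum_entropy": entropy(p_sum),
        "angular_second_moment": float((p**2).sum()),
        "contrast": float(((ii - jj) ** 2 * p).sum()),
        "dissimilarity": float((np.abs(ii - jj) * p).sum()),
        "inverse_difference": float((p / (1.0 + np.abs(ii - jj))).sum()),
        "inverse_difference_normalized": float((p / (1.0 + np.abs(ii - jj) / ng)).sum()),
        "inverse_difference_moment": float((p / (1.0 + (ii - jj) ** 2)).sum()),
        "inverse_difference_moment_normalized": float(
            (p / (1.0 + (ii - jj) ** 2 / ng**2)).sum()
        ),
        "inverse_variance": float((p[inv_var_mask] / (ii - jj)[inv_var_mask] ** 2).sum()),
        "correlation": float(((ii - mu_x) * (jj - mu_y) * p).sum() / (sd_x * sd_y))
        if sd_x > 0 and sd_y > 0
        else 0.0,
        "autocorrelation": float((ii * jj * p).sum()),
        "cluster_tendency": float(((ii + jj - mu_x - mu_y) ** 2 * p).sum()),
        "cluster_shade": float(((ii + jj - mu_x - mu_y) ** 3 * p).sum()),
        "cluster_prominence": float(((ii + jj - mu_x - mu_y) ** 4 * p).sum()),
        "information_correlation_1": float((hxy - hxy1) / max(hx, hy))
        if max(hx, hy) > 0
        else 0.0,
        "information_correlation_2": float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))
        if hxy2 >= hxy
        else 0.0,
    }
    return feats


# ---------------------------------------------------------------------------
# run / zone entry lists and shared size-weighted feature formulas


def _in_bounds(coords: np.ndarray, shape) -> np.ndarray:
    ok = np.ones(len(coords), dtype=bool)
    for ax in range(3):
        ok &= (coords[:, ax] >= 0) & (coords[:, ax] < shape[ax])
    return ok


def run_list(levels: np.ndarray, mask: np.ndarray):
    """All maximal same-level runs over the 13 directions: arrays (level, length)."""
    mask = np.asarray(mask, dtype=bool)
    _check_levels(levels, mask)
    all_levels, all_lengths = [], []
    coords_all = np.argwhere(mask)
    lv_all = levels[mask]
    for d in DIRECTIONS:
        dv = np.asarray(d)
        prev = coords_all - dv
        ok = _in_bounds(prev, levels.shape)
        same_prev = np.zeros(len(coords_all), dtype=bool)
        if ok.any():
            pc = prev[ok]
            same_prev[ok] = mask[pc[:, 0], pc[:, 1], pc[:, 2]] & (
                levels[pc[:, 0], pc[:, 1], pc[:, 2]] == lv_all[ok]
            )
        starts = coords_all[~same_prev]
        slev = lv_all[~same_prev]
        lengths = np.ones(len(starts), dtype=np.int64)
        cur = starts + dv
        alive = np.arange(len(starts))
        while alive.size:
            c = cur[alive]
            ok = _in_bounds(c, levels.shape)
            idx = alive[ok]
            c = c[ok]
            good = mask[c[:, 0], c[:, 1], c[:, 2]] & (
                levels[c[:, 0], c[:, 1], c[:, 2]] == slev[idx]
            )
            idx = idx[good]
            lengths[idx] += 1
            cur[idx] += dv
            alive = idx
        all_levels.append(slev)
        all_lengths.append(lengths)
    return np.concatenate(all_levels), np.concatenate(all_lengths)


def zone_list(levels: np.ndarray, mask: np.ndarray):
    """26-connected constant-level zones: arrays (level, size)."""
    mask = np.asarray(mask, dtype=bool)
    ng = _check_levels(levels, mask)
    zl, zs = [], []
    for g in range(1, ng + 1):
        comp, n = ndimage.label(mask & (levels == g), structure=_STRUCT26)
        if n:
            sizes = np.bincount(comp.ravel())[1:]
            zl.append(np.full(n, g))
            zs.append(sizes)
    return np.concatenate(zl), np.concatenate(zs)


def entries_to_matrix(gs: np.ndarray, sizes: np.ndarray, n_levels: int | None = None) -> np.ndarray:
    """Dense (level, size) count matrix from an entry list (for small inputs)."""
    ng = n_levels or int(gs.max())
    ns = int(sizes.max())
    m = np.zeros((ng, ns))
    np.add.at(m, (gs - 1, sizes - 1), 1.0)
    return m


def _size_weighted_features(gs, sizes, n_total, prefix_small, prefix_large, size_name,
                            extra_denominator=1):
    """Shared GLRLM/GLSZM feature formulas over (level, size) entries.

    ``n_total`` is the voxel count entering the *percentage* denominator and
    ``extra_denominator`` multiplies it (number of directions for runs).
    """
    gs = gs.astype(float)
    sizes = sizes.astype(float)
    n_s = len(gs)
    w = 1.0 / n_s
    mu_g = (gs * w).sum()
    mu_s = (sizes * w).sum()

    # cell probabilities for entropy: group identical (g, size) pairs
    key = gs * (sizes.max() + 1) + sizes
    _, counts = np.unique(key, return_counts=True)
    pcell = counts / n_s

    row = np.bincount(gs.astype(int))[1:].astype(float)  # zones/runs per level
    col_sizes, col_counts = np.unique(sizes.astype(int), return_counts=True)

    return {
        prefix_small: float((w / sizes**2).sum()),
        prefix_large: float((w * sizes**2).sum()),
        "low_gray_level": float((w / gs**2).sum()),
        "high_gray_level": float((w * gs**2).sum()),
        "small_low": float((w / (gs**2 * sizes**2)).sum()),
        "small_high": float((w * gs**2 / sizes**2).sum()),
        "large_low": float((w * sizes**2 / gs**2).sum()),
        "large_high": float((w * gs**2 * sizes**2).sum()),
        "gl_non_uniformity": float((row**2).sum() / n_s),
        "gl_non_uniformity_norm": float((row**2).sum() / n_s**2),
        "size_non_uniformity": float((col_counts.astype(float) ** 2).sum() / n_s),
        "size_non_uniformity_norm": float((col_counts.astype(float) ** 2).sum() / n_s**2),
        "percentage": float(n_s / (n_total * extra_denominator)),
        "gl_variance": float((w * (gs - mu_g) ** 2).sum()),
        f"{size_name}_variance": float((w * (sizes - mu_s) ** 2).sum()),
        "entropy": float(-(pcell * np.log2(pcell)).sum()),
    }


def glrlm_features(levels: np.ndarray, mask: np.ndarray) -> dict[str, float]:
    gs, lengths = run_list(levels, mask)
    f = _size_weighted_features(
        gs, lengths, int(np.asarray(mask, bool).sum()), "short", "long", "run_length",
        extra_denominator=len(DIRECTIONS),
    )
    return {
        "short_runs_emphasis": f["short"],
        "long_runs_emphasis": f["long"],
        "low_gray_level_run_emphasis": f["low_gray_level"],
        "high_gray_level_run_emphasis": f["high_gray_level"],
        "short_run_low_gray_level_emphasis": f["small_low"],
        "short_run_high_gray_level_emphasis": f["small_high"],
        "long_run_low_gray_level_emphasis": f["large_low"],
        "long_run_high_gray_level_emphasis": f["large_high"],
        "gray_level_non_uniformity": f["gl_non_uniformity"],
        "gray_level_non_uniformity_normalized": f["gl_non_uniformity_norm"],
        "run_length_non_uniformity": f["size_non_uniformity"],
        "run_length_non_uniformity_normalized": f["size_non_uniformity_norm"],
        "run_percentage": f["percentage"],
        "gray_level_variance": f["gl_variance"],
        "run_length_variance": f["run_length_variance"],
        "run_entropy": f["entropy"],
    }


def glszm_features(levels: np.ndarray, mask: np.ndarray) -> dict[str, float]:
    gs, sizes = zone_list(levels, mask)
    f = _size_weighted_features(
        gs, sizes, int(np.asarray(mask, bool).sum()), "small", "large", "zone_size"
    )
    return {
        "small_zone_emphasis": f["small"],
        "large_zone_emphasis": f["large"],
        "low_gray_level_zone_emphasis": f["low_gray_level"],
        "high_gray_level_zone_emphasis": f["high_gray_level"],
        "small_zone_low_gray_level_emphasis": f["small_low"],
        "small_zone_high_gray_level_emphasis": f["small_high"],
        "large_zone_low_gray_level_emphasis": f["large_low"],
        "large_zone_high_gray_level_emphasis": f["large_high"],
        "gray_level_non_uniformity": f["gl_non_uniformity"],
        "gray_level_non_uniformity_normalized": f["gl_non_uniformity_norm"],
        "zone_size_non_uniformity": f["size_non_uniformity"],
        "zone_size_non_uniformity_normalized": f["size_non_uniformity_norm"],
        "zone_percentage": f["percentage"],
        "gray_level_variance": f["gl_variance"],
        "zone_size_variance": f["zone_size_variance"],
        "zone_size_entropy": f["entropy"],
    }


# ---------------------------------------------------------------------------
# NGLDM


def dependence_counts(levels: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Per masked voxel: 1 + number of 26-neighbours with an equal level."""
    mask = np.asarray(mask, dtype=bool)
    _check_levels(levels, mask)
    dep = np.zeros(levels.shape, dtype=np.int64)
    for d in itertools.product((-1, 0, 1), repeat=3):
        if d == (0, 0, 0):
            continue
        sl_a, sl_b = [], []
        for ax, step in enumerate(d):
            n = levels.shape[ax]
            if step == 0:
                sl_a.append(slice(None))
                sl_b.append(slice(None))
            elif step == 1:
                sl_a.append(slice(0, n - 1))
                sl_b.append(slice(1, n))
            else:
                sl_a.append(slice(1, n))
                sl_b.append(slice(0, n - 1))
        same = (
            mask[tuple(sl_a)]
            & mask[tuple(sl_b)]
            & (levels[tuple(sl_a)] == levels[tuple(sl_b)])
        )
        dep[tuple(sl_a)] += same
    return dep[mask] + 1


def ngldm_matrix(levels: np.ndarray, mask: np.ndarray, n_levels: int | None = None) -> np.ndarray:
    """Count matrix s(level, dependence count j), j = 1..27."""
    mask = np.asarray(mask, dtype=bool)
    ng = n_levels or _check_levels(levels, mask)
    j = dependence_counts(levels, mask)
    g = levels[mask]
    m = np.zeros((ng, 27))
    np.add.at(m, (g - 1, j - 1), 1.0)
    return m


def ngldm_features(levels: np.ndarray, mask: np.ndarray) -> dict[str, float]:
    m = ngldm_matrix(levels, mask)
    n_v = m.sum()
    p = m / n_v
    ng, nj = m.shape
    g = np.arange(1, ng + 1)
    j = np.arange(1, nj + 1)
    gg, jj = np.meshgrid(g, j, indexing="ij")
    row = m.sum(axis=1)
    col = m.sum(axis=0)
    mu_g = float((gg * p).sum())
    mu_j = float((jj * p).sum())
    pos = p[p > 0]
    return {
        "low_dependence_emphasis": float((p / jj**2).sum()),
        "high_dependence_emphasis": float((p * jj**2).sum()),
        "low_gray_level_count_emphasis": float((p / gg**2).sum()),
        "high_gray_level_count_emphasis": float((p * gg**2).sum()),
        "low_dependence_low_gray_level_emphasis": float((p / (gg**2 * jj**2)).sum()),
        "low_dependence_high_gray_level_emphasis": float((p * gg**2 / jj**2).sum()),
        "high_dependence_low_gray_level_emphasis": float((p * jj**2 / gg**2).sum()),
        "high_dependence_high_gray_level_emphasis": float((p * gg**2 * jj**2).sum()),
        "gray_level_non_uniformity": float((row**2).sum() / n_v),
        "gray_level_non_uniformity_normalized": float((row**2).sum() / n_v**2),
        "dependence_count_non_uniformity": float((col**2).sum() / n_v),
        "dependence_count_non_uniformity_normalized": float((col**2).sum() / n_v**2),
        "dependence_count_percentage": 1.0,  # alpha=0 full neighbourhood
        "gray_level_variance": float((p * (gg - mu_g) ** 2).sum()),
        "dependence_count_variance": float((p * (jj - mu_j) ** 2).sum()),
        "dependence_count_entropy": float(-(pos * np.log2(pos)).sum()),
        "dependence_count_energy": float((pos**2).sum()),
    }


# ---------------------------------------------------------------------------
# NGTDM


def ngtdm_features(levels: np.ndarray, mask: np.ndarray) -> dict[str, float]:
    mask = np.asarray(mask, dtype=bool)
    ng = _check_levels(levels, mask)
    nb_sum = np.zeros(levels.shape, dtype=float)
    nb_cnt = np.zeros(levels.shape, dtype=float)
    for d in itertools.product((-1, 0, 1), repeat=3):
        if d == (0, 0, 0):
            continue
        sl_a, sl_b = [], []
        for ax, step in enumerate(d):
            n = levels.shape[ax]
            if step == 0:
                sl_a.append(slice(None))
                sl_b.append(slice(None))
            elif step == 1:
                sl_a.append(slice(0, n - 1))
                sl_b.append(slice(1, n))
            else:
                sl_a.append(slice(1, n))
                sl_b.append(slice(0, n - 1))
        valid = mask[tuple(sl_b)]
        nb_sum[tuple(sl_a)] += np.where(valid, levels[tuple(sl_b)], 0)
        nb_cnt[tuple(sl_a)] += valid
    use = mask & (nb_cnt > 0)
    n_vc = int(use.sum())
    a = nb_sum[use] / nb_cnt[use]
    g = levels[use].astype(int)
    n_i = np.bincount(g, minlength=ng + 1)[1:].astype(float)
    s_i = np.zeros(ng)
    np.add.at(s_i, g - 1, np.abs(g - a))
    p_i = n_i / n_vc
    present = p_i > 0
    ngp = int(present.sum())
    lv = np.arange(1, ng + 1, dtype=float)

    coarse_den = float((p_i * s_i).sum())
    coarseness = 1.0 / coarse_den if coarse_den > 0 else 1e6

    if ngp > 1:
        pi, pj = np.meshgrid(p_i[present], p_i[present], indexing="ij")
        li, lj = np.meshgrid(lv[present], lv[present], indexing="ij")
        contrast = float(
            (pi * pj * (li - lj) ** 2).sum() / (ngp * (ngp - 1)) * (s_i.sum() / n_vc)
        )
        busy_den = float(np.abs(li * pi - lj * pj).sum())
        busyness = float((p_i * s_i).sum() / busy_den) if busy_den > 0 else 0.0
        si_p, sj_p = np.meshgrid(s_i[present], s_i[present], indexing="ij")
        complexity = float(
            (np.abs(li - lj) * (pi * si_p + pj * sj_p) / (pi + pj)).sum() / n_vc
        )
        s_sum = float(s_i.sum())
        strength = (
            float(((pi + pj) * (li - lj) ** 2).sum() / s_sum) if s_sum > 0 else 0.0
        )
    else:
        contrast = busyness = complexity = strength = 0.0

    return {
        "coarseness": coarseness,
        "contrast": contrast,
        "busyness": busyness,
        "complexity": complexity,
        "strength": strength,
    }
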