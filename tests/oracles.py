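"""Independent brute-force reference implementations used by the tests.

Everything here is written as literal loops or textbook formulas, kept
deliberately separate from the package's vectorized code paths.
"""

from __future__ import annotations

import numpy as np

GLCM_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


def glcm_counts_naive(q: np.ndarray, distance: int, angle: int, levels: int):
    """Symmetric co-occurrence counts by explicit pixel-pair enumeration."""
    dr, dc = GLCM_OFFSETS[angle]
    dr *= distance
    dc *= distance
    h, w = q.shape
    counts = np.zeros((levels, levels))
    for r in range(h):
        for c in range(w):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < h and 0 <= c2 < w:
                counts[q[r, c], q[r2, c2]] += 1
                counts[q[r2, c2], q[r, c]] += 1
    return counts


def glcm_naive(q, distance, angle, levels):
    counts = glcm_counts_naive(q, distance, angle, levels)
    total = counts.sum()
    return counts / total if total else counts


def ngtdm_naive(q: np.ndarray, levels: int):
    """Per-level difference sums and counts with explicit neighbour loops."""
    h, w = q.shape
    s = np.zeros(levels)
    n = np.zeros(levels)
    for r in range(1, h - 1):
        for c in range(1, w - 1):
            acc = 0.0
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    if dr == 0 and dc == 0:
                        continue
                    acc += q[r + dr, c + dc]
            lvl = int(q[r, c])
            s[lvl] += abs(q[r, c] - acc / 8.0)
            n[lvl] += 1
    return s, n


def dbc_counts_naive(patch: np.ndarray, grid_sizes):
    """Differential box counts with per-cell min/max loops."""
    side = patch.shape[0]
    out = []
    for s in grid_sizes:
        h_box = 256.0 * s / side
        total = 0.0
        for r0 in range(0, side, s):
            for c0 in range(0, side, s):
                cell = patch[r0 : r0 + s, c0 : c0 + s]
                total += (
                    np.ceil(cell.max() / h_box) - np.ceil(cell.min() / h_box) + 1
                )
        out.append(total)
    return np.asarray(out)


def mrfd_increment_naive(patch: np.ndarray, k: int) -> float:
    """Mean |I(p) - I(q)| over all ordered pairs at Chebyshev distance k."""
    g = patch.astype(float)
    h, w = g.shape
    total = 0.0
    count = 0
    for r in range(h):
        for c in range(w):
            for dr in range(-k, k + 1):
                for dc in range(-k, k + 1):
                    if max(abs(dr), abs(dc)) != k:
                        continue
                    r2, c2 = r + dr, c + dc
                    if 0 <= r2 < h and 0 <= c2 < w:
                        total += abs(g[r, c] - g[r2, c2])
                        count += 1
    return total / count if count else 0.0


def blanket_area1_naive(patch: np.ndarray) -> float:
    """One blanket step (eps = 1) with explicit cross-neighbourhood loops
    and reflected borders."""
    g = patch.astype(float)
    p = np.pad(g, 1, mode="reflect")
    h, w = g.shape
    u = np.empty_like(g)
    v = np.empty_like(g)
    for r in range(h):
        for c in range(w):
            pr, pc = r + 1, c + 1
            nbr_max = max(p[pr - 1, pc], p[pr + 1, pc], p[pr, pc - 1], p[pr, pc + 1], p[pr, pc])
            nbr_min = min(p[pr - 1, pc], p[pr + 1, pc], p[pr, pc - 1], p[pr, pc + 1], p[pr, pc])
            u[r, c] = max(g[r, c] + 1, nbr_max)
            v[r, c] = min(g[r, c] - 1, nbr_min)
    return (u.sum() - v.sum()) / 2.0


LAWS_VECS = {
    "L5": [1, 4, 6, 4, 1],
    "E5": [-1, -2, 0, 2, 1],
    "S5": [-1, 0, 2, 0, -1],
    "W5": [-1, 2, 0, -2, 1],
    "R5": [1, -4, 6, -4, 1],
}


def laws_energy_naive(patch: np.ndarray, a: str, b: str, mean_window: int = 15):
    """Laws energy via literal sliding-window correlation loops.

    Matches the package semantics: subtract the local mean (reflected
    borders), correlate with outer(a, b) (reflected borders), average
    |response| over the valid interior.
    """
    g = patch.astype(float)
    h, w = g.shape
    half_m = mean_window // 2
    pm = np.pad(g, half_m, mode="symmetric")  # scipy's "reflect"
    flat = np.empty_like(g)
    for r in range(h):
        for c in range(w):
            flat[r, c] = g[r, c] - pm[r : r + mean_window, c : c + mean_window].mean()
    mask = np.outer(LAWS_VECS[a], LAWS_VECS[b]).astype(float)
    pf = np.pad(flat, 2, mode="symmetric")
    acc = 0.0
    n = 0
    for r in range(2, h - 2):
        for c in range(2, w - 2):
            resp = (pf[r : r + 5, c : c + 5] * mask).sum()
            acc += abs(resp)
            n += 1
    return acc / n


def tfcm_features_naive(patch: np.ndarray, delta: float = 2.0):
    """Texture-coding features with per-pixel, per-direction loops."""
    g = patch.astype(float)
    h, w = g.shape
    dirs = [(0, 1), (1, 1), (1, 0), (1, -1)]

    def sgn(d):
        if abs(d) <= delta:
            return 0
        return 1 if d > 0 else -1

    codes = []
    n_zero_dir = 0
    n_ext_dir = 0
    n_dirs = 0
    for r in range(1, h - 1):
        for c in range(1, w - 1):
            code = 0
            for dr, dc in dirs:
                s1 = sgn(g[r - dr, c - dc] - g[r, c])
                s2 = sgn(g[r + dr, c + dc] - g[r, c])
                if s1 == 0 and s2 == 0:
                    cls = 0
                    n_zero_dir += 1
                elif (s1 == 0) != (s2 == 0):
                    cls = 1
                elif s1 * s2 == -1:
                    cls = 2
                else:
                    cls = 3
                    n_ext_dir += 1
                code += cls
                n_dirs += 1
            codes.append(code)
    codes = np.asarray(codes, dtype=float)
    return np.array(
        [
            n_zero_dir / n_dirs,
            float(np.mean(codes == 0)),
            n_ext_dir / n_dirs,
            codes.var(),
        ]
    )


def fos_moments_naive(patch: np.ndarray):
    """Histogram statistics via direct pixel-wise moments."""
    x = patch.astype(float).ravel()
    mean = x.mean()
    std = x.std()
    if std > 1e-12:
        skew = np.mean((x - mean) ** 3) / std**3
        kurt = np.mean((x - mean) ** 4) / std**4
    else:
        skew = kurt = 0.0
    vals, counts = np.unique(patch.astype(int), return_counts=True)
    p = counts / counts.sum()
    energy = float(np.sum(p**2))
    entropy = float(-np.sum(p * np.log2(p)))
    return np.array([mean, std, skew, kurt, energy, entropy])


def auroc_trapezoid(scores, labels):
    """ROC area by trapezoidal integration over score thresholds (handles
    ties via the standard ROC step construction)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    order = np.argsort(-scores, kind="mergesort")
    s = scores[order]
    y = labels[order]
    n1 = y.sum()
    n0 = len(y) - n1
    tps = [0.0]
    fps = [0.0]
    i = 0
    while i < len(s):
        j = i
        while j < len(s) and s[j] == s[i]:
            j += 1
        tps.append(tps[-1] + y[i:j].sum())
        fps.append(fps[-1] + (j - i) - y[i:j].sum())
        i = j
    tps_arr = np.asarray(tps) / n1
    fps_arr = np.asarray(fps) / n0
    return float(np.trapezoid(tps_arr, fps_arr))


def anova_two_way_balanced_naive(values: np.ndarray):
    """Textbook additive two-way ANOVA for a balanced (a x b x n) layout.

    ``values[i, j, k]`` is replicate k of level i of factor A and level j
    of factor B.  Returns (F_A, p_A, F_B, p_B).
    """
    from scipy.stats import f as f_dist

    a, b, n = values.shape
    grand = values.mean()
    mean_a = values.mean(axis=(1, 2))
    mean_b = values.mean(axis=(0, 2))
    ss_a = b * n * np.sum((mean_a - grand) ** 2)
    ss_b = a * n * np.sum((mean_b - grand) ** 2)
    ss_tot = np.sum((values - grand) ** 2)
    ss_res = ss_tot - ss_a - ss_b
    df_a, df_b = a - 1, b - 1
    df_res = a * b * n - 1 - df_a - df_b
    f_a = (ss_a / df_a) / (ss_res / df_res)
    f_b = (ss_b / df_b) / (ss_res / df_res)
    return (
        f_a,
        float(f_dist.sf(f_a, df_a, df_res)),
        f_b,
        float(f_dist.sf(f_b, df_b, df_res)),
    )


def tukey_naive(values: np.ndarray, groups: np.ndarray):
    """Tukey HSD adjusted p-values via the studentized range distribution."""
    from scipy.stats import studentized_range

    uniq = np.unique(groups)
    k = len(uniq)
    ns = np.array([(groups == g).sum() for g in uniq])
    means = np.array([values[groups == g].mean() for g in uniq])
    df = len(values) - k
    msw = sum(((values[groups == g] - values[groups == g].mean()) ** 2).sum() for g in uniq) / df
    out = {}
    for i in range(k):
        for j in range(i + 1, k):
            se = np.sqrt(msw / 2.0 * (1.0 / ns[i] + 1.0 / ns[j]))
            q = abs(means[j] - means[i]) / se
            out[(uniq[i], uniq[j])] = float(studentized_range.sf(q, k, df))
    return out


def kruskal_naive(groups):
    """Tie-corrected Kruskal-Wallis H and chi-square p by the rank formula."""
    from scipy.stats import chi2, rankdata

    flat = np.concatenate(groups)
    n = len(flat)
    ranks = rankdata(flat)
    h = 0.0
    start = 0
    for g in groups:
        rsum = ranks[start : start + len(g)].sum()
        h += rsum**2 / len(g)
        start += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(flat, return_counts=True)
    tie = 1.0 - np.sum(counts**3 - counts) / (n**3 - n)
    h /= tie
    return h, float(chi2.sf(h, len(groups) - 1))


def pearson_naive(x, y):
    """Pearson r by the covariance formula with a two-sided t-test p."""
    from scipy.stats import t as t_dist

    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    r = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
        np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
    )
    t = r * np.sqrt((n - 2) / (1 - r**2))
    return float(r), float(2 * t_dist.sf(abs(t), n - 2))
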