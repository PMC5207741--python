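"""Independent brute-force oracles used to cross-check the optimized code.

Everything here is deliberately naive — explicit loops over voxel pairs,
run scans and flood fills — and shares no code with the package.
"""

from __future__ import annotations

import numpy as np


def glcm_brute(binned: np.ndarray, mask: np.ndarray, offset, n_levels: int) -> np.ndarray:
    """All-pairs enumeration of symmetric co-occurrences for one offset."""
    P = np.zeros((n_levels, n_levels))
    oz, oy, ox = offset
    nz, ny, nx = binned.shape
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                if not mask[z, y, x]:
                    continue
                z2, y2, x2 = z + oz, y + oy, x + ox
                if 0 <= z2 < nz and 0 <= y2 < ny and 0 <= x2 < nx and mask[z2, y2, x2]:
                    i, j = binned[z, y, x] - 1, binned[z2, y2, x2] - 1
                    P[i, j] += 1
                    P[j, i] += 1
    return P


def glcm_stats_brute(P: np.ndarray) -> dict[str, float]:
    """Feature formulas evaluated with explicit double loops."""
    total = P.sum()
    p = P / total
    ng = p.shape[0]
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    homog = sum(
        p[i, j] / (1 + abs(i - j)) for i in range(ng) for j in range(ng)
    )
    mx = sum((i + 1) * px[i] for i in range(ng))
    my = sum((j + 1) * py[j] for j in range(ng))
    vx = sum(((i + 1) - mx) ** 2 * px[i] for i in range(ng))
    vy = sum(((j + 1) - my) ** 2 * py[j] for j in range(ng))
    if vx > 0 and vy > 0:
        corr = (
            sum((i + 1) * (j + 1) * p[i, j] for i in range(ng) for j in range(ng))
            - mx * my
        ) / np.sqrt(vx * vy)
    else:
        corr = float("nan")
    hxy = -sum(
        p[i, j] * np.log2(p[i, j]) for i in range(ng) for j in range(ng) if p[i, j] > 0
    )
    hxy1 = -sum(
        p[i, j] * np.log2(px[i] * py[j])
        for i in range(ng)
        for j in range(ng)
        if p[i, j] > 0 and px[i] * py[j] > 0
    )
    hxy2 = -sum(
        px[i] * py[j] * np.log2(px[i] * py[j])
        for i in range(ng)
        for j in range(ng)
        if px[i] * py[j] > 0
    )
    hx = -sum(px[i] * np.log2(px[i]) for i in range(ng) if px[i] > 0)
    hy = -sum(py[j] * np.log2(py[j]) for j in range(ng) if py[j] > 0)
    denom = max(hx, hy)
    ic1 = (hxy - hxy1) / denom if denom > 0 else float("nan")
    ic2 = np.sqrt(max(0.0, 1 - np.exp(-2 * (hxy2 - hxy))))
    shade = sum(
        ((i + 1) + (j + 1) - mx - my) ** 3 * p[i, j] for i in range(ng) for j in range(ng)
    )
    prom = sum(
        ((i + 1) + (j + 1) - mx - my) ** 4 * p[i, j] for i in range(ng) for j in range(ng)
    )
    return {
        "homogeneity1": homog,
        "correl1": corr,
        "infoCorr1": ic1,
        "infoCorr2": ic2,
        "clusShade": shade,
        "clusProm": prom,
    }


def runs_brute(binned: np.ndarray, mask: np.ndarray, direction) -> list[tuple[int, int]]:
    """Maximal runs (level, length) along one direction, by walking each line."""
    d = np.asarray(direction)
    shape = np.asarray(binned.shape)
    runs = []
    visited = np.zeros(binned.shape, dtype=bool)
    for start in np.argwhere(mask):
        prev = start - d
        if (
            np.all(prev >= 0)
            and np.all(prev < shape)
            and mask[tuple(prev)]
            and binned[tuple(prev)] == binned[tuple(start)]
        ):
            continue  # not a run start
        level = binned[tuple(start)]
        length = 0
        pos = start.copy()
        while (
            np.all(pos >= 0)
            and np.all(pos < shape)
            and mask[tuple(pos)]
            and binned[tuple(pos)] == level
            and not visited[tuple(pos)]
        ):
            visited[tuple(pos)] = True
            length += 1
            pos = pos + d
        runs.append((int(level), length))
    visited[:] = False
    return runs


def lglre_brute(binned: np.ndarray, mask: np.ndarray, directions) -> float:
    vals = []
    for d in directions:
        runs = runs_brute(binned, mask, d)
        vals.append(np.mean([1.0 / (lvl**2) for lvl, _ in runs]))
    return float(np.mean(vals))


def zones_brute(binned: np.ndarray, mask: np.ndarray) -> list[tuple[int, int]]:
    """(level, size) of every 26-connected constant-level zone, by flood fill."""
    visited = np.zeros(binned.shape, dtype=bool)
    shape = np.asarray(binned.shape)
    neighbours = [
        np.array(d)
        for d in np.ndindex(3, 3, 3)
        if d != (1, 1, 1)
    ]
    neighbours = [n - 1 for n in neighbours]
    zones = []
    for seed in np.argwhere(mask):
        if visited[tuple(seed)]:
            continue
        level = binned[tuple(seed)]
        stack = [seed]
        visited[tuple(seed)] = True
        size = 0
        while stack:
            p = stack.pop()
            size += 1
            for d in neighbours:
                q = p + d
                if (
                    np.all(q >= 0)
                    and np.all(q < shape)
                    and mask[tuple(q)]
                    and not visited[tuple(q)]
                    and binned[tuple(q)] == level
                ):
                    visited[tuple(q)] = True
                    stack.append(q)
        zones.append((int(level), size))
    return zones


def glszm_brute(binned: np.ndarray, mask: np.ndarray) -> dict[str, float]:
    zones = zones_brute(binned, mask)
    nz = len(zones)
    lae = sum(s**2 for _, s in zones) / nz
    hilae = sum(g**2 * s**2 for g, s in zones) / nz
    return {"large area emphasis": lae, "high intensity large area emphasis": hilae}


def bh_brute(pvalues: np.ndarray, alpha: float) -> np.ndarray:
    """Step-up rejection set: largest k with p_(k) <= k*alpha/m."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    k_star = 0
    for k in range(1, m + 1):
        if p[order[k - 1]] <= k * alpha / m:
            k_star = k
    reject = np.zeros(m, dtype=bool)
    reject[order[:k_star]] = True
    return reject


def icc_anova_brute(a: np.ndarray, b: np.ndarray) -> float:
    """One-way ANOVA table written out longhand."""
    data = np.column_stack([a, b]).astype(float)
    n, k = data.shape
    grand = data.mean()
    ss_between = sum(k * (row.mean() - grand) ** 2 for row in data)
    ss_within = sum(((row - row.mean()) ** 2).sum() for row in data)
    msb = ss_between / (n - 1)
    msw = ss_within / (n * (k - 1))
    return (msb - msw) / (msb + (k - 1) * msw)


def concordance_brute(x, time, event) -> float:
    """Harrell CI by explicit pair enumeration."""
    x = np.asarray(x, float)
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    num = den = 0.0
    n = len(x)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            if time[i] < time[j] and event[i] == 1:
                den += 1
                if x[i] > x[j]:
                    num += 1
                elif x[i] == x[j]:
                    num += 0.5
    return num / den
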