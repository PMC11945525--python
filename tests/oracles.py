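"""Independent brute-force reference implementations used only by tests.

Everything here is written as directly as possible from the underlying
definitions (explicit loops, no shared code with the package) so it can act
as an oracle for the vectorized implementations.
"""

import numpy as np


# ---- pooling -------------------------------------------------------------

def naive_standard_pool(x: np.ndarray, d: int) -> np.ndarray:
    """Double-loop d×d mean pooling, partial windows dropped."""
    H, W = x.shape
    H0, W0 = H // d, W // d
    out = np.zeros((H0, W0))
    for i0 in range(H0):
        for j0 in range(W0):
            acc = 0.0
            for i in range(d):
                for j in range(d):
                    acc += x[i0 * d + i, j0 * d + j]
            out[i0, j0] = acc / (d * d)
    return out


def naive_strip_h(x: np.ndarray) -> np.ndarray:
    H, W = x.shape
    return np.array([sum(x[i, j] for j in range(W)) / W for i in range(H)])


def naive_strip_v(x: np.ndarray) -> np.ndarray:
    H, W = x.shape
    return np.array([sum(x[i, j] for i in range(H)) / H for j in range(W)])


# ---- adaptive weights ----------------------------------------------------

def naive_pixel_alpha(gt: np.ndarray, window: int = 31) -> np.ndarray:
    """Triple-loop difficulty score: sum over the three neighbourhoods of
    |clipped-window mean − centre|."""
    H, W = gt.shape
    h = window // 2
    alpha = np.zeros((H, W))
    for i in range(H):
        for j in range(W):
            acc = 0.0
            for (wh, ww) in ((window, 1), (1, window), (window, window)):
                hh, hw = wh // 2, ww // 2
                r0, r1 = max(0, i - hh), min(H, i + hh + 1)
                c0, c1 = max(0, j - hw), min(W, j + hw + 1)
                m = gt[r0:r1, c0:c1].mean()
                acc += abs(m - gt[i, j])
            alpha[i, j] = acc
    return alpha


# ---- S-measure -----------------------------------------------------------

def _ssim_region(p, g):
    n = p.size
    if n == 0:
        return 1.0
    x, y = p.mean(), g.mean()
    if n > 1:
        sx, sy = p.var(ddof=1), g.var(ddof=1)
        sxy = float(((p - x) * (g - y)).sum() / (n - 1))
    else:
        sx = sy = sxy = 0.0
    a = 4 * x * y * sxy
    b = (x**2 + y**2) * (sx + sy)
    eps = np.finfo(float).eps
    if a != 0:
        return a / (b + eps)
    return 1.0 if b == 0 else 0.0


def naive_s_measure(p: np.ndarray, gt: np.ndarray) -> float:
    """Loop-structured structure measure, coded separately from the package."""
    gt = gt.astype(bool)
    y = gt.mean()
    if y == 0:
        return 1.0 - p.mean()
    if y == 1:
        return float(p.mean())

    # object term
    def obj(vals):
        if vals.size == 0:
            return 0.0
        m = vals.mean()
        s = vals.std(ddof=1) if vals.size > 1 else 0.0
        return 2 * m / (m * m + 1 + s + np.finfo(float).eps)

    so = gt.mean() * obj(p[gt]) + (1 - gt.mean()) * obj((1 - p)[~gt])

    H, W = gt.shape
    rows, cols = np.nonzero(gt)
    cy = int(round(rows.mean())) + 1
    cx = int(round(cols.mean())) + 1
    quads = [
        (slice(0, cy), slice(0, cx)),
        (slice(0, cy), slice(cx, W)),
        (slice(cy, H), slice(0, cx)),
        (slice(cy, H), slice(cx, W)),
    ]
    sr = 0.0
    for rs, cs in quads:
        sub_g = gt[rs, cs]
        w = sub_g.size / (H * W)
        sr += w * _ssim_region(p[rs, cs], sub_g.astype(float))
    return float(np.clip(0.5 * so + 0.5 * sr, 0, 1))


# ---- weighted F-measure --------------------------------------------------

def naive_weighted_f_measure(p: np.ndarray, gt: np.ndarray) -> float:
    """Loop-based weighted Fβ (β²=1) with explicit distance and kernel sums."""
    gt = gt.astype(bool)
    if not gt.any():
        return 0.0
    H, W = gt.shape
    fg = np.argwhere(gt)
    # explicit nearest-foreground distance and index for every pixel
    dist = np.zeros((H, W))
    near = np.zeros((H, W, 2), dtype=int)
    for i in range(H):
        for j in range(W):
            d2 = (fg[:, 0] - i) ** 2 + (fg[:, 1] - j) ** 2
            k = int(np.argmin(d2))
            dist[i, j] = np.sqrt(d2[k])
            near[i, j] = fg[k]
    err = np.abs(p - gt.astype(float))
    err_t = err.copy()
    for i in range(H):
        for j in range(W):
            if not gt[i, j]:
                err_t[i, j] = err[near[i, j, 0], near[i, j, 1]]
    # 7x7 gaussian, sigma 5, zero-padded correlation
    ax = np.arange(7) - 3
    g1 = np.exp(-(ax**2) / (2 * 25.0))
    K = np.outer(g1, g1)
    K /= K.sum()
    ea = np.zeros((H, W))
    for i in range(H):
        for j in range(W):
            acc = 0.0
            for u in range(-3, 4):
                for v in range(-3, 4):
                    ii, jj = i + u, j + v
                    if 0 <= ii < H and 0 <= jj < W:
                        acc += K[u + 3, v + 3] * err_t[ii, jj]
            ea[i, j] = acc
    min_e = err.copy()
    sel = gt & (ea < err)
    min_e[sel] = ea[sel]
    B = np.ones((H, W))
    B[~gt] = 2 - np.exp(np.log(0.5) / 5.0 * dist[~gt])
    ew = min_e * B
    eps = np.finfo(float).eps
    tpw = gt.sum() - ew[gt].sum()
    fpw = ew[~gt].sum()
    R = 1 - ew[gt].mean()
    P = tpw / (tpw + fpw + eps)
    return float(2 * P * R / (P + R + eps))


# ---- graph paths ---------------------------------------------------------

def brute_force_diameter_path(nodes: list[tuple], edges: set) -> list[tuple]:
    """Longest geodesic (shortest path between the farthest node pair), found
    by running BFS from every node — the central-axis notion of "longest
    segment" in a skeleton."""
    from collections import deque

    adj = {n: [] for n in nodes}
    for a, b in edges:
        adj[a].append(b)
        adj[b].append(a)

    def bfs(src):
        prev = {src: None}
        q = deque([src])
        order = []
        while q:
            u = q.popleft()
            order.append(u)
            for v in adj[u]:
                if v not in prev:
                    prev[v] = u
                    q.append(v)
        return prev, order[-1]

    best: list[tuple] = []
    for n in nodes:
        prev, far = bfs(n)
        path = []
        cur = far
        while cur is not None:
            path.append(cur)
            cur = prev[cur]
        if len(path) > len(best):
            best = path
    return best
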