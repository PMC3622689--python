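"""Independent brute-force oracles used to validate the implementation.

Everything here is deliberately naive — per-pixel loops, exhaustive scans,
full enumeration — and shares no code path with the package.
"""

import itertools

import numpy as np


def brute_otsu_level(frame: np.ndarray) -> int:
    """Exhaustive scan of all 256 candidate levels for max between-class variance."""
    q = np.clip(np.round(np.asarray(frame) * 255), 0, 255).astype(int).ravel()
    best, best_v = None, -np.inf
    for t in range(256):
        bg, fg = q[q <= t], q[q > t]
        if bg.size == 0 or fg.size == 0:
            continue
        w0, w1 = bg.size / q.size, fg.size / q.size
        v = w0 * w1 * (bg.mean() - fg.mean()) ** 2
        if v > best_v + 1e-12:
            best_v, best = v, t
    return best


def brute_huang_level(frame: np.ndarray) -> int:
    """Exhaustive scan minimizing the entropy index of fuzziness, per pixel."""
    q = np.clip(np.round(np.asarray(frame) * 255), 0, 255).astype(int).ravel()
    C = max(int(q.max() - q.min()), 1)
    best, best_v = None, np.inf
    for t in range(256):
        bg, fg = q[q <= t], q[q > t]
        if bg.size == 0 or fg.size == 0:
            continue
        m = np.where(q <= t, bg.mean(), fg.mean())
        mu = 1.0 / (1.0 + np.abs(q - m) / C)
        with np.errstate(divide="ignore", invalid="ignore"):
            s = -mu * np.log(mu) - (1 - mu) * np.log(1 - mu)
        v = float(np.nan_to_num(s, nan=0.0).sum())
        if v < best_v - 1e-9:
            best_v, best = v, t
    return best


def brute_me(manual: np.ndarray, test: np.ndarray) -> float:
    """Misclassification error by explicit pixel counting."""
    agree = 0
    h, w = manual.shape
    for r in range(h):
        for c in range(w):
            if bool(manual[r, c]) == bool(test[r, c]):
                agree += 1
    return 1.0 - agree / (h * w)


def brute_variance(values) -> float:
    """Population variance by the definition."""
    values = [float(v) for v in values]
    m = sum(values) / len(values)
    return sum((v - m) ** 2 for v in values) / len(values)


def brute_opening(mask: np.ndarray, radius: int) -> np.ndarray:
    """Morphological opening computed pixel-by-pixel from the SE definition."""
    se = [
        (i, j)
        for i in range(-radius, radius + 1)
        for j in range(-radius, radius + 1)
        if i * i + j * j <= radius * radius
    ]
    h, w = mask.shape

    def erode(m):
        out = np.zeros_like(m)
        for r in range(h):
            for c in range(w):
                ok = True
                for di, dj in se:
                    rr, cc = r + di, c + dj
                    if not (0 <= rr < h and 0 <= cc < w) or not m[rr, cc]:
                        ok = False
                        break
                out[r, c] = ok
        return out

    def dilate(m):
        out = np.zeros_like(m)
        for r in range(h):
            for c in range(w):
                hit = False
                for di, dj in se:
                    rr, cc = r + di, c + dj
                    if 0 <= rr < h and 0 <= cc < w and m[rr, cc]:
                        hit = True
                        break
                out[r, c] = hit
        return out

    return dilate(erode(mask.astype(bool)))


def flood_fill_components(mask: np.ndarray) -> list[frozenset]:
    """8-connected components by iterative flood fill."""
    h, w = mask.shape
    seen = np.zeros_like(mask, dtype=bool)
    comps = []
    for r in range(h):
        for c in range(w):
            if mask[r, c] and not seen[r, c]:
                stack, comp = [(r, c)], set()
                seen[r, c] = True
                while stack:
                    y, x = stack.pop()
                    comp.add((y, x))
                    for dy in (-1, 0, 1):
                        for dx in (-1, 0, 1):
                            yy, xx = y + dy, x + dx
                            if 0 <= yy < h and 0 <= xx < w and mask[yy, xx] and not seen[yy, xx]:
                                seen[yy, xx] = True
                                stack.append((yy, xx))
                comps.append(frozenset(comp))
    return comps


def brute_link_cost(prev: np.ndarray, curr: np.ndarray, max_radius: float):
    """Exhaustive enumeration of all partial matchings within the radius.

    Returns (best_cost, best_matching) under the objective: matched pair
    costs squared distance; every unmatched detection costs max_radius**2.
    Pairs farther than max_radius are inadmissible.
    """
    n, m = len(prev), len(curr)
    r2 = max_radius**2
    d2 = ((prev[:, None, :] - curr[None, :, :]) ** 2).sum(axis=2)
    best_cost, best_match = np.inf, []
    idx_m = list(range(m))
    for k in range(0, min(n, m) + 1):
        for rows in itertools.combinations(range(n), k):
            for cols in itertools.permutations(idx_m, k):
                if any(d2[i, j] > r2 for i, j in zip(rows, cols)):
                    continue
                cost = sum(d2[i, j] for i, j in zip(rows, cols)) + r2 * (n - k + m - k)
                if cost < best_cost - 1e-12:
                    best_cost, best_match = cost, sorted(zip(rows, cols))
    return best_cost, best_match


def brute_correlation_shift(ref: np.ndarray, moving: np.ndarray, max_shift: int):
    """Best integer shift by direct evaluation of the correlation sum."""
    a = ref - ref.mean()
    b = moving - moving.mean()
    h, w = a.shape
    best, best_v = (0, 0), -np.inf
    for dr in range(-max_shift, max_shift + 1):
        for dc in range(-max_shift, max_shift + 1):
            v = 0.0
            for r in range(h):
                rr = r - dr
                if not (0 <= rr < h):
                    continue
                for c in range(w):
                    cc = c - dc
                    if 0 <= cc < w:
                        v += a[r, c] * b[rr, cc]
            if v > best_v + 1e-9:
                best_v, best = v, (dr, dc)
    return best
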