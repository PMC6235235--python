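"""Independent brute-force reference implementations.

Each function here re-derives a pipeline stage directly from its set-theoretic
or exhaustive definition, with explicit loops and no shared code with the
package.  They are deliberately slow and only meant for small inputs.
"""

from __future__ import annotations

import numpy as np

CROSS_3D = [(0, 0, 0), (1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
CROSS_2D = [(0, 0), (1, 0), (-1, 0), (0, 1), (0, -1)]


def brute_threshold(data: np.ndarray, t: float) -> np.ndarray:
    out = np.zeros(data.shape, dtype=bool)
    for idx in np.ndindex(data.shape):
        out[idx] = data[idx] > t
    return out


def _inside(idx, shape) -> bool:
    return all(0 <= i < n for i, n in zip(idx, shape))


def brute_dilate(mask: np.ndarray, offsets) -> np.ndarray:
    """D(X) = {p : ∃o, p−o ∈ X}; out-of-image is background."""
    out = np.zeros(mask.shape, dtype=bool)
    for idx in np.ndindex(mask.shape):
        for off in offsets:
            src = tuple(i - o for i, o in zip(idx, off))
            if _inside(src, mask.shape) and mask[src]:
                out[idx] = True
                break
    return out


def brute_erode(mask: np.ndarray, offsets, outside: bool) -> np.ndarray:
    """E(X) = {p : ∀o, p+o ∈ X}, with out-of-image voxels valued ``outside``."""
    out = np.zeros(mask.shape, dtype=bool)
    for idx in np.ndindex(mask.shape):
        ok = True
        for off in offsets:
            nb = tuple(i + o for i, o in zip(idx, off))
            val = mask[nb] if _inside(nb, mask.shape) else outside
            if not val:
                ok = False
                break
        out[idx] = ok
    return out


def brute_clean(mask: np.ndarray, radius: int = 1) -> np.ndarray:
    """Closing (extensive: its erosion treats outside as foreground) followed
    by an erosion that treats outside as background; cross element."""
    offsets = CROSS_3D if mask.ndim == 3 else CROSS_2D
    out = mask.copy()
    if radius == 0:
        return out
    for _ in range(radius):
        out = brute_dilate(out, offsets)
    for _ in range(radius):
        out = brute_erode(out, offsets, outside=True)
    for _ in range(radius):
        out = brute_erode(out, offsets, outside=False)
    return out


def _neighbors(connectivity: int, ndim: int):
    offs = []
    for off in np.ndindex(*(3,) * ndim):
        off = tuple(o - 1 for o in off)
        rank = sum(abs(o) for o in off)
        if rank == 0:
            continue
        if connectivity in (6, 4) and rank > 1:
            continue
        if connectivity == 18 and rank > 2:
            continue
        offs.append(off)
    return offs


def brute_label(mask: np.ndarray, connectivity: int) -> np.ndarray:
    """Flood-fill labeling; components numbered in raster order of first voxel."""
    offs = _neighbors(connectivity, mask.ndim)
    labels = np.zeros(mask.shape, dtype=int)
    next_label = 0
    for idx in np.ndindex(mask.shape):
        if mask[idx] and labels[idx] == 0:
            next_label += 1
            stack = [idx]
            labels[idx] = next_label
            while stack:
                cur = stack.pop()
                for off in offs:
                    nb = tuple(i + o for i, o in zip(cur, off))
                    if _inside(nb, mask.shape) and mask[nb] and labels[nb] == 0:
                        labels[nb] = next_label
                        stack.append(nb)
    return labels


def brute_otsu(values) -> float | None:
    """Exhaustive search over distinct values for the threshold maximizing
    ω0·ω1·(μ0−μ1)²; ties toward the smaller threshold; None if degenerate."""
    values = list(float(v) for v in values)
    uniq = sorted(set(values))
    if len(uniq) < 2:
        return None
    n = len(values)
    best_t, best_bcv = None, -1.0
    for t in uniq[:-1]:
        lo = [v for v in values if v <= t]
        hi = [v for v in values if v > t]
        w0 = len(lo) / n
        w1 = len(hi) / n
        mu0 = sum(lo) / len(lo)
        mu1 = sum(hi) / len(hi)
        bcv = w0 * w1 * (mu0 - mu1) ** 2
        if bcv > best_bcv:
            best_bcv, best_t = bcv, t
    return best_t


def brute_otsu_refine(data: np.ndarray, labels: np.ndarray, rounds: int, connectivity: int) -> np.ndarray:
    lab = labels.copy()
    for _ in range(rounds):
        if lab.max() == 0:
            break
        keep = np.zeros(lab.shape, dtype=bool)
        for l in range(1, int(lab.max()) + 1):
            vals = data[lab == l]
            if vals.size == 0:
                continue
            t = brute_otsu(vals)
            if t is None:
                keep |= lab == l
            else:
                keep |= (lab == l) & (data > t)
        lab = brute_label(keep, connectivity)
    return lab


def brute_crosscorr(p: np.ndarray, q: np.ndarray, max_lag: int, min_frac: float = 0.25, scoring: str = "pearson"):
    """Exhaustive shift scorer; returns (best_lag, score).

    scoring "pearson": Pearson correlation of the overlapping segments,
    computed from first principles; "product": overlap-normalized Σ p·q.
    """
    n_p, n_q = len(p), len(q)
    min_overlap = max(2, int(np.ceil(min_frac * n_q)))

    def var_of(vals):
        m = sum(vals) / len(vals)
        return sum((v - m) ** 2 for v in vals) / len(vals)

    var_floor_p = 1e-3 * var_of(list(p))
    var_floor_q = 1e-3 * var_of(list(q))
    best = None
    for k in range(-max_lag, max_lag + 1):
        sp, sq = [], []
        for i in range(n_p):
            j = i - k
            if 0 <= j < n_q:
                sp.append(p[i])
                sq.append(q[j])
        overlap = len(sp)
        if overlap < min_overlap:
            continue
        if scoring == "pearson":
            mp = sum(sp) / overlap
            mq = sum(sq) / overlap
            vp = sum((a - mp) ** 2 for a in sp) / overlap
            vq = sum((b - mq) ** 2 for b in sq) / overlap
            if vp == 0 or vq == 0 or vp < var_floor_p or vq < var_floor_q:
                continue
            score = sum((a - mp) * (b - mq) for a, b in zip(sp, sq)) / overlap / (vp**0.5 * vq**0.5)
        else:
            score = sum(a * b for a, b in zip(sp, sq)) / overlap
        if best is None or score > best[1] + 1e-12 or (
            abs(score - best[1]) <= 1e-12 and abs(k) < abs(best[0])
        ):
            best = (k, score)
    return best
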