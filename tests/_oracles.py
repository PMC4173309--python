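"""Independent brute-force oracles used to cross-check the fast implementations.

Each routine here re-derives an operation from its definition with naive
per-pixel / per-position loops, deliberately sharing no code with the
package's vectorized paths.
"""

import math

import numpy as np

EPS = 1e-9  # same half-open stamping convention as the renderer


def segment_mask_oracle(p0, p1, shape):
    """Naive per-pixel rasterizer for one 2-px-thick segment.

    Pixel (r, c) is ON iff some parameter t in [0, 1] puts the segment point
    within the stamp window [c-1, c+1) x [r-1, r+1); solved per pixel with
    scalar interval arithmetic.
    """
    h, w = shape
    (u0, v0), (u1, v1) = p0, p1
    mask = np.zeros(shape, dtype=bool)
    for r in range(h):
        for c in range(w):
            t_lo, t_hi = 0.0, 1.0
            ok = True
            for (a0, a1, x) in ((u0, u1, c), (v0, v1, r)):
                lo_b, hi_b = x - 1.0, x + 1.0 - EPS
                d = a1 - a0
                if d == 0.0:
                    if not (lo_b <= a0 <= hi_b):
                        ok = False
                        break
                else:
                    ta = (lo_b - a0) / d
                    tb = (hi_b - a0) / d
                    if ta > tb:
                        ta, tb = tb, ta
                    t_lo = max(t_lo, ta)
                    t_hi = min(t_hi, tb)
            if ok and t_lo <= t_hi:
                mask[r, c] = True
    return mask


def s1_oracle(level, filt):
    """Dense normalized cross-correlation by explicit nested loops:
    response = |sum(filter * patch)| / ||patch||, valid positions."""
    k = filt.shape[0]
    H = level.shape[0] - k + 1
    W = level.shape[1] - k + 1
    out = np.zeros((H, W))
    for i in range(H):
        for j in range(W):
            patch = np.asarray(level[i:i + k, j:j + k], dtype=float)
            nrm = math.sqrt(float((patch ** 2).sum()))
            if nrm < 1e-9:
                out[i, j] = 0.0
            else:
                out[i, j] = abs(float((patch * filt).sum())) / nrm
    return np.clip(out, 0.0, 1.0)


def max_pool_oracle(m, pool, stride):
    """Spatial max pooling by explicit window enumeration."""
    H, W = m.shape[-2], m.shape[-1]
    rows = range(0, H - pool + 1, stride)
    cols = range(0, W - pool + 1, stride)
    out = np.zeros(m.shape[:-2] + (len(rows), len(cols)), dtype=m.dtype)
    for oi, i in enumerate(rows):
        for oj, j in enumerate(cols):
            out[..., oi, oj] = m[..., i:i + pool, j:j + pool].max(axis=(-2, -1))
    return out


def s2_oracle(c1_band, prototype, size):
    """Per-position normalized dot product with one unit-norm prototype."""
    n_orient, H, W = c1_band.shape
    out = np.zeros((H - size + 1, W - size + 1))
    p = np.asarray(prototype, dtype=float)
    for i in range(out.shape[0]):
        for j in range(out.shape[1]):
            patch = np.asarray(c1_band[:, i:i + size, j:j + size], dtype=float).ravel()
            nrm = math.sqrt(float((patch ** 2).sum()))
            out[i, j] = 0.0 if nrm < 1e-9 else float(patch @ p) / nrm
    return np.clip(out, 0.0, 1.0)


def extra_ss_f_oracle(p_obs, p_full, n_params_full=2):
    """Extra-sum-of-squares F statistic computed straight from its textbook
    definition, given observed and full-model-predicted proportions; the
    null model is the fixed flat line at 0.5."""
    p_obs = np.asarray(p_obs, float)
    sse_full = float(((p_obs - np.asarray(p_full, float)) ** 2).sum())
    sse_null = float(((p_obs - 0.5) ** 2).sum())
    df_full = len(p_obs) - n_params_full
    df_extra = n_params_full
    return ((sse_null - sse_full) / df_extra) / (sse_full / df_full), df_extra, df_full
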