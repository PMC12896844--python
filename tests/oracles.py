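"""Independent scalar-loop oracles used to cross-check vectorized operators.

Everything here is written with explicit Python loops over numpy scalars and
deliberately does not import the package's autodiff engine, so agreement
between an oracle and the corresponding vectorized operator is a meaningful
check rather than a tautology.
"""

from __future__ import annotations

import numpy as np


def sigmoid(v):
    return 1.0 / (1.0 + np.exp(-v))


def conv2d_loop(x: np.ndarray, w: np.ndarray, b: np.ndarray | None = None
                ) -> np.ndarray:
    """Direct same-padding convolution; x (C,H,W), w (O,C,kh,kw)."""
    c, h, wd = x.shape
    o, _, kh, kw = w.shape
    ph, pw = kh // 2, kw // 2
    out = np.zeros((o, h, wd))
    for oc in range(o):
        for i in range(h):
            for j in range(wd):
                acc = 0.0
                for ic in range(c):
                    for di in range(kh):
                        for dj in range(kw):
                            ii, jj = i + di - ph, j + dj - pw
                            if 0 <= ii < h and 0 <= jj < wd:
                                acc += x[ic, ii, jj] * w[oc, ic, di, dj]
                out[oc, i, j] = acc + (b[oc] if b is not None else 0.0)
    return out


def bn2d_eval_loop(x, gamma, beta, rm, rv, eps=1e-5):
    """Stored-statistics batch norm on a (C,H,W) map."""
    out = np.empty_like(x)
    for c in range(x.shape[0]):
        out[c] = (x[c] - rm[c]) / np.sqrt(rv[c] + eps) * gamma[c] + beta[c]
    return out


def channel_attention_loop(f: np.ndarray, w0: np.ndarray, w1: np.ndarray
                           ) -> np.ndarray:
    """Per-channel gate on one (C,H,W) map; returns shape (C,)."""
    c = f.shape[0]
    avg = np.array([f[i].mean() for i in range(c)])
    mx = np.array([f[i].max() for i in range(c)])

    def mlp(v):
        hidden = np.maximum(w0 @ v, 0.0)
        return w1 @ hidden

    return sigmoid(mlp(avg) + mlp(mx))


def spatial_attention_loop(f: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Spatial gate on one (C,H,W) map with a (1,2,7,7) kernel; returns (H,W)."""
    c, h, w = f.shape
    pooled = np.stack([f.mean(axis=0), f.max(axis=0)])  # (2,H,W)
    conv = conv2d_loop(pooled, kernel)
    return sigmoid(conv[0])


def cbam_loop(f: np.ndarray, w0, w1, spatial_kernel) -> np.ndarray:
    mc = channel_attention_loop(f, w0, w1)
    fp = f * mc[:, None, None]
    ms = spatial_attention_loop(fp, spatial_kernel)
    return fp * ms[None]


def sk_attention_loop(x: np.ndarray, params: dict) -> tuple:
    """Selective-kernel attention on one (C,H,W) map, eval-mode batch norms.

    ``params`` holds branch conv weights/biases, branch BN stats, the fuse
    FC weight, fuse BN stats, and per-branch select FC weights/biases.
    Returns (V, a_b_weights) with a_b_weights of shape (2, C).
    """
    us = []
    for i in range(2):
        u = conv2d_loop(x, params["branch_w"][i], params["branch_b"][i])
        u = bn2d_eval_loop(u, params["bn_gamma"][i], params["bn_beta"][i],
                           params["bn_rm"][i], params["bn_rv"][i])
        us.append(np.maximum(u, 0.0))
    u_sum = us[0] + us[1]
    c = x.shape[0]
    s = np.array([u_sum[i].mean() for i in range(c)])          # GAP
    z = params["fuse_w"] @ s
    z = (z - params["fuse_rm"]) / np.sqrt(params["fuse_rv"] + 1e-5)
    z = z * params["fuse_gamma"] + params["fuse_beta"]
    z = np.maximum(z, 0.0)
    logits = np.stack([
        params["sel_w"][i] @ z + params["sel_b"][i] for i in range(2)
    ])                                                          # (2, C)
    e = np.exp(logits - logits.max(axis=0, keepdims=True))
    ab = e / e.sum(axis=0, keepdims=True)
    v = us[0] * ab[0][:, None, None] + us[1] * ab[1][:, None, None]
    return v, ab


def point_in_polygon(px: float, py: float, poly: list[tuple]) -> bool:
    """Ray-casting point-in-polygon test (strict interior, generic points)."""
    inside = False
    n = len(poly)
    for i in range(n):
        x0, y0 = poly[i]
        x1, y1 = poly[(i + 1) % n]
        if (y0 > py) != (y1 > py):
            xcross = x0 + (py - y0) * (x1 - x0) / (y1 - y0)
            if px < xcross:
                inside = not inside
    return inside


def binary_dilate_loop(mask: np.ndarray, se: np.ndarray) -> np.ndarray:
    """Set-arithmetic dilation with the structuring element centered."""
    h, w = mask.shape
    kh, kw = se.shape
    ch, cw = kh // 2, kw // 2
    out = np.zeros_like(mask, dtype=bool)
    for i in range(h):
        for j in range(w):
            hit = False
            for di in range(kh):
                for dj in range(kw):
                    if not se[di, dj]:
                        continue
                    ii, jj = i + di - ch, j + dj - cw
                    if 0 <= ii < h and 0 <= jj < w and mask[ii, jj]:
                        hit = True
            out[i, j] = hit
    return out


def binary_erode_loop(mask: np.ndarray, se: np.ndarray) -> np.ndarray:
    h, w = mask.shape
    kh, kw = se.shape
    ch, cw = kh // 2, kw // 2
    out = np.zeros_like(mask, dtype=bool)
    for i in range(h):
        for j in range(w):
            ok = True
            for di in range(kh):
                for dj in range(kw):
                    if not se[di, dj]:
                        continue
                    ii, jj = i + di - ch, j + dj - cw
                    if not (0 <= ii < h and 0 <= jj < w and mask[ii, jj]):
                        ok = False
            out[i, j] = ok
    return out


def closing_loop(mask, se):
    return binary_erode_loop(binary_dilate_loop(mask, se), se)


def opening_loop(mask, se):
    return binary_dilate_loop(binary_erode_loop(mask, se), se)


def confusion_loop(pred: np.ndarray, gt: np.ndarray, k: int):
    """Per-pixel loop confusion counts; returns (tp, fp, fn, tn) arrays."""
    tp = np.zeros(k, dtype=int)
    fp = np.zeros(k, dtype=int)
    fn = np.zeros(k, dtype=int)
    tn = np.zeros(k, dtype=int)
    for c in range(k):
        for p, g in zip(pred.ravel(), gt.ravel()):
            if p == c and g == c:
                tp[c] += 1
            elif p == c:
                fp[c] += 1
            elif g == c:
                fn[c] += 1
            else:
                tn[c] += 1
    return tp, fp, fn, tn


def composite_loss_loop(logits: np.ndarray, target: np.ndarray,
                        weights=(0.5, 0.5)) -> float:
    """Scalar per-pixel cross-entropy + soft Dice loss; logits (N,K,H,W)."""
    n, k, h, w = logits.shape
    ce = 0.0
    probs = np.zeros_like(logits)
    for b in range(n):
        for i in range(h):
            for j in range(w):
                z = logits[b, :, i, j]
                e = np.exp(z - z.max())
                p = e / e.sum()
                probs[b, :, i, j] = p
                ce -= np.log(p[target[b, i, j]])
    ce /= n * h * w
    eps = 1e-6
    dice_sum = 0.0
    for c in range(k):
        inter = 0.0
        psum = 0.0
        tsum = 0.0
        for b in range(n):
            for i in range(h):
                for j in range(w):
                    t = 1.0 if target[b, i, j] == c else 0.0
                    inter += probs[b, c, i, j] * t
                    psum += probs[b, c, i, j]
                    tsum += t
        dice_sum += (2 * inter + eps) / (psum + tsum + eps)
    dice_loss = 1.0 - dice_sum / k
    return weights[0] * ce + weights[1] * dice_loss
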