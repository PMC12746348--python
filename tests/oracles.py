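"""Independent reference implementations used to validate the network.

Everything here is deliberately naive — explicit Python loops over
pixels, channels and kernel taps — and shares no code with the package's
vectorised/autodiff path.
"""

import numpy as np


def naive_conv2d(x, w, b=None, stride=1, dilation=1, padding=0):
    """Per-pixel cross-correlation; x (B,C,H,W), w (O,C,k,k)."""
    bsz, cin, h, wdt = x.shape
    cout, _, k, _ = w.shape
    xp = np.pad(x, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    eff = (k - 1) * dilation + 1
    hout = (h + 2 * padding - eff) // stride + 1
    wout = (wdt + 2 * padding - eff) // stride + 1
    out = np.zeros((bsz, cout, hout, wout), dtype=x.dtype)
    for n in range(bsz):
        for o in range(cout):
            for i in range(hout):
                for j in range(wout):
                    acc = 0.0
                    for c in range(cin):
                        for u in range(k):
                            for v in range(k):
                                acc += (w[o, c, u, v]
                                        * xp[n, c, i * stride + u * dilation,
                                             j * stride + v * dilation])
                    out[n, o, i, j] = acc + (b[o] if b is not None else 0.0)
    return out


def naive_batchnorm_eval(x, gamma, beta, running_mean, running_var, eps=1e-5):
    out = np.empty_like(x)
    for c in range(x.shape[1]):
        out[:, c] = ((x[:, c] - running_mean[c]) / np.sqrt(running_var[c] + eps)
                     * gamma[c] + beta[c])
    return out


def _sigmoid(v):
    return 1.0 / (1.0 + np.exp(-v))


def naive_channel_attention(x, w1, b1, w2, b2):
    """Squeeze-excitation: global pool, FC-ReLU-FC-sigmoid, rescale."""
    bsz, c, h, wdt = x.shape
    out = np.empty_like(x)
    for n in range(bsz):
        z = np.array([x[n, ch].sum() / (h * wdt) for ch in range(c)])
        hid = np.maximum(z @ w1 + b1, 0.0)
        s = _sigmoid(hid @ w2 + b2)
        for ch in range(c):
            out[n, ch] = s[ch] * x[n, ch]
    return out


def naive_coordinate_attention(x, ws, bs, wh, bh, ww, bw):
    """Directional pools, shared reduce, split, per-direction expand."""
    bsz, c, h, wdt = x.shape
    out = np.empty_like(x)
    for n in range(bsz):
        zh = np.array([[x[n, ch, i, :].mean() for ch in range(c)] for i in range(h)])
        zw = np.array([[x[n, ch, :, j].mean() for ch in range(c)] for j in range(wdt)])
        seq = np.vstack([zh, zw])                       # (H+W, C)
        y = np.maximum(seq @ ws + bs, 0.0)              # (H+W, hidden)
        ah = _sigmoid(y[:h] @ wh + bh)                  # (H, C)
        aw = _sigmoid(y[h:] @ ww + bw)                  # (W, C)
        for ch in range(c):
            for i in range(h):
                for j in range(wdt):
                    out[n, ch, i, j] = x[n, ch, i, j] * ah[i, ch] * aw[j, ch]
    return out


def naive_focal_loss(logits, target, gamma):
    """Per-pixel softmax CE with (1-pt)^gamma modulation, then mean."""
    bsz, c, h, w = logits.shape
    total = 0.0
    for n in range(bsz):
        for i in range(h):
            for j in range(w):
                v = logits[n, :, i, j]
                e = np.exp(v - v.max())
                p = e / e.sum()
                ce = -np.log(p[target[n, i, j]])
                pt = np.exp(-ce)
                total += (1.0 - pt) ** gamma * ce
    return total / (bsz * h * w)


def naive_dice_per_class(probs, onehot, eps):
    bsz, c, h, w = probs.shape
    out = np.zeros(c)
    for ch in range(c):
        inter = size = 0.0
        for n in range(bsz):
            for i in range(h):
                for j in range(w):
                    inter += probs[n, ch, i, j] * onehot[n, ch, i, j]
                    size += probs[n, ch, i, j] + onehot[n, ch, i, j]
        out[ch] = (2.0 * inter + eps) / (size + eps)
    return out


def brute_hausdorff(p, q, spacing=None):
    """Exhaustive max-min over all point pairs."""
    p = np.atleast_2d(np.asarray(p, float))
    q = np.atleast_2d(np.asarray(q, float))
    if spacing is not None:
        p = p * np.asarray(spacing, float)
        q = q * np.asarray(spacing, float)
    d = np.sqrt(((p[:, None, :] - q[None, :, :]) ** 2).sum(-1))
    return max(d.min(axis=1).max(), d.min(axis=0).max())


def brute_boundary(mask):
    """Foreground voxels with a face-adjacent neighbour of different value."""
    mask = np.asarray(mask).astype(bool)
    pts = []
    for idx in np.argwhere(mask):
        for axis in range(mask.ndim):
            for step in (-1, 1):
                nb = idx.copy()
                nb[axis] += step
                if (nb < 0).any() or (nb >= np.array(mask.shape)).any():
                    pts.append(idx)
                    break
                if not mask[tuple(nb)]:
                    pts.append(idx)
                    break
            else:
                continue
            break
    return np.array(pts, dtype=float) if pts else np.empty((0, mask.ndim))


def brute_hd95(gt, pred, spacing):
    """95th percentile of pooled bidirectional boundary min-distances."""
    sp = np.asarray(spacing, float)
    p = brute_boundary(gt) * sp
    q = brute_boundary(pred) * sp
    d = np.sqrt(((p[:, None, :] - q[None, :, :]) ** 2).sum(-1))
    pooled = np.concatenate([d.min(axis=1), d.min(axis=0)])
    return np.percentile(pooled, 95)
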