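"""Independent straight-line / brute-force oracles used by the tests.

Each function re-derives an operation directly from its defining formula
(explicit loops, O(N^2) DFT sums, scalar arithmetic) without touching the
package's autograd path, so agreement is a real cross-check.
"""

import numpy as np


def sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def channel_attention_oracle(f, w0, w1):
    """Straight-line channel attention on a single (C,H,W) map:
    pool -> two matrix products -> sum -> sigmoid -> broadcast gate."""
    avg = f.mean(axis=(1, 2))
    mx = f.max(axis=(1, 2))
    z = w1 @ (w0 @ avg) + w1 @ (w0 @ mx)
    mask = sigmoid(z)
    return mask, mask[:, None, None] * f


def spatial_attention_oracle(f, kernel):
    """Brute-force spatial attention on (C,H,W): channel mean/max maps,
    loop convolution with zero padding, sigmoid gate."""
    c, h, w = f.shape
    k = kernel.shape[-1]
    pad = k // 2
    stacked = np.stack([f.mean(axis=0), f.max(axis=0)])
    padded = np.pad(stacked, ((0, 0), (pad, pad), (pad, pad)))
    conv = np.zeros((h, w))
    for i in range(h):
        for j in range(w):
            conv[i, j] = (kernel * padded[:, i:i + k, j:j + k]).sum()
    mask = sigmoid(conv)
    return mask, mask[None] * f


def dft2_oracle(plane):
    """O(N^2) direct-summation 2-D DFT of a real (H,W) plane."""
    h, w = plane.shape
    out = np.zeros((h, w), dtype=complex)
    for u in range(h):
        for v in range(w):
            acc = 0.0j
            for y in range(h):
                for x in range(w):
                    acc += plane[y, x] * np.exp(-2j * np.pi * (u * y / h + v * x / w))
            out[u, v] = acc
    return out


def idft2_oracle(spec):
    """O(N^2) direct-summation inverse 2-D DFT; returns the complex plane."""
    h, w = spec.shape
    out = np.zeros((h, w), dtype=complex)
    for y in range(h):
        for x in range(w):
            acc = 0.0j
            for u in range(h):
                for v in range(w):
                    acc += spec[u, v] * np.exp(2j * np.pi * (u * y / h + v * x / w))
            out[y, x] = acc / (h * w)
    return out


def conv1x1_oracle(x, w):
    """Pointwise convolution on (C,H,W) with weights (Cout, Cin, 1, 1)."""
    return np.einsum("oc,chw->ohw", w[:, :, 0, 0], x)


def conv3x3_oracle(x, w):
    """Loop 3x3 same-padding convolution on (C,H,W), weights (Cout,Cin,3,3)."""
    cin, h, wd = x.shape
    cout = w.shape[0]
    padded = np.pad(x, ((0, 0), (1, 1), (1, 1)))
    out = np.zeros((cout, h, wd))
    for o in range(cout):
        for i in range(h):
            for j in range(wd):
                out[o, i, j] = (w[o] * padded[:, i:i + 3, j:j + 3]).sum()
    return out


def frequency_attention_oracle(x_l, x_g, w_local, w_spectral, w_l2g, w_g2l):
    """Two-path frequency attention on single (C,H,W) halves, with the global
    transform done via the direct-summation DFT (identity activation)."""
    y_l = conv3x3_oracle(x_l, w_local) + conv1x1_oracle(x_g, w_g2l)
    cg = x_g.shape[0]
    spec = np.stack([dft2_oracle(p) for p in x_g])
    stacked = np.concatenate([spec.real, spec.imag], axis=0)
    mixed = conv1x1_oracle(stacked, w_spectral)
    recon = np.stack([
        idft2_oracle(mixed[c] + 1j * mixed[cg + c]).real for c in range(cg)
    ])
    y_g = recon + conv1x1_oracle(x_l, w_l2g)
    return y_l, y_g


def fag_oracle(f_img, f_vol, w_i, w_v, w_gate, b_gate):
    """Straight-line fusion attention gate on single (C,H,W) inputs:
    sigmoid(Conv1x1(ReLU(W_i F_img + W_v F_vol))), convex combination."""
    p_i = conv1x1_oracle(f_img, w_i)
    p_v = conv1x1_oracle(f_vol, w_v)
    z = np.maximum(p_i + p_v, 0.0)
    gate = sigmoid(conv1x1_oracle(z, w_gate) + b_gate)
    fused = gate * p_i + (1.0 - gate) * p_v
    return gate[0], fused


def confusion_tally_oracle(y_true, y_pred, k):
    """Dictionary-counting confusion matrix."""
    counts = {}
    for a, b in zip(y_true, y_pred):
        counts[(a, b)] = counts.get((a, b), 0) + 1
    cm = np.zeros((k, k), dtype=int)
    for (a, b), c in counts.items():
        cm[a, b] = c
    return cm


def weighted_metrics_oracle(cm):
    """Per-class one-vs-rest precision/recall/F1, support-weighted by hand."""
    k = cm.shape[0]
    total = cm.sum()
    acc = sum(cm[i, i] for i in range(k)) / total
    prec_w = rec_w = f1_w = 0.0
    for i in range(k):
        tp = cm[i, i]
        fp = cm[:, i].sum() - tp
        fn = cm[i, :].sum() - tp
        prec = tp / (tp + fp) if tp + fp > 0 else 0.0
        rec = tp / (tp + fn) if tp + fn > 0 else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec > 0 else 0.0
        w = cm[i, :].sum() / total
        prec_w += w * prec
        rec_w += w * rec
        f1_w += w * f1
    return acc, prec_w, rec_w, f1_w
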