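"""Independent brute-force reference implementations used to cross-check
the package.  Everything here is written as plain loops / first-principles
sums, deliberately sharing no code with the implementation under test."""

from __future__ import annotations

import numpy as np


# -- signal processing ------------------------------------------------------

def dft_magnitude_direct(frame: np.ndarray) -> np.ndarray:
    """|X_k| via the literal DFT sum X_k = sum_n x_n e^{-j 2 pi k n / N}."""
    n_pts = len(frame)
    ks = np.arange(n_pts // 2 + 1)
    out = np.empty(len(ks))
    n = np.arange(n_pts)
    for idx, k in enumerate(ks):
        out[idx] = np.abs(np.sum(frame * np.exp(-2j * np.pi * k * n / n_pts)))
    return out


def dct2_direct(column: np.ndarray, n_keep: int) -> np.ndarray:
    """Orthonormal type-II DCT coefficients by the explicit cosine sum."""
    n_bands = len(column)
    out = np.zeros(n_keep)
    for k in range(n_keep):
        s = sum(column[m] * np.cos(np.pi * k * (2 * m + 1) / (2 * n_bands))
                for m in range(n_bands))
        scale = np.sqrt(1.0 / n_bands) if k == 0 else np.sqrt(2.0 / n_bands)
        out[k] = scale * s
    return out


# -- model cells ------------------------------------------------------------

def lstm_cell_scalar(x_t, h_prev, c_prev, W_f, W_i, W_C, W_o,
                     b_f, b_i, b_C, b_o):
    """One LSTM step computed entry-by-entry with scalar arithmetic."""
    def sig(v):
        return 1.0 / (1.0 + np.exp(-v))

    z = list(h_prev) + list(x_t)
    hidden = len(h_prev)
    h_new, c_new = [], []
    for u in range(hidden):
        f = sig(sum(z[r] * W_f[r][u] for r in range(len(z))) + b_f[u])
        i = sig(sum(z[r] * W_i[r][u] for r in range(len(z))) + b_i[u])
        c_hat = np.tanh(sum(z[r] * W_C[r][u] for r in range(len(z))) + b_C[u])
        c = f * c_prev[u] + i * c_hat
        o = sig(sum(z[r] * W_o[r][u] for r in range(len(z))) + b_o[u])
        c_new.append(c)
        h_new.append(o * np.tanh(c))
    return np.array(h_new), np.array(c_new)


def ca_reweight_loops(x, g_h, g_w):
    """y[c,i,j] = x[c,i,j] * g_h[c,i] * g_w[c,j] by explicit loops."""
    C, H, W = x.shape
    y = np.zeros_like(x)
    for c in range(C):
        for i in range(H):
            for j in range(W):
                y[c, i, j] = x[c, i, j] * g_h[c, i] * g_w[c, j]
    return y


# -- metrics ----------------------------------------------------------------

def accuracy_bf(pred, truth):
    return sum(int(p == t) for p, t in zip(pred, truth)) / len(truth)


def prf1_bf(pred, truth, label):
    tp = sum(int(p == label and t == label) for p, t in zip(pred, truth))
    fp = sum(int(p == label and t != label) for p, t in zip(pred, truth))
    fn = sum(int(p != label and t == label) for p, t in zip(pred, truth))
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall else 0.0)
    return precision, recall, f1


def auc_bf(scores, flags, tie_credit=0.5):
    pos = [s for s, f in zip(scores, flags) if f]
    neg = [s for s, f in zip(scores, flags) if not f]
    total = 0.0
    for s0 in neg:
        for s1 in pos:
            if s1 > s0:
                total += 1.0
            elif s1 == s0:
                total += tie_credit
    return total / (len(pos) * len(neg))


def top5_bf(scores, truth):
    hits = 0
    for row, t in zip(scores, truth):
        ranked = sorted(range(len(row)), key=lambda k: (-row[k], k))
        hits += int(t in ranked[:5])
    return hits / len(truth)


def average_precision_bf(scores_k, flags):
    """AP = sum_s P(s) * dR(s) over the descending-score ranking."""
    order = sorted(range(len(scores_k)), key=lambda i: (-scores_k[i], i))
    n_pos = sum(flags)
    tp = 0
    ap = 0.0
    for rank, i in enumerate(order, start=1):
        if flags[i]:
            tp += 1
            ap += (tp / rank) * (1.0 / n_pos)
    return ap


def map_bf(scores, truth):
    n_classes = scores.shape[1]
    aps = []
    for k in range(n_classes):
        flags = [t == k for t in truth]
        if any(flags):
            aps.append(average_precision_bf(scores[:, k].tolist(), flags))
    return float(np.mean(aps))


def random_score_set(rng, n_max=30, k_max=6):
    """A random softmax-like score matrix with every class represented."""
    k = rng.integers(2, k_max + 1)
    n = rng.integers(k + 2, n_max + 1)
    raw = rng.random((n, k))
    scores = raw / raw.sum(axis=1, keepdims=True)
    truth = np.concatenate([np.arange(k), rng.integers(0, k, size=n - k)])
    rng.shuffle(truth)
    return scores, truth
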