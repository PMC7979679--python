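"""1-D convolutional classifier.

Architecture: conv(128, k10) - conv(128, k10) - maxpool(2) -
conv(256, k10) - conv(256, k10) - global average pool - dense 16 -
dense 8 - dense C, softmax output trained with categorical
cross-entropy.  Hidden activations are leaky rectifiers; convolutions are
"valid" (no padding).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .core import Adam, clip_global_norm, glorot_uniform, one_hot, softmax

LOG_CLIP = 1e-12
#: leaky-rectifier slope for hidden layers (keeps small desk-scale
#: batches from dying into all-zero activations)
LEAK = 0.01


def _lrelu(x):
    return np.where(x > 0, x, LEAK * x)


def _lrelu_grad(z):
    return np.where(z > 0, 1.0, LEAK)



def categorical_cross_entropy(targets, probs):
    """CE = -sum_i t_i log f_i, averaged over the batch if 2-D.

    Probabilities are clipped at 1e-12 before the log for numerical
    safety.
    """
    t = np.atleast_2d(np.asarray(targets, dtype=float))
    f = np.atleast_2d(np.asarray(probs, dtype=float))
    if t.shape != f.shape:
        raise ValueError("targets and probabilities must align")
    ce = -np.sum(t * np.log(np.clip(f, LOG_CLIP, 1.0)), axis=1)
    return float(np.mean(ce))


def _conv1d_forward(X, W, b):
    """X: (B, L, Cin), W: (K, Cin, F) -> (B, L-K+1, F)."""
    K = W.shape[0]
    win = sliding_window_view(X, K, axis=1)       # (B, Lout, Cin, K)
    out = np.einsum('blck,kcf->blf', win, W, optimize=True) + b
    return out, win


def _conv1d_backward(dY, win, W, input_len):
    """Gradients of a valid 1-D convolution."""
    K = W.shape[0]
    dW = np.einsum('blck,blf->kcf', win, dY, optimize=True)
    db = dY.sum(axis=(0, 1))
    # full correlation of dY with the kernel flipped along K gives dX
    pad = np.pad(dY, ((0, 0), (K - 1, K - 1), (0, 0)))
    win_d = sliding_window_view(pad, K, axis=1)   # (B, Lin, F, K)
    dX = np.einsum('blfk,kcf->blc', win_d, W[::-1], optimize=True)
    assert dX.shape[1] == input_len
    return dX, dW, db


def _maxpool2(X):
    """Window-2 stride-2 max pooling; odd trailing sample dropped."""
    B, L, C = X.shape
    L2 = L // 2
    x = X[:, :2 * L2].reshape(B, L2, 2, C)
    idx = np.argmax(x, axis=2)
    out = np.max(x, axis=2)
    return out, (idx, X.shape)


def _maxpool2_backward(dY, cache):
    idx, shape = cache
    B, L, C = shape
    L2 = L // 2
    dx = np.zeros((B, L2, 2, C))
    bi, li, ci = np.meshgrid(np.arange(B), np.arange(L2), np.arange(C),
                             indexing='ij')
    dx[bi, li, idx, ci] = dY
    out = np.zeros((B, L, C))
    out[:, :2 * L2] = dx.reshape(B, 2 * L2, C)
    return out


class ConvClassifier:
    """Severity classifier over a single fixed-length pressure cycle.

    Hidden activations are leaky rectifiers (slope 0.01).
    """

    def __init__(self, n_classes: int = 4, input_len: int = 200,
                 kernel: int = 10, filters=(128, 128, 256, 256),
                 dense=(16, 8), seed: int = 0):
        self.n_classes = n_classes
        self.kernel = kernel
        self.filters = tuple(filters)
        self.input_len = input_len
        L = input_len
        for stage, _ in enumerate(filters):
            L = L - (kernel - 1)
            if L < 1:
                raise ValueError(
                    f"input length {input_len} shorter than the receptive "
                    f"field at conv layer {stage + 1}")
            if stage == 1:
                L //= 2
        rng = np.random.default_rng(seed)
        self.Wc, self.bc = [], []
        cin = 1
        for f in filters:
            self.Wc.append(glorot_uniform(rng, (kernel, cin, f),
                                          kernel * cin, f))
            self.bc.append(np.zeros(f))
            cin = f
        dims = [filters[-1], *dense, n_classes]
        self.Wd, self.bd = [], []
        for a, bdim in zip(dims[:-1], dims[1:]):
            self.Wd.append(glorot_uniform(rng, (a, bdim), a, bdim))
            self.bd.append(np.zeros(bdim))

    @property
    def params(self):
        out = []
        for W, b in zip(self.Wc, self.bc):
            out.extend([W, b])
        for W, b in zip(self.Wd, self.bd):
            out.extend([W, b])
        return out

    def param_count(self):
        return sum(p.size for p in self.params)

    def forward(self, X: np.ndarray):
        """X: (B, L) or (B, L, 1) -> logits (B, C) + cache."""
        if X.ndim == 2:
            X = X[:, :, None]
        cache = {"acts": [], "wins": [], "pool": None, "dense_in": []}
        A = X
        for li in range(len(self.Wc)):
            Z, win = _conv1d_forward(A, self.Wc[li], self.bc[li])
            A_new = _lrelu(Z)
            cache["acts"].append((A, Z))
            cache["wins"].append(win)
            A = A_new
            if li == 1:
                A, pc = _maxpool2(A)
                cache["pool"] = pc
        v = A.mean(axis=1)                       # global average pooling
        cache["conv_out_shape"] = A.shape
        cache["gap_out"] = v
        for di in range(len(self.Wd)):
            z = v @ self.Wd[di] + self.bd[di]
            v = _lrelu(z) if di < len(self.Wd) - 1 else z
        return v, cache

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        logits, _ = self.forward(X)
        return softmax(logits, axis=1)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.argmax(self.predict_proba(X), axis=1)

    def loss_and_grads(self, X: np.ndarray, labels: np.ndarray):
        """Softmax + categorical cross-entropy loss and gradients."""
        logits, cache = self.forward(X)
        T = one_hot(labels, self.n_classes)
        P = softmax(logits, axis=1)
        loss = categorical_cross_entropy(T, P)
        B = X.shape[0]
        d = (P - T) / B

        gWd = [None] * len(self.Wd)
        gbd = [None] * len(self.Wd)
        # recompute dense activations for the backward pass
        dense_acts = [cache["gap_out"]]
        v = dense_acts[0]
        zs = []
        for di in range(len(self.Wd)):
            z = v @ self.Wd[di] + self.bd[di]
            zs.append(z)
            v = _lrelu(z) if di < len(self.Wd) - 1 else z
            dense_acts.append(v)
        for di in range(len(self.Wd) - 1, -1, -1):
            gWd[di] = dense_acts[di].T @ d
            gbd[di] = d.sum(axis=0)
            d = d @ self.Wd[di].T
            if di > 0:
                d = d * _lrelu_grad(zs[di - 1])

        # back through global average pooling
        Bsz, Lg, Cg = cache["conv_out_shape"]
        dA = np.repeat(d[:, None, :], Lg, axis=1) / Lg

        gWc = [None] * len(self.Wc)
        gbc = [None] * len(self.Wc)
        for li in range(len(self.Wc) - 1, -1, -1):
            if li == 1:
                dA = _maxpool2_backward(dA, cache["pool"])
            A_in, Z = cache["acts"][li]
            dZ = dA * _lrelu_grad(Z)
            dA, gWc[li], gbc[li] = _conv1d_backward(
                dZ, cache["wins"][li], self.Wc[li], A_in.shape[1])

        grads = []
        for gW, gb in zip(gWc, gbc):
            grads.extend([gW, gb])
        for gW, gb in zip(gWd, gbd):
            grads.extend([gW, gb])
        return loss, grads

    def fit(self, X, labels, epochs: int, batch_size: int = 32,
            lr: float = 1e-3, seed: int = 0, clip_norm: float = 5.0,
            verbose: bool = False):
        n = X.shape[0]
        opt = Adam(self.params, lr=lr)
        rng = np.random.default_rng(seed)
        history = []
        for epoch in range(epochs):
            order = rng.permutation(n)
            total, nb = 0.0, 0
            for start in range(0, n, batch_size):
                idx = order[start:start + batch_size]
                loss, grads = self.loss_and_grads(X[idx], labels[idx])
                if not np.isfinite(loss):
                    raise FloatingPointError(
                        f"NaN/inf classifier loss at epoch {epoch}")
                clip_global_norm(grads, clip_norm)
                opt.step(grads)
                total += loss
                nb += 1
            history.append(total / max(nb, 1))
            if verbose and (epoch + 1) % max(1, epochs // 5) == 0:
                print(f"    epoch {epoch + 1}/{epochs} CE={history[-1]:.3f}")
        return history

    def get_weights(self):
        return [p.copy() for p in self.params]

    def set_weights(self, weights):
        for p, w in zip(self.params, weights):
            p[...] = w
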