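"""Stacked LSTM sequence regressor trained by full backpropagation
through time.

Gate layout in the fused weight matrix is (input, forget, candidate,
output); the forget-gate bias is initialized to 1.  A single dense
output layer maps the top hidden state to the output channels at every
timestep, and the loss is mean squared error.
"""

from __future__ import annotations

import numpy as np

from .core import Adam, clip_global_norm, glorot_uniform, sigmoid


class LSTMLayer:
    def __init__(self, n_in: int, n_hidden: int, rng: np.random.Generator):
        self.n_in = n_in
        self.h = n_hidden
        self.W = glorot_uniform(rng, (n_in + n_hidden, 4 * n_hidden),
                                n_in + n_hidden, 4 * n_hidden)
        self.b = np.zeros(4 * n_hidden)
        self.b[n_hidden:2 * n_hidden] = 1.0   # forget-gate bias

    @property
    def params(self):
        return [self.W, self.b]

    def forward(self, X: np.ndarray):
        """X: (B, T, n_in) -> H: (B, T, h) plus the BPTT cache."""
        B, T, _ = X.shape
        h = self.h
        H = np.zeros((B, T, h))
        gates = np.zeros((B, T, 4 * h))
        C = np.zeros((B, T, h))
        tanhC = np.zeros((B, T, h))
        h_t = np.zeros((B, h))
        c_t = np.zeros((B, h))
        for t in range(T):
            z = np.concatenate([X[:, t, :], h_t], axis=1) @ self.W + self.b
            i = sigmoid(z[:, :h])
            f = sigmoid(z[:, h:2 * h])
            g = np.tanh(z[:, 2 * h:3 * h])
            o = sigmoid(z[:, 3 * h:])
            c_t = f * c_t + i * g
            tc = np.tanh(c_t)
            h_t = o * tc
            H[:, t] = h_t
            C[:, t] = c_t
            tanhC[:, t] = tc
            gates[:, t, :h] = i
            gates[:, t, h:2 * h] = f
            gates[:, t, 2 * h:3 * h] = g
            gates[:, t, 3 * h:] = o
        return H, (X, H, C, tanhC, gates)

    def backward(self, dH: np.ndarray, cache):
        X, H, C, tanhC, gates = cache
        B, T, _ = X.shape
        h = self.h
        dW = np.zeros_like(self.W)
        db = np.zeros_like(self.b)
        dX = np.zeros_like(X)
        dh_next = np.zeros((B, h))
        dc_next = np.zeros((B, h))
        for t in range(T - 1, -1, -1):
            i = gates[:, t, :h]
            f = gates[:, t, h:2 * h]
            g = gates[:, t, 2 * h:3 * h]
            o = gates[:, t, 3 * h:]
            tc = tanhC[:, t]
            c_prev = C[:, t - 1] if t > 0 else np.zeros((B, h))
            h_prev = H[:, t - 1] if t > 0 else np.zeros((B, h))

            dh = dH[:, t] + dh_next
            dc = dc_next + dh * o * (1.0 - tc * tc)
            do = dh * tc
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate([
                di * i * (1.0 - i),
                df * f * (1.0 - f),
                dg * (1.0 - g * g),
                do * o * (1.0 - o),
            ], axis=1)
            inp = np.concatenate([X[:, t, :], h_prev], axis=1)
            dW += inp.T @ dz
            db += dz.sum(axis=0)
            dinp = dz @ self.W.T
            dX[:, t] = dinp[:, :self.n_in]
            dh_next = dinp[:, self.n_in:]
            dc_next = dc * f
        return dX, [dW, db]


class LSTMRegressor:
    """n_in channels -> stacked LSTM layers -> dense -> n_out channels,
    applied at every timestep."""

    def __init__(self, n_in: int = 3, n_out: int = 4, n_hidden: int = 32,
                 n_layers: int = 2, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.layers = []
        fan = n_in
        for _ in range(n_layers):
            self.layers.append(LSTMLayer(fan, n_hidden, rng))
            fan = n_hidden
        self.Wd = glorot_uniform(rng, (n_hidden, n_out), n_hidden, n_out)
        self.bd = np.zeros(n_out)
        self.n_in = n_in
        self.n_out = n_out

    @property
    def params(self):
        out = []
        for layer in self.layers:
            out.extend(layer.params)
        out.extend([self.Wd, self.bd])
        return out

    def param_count(self) -> int:
        return sum(p.size for p in self.params)

    def forward(self, X: np.ndarray):
        if X.ndim != 3 or X.shape[2] != self.n_in:
            raise ValueError(
                f"expected input of shape (B, T, {self.n_in}), got {X.shape}")
        caches = []
        H = X
        for layer in self.layers:
            H, cache = layer.forward(H)
            caches.append(cache)
        Y = H @ self.Wd + self.bd
        return Y, (caches, H)

    def predict(self, X: np.ndarray) -> np.ndarray:
        Y, _ = self.forward(X)
        return Y

    def loss_and_grads(self, X: np.ndarray, Y_true: np.ndarray):
        """Mean-squared-error loss and gradients for one batch."""
        Y_hat, (caches, H) = self.forward(X)
        diff = Y_hat - Y_true
        loss = float(np.mean(diff * diff))
        dY = 2.0 * diff / diff.size
        gWd = np.einsum('bth,btm->hm', H, dY)
        gbd = dY.sum(axis=(0, 1))
        dH = dY @ self.Wd.T
        grads_layers = []
        for layer, cache in zip(reversed(self.layers), reversed(caches)):
            dH, g = layer.backward(dH, cache)
            grads_layers.append(g)
        grads = []
        for g in reversed(grads_layers):
            grads.extend(g)
        grads.extend([gWd, gbd])
        return loss, grads

    def fit(self, X, Y, epochs: int, batch_size: int = 300, lr: float = 2e-3,
            seed: int = 0, X_val=None, Y_val=None, clip_norm: float = 5.0,
            lr_decay=((0.7, 0.3), (0.9, 0.3)), verbose: bool = False):
        """Adam minimization of the MSE; returns the loss history.

        ``lr_decay`` holds (epoch fraction, multiplier) milestones.
        """
        n = X.shape[0]
        opt = Adam(self.params, lr=lr)
        rng = np.random.default_rng(seed)
        decay_at = {int(frac * epochs): mult for frac, mult in (lr_decay or ())}
        history = {"loss": [], "val_loss": []}
        for epoch in range(epochs):
            if epoch in decay_at:
                opt.lr *= decay_at[epoch]
            order = rng.permutation(n)
            epoch_loss = 0.0
            nb = 0
            for start in range(0, n, batch_size):
                idx = order[start:start + batch_size]
                loss, grads = self.loss_and_grads(X[idx], Y[idx])
                if not np.isfinite(loss):
                    raise FloatingPointError(
                        f"NaN/inf training loss at epoch {epoch}")
                clip_global_norm(grads, clip_norm)
                opt.step(grads)
                epoch_loss += loss
                nb += 1
            history["loss"].append(epoch_loss / max(nb, 1))
            if X_val is not None and len(X_val):
                pv = self.predict(X_val)
                history["val_loss"].append(float(np.mean((pv - Y_val) ** 2)))
            if verbose and (epoch + 1) % max(1, epochs // 10) == 0:
                print(f"    epoch {epoch + 1}/{epochs} "
                      f"loss={history['loss'][-1]:.3e}")
        return history

    def get_weights(self):
        return [p.copy() for p in self.params]

    def set_weights(self, weights):
        for p, w in zip(self.params, weights):
            p[...] = w
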