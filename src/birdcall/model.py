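"""Coordinate-attention stacked-LSTM classifier for bird-call features.

Architecture
------------
The fused 148 x 801 feature matrix is treated as a one-channel map
(C=1, H=148 feature rows, W=801 time frames).  Coordinate attention pools
the map along each spatial axis, mixes the concatenated pooled maps with a
shared 1x1 transform (intermediate width ``ca_mid``), normalises, applies
SiLU, splits back into the two directions, restores the channel count with
per-direction 1x1 transforms, and squashes through sigmoids to produce a
per-row gate g^h (length H) and per-column gate g^w (length W).  The map is
re-weighted elementwise: y[c,i,j] = x[c,i,j] * g^h[i] * g^w[j].

The re-weighted map, read column-by-column, is a W-step sequence of
H-dimensional inputs for a 2-layer LSTM (hidden 512 at full scale, dropout
0.3 between layers during training).  The last timestep's top hidden state
feeds two fully connected layers with SiLU between them, and a softmax
yields the species posterior.

Plain-numpy reference functions (:func:`silu`, :func:`ca_pool`,
:func:`ca_reweight`, :func:`lstm_cell`) expose the cell-level math for
direct testing against brute-force oracles; the trainable network mirrors
them with autodiff tensors.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor, concat, no_grad, parameter, softmax


# ---------------------------------------------------------------------------
# reference (plain numpy) cell-level operations
# ---------------------------------------------------------------------------

def sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


def silu(x):
    """SiLU activation: x * sigmoid(x)."""
    x = np.asarray(x, dtype=float)
    return x * sigmoid(x)


def ca_pool(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Directional average pooling of a (C, H, W) map.

    Returns ``(pooled_h, pooled_w)`` with shapes (C, H) and (C, W):
    pooled_h[c, i] is the mean over columns j, pooled_w[c, j] the mean over
    rows i.
    """
    x = np.asarray(x, dtype=float)
    return x.mean(axis=2), x.mean(axis=1)


@dataclasses.dataclass
class CAGates:
    """Attention gate vectors, entries strictly in (0, 1)."""

    g_h: np.ndarray  # (C, H)
    g_w: np.ndarray  # (C, W)


def ca_reweight(x: np.ndarray, gates: CAGates) -> np.ndarray:
    """y[c, i, j] = x[c, i, j] * g_h[c, i] * g_w[c, j]."""
    x = np.asarray(x, dtype=float)
    if gates.g_h.shape != x.shape[:2] or gates.g_w.shape != (x.shape[0], x.shape[2]):
        raise ValueError("gate shapes do not match the feature map")
    return x * gates.g_h[:, :, None] * gates.g_w[:, None, :]


@dataclasses.dataclass
class LSTMState:
    """Hidden and cell vectors of one layer at one timestep."""

    h: np.ndarray
    C: np.ndarray


@dataclasses.dataclass
class LSTMLayerParams:
    """Per-gate weights over the concatenation [h_{t-1}, x_t] plus biases."""

    W_f: np.ndarray
    W_i: np.ndarray
    W_C: np.ndarray
    W_o: np.ndarray
    b_f: np.ndarray
    b_i: np.ndarray
    b_C: np.ndarray
    b_o: np.ndarray


def lstm_cell(x_t: np.ndarray, state: LSTMState,
              p: LSTMLayerParams) -> LSTMState:
    """One LSTM step:

    f = sigma(W_f [h, x] + b_f);  i = sigma(W_i [h, x] + b_i)
    C_hat = tanh(W_C [h, x] + b_C);  C' = f * C + i * C_hat
    o = sigma(W_o [h, x] + b_o);  h' = o * tanh(C')
    """
    z = np.concatenate([state.h, np.asarray(x_t, dtype=float)])
    f = sigmoid(z @ p.W_f + p.b_f)
    i = sigmoid(z @ p.W_i + p.b_i)
    c_hat = np.tanh(z @ p.W_C + p.b_C)
    c_new = f * state.C + i * c_hat
    o = sigmoid(z @ p.W_o + p.b_o)
    return LSTMState(h=o * np.tanh(c_new), C=c_new)


# ---------------------------------------------------------------------------
# trainable network
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class ModelConfig:
    n_features: int = 148       # input rows per timestep (H)
    n_species: int = 264
    hidden: int = 512
    n_layers: int = 2
    dropout: float = 0.3
    use_ca: bool = True
    ca_mid: int = 8             # intermediate width of the shared CA transform
    activation: str = "silu"    # "silu" or "relu" (ablation switch)
    bidirectional: bool = False
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self))

    @staticmethod
    def from_json(s: str) -> "ModelConfig":
        return ModelConfig(**json.loads(s))


def _activate(t: Tensor, kind: str) -> Tensor:
    if kind == "silu":
        return t.silu()
    if kind == "relu":
        return t.clip(0.0, np.inf)
    raise ValueError(f"unknown activation {kind!r}")


class CoordinateAttention:
    """1-channel coordinate attention producing row/column gates."""

    def __init__(self, rng: np.random.Generator, channels: int, mid: int):
        self.W1 = parameter(rng, (channels, mid), fan_in=channels)
        self.b1 = parameter(rng, (mid,), fan_in=channels)
        self.gamma = Tensor(np.ones(mid), requires_grad=True)
        self.beta = Tensor(np.zeros(mid), requires_grad=True)
        self.Wh = parameter(rng, (mid, channels), fan_in=mid)
        self.bh = parameter(rng, (channels,), fan_in=mid)
        self.Ww = parameter(rng, (mid, channels), fan_in=mid)
        self.bw = parameter(rng, (channels,), fan_in=mid)

    def parameters(self) -> list[Tensor]:
        return [self.W1, self.b1, self.gamma, self.beta,
                self.Wh, self.bh, self.Ww, self.bw]

    def gates(self, x: Tensor) -> tuple[Tensor, Tensor]:
        """x: (B, C, H, W) -> gate tensors (B, C, H) and (B, C, W)."""
        B, C, H, W = x.shape
        pooled_h = x.mean(axis=3)            # (B, C, H)
        pooled_w = x.mean(axis=2)            # (B, C, W)
        cat = concat([pooled_h, pooled_w], axis=2)     # (B, C, H + W)
        # shared 1x1 transform: mix channels at every spatial position
        y = cat.transpose(0, 2, 1) @ self.W1 + self.b1  # (B, H+W, mid)
        # normalise over all elements of each sample's concatenated map
        mu = y.mean(axis=(1, 2), keepdims=True)
        var = ((y - mu) ** 2).mean(axis=(1, 2), keepdims=True)
        y = (y - mu) / ((var + 1e-5) ** 0.5)
        y = y * self.gamma + self.beta
        y = y.silu()
        f_h = y[:, :H, :]                    # (B, H, mid)
        f_w = y[:, H:, :]                    # (B, W, mid)
        g_h = (f_h @ self.Wh + self.bh).sigmoid().transpose(0, 2, 1)
        g_w = (f_w @ self.Ww + self.bw).sigmoid().transpose(0, 2, 1)
        return g_h, g_w                      # (B, C, H), (B, C, W)

    def __call__(self, x: Tensor) -> Tensor:
        g_h, g_w = self.gates(x)
        B, C, H, W = x.shape
        return x * g_h.reshape(B, C, H, 1) * g_w.reshape(B, C, 1, W)

    def gates_numpy(self, x: np.ndarray) -> CAGates:
        """Eval-mode gates for a single (C, H, W) map as plain arrays."""
        with no_grad():
            g_h, g_w = self.gates(Tensor(x[None]))
        return CAGates(g_h=g_h.data[0], g_w=g_w.data[0])


class LSTMLayer:
    def __init__(self, rng: np.random.Generator, n_in: int, hidden: int):
        self.n_in, self.hidden = n_in, hidden
        fan = n_in + hidden
        self.W_f = parameter(rng, (fan, hidden), fan_in=fan)
        self.W_i = parameter(rng, (fan, hidden), fan_in=fan)
        self.W_C = parameter(rng, (fan, hidden), fan_in=fan)
        self.W_o = parameter(rng, (fan, hidden), fan_in=fan)
        self.b_f = parameter(rng, (hidden,), fan_in=fan)
        self.b_i = parameter(rng, (hidden,), fan_in=fan)
        self.b_C = parameter(rng, (hidden,), fan_in=fan)
        self.b_o = parameter(rng, (hidden,), fan_in=fan)

    def parameters(self) -> list[Tensor]:
        return [self.W_f, self.W_i, self.W_C, self.W_o,
                self.b_f, self.b_i, self.b_C, self.b_o]

    def numpy_params(self) -> LSTMLayerParams:
        return LSTMLayerParams(
            *(p.data for p in (self.W_f, self.W_i, self.W_C, self.W_o,
                               self.b_f, self.b_i, self.b_C, self.b_o)))

    def run(self, xs: list[Tensor]) -> list[Tensor]:
        """xs: list of T tensors of shape (B, n_in); returns hidden states."""
        B = xs[0].shape[0]
        W = concat([self.W_f, self.W_i, self.W_C, self.W_o], axis=1)
        b = concat([self.b_f, self.b_i, self.b_C, self.b_o], axis=0)
        h = Tensor(np.zeros((B, self.hidden)))
        c = Tensor(np.zeros((B, self.hidden)))
        hs = []
        H = self.hidden
        for x_t in xs:
            z = concat([h, x_t], axis=1) @ W + b
            f = z[:, :H].sigmoid()
            i = z[:, H:2 * H].sigmoid()
            c_hat = z[:, 2 * H:3 * H].tanh()
            c = f * c + i * c_hat
            o = z[:, 3 * H:].sigmoid()
            h = o * c.tanh()
            hs.append(h)
        return hs


class BirdcallNet:
    """Coordinate-attention + stacked-LSTM species classifier."""

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.ca = (CoordinateAttention(rng, channels=1, mid=config.ca_mid)
                   if config.use_ca else None)
        dirs = 2 if config.bidirectional else 1
        self.layers: list[LSTMLayer] = []
        n_in = config.n_features
        for _ in range(config.n_layers):
            layer = [LSTMLayer(rng, n_in, config.hidden) for _ in range(dirs)]
            self.layers.append(layer)
            n_in = config.hidden * dirs
        head_in = config.hidden * dirs
        self.fc1_W = parameter(rng, (head_in, config.hidden), fan_in=head_in)
        self.fc1_b = parameter(rng, (config.hidden,), fan_in=head_in)
        self.fc2_W = parameter(rng, (config.hidden, config.n_species),
                               fan_in=config.hidden)
        self.fc2_b = parameter(rng, (config.n_species,), fan_in=config.hidden)

    def parameters(self) -> list[Tensor]:
        ps: list[Tensor] = []
        if self.ca is not None:
            ps += self.ca.parameters()
        for layer in self.layers:
            for direction in layer:
                ps += direction.parameters()
        ps += [self.fc1_W, self.fc1_b, self.fc2_W, self.fc2_b]
        return ps

    def forward(self, x: Tensor, train: bool = False,
                rng: np.random.Generator | None = None) -> Tensor:
        """x: (B, H, W) feature maps -> (B, n_species) softmax posteriors."""
        B, H, W = x.shape
        if H != self.config.n_features:
            raise ValueError(
                f"expected {self.config.n_features} feature rows, got {H}")
        if self.ca is not None:
            x = self.ca(x.reshape(B, 1, H, W)).reshape(B, H, W)
        # columns become timesteps: T tensors of (B, H)
        xs = [x[:, :, t] for t in range(W)]
        p_drop = self.config.dropout if train else 0.0
        for li, layer in enumerate(self.layers):
            hs_fwd = layer[0].run(xs)
            if self.config.bidirectional:
                hs_bwd = layer[1].run(xs[::-1])[::-1]
                hs = [concat([f, b], axis=1) for f, b in zip(hs_fwd, hs_bwd)]
            else:
                hs = hs_fwd
            if p_drop > 0 and li < len(self.layers) - 1:
                hs = [self._dropout(h, p_drop, rng) for h in hs]
            xs = hs
        last = xs[-1]
        z = _activate(last @ self.fc1_W + self.fc1_b, self.config.activation)
        if p_drop > 0:
            z = self._dropout(z, p_drop, rng)
        logits = z @ self.fc2_W + self.fc2_b
        return softmax(logits, axis=1)

    @staticmethod
    def _dropout(t: Tensor, p: float, rng: np.random.Generator | None) -> Tensor:
        if rng is None:
            rng = np.random.default_rng()
        mask = (rng.random(t.shape) >= p) / (1.0 - p)
        return t * Tensor(mask)

    def predict_proba(self, X: np.ndarray, batch_size: int = 64) -> np.ndarray:
        """Eval-mode posteriors for an (N, H, W) stack of feature maps."""
        outs = []
        with no_grad():
            for i in range(0, len(X), batch_size):
                outs.append(self.forward(Tensor(X[i:i + batch_size])).data)
        return np.concatenate(outs, axis=0)

    # -- persistence ------------------------------------------------------

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.savez(directory / "params.npz",
                 **{f"p{i}": p.data for i, p in enumerate(self.parameters())})
        (directory / "config.json").write_text(self.config.to_json())

    @staticmethod
    def load(directory: str | Path) -> "BirdcallNet":
        directory = Path(directory)
        config = ModelConfig.from_json((directory / "config.json").read_text())
        net = BirdcallNet(config)
        archive = np.load(directory / "params.npz")
        for i, p in enumerate(net.parameters()):
            p.data = archive[f"p{i}"]
        return net
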