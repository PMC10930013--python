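"""Densely connected convolutional regression network for noise estimation.

The network maps a pseudo noise map to an estimate of the real noise map.
It is a compact DenseNet-style regressor: an initial 3x3 convolution,
a stack of densely connected 3x3 layers (each layer sees the concatenation
of every preceding feature map, contributing ``growth_rate`` new channels),
and a linear 3x3 reconstruction layer that also sees the full concatenation
— a skip connection from every depth to the output.  All layers use zero
padding, so output spatial size equals input size and the network can be
applied fully convolutionally to whole 512x512 maps after being trained on
25x25 patches.

Implementation is pure numpy with hand-derived backpropagation: forward
convolution as nine shifted channel-mixing matmuls, RMSE loss on the HU
scale, Adam with decoupled L2 weight decay on convolution weights, and
MSRA (He) initialization — zero-mean Gaussians with variance 2/fan_in and
zero biases.  Everything is deterministic given the seeds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from cacdn.noisemaps import NoiseMap, PatchSet, pseudo_noise_map
from cacdn.phantoms import CTImage


@dataclass(frozen=True)
class ModelConfig:
    """Topology of the dense regression network (desk-scale defaults)."""

    init_features: int = 8
    n_dense_blocks: int = 4
    layers_per_block: int = 2
    growth_rate: int = 6
    kernel_size: int = 3

    def __post_init__(self) -> None:
        if min(self.init_features, self.n_dense_blocks,
               self.layers_per_block, self.growth_rate) < 1:
            raise ValueError("all topology counts must be >= 1")
        if self.kernel_size % 2 != 1:
            raise ValueError("kernel size must be odd (zero padding)")


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 32
    learning_rate: float = 1e-4
    beta1: float = 0.9          # Adam first-moment decay ("momentum")
    beta2: float = 0.999
    weight_decay: float = 1e-4  # decoupled L2 on conv weights only
    max_iterations: int = 2000
    eval_interval: int = 100
    seed: int = 0
    precision: str = "float32"  # training arithmetic; float64 for audits

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")
        if self.precision not in ("float32", "float64"):
            raise ValueError("precision must be float32 or float64")


@dataclass
class TrainState:
    iteration: int
    loss_history: list[tuple[int, float]]
    model: "DenseNoiseNet"


class _Conv2d:
    """Same-padding convolution with manual backprop.

    Executed as k^2 channel-mixing matmuls over shifted views of the
    zero-padded input — cache-friendly at both patch and whole-image
    scale, with no im2col expansion.
    """

    def __init__(self, c_in: int, c_out: int, k: int,
                 rng: np.random.Generator):
        fan_in = k * k * c_in
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                            size=(c_out, c_in, k, k))
        self.b = np.zeros(c_out)
        self.k = k
        self._x: np.ndarray | None = None
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray, cache: bool = True) -> np.ndarray:
        n, ci, h, w = x.shape
        k, p = self.k, self.k // 2
        co = len(self.b)
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        out = np.broadcast_to(self.b[None, :, None, None],
                              (n, co, h, w)).copy()
        of = out.reshape(n, co, h * w)
        for ky in range(k):
            for kx in range(k):
                patch = xp[:, :, ky:ky + h, kx:kx + w].reshape(n, ci, h * w)
                of += np.matmul(self.W[:, :, ky, kx], patch)
        if cache:
            self._x = x
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x = self._x
        assert x is not None, "forward(cache=True) must precede backward"
        n, ci, h, w = x.shape
        k, p = self.k, self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        dxp = np.zeros_like(xp)
        df = dout.reshape(n, -1, h * w)
        for ky in range(k):
            for kx in range(k):
                patch = xp[:, :, ky:ky + h, kx:kx + w]
                self.dW[:, :, ky, kx] += np.tensordot(
                    dout, patch, axes=([0, 2, 3], [0, 2, 3]))
                dxp[:, :, ky:ky + h, kx:kx + w] += np.matmul(
                    self.W[:, :, ky, kx].T, df).reshape(n, ci, h, w)
        self.db += dout.sum(axis=(0, 2, 3))
        self._x = None
        return dxp[:, :, p:p + h, p:p + w]

    def zero_grad(self) -> None:
        self.dW[...] = 0.0
        self.db[...] = 0.0


class DenseNoiseNet:
    """See module docstring.  Build with :func:`build_model`."""

    def __init__(self, cfg: ModelConfig, seed: int):
        self.cfg = cfg
        self.seed = seed
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0xD5E]))
        k, g = cfg.kernel_size, cfg.growth_rate
        self.n_dense = cfg.n_dense_blocks * cfg.layers_per_block
        self.init_conv = _Conv2d(1, cfg.init_features, k, rng)
        self.dense: list[_Conv2d] = []
        c = cfg.init_features
        for _ in range(self.n_dense):
            self.dense.append(_Conv2d(c, g, k, rng))
            c += g
        self.recon = _Conv2d(c, 1, k, rng)

    # -- architecture facts -------------------------------------------------
    @property
    def layers(self) -> list[_Conv2d]:
        return [self.init_conv, *self.dense, self.recon]

    @property
    def n_parameters(self) -> int:
        return sum(l.W.size + l.b.size for l in self.layers)

    @property
    def receptive_field(self) -> int:
        return 1 + (self.cfg.kernel_size - 1) * len(self.layers)

    # -- forward / backward -------------------------------------------------
    def forward(self, x: np.ndarray, cache: bool = False) -> np.ndarray:
        """x: (N, 1, H, W) float array -> (N, 1, H, W) noise estimate."""
        x = np.asarray(x, dtype=np.float64)
        h0 = self.init_conv.forward(x, cache)
        feats = [np.maximum(h0, 0.0)]
        if cache:
            self._relu_masks = [feats[0] > 0.0]
        for conv in self.dense:
            inp = np.concatenate(feats, axis=1)
            h = conv.forward(inp, cache)
            a = np.maximum(h, 0.0)
            if cache:
                self._relu_masks.append(h > 0.0)
            feats.append(a)
        out = self.recon.forward(np.concatenate(feats, axis=1), cache)
        if cache:
            self._feat_channels = [f.shape[1] for f in feats]
        return out

    def backward(self, dout: np.ndarray) -> None:
        """Accumulate parameter gradients for the cached forward pass."""
        chans = self._feat_channels
        dfeats = list(np.split(self.recon.backward(dout),
                               np.cumsum(chans)[:-1], axis=1))
        for i in range(len(self.dense) - 1, -1, -1):
            da = dfeats[i + 1] * self._relu_masks[i + 1]
            dinp = self.dense[i].backward(da)
            split_at = np.cumsum(chans[:i + 1])[:-1]
            for j, dj in enumerate(np.split(dinp, split_at, axis=1)):
                dfeats[j] += dj
        self.init_conv.backward(dfeats[0] * self._relu_masks[0])

    def zero_grad(self) -> None:
        for l in self.layers:
            l.zero_grad()

    # -- persistence ---------------------------------------------------------
    def state_arrays(self) -> dict[str, np.ndarray]:
        out = {}
        for i, l in enumerate(self.layers):
            out[f"W{i}"] = l.W
            out[f"b{i}"] = l.b
        return out

    def load_state_arrays(self, arrays: dict[str, np.ndarray]) -> None:
        for i, l in enumerate(self.layers):
            l.W[...] = arrays[f"W{i}"]
            l.b[...] = arrays[f"b{i}"]


def build_model(cfg: ModelConfig | None = None, seed: int = 0) -> DenseNoiseNet:
    """Fresh MSRA-initialized network (all biases zero); deterministic."""
    return DenseNoiseNet(cfg or ModelConfig(), seed)


def rmse_loss(predicted: np.ndarray, label: np.ndarray) -> float:
    """Root-mean-square error over all pixels of the batch, in HU."""
    predicted = np.asarray(predicted, dtype=np.float64)
    label = np.asarray(label, dtype=np.float64)
    if predicted.shape != label.shape:
        raise ValueError("shape mismatch between prediction and label")
    return float(np.sqrt(np.mean((predicted - label) ** 2)))


class _Adam:
    """Adam with decoupled L2 decay applied to weights only."""

    def __init__(self, model: DenseNoiseNet, tc: TrainConfig):
        self.tc = tc
        self.t = 0
        self.m = [(np.zeros_like(l.W), np.zeros_like(l.b))
                  for l in model.layers]
        self.v = [(np.zeros_like(l.W), np.zeros_like(l.b))
                  for l in model.layers]

    def step(self, model: DenseNoiseNet) -> None:
        tc = self.tc
        self.t += 1
        b1c = 1.0 - tc.beta1 ** self.t
        b2c = 1.0 - tc.beta2 ** self.t
        eps = 1e-8
        for l, (mW, mb), (vW, vb) in zip(model.layers, self.m, self.v):
            for p, g, m, v, decay in ((l.W, l.dW, mW, vW, tc.weight_decay),
                                      (l.b, l.db, mb, vb, 0.0)):
                m *= tc.beta1
                m += (1.0 - tc.beta1) * g
                v *= tc.beta2
                v += (1.0 - tc.beta2) * g * g
                p -= tc.learning_rate * (
                    (m / b1c) / (np.sqrt(v / b2c) + eps) + decay * p)


def _cast_precision(model: DenseNoiseNet, opt: "_Adam",
                    dtype: np.dtype) -> None:
    """Cast parameters, gradients and optimizer state to one dtype so a
    resumed run is bit-identical to an uninterrupted one."""
    for i, l in enumerate(model.layers):
        l.W = l.W.astype(dtype)
        l.b = l.b.astype(dtype)
        l.dW = np.zeros_like(l.W)
        l.db = np.zeros_like(l.b)
        opt.m[i] = (opt.m[i][0].astype(dtype), opt.m[i][1].astype(dtype))
        opt.v[i] = (opt.v[i][0].astype(dtype), opt.v[i][1].astype(dtype))


def _batch_indices(seed: int, n: int, batch: int, iteration: int) -> np.ndarray:
    """Stateless epoch-shuffled minibatch schedule.

    Iteration t consumes samples [t*B, (t+1)*B) of the virtual stream that
    concatenates per-epoch permutations; being a pure function of (seed,
    t) it makes checkpoint resumption exact.
    """
    start = iteration * batch
    idx = np.empty(batch, dtype=np.intp)
    got = 0
    while got < batch:
        epoch, off = divmod(start + got, n)
        rng = np.random.default_rng(np.random.SeedSequence([seed, epoch]))
        perm = rng.permutation(n)
        take = min(batch - got, n - off)
        idx[got:got + take] = perm[off:off + take]
        got += take
    return idx


def train(model: DenseNoiseNet, ps: PatchSet, tc: TrainConfig,
          optimizer: _Adam | None = None, start_iteration: int = 0,
          loss_history: list[tuple[int, float]] | None = None) -> TrainState:
    """Minibatch RMSE training with Adam; deterministic given tc.seed.

    ``optimizer``/``start_iteration``/``loss_history`` allow bit-exact
    resumption from a checkpoint (see :func:`save_checkpoint`).
    """
    if len(ps) == 0:
        raise ValueError("empty patch set")
    dt = np.dtype(tc.precision)
    x = np.asarray(ps.inputs, dtype=dt)[:, None]
    y = np.asarray(ps.labels, dtype=dt)[:, None]
    opt = optimizer or _Adam(model, tc)
    _cast_precision(model, opt, dt)
    history = loss_history if loss_history is not None else []
    for it in range(start_iteration, tc.max_iterations):
        idx = _batch_indices(tc.seed, len(ps), tc.batch_size, it)
        xb, yb = x[idx], y[idx]
        model.zero_grad()
        pred = model.forward(xb, cache=True)
        diff = pred - yb
        loss = float(np.sqrt(np.mean(diff ** 2)))
        if not np.isfinite(loss):
            raise RuntimeError(f"non-finite training loss at iteration {it}")
        if it % tc.eval_interval == 0:
            history.append((it, loss))
        if loss > 0.0:
            model.backward(diff / (diff.size * loss))
        opt.step(model)
    return TrainState(iteration=tc.max_iterations, loss_history=history,
                      model=model)


def evaluate_loss(model: DenseNoiseNet, ps: PatchSet,
                  batch: int = 250) -> float:
    """RMSE of the model over a whole patch set (batched forward passes)."""
    sq_sum, n = 0.0, 0
    for i in range(0, len(ps), batch):
        pred = model.forward(ps.inputs[i:i + batch][:, None])
        d = pred - ps.labels[i:i + batch][:, None]
        sq_sum += float(np.sum(d * d))
        n += d.size
    return float(np.sqrt(sq_sum / n))


def predict_noise(model: DenseNoiseNet, thin: CTImage) -> NoiseMap:
    """Whole-image noise estimate: model applied to the pseudo noise map,
    fully convolutionally (no tiling seams)."""
    pmap = pseudo_noise_map(thin)
    out = model.forward(pmap.values[None, None], cache=False)[0, 0]
    return NoiseMap(values=out, role="predicted", z=thin.slice_thickness,
                    grid=thin.grid,
                    provenance=f"cnn({thin.provenance})")


# ---------------------------------------------------------------------------
# Checkpointing: single .npz with a JSON header entry.
# ---------------------------------------------------------------------------

def save_checkpoint(path, model: DenseNoiseNet, tc: TrainConfig,
                    optimizer: _Adam, iteration: int,
                    loss_history: list[tuple[int, float]]) -> None:
    header = {
        "model_config": asdict(model.cfg),
        "train_config": asdict(tc),
        "seed": model.seed,
        "iteration": iteration,
        "adam_t": optimizer.t,
        "loss_history": loss_history,
    }
    arrays = dict(model.state_arrays())
    for i, ((mW, mb), (vW, vb)) in enumerate(zip(optimizer.m, optimizer.v)):
        arrays[f"adam_mW{i}"] = mW
        arrays[f"adam_mb{i}"] = mb
        arrays[f"adam_vW{i}"] = vW
        arrays[f"adam_vb{i}"] = vb
    np.savez(path, header=np.frombuffer(
        json.dumps(header).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path) -> tuple[DenseNoiseNet, TrainConfig, _Adam, int,
                                   list[tuple[int, float]]]:
    with np.load(path) as data:
        header = json.loads(bytes(data["header"]).decode())
        arrays = {k: data[k] for k in data.files if k != "header"}
    cfg = ModelConfig(**header["model_config"])
    tc = TrainConfig(**header["train_config"])
    model = DenseNoiseNet(cfg, header["seed"])
    model.load_state_arrays(arrays)
    opt = _Adam(model, tc)
    opt.t = header["adam_t"]
    for i in range(len(model.layers)):
        opt.m[i][0][...] = arrays[f"adam_mW{i}"]
        opt.m[i][1][...] = arrays[f"adam_mb{i}"]
        opt.v[i][0][...] = arrays[f"adam_vW{i}"]
        opt.v[i][1][...] = arrays[f"adam_vb{i}"]
    history = [tuple(h) for h in header["loss_history"]]
    return model, tc, opt, header["iteration"], history
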