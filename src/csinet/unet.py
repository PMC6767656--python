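"""U-Net image-to-image regression implemented in numpy.

The enhancement stage learns a mapping G from rough CSI permittivity
reconstructions to the true permittivity maps.  Inputs are three channels
on a common pixel grid — the real part, the imaginary part and the
magnitude sqrt(re^2 + im^2) of the reconstructed complex permittivity.
Two architectures are supported:

* Architecture 1 — two independent single-output networks, one trained to
  output the true real part and one the true imaginary part (the two
  parts have very different scales, so separate networks avoid one
  component dominating the loss);
* Architecture 2 — one network with three outputs: magnitude, real and
  imaginary parts of the true permittivity.

The network is the classic encoder-decoder with skip connections: 3x3
convolutions + ReLU, 2x2 max-pooling on the way down, 2x2 transposed
convolutions on the way up, concatenation of matching-resolution encoder
features, and a linear 1x1 output head.  The loss is the pixelwise
squared reconstruction error.  Weights use Glorot (Xavier) normal
initialization; optimisation is Adam with seeded shuffling, so training
is fully deterministic for a fixed seed.

Everything (forward, backward, optimiser) is plain numpy; convolutions
use im2col/matmul, which is adequate for the desk-scale grids this
package targets.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


# ---------------------------------------------------------------------------
# layers


def _im2col(x, k=3):
    """(B, C, H, W) -> (B*H*W, C*k*k) with zero 'same' padding."""
    p = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    win = sliding_window_view(xp, (k, k), axis=(2, 3))  # (B, C, H, W, k, k)
    B, C, H, W = x.shape
    return win.transpose(0, 2, 3, 1, 4, 5).reshape(B * H * W, C * k * k)


def _col2im(cols, shape, k=3):
    """Adjoint of _im2col: scatter-add columns back to (B, C, H, W)."""
    B, C, H, W = shape
    p = k // 2
    xp = np.zeros((B, C, H + 2 * p, W + 2 * p), dtype=cols.dtype)
    cols = cols.reshape(B, H, W, C, k, k)
    for di in range(k):
        for dj in range(k):
            xp[:, :, di:di + H, dj:dj + W] += cols[:, :, :, :, di, dj].transpose(0, 3, 1, 2)
    return xp[:, :, p:p + H, p:p + W]


class Conv3x3:
    def __init__(self, c_in, c_out, rng):
        std = np.sqrt(2.0 / (9 * c_in + 9 * c_out))  # Glorot normal
        self.W = rng.normal(0.0, std, size=(c_out, c_in, 3, 3))
        self.b = np.zeros(c_out)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)

    def forward(self, x):
        self._shape = x.shape
        self._cols = _im2col(x)
        B, C, H, W = x.shape
        self._Wm = self.W.reshape(self.W.shape[0], -1).astype(x.dtype, copy=False)
        out = self._cols @ self._Wm.T + self.b.astype(x.dtype, copy=False)
        return out.reshape(B, H, W, -1).transpose(0, 3, 1, 2)

    def backward(self, g):
        B, Co, H, W = g.shape
        gmat = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(B * H * W, Co)
        self.gW += (gmat.T @ self._cols).reshape(self.W.shape)
        self.gb += gmat.sum(axis=0)
        gcols = gmat @ self._Wm
        return _col2im(gcols, self._shape)

    def params(self):
        return [(self.W, self.gW), (self.b, self.gb)]


class ReLU:
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, g):
        return g * self._mask

    def params(self):
        return []


class MaxPool2:
    def forward(self, x):
        B, C, H, W = x.shape
        xr = x.reshape(B, C, H // 2, 2, W // 2, 2)
        out = xr.max(axis=(3, 5))
        self._argmask = xr == out[:, :, :, None, :, None]
        self._shape = x.shape
        return out

    def backward(self, g):
        B, C, H, W = self._shape
        gr = np.where(self._argmask, g[:, :, :, None, :, None], 0.0)
        # distribute equally among tied maxima to stay a true adjoint
        counts = self._argmask.sum(axis=(3, 5), keepdims=True)
        gr = gr / counts
        return gr.reshape(B, C, H, W)

    def params(self):
        return []


class UpConv2:
    """2x2 stride-2 transposed convolution."""

    def __init__(self, c_in, c_out, rng):
        std = np.sqrt(2.0 / (4 * c_in + 4 * c_out))
        self.W = rng.normal(0.0, std, size=(c_in, c_out, 2, 2))
        self.b = np.zeros(c_out)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)

    def forward(self, x):
        B, C, H, W = x.shape
        D = self.W.shape[1]
        xm = x.transpose(0, 2, 3, 1).reshape(B * H * W, C)
        self._xm = xm
        self._dims = (B, C, H, W)
        out = xm @ self.W.reshape(C, D * 4).astype(x.dtype, copy=False)
        out = out.reshape(B, H, W, D, 2, 2).transpose(0, 3, 1, 4, 2, 5)
        out = out.reshape(B, D, 2 * H, 2 * W)
        return out + self.b.astype(x.dtype, copy=False)[None, :, None, None]

    def backward(self, g):
        B, C, H, W = self._dims
        D = self.W.shape[1]
        gr = g.reshape(B, D, H, 2, W, 2).transpose(0, 2, 4, 1, 3, 5)
        gm = gr.reshape(B * H * W, D * 4)
        self.gW += (self._xm.T @ gm).reshape(self.W.shape)
        self.gb += g.sum(axis=(0, 2, 3))
        gx = gm @ self.W.reshape(C, D * 4).astype(g.dtype, copy=False).T
        return gx.reshape(B, H, W, C).transpose(0, 3, 1, 2)

    def params(self):
        return [(self.W, self.gW), (self.b, self.gb)]


class Conv1x1:
    def __init__(self, c_in, c_out, rng):
        std = np.sqrt(2.0 / (c_in + c_out))
        self.W = rng.normal(0.0, std, size=(c_out, c_in))
        self.b = np.zeros(c_out)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)

    def forward(self, x):
        self._x = x
        Wm = self.W.astype(x.dtype, copy=False)
        out = np.einsum("bchw,dc->bdhw", x, Wm)
        return out + self.b.astype(x.dtype, copy=False)[None, :, None, None]

    def backward(self, g):
        self.gW += np.einsum("bdhw,bchw->dc", g, self._x)
        self.gb += g.sum(axis=(0, 2, 3))
        return np.einsum("bdhw,dc->bchw", g, self.W.astype(g.dtype, copy=False))

    def params(self):
        return [(self.W, self.gW), (self.b, self.gb)]


# ---------------------------------------------------------------------------
# network


@dataclasses.dataclass
class TrainConfig:
    """U-Net training configuration with the published defaults."""

    architecture: int = 1       # 1: two single-output nets; 2: one 3-output net
    batch_size: int = 10
    epochs: int = 75
    learning_rate: float = 1e-3
    base_filters: int = 32
    depth: int = 4              # number of down/up levels
    seed: int = 0
    #: step learning-rate decay: multiply by 0.3 at these epoch fractions
    lr_decay_at: tuple = (0.6, 0.85)
    #: short multi-start: train this many inits for a few epochs and keep
    #: the one with the lowest loss (guards against rare bad basins)
    n_init_candidates: int = 2
    init_select_epochs: int = 5

    def __post_init__(self):
        if self.architecture not in (1, 2):
            raise ValueError("architecture must be 1 or 2")
        if self.depth < 2:
            raise ValueError("depth must be >= 2")


class UNet:
    """Encoder-decoder with skip connections and a linear output head."""

    def __init__(self, in_channels=3, out_channels=1, base_filters=32, depth=4,
                 seed=0):
        rng = np.random.default_rng(seed)
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.depth = depth
        self.enc = []
        c_prev = in_channels
        c = base_filters
        for _ in range(depth):
            self.enc.append(
                [Conv3x3(c_prev, c, rng), ReLU(), Conv3x3(c, c, rng), ReLU()]
            )
            c_prev = c
            c *= 2
        self.bottleneck = [Conv3x3(c_prev, c, rng), ReLU(), Conv3x3(c, c, rng), ReLU()]
        self.pools = [MaxPool2() for _ in range(depth)]
        self.ups = []
        self.dec = []
        for _ in range(depth):
            self.ups.append(UpConv2(c, c // 2, rng))
            self.dec.append(
                [Conv3x3(c, c // 2, rng), ReLU(), Conv3x3(c // 2, c // 2, rng), ReLU()]
            )
            c //= 2
        self.head = Conv1x1(c, out_channels, rng)

    # -- plumbing

    def _layers(self):
        for block in self.enc:
            yield from block
        yield from self.pools
        yield from self.bottleneck
        yield from self.ups
        for block in self.dec:
            yield from block
        yield self.head

    def parameters(self):
        out = []
        for layer in self._layers():
            out.extend(layer.params())
        return out

    def zero_grad(self):
        for _, g in self.parameters():
            g[...] = 0.0

    def n_parameters(self):
        return int(sum(p.size for p, _ in self.parameters()))

    # -- forward / backward

    def forward(self, x):
        if x.shape[1] != self.in_channels:
            raise ValueError(
                f"expected {self.in_channels} input channels, got {x.shape[1]}"
            )
        h, w = x.shape[2], x.shape[3]
        if h % (1 << self.depth) or w % (1 << self.depth):
            raise ValueError(
                f"spatial dims {h}x{w} must be divisible by 2^depth = "
                f"{1 << self.depth}; pad the images to the next multiple"
            )
        skips = []
        for block, pool in zip(self.enc, self.pools):
            for layer in block:
                x = layer.forward(x)
            skips.append(x)
            x = pool.forward(x)
        for layer in self.bottleneck:
            x = layer.forward(x)
        self._skip_channels = []
        for up, block, skip in zip(self.ups, self.dec, reversed(skips)):
            x = up.forward(x)
            self._skip_channels.append(skip.shape[1])
            x = np.concatenate([skip, x], axis=1)
            for layer in block:
                x = layer.forward(x)
        return self.head.forward(x)

    def backward(self, g):
        g = self.head.backward(g)
        skip_grads = []
        for up, block, c_skip in zip(reversed(self.ups), reversed(self.dec),
                                     reversed(self._skip_channels)):
            for layer in reversed(block):
                g = layer.backward(g)
            skip_grads.append(g[:, :c_skip])
            g = up.backward(g[:, c_skip:])
        for layer in reversed(self.bottleneck):
            g = layer.backward(g)
        for block, pool, gs in zip(reversed(self.enc), reversed(self.pools),
                                   reversed(skip_grads)):
            g = pool.backward(g)
            g = g + gs
            for layer in reversed(block):
                g = layer.backward(g)
        return g


class Adam:
    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]
        self.t = 0

    def step(self):
        self.t += 1
        for (p, g), m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mh = m / (1 - self.b1 ** self.t)
            vh = v / (1 - self.b2 ** self.t)
            p -= self.lr * mh / (np.sqrt(vh) + self.eps)


# ---------------------------------------------------------------------------
# normalization and input stacks


class ChannelNormalizer:
    """Per-channel affine min-max normalization fit on the training split."""

    def __init__(self):
        self.lo = None
        self.hi = None

    def fit(self, x):
        """x: (N, C, H, W); records per-channel min/max."""
        self.lo = x.min(axis=(0, 2, 3))
        self.hi = x.max(axis=(0, 2, 3))
        span = self.hi - self.lo
        self.hi = np.where(span == 0, self.lo + 1.0, self.hi)
        return self

    def transform(self, x):
        if self.lo is None:
            raise ValueError("normalizer not fitted")
        lo = self.lo[None, :, None, None]
        hi = self.hi[None, :, None, None]
        return (x - lo) / (hi - lo)

    def inverse(self, x):
        lo = self.lo[None, :, None, None]
        hi = self.hi[None, :, None, None]
        return x * (hi - lo) + lo

    def to_dict(self):
        return {"lo": self.lo.tolist(), "hi": self.hi.tolist()}

    @classmethod
    def from_dict(cls, d):
        out = cls()
        out.lo = np.asarray(d["lo"], dtype=float)
        out.hi = np.asarray(d["hi"], dtype=float)
        return out


def make_input_stack(recon_real, recon_imag):
    """Stack (real, imag, magnitude) channels from CSI reconstructions.

    Accepts single images (H, W) or batches (N, H, W); returns
    (N, 3, H, W) unnormalized.
    """
    re = np.atleast_3d(np.asarray(recon_real, dtype=float))
    im = np.atleast_3d(np.asarray(recon_imag, dtype=float))
    if re.ndim == 3 and re.shape == im.shape and np.asarray(recon_real).ndim == 2:
        re = re.reshape(1, *np.asarray(recon_real).shape)
        im = im.reshape(1, *np.asarray(recon_imag).shape)
    if re.shape != im.shape:
        raise ValueError("real/imag image shapes differ")
    mag = np.sqrt(re ** 2 + im ** 2)
    return np.stack([re, im, mag], axis=1)


def make_target_stack(true_eps_real, true_eps_imag, architecture, part=None):
    """Target channels for the requested architecture.

    Architecture 1 targets one channel (``part`` in {"real", "imag"});
    architecture 2 targets (magnitude, real, imag).
    """
    re = np.asarray(true_eps_real, dtype=float)
    im = np.asarray(true_eps_imag, dtype=float)
    if re.ndim == 2:
        re, im = re[None], im[None]
    if architecture == 1:
        if part not in ("real", "imag"):
            raise ValueError("architecture 1 needs part='real' or 'imag'")
        return (re if part == "real" else im)[:, None]
    return np.stack([np.sqrt(re ** 2 + im ** 2), re, im], axis=1)


# ---------------------------------------------------------------------------
# training


def train_unet(net, x_norm, y_norm, config: TrainConfig, loss_weights=None):
    """Minimise the pixelwise squared error with Adam; returns loss curve.

    ``loss_weights`` optionally reweights output channels (defaults to
    uniform weighting, under which the larger-scale channel dominates the
    cost — intentionally reproducing the published behaviour).
    """
    x_norm = np.ascontiguousarray(x_norm, dtype=np.float32)
    y_norm = np.ascontiguousarray(y_norm, dtype=np.float32)
    n = x_norm.shape[0]
    rng = np.random.default_rng(config.seed)
    opt = Adam(net.parameters(), lr=config.learning_rate)
    w = None
    if loss_weights is not None:
        w = np.asarray(loss_weights, dtype=np.float32)[None, :, None, None]
    decay_epochs = {int(f * config.epochs) for f in config.lr_decay_at}
    losses = []
    for epoch in range(config.epochs):
        if epoch in decay_epochs:
            opt.lr *= 0.3
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            xb, yb = x_norm[idx], y_norm[idx]
            pred = net.forward(xb)
            diff = pred - yb
            if w is not None:
                loss = float(np.mean(w * diff * diff))
                grad = 2.0 * w * diff / diff.size
            else:
                loss = float(np.mean(diff * diff))
                grad = 2.0 * diff / diff.size
            if not np.isfinite(loss):
                raise FloatingPointError("NaN/inf training loss")
            net.zero_grad()
            net.backward(grad)
            opt.step()
            epoch_loss += loss * len(idx)
        losses.append(epoch_loss / n)
    return losses


def train_unet_multistart(net_factory, x_norm, y_norm, config: TrainConfig,
                          loss_weights=None):
    """Train with a short multi-start: probe a few inits briefly, then run
    the full schedule from the most promising one.

    ``net_factory(seed)`` must build a fresh network.  Returns
    (trained net, loss curve).  Fully deterministic for a fixed config.
    """
    if config.n_init_candidates <= 1:
        net = net_factory(config.seed)
        return net, train_unet(net, x_norm, y_norm, config, loss_weights)
    probe_epochs = min(config.init_select_epochs, config.epochs)
    best_seed, best_loss = None, np.inf
    for k in range(config.n_init_candidates):
        seed_k = config.seed + 7919 * k
        probe_cfg = dataclasses.replace(config, epochs=probe_epochs, seed=seed_k)
        net = net_factory(seed_k)
        curve = train_unet(net, x_norm, y_norm, probe_cfg, loss_weights)
        if curve[-1] < best_loss:
            best_seed, best_loss = seed_k, curve[-1]
    net = net_factory(best_seed)
    curve = train_unet(net, x_norm, y_norm,
                       dataclasses.replace(config, seed=best_seed), loss_weights)
    return net, curve


# ---------------------------------------------------------------------------
# model / results


class UNetEnhancer:
    """Enhancement model: learns CSI reconstruction -> true permittivity.

    Parameters
    ----------
    inputs : (N, 3, H, W)
        Unnormalized input stacks (real, imag, magnitude of the CSI
        reconstruction), e.g. from :func:`make_input_stack`.
    targets_real, targets_imag : (N, H, W)
        True permittivity parts for the same phantoms.
    config : TrainConfig
    """

    def __init__(self, inputs, targets_real, targets_imag, config: TrainConfig):
        self.inputs = np.asarray(inputs, dtype=float)
        self.targets_real = np.asarray(targets_real, dtype=float)
        self.targets_imag = np.asarray(targets_imag, dtype=float)
        if self.inputs.ndim != 4 or self.inputs.shape[1] != 3:
            raise ValueError("inputs must have shape (N, 3, H, W)")
        self.config = config

    def fit(self) -> "UNetResults":
        cfg = self.config
        in_norm = ChannelNormalizer().fit(self.inputs)
        x = in_norm.transform(self.inputs)
        nets, out_norms, curves = {}, {}, {}
        if cfg.architecture == 1:
            for i, part in enumerate(("real", "imag")):
                y = make_target_stack(self.targets_real, self.targets_imag, 1, part)
                norm = ChannelNormalizer().fit(y)
                head_cfg = dataclasses.replace(cfg, seed=cfg.seed + i)
                net, curve = train_unet_multistart(
                    lambda sd: UNet(3, 1, cfg.base_filters, cfg.depth, seed=sd),
                    x, norm.transform(y), head_cfg)
                curves[part] = curve
                nets[part], out_norms[part] = net, norm
        else:
            y = make_target_stack(self.targets_real, self.targets_imag, 2)
            norm = ChannelNormalizer().fit(y)
            net, curve = train_unet_multistart(
                lambda sd: UNet(3, 3, cfg.base_filters, cfg.depth, seed=sd),
                x, norm.transform(y), cfg)
            curves["joint"] = curve
            nets["joint"], out_norms["joint"] = net, norm
        return UNetResults(self, in_norm, nets, out_norms, curves)


class UNetResults:
    """Trained enhancement networks with their normalization constants."""

    def __init__(self, model, input_normalizer, nets, output_normalizers, curves,
                 config=None):
        self.model = model
        self.config = config if config is not None else model.config
        self.input_normalizer = input_normalizer
        self.nets = nets
        self.output_normalizers = output_normalizers
        self.loss_curves = curves

    def predict(self, inputs, batch_size=16):
        """Denormalized (real, imag) permittivity maps for raw input stacks.

        ``inputs``: (N, 3, H, W) unnormalized.  Returns (real, imag) each
        (N, H, W).  For architecture 2 the magnitude output channel is
        computed but only real/imag are returned; use
        :meth:`predict_channels` for all three.
        """
        ch = self.predict_channels(inputs, batch_size)
        return ch["real"], ch["imag"]

    def predict_channels(self, inputs, batch_size=16):
        x = self.input_normalizer.transform(np.asarray(inputs, dtype=float))
        out = {}
        if self.config.architecture == 1:
            for part in ("real", "imag"):
                pred = self._run(self.nets[part], x, batch_size)
                out[part] = self.output_normalizers[part].inverse(pred)[:, 0]
        else:
            pred = self._run(self.nets["joint"], x, batch_size)
            pred = self.output_normalizers["joint"].inverse(pred)
            out["magnitude"], out["real"], out["imag"] = pred[:, 0], pred[:, 1], pred[:, 2]
        return out

    @staticmethod
    def _run(net, x, batch_size):
        x = np.ascontiguousarray(x, dtype=np.float32)
        chunks = [net.forward(x[i:i + batch_size])
                  for i in range(0, x.shape[0], batch_size)]
        return np.concatenate(chunks, axis=0).astype(float)

    def summary(self):
        cfg = self.config
        lines = [
            "U-Net enhancement results",
            f"  architecture     : {cfg.architecture}",
            f"  networks trained : {len(self.nets)} ({', '.join(self.nets)})",
            f"  parameters/net   : {next(iter(self.nets.values())).n_parameters()}",
            f"  epochs x batch   : {cfg.epochs} x {cfg.batch_size}",
        ]
        for name, curve in self.loss_curves.items():
            lines.append(
                f"  loss[{name}]       : {curve[0]:.3e} -> {curve[-1]:.3e}"
            )
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# model persistence (weights as npz + JSON sidecar)


def save_unet_results(results: UNetResults, path_prefix):
    """Persist trained networks: <prefix>.npz (weights) + <prefix>.json."""
    import json
    from pathlib import Path

    arrays = {}
    for name, net in results.nets.items():
        for i, (p, _) in enumerate(net.parameters()):
            arrays[f"{name}/{i}"] = p
    np.savez(str(path_prefix) + ".npz", **arrays)
    cfg = results.config
    sidecar = {
        "config": dataclasses.asdict(cfg),
        "input_normalizer": results.input_normalizer.to_dict(),
        "output_normalizers": {
            k: v.to_dict() for k, v in results.output_normalizers.items()
        },
        "loss_curves": {k: list(map(float, v)) for k, v in results.loss_curves.items()},
        "heads": {name: net.out_channels for name, net in results.nets.items()},
    }
    Path(str(path_prefix) + ".json").write_text(json.dumps(sidecar))


def load_unet_results(path_prefix) -> UNetResults:
    import json
    from pathlib import Path

    sidecar = json.loads(Path(str(path_prefix) + ".json").read_text())
    cfg = TrainConfig(**sidecar["config"])
    data = np.load(str(path_prefix) + ".npz")
    nets = {}
    for name, out_ch in sidecar["heads"].items():
        net = UNet(3, out_ch, cfg.base_filters, cfg.depth, seed=cfg.seed)
        for i, (p, _) in enumerate(net.parameters()):
            p[...] = data[f"{name}/{i}"]
        nets[name] = net
    return UNetResults(
        model=None,
        input_normalizer=ChannelNormalizer.from_dict(sidecar["input_normalizer"]),
        nets=nets,
        output_normalizers={
            k: ChannelNormalizer.from_dict(v)
            for k, v in sidecar["output_normalizers"].items()
        },
        curves={k: list(v) for k, v in sidecar["loss_curves"].items()},
        config=cfg,
    )
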