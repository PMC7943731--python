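"""Deep-PAT reconstruction: fixed back-projection proxy + trainable network.

The method factors image recovery from compressive measurements into two
stages.  A fixed, non-trained linear stage lifts the measurement vector v
back to image space, V-hat = K^T v (the "fully connected" proxy — its
weights are the transpose of the measurement matrix, designed rather than
learned).  A convolutional network then removes the undersampling
artifacts from V-hat.  Three families are provided:

* ``cnn3``  — three convolutional layers (9x9, 5x5, 5x5 kernels) with ReLU
  between them; the minimal image-restoration baseline.
* ``unet``  — encoder/decoder with 3x3 convolutions, 2x2 max pooling, 2x2
  stride-2 transposed convolutions and skip concatenations; channel count
  doubles per level.
* ``resunet`` — the U-Net with each double-convolution replaced by a
  residual block (conv-BN-ReLU-conv-BN plus identity shortcut, a 1x1
  convolution on the shortcut when channel counts differ, ReLU after the
  sum).

Training minimizes the mean-absolute (l1) reconstruction error with Adam
(default learning rate 0.005, batch size 1); SGD is selectable.  A model is
always trained for one specific measurement matrix, hence for one
undersampling ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence

import numpy as np

from . import nn
from .errors import (ArchitectureError, DimensionMismatchError,
                     InvalidArgumentError, TrainingDivergedError)
from .phantom_forge import DatasetSplit, Phantom
from .quality_metrics import MetricRecord, AggregateReport, aggregate, psnr, ssim
from .sensing import MeasurementMatrix, MeasurementVector, measure, proxy

__all__ = ["NetworkSpec", "TrainConfig", "ReconModel", "build_model", "train",
           "reconstruct", "compare_families", "DESK_SPECS"]


@dataclass(frozen=True)
class NetworkSpec:
    family: str  # cnn3 | unet | resunet
    depth: int = 3  # encoder levels (unet/resunet)
    base_channels: int = 8
    use_batchnorm: bool = True  # resunet blocks

    def __post_init__(self):
        if self.family not in ("cnn3", "unet", "resunet"):
            raise InvalidArgumentError(f"unknown family {self.family!r}")
        if self.depth < 1 or self.base_channels < 1:
            raise InvalidArgumentError("depth and base_channels must be >= 1")


#: laptop-scale presets used by the shipped benchmark profile
DESK_SPECS = {
    "cnn3": NetworkSpec("cnn3", base_channels=8),
    "unet": NetworkSpec("unet", depth=3, base_channels=8),
    "resunet": NetworkSpec("resunet", depth=3, base_channels=8),
}


@dataclass
class TrainConfig:
    learning_rate: float = 0.005
    batch_size: int = 1
    epochs: int = 20
    optimizer: str = "adam"
    loss: str = "l1"
    seed: int = 0
    undersampling_ratio: float = 0.3
    device_hint: str = "cpu"

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise InvalidArgumentError("learning_rate must be positive")
        if self.batch_size < 1 or self.epochs < 1:
            raise InvalidArgumentError("batch_size and epochs must be >= 1")
        if self.optimizer not in ("adam", "sgd"):
            raise InvalidArgumentError(f"unknown optimizer {self.optimizer!r}")
        if self.loss != "l1":
            raise InvalidArgumentError("only the l1 loss is supported")


class _DoubleConv:
    def __init__(self, in_ch, out_ch, rng, name):
        self.c1 = nn.Conv2d(in_ch, out_ch, 3, rng, f"{name}.c1")
        self.r1 = nn.ReLU()
        self.c2 = nn.Conv2d(out_ch, out_ch, 3, rng, f"{name}.c2")
        self.r2 = nn.ReLU()

    def forward(self, x, train):
        return self.r2.forward(self.c2.forward(self.r1.forward(self.c1.forward(x))))

    def backward(self, d):
        return self.c1.backward(self.r1.backward(
            self.c2.backward(self.r2.backward(d))))

    def params(self):
        return self.c1.params() + self.c2.params()

    def layers(self):
        return [self.c1, self.c2]


class _ResBlock:
    """conv-BN-ReLU-conv-BN with identity shortcut (1x1 conv if needed)."""

    def __init__(self, in_ch, out_ch, rng, name, use_bn=True):
        self.c1 = nn.Conv2d(in_ch, out_ch, 3, rng, f"{name}.c1")
        self.c2 = nn.Conv2d(out_ch, out_ch, 3, rng, f"{name}.c2")
        self.bn1 = nn.BatchNorm2d(out_ch, f"{name}.bn1") if use_bn else None
        self.bn2 = nn.BatchNorm2d(out_ch, f"{name}.bn2") if use_bn else None
        self.relu_mid = nn.ReLU()
        self.relu_out = nn.ReLU()
        self.shortcut = (nn.Conv2d(in_ch, out_ch, 1, rng, f"{name}.proj")
                         if in_ch != out_ch else None)

    def forward(self, x, train):
        h = self.c1.forward(x)
        if self.bn1 is not None:
            h = self.bn1.forward(h, train)
        h = self.relu_mid.forward(h)
        h = self.c2.forward(h)
        if self.bn2 is not None:
            h = self.bn2.forward(h, train)
        idt = x if self.shortcut is None else self.shortcut.forward(x)
        return self.relu_out.forward(h + idt)

    def backward(self, d):
        d = self.relu_out.backward(d)
        d_idt = d if self.shortcut is None else self.shortcut.backward(d)
        h = d
        if self.bn2 is not None:
            h = self.bn2.backward(h)
        h = self.c2.backward(h)
        h = self.relu_mid.backward(h)
        if self.bn1 is not None:
            h = self.bn1.backward(h)
        h = self.c1.backward(h)
        return h + d_idt

    def params(self):
        out = self.c1.params() + self.c2.params()
        for bn in (self.bn1, self.bn2):
            if bn is not None:
                out += bn.params()
        if self.shortcut is not None:
            out += self.shortcut.params()
        return out

    def layers(self):
        out = [self.c1, self.c2]
        if self.shortcut is not None:
            out.append(self.shortcut)
        return out


class _EncDecNet:
    """U-Net topology; ``block_cls`` selects plain or residual blocks."""

    def __init__(self, spec: NetworkSpec, rng: np.random.Generator):
        self.spec = spec
        d, c = spec.depth, spec.base_channels
        block = (_ResBlock if spec.family == "resunet" else _DoubleConv)
        kw = {"use_bn": spec.use_batchnorm} if spec.family == "resunet" else {}
        self.enc = []
        in_ch = 1
        for i in range(d):
            self.enc.append(block(in_ch, c * 2**i, rng, f"enc{i}", **kw))
            in_ch = c * 2**i
        self.pools = [nn.MaxPool2x2() for _ in range(d)]
        self.bottleneck = block(in_ch, c * 2**d, rng, "bottleneck", **kw)
        self.ups = []
        self.dec = []
        prev = c * 2**d
        for i in reversed(range(d)):
            ci = c * 2**i
            self.ups.append(nn.ConvTranspose2x2(prev, ci, rng, f"up{i}"))
            self.dec.append(block(2 * ci, ci, rng, f"dec{i}", **kw))
            prev = ci
        self.head = nn.Conv2d(c, 1, 1, rng, "head")
        # small-output initialization: starting near zero keeps the first
        # batch-1 Adam steps gentle and avoids whole-network ReLU die-off
        self.head.W.value *= 0.1

    def forward(self, x, train=True):
        n = x.shape[-1]
        if n % (2**self.spec.depth) != 0:
            raise ArchitectureError(
                f"input side {n} not divisible by 2^{self.spec.depth}; "
                f"level {self.spec.depth} cannot pool")
        h = x[None, :, :].astype(nn.DTYPE) if x.ndim == 2 else x.astype(nn.DTYPE)
        skips = []
        for blk, pool in zip(self.enc, self.pools):
            h = blk.forward(h, train)
            skips.append(h)
            h = pool.forward(h)
        h = self.bottleneck.forward(h, train)
        self._split = []
        for up, blk, skip in zip(self.ups, self.dec, reversed(skips)):
            h = up.forward(h)
            self._split.append(skip.shape[0])
            h = np.concatenate([skip, h], axis=0)
            h = blk.forward(h, train)
        out = self.head.forward(h)
        return out[0]

    def backward(self, dout):
        d = dout[None, :, :].astype(nn.DTYPE) if dout.ndim == 2 else dout
        d = self.head.backward(d)
        skip_grads = []
        for up, blk, nsplit in zip(reversed(self.ups), reversed(self.dec),
                                   reversed(self._split)):
            d = blk.backward(d)
            skip_grads.append(d[:nsplit])
            d = up.backward(d[nsplit:])
        d = self.bottleneck.backward(d)
        # skip_grads collected decoder-deepest-last; enc order is shallow->deep
        skip_grads = skip_grads  # index 0 corresponds to enc[-1]... reversed below
        for i, (blk, pool) in enumerate(zip(reversed(self.enc), reversed(self.pools))):
            d = pool.backward(d)
            d = d + skip_grads[len(self.enc) - 1 - i]
            d = blk.backward(d)
        return d[0]

    def params(self):
        out = []
        for blk in self.enc + [self.bottleneck] + self.dec:
            out += blk.params()
        for up in self.ups:
            out += up.params()
        out += self.head.params()
        return out

    def conv_layers(self):
        out = []
        for blk in self.enc + [self.bottleneck] + self.dec:
            out += blk.layers()
        return out


class _CNN3:
    """Three-layer restoration CNN: 9x9/5x5/5x5 kernels, ReLU between."""

    def __init__(self, spec: NetworkSpec, rng: np.random.Generator):
        self.spec = spec
        c = spec.base_channels
        self.c1 = nn.Conv2d(1, 4 * c, 9, rng, "c1")
        self.r1 = nn.ReLU()
        self.c2 = nn.Conv2d(4 * c, 2 * c, 5, rng, "c2")
        self.r2 = nn.ReLU()
        self.c3 = nn.Conv2d(2 * c, 1, 5, rng, "c3")
        self.c3.W.value *= 0.1  # small-output init; see _EncDecNet

    def forward(self, x, train=True):
        h = x[None, :, :].astype(nn.DTYPE) if x.ndim == 2 else x.astype(nn.DTYPE)
        h = self.r1.forward(self.c1.forward(h))
        h = self.r2.forward(self.c2.forward(h))
        return self.c3.forward(h)[0]

    def backward(self, dout):
        d = dout[None, :, :].astype(nn.DTYPE) if dout.ndim == 2 else dout
        d = self.c3.backward(d)
        d = self.c2.backward(self.r2.backward(d))
        d = self.c1.backward(self.r1.backward(d))
        return d[0]

    def params(self):
        return self.c1.params() + self.c2.params() + self.c3.params()

    def conv_layers(self):
        return [self.c1, self.c2, self.c3]


@dataclass
class ReconModel:
    proxy_matrix: MeasurementMatrix
    network: object
    spec: NetworkSpec
    train_history: List[tuple] = field(default_factory=list)
    provenance: Optional[TrainConfig] = None
    #: fixed affine scaling applied to the raw K^T v proxy before the
    #: network (the back-projection has arbitrary scale; see methods note)
    proxy_scale: float = 1.0

    def proxy_image(self, v) -> Phantom:
        ph = proxy(self.proxy_matrix, v)
        ph.pixels = np.clip(ph.pixels * self.proxy_scale, -1.0, 1.0)
        return ph

    def forward(self, v, train=False) -> np.ndarray:
        ph = self.proxy_image(v)
        return self.network.forward(ph.pixels, train)


def build_model(spec: NetworkSpec, matrix: MeasurementMatrix, seed: int) -> ReconModel:
    """Build a reconstruction model with seeded deterministic initialization."""
    n = matrix.grid_side
    if spec.family in ("unet", "resunet") and n % (2**spec.depth) != 0:
        bad = next(l for l in range(1, spec.depth + 1) if (n // 2**(l - 1)) % 2)
        raise ArchitectureError(
            f"grid side {n} is not divisible by 2^{spec.depth}: encoder level "
            f"{bad} would pool an odd side")
    rng = np.random.default_rng(seed)
    net = _CNN3(spec, rng) if spec.family == "cnn3" else _EncDecNet(spec, rng)
    # scale the K^T back-projection so unit-norm images land at O(1)
    # amplitude: 1 / ||K^T K||-ish estimate from a probe image
    probe = np.random.default_rng(seed + 1).uniform(-1, 1, size=(n, n))
    bp = np.real(matrix.entries.conj().T @ (matrix.entries @ probe.ravel()))
    denom = float(np.abs(bp).max())
    scale = 1.0 if denom == 0 else float(np.abs(probe).max()) / denom
    return ReconModel(proxy_matrix=matrix, network=net, spec=spec,
                      proxy_scale=scale)


def train(model: ReconModel, split: DatasetSplit, cfg: TrainConfig) -> ReconModel:
    """Train on (x, v = K x) pairs generated on the fly; l1 loss, Adam/SGD.

    Records the mean per-epoch training loss in ``model.train_history`` and
    returns the model.  Fully reproducible under ``cfg.seed``.
    """
    if not split.train:
        raise InvalidArgumentError("empty training split")
    opt_cls = nn.Adam if cfg.optimizer == "adam" else nn.SGD
    opt = opt_cls(model.network.params(), lr=cfg.learning_rate)
    rng = np.random.default_rng(cfg.seed)
    K = model.proxy_matrix
    pairs = []
    for ph in split.train:
        v = measure(K, ph)
        pairs.append((model.proxy_image(v).pixels.astype(nn.DTYPE),
                      ph.pixels.astype(nn.DTYPE)))
    history = []
    for epoch in range(1, cfg.epochs + 1):
        order = rng.permutation(len(pairs))
        losses = []
        opt.zero_grad()
        in_batch = 0
        for j in order:
            vin, target = pairs[j]
            out = model.network.forward(vin, train=True)
            loss, dgrad = nn.l1_loss_and_grad(out, target)
            if not np.isfinite(loss):
                raise TrainingDivergedError(
                    f"non-finite loss at epoch {epoch}", history=history)
            losses.append(loss)
            model.network.backward(dgrad)
            in_batch += 1
            if in_batch == cfg.batch_size:
                if cfg.batch_size > 1:
                    for p in model.network.params():
                        p.grad /= cfg.batch_size
                opt.step()
                opt.zero_grad()
                in_batch = 0
        if in_batch:  # trailing partial batch
            for p in model.network.params():
                p.grad /= in_batch
            opt.step()
            opt.zero_grad()
        history.append((epoch, float(np.mean(losses))))
    model.train_history.extend(history)
    model.provenance = cfg
    return model


def reconstruct(model: ReconModel, v) -> Phantom:
    """Run inference: proxy -> network -> clamp to [-1, 1]."""
    vals = v.values if isinstance(v, MeasurementVector) else np.asarray(v)
    if vals.shape[0] != model.proxy_matrix.entries.shape[0]:
        raise DimensionMismatchError(
            f"measurement length {vals.shape[0]} != matrix rows "
            f"{model.proxy_matrix.entries.shape[0]}")
    out = model.forward(vals, train=False)
    out = np.clip(np.asarray(out, dtype=np.float64), -1.0, 1.0)
    return Phantom(pixels=out, side_length=model.proxy_matrix.grid_side,
                   label=f"deeppat/{model.spec.family}")


def _evaluate(model: ReconModel, phantoms, method: str, ratio: float,
              include_proxy: bool):
    from .quality_metrics import MetricRecord

    records = []
    for i, ph in enumerate(phantoms):
        v = measure(model.proxy_matrix, ph)
        rec = reconstruct(model, v)
        records.append(MetricRecord(f"img{i}", method, ratio,
                                    ssim(rec, ph), psnr(rec, ph)))
        if include_proxy:
            pimg = model.proxy_image(v)
            records.append(MetricRecord(f"img{i}", "proxy-input", ratio,
                                        ssim(pimg, ph), psnr(pimg, ph)))
    return records


def compare_families(split: DatasetSplit, ratios: Sequence[float],
                     cfgs: Dict[str, TrainConfig], seed: int,
                     specs: Optional[Dict[str, NetworkSpec]] = None,
                     matrix_builder=None) -> AggregateReport:
    """Train one model per (family, ratio) and evaluate on the test split.

    Returns an aggregate including the untrained ``proxy-input`` baseline
    row for every ratio, mirroring the input/CNN/U-Net/ResU-Net comparison
    protocol.
    """
    from .sensing import build_gaussian_matrix

    if not ratios:
        raise InvalidArgumentError("need at least one undersampling ratio")
    specs = specs or DESK_SPECS
    n = split.train[0].side_length
    build = matrix_builder or (lambda ratio, s: build_gaussian_matrix(n, ratio, s))
    records = []
    for ratio in ratios:
        K = build(ratio, seed)
        proxy_done = False
        for family, cfg in cfgs.items():
            model = build_model(specs[family], K, seed)
            cfg_r = replace(cfg, undersampling_ratio=ratio)
            train(model, split, cfg_r)
            records += _evaluate(model, split.test, family, ratio,
                                 include_proxy=not proxy_done)
            proxy_done = True
    return aggregate(records)
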