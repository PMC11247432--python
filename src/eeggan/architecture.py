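"""Model definitions: conditional generator, SE-attention discriminator, classifier.

The generator maps a 101-dimensional input (100-d Gaussian noise plus a
scalar class code) through two fully connected layers, a reshape to a
single-channel sequence of 936 samples, and three stride-1 transposed
convolutions with 64-tap kernels, each adding 63 samples: 936 -> 999 ->
1062 -> 1125.  The output layer has no batch normalization and ends in Tanh,
so generated trials live in (-1, 1) and match tanh-normalized real data.

The discriminator is an EEGNet-style depthwise-separable CNN with a
squeeze-and-excitation (SE) block after the spatial stage: a temporal
convolution (F1 maps, 64 taps, same-padded), a full-height depthwise spatial
filter (depth multiplier D, collapsing the electrode axis), average pooling
by 4, SE recalibration, a separable temporal convolution (F2 maps), pooling
by 8 and a dense head.  Class conditioning enters as one extra time column
carrying an encoded label, hence the (1, C, T+1) input.  Swapping the dense
head for an n_c-way softmax turns the trained discriminator into the
motor-imagery classifier.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from . import nn
from .nn import Tensor

__all__ = [
    "GeneratorConfig",
    "DiscriminatorConfig",
    "LatentBatch",
    "Generator",
    "Discriminator",
    "SEBlock",
    "build_generator",
    "build_discriminator",
    "sample_latent",
    "encode_label",
    "decode_label",
    "condition_input",
    "se_recalibrate",
    "to_classifier",
    "save_checkpoint",
    "load_checkpoint",
]


# ---------------------------------------------------------------------------
# Configs
# ---------------------------------------------------------------------------


@dataclass
class GeneratorConfig:
    out_channels: int = 22
    n_c: int = 4
    latent_dim: int = 100
    label_code_dim: int = 1
    fc_dims: tuple[int, int] = (256, 936)
    deconv_kernel: int = 64
    deconv_stride: int = 1
    deconv_filters: tuple[int, int] = (64, 32)
    out_length: int = 1125
    leaky_slope: float = 0.2

    @property
    def input_dim(self) -> int:
        return self.latent_dim + self.label_code_dim

    def validate(self) -> None:
        # three stride-1 transposed convolutions each add (kernel - 1) samples
        expected = self.fc_dims[-1] + 3 * (self.deconv_kernel - 1)
        if self.deconv_stride != 1:
            raise ValueError("only stride-1 transposed convolutions are supported")
        if expected != self.out_length:
            raise ValueError(
                f"transposed-convolution stack: {self.fc_dims[-1]} + 3*"
                f"({self.deconv_kernel}-1) = {expected} != out_length {self.out_length}"
            )

    def intermediate_lengths(self) -> tuple[int, int, int]:
        k = self.deconv_kernel - 1
        base = self.fc_dims[-1]
        return (base + k, base + 2 * k, base + 3 * k)


@dataclass
class DiscriminatorConfig:
    in_channels: int = 22  # C, EEG electrodes
    input_time: int = 1126  # T+1: trial length plus the label column
    f1: int = 8  # temporal filter count
    depth: int = 2  # depth multiplier D of the spatial stage
    f2: int = 16  # separable filter count
    temporal_kernel: int = 64
    pool1: int = 4
    pool2: int = 8
    dropout_p: float = 0.25
    separable_kernel: int = 16
    se_reduction: int = 8
    head: str = "real_fake"  # or "classifier"
    n_c: int = 4
    use_se: bool = True

    def validate(self) -> None:
        if self.head not in ("real_fake", "classifier"):
            raise ValueError(f"unknown head {self.head!r}")
        if self.depth * self.f1 < 1 or self.f2 < 1:
            raise ValueError("filter counts must be positive")

    @property
    def flatten_size(self) -> int:
        return self.f2 * (self.input_time // (self.pool1 * self.pool2))


@dataclass
class LatentBatch:
    """Conditional generator input: noise vectors plus class labels."""

    z: np.ndarray  # (n, latent_dim)
    labels: np.ndarray  # (n,) in [0, n_c)
    mu: float
    sigma: float
    n_d: int = field(default=0)

    def __post_init__(self):
        if self.n_d == 0:
            self.n_d = self.z.shape[1]


# ---------------------------------------------------------------------------
# Label conditioning
# ---------------------------------------------------------------------------


def encode_label(label, n_c: int) -> np.ndarray:
    """Map integer labels to codes spread evenly over [-1, 1] (the data range)."""
    label = np.asarray(label)
    if np.any((label < 0) | (label >= n_c)):
        raise ValueError(f"labels must lie in [0, {n_c})")
    if n_c == 1:
        return np.zeros_like(label, dtype=np.float64)
    return -1.0 + 2.0 * label.astype(np.float64) / (n_c - 1)


def decode_label(code, n_c: int) -> np.ndarray:
    """Inverse of :func:`encode_label` (nearest valid label)."""
    code = np.asarray(code, dtype=np.float64)
    if n_c == 1:
        return np.zeros(code.shape, dtype=np.int64)
    raw = (code + 1.0) * (n_c - 1) / 2.0
    return np.clip(np.rint(raw), 0, n_c - 1).astype(np.int64)


def condition_input(x: np.ndarray, label, n_c: int) -> np.ndarray:
    """Append one time column carrying the encoded label, broadcast over channels.

    Accepts a single (C, T) trial with an integer label, or a batch
    (n, C, T) with a label vector; returns (C, T+1) or (n, C, T+1).
    """
    x = np.asarray(x, dtype=np.float64)
    single = x.ndim == 2
    xb = x[None] if single else x
    labels = np.atleast_1d(label)
    code = encode_label(labels, n_c)  # (n,)
    col = np.broadcast_to(code[:, None, None], (xb.shape[0], xb.shape[1], 1))
    out = np.concatenate([xb, col], axis=-1)
    return out[0] if single else out


# ---------------------------------------------------------------------------
# Generator
# ---------------------------------------------------------------------------


def _conv_param(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int,
                fan_out: int) -> nn.Parameter:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return nn.Parameter(rng.uniform(-limit, limit, size=shape))


class Generator(nn.Module):
    """Conditional EEG generator; forward maps (n, 101) -> (n, C, 1125)."""

    def __init__(self, cfg: GeneratorConfig, rng: np.random.Generator):
        super().__init__()
        cfg.validate()
        self.cfg = cfg
        d1, d2 = cfg.fc_dims
        k = cfg.deconv_kernel
        g1, g2 = cfg.deconv_filters
        self.fc1 = nn.Linear(cfg.input_dim, d1, rng)
        self.bn1 = nn.BatchNorm(d1)
        self.fc2 = nn.Linear(d1, d2, rng)
        self.bn2 = nn.BatchNorm(d2)
        # transposed-conv weights are (in_channels, out_channels, kernel)
        self.w_deconv1 = _conv_param(rng, (1, g1, k), k, g1 * k)
        self.bn3 = nn.BatchNorm(g1)
        self.w_deconv2 = _conv_param(rng, (g1, g2, k), g1 * k, g2 * k)
        self.bn4 = nn.BatchNorm(g2)
        self.w_out = _conv_param(rng, (g2, cfg.out_channels, k), g2 * k,
                                 cfg.out_channels * k)

    def forward(self, x: Tensor) -> Tensor:
        s = self.cfg.leaky_slope
        h = self.bn1(self.fc1(x)).leaky_relu(s)
        h = self.bn2(self.fc2(h)).leaky_relu(s)
        h = h.reshape(h.shape[0], 1, self.cfg.fc_dims[1])
        h = self.bn3(nn.conv_transpose1d(h, self.w_deconv1)).leaky_relu(s)
        h = self.bn4(nn.conv_transpose1d(h, self.w_deconv2)).leaky_relu(s)
        return nn.conv_transpose1d(h, self.w_out).tanh()  # no batchnorm on output

    def generate(self, batch: LatentBatch) -> Tensor:
        """Generate trials from a latent batch (noise + labels)."""
        code = encode_label(batch.labels, self.cfg.n_c)[:, None]
        x = Tensor(np.concatenate([batch.z, code], axis=1))
        return self.forward(x)

    def trace_shapes(self, n: int = 1) -> list[tuple[str, tuple[int, ...]]]:
        """Analytic per-layer output shapes (for structural verification)."""
        cfg = self.cfg
        l1, l2, l3 = cfg.intermediate_lengths()
        g1, g2 = cfg.deconv_filters
        return [
            ("input", (n, cfg.input_dim)),
            ("linear1", (n, cfg.fc_dims[0])),
            ("linear2", (n, cfg.fc_dims[1])),
            ("reshape", (n, 1, cfg.fc_dims[1])),
            ("deconv1", (n, g1, l1)),
            ("deconv2", (n, g2, l2)),
            ("output", (n, cfg.out_channels, l3)),
        ]


def build_generator(cfg: GeneratorConfig, seed: int = 0) -> Generator:
    return Generator(cfg, np.random.default_rng(seed))


def sample_latent(
    n: int,
    stats: tuple[float, float] | np.ndarray,
    n_c: int,
    seed: int | np.random.Generator = 0,
    latent_dim: int = 100,
) -> LatentBatch:
    """Draw n latent vectors ~ N(mu, sigma^2) with uniform random class labels.

    `stats` is either a (mu, sigma) pair or an array of preprocessed training
    data from which the pair is estimated.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if isinstance(stats, tuple):
        mu, sigma = stats
    else:
        arr = np.asarray(stats)
        mu, sigma = float(arr.mean()), float(arr.std())
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    z = rng.normal(mu, sigma, size=(n, latent_dim))
    labels = rng.integers(0, n_c, size=n)
    return LatentBatch(z, labels, mu, sigma, latent_dim)


# ---------------------------------------------------------------------------
# SE block and discriminator
# ---------------------------------------------------------------------------


class SEBlock(nn.Module):
    """Squeeze-and-excitation gate over feature maps.

    Squeeze: global average over the time extent of each map.  Excitation:
    bottleneck of width max(K // reduction, 1) with ReLU, then a sigmoid gate
    in (0, 1) that rescales each map.
    """

    def __init__(self, n_maps: int, reduction: int, rng: np.random.Generator):
        super().__init__()
        hidden = max(n_maps // reduction, 1)
        self.fc1 = nn.Linear(n_maps, hidden, rng)
        self.fc2 = nn.Linear(hidden, n_maps, rng)

    def forward(self, x: Tensor) -> Tensor:
        # x: (n, K, L)
        squeezed = x.mean(axis=-1)  # (n, K)
        gate = self.fc2(self.fc1(squeezed).relu()).sigmoid()  # (n, K)
        return x * gate.reshape(x.shape[0], x.shape[1], 1)


def se_recalibrate(features, block: SEBlock | None = None, reduction: int = 8,
                   seed: int = 0) -> np.ndarray | Tensor:
    """Apply SE recalibration to (n, K, 1, L) or (n, K, L) feature maps.

    A fresh randomly initialized block is created when none is given (useful
    for probing the op in isolation); pass a trained block otherwise.
    """
    arr = features if isinstance(features, Tensor) else Tensor(np.asarray(features))
    squeeze_4d = arr.ndim == 4
    if squeeze_4d:
        n, k, one, length = arr.shape
        arr = arr.reshape(n, k, length)
    if block is None:
        block = SEBlock(arr.shape[1], reduction, np.random.default_rng(seed))
    out = block(arr)
    if squeeze_4d:
        out = out.reshape(n, k, 1, length)
    return out if isinstance(features, Tensor) else out.data


class Discriminator(nn.Module):
    """EEGNet-style CNN with SE attention; real/fake or n_c-way head.

    The convolutional body is time-length agnostic; only the flatten-to-head
    weights depend on the configured input_time.
    """

    def __init__(self, cfg: DiscriminatorConfig, rng: np.random.Generator):
        super().__init__()
        cfg.validate()
        self.cfg = cfg
        f1, d, f2 = cfg.f1, cfg.depth, cfg.f2
        kt, ks = cfg.temporal_kernel, cfg.separable_kernel
        self.w_temporal = _conv_param(rng, (f1, 1, kt), kt, f1 * kt)
        self.bn1 = nn.BatchNorm(f1)
        self.w_spatial = _conv_param(rng, (f1, d, cfg.in_channels),
                                     cfg.in_channels, d * cfg.in_channels)
        self.bn2 = nn.BatchNorm(d * f1)
        self.drop1 = nn.Dropout(cfg.dropout_p, rng)
        self.se = SEBlock(d * f1, cfg.se_reduction, rng) if cfg.use_se else None
        self.w_sep_dw = _conv_param(rng, (d * f1, ks), ks, ks)
        self.w_sep_pw = _conv_param(rng, (d * f1, f2), d * f1, f2)
        self.bn3 = nn.BatchNorm(f2)
        self.drop2 = nn.Dropout(cfg.dropout_p, rng)
        n_out = 1 if cfg.head == "real_fake" else cfg.n_c
        self.head = nn.Linear(cfg.flatten_size, n_out, rng)

    # body: everything up to and including the flatten
    def features(self, x: Tensor) -> Tensor:
        cfg = self.cfg
        n, c, length = x.shape
        if length != cfg.input_time:
            raise ValueError(
                f"input time length {length} != configured {cfg.input_time}"
            )
        kt = cfg.temporal_kernel
        # temporal convolution, same-padded, applied per electrode row
        h = x.reshape(n * c, 1, length)
        h = nn.conv1d(h, self.w_temporal, pad=((kt - 1) // 2, kt // 2))
        h = h.reshape(n, c, cfg.f1, length).transpose(0, 2, 1, 3)  # (n, F1, C, L)
        h = self.bn1(h)
        h = nn.spatial_filter(h, self.w_spatial)  # (n, D*F1, L)
        h = self.bn2(h).elu()
        h = nn.avg_pool1d(h, cfg.pool1)
        h = self.drop1(h)
        if self.se is not None:
            h = self.se(h)
        ks = cfg.separable_kernel
        h = nn.dwconv1d(h, self.w_sep_dw, pad=((ks - 1) // 2, ks // 2))
        # pointwise 1x1 mixing into F2 maps
        nb, km, lm = h.shape
        h = h.transpose(0, 2, 1).reshape(nb * lm, km) @ self.w_sep_pw
        h = h.reshape(nb, lm, cfg.f2).transpose(0, 2, 1)  # (n, F2, L//4)
        h = self.bn3(h).elu()
        h = nn.avg_pool1d(h, cfg.pool2)
        h = self.drop2(h)
        return h.reshape(nb, cfg.f2 * (lm // cfg.pool2))

    def forward(self, x: Tensor, return_features: bool = False):
        feats = self.features(x)
        out = self.head(feats)
        if self.cfg.head == "real_fake":
            out = out.reshape(out.shape[0]).sigmoid()
        if return_features:
            return out, feats
        return out

    def predict_log_proba(self, x: Tensor) -> Tensor:
        if self.cfg.head != "classifier":
            raise ValueError("predict_log_proba requires the classifier head")
        return nn.log_softmax(self.head(self.features(x)), axis=-1)

    def trace_shapes(self, n: int = 1) -> list[tuple[str, tuple[int, ...]]]:
        """Analytic per-layer output shapes (for structural verification)."""
        cfg = self.cfg
        c, L = cfg.in_channels, cfg.input_time
        f1, df1, f2 = cfg.f1, cfg.depth * cfg.f1, cfg.f2
        l4, l32 = L // cfg.pool1, L // (cfg.pool1 * cfg.pool2)
        rows = [
            ("input", (n, 1, c, L)),
            ("conv2d", (n, f1, c, L)),
            ("depthwise", (n, df1, 1, L)),
            ("avgpool1", (n, df1, 1, l4)),
            ("se", (n, df1, 1, l4)),
            ("separable", (n, f2, 1, l4)),
            ("avgpool2", (n, f2, 1, l32)),
            ("flatten", (n, f2 * l32)),
            ("head", (n, 1 if cfg.head == "real_fake" else cfg.n_c)),
        ]
        return rows


def build_discriminator(cfg: DiscriminatorConfig, seed: int = 0) -> Discriminator:
    return Discriminator(cfg, np.random.default_rng(seed))


def to_classifier(
    disc: Discriminator,
    n_c: int,
    input_time: int | None = None,
    share_body: bool = True,
    seed: int = 0,
) -> Discriminator:
    """Swap the discriminator's real/fake head for an n_c-way classifier head.

    The convolutional body is reused: by reference when ``share_body`` (the
    classifier fine-tunes the trained discriminator), otherwise as a deep
    copy.  ``input_time`` may differ from the discriminator's (e.g. crop
    windows without the label column); only the new head depends on it.
    """
    cfg = DiscriminatorConfig(**{**asdict(disc.cfg), "head": "classifier",
                                 "n_c": n_c,
                                 "input_time": input_time or disc.cfg.input_time})
    rng = np.random.default_rng(seed)
    clf = Discriminator(cfg, rng)
    body_params = dict(disc.named_parameters())
    for name, p in clf.named_parameters():
        if name.startswith("head."):
            continue
        src = body_params[name]
        p.data = src.data if share_body else src.data.copy()
        if share_body:
            # share the Parameter objects so further training updates both
            _assign_param(clf, name, src)
    # carry over batch-norm running statistics
    src_state = disc.state_dict()
    for name in list(clf.state_dict()):
        if name.startswith("head.") or name in dict(clf.named_parameters()):
            continue
        _assign_buffer(clf, name, src_state[name] if share_body else src_state[name].copy())
    return clf


def _assign_param(module: nn.Module, dotted: str, param: nn.Parameter) -> None:
    parts = dotted.split(".")
    obj = module
    for part in parts[:-1]:
        obj = getattr(obj, part)
    setattr(obj, parts[-1], param)


def _assign_buffer(module: nn.Module, dotted: str, value: np.ndarray) -> None:
    parts = dotted.split(".")
    obj = module
    for part in parts[:-1]:
        obj = getattr(obj, part)
    obj._buffers[parts[-1]] = value


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

_MODEL_CLASSES = {
    "generator": (Generator, GeneratorConfig),
    "discriminator": (Discriminator, DiscriminatorConfig),
}


def save_checkpoint(path, model: nn.Module) -> None:
    """Serialize model weights plus embedded config as an NPZ bundle."""
    kind = "generator" if isinstance(model, Generator) else "discriminator"
    meta = json.dumps({"kind": kind, "config": asdict(model.cfg)})
    state = model.state_dict()
    np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8), **state)


def load_checkpoint(path) -> nn.Module:
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(bytes(z["__meta__"].tobytes()).decode())
        state = {k: z[k] for k in z.files if k != "__meta__"}
    cls, cfg_cls = _MODEL_CLASSES[meta["kind"]]
    cfg_dict = meta["config"]
    for key in ("fc_dims", "deconv_filters"):
        if key in cfg_dict:
            cfg_dict[key] = tuple(cfg_dict[key])
    model = cls(cfg_cls(**cfg_dict), np.random.default_rng(0))
    model.load_state_dict(state)
    return model.eval()
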