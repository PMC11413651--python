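"""SFCN-style volumetric encoder plus disease and scanner heads.

The encoder is the lightweight fully convolutional stack commonly used for
3D brain-scan classification: five blocks of [3x3x3 conv, batch norm, 2x2x2
max pool, ReLU], one block of [1x1x1 conv, batch norm, ReLU], then an
average-pool / dropout / flatten tail.  For the full-resolution input of
160 x 192 x 160 voxels with the canonical channel widths the flattened
feature vector has exactly 768 entries (5x6x5 spatial cells halve to 2x3x2
under the kernel-2 average pool, times 64 channels).

Two heads share the feature vector: a single dense unit with sigmoid output
for the binary disease label, and a dense layer with softmax output over the
M scanner types that serves as the adversary during harmonization.

Pooling uses floor division on odd extents, and any axis whose extent has
already collapsed to 1 passes through both pool types unchanged, so the same
block stack runs on desk-scale volumes (e.g. 24^3) as well.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from . import nn

DEFAULT_WIDTHS = (32, 64, 128, 256, 256, 64)

__all__ = [
    "EncoderConfig",
    "ScannerLabelSpace",
    "ModelBundle",
    "feature_length",
    "build_bundle",
    "forward_features",
    "predict_disease",
    "predict_scanner",
    "save_bundle",
    "load_bundle",
]


@dataclass(frozen=True)
class EncoderConfig:
    """Architecture of the volumetric encoder.

    Parameters
    ----------
    input_shape
        Spatial extents (D, H, W) of the input volumes; each must be >= 1.
    channel_widths
        Output channels of the six convolutional blocks.
    dropout_rate
        Dropout probability in the flattening tail (default 0.2).
    avgpool_kernel
        Kernel (= stride) of the tail average pool; axes smaller than the
        kernel pass through unchanged.
    """

    input_shape: tuple = (160, 192, 160)
    channel_widths: tuple = DEFAULT_WIDTHS
    dropout_rate: float = 0.2
    avgpool_kernel: int = 2
    normalize: str = "none"  # "none" | "zscore": per-volume input scaling

    def __post_init__(self):
        if len(self.channel_widths) != 6:
            raise ValueError("exactly six channel widths are required")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if len(self.input_shape) != 3 or any(int(e) < 1 for e in self.input_shape):
            raise ValueError("input_shape must be three positive extents")
        if self.normalize not in ("none", "zscore"):
            raise ValueError("normalize must be 'none' or 'zscore'")


@dataclass(frozen=True)
class ScannerLabelSpace:
    """The global pool of M scanner types shared by all centers."""

    names: tuple

    @classmethod
    def of_size(cls, m: int) -> "ScannerLabelSpace":
        if m < 2:
            raise ValueError("need at least two scanner types")
        return cls(tuple(f"scanner_{i}" for i in range(m)))

    @property
    def M(self) -> int:
        return len(self.names)

    @property
    def ids(self) -> np.ndarray:
        return np.arange(self.M)


def _pooled_extents(config: EncoderConfig) -> tuple:
    """Spatial extents after the five max pools and the tail average pool."""
    extents = [int(e) for e in config.input_shape]
    for _ in range(5):  # conv3 is 'same'; each max pool floors extents >= 2
        nxt = []
        for e in extents:
            if e < 1:
                raise ValueError("spatial extent collapsed below 1")
            nxt.append(e // 2 if e >= 2 else e)
        extents = nxt
    k = config.avgpool_kernel
    extents = [e // k if e >= k else e for e in extents]
    if any(e < 1 for e in extents):
        raise ValueError("spatial extent reached 0 in the pooling chain")
    return tuple(extents)


def feature_length(config: EncoderConfig) -> int:
    """Length of the flattened encoder output for a given configuration."""
    extents = _pooled_extents(config)
    return int(np.prod(extents)) * int(config.channel_widths[-1])


@dataclass
class ModelBundle:
    """Encoder + disease head + scanner head with shared feature width.

    Batch-norm statistics live inside the encoder and travel with the bundle
    between centers: there is a single shared model state, exactly as a
    sequentially transferred model would carry it.
    """

    config: EncoderConfig
    label_space: ScannerLabelSpace
    encoder: nn.Sequential
    disease_head: nn.Dense
    scanner_head: nn.Dense
    feature_length: int
    rng: np.random.Generator = field(repr=False, default=None)

    # -- parameter-group views used by the per-step optimizers ------------
    def encoder_params(self):
        return {f"enc.{k}": v for k, v in self.encoder.params().items()}

    def encoder_grads(self):
        return {f"enc.{k}": v for k, v in self.encoder.grads().items()}

    def disease_params(self):
        return {f"dis.{k}": v for k, v in self.disease_head.params().items()}

    def disease_grads(self):
        return {f"dis.{k}": v for k, v in self.disease_head.grads().items()}

    def scanner_params(self):
        return {f"sca.{k}": v for k, v in self.scanner_head.params().items()}

    def scanner_grads(self):
        return {f"sca.{k}": v for k, v in self.scanner_head.grads().items()}

    def state_dict(self) -> dict:
        state = dict(self.encoder_params())
        state.update({f"encbuf.{k}": v for k, v in self.encoder.buffers().items()})
        state.update(self.disease_params())
        state.update(self.scanner_params())
        return state

    def snapshot(self) -> dict:
        return {k: v.copy() for k, v in self.state_dict().items()}

    def clone(self) -> "ModelBundle":
        return copy.deepcopy(self)


def build_bundle(config: EncoderConfig, label_space: ScannerLabelSpace,
                 seed: int = 0, dtype=np.float32) -> ModelBundle:
    """Construct a freshly initialised model (He init, seeded)."""
    rng = np.random.default_rng(seed)
    w = config.channel_widths
    layers = []
    in_ch = 1
    for i in range(5):
        layers += [
            nn.Conv3d(in_ch, w[i], 3, rng, dtype=dtype, needs_input_grad=i > 0),
            nn.BatchNorm3d(w[i], dtype=dtype),
            nn.MaxPool3d(),
            nn.ReLU(),
        ]
        in_ch = w[i]
    layers += [
        nn.Conv3d(in_ch, w[5], 1, rng, dtype=dtype),
        nn.BatchNorm3d(w[5], dtype=dtype),
        nn.ReLU(),
    ]
    # the pool itself passes extent-1 axes through, matching feature_length
    layers.append(nn.AvgPool3d(config.avgpool_kernel))
    dropout = nn.Dropout(config.dropout_rate)
    dropout.rng = np.random.default_rng(np.random.SeedSequence([seed, 7]))
    layers += [dropout, nn.Flatten()]
    encoder = nn.Sequential(layers)
    flen = feature_length(config)
    disease_head = nn.Dense(flen, 1, rng, dtype=dtype)
    scanner_head = nn.Dense(flen, label_space.M, rng, dtype=dtype)
    return ModelBundle(config=config, label_space=label_space, encoder=encoder,
                       disease_head=disease_head, scanner_head=scanner_head,
                       feature_length=flen, rng=rng)


def _as_batch(volumes, config: EncoderConfig) -> np.ndarray:
    x = np.asarray(volumes, dtype=np.float32)
    if x.ndim == 3:
        x = x[None]
    if x.ndim != 4 or x.shape[1:] != tuple(config.input_shape):
        raise ValueError(
            f"volumes of shape {x.shape[1:]} do not match input_shape "
            f"{tuple(config.input_shape)}")
    if config.normalize == "zscore":
        # per-volume standardisation, the usual first step of volumetric CNN
        # pipelines; removes global intensity gain/offset at the input
        flat = x.reshape(len(x), -1)
        mu = flat.mean(axis=1).reshape(-1, 1, 1, 1)
        sd = flat.std(axis=1).reshape(-1, 1, 1, 1)
        x = (x - mu) / np.maximum(sd, 1e-6)
    return x[:, None]  # single intensity channel


def forward_features(bundle: ModelBundle, volumes, train: bool = False) -> np.ndarray:
    """Encode a batch of volumes into the (N, feature_length) matrix.

    Evaluation mode (``train=False``) uses running batch-norm statistics and
    disables dropout, so it is deterministic for fixed parameters.
    """
    x = _as_batch(volumes, bundle.config)
    feats = bundle.encoder.forward(x, train=train)
    if feats.shape[1] != bundle.feature_length:
        raise RuntimeError("encoder output width disagrees with feature_length")
    return feats


def predict_disease(bundle: ModelBundle, features: np.ndarray) -> np.ndarray:
    """Sigmoid disease probability per feature row."""
    features = np.asarray(features)
    if features.shape[1] != bundle.feature_length:
        raise ValueError("feature width mismatch")
    logits = bundle.disease_head.forward(features)[:, 0]
    return 1.0 / (1.0 + np.exp(-logits))


def predict_scanner(bundle: ModelBundle, features: np.ndarray) -> np.ndarray:
    """Row-stochastic softmax over the M scanner types."""
    features = np.asarray(features)
    if features.shape[1] != bundle.feature_length:
        raise ValueError("feature width mismatch")
    logits = bundle.scanner_head.forward(features)
    if logits.shape[1] != bundle.label_space.M:
        raise ValueError("scanner head width disagrees with label space")
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def save_bundle(bundle: ModelBundle, path) -> None:
    """Single-file parameter archive (.npz) of all weights and buffers."""
    meta = dict(
        input_shape=np.asarray(bundle.config.input_shape),
        channel_widths=np.asarray(bundle.config.channel_widths),
        dropout_rate=np.asarray(bundle.config.dropout_rate),
        avgpool_kernel=np.asarray(bundle.config.avgpool_kernel),
        normalize=np.asarray(bundle.config.normalize),
        n_scanners=np.asarray(bundle.label_space.M),
    )
    state = {f"state/{k}": v for k, v in bundle.state_dict().items()}
    np.savez(path, **meta, **state)


def load_bundle(path) -> ModelBundle:
    with np.load(path) as archive:
        config = EncoderConfig(
            input_shape=tuple(int(v) for v in archive["input_shape"]),
            channel_widths=tuple(int(v) for v in archive["channel_widths"]),
            dropout_rate=float(archive["dropout_rate"]),
            avgpool_kernel=int(archive["avgpool_kernel"]),
            normalize=str(archive["normalize"]) if "normalize" in archive.files
            else "none",
        )
        space = ScannerLabelSpace.of_size(int(archive["n_scanners"]))
        bundle = build_bundle(config, space, seed=0)
        state = {k[len("state/"):]: archive[k]
                 for k in archive.files if k.startswith("state/")}
    _load_state(bundle, state)
    return bundle


def _load_state(bundle: ModelBundle, state: dict) -> None:
    enc = {k[len("enc."):]: v for k, v in state.items() if k.startswith("enc.")}
    buf = {k[len("encbuf."):]: v for k, v in state.items() if k.startswith("encbuf.")}
    bundle.encoder.set_params(enc)
    bundle.encoder.set_buffers(buf)
    for key, v in state.items():
        if key.startswith("dis."):
            getattr(bundle.disease_head, key.split(".", 1)[1])[...] = v
        elif key.startswith("sca."):
            getattr(bundle.scanner_head, key.split(".", 1)[1])[...] = v
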