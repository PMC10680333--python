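"""The four neural architectures, parameter accounting and model bundles.

All four models map a left-padded integer-encoded tool sequence to a vector
of per-tool sigmoid scores (multi-class, multi-label classification):

* **transformer** — token embedding plus learned positional embedding, one
  encoder block (4-head self-attention with 128-dimensional heads, residual
  + layer norm, a two-layer 128-unit position-wise feed-forward network,
  residual + layer norm), the final-position representation, a 128-unit
  relu dense layer and a sigmoid output layer;
* **rnn** — embedding, two stacked 128-unit GRU layers, sigmoid output;
* **cnn** — embedding viewed as a (N x d_model) single-channel image, a
  128-filter 16x3 valid convolution with relu, 2x2 max pooling, flatten,
  128-unit dense, sigmoid output;
* **dnn** — embedding, flatten, two 128-unit relu dense layers, sigmoid
  output.

Every architecture has a closed-form trainable-parameter count that the
framework count must match; with the full-scale configuration (2,354 tools,
sequence length 25) the transformer has 922,291, the CNN 5,772,723 and the
DNN 1,031,603 trainable parameters.

A saved model bundle is a single HDF5 container holding weights, the
configuration and the tool vocabulary, so one file is enough to recommend.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict, replace

import h5py
import numpy as np

from . import nn
from .dataset import ToolVocabulary, PAD_INDEX

__all__ = [
    "ModelConfig",
    "ModelBundle",
    "AttentionMap",
    "BundleError",
    "UnsupportedArchitectureError",
    "ARCHITECTURES",
    "config_for_vocabulary",
    "build_model",
    "build_transformer",
    "build_rnn",
    "build_cnn",
    "build_dnn",
    "count_trainable_parameters",
    "parameter_formula",
    "save_bundle",
    "load_bundle",
    "attention_matrix",
]

FORMAT_VERSION = "1"
ARCHITECTURES = ("transformer", "rnn", "cnn", "dnn")


class BundleError(ValueError):
    """Unreadable, corrupt or version-incompatible model bundle."""


class UnsupportedArchitectureError(TypeError):
    pass


@dataclass(frozen=True)
class ModelConfig:
    """Architecture and training hyperparameters.

    Defaults are the full-scale settings: 128-wide embeddings and hidden
    layers, 4 attention heads of dimension 128, dropout 0.2, maximum
    sequence length 25, Adam at learning rate 0.001, batch size 512.
    """

    vocab_in: int
    vocab_out: int
    architecture: str = "transformer"
    d_model: int = 128
    n_heads: int = 4
    head_dim: int = 128
    ffn_dims: tuple[int, int] = (128, 128)
    hidden_dense_dim: int = 128
    dropout_rate: float = 0.2
    max_len: int = 25
    conv_kernel: tuple[int, int] = (16, 3)
    conv_filters: int = 128
    pool: tuple[int, int] = (2, 2)
    gru_units: int = 128
    gru_layers: int = 2
    learning_rate: float = 0.001
    batch_size: int = 512
    iterations: int = 35000

    def __post_init__(self):
        dims = (
            self.vocab_in, self.vocab_out, self.d_model, self.n_heads,
            self.head_dim, *self.ffn_dims, self.hidden_dense_dim,
            self.max_len, *self.conv_kernel, self.conv_filters, *self.pool,
            self.gru_units, self.gru_layers, self.batch_size, self.iterations,
        )
        if any(d <= 0 for d in dims):
            raise ValueError("all model dimensions must be positive")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout rate must lie in [0, 1)")
        if self.architecture not in ARCHITECTURES:
            raise ValueError(f"unknown architecture: {self.architecture!r}")
        if self.architecture == "transformer" and self.ffn_dims[-1] != self.d_model:
            raise ValueError(
                "last feed-forward dimension must equal d_model for the residual"
            )


def config_for_vocabulary(architecture: str, n_tools: int, **overrides) -> ModelConfig:
    """Full-scale config for a vocabulary of ``n_tools`` real tools.

    The output dimension is V+1 (index 0 is the unused padding slot).  The
    embedding input dimension is V+1 for the transformer and RNN and V+2
    for the CNN and DNN, which carry one extra reserved embedding row.
    """
    if architecture not in ARCHITECTURES:
        raise UnsupportedArchitectureError(f"unknown architecture: {architecture!r}")
    extra = 2 if architecture in ("cnn", "dnn") else 1
    return ModelConfig(
        vocab_in=n_tools + extra,
        vocab_out=n_tools + 1,
        architecture=architecture,
        **overrides,
    )


# -- models ----------------------------------------------------------------


class _Model:
    """Common machinery: an ordered parameter table and prediction."""

    arch: str = ""

    def __init__(self, config: ModelConfig):
        self.config = config
        self.params: dict[str, nn.Tensor] = {}

    def _param(self, name: str, data) -> nn.Tensor:
        t = nn.parameter(data)
        self.params[name] = t
        return t

    def parameters(self) -> list[nn.Tensor]:
        return list(self.params.values())

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.params.values())

    def forward(self, ids: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None) -> nn.Tensor:
        raise NotImplementedError

    def predict(self, ids: np.ndarray) -> np.ndarray:
        """Sigmoid scores, shape (batch, vocab_out); values in (0, 1)."""
        ids = np.atleast_2d(np.asarray(ids, dtype=np.int64))
        logits = self.forward(ids, train=False).data
        return 1.0 / (1.0 + np.exp(-np.clip(logits, -500, 500)))


class TransformerModel(_Model):
    arch = "transformer"

    def __init__(self, config: ModelConfig, seed: int = 0):
        super().__init__(config)
        c = config
        rng = np.random.default_rng(seed)
        d, h, hd = c.d_model, c.n_heads, c.head_dim
        proj = h * hd
        emb_init = lambda shape: rng.uniform(-0.05, 0.05, size=shape)
        self._param("tok_emb", emb_init((c.vocab_in, d)))
        self._param("pos_emb", emb_init((c.max_len, d)))
        for nm in ("wq", "wk", "wv"):
            self._param(nm, nn.glorot_uniform(rng, (d, proj)))
            self._param(nm + "_b", np.zeros(proj))
        self._param("wo", nn.glorot_uniform(rng, (proj, d)))
        self._param("wo_b", np.zeros(d))
        self._param("ln1_g", np.ones(d))
        self._param("ln1_b", np.zeros(d))
        f1, f2 = c.ffn_dims
        self._param("ffn_w1", nn.glorot_uniform(rng, (d, f1)))
        self._param("ffn_b1", np.zeros(f1))
        self._param("ffn_w2", nn.glorot_uniform(rng, (f1, f2)))
        self._param("ffn_b2", np.zeros(f2))
        self._param("ln2_g", np.ones(d))
        self._param("ln2_b", np.zeros(d))
        self._param("wh", nn.glorot_uniform(rng, (d, c.hidden_dense_dim)))
        self._param("wh_b", np.zeros(c.hidden_dense_dim))
        self._param("wout", nn.glorot_uniform(rng, (c.hidden_dense_dim, c.vocab_out)))
        self._param("wout_b", np.zeros(c.vocab_out))
        self.last_attention: np.ndarray | None = None
        self.last_key_mask: np.ndarray | None = None

    def forward(self, ids, train=False, rng=None):
        c = self.config
        p = self.params
        drop_rng = rng if train else None
        b, n_len = ids.shape
        h, hd = c.n_heads, c.head_dim
        key_mask = ids != PAD_INDEX  # (B, N)

        x = nn.add(nn.embedding(p["tok_emb"], ids), p["pos_emb"])
        x = nn.dropout(x, c.dropout_rate, drop_rng)

        def heads(w, bias):
            y = nn.add(nn.matmul(x, w), bias)  # (B, N, H*hd)
            return nn.transpose(nn.reshape(y, (b, n_len, h, hd)), (0, 2, 1, 3))

        q = heads(p["wq"], p["wq_b"])
        k = heads(p["wk"], p["wk_b"])
        v = heads(p["wv"], p["wv_b"])
        scores = nn.mul(
            nn.matmul(q, nn.transpose(k, (0, 1, 3, 2))),
            nn.constant(1.0 / math.sqrt(hd)),
        )  # (B, H, N, N)
        attn = nn.masked_softmax(scores, key_mask[:, None, None, :])
        self.last_attention = attn.data.copy()
        self.last_key_mask = key_mask.copy()
        ctx = nn.reshape(
            nn.transpose(nn.matmul(attn, v), (0, 2, 1, 3)), (b, n_len, h * hd)
        )
        a_out = nn.add(nn.matmul(ctx, p["wo"]), p["wo_b"])
        a_out = nn.dropout(a_out, c.dropout_rate, drop_rng)
        x = nn.layer_norm(nn.add(x, a_out), p["ln1_g"], p["ln1_b"])

        f = nn.relu(nn.add(nn.matmul(x, p["ffn_w1"]), p["ffn_b1"]))
        f = nn.add(nn.matmul(f, p["ffn_w2"]), p["ffn_b2"])
        f = nn.dropout(f, c.dropout_rate, drop_rng)
        x = nn.layer_norm(nn.add(x, f), p["ln2_g"], p["ln2_b"])

        pooled = x[:, -1, :]  # most recent position (left-padding)
        hdn = nn.relu(nn.add(nn.matmul(pooled, p["wh"]), p["wh_b"]))
        hdn = nn.dropout(hdn, c.dropout_rate, drop_rng)
        return nn.add(nn.matmul(hdn, p["wout"]), p["wout_b"])


class RnnModel(_Model):
    arch = "rnn"

    def __init__(self, config: ModelConfig, seed: int = 0):
        super().__init__(config)
        c = config
        rng = np.random.default_rng(seed)
        d, u = c.d_model, c.gru_units
        self._param("tok_emb", rng.uniform(-0.05, 0.05, size=(c.vocab_in, d)))
        in_dim = d
        for i in range(c.gru_layers):
            self._param(f"gru{i}_w", nn.glorot_uniform(rng, (in_dim, 3 * u)))
            self._param(f"gru{i}_u", nn.glorot_uniform(rng, (u, 3 * u)))
            self._param(f"gru{i}_b", np.zeros((2, 3 * u)))
            in_dim = u
        self._param("wout", nn.glorot_uniform(rng, (u, c.vocab_out)))
        self._param("wout_b", np.zeros(c.vocab_out))

    def forward(self, ids, train=False, rng=None):
        c = self.config
        p = self.params
        drop_rng = rng if train else None
        x = nn.embedding(p["tok_emb"], ids)
        x = nn.dropout(x, c.dropout_rate, drop_rng)
        for i in range(c.gru_layers):
            last_layer = i == c.gru_layers - 1
            x = nn.gru_layer(
                x, p[f"gru{i}_w"], p[f"gru{i}_u"], p[f"gru{i}_b"],
                return_sequences=not last_layer,
            )
        x = nn.dropout(x, c.dropout_rate, drop_rng)
        return nn.add(nn.matmul(x, p["wout"]), p["wout_b"])


class CnnModel(_Model):
    arch = "cnn"

    def __init__(self, config: ModelConfig, seed: int = 0):
        super().__init__(config)
        c = config
        rng = np.random.default_rng(seed)
        kh, kw = c.conv_kernel
        if c.max_len < kh or c.d_model < kw:
            raise ValueError("convolution kernel larger than the input plane")
        self._param("tok_emb", rng.uniform(-0.05, 0.05, size=(c.vocab_in, c.d_model)))
        self._param(
            "conv_k",
            nn.glorot_uniform(
                rng, (kh, kw, 1, c.conv_filters), fan_in=kh * kw, fan_out=c.conv_filters
            ),
        )
        self._param("conv_b", np.zeros(c.conv_filters))
        flat = self.flat_dim(c)
        self._param("wh", nn.glorot_uniform(rng, (flat, c.hidden_dense_dim)))
        self._param("wh_b", np.zeros(c.hidden_dense_dim))
        self._param("wout", nn.glorot_uniform(rng, (c.hidden_dense_dim, c.vocab_out)))
        self._param("wout_b", np.zeros(c.vocab_out))

    @staticmethod
    def flat_dim(c: ModelConfig) -> int:
        kh, kw = c.conv_kernel
        ph, pw = c.pool
        h = (c.max_len - kh + 1) // ph
        w = (c.d_model - kw + 1) // pw
        if h < 1 or w < 1:
            raise ValueError("pooled convolution output has an empty dimension")
        return h * w * c.conv_filters

    def forward(self, ids, train=False, rng=None):
        c = self.config
        p = self.params
        drop_rng = rng if train else None
        b = ids.shape[0]
        x = nn.embedding(p["tok_emb"], ids)
        x = nn.dropout(x, c.dropout_rate, drop_rng)
        x = nn.reshape(x, (b, c.max_len, c.d_model, 1))
        x = nn.relu(nn.conv2d_valid(x, p["conv_k"], p["conv_b"]))
        x = nn.maxpool2d(x, c.pool)
        x = nn.reshape(x, (b, -1))
        h = nn.relu(nn.add(nn.matmul(x, p["wh"]), p["wh_b"]))
        h = nn.dropout(h, c.dropout_rate, drop_rng)
        return nn.add(nn.matmul(h, p["wout"]), p["wout_b"])


class DnnModel(_Model):
    arch = "dnn"

    def __init__(self, config: ModelConfig, seed: int = 0):
        super().__init__(config)
        c = config
        rng = np.random.default_rng(seed)
        self._param("tok_emb", rng.uniform(-0.05, 0.05, size=(c.vocab_in, c.d_model)))
        flat = c.max_len * c.d_model
        f1, f2 = c.ffn_dims
        self._param("w1", nn.glorot_uniform(rng, (flat, f1)))
        self._param("b1", np.zeros(f1))
        self._param("w2", nn.glorot_uniform(rng, (f1, f2)))
        self._param("b2", np.zeros(f2))
        self._param("wout", nn.glorot_uniform(rng, (f2, c.vocab_out)))
        self._param("wout_b", np.zeros(c.vocab_out))

    def forward(self, ids, train=False, rng=None):
        c = self.config
        p = self.params
        drop_rng = rng if train else None
        b = ids.shape[0]
        x = nn.embedding(p["tok_emb"], ids)
        x = nn.dropout(x, c.dropout_rate, drop_rng)
        x = nn.reshape(x, (b, -1))
        h = nn.relu(nn.add(nn.matmul(x, p["w1"]), p["b1"]))
        h = nn.dropout(h, c.dropout_rate, drop_rng)
        h = nn.relu(nn.add(nn.matmul(h, p["w2"]), p["b2"]))
        h = nn.dropout(h, c.dropout_rate, drop_rng)
        return nn.add(nn.matmul(h, p["wout"]), p["wout_b"])


_MODEL_CLASSES = {
    "transformer": TransformerModel,
    "rnn": RnnModel,
    "cnn": CnnModel,
    "dnn": DnnModel,
}


def build_model(config: ModelConfig, seed: int = 0) -> _Model:
    return _MODEL_CLASSES[config.architecture](config, seed=seed)


def build_transformer(config: ModelConfig, seed: int = 0) -> TransformerModel:
    return TransformerModel(replace(config, architecture="transformer"), seed=seed)


def build_rnn(config: ModelConfig, seed: int = 0) -> RnnModel:
    return RnnModel(replace(config, architecture="rnn"), seed=seed)


def build_cnn(config: ModelConfig, seed: int = 0) -> CnnModel:
    return CnnModel(replace(config, architecture="cnn"), seed=seed)


def build_dnn(config: ModelConfig, seed: int = 0) -> DnnModel:
    return DnnModel(replace(config, architecture="dnn"), seed=seed)


# -- parameter accounting --------------------------------------------------


def count_trainable_parameters(model: _Model) -> int:
    """Sum of sizes of all trainable tensors."""
    return model.n_parameters()


def _transformer_formula(c: ModelConfig) -> int:
    d, proj = c.d_model, c.n_heads * c.head_dim
    f1, f2 = c.ffn_dims
    total = c.vocab_in * d + c.max_len * d  # token + positional embeddings
    total += 3 * (d * proj + proj) + (proj * d + d)  # q, k, v, output proj
    total += 2 * 2 * d  # two layer norms (gain + bias)
    total += (d * f1 + f1) + (f1 * f2 + f2)  # feed-forward
    total += d * c.hidden_dense_dim + c.hidden_dense_dim  # hidden dense
    total += c.hidden_dense_dim * c.vocab_out + c.vocab_out  # output
    return total


def _gru_layer_params(in_dim: int, units: int) -> int:
    # reset-after convention: doubled biases, 2 per gate set of 3
    return 3 * (in_dim * units + units * units + 2 * units)


def _rnn_formula(c: ModelConfig) -> int:
    total = c.vocab_in * c.d_model
    in_dim = c.d_model
    for _ in range(c.gru_layers):
        total += _gru_layer_params(in_dim, c.gru_units)
        in_dim = c.gru_units
    total += c.gru_units * c.vocab_out + c.vocab_out
    return total


def _cnn_formula(c: ModelConfig) -> int:
    kh, kw = c.conv_kernel
    total = c.vocab_in * c.d_model
    total += kh * kw * 1 * c.conv_filters + c.conv_filters
    flat = CnnModel.flat_dim(c)
    total += flat * c.hidden_dense_dim + c.hidden_dense_dim
    total += c.hidden_dense_dim * c.vocab_out + c.vocab_out
    return total


def _dnn_formula(c: ModelConfig) -> int:
    f1, f2 = c.ffn_dims
    flat = c.max_len * c.d_model
    total = c.vocab_in * c.d_model
    total += flat * f1 + f1
    total += f1 * f2 + f2
    total += f2 * c.vocab_out + c.vocab_out
    return total


_FORMULAS = {
    "transformer": _transformer_formula,
    "rnn": _rnn_formula,
    "cnn": _cnn_formula,
    "dnn": _dnn_formula,
}


def parameter_formula(config: ModelConfig) -> int:
    """Closed-form trainable-parameter count for a configuration."""
    return _FORMULAS[config.architecture](config)


# -- bundles ---------------------------------------------------------------


@dataclass
class ModelBundle:
    """A loaded model: weights + configuration + vocabulary in one unit."""

    config: ModelConfig
    model: _Model
    vocabulary: ToolVocabulary
    format_version: str = FORMAT_VERSION

    def predict(self, ids: np.ndarray) -> np.ndarray:
        return self.model.predict(ids)


_TUPLE_FIELDS = {"ffn_dims", "conv_kernel", "pool"}


def save_bundle(model: _Model, vocab: ToolVocabulary, path) -> None:
    """Write weights, config and vocabulary into one HDF5 container."""
    if vocab.size + 1 != model.config.vocab_out:
        raise ValueError(
            f"vocabulary size {vocab.size} inconsistent with "
            f"vocab_out {model.config.vocab_out}"
        )
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = FORMAT_VERSION
        wg = f.create_group("weights")
        for name, tensor in model.params.items():
            wg.create_dataset(name, data=tensor.data)
        cg = f.create_group("config")
        for key, value in asdict(model.config).items():
            cg.attrs[key] = (
                np.asarray(value) if key in _TUPLE_FIELDS else value
            )
        names = [vocab.name(i) for i in range(1, vocab.size + 1)]
        f.create_group("vocabulary").create_dataset(
            "names", data=np.array(names, dtype=h5py.string_dtype("utf-8"))
        )


def load_bundle(path) -> ModelBundle:
    """Reconstruct a model bundle; predictions match the saved model bitwise."""
    try:
        f = h5py.File(path, "r")
    except FileNotFoundError:
        raise
    except OSError as exc:
        raise BundleError(f"corrupt or unreadable model bundle {path!s}: {exc}") from exc
    with f:
        version = f.attrs.get("format_version")
        if version != FORMAT_VERSION:
            raise BundleError(
                f"bundle format version {version!r} unsupported "
                f"(expected {FORMAT_VERSION!r})"
            )
        try:
            cfg_attrs = dict(f["config"].attrs)
            for key in _TUPLE_FIELDS:
                cfg_attrs[key] = tuple(int(v) for v in cfg_attrs[key])
            for key in ("vocab_in", "vocab_out", "d_model", "n_heads", "head_dim",
                        "hidden_dense_dim", "max_len", "conv_filters", "gru_units",
                        "gru_layers", "batch_size", "iterations"):
                cfg_attrs[key] = int(cfg_attrs[key])
            config = ModelConfig(**cfg_attrs)
            model = build_model(config, seed=0)
            for name, tensor in model.params.items():
                tensor.data = f["weights"][name][:].astype(np.float64)
            names = [
                s.decode() if isinstance(s, bytes) else s
                for s in f["vocabulary"]["names"][:]
            ]
        except (KeyError, TypeError) as exc:
            raise BundleError(f"corrupt model bundle {path!s}: {exc}") from exc
    vocab = ToolVocabulary(index_of={t: i + 1 for i, t in enumerate(names)})
    return ModelBundle(config=config, model=model, vocabulary=vocab,
                       format_version=str(version))


# -- attention interpretation ---------------------------------------------


@dataclass
class AttentionMap:
    """Post-softmax self-attention weights for one encoded input.

    ``weights`` has one N x N matrix per head; ``averaged`` is their
    arithmetic mean.  Rows sum to one over unmasked key positions, and
    padded key positions carry zero weight.
    """

    weights: np.ndarray  # (heads, N, N)
    averaged: np.ndarray  # (N, N)
    labels: tuple[str, ...]  # tool name or "PAD" per position
    key_mask: np.ndarray  # (N,) bool


def attention_matrix(
    model: _Model, input_ids: np.ndarray, vocab: ToolVocabulary | None = None
) -> AttentionMap:
    """Extract per-head encoder attention for one encoded input row."""
    if getattr(model, "arch", None) != "transformer":
        raise UnsupportedArchitectureError(
            "attention maps are only defined for the transformer architecture"
        )
    ids = np.atleast_2d(np.asarray(input_ids, dtype=np.int64))
    if ids.shape[0] != 1:
        raise ValueError("attention_matrix expects a single encoded input")
    model.forward(ids, train=False)
    weights = model.last_attention[0]  # (H, N, N)
    key_mask = model.last_key_mask[0]  # (N,)
    if key_mask.any():
        weights = weights * key_mask[None, None, :]  # exact zeros on padding
    labels = tuple(
        "PAD" if i == PAD_INDEX else (vocab.name(int(i)) if vocab else str(int(i)))
        for i in ids[0]
    )
    return AttentionMap(
        weights=weights,
        averaged=weights.mean(axis=0),
        labels=labels,
        key_mask=key_mask,
    )
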