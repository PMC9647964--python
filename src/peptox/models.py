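"""Evolutionary-feature extractors and the five model variants.

The baseline extractor is a CNN over the BLOSUM62 grid followed by a
stacked bidirectional GRU; the concatenated final hidden states (2 layers
x 2 directions x hidden 512 = 2048 by default) are the per-sequence
evolutionary feature.  Variants modify this stack:

* ``design1`` — scaled dot-product self-attention over the BiGRU's
  per-position outputs, pooled and projected back to the baseline width;
* ``design2`` — the BiGRU is replaced by a transformer encoder
  (sinusoidal positional encoding, 6 layers, 8 heads, d = 512,
  feed-forward inner width 2048, residual + layer norm);
* ``design3`` — channel attention: sigmoid gates on the CNN feature-map
  channels, and a gated weighted sum of the four BiGRU hidden-state
  vectors that reduces the evolutionary feature to 512 dimensions;
* ``design4`` — the modified graphical (FEGS) encoder; structurally the
  baseline composition, since the modified coordinate rule is the only
  one this package ships;
* ``design5`` — the variational information-bottleneck head
  (see :mod:`peptox.bottleneck`).

Padded positions are masked out of attention softmaxes and pooling.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .autodiff import Tensor, concatenate, softmax, stack
from .nn import (
    MLP,
    BiGRU,
    ConvEncoder,
    LayerNorm,
    Linear,
    Module,
    masked_mean_pool,
    sinusoidal_positions,
)

ENCODER_VARIANTS = ("baseline", "self_attention", "transformer", "channel_attention")

#: modification-design ids -> (encoder variant, head kind)
DESIGN_TABLE = {
    "baseline": ("baseline", "ib"),
    "design1": ("self_attention", "ib"),
    "design2": ("transformer", "ib"),
    "design3": ("channel_attention", "ib"),
    "design4": ("baseline", "ib"),  # modified FEGS is the package's only FEGS rule
    "design5": ("baseline", "vib"),
}


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class EncoderConfig:
    """Hyperparameters of the evolutionary feature extractor.

    Defaults reproduce the printed dimensions: 2048-dim baseline feature
    (hidden 512, 2 stacked bidirectional layers -> 4 state vectors),
    512-dim channel-attention reduction, transformer with d = 512, h = 8
    heads (per-head key/value width 64), 6 encoder layers and inner
    feed-forward width 2048.
    """

    max_len: int = 1002
    cnn_filters: int = 64
    cnn_kernel: int = 8
    cnn_stride: int = 4
    gru_hidden: int = 512
    gru_layers: int = 2
    variant: str = "baseline"
    d_model: int = 512
    n_heads: int = 8
    n_encoder_layers: int = 6
    ffn_dim: int = 2048
    channel_reduction: int = 8
    seed: int = 0

    def __post_init__(self):
        if self.variant not in ENCODER_VARIANTS:
            raise ConfigError(f"unknown encoder variant {self.variant!r}")
        for name in ("max_len", "cnn_filters", "cnn_kernel", "cnn_stride",
                     "gru_hidden", "gru_layers", "d_model", "n_heads",
                     "n_encoder_layers", "ffn_dim"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be positive")
        if self.d_model % self.n_heads != 0:
            raise ConfigError(
                f"d_model {self.d_model} not divisible by n_heads {self.n_heads}"
            )
        if (self.max_len - self.cnn_kernel) // self.cnn_stride + 1 < 1:
            raise ConfigError("CNN kernel/stride leave no output positions")

    @property
    def head_dim(self) -> int:
        return self.d_model // self.n_heads

    @property
    def evolutionary_dim(self) -> int:
        """Per-sequence evolutionary feature width this config produces."""
        if self.variant == "channel_attention":
            return self.gru_hidden
        return 2 * self.gru_layers * self.gru_hidden


def self_attention(
    queries: Tensor,
    keys: Tensor,
    values: Tensor,
    scale: float | None = None,
    key_mask: np.ndarray | None = None,
) -> tuple[Tensor, Tensor]:
    """Scaled dot-product attention: softmax(Q K^T * scale) V.

    Shapes (..., Lq, d), (..., Lk, d), (..., Lk, dv); ``key_mask`` is a
    0/1 array over key positions broadcastable to the score shape.
    Returns (output, attention weights).
    """
    if queries.shape[-1] != keys.shape[-1]:
        raise ValueError(
            f"query dim {queries.shape[-1]} != key dim {keys.shape[-1]}"
        )
    if keys.shape[-2] != values.shape[-2]:
        raise ValueError("keys and values must agree on sequence length")
    if scale is None:
        scale = 1.0 / np.sqrt(keys.shape[-1])
    scores = (queries @ keys.transpose(*range(keys.ndim - 2), keys.ndim - 1, keys.ndim - 2)) * scale
    if key_mask is not None:
        scores = scores + Tensor(-1e9 * (1.0 - key_mask))
    weights = softmax(scores, axis=-1)
    return weights @ values, weights


class MultiHeadAttention(Module):
    """h parallel scaled dot-product heads over learned projections,
    concatenated and re-projected."""

    def __init__(self, rng, d_model: int, n_heads: int):
        if d_model % n_heads != 0:
            raise ConfigError(f"d_model {d_model} not divisible by {n_heads} heads")
        self.h = n_heads
        self.dk = d_model // n_heads
        self.Wq = Linear(rng, d_model, d_model, bias=False)
        self.Wk = Linear(rng, d_model, d_model, bias=False)
        self.Wv = Linear(rng, d_model, d_model, bias=False)
        self.Wo = Linear(rng, d_model, d_model, bias=False)

    def _split(self, x: Tensor) -> Tensor:
        B, L, _ = x.shape
        return x.reshape(B, L, self.h, self.dk).transpose(0, 2, 1, 3)  # (B, h, L, dk)

    def __call__(self, x: Tensor, mask: np.ndarray | None = None) -> tuple[Tensor, Tensor]:
        B, L, D = x.shape
        q, k, v = self._split(self.Wq(x)), self._split(self.Wk(x)), self._split(self.Wv(x))
        key_mask = None if mask is None else mask[:, None, None, :]
        out, weights = self_attention(q, k, v, scale=1.0 / np.sqrt(self.dk), key_mask=key_mask)
        out = out.transpose(0, 2, 1, 3).reshape(B, L, D)
        return self.Wo(out), weights


class TransformerEncoderLayer(Module):
    """Multihead self-attention + position-wise feed-forward, each sublayer
    wrapped as LayerNorm(x + Sublayer(x))."""

    def __init__(self, rng, d_model: int, n_heads: int, ffn_dim: int):
        self.mha = MultiHeadAttention(rng, d_model, n_heads)
        self.norm1 = LayerNorm(d_model)
        self.ffn1 = Linear(rng, d_model, ffn_dim)
        self.ffn2 = Linear(rng, ffn_dim, d_model)
        self.norm2 = LayerNorm(d_model)

    def __call__(self, x: Tensor, mask: np.ndarray | None) -> Tensor:
        attn_out, _ = self.mha(x, mask)
        x = self.norm1(x + attn_out)
        ffn_out = self.ffn2(self.ffn1(x).relu())
        return self.norm2(x + ffn_out)


def channel_attention_cnn(
    feature_maps: Tensor,
    mlp: MLP,
    mask: np.ndarray | None = None,
) -> tuple[Tensor, Tensor]:
    """Squeeze-and-gate over CNN channels.

    (B, L, C) maps are spatially pooled (masked mean) to (B, C), passed
    through the MLP, squashed by a sigmoid into per-channel gates in
    (0, 1), and broadcast-multiplied back onto the input.
    Returns (gated maps, gates).
    """
    if feature_maps.ndim != 3:
        raise ValueError(f"expected (B, L, C) maps, got shape {feature_maps.shape}")
    if mask is None:
        squeezed = feature_maps.mean(axis=1)
    else:
        squeezed = masked_mean_pool(feature_maps, mask)
    gates = mlp(squeezed).sigmoid()  # (B, C)
    B, C = gates.shape
    return feature_maps * gates.reshape(B, 1, C), gates


def channel_attention_gru(
    hidden_stack: list[Tensor],
    mlp: MLP,
) -> tuple[Tensor, Tensor]:
    """Gated weighted sum of the BiGRU hidden-layer state vectors.

    Each of the (default four) (B, H) state vectors gets a scalar sigmoid
    gate from the shared MLP; the output is the gate-weighted sum, so the
    evolutionary feature is reduced to H (512 by default) dimensions.
    Returns (reduced feature, gates of shape (B, n_layers)).
    """
    if not hidden_stack:
        raise ConfigError("hidden stack is empty")
    dims = {h.shape for h in hidden_stack}
    if len(dims) != 1:
        raise ConfigError(f"hidden vectors disagree in shape: {dims}")
    stacked = stack(hidden_stack, axis=1)  # (B, n, H)
    gates = mlp(stacked).sigmoid()  # (B, n, 1)
    out = (stacked * gates).sum(axis=1)  # (B, H)
    B, n, _ = gates.shape
    return out, gates.reshape(B, n)


class EvolutionaryEncoder(Module):
    """CNN front end + variant-specific sequence model -> per-sequence
    evolutionary feature vector."""

    def __init__(self, config: EncoderConfig, rng: np.random.Generator):
        self.config = config
        self.conv = ConvEncoder(
            rng, 20, config.cnn_filters, config.cnn_kernel, config.cnn_stride
        )
        v = config.variant
        if v == "transformer":
            self.input_proj = Linear(rng, config.cnn_filters, config.d_model)
            n_pos = self.conv.out_length(config.max_len)
            self.positional_encoding = sinusoidal_positions(n_pos, config.d_model)
            self.layers = [
                TransformerEncoderLayer(rng, config.d_model, config.n_heads, config.ffn_dim)
                for _ in range(config.n_encoder_layers)
            ]
            self.output_proj = Linear(rng, config.d_model, config.evolutionary_dim)
        else:
            self.bigru = BiGRU(rng, config.cnn_filters, config.gru_hidden, config.gru_layers)
            if v == "self_attention":
                width = 2 * config.gru_hidden
                self.output_proj = Linear(rng, width, config.evolutionary_dim)
            elif v == "channel_attention":
                c = config.cnn_filters
                r = max(c // config.channel_reduction, 1)
                self.cnn_gate_mlp = MLP(rng, [c, r, c])
                h = config.gru_hidden
                self.gru_gate_mlp = MLP(rng, [h, max(h // config.channel_reduction, 1), 1])

    def __call__(self, blosum: np.ndarray, mask: np.ndarray) -> tuple[Tensor, dict]:
        """(B, max_len, 20) grids + (B, max_len) masks -> (B, evo_dim) features.

        The second return value carries inspectable attention weights.
        """
        cfg = self.config
        if blosum.shape[1] != cfg.max_len or blosum.shape[2] != 20:
            raise ConfigError(
                f"encoded shape {blosum.shape[1:]} does not match config ({cfg.max_len}, 20)"
            )
        x = self.conv(Tensor(blosum))
        conv_mask = self.conv.pool_mask(mask)
        extras: dict = {}
        v = cfg.variant
        if v == "transformer":
            h = self.input_proj(x) + Tensor(self.positional_encoding[None, : x.shape[1]])
            for layer in self.layers:
                h = layer(h, conv_mask)
            return self.output_proj(masked_mean_pool(h, conv_mask)), extras
        if v == "channel_attention":
            x, cnn_gates = channel_attention_cnn(x, self.cnn_gate_mlp, conv_mask)
            extras["cnn_gates"] = cnn_gates
            _, finals = self.bigru(x, conv_mask)
            out, gru_gates = channel_attention_gru(finals, self.gru_gate_mlp)
            extras["gru_gates"] = gru_gates
            return out, extras
        outputs, finals = self.bigru(x, conv_mask)
        if v == "self_attention":
            attended, weights = self_attention(
                outputs, outputs, outputs, key_mask=conv_mask[:, None, :]
            )
            extras["attention"] = weights
            return self.output_proj(masked_mean_pool(attended, conv_mask)), extras
        return concatenate(finals, axis=1), extras  # baseline: 4 x H -> 2048


def cnn_bigru_forward(
    blosum: np.ndarray, mask: np.ndarray, config: EncoderConfig | None = None,
    encoder: EvolutionaryEncoder | None = None,
) -> Tensor:
    """Baseline CNN_BiGRU forward pass; builds a seeded encoder if none given."""
    if encoder is None:
        config = config or EncoderConfig()
        if config.variant != "baseline":
            config = replace(config, variant="baseline")
        encoder = EvolutionaryEncoder(config, np.random.default_rng(config.seed))
    features, _ = encoder(blosum, mask)
    return features


def transformer_encoder_forward(
    blosum: np.ndarray, mask: np.ndarray, config: EncoderConfig | None = None,
    encoder: EvolutionaryEncoder | None = None,
) -> Tensor:
    """Transformer-variant forward pass; builds a seeded encoder if none given."""
    if encoder is None:
        config = replace(config or EncoderConfig(), variant="transformer")
        encoder = EvolutionaryEncoder(config, np.random.default_rng(config.seed))
    features, _ = encoder(blosum, mask)
    return features
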