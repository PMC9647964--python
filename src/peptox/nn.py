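"""Neural building blocks: parameter containers, linear/conv/GRU layers,
layer normalization and the sinusoidal positional-encoding table.

All layers operate on :class:`peptox.autodiff.Tensor` batches and are
deterministic given their weights; weight initialization is driven by an
explicit ``numpy.random.Generator``.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, concatenate, stack, unfold


class Module:
    """Base class: recursively collects trainable parameters."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for value in vars(self).values():
            if isinstance(value, Tensor) and value.requires_grad:
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Tensor) and item.requires_grad:
                        params.append(item)
        return params

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError(f"checkpoint has {len(arrays)} arrays, model expects {len(params)}")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError(f"shape mismatch {p.data.shape} vs {a.shape}")
            p.data = a.astype(np.float64)


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape=None) -> Tensor:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    shape = shape if shape is not None else (fan_in, fan_out)
    return Tensor(rng.uniform(-limit, limit, size=shape), requires_grad=True)


class Linear(Module):
    def __init__(self, rng: np.random.Generator, in_dim: int, out_dim: int, bias: bool = True):
        self.W = glorot(rng, in_dim, out_dim)
        self.b = Tensor(np.zeros(out_dim), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.W
        return out + self.b if self.b is not None else out


class MLP(Module):
    """Fully connected stack with ReLU between hidden layers."""

    def __init__(self, rng, dims: list[int]):
        self.layers = [Linear(rng, a, b) for a, b in zip(dims[:-1], dims[1:])]

    def __call__(self, x: Tensor) -> Tensor:
        for i, layer in enumerate(self.layers):
            x = layer(x)
            if i < len(self.layers) - 1:
                x = x.relu()
        return x


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=-1, keepdims=True)
        return centered * ((var + self.eps) ** -0.5) * self.gamma + self.beta


class ConvEncoder(Module):
    """2D convolution over the substitution-score grid.

    The kernel spans the full 20-column residue axis, so the layer slides
    only along sequence positions — a (kernel, 20) receptive field per
    filter, followed by ReLU.  Input (B, L, 20) -> output (B, L', filters).
    """

    def __init__(self, rng, in_width: int, filters: int, kernel: int, stride: int):
        if kernel < 1 or stride < 1:
            raise ValueError("kernel and stride must be positive")
        self.kernel = kernel
        self.stride = stride
        self.W = glorot(rng, kernel * in_width, filters)
        self.b = Tensor(np.zeros(filters), requires_grad=True)

    def out_length(self, length: int) -> int:
        return (length - self.kernel) // self.stride + 1

    def __call__(self, x: Tensor) -> Tensor:
        windows = unfold(x, self.kernel, self.stride)  # (B, L', k*20)
        return (windows @ self.W + self.b).relu()

    def pool_mask(self, mask: np.ndarray) -> np.ndarray:
        """Downsample a (B, L) real/pad mask to conv output positions.

        A conv position is real when its window touches at least one real
        input position.
        """
        B, L = mask.shape
        n_out = self.out_length(L)
        idx = np.arange(n_out)[:, None] * self.stride + np.arange(self.kernel)[None, :]
        return mask[:, idx].max(axis=2)


class GRUCell(Module):
    def __init__(self, rng, in_dim: int, hidden: int):
        self.Wz = glorot(rng, in_dim, hidden)
        self.Uz = glorot(rng, hidden, hidden)
        self.bz = Tensor(np.zeros(hidden), requires_grad=True)
        self.Wr = glorot(rng, in_dim, hidden)
        self.Ur = glorot(rng, hidden, hidden)
        self.br = Tensor(np.zeros(hidden), requires_grad=True)
        self.Wn = glorot(rng, in_dim, hidden)
        self.Un = glorot(rng, hidden, hidden)
        self.bn = Tensor(np.zeros(hidden), requires_grad=True)
        self.hidden = hidden

    def step(self, x_t: Tensor, h: Tensor) -> Tensor:
        z = (x_t @ self.Wz + h @ self.Uz + self.bz).sigmoid()
        r = (x_t @ self.Wr + h @ self.Ur + self.br).sigmoid()
        n = (x_t @ self.Wn + (r * h) @ self.Un + self.bn).tanh()
        return (1.0 - z) * n + z * h


class BiGRU(Module):
    """Stacked bidirectional GRU over (B, L, F) inputs.

    Padded positions (mask 0) freeze the hidden state, so the forward
    direction's final state is the state at the last real position.
    """

    def __init__(self, rng, in_dim: int, hidden: int, layers: int = 2):
        self.cells_fwd = []
        self.cells_bwd = []
        dim = in_dim
        for _ in range(layers):
            self.cells_fwd.append(GRUCell(rng, dim, hidden))
            self.cells_bwd.append(GRUCell(rng, dim, hidden))
            dim = 2 * hidden
        self.hidden = hidden
        self.n_layers = layers

    def _run_direction(self, cell: GRUCell, seq: list[Tensor], mask: np.ndarray) -> tuple[list[Tensor], Tensor]:
        B = seq[0].shape[0]
        h = Tensor(np.zeros((B, cell.hidden)))
        outputs = []
        for t, x_t in enumerate(seq):
            m = Tensor(mask[:, t : t + 1])
            h = m * cell.step(x_t, h) + (1.0 - m) * h
            outputs.append(h)
        return outputs, h

    def __call__(self, x: Tensor, mask: np.ndarray) -> tuple[Tensor, list[Tensor]]:
        """Return (per-position outputs (B, L, 2H), final states [L0f, L0b, L1f, L1b, ...])."""
        L = x.shape[1]
        seq = [x[:, t, :] for t in range(L)]
        finals: list[Tensor] = []
        for cell_f, cell_b in zip(self.cells_fwd, self.cells_bwd):
            out_f, h_f = self._run_direction(cell_f, seq, mask)
            out_b_rev, h_b = self._run_direction(cell_b, seq[::-1], mask[:, ::-1])
            out_b = out_b_rev[::-1]
            seq = [concatenate([f, b], axis=1) for f, b in zip(out_f, out_b)]
            finals.extend([h_f, h_b])
        outputs = stack(seq, axis=1)  # (B, L, 2H)
        return outputs, finals


def sinusoidal_positions(n_positions: int, dim: int) -> np.ndarray:
    """Standard sine/cosine positional-encoding table, shape (n_positions, dim)."""
    pos = np.arange(n_positions)[:, None].astype(float)
    i = np.arange(dim // 2)[None, :].astype(float)
    angles = pos / np.power(10000.0, 2.0 * i / dim)
    table = np.zeros((n_positions, dim))
    table[:, 0::2] = np.sin(angles)
    table[:, 1::2] = np.cos(angles)
    return table


def masked_mean_pool(x: Tensor, mask: np.ndarray) -> Tensor:
    """Mean over real positions of (B, L, F); padded positions excluded."""
    m = mask[:, :, None]
    denom = np.maximum(m.sum(axis=1), 1.0)
    return (x * Tensor(m)).sum(axis=1) * Tensor(1.0 / denom)
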