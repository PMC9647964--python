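"""Feature fusion and the (variational) information-bottleneck head.

The per-sequence evolutionary feature and the graphical/statistical
(FEGS) feature are concatenated, optionally passed through an extra MLP
(design5), and compressed to a latent z.  The variational head emits a
diagonal Gaussian (mu, log sigma^2), samples z by reparameterization
during training and uses z = mu at inference; the deterministic
information-bottleneck baseline is the same architecture with beta = 0
and z = mu throughout.  Classification is a fully connected layer plus
sigmoid on z alone; the training loss is binary cross-entropy plus
beta times the KL divergence of the latent to the standard-normal prior.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, as_tensor, concatenate
from .nn import MLP, Linear, Module

BCE_EPS = 1e-7


@dataclass
class FeatureStandardizer:
    """Per-feature z-scoring with statistics fit on the training fold."""

    mean: np.ndarray
    std: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray) -> "FeatureStandardizer":
        X = np.asarray(X, dtype=np.float64)
        return cls(mean=X.mean(axis=0), std=np.maximum(X.std(axis=0), 1e-8))

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=np.float64) - self.mean) / self.std


@dataclass
class FusedFeature:
    """Concatenated [evolutionary | FEGS] vector with recorded block dims."""

    vector: Tensor
    evolutionary_dim: int
    fegs_dim: int

    @property
    def dim(self) -> int:
        return self.evolutionary_dim + self.fegs_dim

    def evolutionary_block(self) -> Tensor:
        return self.vector[..., : self.evolutionary_dim]

    def fegs_block(self) -> Tensor:
        return self.vector[..., self.evolutionary_dim :]


def fuse_features(evolutionary, fegs) -> FusedFeature:
    """Concatenate the two per-sequence feature blocks, order
    [evolutionary | FEGS]; accepts 1D vectors or (B, d) batches."""
    evolutionary = as_tensor(evolutionary)
    fegs = as_tensor(fegs)
    if evolutionary.ndim != fegs.ndim:
        raise ValueError(
            f"rank mismatch: evolutionary {evolutionary.ndim}D vs FEGS {fegs.ndim}D"
        )
    vector = concatenate([evolutionary, fegs], axis=-1 if evolutionary.ndim == 1 else 1)
    return FusedFeature(
        vector=vector,
        evolutionary_dim=evolutionary.shape[-1],
        fegs_dim=fegs.shape[-1],
    )


@dataclass
class LatentRepresentation:
    """Diagonal-Gaussian latent: mean, log-variance and (optionally) a draw."""

    mu: Tensor
    log_var: Tensor
    z: Tensor | None = None

    @property
    def dim(self) -> int:
        return self.mu.shape[-1]


def vib_sample(
    latent: LatentRepresentation,
    rng: np.random.Generator | int | None = None,
    training: bool = True,
) -> Tensor:
    """Reparameterized draw z = mu + sigma * eps; z = mu at inference."""
    if not training:
        return latent.mu
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    eps = rng.standard_normal(latent.mu.shape)
    sigma = (latent.log_var * 0.5).exp()
    return latent.mu + sigma * Tensor(eps)


def kl_to_standard_normal(latent: LatentRepresentation) -> Tensor:
    """Closed-form KL( N(mu, diag sigma^2) || N(0, I) ) in nats, summed over
    latent dimensions: 0.5 * sum(mu^2 + sigma^2 - 1 - log sigma^2)."""
    var = latent.log_var.exp()
    per_dim = (latent.mu * latent.mu + var - 1.0 - latent.log_var) * 0.5
    return per_dim.sum(axis=-1)


def binary_cross_entropy(probability: Tensor, labels: np.ndarray) -> Tensor:
    """Mean BCE in nats; probabilities squeezed into [eps, 1-eps] smoothly
    so confident mispredictions stay finite and differentiable."""
    labels = np.asarray(labels, dtype=np.float64).reshape(probability.shape)
    p = probability * (1.0 - 2.0 * BCE_EPS) + BCE_EPS
    y = Tensor(labels)
    return -(y * p.log() + (1.0 - y) * (1.0 - p).log()).mean()


@dataclass
class LossBreakdown:
    classification: float
    kl: float
    beta: float

    @property
    def total(self) -> float:
        return self.classification + self.beta * self.kl


def vib_loss(
    probability: Tensor,
    labels: np.ndarray,
    latent: LatentRepresentation,
    beta: float,
) -> tuple[Tensor, LossBreakdown]:
    """Total loss = BCE + beta * mean KL; returns the differentiable total
    and a float breakdown for tracing."""
    if beta < 0:
        raise ValueError(f"beta must be >= 0, got {beta}")
    bce = binary_cross_entropy(probability, labels)
    kl = kl_to_standard_normal(latent).mean()
    total = bce + beta * kl
    return total, LossBreakdown(
        classification=float(bce.data), kl=float(kl.data), beta=beta
    )


class BottleneckHead(Module):
    """Fusion -> (optional extra MLP) -> latent bottleneck -> sigmoid classifier.

    kind "ib": deterministic bottleneck (z = mu, beta forced to 0);
    kind "vib": stochastic latent with KL regularization (design5), with
    an extra MLP on the concatenated feature vector before the bottleneck.
    """

    def __init__(
        self,
        rng: np.random.Generator,
        in_dim: int,
        latent_dim: int = 128,
        kind: str = "ib",
        beta: float = 1e-3,
        mlp_hidden: int = 256,
    ):
        if kind not in ("ib", "vib"):
            raise ValueError(f"unknown head kind {kind!r}")
        self.kind = kind
        self.beta = beta if kind == "vib" else 0.0
        self.latent_dim = latent_dim
        self.pre_mlp = MLP(rng, [in_dim, mlp_hidden, mlp_hidden]) if kind == "vib" else None
        enc_in = mlp_hidden if kind == "vib" else in_dim
        self.mu_layer = Linear(rng, enc_in, latent_dim)
        self.log_var_layer = Linear(rng, enc_in, latent_dim)
        self.classifier = Linear(rng, latent_dim, 1)

    def vib_encode(self, fused: FusedFeature | Tensor) -> LatentRepresentation:
        x = fused.vector if isinstance(fused, FusedFeature) else as_tensor(fused)
        if self.pre_mlp is not None:
            x = self.pre_mlp(x).relu()
        h = x
        return LatentRepresentation(mu=self.mu_layer(h), log_var=self.log_var_layer(h))

    def classify(self, z: Tensor) -> Tensor:
        """Toxicity probability from the latent alone."""
        return self.classifier(z).sigmoid()

    def __call__(
        self,
        fused: FusedFeature | Tensor,
        rng: np.random.Generator | None = None,
        training: bool = False,
    ) -> tuple[Tensor, LatentRepresentation]:
        latent = self.vib_encode(fused)
        stochastic = training and self.kind == "vib"
        z = vib_sample(latent, rng, training=stochastic)
        latent.z = z
        return self.classify(z), latent
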