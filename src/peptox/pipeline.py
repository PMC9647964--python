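"""End-to-end toxicity model: dual encoders, fusion, bottleneck head.

:func:`assemble_variant` composes the five modification designs from
their parts: an evolutionary feature extractor (CNN + BiGRU / attention
variants), the graphical/statistical (FEGS) encoder, feature fusion and
an information-bottleneck classification head.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace

import numpy as np

from .autodiff import Tensor, no_grad
from .blosum import encode_batch
from .bottleneck import (
    BottleneckHead,
    FeatureStandardizer,
    LatentRepresentation,
    fuse_features,
)
from .fegs import FegsEncoder
from .models import DESIGN_TABLE, ConfigError, EncoderConfig, EvolutionaryEncoder
from .nn import Module
from .sequence_io import SequenceRecord


@dataclass(frozen=True)
class VariantConfig:
    """Full configuration of one modification design."""

    variant: str = "baseline"
    encoder: EncoderConfig = field(default_factory=EncoderConfig)
    fegs_dim: int = 578
    latent_dim: int = 128
    beta: float = 1e-3
    mlp_hidden: int = 256
    standardize_fegs: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.variant not in DESIGN_TABLE:
            raise ConfigError(
                f"unknown variant {self.variant!r}; expected one of {sorted(DESIGN_TABLE)}"
            )

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


class ToxicityModel(Module):
    """Composed encoder + fusion + bottleneck head for one design variant."""

    def __init__(self, config: VariantConfig, fegs_encoder: FegsEncoder | None = None):
        encoder_variant, head_kind = DESIGN_TABLE[config.variant]
        enc_cfg = replace(config.encoder, variant=encoder_variant, seed=config.seed)
        rng = np.random.default_rng(config.seed)
        self.config = replace(config, encoder=enc_cfg)
        self.encoder = EvolutionaryEncoder(enc_cfg, rng)
        self.head = BottleneckHead(
            rng,
            in_dim=enc_cfg.evolutionary_dim + config.fegs_dim,
            latent_dim=config.latent_dim,
            kind=head_kind,
            beta=config.beta,
            mlp_hidden=config.mlp_hidden,
        )
        self.fegs_encoder = fegs_encoder  # set lazily; not a trainable part
        self.standardizer: FeatureStandardizer | None = None

    # -- encoding -------------------------------------------------------------
    def _require_fegs(self) -> FegsEncoder:
        if self.fegs_encoder is None:
            self.fegs_encoder = FegsEncoder()
            if self.fegs_encoder.n_features != self.config.fegs_dim:
                raise ConfigError(
                    f"packaged FEGS width {self.fegs_encoder.n_features} != "
                    f"configured fegs_dim {self.config.fegs_dim}"
                )
        return self.fegs_encoder

    def encode_records(
        self, records: list[SequenceRecord]
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Records -> (BLOSUM grids, masks, standardized FEGS features)."""
        blosum, mask = encode_batch(records, max_len=self.config.encoder.max_len)
        fegs = self._require_fegs().encode_many([r.residues for r in records])
        if self.standardizer is not None:
            fegs = self.standardizer.transform(fegs)
        return blosum, mask, fegs

    def fit_standardizer(self, records: list[SequenceRecord]) -> None:
        if not self.config.standardize_fegs:
            return
        fegs = self._require_fegs().encode_many([r.residues for r in records])
        self.standardizer = FeatureStandardizer.fit(fegs)

    # -- forward --------------------------------------------------------------
    def forward(
        self,
        blosum: np.ndarray,
        mask: np.ndarray,
        fegs: np.ndarray,
        rng: np.random.Generator | None = None,
        training: bool = False,
    ) -> tuple[Tensor, LatentRepresentation, dict]:
        evolutionary, extras = self.encoder(blosum, mask)
        fused = fuse_features(evolutionary, fegs)
        prob, latent = self.head(fused, rng=rng, training=training)
        return prob, latent, extras

    def predict_proba(
        self, records: list[SequenceRecord], batch_size: int = 64
    ) -> np.ndarray:
        """Toxicity probabilities at inference (z = mu, no sampling)."""
        probs = []
        with no_grad():
            for start in range(0, len(records), batch_size):
                chunk = records[start : start + batch_size]
                blosum, mask, fegs = self.encode_records(chunk)
                prob, _, _ = self.forward(blosum, mask, fegs, training=False)
                probs.append(prob.data.reshape(-1))
        return np.concatenate(probs) if probs else np.zeros(0)

    def predict(
        self, records: list[SequenceRecord], threshold: float = 0.5
    ) -> np.ndarray:
        return (self.predict_proba(records) >= threshold).astype(int)

    # -- persistence ----------------------------------------------------------
    def save(self, path) -> None:
        arrays = {f"param_{i}": a for i, a in enumerate(self.state_arrays())}
        meta = dict(config=asdict(self.config), config_hash=self.config.config_hash())
        if self.standardizer is not None:
            arrays["std_mean"] = self.standardizer.mean
            arrays["std_std"] = self.standardizer.std
        np.savez(path, meta=json.dumps(meta, default=str), **arrays)

    @classmethod
    def load(cls, path) -> "ToxicityModel":
        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(str(data["meta"]))
            cfg = meta["config"]
            cfg["encoder"] = EncoderConfig(**cfg["encoder"])
            config = VariantConfig(**cfg)
            model = cls(config)
            n = len([k for k in data.files if k.startswith("param_")])
            model.load_state_arrays([data[f"param_{i}"] for i in range(n)])
            if "std_mean" in data.files:
                model.standardizer = FeatureStandardizer(
                    mean=data["std_mean"], std=data["std_std"]
                )
        return model


def assemble_variant(
    variant: str,
    encoder: EncoderConfig | None = None,
    fegs_encoder: FegsEncoder | None = None,
    **overrides,
) -> ToxicityModel:
    """Build one of the modification designs by id.

    ids: ``baseline`` (CNN_BiGRU + FEGS + deterministic bottleneck),
    ``design1`` (self-attention over BiGRU states), ``design2``
    (transformer encoder), ``design3`` (channel attention, 512-dim
    reduction), ``design4`` (modified FEGS; baseline composition),
    ``design5`` (variational information bottleneck).
    """
    if variant not in DESIGN_TABLE:
        raise ConfigError(
            f"unknown variant {variant!r}; expected one of {sorted(DESIGN_TABLE)}"
        )
    kwargs = dict(variant=variant, **overrides)
    if encoder is not None:
        kwargs["encoder"] = encoder
    if fegs_encoder is not None:
        kwargs.setdefault("fegs_dim", fegs_encoder.n_features)
    return ToxicityModel(VariantConfig(**kwargs), fegs_encoder=fegs_encoder)
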