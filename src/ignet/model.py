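"""The two-channel imaging-genetics classifier.

The imaging channel is a five-stage 3D CNN (filter counts [4, 8, 16, 32, 32],
3x3x3 kernels with stride 1 and "same" padding, each convolution followed by
2x2x2 max pooling with stride 2) ending in three dense layers that produce a
16-dimensional imaging embedding. The genetic channel embeds a sequence of
SNP dosage tokens (a separate vocabulary for the flagged APOE e4 position),
adds learned positional embeddings, applies a two-layer four-head pre-norm
Transformer encoder, mean-pools over positions and maps to a 16-dimensional
genetic embedding. The embeddings are fused by element-wise multiplication
and classified by an MLP with two 16-unit hidden layers and a softmax over
the two diagnostic classes (control vs. AD).

Restricted variants pass a single channel's embedding straight to the MLP:
``imaging_only`` ignores the genetic input, ``genetic_only`` the volumes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass

import numpy as np

from . import nn

VARIANTS = ("full", "imaging_only", "genetic_only")


@dataclass
class ModelConfig:
    """Architectural hyperparameters; shapes of all weights follow from it."""

    conv_filters: tuple = (4, 8, 16, 32, 32)
    fc_sizes_imaging: tuple = (128, 32, 16)
    embed_dim: int = 16
    n_encoder_layers: int = 2
    n_heads: int = 4
    ffn_dim: int = 32
    seq_len: int = 99
    mlp_hidden: tuple = (16, 16)
    n_classes: int = 2
    dropout_imaging: float = 0.2
    dropout_genetic: float = 0.2
    volume_shape: tuple = (128, 128, 128)
    variant: str = "full"

    def __post_init__(self):
        self.conv_filters = tuple(self.conv_filters)
        self.fc_sizes_imaging = tuple(self.fc_sizes_imaging)
        self.mlp_hidden = tuple(self.mlp_hidden)
        self.volume_shape = tuple(self.volume_shape)
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")
        if self.n_classes != 2:
            raise ValueError("binary diagnosis requires n_classes = 2")
        if self.fc_sizes_imaging[-1] != self.embed_dim:
            raise ValueError("last imaging FC width must equal embed_dim")
        factor = 2 ** len(self.conv_filters)
        if any(s % factor for s in self.volume_shape):
            raise ValueError(
                f"volume dims {self.volume_shape} must be divisible by {factor}")

    @property
    def flatten_width(self) -> int:
        factor = 2 ** len(self.conv_filters)
        red = [s // factor for s in self.volume_shape]
        return int(np.prod(red)) * self.conv_filters[-1]

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def count_parameters(config: ModelConfig) -> int:
    """Closed-form count of trainable scalars implied by the configuration.

    Counts only what the configured variant trains is *not* done here: the
    count covers the full two-channel model, the quantity quoted against the
    memory budget.
    """
    total = 0
    c_in = 1
    for c_out in config.conv_filters:
        total += c_in * 27 * c_out + c_out
        c_in = c_out
    w = config.flatten_width
    for w_out in config.fc_sizes_imaging:
        total += w * w_out + w_out
        w = w_out
    d, f = config.embed_dim, config.ffn_dim
    total += 3 * d + 3 * d + config.seq_len * d        # token, APOE, positional
    per_layer = (2 * d                                  # ln1
                 + d * 3 * d + 3 * d                    # qkv projection
                 + d * d + d                            # output projection
                 + 2 * d                                # ln2
                 + d * f + f + f * d + d)               # feed-forward
    total += config.n_encoder_layers * per_layer
    total += d * d + d                                  # post-pool linear
    w = d
    for w_out in config.mlp_hidden:
        total += w * w_out + w_out
        w = w_out
    total += w * config.n_classes + config.n_classes
    return total


class IGnet(nn.Module):
    """Forward/backward graph over explicit parameter arrays."""

    def __init__(self, config: ModelConfig, init_seed: int = 0,
                 dtype=nn.DEFAULT_DTYPE) -> None:
        super().__init__()
        self.config = config
        self.init_seed = int(init_seed)
        rng = np.random.default_rng(self.init_seed)

        # Dropout lives in the dense head, not on conv feature maps: spatial
        # dropout deletes localized class signal (a few voxels deep in the
        # pooling pyramid) and stalls optimization.
        layers = []
        c_in = 1
        for li, c_out in enumerate(config.conv_filters):
            layers += [nn.Conv3d(c_in, c_out, rng, dtype=dtype,
                                 input_grad=li > 0), nn.ReLU(), nn.MaxPool3d()]
            c_in = c_out
        layers.append(nn.Flatten())
        w = config.flatten_width
        for i, w_out in enumerate(config.fc_sizes_imaging):
            last = i == len(config.fc_sizes_imaging) - 1
            layers.append(nn.Linear(w, w_out, rng,
                                    scale="linear" if last else "relu",
                                    dtype=dtype))
            if not last:
                layers += [nn.ReLU(), nn.Dropout(config.dropout_imaging)]
            w = w_out
        self.add_child("imaging", nn.Sequential(*layers))

        self.add_child("embedding",
                       nn.TokenEmbedding(config.seq_len, config.embed_dim, rng,
                                         dtype=dtype))
        encoders = [nn.EncoderLayer(config.embed_dim, config.n_heads,
                                    config.ffn_dim, config.dropout_genetic,
                                    rng, dtype=dtype)
                    for _ in range(config.n_encoder_layers)]
        self.add_child("encoder", nn.Sequential(*encoders))
        self.add_child("pool", nn.MeanPoolSeq())
        self.add_child("genetic_out",
                       nn.Linear(config.embed_dim, config.embed_dim, rng,
                                 scale="linear", dtype=dtype))

        # start both embeddings near the multiplicative identity so the
        # element-wise product behaves additively early in training and
        # neither channel's gradient is damped by the other's magnitude
        self.children["imaging"].layers[-1].params["b"][...] = 1.0
        self.children["genetic_out"].params["b"][...] = 1.0

        mlp = []
        w = config.embed_dim
        for w_out in config.mlp_hidden:
            mlp += [nn.Linear(w, w_out, rng, scale="relu", dtype=dtype), nn.ReLU()]
            w = w_out
        mlp.append(nn.Linear(w, config.n_classes, rng, scale="linear", dtype=dtype))
        self.add_child("classifier", nn.Sequential(*mlp))

    # ---------------- forward passes ----------------

    def imaging_forward(self, volumes, train=False, rng=None):
        """Volumes (B, D, H, W) with intensities normalized to [0, 1] -> (B, 16)."""
        volumes = np.asarray(volumes)
        if volumes.ndim != 4:
            raise ValueError("expected a batch of 3D volumes (B, D, H, W)")
        if volumes.shape[1:] != self.config.volume_shape:
            raise ValueError(
                f"volume shape {volumes.shape[1:]} does not match config "
                f"{self.config.volume_shape}")
        x = volumes[:, None].astype(self.children["imaging"].layers[0].params["W"].dtype)
        return self.children["imaging"].forward(x, train, rng)

    def genetic_forward(self, tokens, apoe_position=None, train=False, rng=None):
        """Dosage token batch (B, seq_len) -> (B, 16)."""
        x = self.children["embedding"].forward(tokens, apoe_position, train, rng)
        x = self.children["encoder"].forward(x, train, rng)
        x = self.children["pool"].forward(x)
        return self.children["genetic_out"].forward(x)

    @staticmethod
    def fuse(img_emb, gen_emb):
        img_emb, gen_emb = np.asarray(img_emb), np.asarray(gen_emb)
        if img_emb.shape != gen_emb.shape:
            raise ValueError("embedding shapes differ")
        return img_emb * gen_emb

    def classify(self, embedding, train=False, rng=None, return_scores=False):
        """16-vector batch -> class probabilities (rows sum to 1)."""
        embedding = np.asarray(embedding)
        if not np.isfinite(embedding).all():
            raise ValueError("non-finite embedding")
        scores = self.children["classifier"].forward(embedding, train, rng)
        probs = nn.softmax(scores)
        return (probs, scores) if return_scores else probs

    def forward(self, volumes=None, tokens=None, apoe_position=None,
                train=False, rng=None, return_scores=False):
        """Variant-aware forward pass; returns class probabilities."""
        variant = self.config.variant
        if variant in ("full", "imaging_only") and volumes is None:
            raise ValueError(f"variant {variant!r} requires volumes")
        if variant in ("full", "genetic_only") and tokens is None:
            raise ValueError(f"variant {variant!r} requires token sequences")
        img = gen = None
        if variant in ("full", "imaging_only"):
            img = self.imaging_forward(volumes, train, rng)
        if variant in ("full", "genetic_only"):
            gen = self.genetic_forward(tokens, apoe_position, train, rng)
        if variant == "full":
            emb = self.fuse(img, gen)
        else:
            emb = img if variant == "imaging_only" else gen
        self._fwd_cache = (img, gen)
        return self.classify(emb, train, rng, return_scores=return_scores)

    def backward_from_scores(self, dscores):
        """Backpropagate the loss gradient w.r.t. the classifier scores."""
        variant = self.config.variant
        img, gen = self._fwd_cache
        dtype = next(iter(self.children["classifier"].layers[0].params.values())).dtype
        demb = self.children["classifier"].backward(dscores.astype(dtype))
        if variant == "full":
            dimg, dgen = demb * gen, demb * img
        elif variant == "imaging_only":
            dimg, dgen = demb, None
        else:
            dimg, dgen = None, demb
        if dgen is not None:
            dx = self.children["genetic_out"].backward(dgen)
            dx = self.children["pool"].backward(dx)
            dx = self.children["encoder"].backward(dx)
            self.children["embedding"].backward(dx)
        if dimg is not None:
            self.children["imaging"].backward(dimg)


# ---------------- checkpoints ----------------

def save_checkpoint(model: IGnet, path) -> None:
    """Archive the parameter arrays plus a JSON sidecar of config and seed."""
    arrays = {name: value for name, value, _ in model.named_parameters()}
    meta = {"config": model.config.to_dict(),
            "config_hash": model.config.hash(),
            "init_seed": model.init_seed}
    np.savez(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path, expected_config: ModelConfig | None = None) -> IGnet:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        arrays = {k: data[k] for k in data.files if k != "__meta__"}
    config = ModelConfig(**meta["config"])
    if expected_config is not None and expected_config.hash() != meta["config_hash"]:
        raise ValueError("checkpoint config hash does not match the requested config")
    model = IGnet(config, init_seed=meta["init_seed"])
    for name, value, _ in model.named_parameters():
        value[...] = arrays[name].astype(value.dtype)
    return model


def get_state(model: IGnet) -> dict:
    return {name: value.copy() for name, value, _ in model.named_parameters()}


def set_state(model: IGnet, state: dict) -> None:
    for name, value, _ in model.named_parameters():
        value[...] = state[name]
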