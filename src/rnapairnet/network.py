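"""The trainable pair-scoring stack.

Pipeline: integer codes -> learned embedding (channel 10) -> global
semantic extractor (single-layer Bi-LSTM, then a Transformer encoder whose
input order information comes from the recurrent stage, so no positional
encoding is added) -> pairwise concatenation into an L x L grid of joined
word vectors -> U-Net style encoder/decoder generator with additive skip
connections -> one L x L matrix of pairing logits per sequence.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from . import autograd as ag
from . import nn
from .autograd import Tensor

__all__ = ["ModelConfig", "PairScorer", "pairwise_concat", "save_checkpoint", "load_checkpoint"]

N_SYMBOLS = 5  # four bases + padding


@dataclass
class ModelConfig:
    encoding_length: int = 128
    embed_dim: int = 10
    lstm_hidden: int = 32
    n_encoder_layers: int = 6
    n_heads: int = 2
    unet_depth: int = 3
    unet_base_channels: int = 16
    seed: int = 0

    @property
    def d_model(self) -> int:
        return 2 * self.lstm_hidden

    def __post_init__(self):
        if self.d_model % self.n_heads:
            raise ValueError("d_model (= 2*lstm_hidden) must be divisible by n_heads")
        if self.encoding_length % (2 ** self.unet_depth):
            raise ValueError("encoding_length must be divisible by 2**unet_depth")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(**d)


def pairwise_concat(h: Tensor) -> Tensor:
    """(B, L, D) -> (B, 2D, L, L) grid; entry (i, j) is [h_i ; h_j]."""
    b, l, d = h.shape
    rows = ag.broadcast_to(h.reshape(b, l, 1, d), (b, l, l, d))
    cols = ag.broadcast_to(h.reshape(b, 1, l, d), (b, l, l, d))
    grid = ag.concat([rows, cols], axis=-1)  # (B, L, L, 2D)
    return grid.transpose(0, 3, 1, 2)


class _UNet(nn.Module):
    """Symmetric encoder/decoder; the output of down level i is added to the
    mirrored up level (the skip connection), and a final 1x1 head maps to a
    single-channel logit matrix."""

    def __init__(self, in_channels: int, base: int, depth: int, rng: np.random.Generator):
        self.depth = depth
        chans = [base * (2 ** i) for i in range(depth + 1)]

        def conv_param(c_in, c_out, k):
            limit = np.sqrt(6.0 / (c_in * k * k + c_out * k * k))
            return Tensor(rng.uniform(-limit, limit, size=(c_out, c_in, k, k)), requires_grad=True)

        self.stem_w = conv_param(in_channels, chans[0], 3)
        self.stem_b = Tensor(np.zeros(chans[0]), requires_grad=True)
        self.down_w = [conv_param(chans[i], chans[i + 1], 3) for i in range(depth)]
        self.down_b = [Tensor(np.zeros(chans[i + 1]), requires_grad=True) for i in range(depth)]
        self.up_w = [conv_param(chans[i + 1], chans[i], 3) for i in reversed(range(depth))]
        self.up_b = [Tensor(np.zeros(chans[i]), requires_grad=True) for i in reversed(range(depth))]
        self.head_w = conv_param(chans[0], 1, 1)
        self.head_b = Tensor(np.zeros(1), requires_grad=True)

    def parameters(self):
        out = {"stem_w": self.stem_w, "stem_b": self.stem_b,
               "head_w": self.head_w, "head_b": self.head_b}
        for i in range(self.depth):
            out[f"down_w.{i}"], out[f"down_b.{i}"] = self.down_w[i], self.down_b[i]
            out[f"up_w.{i}"], out[f"up_b.{i}"] = self.up_w[i], self.up_b[i]
        return out

    def __call__(self, x: Tensor) -> Tensor:
        h = ag.relu(ag.conv2d(x, self.stem_w, self.stem_b))
        skips = [h]
        for i in range(self.depth):
            h = ag.avg_pool2d(h, 2)
            h = ag.relu(ag.conv2d(h, self.down_w[i], self.down_b[i]))
            skips.append(h)
        for i in range(self.depth):
            h = ag.upsample_nearest2d(h, 2)
            h = ag.relu(ag.conv2d(h, self.up_w[i], self.up_b[i]))
            h = h + skips[self.depth - 1 - i]
        return ag.conv2d(h, self.head_w, self.head_b)


class PairScorer(nn.Module):
    """End-to-end scorer producing an L x L logit matrix per sequence."""

    def __init__(self, cfg: ModelConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        self.embedding = nn.Embedding(N_SYMBOLS, cfg.embed_dim, rng)
        self.bilstm = nn.BiLSTM(cfg.embed_dim, cfg.lstm_hidden, rng)
        self.encoder_layers = [
            nn.TransformerEncoderLayer(cfg.d_model, cfg.n_heads, 4 * cfg.d_model, rng)
            for _ in range(cfg.n_encoder_layers)
        ]
        self.generator = _UNet(2 * cfg.d_model, cfg.unet_base_channels, cfg.unet_depth, rng)

    # --- stages -----------------------------------------------------------
    def embed(self, codes: np.ndarray) -> Tensor:
        codes = np.asarray(codes)
        if codes.min() < 0 or codes.max() >= N_SYMBOLS:
            raise ValueError("codes must lie in 0..4")
        return self.embedding(codes)

    def global_semantic_extract(self, emb: Tensor) -> Tensor:
        h = self.bilstm(emb)
        for layer in self.encoder_layers:
            h = layer(h)
        return h

    def generate_scores(self, pairgrid: Tensor) -> Tensor:
        out = self.generator(pairgrid)  # (B, 1, L, L)
        b, _, l, _ = out.shape
        return out.reshape(b, l, l)

    def forward_score(self, codes: np.ndarray) -> Tensor:
        codes = np.asarray(codes)
        squeeze = codes.ndim == 1
        if squeeze:
            codes = codes[None, :]
        scores = self.generate_scores(pairwise_concat(self.global_semantic_extract(self.embed(codes))))
        return scores[0] if squeeze else scores

    __call__ = forward_score

    @property
    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters().values()))


def save_checkpoint(path, model: PairScorer, manifest: dict | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, **model.state_dict())
    sidecar = {"model_config": model.cfg.to_dict(), **(manifest or {})}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_checkpoint(path) -> tuple[PairScorer, dict]:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    cfg = ModelConfig.from_dict(sidecar["model_config"])
    model = PairScorer(cfg)
    with np.load(path if path.suffix == ".npz" else path.with_suffix(".npz")) as archive:
        model.load_state_dict({k: archive[k] for k in archive.files})
    return model, sidecar
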