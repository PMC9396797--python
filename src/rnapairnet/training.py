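"""Two-stage transfer-learning driver.

Stage one (pre-training) fits the scorer alone — embedding, global
semantic extractor, generator — against padded label matrices with the
pw-weighted logistic loss and Adam.  Stage two (fine-tuning) appends the
constraint-projection layer on top, switches to the negative soft-F1 loss
on the layer's soft output, and either trains everything (``full``) or
freezes all parameters below the topmost trainable stage
(``freeze_below_top``: only the generator's final up-convolution and the
1x1 output head stay trainable; the projection layer itself has no
parameters).  The learning rate is halved whenever consecutive epoch
losses differ by less than 0.0004.

Every run emits a manifest (config snapshot, seed, per-epoch losses) next
to its checkpoint so results are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from . import constraint_layer as clayer
from . import evaluation as ev
from . import losses as ls
from . import nn
from .constraint_layer import ConstraintLayerConfig
from .constraints import build_constraint_matrix
from .io import RnaSequence, SecondaryStructure, encode_sequence, structure_to_pair_matrix
from .network import ModelConfig, PairScorer

__all__ = [
    "TrainConfig",
    "TrainResult",
    "lr_schedule_step",
    "pretrain",
    "finetune",
    "predict_structure",
    "evaluate_model",
    "prepare_records",
]

LR_DROP_THRESHOLD = 0.0004
TOP_LAYER_PARAMS = ("generator.up_w", "generator.up_b", "generator.head_w", "generator.head_b")


@dataclass
class TrainConfig:
    stage: str = "pretrain"
    loss: ls.LossConfig = field(default_factory=ls.LossConfig)
    lr: float = 1e-3
    lr_drop_threshold: float = LR_DROP_THRESHOLD
    lr_drop_factor: float = 0.5
    epochs: int = 30
    batch_size: int = 8
    freeze_strategy: str = "full"
    seed: int = 0
    constraint: ConstraintLayerConfig = field(default_factory=ConstraintLayerConfig)

    def __post_init__(self):
        if self.lr <= 0 or self.epochs < 0 or self.batch_size < 1:
            raise ValueError("invalid training configuration")
        if self.freeze_strategy not in ("full", "freeze_below_top"):
            raise ValueError(f"unknown freeze strategy {self.freeze_strategy!r}")


@dataclass
class TrainResult:
    model: PairScorer
    manifest: dict


def lr_schedule_step(prev_loss: float, curr_loss: float, lr: float,
                     cfg: TrainConfig) -> float:
    """Halve (by ``lr_drop_factor``) when epoch losses differ by < threshold."""
    if abs(prev_loss - curr_loss) < cfg.lr_drop_threshold:
        return lr * cfg.lr_drop_factor
    return lr


def prepare_records(records, encoding_length: int):
    """(RnaSequence, SecondaryStructure) pairs -> (codes, label, mask, true_length)."""
    out = []
    for seq, structure in records:
        enc = encode_sequence(seq, encoding_length)
        label = structure_to_pair_matrix(structure, padded_length=encoding_length)
        mask = build_constraint_matrix(seq, padded_length=encoding_length)
        out.append((enc.codes, label, mask, len(seq)))
    return out


def _batches(prepared, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(len(prepared))
    for start in range(0, len(prepared), batch_size):
        chunk = [prepared[i] for i in order[start:start + batch_size]]
        codes = np.stack([c for c, _, _, _ in chunk])
        labels = np.stack([l for _, l, _, _ in chunk]).astype(float)
        masks = [m for _, _, m, _ in chunk]
        yield codes, labels, masks


def pretrain(records, model_cfg: ModelConfig, train_cfg: TrainConfig,
             model: PairScorer | None = None) -> TrainResult:
    """Train the scorer (no projection layer) with the weighted logistic loss."""
    if train_cfg.stage != "pretrain":
        raise ValueError("train_cfg.stage must be 'pretrain'")
    if not records:
        raise ValueError("empty training set")
    model = model or PairScorer(model_cfg)
    prepared = prepare_records(records, model_cfg.encoding_length)
    loss_fn = lambda s, y: ls.weighted_logistic_loss(s, y, pw=train_cfg.loss.pw)
    opt = nn.Adam(model.parameters(), lr=train_cfg.lr)
    rng = np.random.default_rng(train_cfg.seed)
    epoch_losses = []
    lr = train_cfg.lr
    for _ in range(train_cfg.epochs):
        total, count = 0.0, 0
        for codes, labels, _ in _batches(prepared, train_cfg.batch_size, rng):
            scores = model.forward_score(codes)
            loss = loss_fn(scores, labels)
            opt.zero_grad()
            loss.backward()
            opt.lr = lr
            opt.step()
            total += loss.item() * len(codes)
            count += len(codes)
        epoch_losses.append(total / count)
        if len(epoch_losses) >= 2:
            lr = lr_schedule_step(epoch_losses[-2], epoch_losses[-1], lr, train_cfg)
    manifest = {
        "stage": "pretrain",
        "seed": train_cfg.seed,
        "epoch_losses": epoch_losses,
        "train_config": _cfg_dict(train_cfg),
        "n_records": len(records),
    }
    return TrainResult(model=model, manifest=manifest)


def finetune(model: PairScorer, records, train_cfg: TrainConfig,
             validation=None) -> TrainResult:
    """Append the projection layer and train with the negative soft-F1 loss.

    ``freeze_below_top`` keeps only the generator's up path and output head
    trainable; ``full`` trains everything.  If a validation set is given,
    per-epoch validation F1 is recorded and the best-F1 parameters are
    restored at the end.
    """
    prepared = prepare_records(records, model.cfg.encoding_length)
    params = model.parameters()
    if train_cfg.freeze_strategy == "freeze_below_top":
        trainable = {k: p for k, p in params.items() if k.startswith(TOP_LAYER_PARAMS)}
        frozen = {k: p for k, p in params.items() if k not in trainable}
        for p in frozen.values():
            p.requires_grad = False
    else:
        trainable, frozen = dict(params), {}
    opt = nn.Adam(trainable, lr=train_cfg.lr)
    rng = np.random.default_rng(train_cfg.seed)
    epoch_losses, val_f1s = [], []
    best = (None, -1.0)
    lr = train_cfg.lr
    ccfg = train_cfg.constraint
    for _ in range(train_cfg.epochs):
        total, count = 0.0, 0
        for codes, labels, masks in _batches(prepared, train_cfg.batch_size, rng):
            batch_loss = None
            for b in range(len(codes)):
                scores = model.forward_score(codes[b])
                soft, _ = clayer.postprocess(scores, masks[b], y=labels[b], cfg=ccfg)
                term = ls.negative_f1_loss(soft, ls.Tensor(labels[b]))
                batch_loss = term if batch_loss is None else batch_loss + term
            batch_loss = batch_loss * (1.0 / len(codes))
            opt.zero_grad()
            batch_loss.backward()
            opt.lr = lr
            opt.step()
            total += batch_loss.item() * len(codes)
            count += len(codes)
        epoch_losses.append(total / count)
        if len(epoch_losses) >= 2:
            lr = lr_schedule_step(epoch_losses[-2], epoch_losses[-1], lr, train_cfg)
        if validation is not None:
            report = evaluate_model(model, validation, ccfg)
            val_f1s.append(report.f1)
            if report.f1 > best[1]:
                best = (model.state_dict(), report.f1)
    for p in frozen.values():
        p.requires_grad = True
    if validation is not None and best[0] is not None:
        model.load_state_dict(best[0])
    manifest = {
        "stage": "finetune",
        "seed": train_cfg.seed,
        "epoch_losses": epoch_losses,
        "validation_f1": val_f1s,
        "freeze_strategy": train_cfg.freeze_strategy,
        "train_config": _cfg_dict(train_cfg),
        "n_records": len(records),
    }
    return TrainResult(model=model, manifest=manifest)


def predict_structure(model: PairScorer, seq: RnaSequence,
                      ccfg: ConstraintLayerConfig | None = None) -> SecondaryStructure:
    enc = encode_sequence(seq, model.cfg.encoding_length)
    scores = model.forward_score(enc.codes).data
    mask = build_constraint_matrix(seq, padded_length=model.cfg.encoding_length)
    _, hard = clayer.postprocess(scores, mask, y=None, cfg=ccfg or ConstraintLayerConfig())
    from .io import pair_matrix_to_structure

    return pair_matrix_to_structure(hard, true_length=len(seq))


def evaluate_model(model: PairScorer, records,
                   ccfg: ConstraintLayerConfig | None = None,
                   use_constraint_layer: bool = True) -> ev.MetricReport:
    """Micro-averaged pair-level metrics over padded matrices.

    With ``use_constraint_layer=False`` the raw scores are thresholded at
    0.5 on the sigmoid scale instead — the "pre-trained model alone"
    operating mode.
    """
    prepared = prepare_records(records, model.cfg.encoding_length)
    reports = []
    for codes, label, mask, _ in prepared:
        scores = model.forward_score(codes).data
        if use_constraint_layer:
            _, hard = clayer.postprocess(scores, mask, y=None,
                                         cfg=ccfg or ConstraintLayerConfig())
        else:
            hard = (1.0 / (1.0 + np.exp(-scores)) > 0.5).astype(np.int8)
        reports.append(ev.report_from_counts(ev.confusion_counts(hard, label)))
    return ev.aggregate(reports, mode="micro")


def _cfg_dict(cfg: TrainConfig) -> dict:
    d = asdict(cfg)
    return d
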