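"""Weighted-BCE training for both ensemble variants.

Contact-map cells are overwhelmingly negative (a length-n sequence has at
most n/2 of the ~n^2 cells positive), so the binary cross-entropy puts a
large weight — 300 by default — on positive cells.  Optimization is Adam
with its usual defaults, batch size 4; examples in a batch are zero-padded
to the batch's longest sequence with validity masks so padding never
contributes to the loss.  Model selection follows validation F1 computed
after full constrained decoding, and the best-epoch parameters are
returned alongside a per-epoch history.
"""

from __future__ import annotations

import copy
import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .decoder import DecoderConfig, decode
from .ensemble_net import (
    CbamParams,
    LiteParams,
    backward,
    forward_cached,
    lite_backward,
    lite_forward,
)
from .learner_stack import LearnerStack
from .metrics import confusion, precision_recall_f1
from .structure_io import ContactMap, RnaSequence, StructureRecord

logger = logging.getLogger(__name__)

_EPS = 1e-7


@dataclass(frozen=True)
class TrainConfig:
    """Training hyper-parameters (positive-class weight 300, Adam, batch 4)."""

    pos_weight: float = 300.0
    batch_size: int = 4
    epochs: int = 100
    learning_rate: float = 1e-3
    seed: int = 0
    max_len: int = 500
    reduction_ratio: int = 1
    decoder: DecoderConfig = field(default_factory=DecoderConfig)

    def __post_init__(self) -> None:
        if self.pos_weight < 1:
            raise ValueError("pos_weight must be >= 1")
        if min(self.batch_size, self.epochs, self.max_len) < 1:
            raise ValueError("batch_size, epochs and max_len must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


@dataclass(frozen=True)
class TrainingExample:
    """One padded example: learner stack, truth matrix and validity mask."""

    stack: LearnerStack
    truth: ContactMap
    valid_mask: np.ndarray  # (n_pad, n_pad); 1 exactly on the real n x n block

    @property
    def n(self) -> int:
        return self.truth.n


# ---------------------------------------------------------------------------
# Loss
# ---------------------------------------------------------------------------

def weighted_bce(
    Y: np.ndarray, Z: np.ndarray, mask: np.ndarray | None, pos_weight: float
) -> float:
    """Mean weighted binary cross-entropy over masked cells.

    ``-[w * y * log(p) + (1 - y) * log(1 - p)]`` with ``w = pos_weight`` on
    positive cells; probabilities at exactly 0 or 1 are clamped to
    ``1e-7`` away from the boundary (logged once per call).
    """
    Y = np.asarray(Y, dtype=np.float64)
    Z = np.asarray(Z, dtype=np.float64)
    mask = np.ones_like(Y) if mask is None else np.asarray(mask, dtype=np.float64)
    if np.any((Y <= 0) | (Y >= 1)):
        logger.debug("clamping probabilities at the [%g, %g] boundary", _EPS, 1 - _EPS)
    p = np.clip(Y, _EPS, 1.0 - _EPS)
    cell = -(pos_weight * Z * np.log(p) + (1.0 - Z) * np.log(1.0 - p))
    total = float((cell * mask).sum())
    count = float(mask.sum())
    return total / count if count else 0.0


def weighted_bce_grad(
    Y: np.ndarray, Z: np.ndarray, mask: np.ndarray | None, pos_weight: float
) -> np.ndarray:
    """d(loss)/dY for the clamped loss (zero where clamping saturates)."""
    Y = np.asarray(Y, dtype=np.float64)
    Z = np.asarray(Z, dtype=np.float64)
    mask = np.ones_like(Y) if mask is None else np.asarray(mask, dtype=np.float64)
    p = np.clip(Y, _EPS, 1.0 - _EPS)
    g = (-pos_weight * Z / p + (1.0 - Z) / (1.0 - p)) * mask
    count = float(mask.sum())
    return g / count if count else g


def _bce_grad_logits(
    Y: np.ndarray, Z: np.ndarray, mask: np.ndarray | None, pos_weight: float
) -> np.ndarray:
    """d(loss)/d(logits) for a sigmoid head: numerically stable form."""
    mask = np.ones_like(Y) if mask is None else np.asarray(mask, dtype=np.float64)
    g = (Y * (pos_weight * Z + 1.0 - Z) - pos_weight * Z) * mask
    count = float(mask.sum())
    return g / count if count else g


# ---------------------------------------------------------------------------
# Batching
# ---------------------------------------------------------------------------

def make_batches(
    dataset: Sequence[tuple[LearnerStack, ContactMap]],
    batch_size: int,
    seed: int,
) -> list[list[TrainingExample]]:
    """Shuffle, batch and zero-pad examples to each batch's longest n."""
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(dataset))
    batches: list[list[TrainingExample]] = []
    for start in range(0, len(dataset), batch_size):
        chunk = [dataset[i] for i in order[start : start + batch_size]]
        n_pad = max(stack.n for stack, _ in chunk)
        batch = []
        for stack, truth in chunk:
            n = stack.n
            A = np.zeros((stack.l, n_pad, n_pad))
            A[:, :n, :n] = stack.A
            mask = np.zeros((n_pad, n_pad))
            mask[:n, :n] = 1.0
            batch.append(
                TrainingExample(
                    stack=LearnerStack(stack.learner_names, A),
                    truth=truth,
                    valid_mask=mask,
                )
            )
        batches.append(batch)
    return batches


# ---------------------------------------------------------------------------
# Adam
# ---------------------------------------------------------------------------

class Adam:
    """Plain Adam over a dict of named parameter arrays."""

    def __init__(self, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}
        self.t = 0

    def step(self, arrays: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
        self.t += 1
        out = {}
        for k, a in arrays.items():
            g = np.asarray(grads[k], dtype=np.float64)
            self.m[k] = self.beta1 * self.m.get(k, 0.0) + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v.get(k, 0.0) + (1 - self.beta2) * g * g
            mhat = self.m[k] / (1 - self.beta1**self.t)
            vhat = self.v[k] / (1 - self.beta2**self.t)
            out[k] = a - self.lr * mhat / (np.sqrt(vhat) + self.eps)
        return out


# ---------------------------------------------------------------------------
# Training loop
# ---------------------------------------------------------------------------

def _example_grads(example: TrainingExample, params, pos_weight: float):
    """Loss and parameter gradients for one (padded) example.

    The forward pass runs on the unpadded n x n block — pooling statistics
    must not see padding — which is exact because every mask is a top-left
    block.
    """
    n = example.n
    A = example.stack.A[:, :n, :n]
    Z = example.truth.matrix()
    if isinstance(params, LiteParams):
        Y = lite_forward(A, params)
        loss = weighted_bce(Y, Z, None, pos_weight)
        dY = weighted_bce_grad(Y, Z, None, pos_weight)
        return loss, lite_backward(A, params, dY)
    cache = forward_cached(A, params)
    loss = weighted_bce(cache["Y"], Z, None, pos_weight)
    dlogits = _bce_grad_logits(cache["Y"], Z, None, pos_weight)
    return loss, backward(cache, dlogits, params)


def _validation_f1(params, val_set, decoder_cfg: DecoderConfig) -> float:
    f1s = []
    for stack, truth, seq in val_set:
        Y = (
            lite_forward(stack, params)
            if isinstance(params, LiteParams)
            else _padded_forward(stack, params)
        )
        pred = decode(Y, seq, decoder_cfg)
        _, _, f1 = precision_recall_f1(confusion(pred, truth))
        f1s.append(f1)
    return float(np.median(f1s)) if f1s else 0.0


def _padded_forward(stack: LearnerStack, params: CbamParams) -> np.ndarray:
    return forward_cached(stack.A, params)["Y"]


def train(
    dataset: Sequence[tuple[LearnerStack, ContactMap]],
    val_set: Sequence[tuple[LearnerStack, ContactMap, RnaSequence]],
    cfg: TrainConfig,
    model: str = "attention",
    init_params: CbamParams | LiteParams | None = None,
) -> tuple[CbamParams | LiteParams, list[dict]]:
    """Train an ensemble; return best-validation-F1 parameters and history.

    ``dataset`` holds (stack, truth) pairs; ``val_set`` additionally carries
    the sequence so validation predictions can be decoded under the hard
    constraints.  Deterministic given ``cfg.seed``.
    """
    if not dataset:
        raise ValueError("empty training dataset")
    _warn_degenerate(dataset)
    l = dataset[0][0].l
    if init_params is not None:
        params = copy.deepcopy(init_params)
    elif model == "lite":
        params = LiteParams.init(l)
    elif model == "attention":
        params = CbamParams.init(
            l, r=cfg.reduction_ratio, rng=np.random.default_rng(cfg.seed)
        )
    else:
        raise ValueError(f"unknown model {model!r}")

    opt = Adam(lr=cfg.learning_rate)
    history: list[dict] = []
    best_f1, best_params = -1.0, copy.deepcopy(params)
    for epoch in range(cfg.epochs):
        batches = make_batches(dataset, cfg.batch_size, seed=cfg.seed + epoch)
        epoch_loss = 0.0
        n_examples = 0
        for batch in batches:
            grads_sum: dict[str, np.ndarray] = {}
            for ex in batch:
                loss, grads = _example_grads(ex, params, cfg.pos_weight)
                epoch_loss += loss
                n_examples += 1
                for k, g in grads.items():
                    grads_sum[k] = grads_sum.get(k, 0.0) + g
            grads_mean = {k: g / len(batch) for k, g in grads_sum.items()}
            params = params.with_arrays(opt.step(params.arrays(), grads_mean))
        val_f1 = _validation_f1(params, val_set, cfg.decoder)
        epoch_loss /= max(n_examples, 1)
        history.append({"epoch": epoch, "loss": epoch_loss, "val_f1": val_f1})
        logger.info("epoch %d loss %.4f val_f1 %.4f", epoch, epoch_loss, val_f1)
        # ties prefer the later epoch: continued descent on the training loss
        if val_f1 >= best_f1:
            best_f1, best_params = val_f1, copy.deepcopy(params)
    return best_params, history


def _warn_degenerate(dataset) -> None:
    n_pos = sum(len(truth.pairs) for _, truth in dataset)
    if n_pos == 0:
        warnings.warn("training labels are all-negative (no pairs)", stacklevel=2)


def dataset_views(
    records: Sequence[StructureRecord], stacks: Sequence[LearnerStack]
) -> tuple[list[tuple[LearnerStack, ContactMap]], list[tuple[LearnerStack, ContactMap, RnaSequence]]]:
    """Convenience: (train-style, validation-style) views of a benchmark."""
    train_view = [(s, r.structure) for r, s in zip(records, stacks)]
    val_view = [(s, r.structure, r.sequence) for r, s in zip(records, stacks)]
    return train_view, val_view
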