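"""Ensemble networks over base-learner contact-map stacks.

Two variants are implemented:

* the full attention ensemble — channel attention over learners (the "RSS
  pattern" block), spatial attention over positions (the "domain focus"
  block, a 7x7 convolution over channel-pooled descriptors), and a learned
  1x1 channel-reduction head with a sigmoid, producing an n x n
  pair-probability map; and
* the lite ensemble — a softmax-normalized weight per learner and a convex
  combination of their binary contact maps, which already lies in [0, 1].

The parameter count is tiny (order 10^2 for four learners), so the model is
implemented directly in numpy with hand-derived backpropagation; gradients
are validated against finite differences in the test suite.  Forward passes
are pure functions of (stack, params).

Conventions: the channel-attention MLP is the CBAM two-layer perceptron
``W2 @ relu(W1 @ x + b1) + b2`` shared between the average- and max-pooled
descriptors; spatial pooling reduces over both spatial axes per channel,
channel pooling reduces over learners per cell; max-pool gradients are
routed to the first arg-max in case of ties.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
from scipy.signal import convolve2d

from .learner_stack import LearnerStack

CHECKPOINT_VERSION = 1


def sigmoid(x: np.ndarray | float) -> np.ndarray | float:
    return 0.5 * (1.0 + np.tanh(0.5 * np.asarray(x, dtype=np.float64)))


@dataclass
class CbamParams:
    """All learned quantities of the attention ensemble.

    ``mlp_w1`` maps the l-vector of pooled channel descriptors to a hidden
    layer of size ``max(l // r, 1)`` (reduction ratio ``r``; with few
    learners the default r=1 means no bottleneck); ``mlp_w2`` maps back to
    l.  ``conv7`` is a (2, 7, 7) kernel over the [avg; max] channel-pooled
    spatial descriptor pair, with scalar bias ``conv_b``.  ``head_w`` /
    ``head_b`` form the 1x1 channel-reduction head.
    """

    mlp_w1: np.ndarray
    mlp_b1: np.ndarray
    mlp_w2: np.ndarray
    mlp_b2: np.ndarray
    conv7: np.ndarray
    conv_b: float
    head_w: np.ndarray
    head_b: float
    r: int = 1

    @property
    def l(self) -> int:
        return self.head_w.shape[0]

    @classmethod
    def init(cls, l: int, r: int = 1, rng: np.random.Generator | None = None) -> "CbamParams":
        if rng is None:
            rng = np.random.default_rng(0)
        h = max(l // r, 1)
        scale = 0.1
        return cls(
            mlp_w1=scale * rng.standard_normal((h, l)),
            mlp_b1=np.zeros(h),
            mlp_w2=scale * rng.standard_normal((l, h)),
            mlp_b2=np.zeros(l),
            conv7=scale * rng.standard_normal((2, 7, 7)),
            conv_b=0.0,
            head_w=np.full(l, 1.0),
            head_b=-0.5,
            r=r,
        )

    def arrays(self) -> dict[str, np.ndarray]:
        """Named parameter arrays (scalars as 0-d arrays), for the optimizer."""
        return {
            "mlp_w1": self.mlp_w1,
            "mlp_b1": self.mlp_b1,
            "mlp_w2": self.mlp_w2,
            "mlp_b2": self.mlp_b2,
            "conv7": self.conv7,
            "conv_b": np.asarray(self.conv_b, dtype=np.float64),
            "head_w": self.head_w,
            "head_b": np.asarray(self.head_b, dtype=np.float64),
        }

    def with_arrays(self, arrays: Mapping[str, np.ndarray]) -> "CbamParams":
        return CbamParams(
            mlp_w1=np.asarray(arrays["mlp_w1"]),
            mlp_b1=np.asarray(arrays["mlp_b1"]),
            mlp_w2=np.asarray(arrays["mlp_w2"]),
            mlp_b2=np.asarray(arrays["mlp_b2"]),
            conv7=np.asarray(arrays["conv7"]),
            conv_b=float(np.asarray(arrays["conv_b"]).reshape(())[()]),
            head_w=np.asarray(arrays["head_w"]),
            head_b=float(np.asarray(arrays["head_b"]).reshape(())[()]),
            r=self.r,
        )


@dataclass
class LiteParams:
    """Pre-softmax learner weights of the lite ensemble."""

    raw_weights: np.ndarray

    @property
    def l(self) -> int:
        return self.raw_weights.shape[0]

    @classmethod
    def init(cls, l: int) -> "LiteParams":
        return cls(raw_weights=np.zeros(l))

    def arrays(self) -> dict[str, np.ndarray]:
        return {"raw_weights": self.raw_weights}

    def with_arrays(self, arrays: Mapping[str, np.ndarray]) -> "LiteParams":
        return LiteParams(raw_weights=np.asarray(arrays["raw_weights"]))

    @property
    def weights(self) -> np.ndarray:
        return lite_softmax(self.raw_weights)


# ---------------------------------------------------------------------------
# Attention ensemble: forward blocks
# ---------------------------------------------------------------------------

def _mlp(x: np.ndarray, p: CbamParams) -> np.ndarray:
    h = p.mlp_w1 @ x + p.mlp_b1
    return p.mlp_w2 @ np.maximum(h, 0.0) + p.mlp_b2


def rss_pattern_block(
    A: np.ndarray | LearnerStack, p: CbamParams
) -> tuple[np.ndarray, np.ndarray]:
    """Channel attention: reweight learners by pooled spatial descriptors.

    Returns ``(Fp, A')`` where ``Fp = sigmoid(MLP(avgpool(A)) +
    MLP(maxpool(A)))`` is the length-l attention vector and
    ``A'[c] = Fp[c] * A[c]``.
    """
    A = A.A if isinstance(A, LearnerStack) else np.asarray(A, dtype=np.float64)
    avg = A.mean(axis=(1, 2))
    mx = A.max(axis=(1, 2))
    Fp = sigmoid(_mlp(avg, p) + _mlp(mx, p))
    return Fp, Fp[:, None, None] * A


def _conv_same(D: np.ndarray, kernel: np.ndarray, bias: float) -> np.ndarray:
    """2-channel 7x7 cross-correlation with same (zero) padding."""
    pad = kernel.shape[-1] // 2
    n = D.shape[1]
    S = np.full((n, n), bias, dtype=np.float64)
    for c in range(D.shape[0]):
        # correlate == convolve with the flipped kernel
        S += convolve2d(D[c], kernel[c, ::-1, ::-1], mode="same")
    return S


def domain_focus_block(
    A_prime: np.ndarray, p: CbamParams
) -> tuple[np.ndarray, np.ndarray]:
    """Spatial attention: a 7x7 conv over channel-pooled descriptors.

    Returns ``(Fd, A'')`` with ``Fd = sigmoid(conv7([avgpool_c; maxpool_c]))``
    an n x n map and ``A''[c] = Fd * A'[c]``.
    """
    A_prime = np.asarray(A_prime, dtype=np.float64)
    D = np.stack([A_prime.mean(axis=0), A_prime.max(axis=0)])
    Fd = sigmoid(_conv_same(D, p.conv7, p.conv_b))
    return Fd, Fd[None, :, :] * A_prime


def channel_head(A_dprime: np.ndarray, p: CbamParams) -> np.ndarray:
    """1x1 channel reduction to a pair-probability map Y = sigmoid(w.A'' + b)."""
    return sigmoid(np.tensordot(p.head_w, A_dprime, axes=(0, 0)) + p.head_b)


def attention_forward(stack: LearnerStack | np.ndarray, p: CbamParams) -> np.ndarray:
    """Full attention-ensemble forward pass: stack -> pair-probability map."""
    _, A_prime = rss_pattern_block(stack, p)
    _, A_dprime = domain_focus_block(A_prime, p)
    return channel_head(A_dprime, p)


# ---------------------------------------------------------------------------
# Attention ensemble: forward with cache + backward
# ---------------------------------------------------------------------------

def forward_cached(A: np.ndarray, p: CbamParams) -> dict:
    """Forward pass retaining every intermediate needed by the backward pass.

    The returned cache holds ``Y`` (probabilities) and ``logits`` (the head
    pre-activation), which the loss differentiates directly.
    """
    A = np.asarray(A, dtype=np.float64)
    l, n, _ = A.shape
    avg = A.mean(axis=(1, 2))
    flat = A.reshape(l, -1)
    mx_idx = flat.argmax(axis=1)
    mx = flat[np.arange(l), mx_idx]

    h_a_pre = p.mlp_w1 @ avg + p.mlp_b1
    h_m_pre = p.mlp_w1 @ mx + p.mlp_b1
    m_a = p.mlp_w2 @ np.maximum(h_a_pre, 0.0) + p.mlp_b2
    m_m = p.mlp_w2 @ np.maximum(h_m_pre, 0.0) + p.mlp_b2
    Fp = sigmoid(m_a + m_m)
    A_prime = Fp[:, None, None] * A

    cavg = A_prime.mean(axis=0)
    cmax_idx = A_prime.argmax(axis=0)
    cmax = np.take_along_axis(A_prime, cmax_idx[None], axis=0)[0]
    D = np.stack([cavg, cmax])
    S = _conv_same(D, p.conv7, p.conv_b)
    Fd = sigmoid(S)
    A_dprime = Fd[None] * A_prime

    logits = np.tensordot(p.head_w, A_dprime, axes=(0, 0)) + p.head_b
    Y = sigmoid(logits)
    return {
        "A": A, "avg": avg, "mx_idx": mx_idx,
        "h_a_pre": h_a_pre, "h_m_pre": h_m_pre, "Fp": Fp, "A_prime": A_prime,
        "cmax_idx": cmax_idx, "D": D, "Fd": Fd, "A_dprime": A_dprime,
        "logits": logits, "Y": Y,
    }


def backward(cache: dict, dlogits: np.ndarray, p: CbamParams) -> dict[str, np.ndarray]:
    """Backpropagate d(loss)/d(logits) to gradients for every parameter."""
    A = cache["A"]
    l, n, _ = A.shape
    A_prime, A_dprime, Fd, Fp = (
        cache["A_prime"], cache["A_dprime"], cache["Fd"], cache["Fp"],
    )

    # head
    d_head_w = np.tensordot(dlogits, A_dprime, axes=([0, 1], [1, 2]))
    d_head_b = dlogits.sum()
    dA_dprime = p.head_w[:, None, None] * dlogits[None]

    # spatial attention
    dFd = (dA_dprime * A_prime).sum(axis=0)
    dA_prime = dA_dprime * Fd[None]
    dS = dFd * Fd * (1.0 - Fd)
    pad = p.conv7.shape[-1] // 2
    Dp = np.pad(cache["D"], ((0, 0), (pad, pad), (pad, pad)))
    d_conv7 = np.empty_like(p.conv7)
    dD = np.empty_like(cache["D"])
    for c in range(2):
        # dK[c,u,v] = sum_ij dS[i,j] * Dp[c,i+u,j+v]  (valid correlation)
        d_conv7[c] = convolve2d(Dp[c], dS[::-1, ::-1], mode="valid")
        # gradient w.r.t. the padded input, then crop the interior
        dD[c] = convolve2d(dS, p.conv7[c], mode="full")[pad:pad + n, pad:pad + n]
    d_conv_b = dS.sum()
    # channel-pool backward: avg spreads evenly, max routes to the arg max
    dA_prime += dD[0][None] / l
    np.put_along_axis(
        dA_prime, cache["cmax_idx"][None],
        np.take_along_axis(dA_prime, cache["cmax_idx"][None], axis=0) + dD[1][None],
        axis=0,
    )

    # channel attention
    dFp = (dA_prime * A).sum(axis=(1, 2))
    dA = dA_prime * Fp[:, None, None]
    dpre = dFp * Fp * (1.0 - Fp)  # through sigmoid; shared by both MLP branches

    d_mlp_w1 = np.zeros_like(p.mlp_w1)
    d_mlp_b1 = np.zeros_like(p.mlp_b1)
    d_mlp_w2 = np.zeros_like(p.mlp_w2)
    d_mlp_b2 = np.zeros_like(p.mlp_b2)
    for x, h_pre in ((cache["avg"], cache["h_a_pre"]), (_gather_mx(cache), cache["h_m_pre"])):
        h = np.maximum(h_pre, 0.0)
        d_mlp_w2 += np.outer(dpre, h)
        d_mlp_b2 += dpre
        dh = (p.mlp_w2.T @ dpre) * (h_pre > 0)
        d_mlp_w1 += np.outer(dh, x)
        d_mlp_b1 += dh
    # (gradients w.r.t. A itself are not needed: A is the binary input)

    return {
        "mlp_w1": d_mlp_w1, "mlp_b1": d_mlp_b1,
        "mlp_w2": d_mlp_w2, "mlp_b2": d_mlp_b2,
        "conv7": d_conv7, "conv_b": np.asarray(d_conv_b),
        "head_w": d_head_w, "head_b": np.asarray(d_head_b),
    }


def _gather_mx(cache: dict) -> np.ndarray:
    A = cache["A"]
    flat = A.reshape(A.shape[0], -1)
    return flat[np.arange(A.shape[0]), cache["mx_idx"]]


# ---------------------------------------------------------------------------
# Lite ensemble
# ---------------------------------------------------------------------------

def lite_softmax(raw_weights: np.ndarray) -> np.ndarray:
    """Numerically stabilized softmax of the pre-softmax learner weights."""
    raw = np.asarray(raw_weights, dtype=np.float64)
    e = np.exp(raw - raw.max())
    return e / e.sum()


def lite_combine(stack: LearnerStack | np.ndarray, pi: np.ndarray) -> np.ndarray:
    """Convex combination of learner contact maps: Y = sum_v pi[v] A[v].

    With simplex weights over binary maps the result is already in [0, 1];
    no extra squashing is applied.
    """
    A = stack.A if isinstance(stack, LearnerStack) else np.asarray(stack, dtype=np.float64)
    pi = np.asarray(pi, dtype=np.float64)
    if pi.shape[0] != A.shape[0]:
        raise ValueError(f"{pi.shape[0]} weights for {A.shape[0]} learners")
    return np.tensordot(pi, A, axes=(0, 0))


def lite_forward(stack: LearnerStack | np.ndarray, p: LiteParams) -> np.ndarray:
    return lite_combine(stack, lite_softmax(p.raw_weights))


def lite_backward(
    A: np.ndarray, p: LiteParams, dY: np.ndarray
) -> dict[str, np.ndarray]:
    """Gradient of the loss w.r.t. the raw (pre-softmax) weights."""
    pi = lite_softmax(p.raw_weights)
    dpi = np.tensordot(dY, A, axes=([0, 1], [1, 2]))
    draw = pi * (dpi - float(pi @ dpi))
    return {"raw_weights": draw}


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

class CheckpointError(ValueError):
    """Raised when a checkpoint cannot be loaded for the supplied stack."""


def save_checkpoint(
    path: str | Path,
    params: CbamParams | LiteParams,
    learner_names: tuple[str, ...] | list[str],
    seed: int | None = None,
) -> None:
    """Serialize parameters plus provenance (learner order, seed) as JSON."""
    kind = "attention" if isinstance(params, CbamParams) else "lite"
    payload = {
        "version": CHECKPOINT_VERSION,
        "kind": kind,
        "learner_names": list(learner_names),
        "l": len(learner_names),
        "r": params.r if isinstance(params, CbamParams) else None,
        "seed": seed,
        "arrays": {k: v.tolist() for k, v in params.arrays().items()},
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_checkpoint(
    path: str | Path, expected_learner_names: tuple[str, ...] | list[str] | None = None
) -> tuple[CbamParams | LiteParams, dict]:
    """Load a checkpoint; refuse it if the learner order disagrees."""
    payload = json.loads(Path(path).read_text())
    if payload.get("version") != CHECKPOINT_VERSION:
        raise CheckpointError(f"unsupported checkpoint version {payload.get('version')}")
    names = tuple(payload["learner_names"])
    if expected_learner_names is not None and tuple(expected_learner_names) != names:
        raise CheckpointError(
            f"checkpoint learner order {names} does not match supplied stack "
            f"order {tuple(expected_learner_names)}"
        )
    arrays = {k: np.asarray(v, dtype=np.float64) for k, v in payload["arrays"].items()}
    if payload["kind"] == "lite":
        params: CbamParams | LiteParams = LiteParams(raw_weights=arrays["raw_weights"])
    else:
        params = CbamParams.init(payload["l"], r=payload["r"] or 1).with_arrays(arrays)
    meta = {k: payload[k] for k in ("kind", "learner_names", "l", "r", "seed")}
    return params, meta
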