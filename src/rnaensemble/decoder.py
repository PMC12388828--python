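"""Hard-constraint decoding of pair-probability maps into contact maps.

A predicted structure must satisfy four validity rules: (1) only canonical
Watson-Crick pairs plus the G-U wobble; (2) the contact map is symmetric;
(3) paired bases are at least four positions apart (|i - j| >= 4); (4) each
base has at most one partner.  Decoding proceeds in four steps:

1. ``build_mask`` — a sequence-derived binary mask enforcing rules 1-3;
2. ``phi_transform`` — symmetrize and mask the raw scores,
   phi(Y) = 1/2 (Y + Y^T) * M;
3. ``solve_matching`` — maximize <Yhat, phi> - rho * ||Yhat||_1 subject to
   row sums <= 1, entries in [0, 1] and symmetry.  The ``exact_matching``
   solver reduces this to maximum-weight graph matching over the edges with
   phi > rho (blossom algorithm); the ``relaxation`` solver runs a
   projected-ascent scheme with Lagrange multipliers on the row constraints
   and a fixed iteration budget.
4. ``binarize`` — keep entries strictly greater than the threshold P.

The exact solver returns a *soft* assignment: phi values on the support of
the optimal matching.  The support is exactly the arg-max of the objective
(the optimum places Yhat = 1 there), but carrying the phi scores forward
lets the final threshold prune matched pairs the model is not confident
about — the same role the threshold plays after the soft relaxation.
``matching_objective`` evaluates the objective on a support with Yhat = 1,
which is the quantity the solvers maximize.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .structure_io import (
    CANONICAL_PAIRS,
    MIN_PAIR_DISTANCE,
    ContactMap,
    RnaSequence,
)


@dataclass(frozen=True)
class ConstraintMask:
    """Binary n x n mask of allowed base pairs for one sequence."""

    M: np.ndarray

    @property
    def n(self) -> int:
        return self.M.shape[0]


@dataclass(frozen=True)
class DecoderConfig:
    """Decoding hyper-parameters.

    ``rho`` is the sparsity penalty of the matching objective (pairs only
    enter the matching if their score exceeds it); ``threshold_P`` prunes
    low-confidence pairs after the optimization.  The exact blossom solver
    is the default; the iterative relaxation is provided for fidelity to
    the end-to-end style of decoder it emulates and is benchmarked against
    the exact optimum in the tests.
    """

    rho: float = 0.0
    threshold_P: float = 0.5
    solver: str = "exact_matching"
    relax_steps: int = 2000
    relax_step_scale: float = 0.99

    def __post_init__(self) -> None:
        if self.rho < 0:
            raise ValueError("rho must be >= 0")
        if not 0.0 < self.threshold_P < 1.0:
            raise ValueError("threshold_P must be in (0, 1)")
        if self.solver not in ("exact_matching", "relaxation"):
            raise ValueError(f"unknown solver {self.solver!r}")


def build_mask(seq: RnaSequence) -> ConstraintMask:
    """Mask allowed pairs: canonical+GU only, |i-j| >= 4; non-ACGU never pair."""
    res = seq.residues
    n = len(res)
    M = np.zeros((n, n), dtype=np.float64)
    for i in range(n):
        for j in range(i + MIN_PAIR_DISTANCE, n):
            if (res[i], res[j]) in CANONICAL_PAIRS:
                M[i, j] = M[j, i] = 1.0
    return ConstraintMask(M=M)


def phi_transform(Y: np.ndarray, M: ConstraintMask | np.ndarray) -> np.ndarray:
    """Symmetrized, masked scores: phi(Y) = 1/2 (Y + Y^T) * M."""
    M = M.M if isinstance(M, ConstraintMask) else np.asarray(M, dtype=np.float64)
    Y = np.asarray(Y, dtype=np.float64)
    if Y.shape != M.shape:
        raise ValueError(f"score shape {Y.shape} != mask shape {M.shape}")
    return 0.5 * (Y + Y.T) * M


def matching_objective(support: set[tuple[int, int]] | frozenset, phi: np.ndarray, rho: float) -> float:
    """Objective sum_(i,j) (phi[i,j] - rho) over a candidate matching."""
    return float(sum(phi[i, j] - rho for i, j in support))


def solve_matching(phiY: np.ndarray, cfg: DecoderConfig | None = None) -> np.ndarray:
    """Maximize <Yhat, phi> - rho ||Yhat||_1 under the one-partner rule."""
    cfg = cfg or DecoderConfig()
    phiY = np.asarray(phiY, dtype=np.float64)
    if not np.allclose(phiY, phiY.T):
        raise ValueError("scores must be symmetric; run phi_transform first")
    if np.any(phiY < 0):
        raise ValueError("scores must be nonnegative")
    if cfg.solver == "exact_matching":
        return _solve_exact(phiY, cfg.rho)
    return _solve_relaxation(phiY, cfg)


def _solve_exact(phi: np.ndarray, rho: float) -> np.ndarray:
    """Maximum-weight matching on edges with phi > rho (blossom, exact)."""
    n = phi.shape[0]
    G = nx.Graph()
    ii, jj = np.nonzero(np.triu(phi, k=1) > rho)
    for i, j in zip(ii.tolist(), jj.tolist()):
        G.add_edge(i, j, weight=phi[i, j] - rho)
    matching = nx.max_weight_matching(G, maxcardinality=False)
    Yhat = np.zeros_like(phi)
    for a, b in matching:
        i, j = (a, b) if a < b else (b, a)
        Yhat[i, j] = Yhat[j, i] = phi[i, j]
    return Yhat


def _solve_relaxation(phi: np.ndarray, cfg: DecoderConfig) -> np.ndarray:
    """Primal-dual hybrid gradient (PDHG) ascent on the LP relaxation.

    Variables are the upper-triangle entries with positive gain
    ``phi - rho``; Lagrange multipliers price each base's one-partner
    budget.  The primal step is projected gradient ascent on
    ``gain - lambda_i - lambda_j`` clipped to [0, 1], the dual step uses the
    extrapolated primal iterate; step sizes respect the incidence-operator
    norm, which makes the scheme provably convergent to the LP optimum.
    The second-half iterate average is returned after a row-scaling
    projection restores strict feasibility.  Because the LP relaxes the
    integral matching problem, a converged run is never below the exact
    matching objective by more than the feasibility-projection slack.
    """
    n = phi.shape[0]
    gain = phi - cfg.rho
    ii, jj = np.nonzero(np.triu(gain, 1) > 0)
    g = gain[ii, jj]
    if g.size == 0:
        return np.zeros_like(phi)
    deg = np.bincount(np.r_[ii, jj], minlength=n)
    step = cfg.relax_step_scale / np.sqrt(2.0 * max(deg.max(), 1))
    y = np.clip(g, 0.0, 1.0)
    lam = np.zeros(n)
    ysum = np.zeros_like(y)
    count = 0
    for k in range(cfg.relax_steps):
        y_new = np.clip(y + step * (g - lam[ii] - lam[jj]), 0.0, 1.0)
        ybar = 2.0 * y_new - y
        rowsum = np.bincount(ii, ybar, minlength=n) + np.bincount(jj, ybar, minlength=n)
        lam = np.maximum(lam + step * (rowsum - 1.0), 0.0)
        y = y_new
        if k >= cfg.relax_steps // 2:
            ysum += y
            count += 1
    y = ysum / max(count, 1)
    Yhat = np.zeros_like(phi)
    Yhat[ii, jj] = y
    Yhat = Yhat + Yhat.T
    for _ in range(200):
        rowsum = Yhat.sum(axis=1)
        if np.all(rowsum <= 1.0 + 1e-9):
            break
        scale = np.minimum(1.0, 1.0 / np.maximum(rowsum, 1e-12))
        Yhat = Yhat * np.minimum(scale[:, None], scale[None, :])
    return np.clip(Yhat, 0.0, 1.0)


def binarize(Yhat: np.ndarray, threshold_P: float = 0.5) -> ContactMap:
    """Keep entries strictly above the threshold; assert hard constraints."""
    Yhat = np.asarray(Yhat, dtype=np.float64)
    Z = (0.5 * (Yhat + Yhat.T) > threshold_P).astype(np.float64)
    cm = ContactMap.from_matrix(Z)  # raises if one-partner/symmetry violated
    return cm


def check_constraints(cm: ContactMap, seq: RnaSequence) -> None:
    """Assert all four validity rules on a decoded structure."""
    res = seq.residues
    for i, j in cm.pairs:
        if (res[i], res[j]) not in CANONICAL_PAIRS:
            raise AssertionError(f"non-canonical pair ({i},{j}) = {res[i]}{res[j]}")
        if j - i < MIN_PAIR_DISTANCE:
            raise AssertionError(f"pair ({i},{j}) closer than {MIN_PAIR_DISTANCE}")
    # symmetry and the one-partner rule are enforced by the ContactMap type


def decode(Y: np.ndarray, seq: RnaSequence, cfg: DecoderConfig | None = None) -> ContactMap:
    """Full pipeline: mask, symmetrize, match, threshold."""
    cfg = cfg or DecoderConfig()
    phi = phi_transform(Y, build_mask(seq))
    Yhat = solve_matching(phi, cfg)
    cm = binarize(Yhat, cfg.threshold_P)
    check_constraints(cm, seq)
    return cm


# ---------------------------------------------------------------------------
# Brute-force reference (small n), used as the oracle in tests
# ---------------------------------------------------------------------------

def brute_force_matching(phi: np.ndarray, rho: float) -> tuple[frozenset, float]:
    """Enumerate all matchings over positive-gain edges; exact for small n."""
    edges = [
        (i, j)
        for i, j in zip(*np.nonzero(np.triu(phi, k=1) > rho))
    ]
    edges = [(int(i), int(j)) for i, j in edges]
    best: tuple[frozenset, float] = (frozenset(), 0.0)

    def extend(k: int, used: set[int], chosen: list, value: float) -> None:
        nonlocal best
        if value > best[1]:
            best = (frozenset(chosen), value)
        for m in range(k, len(edges)):
            i, j = edges[m]
            if i in used or j in used:
                continue
            chosen.append((i, j))
            extend(m + 1, used | {i, j}, chosen, value + phi[i, j] - rho)
            chosen.pop()

    extend(0, set(), [], 0.0)
    return best
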