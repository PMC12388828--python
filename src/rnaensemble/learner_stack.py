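"""Base-learner contact-map stacks and the synthetic learner simulator.

The ensemble consumes a rank-3 binary array ``A`` of shape ``(l, n, n)``
holding one contact-map slice per base learner.  This module assembles that
stack from prediction files, and — so the ensemble can be trained and tested
without running any external predictor — provides:

* a stochastic stem/loop grammar that generates realistic pseudoknot-free
  structures with Watson-Crick/wobble-complementary sequences, and
* a learner simulator with configurable sensitivity, false-pair rate and
  error bias, emulating the partially independent error modes real
  predictors exhibit (their pairwise Jaccard distances sit roughly in the
  0.3-0.65 band).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .structure_io import (
    CANONICAL_PAIRS,
    MIN_PAIR_DISTANCE,
    ContactMap,
    DimensionError,
    RnaSequence,
    StructureRecord,
    read_structure_file,
)

BIAS_MODES = ("none", "shift", "long_range", "short_range")


@dataclass(frozen=True)
class LearnerStack:
    """Ordered base-learner predictions for one sequence as a binary array."""

    learner_names: tuple[str, ...]
    A: np.ndarray  # (l, n, n) binary

    def __post_init__(self) -> None:
        A = np.asarray(self.A, dtype=np.float64)
        object.__setattr__(self, "A", A)
        object.__setattr__(self, "learner_names", tuple(self.learner_names))
        if A.ndim != 3 or A.shape[1] != A.shape[2]:
            raise ValueError(f"stack must have shape (l, n, n), got {A.shape}")
        if A.shape[0] != len(self.learner_names):
            raise ValueError("learner_names length must match first axis")
        if A.shape[0] < 1:
            raise ValueError("need at least one learner")

    @property
    def l(self) -> int:
        return self.A.shape[0]

    @property
    def n(self) -> int:
        return self.A.shape[1]

    def slice_map(self, v: int) -> ContactMap:
        return ContactMap.from_matrix(self.A[v])

    def subset(self, indices: Sequence[int]) -> "LearnerStack":
        idx = list(indices)
        return LearnerStack(
            learner_names=tuple(self.learner_names[i] for i in idx), A=self.A[idx]
        )


@dataclass(frozen=True)
class LearnerProfile:
    """Error model of one simulated base learner.

    sensitivity
        Probability that a true pair is reported.
    false_pair_rate
        Expected number of spurious pairs per 100 nt.
    bias_mode
        Which spurious pairs the learner favors: ``long_range`` weights by
        span, ``short_range`` by inverse span, ``shift`` prefers pairs
        register-shifted off true helices, ``none`` is uniform.
    seed_offset
        Decorrelates this learner's random substream from the others.
    """

    name: str
    sensitivity: float = 0.8
    false_pair_rate: float = 8.0
    bias_mode: str = "none"
    seed_offset: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.sensitivity <= 1.0:
            raise ValueError("sensitivity must be in [0, 1]")
        if self.false_pair_rate < 0:
            raise ValueError("false_pair_rate must be >= 0")
        if self.bias_mode not in BIAS_MODES:
            raise ValueError(f"bias_mode must be one of {BIAS_MODES}")


def default_profiles() -> list[LearnerProfile]:
    """Four simulated learners with distinct error biases.

    Sensitivity 0.8 and 8 spurious pairs per 100 nt put single-learner F1
    in the 0.7-0.8 range typical of modern predictors on unseen families,
    and the distinct biases keep their false-positive sets partially
    disjoint so ensembling has something to gain.
    """
    return [
        LearnerProfile("sim_uniform", 0.8, 8.0, "none", seed_offset=0),
        LearnerProfile("sim_shift", 0.8, 8.0, "shift", seed_offset=1),
        LearnerProfile("sim_long", 0.8, 8.0, "long_range", seed_offset=2),
        LearnerProfile("sim_short", 0.8, 8.0, "short_range", seed_offset=3),
    ]


@dataclass(frozen=True)
class SyntheticStructureConfig:
    """Parameters of the stochastic stem/loop structure grammar."""

    n_range: tuple[int, int] = (40, 80)
    min_loop: int = 3
    stem_extension_prob: float = 0.75
    branch_prob: float = 0.15
    gu_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_loop < 3:
            raise ValueError("min_loop must be >= 3 (pairs need |i-j| >= 4)")
        if self.n_range[0] > self.n_range[1] or self.n_range[0] < 1:
            raise ValueError("invalid n_range")


# ---------------------------------------------------------------------------
# Stack assembly from files
# ---------------------------------------------------------------------------

def stack_from_files(
    seq: RnaSequence, files: Mapping[str, str | Path]
) -> LearnerStack:
    """Assemble a stack from per-learner structure files (ordered mapping)."""
    names: list[str] = []
    slices: list[np.ndarray] = []
    for name, path in files.items():
        rec = read_structure_file(path, seq=seq)
        if rec.structure.n != len(seq):
            raise DimensionError(
                f"learner {name!r}: structure length {rec.structure.n} != "
                f"sequence length {len(seq)}"
            )
        names.append(name)
        slices.append(rec.structure.matrix())
    return LearnerStack(learner_names=tuple(names), A=np.stack(slices))


def stack_from_maps(
    maps: Mapping[str, ContactMap] | Sequence[tuple[str, ContactMap]]
) -> LearnerStack:
    items = list(maps.items()) if isinstance(maps, Mapping) else list(maps)
    names = tuple(name for name, _ in items)
    A = np.stack([cm.matrix() for _, cm in items])
    return LearnerStack(learner_names=names, A=A)


# ---------------------------------------------------------------------------
# Synthetic structure generation
# ---------------------------------------------------------------------------

def generate_structure(
    cfg: SyntheticStructureConfig, rng: np.random.Generator, id: str = "synth"
) -> StructureRecord:
    """Generate one nested structure and a compatible random sequence.

    The grammar opens a stem, extends it with probability
    ``stem_extension_prob`` per additional base pair, then either branches
    into a multiloop (probability ``branch_prob``) or closes with a hairpin
    of at least ``min_loop`` unpaired bases.  Paired positions receive
    Watson-Crick complements, or a G-U wobble with probability
    ``gu_fraction``; loop positions are uniform random bases.  Every emitted
    pair satisfies the hard constraints by construction.
    """
    n = int(rng.integers(cfg.n_range[0], cfg.n_range[1] + 1))
    pairs: list[tuple[int, int]] = []
    _fold_interval(0, n - 1, cfg, rng, pairs, exterior=True)
    cm = ContactMap(n=n, pairs=frozenset(pairs))
    seq = _sequence_for(cm, cfg, rng, id=id)
    return StructureRecord(sequence=seq, structure=cm, source="ground_truth")


def _fold_interval(i, j, cfg, rng, pairs, exterior=False):
    """Recursively place stems in [i, j] (inclusive)."""
    span = j - i + 1
    min_stem_span = 2 + cfg.min_loop  # one pair plus its hairpin loop
    if span < min_stem_span:
        return
    if exterior:
        # Exterior loop: a run of stems separated by unpaired spacers.
        pos = i
        while j - pos + 1 >= min_stem_span:
            spacer = int(rng.integers(0, 3))
            start = pos + spacer
            if j - start + 1 < min_stem_span:
                break
            width = int(rng.integers(min_stem_span, j - start + 2))
            _fold_interval(start, start + width - 1, cfg, rng, pairs)
            pos = start + width
        return
    # Open a helix at the interval ends and extend inward.
    a, b = i, j
    pairs.append((a, b))
    while (
        b - 1 - (a + 1) + 1 >= cfg.min_loop + 2
        and rng.random() < cfg.stem_extension_prob
    ):
        a, b = a + 1, b - 1
        pairs.append((a, b))
    inner_lo, inner_hi = a + 1, b - 1
    inner_span = inner_hi - inner_lo + 1
    if inner_span >= 2 * (2 + cfg.min_loop) + 1 and rng.random() < cfg.branch_prob:
        # Multiloop: split the interior into two branches around a gap.
        split = int(rng.integers(inner_lo + 2 + cfg.min_loop, inner_hi - (2 + cfg.min_loop) + 1))
        _fold_interval(inner_lo, split - 1, cfg, rng, pairs)
        _fold_interval(split + 1, inner_hi, cfg, rng, pairs)
    elif inner_span >= (2 + cfg.min_loop) + 2 and rng.random() < 0.5:
        # Interior loop: skip a few unpaired bases then continue one stem.
        lo_gap = int(rng.integers(1, 3))
        hi_gap = int(rng.integers(1, 3))
        if inner_hi - hi_gap - (inner_lo + lo_gap) + 1 >= 2 + cfg.min_loop:
            _fold_interval(inner_lo + lo_gap, inner_hi - hi_gap, cfg, rng, pairs)
    # else: hairpin loop (interior left unpaired; >= min_loop by the guards)


_WC = {"A": "U", "U": "A", "G": "C", "C": "G"}
_BASES = np.array(list("ACGU"))


def _sequence_for(cm, cfg, rng, id="synth"):
    residues = rng.choice(_BASES, size=cm.n).tolist()
    for i, j in sorted(cm.pairs):
        if rng.random() < cfg.gu_fraction:
            residues[i], residues[j] = ("G", "U") if rng.random() < 0.5 else ("U", "G")
        else:
            residues[i] = str(rng.choice(_BASES))
            residues[j] = _WC[residues[i]]
    return RnaSequence(id=id, residues="".join(residues))


def generate_dataset(
    n_structures: int,
    cfg: SyntheticStructureConfig,
    seed: int | None = None,
) -> list[StructureRecord]:
    """Generate a list of structures with ids ``synth_0000``.. (seedable)."""
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    return [
        generate_structure(cfg, rng, id=f"synth_{k:04d}") for k in range(n_structures)
    ]


# ---------------------------------------------------------------------------
# Learner simulation
# ---------------------------------------------------------------------------

def _allowed_pair(a: str, b: str) -> bool:
    return (a, b) in CANONICAL_PAIRS


def simulate_learner(
    truth: ContactMap,
    seq: RnaSequence,
    profile: LearnerProfile,
    rng: np.random.Generator,
) -> ContactMap:
    """Corrupt a true structure into one simulated learner prediction.

    Each true pair is kept independently with probability ``sensitivity``;
    a Poisson(false_pair_rate * n / 100) number of spurious pairs is then
    drawn from the constraint-valid pairs whose endpoints are still free,
    with sampling weights set by ``bias_mode``.  The output is always a
    valid contact map satisfying the hard constraints.
    """
    n = truth.n
    kept = [p for p in sorted(truth.pairs) if rng.random() < profile.sensitivity]
    used = {k for p in kept for k in p}

    n_spurious = int(rng.poisson(profile.false_pair_rate * n / 100.0))
    if n_spurious > 0:
        candidates, weights = _spurious_candidates(truth, seq, used, profile)
        for _ in range(n_spurious):
            if not candidates:
                break
            w = np.asarray(weights, dtype=np.float64)
            pick = int(rng.choice(len(candidates), p=w / w.sum()))
            i, j = candidates[pick]
            kept.append((i, j))
            used.update((i, j))
            keepers = [
                k for k, (a, b) in enumerate(candidates) if a not in (i, j) and b not in (i, j)
            ]
            candidates = [candidates[k] for k in keepers]
            weights = [weights[k] for k in keepers]
    return ContactMap(n=n, pairs=frozenset(kept))


def _spurious_candidates(truth, seq, used, profile):
    """Constraint-valid free pairs and their bias weights."""
    n = truth.n
    res = seq.residues
    true_pairs = truth.pairs
    candidates: list[tuple[int, int]] = []
    weights: list[float] = []
    shift_targets: set[tuple[int, int]] = set()
    if profile.bias_mode == "shift":
        for i, j in true_pairs:
            for di, dj in ((1, 1), (-1, -1), (1, -1), (-1, 1), (0, 1), (1, 0), (0, -1), (-1, 0)):
                a, b = i + di, j + dj
                if 0 <= a < b < n:
                    shift_targets.add((a, b))
    for i in range(n):
        if i in used:
            continue
        for j in range(i + MIN_PAIR_DISTANCE, n):
            if j in used or (i, j) in true_pairs:
                continue
            if not _allowed_pair(res[i], res[j]):
                continue
            span = j - i
            if profile.bias_mode == "long_range":
                w = float(span)
            elif profile.bias_mode == "short_range":
                w = 1.0 / span
            elif profile.bias_mode == "shift":
                w = 50.0 if (i, j) in shift_targets else 1.0
            else:
                w = 1.0
            candidates.append((i, j))
            weights.append(w)
    return candidates, weights


def learner_rng(global_seed: int, seed_offset: int) -> np.random.Generator:
    """Per-learner substream; adding a learner never perturbs the others."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=global_seed, spawn_key=(seed_offset,))
    )


def simulate_stack(
    truth: ContactMap,
    seq: RnaSequence,
    profiles: Sequence[LearnerProfile],
    seed: int,
) -> LearnerStack:
    """Simulate all learners on one structure with decorrelated substreams."""
    slices = []
    for prof in profiles:
        rng = learner_rng(seed, prof.seed_offset)
        slices.append(simulate_learner(truth, seq, prof, rng).matrix())
    return LearnerStack(
        learner_names=tuple(p.name for p in profiles), A=np.stack(slices)
    )


def simulate_benchmark(
    n_structures: int,
    profiles: Sequence[LearnerProfile] | None = None,
    cfg: SyntheticStructureConfig | None = None,
    seed: int = 0,
) -> tuple[list[StructureRecord], list[LearnerStack]]:
    """Generate structures and simulated learner stacks for each of them.

    Per-structure simulation seeds are drawn from the structure stream so
    the whole benchmark is reproducible from ``seed`` alone.
    """
    profiles = list(profiles) if profiles is not None else default_profiles()
    cfg = cfg if cfg is not None else SyntheticStructureConfig()
    records = generate_dataset(n_structures, cfg, seed=seed)
    seed_rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(997,)))
    stacks = [
        simulate_stack(
            rec.structure, rec.sequence, profiles, int(seed_rng.integers(2**31 - 1))
        )
        for rec in records
    ]
    return records, stacks
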