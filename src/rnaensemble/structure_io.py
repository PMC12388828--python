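"""Reading, writing and converting RNA secondary-structure representations.

A secondary structure is held as a :class:`ContactMap`: a set of base-pair
index pairs ``(i, j)`` with ``i < j`` (0-based), equivalently an ``n x n``
binary symmetric matrix with zero diagonal and row sums <= 1.  Supported
file formats are multi-FASTA (sequences), Vienna dot-bracket (including
multi-alphabet pseudoknot layers), 6-column CT and 3-column BPSEQ.  Internal
coordinates are always 0-based; CT/BPSEQ use their native 1-based indexing
on disk.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: Bases that may pair (canonical Watson-Crick plus the G-U wobble pair).
CANONICAL_PAIRS = frozenset(
    {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}
)

#: Minimum sequence separation of a base pair: |i - j| >= 4.
MIN_PAIR_DISTANCE = 4

# Bracket alphabets for dot-bracket strings.  The first four are the common
# ASCII bracket pairs; further pseudoknot layers use letter pairs Aa, Bb, ...
_OPENERS = "([{<" + "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
_CLOSERS = ")]}>" + "abcdefghijklmnopqrstuvwxyz"
_OPEN_OF = {c: o for o, c in zip(_OPENERS, _CLOSERS)}


class StructureFormatError(ValueError):
    """Raised when a structure file or string violates its format contract."""


class DimensionError(ValueError):
    """Raised when structure and sequence lengths disagree."""


@dataclass(frozen=True)
class RnaSequence:
    """An RNA sequence; residues are uppercase with T mapped to U."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        norm = self.residues.upper().replace("T", "U")
        object.__setattr__(self, "residues", norm)
        if len(norm) < 1:
            raise ValueError(f"sequence {self.id!r} is empty")
        unknown = set(norm) - set("ACGU")
        if unknown:
            # Non-ACGU IUPAC codes are kept; the constraint mask excludes
            # them from pairing later.
            warnings.warn(
                f"sequence {self.id!r} contains non-ACGU residues {sorted(unknown)}; "
                "they will never pair",
                stacklevel=2,
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class ContactMap:
    """A base-pair set over ``n`` residues with a consistent matrix view."""

    n: int
    pairs: frozenset[tuple[int, int]] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        pairs = frozenset((int(i), int(j)) for i, j in self.pairs)
        object.__setattr__(self, "pairs", pairs)
        seen: set[int] = set()
        for i, j in pairs:
            if not (0 <= i < j < self.n):
                raise ValueError(f"pair ({i}, {j}) out of range for n={self.n}")
            if i in seen or j in seen:
                raise ValueError(f"base in pair ({i}, {j}) has more than one partner")
            seen.update((i, j))

    def matrix(self, dtype=np.float64) -> np.ndarray:
        """Return the symmetric binary matrix view Z."""
        Z = np.zeros((self.n, self.n), dtype=dtype)
        for i, j in self.pairs:
            Z[i, j] = Z[j, i] = 1
        return Z

    @classmethod
    def from_matrix(cls, Z: np.ndarray) -> "ContactMap":
        Z = np.asarray(Z)
        if Z.ndim != 2 or Z.shape[0] != Z.shape[1]:
            raise ValueError("contact matrix must be square")
        if not np.array_equal(Z, Z.T):
            raise ValueError("contact matrix must be symmetric")
        if np.any(np.diag(Z) != 0):
            raise ValueError("contact matrix diagonal must be zero")
        ii, jj = np.nonzero(np.triu(Z, k=1))
        return cls(n=Z.shape[0], pairs=frozenset(zip(ii.tolist(), jj.tolist())))

    @property
    def partner(self) -> dict[int, int]:
        """Map each paired index to its partner (both directions)."""
        out: dict[int, int] = {}
        for i, j in self.pairs:
            out[i] = j
            out[j] = i
        return out

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass(frozen=True)
class StructureRecord:
    """A sequence together with one structure and its provenance."""

    sequence: RnaSequence
    structure: ContactMap
    source: str = "ground_truth"

    def __post_init__(self) -> None:
        if self.structure.n != len(self.sequence):
            raise DimensionError(
                f"structure n={self.structure.n} != sequence length "
                f"{len(self.sequence)} for {self.sequence.id!r}"
            )


# ---------------------------------------------------------------------------
# Dot-bracket
# ---------------------------------------------------------------------------

def parse_dot_bracket(db: str, seq: RnaSequence) -> ContactMap:
    """Parse a (possibly pseudoknotted) dot-bracket string.

    Each bracket alphabet — ``()``, ``[]``, ``{}``, ``<>`` and letter pairs
    ``Aa``, ``Bb``, ... — is matched with its own stack, so crossing pairs in
    different layers are recovered exactly.
    """
    db = db.strip()
    if len(db) != len(seq):
        raise DimensionError(
            f"dot-bracket length {len(db)} != sequence length {len(seq)}"
        )
    stacks: dict[str, list[int]] = {}
    pairs: set[tuple[int, int]] = set()
    for pos, ch in enumerate(db):
        if ch == ".":
            continue
        if ch in _OPENERS:
            stacks.setdefault(ch, []).append(pos)
        elif ch in _CLOSERS:
            opener = _OPEN_OF[ch]
            stack = stacks.get(opener)
            if not stack:
                raise StructureFormatError(
                    f"unbalanced {ch!r} at position {pos}: no matching {opener!r}"
                )
            pairs.add((stack.pop(), pos))
        else:
            raise StructureFormatError(f"invalid character {ch!r} at position {pos}")
    for opener, stack in stacks.items():
        if stack:
            raise StructureFormatError(
                f"unbalanced {opener!r} opened at position {stack[-1]}"
            )
    return ContactMap(n=len(db), pairs=frozenset(pairs))


def write_dot_bracket(cm: ContactMap) -> str:
    """Write a dot-bracket string, assigning crossing pairs to extra layers.

    Pairs are assigned greedily to the first layer whose existing pairs they
    do not cross; nested structures therefore use plain ``()``.
    """
    layers: list[list[tuple[int, int]]] = []
    for i, j in sorted(cm.pairs):
        for layer in layers:
            if all(not _crosses((i, j), p) for p in layer):
                layer.append((i, j))
                break
        else:
            layers.append([(i, j)])
    if len(layers) > len("([{<") + 26:
        raise StructureFormatError("too many pseudoknot layers to encode")
    chars = ["."] * cm.n
    for k, layer in enumerate(layers):
        for i, j in layer:
            chars[i] = _OPENERS[k]
            chars[j] = _CLOSERS[k]
    return "".join(chars)


def _crosses(a: tuple[int, int], b: tuple[int, int]) -> bool:
    (i, j), (k, l) = a, b
    return (i < k < j < l) or (k < i < l < j)


# ---------------------------------------------------------------------------
# CT / BPSEQ
# ---------------------------------------------------------------------------

def _pairs_from_1based(
    pair_col: Mapping[int, int], n: int, what: str
) -> frozenset[tuple[int, int]]:
    """Validate a 1-based index->partner map and convert to 0-based pairs."""
    pairs: set[tuple[int, int]] = set()
    for i, j in pair_col.items():
        if j == 0:
            continue
        if not (1 <= j <= n):
            raise StructureFormatError(f"{what}: pair index {j} out of range at row {i}")
        if j == i:
            raise StructureFormatError(f"{what}: base {i} pairs with itself")
        if pair_col.get(j, 0) != i:
            raise StructureFormatError(
                f"{what}: asymmetric record — {i} pairs {j} but {j} pairs "
                f"{pair_col.get(j, 0)}"
            )
        pairs.add((min(i, j) - 1, max(i, j) - 1))
    return frozenset(pairs)


def parse_ct(text: str, id: str = "ct") -> StructureRecord:
    """Parse a 6-column CT record (header line with count, then rows)."""
    lines = [ln.rstrip() for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise StructureFormatError("empty CT input")
    try:
        count = int(lines[0].split()[0])
    except (ValueError, IndexError) as exc:
        raise StructureFormatError(f"bad CT header: {lines[0]!r}") from exc
    rows = lines[1 : 1 + count]
    if len(rows) != count:
        raise StructureFormatError(f"CT: expected {count} rows, found {len(rows)}")
    bases: list[str] = []
    pair_col: dict[int, int] = {}
    for k, row in enumerate(rows, start=1):
        fields = row.split()
        if len(fields) < 6:
            raise StructureFormatError(f"CT row {k}: expected 6 columns: {row!r}")
        idx = int(fields[0])
        if idx != k:
            raise StructureFormatError(f"CT: non-contiguous index {idx} at row {k}")
        bases.append(fields[1])
        pair_col[k] = int(fields[4])
    seq = RnaSequence(id=id, residues="".join(bases))
    cm = ContactMap(n=count, pairs=_pairs_from_1based(pair_col, count, "CT"))
    return StructureRecord(sequence=seq, structure=cm)


def parse_bpseq(text: str, id: str = "bpseq") -> StructureRecord:
    """Parse a 3-column BPSEQ record (index, base, 1-based partner or 0)."""
    lines = [ln.strip() for ln in text.splitlines()]
    rows = [ln for ln in lines if ln and not ln.startswith("#")]
    if not rows:
        raise StructureFormatError("empty BPSEQ input")
    bases: list[str] = []
    pair_col: dict[int, int] = {}
    for k, row in enumerate(rows, start=1):
        fields = row.split()
        if len(fields) != 3:
            raise StructureFormatError(f"BPSEQ row {k}: expected 3 columns: {row!r}")
        idx = int(fields[0])
        if idx != k:
            raise StructureFormatError(f"BPSEQ: non-contiguous index {idx} at row {k}")
        bases.append(fields[1])
        pair_col[k] = int(fields[2])
    n = len(rows)
    seq = RnaSequence(id=id, residues="".join(bases))
    cm = ContactMap(n=n, pairs=_pairs_from_1based(pair_col, n, "BPSEQ"))
    return StructureRecord(sequence=seq, structure=cm)


def write_ct(record: StructureRecord) -> str:
    seq = record.sequence
    partner = record.structure.partner
    n = len(seq)
    out = [f"{n} {seq.id}"]
    for i in range(n):
        p = partner.get(i, -1) + 1
        out.append(
            f"{i + 1} {seq.residues[i]} {i} {i + 2 if i + 1 < n else 0} {p} {i + 1}"
        )
    return "\n".join(out) + "\n"


def write_bpseq(record: StructureRecord) -> str:
    seq = record.sequence
    partner = record.structure.partner
    out = [
        f"{i + 1} {seq.residues[i]} {partner.get(i, -1) + 1}" for i in range(len(seq))
    ]
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# FASTA and generic structure files
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[RnaSequence]:
    """Read a multi-FASTA file into normalized RNA sequences."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise StructureFormatError(f"no FASTA records in {path}")
    ids = [r.id for r in records]
    dupes = {i for i in ids if ids.count(i) > 1}
    if dupes:
        warnings.warn(f"duplicate FASTA ids in {path}: {sorted(dupes)}", stacklevel=2)
    return [RnaSequence(id=r.id, residues=str(r.seq)) for r in records]


def write_fasta(seqs: Iterable[RnaSequence], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(s.residues), id=s.id, description="") for s in seqs
    ]
    SeqIO.write(records, str(path), "fasta")


def read_structure_file(path: str | Path, seq: RnaSequence | None = None) -> StructureRecord:
    """Read one structure from a dot-bracket (.db/.dbn), CT or BPSEQ file.

    Dot-bracket files may carry their own sequence line (``>id``, sequence,
    structure) or just the structure string, in which case ``seq`` is
    required.
    """
    path = Path(path)
    text = path.read_text()
    suffix = path.suffix.lower()
    if suffix in {".ct"}:
        return parse_ct(text, id=path.stem)
    if suffix in {".bpseq", ".bpsq"}:
        return parse_bpseq(text, id=path.stem)
    # dot-bracket flavours
    lines = [ln.strip() for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise StructureFormatError(f"empty structure file {path}")
    if lines[0].startswith(">"):
        if len(lines) < 3:
            raise StructureFormatError(f"{path}: expected header, sequence, structure")
        rec_seq = RnaSequence(id=lines[0][1:].split()[0] or path.stem, residues=lines[1])
        cm = parse_dot_bracket(lines[2].split()[0], rec_seq)
        return StructureRecord(sequence=rec_seq, structure=cm)
    if len(lines) >= 2 and set(lines[0].upper()) <= set("ACGUTN"):
        rec_seq = RnaSequence(id=path.stem, residues=lines[0])
        cm = parse_dot_bracket(lines[1].split()[0], rec_seq)
        return StructureRecord(sequence=rec_seq, structure=cm)
    if seq is None:
        raise StructureFormatError(
            f"{path}: bare dot-bracket needs an accompanying sequence"
        )
    return StructureRecord(
        sequence=seq, structure=parse_dot_bracket(lines[0].split()[0], seq)
    )


def write_structure_file(record: StructureRecord, path: str | Path, format: str = "db") -> None:
    path = Path(path)
    if format == "db":
        text = (
            f">{record.sequence.id}\n{record.sequence.residues}\n"
            f"{write_dot_bracket(record.structure)}\n"
        )
    elif format == "ct":
        text = write_ct(record)
    elif format == "bpseq":
        text = write_bpseq(record)
    else:
        raise ValueError(f"unknown structure format {format!r}")
    path.write_text(text)


def write_outputs(
    records: Sequence[StructureRecord], format: str, directory: str | Path
) -> list[Path]:
    """Write one structure file per record into ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    ext = {"db": ".db", "ct": ".ct", "bpseq": ".bpseq"}[format]
    paths = []
    for rec in records:
        p = directory / f"{rec.sequence.id}{ext}"
        write_structure_file(rec, p, format=format)
        paths.append(p)
    return paths


def drop_crossing_pairs(cm: ContactMap) -> ContactMap:
    """Remove pseudoknotted (crossing) pairs, keeping a maximal nested subset.

    Greedy by pair span: shorter pairs are kept first, mirroring the common
    filter that strips pseudoknots from training data.
    """
    kept: list[tuple[int, int]] = []
    for p in sorted(cm.pairs, key=lambda q: (q[1] - q[0], q)):
        if all(not _crosses(p, q) for q in kept):
            kept.append(p)
    return ContactMap(n=cm.n, pairs=frozenset(kept))
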