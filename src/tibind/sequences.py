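"""Peptide permutation libraries and motif statistics.

The titanium-binding hexapeptide RKLPDA (min TBP-1) defines a six-letter
residue multiset {R, K, L, P, D, A}.  Permuting it yields 720 orderings; a
sequence and its reversal share residue composition, so one representative
per reverse pair is kept, giving the 360-member library whose members are
ranked by the fraction of simulation time spent adsorbed.  Motif tables
count contiguous residue pairs/triplets (optionally position-resolved) over
a ranked subset of the library.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

TBP_ALPHABET = frozenset("RKLPDA")
TBP_SEQUENCE = "RKLPDA"


class DedupPolicy(str, Enum):
    lexicographic_first = "lexicographic_first"
    keep_list = "keep_list"
    none = "none"


class MotifMode(str, Enum):
    ordered = "ordered"
    order_agnostic = "order_agnostic"


class PositionScope(str, Enum):
    """Which window start positions (1-based) are tallied.

    ``all``          every window in the sequence
    ``interior_2_5`` windows fully inside positions 2..5
    ``nterm_1_2``    the window starting at position 1
    ``cterm_5_6``    the window ending at the last position
    ``positional``   all windows, counted jointly with their start position
    """

    all = "all"
    interior_2_5 = "interior_2_5"
    nterm_1_2 = "nterm_1_2"
    cterm_5_6 = "cterm_5_6"
    positional = "positional"


def validate_sequence(seq: str, alphabet: Iterable[str] = TBP_ALPHABET,
                      length: int | None = None) -> str:
    """Validate a one-letter peptide string against an alphabet.

    Returns the (uppercased) sequence or raises ``ValueError``.
    """
    s = str(seq).strip().upper()
    if not s:
        raise ValueError("empty peptide sequence")
    alpha = set(alphabet)
    bad = sorted(set(s) - alpha)
    if bad:
        raise ValueError(f"residues {bad} not in alphabet {sorted(alpha)}")
    if length is not None and len(s) != length:
        raise ValueError(f"sequence {s!r} has length {len(s)}, expected {length}")
    return s


@dataclass
class SequenceLibrary:
    """An ordered, duplicate-free list of peptide sequences."""

    sequences: list[str]
    dedup_policy: DedupPolicy = DedupPolicy.none
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.sequences)) != len(self.sequences):
            raise ValueError("library contains duplicate sequences")

    def __len__(self) -> int:
        return len(self.sequences)

    def __iter__(self):
        return iter(self.sequences)

    def __contains__(self, seq: str) -> bool:
        return seq in set(self.sequences)

    def write(self, path: str | Path) -> None:
        Path(path).write_text("\n".join(self.sequences) + "\n")

    @classmethod
    def read(cls, path: str | Path) -> "SequenceLibrary":
        lines = [ln.strip() for ln in Path(path).read_text().splitlines()]
        return cls([ln.split("\t")[0] for ln in lines if ln and not ln.startswith("#")],
                   provenance={"source": str(path)})


@dataclass(frozen=True)
class MotifTable:
    """One motif-count row: a k-letter motif with its tally."""

    motif: str
    count: int
    mode: MotifMode
    position_scope: PositionScope
    position: int | None = None  # 1-based window start, positional scope only


def enumerate_permutations(residues: str | Sequence[str]) -> SequenceLibrary:
    """All distinct orderings of a residue multiset, lexicographically sorted.

    For the six distinct residues of RKLPDA this is the full 720-member
    permutation library.
    """
    letters = list(residues)
    if not letters:
        raise ValueError("residue multiset is empty")
    seqs = ["".join(p) for p in itertools.permutations(sorted(letters))]
    unique = sorted(set(seqs))
    # validate against the multiset's own alphabet
    for s in unique:
        validate_sequence(s, alphabet=set(letters))
    return SequenceLibrary(unique, provenance={"residues": "".join(sorted(letters)),
                                               "operation": "enumerate_permutations"})


def canonicalize_reverse_pairs(library: SequenceLibrary,
                               policy: DedupPolicy | str = DedupPolicy.lexicographic_first,
                               keep_list: Iterable[str] | None = None) -> SequenceLibrary:
    """Retain exactly one member of every {s, reverse(s)} pair.

    Palindromic sequences are retained once.  The default keeps the
    lexicographically smaller member; ``keep_list`` lets a caller impose the
    published representative set (e.g. retaining RKLPDA rather than ADPLKR).
    Idempotent: applying it to an already-canonical library is a no-op.
    """
    policy = DedupPolicy(policy)
    seqs = list(library.sequences)
    present = set(seqs)
    if policy is DedupPolicy.none:
        return SequenceLibrary(seqs, dedup_policy=policy,
                               provenance={**library.provenance, "dedup": "none"})

    if policy is DedupPolicy.keep_list:
        if keep_list is None:
            raise ValueError("policy 'keep_list' requires a keep_list")
        keep = list(dict.fromkeys(keep_list))
        keepset = set(keep)
        offending = []
        for s in keep:
            if s[::-1] in keepset and s != s[::-1]:
                offending.append((min(s, s[::-1]), max(s, s[::-1])))
        covered = keepset | {s[::-1] for s in keepset}
        missing = sorted({min(s, s[::-1]) for s in present if s not in covered})
        if offending or missing:
            raise ValueError(
                "invalid keep_list: "
                + (f"both members present for pairs {sorted(set(offending))}; " if offending else "")
                + (f"pairs with no member kept: {missing}" if missing else ""))
        out = [s for s in seqs if s in keepset]
    else:  # lexicographic_first
        out = []
        for s in seqs:
            r = s[::-1]
            if r in present and r < s:
                continue
            out.append(s)

    return SequenceLibrary(out, dedup_policy=policy,
                           provenance={**library.provenance, "dedup": policy.value})


def select_by_rank(library: SequenceLibrary,
                   binding_fractions: Mapping[str, float],
                   threshold_percent: float) -> SequenceLibrary:
    """Sequences bound strictly more than ``threshold_percent`` of the time.

    Ordered by binding fraction descending, ties broken lexicographically.
    """
    missing = [s for s in library if s not in binding_fractions]
    if missing:
        raise KeyError(f"no binding fraction for sequences: {missing}")
    for s in library:
        f = binding_fractions[s]
        if not (0.0 <= f <= 100.0):
            raise ValueError(f"binding fraction for {s} out of [0, 100]: {f}")
    kept = [s for s in library if binding_fractions[s] > threshold_percent]
    kept.sort(key=lambda s: (-binding_fractions[s], s))
    return SequenceLibrary(kept, dedup_policy=library.dedup_policy,
                           provenance={**library.provenance,
                                       "selection": f"percent_bound > {threshold_percent}"})


def _window_starts(length: int, k: int, scope: PositionScope) -> range:
    """1-based window start positions admitted by a scope."""
    last = length - k + 1
    if scope is PositionScope.all or scope is PositionScope.positional:
        return range(1, last + 1)
    if scope is PositionScope.interior_2_5:
        return range(2, min(last, 5 - k + 1) + 1)
    if scope is PositionScope.nterm_1_2:
        return range(1, 2)
    if scope is PositionScope.cterm_5_6:
        return range(last, last + 1)
    raise ValueError(f"unsupported scope {scope}")


def _check_equal_lengths(seqs: Iterable[str], k: int) -> int:
    lengths = {len(s) for s in seqs}
    if len(lengths) > 1:
        raise ValueError(f"sequences of unequal length: {sorted(lengths)}")
    if not lengths:
        return 0
    (length,) = lengths
    if length < k:
        raise ValueError(f"window length {k} exceeds sequence length {length}")
    return length


def _motif_counts(seqs: Iterable[str], k: int, mode: MotifMode,
                  scope: PositionScope, positional: bool) -> list[MotifTable]:
    seqs = list(seqs)
    counts: Counter = Counter()
    if seqs:
        length = _check_equal_lengths(seqs, k)
        for s in seqs:
            for start in _window_starts(length, k, scope):
                w = s[start - 1:start - 1 + k]
                if mode is MotifMode.order_agnostic:
                    w = "".join(sorted(w))
                counts[(w, start if positional else None)] += 1
    rows = [MotifTable(motif=m, count=c, mode=mode, position_scope=scope, position=pos)
            for (m, pos), c in counts.items()]
    rows.sort(key=lambda r: (-r.count, r.motif, r.position or 0))
    return rows


def motif_pair_counts(seqs: SequenceLibrary | Iterable[str],
                      mode: MotifMode | str = MotifMode.ordered,
                      position_scope: PositionScope | str = PositionScope.all) -> list[MotifTable]:
    """Counts of adjacent residue pairs over a sequence set.

    ``ordered`` counts XY as written; ``order_agnostic`` merges XY and YX
    under the alphabetically sorted key.
    """
    return _motif_counts(seqs, 2, MotifMode(mode), PositionScope(position_scope),
                         positional=False)


def motif_triplet_counts(seqs: SequenceLibrary | Iterable[str],
                         position_scope: PositionScope | str = PositionScope.all,
                         mode: MotifMode | str = MotifMode.ordered) -> list[MotifTable]:
    """Counts of adjacent residue triplets over a sequence set."""
    return _motif_counts(seqs, 3, MotifMode(mode), PositionScope(position_scope),
                         positional=False)


def positional_motif_counts(seqs: SequenceLibrary | Iterable[str],
                            k: int = 2) -> list[MotifTable]:
    """Joint (motif, 1-based start position) counts for k = 2 or 3."""
    if k not in (2, 3):
        raise ValueError("k must be 2 or 3")
    return _motif_counts(seqs, k, MotifMode.ordered, PositionScope.positional,
                         positional=True)


def write_motif_table(rows: Sequence[MotifTable], path: str | Path) -> None:
    """TSV export: motif, position (or '-'), mode, scope, count."""
    with open(path, "w") as fh:
        fh.write("motif\tposition\tmode\tscope\tcount\n")
        for r in rows:
            fh.write(f"{r.motif}\t{r.position if r.position is not None else '-'}\t"
                     f"{r.mode.value}\t{r.position_scope.value}\t{r.count}\n")
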