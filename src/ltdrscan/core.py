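"""Alphabet, interval and alignment primitives plus the structural detectors.

Three short detectors carry most of the biology in this package:

``find_tir``
    Terminal inverted repeats: the first L bases of an element read as the
    reverse complement of its last L bases (here 11-18 bp arms, perfect or
    imperfect).

``terminal_signature``
    The Kolobok-superfamily hallmark that an element starts with two
    purines and ends with two pyrimidines (5'-RR..YY-3').

``detect_tsd``
    Target site duplications: the short host motif (3-5 bp typically,
    TTAA for canonical Kolobok) duplicated on both sides of an insertion.

All coordinates in this package are 0-based half-open; conversion to
1-based happens only when writing GFF3.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

from ltdrscan.errors import ConfigError, InputError

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    from Bio import Align

ALPHABET = frozenset("ACGTN")
PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement over {A,C,G,T,N}; N maps to N."""
    if not set(seq) <= ALPHABET:
        bad = sorted(set(seq) - ALPHABET)
        raise InputError(f"non-alphabet characters in sequence: {bad}")
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomeSequence:
    """A named DNA contig over the uppercase alphabet {A,C,G,T,N}."""

    contig_id: str
    seq: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq", self.seq.upper())
        if len(self.seq) < 1:
            raise InputError(f"contig {self.contig_id!r}: empty sequence")
        if not set(self.seq) <= ALPHABET:
            bad = sorted(set(self.seq) - ALPHABET)
            raise InputError(f"contig {self.contig_id!r}: bad characters {bad}")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class Interval:
    """0-based half-open genomic interval with strand."""

    contig_id: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise InputError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise InputError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def shifted(self, offset: int) -> "Interval":
        return Interval(self.contig_id, self.start + offset, self.end + offset, self.strand)

    def overlaps(self, other: "Interval") -> bool:
        return (
            self.contig_id == other.contig_id
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class Scoring:
    """Affine-gap scoring: a gap of length L costs gap_open + L * gap_extend."""

    match: float = 2.0
    mismatch: float = -3.0
    gap_open: float = -5.0
    gap_extend: float = -2.0

    def __post_init__(self) -> None:
        if self.gap_open > 0 or self.gap_extend >= 0:
            raise ConfigError("gap penalties must be negative")
        if self.match <= 0:
            raise ConfigError("match score must be positive")


@dataclass(frozen=True)
class PairwiseAlignment:
    """One pairwise alignment; aligned_a/aligned_b are equal-length gapped rows.

    ``identity`` is the fraction of matching columns among the aligned
    (non-terminal-gap) columns; N never counts as a match.  ``a_span`` and
    ``b_span`` give the half-open coordinates of the aligned region on the
    ungapped inputs.
    """

    aligned_a: str
    aligned_b: str
    score: float
    identity: float
    mode: str
    a_span: tuple[int, int]
    b_span: tuple[int, int]


@dataclass(frozen=True)
class TirReport:
    """Longest qualifying terminal-inverted-repeat arm of an element.

    ``length`` is 0 (with empty arms) when no arm in the configured range
    qualifies.
    """

    length: int
    mismatches: int
    left_arm: Optional[Interval]
    right_arm: Optional[Interval]


@dataclass(frozen=True)
class TsdCall:
    """A detected target site duplication flanking an insertion."""

    tsd: str
    length: int
    left_pos: Interval
    right_pos: Interval


_MODES = ("global", "local", "glocal")


def _make_aligner(mode: str, scoring: Scoring) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.match_score = scoring.match
    aligner.mismatch_score = scoring.mismatch
    aligner.open_gap_score = scoring.gap_open + scoring.gap_extend
    aligner.extend_gap_score = scoring.gap_extend
    if mode == "glocal":
        # Query fully aligned, target local: end gaps on the target side
        # (rendered as gaps in the query row) are free.
        aligner.mode = "global"
        aligner.open_left_deletion_score = 0
        aligner.extend_left_deletion_score = 0
        aligner.open_right_deletion_score = 0
        aligner.extend_right_deletion_score = 0
    else:
        aligner.mode = mode
    return aligner


def _column_identity(row_a: str, row_b: str) -> float:
    """Match fraction over columns, terminal gap runs excluded; N never matches."""
    n = len(row_a)
    lo, hi = 0, n
    while lo < hi and (row_a[lo] == "-" or row_b[lo] == "-"):
        lo += 1
    while hi > lo and (row_a[hi - 1] == "-" or row_b[hi - 1] == "-"):
        hi -= 1
    cols = matches = 0
    for x, y in zip(row_a[lo:hi], row_b[lo:hi]):
        cols += 1
        if x == y and x not in ("-", "N"):
            matches += 1
    return matches / cols if cols else 0.0


def align_pair(
    a: str,
    b: str,
    mode: str = "global",
    scoring: Scoring = Scoring(),
) -> PairwiseAlignment:
    """Optimal affine-gap pairwise alignment of two DNA strings.

    Modes: ``global`` (Needleman-Wunsch), ``local`` (Smith-Waterman) and
    ``glocal`` (``a`` fully aligned, ``b`` local - the shape used to place a
    short part consensus inside a genomic window).  The returned rows are
    the full inputs for global/glocal and the aligned substrings for local.
    """
    if not a or not b:
        raise InputError("align_pair requires two non-empty sequences")
    if mode not in _MODES:
        raise ConfigError(f"unknown alignment mode {mode!r}; use one of {_MODES}")
    aligner = _make_aligner(mode, scoring)
    # biopython's first sequence is the one whose end gaps we freed ("b").
    aln = aligner.align(b, a)[0]
    row_b, row_a = str(aln[0]), str(aln[1])
    coords = aln.coordinates
    # Spans cover the terminal-gap-trimmed core of the alignment; for local
    # mode the rows already are that core.
    n_cols = len(row_a)
    lo, hi = 0, n_cols
    while lo < hi and (row_a[lo] == "-" or row_b[lo] == "-"):
        lo += 1
    while hi > lo and (row_a[hi - 1] == "-" or row_b[hi - 1] == "-"):
        hi -= 1
    b_off = int(coords[0][0])
    a_off = int(coords[1][0])
    b_span = (
        b_off + lo - row_b[:lo].count("-"),
        b_off + hi - row_b[:hi].count("-"),
    )
    a_span = (
        a_off + lo - row_a[:lo].count("-"),
        a_off + hi - row_a[:hi].count("-"),
    )
    identity = _column_identity(row_a, row_b)
    return PairwiseAlignment(
        aligned_a=row_a,
        aligned_b=row_b,
        score=float(aln.score),
        identity=identity,
        mode=mode,
        a_span=a_span,
        b_span=b_span,
    )


def default_tir_mismatch_budget(length: int) -> int:
    """Default mismatch tolerance for an arm of the given length.

    Arms are 'perfect or imperfect'; we allow 15 % non-complementary
    columns, but always at least one.
    """
    return max(1, int(0.15 * length))


def find_tir(
    element_seq: str,
    min_len: int = 8,
    max_len: int = 30,
    max_mismatch: Optional[int] = None,
) -> TirReport:
    """Longest terminal-inverted-repeat arm of an element sequence.

    Searches arm lengths from ``max_len`` down to ``min_len`` and returns
    the longest L for which the first L bases align to the reverse
    complement of the last L bases with at most ``max_mismatch``
    mismatches (default: :func:`default_tir_mismatch_budget`).  Returns a
    zero-length report when nothing qualifies.
    """
    if min_len > max_len:
        raise ConfigError("find_tir: min_len > max_len")
    if min_len < 1:
        raise ConfigError("find_tir: min_len must be >= 1")
    if len(element_seq) < 2 * min_len:
        raise InputError("find_tir: element shorter than two minimal arms")
    if not set(element_seq) <= ALPHABET:
        raise InputError("find_tir: non-alphabet characters")
    top = min(max_len, len(element_seq) // 2)
    for length in range(top, min_len - 1, -1):
        left = element_seq[:length]
        right_rc = reverse_complement(element_seq[-length:])
        mism = sum(
            1 for x, y in zip(left, right_rc) if x != y or x == "N" or y == "N"
        )
        budget = max_mismatch if max_mismatch is not None else default_tir_mismatch_budget(length)
        if mism <= budget:
            return TirReport(
                length=length,
                mismatches=mism,
                left_arm=Interval("element", 0, length),
                right_arm=Interval("element", len(element_seq) - length, len(element_seq)),
            )
    return TirReport(length=0, mismatches=0, left_arm=None, right_arm=None)


def terminal_signature(element_seq: str) -> Optional[bool]:
    """True iff the element starts 5'-RR (two purines) and ends YY-3'.

    Returns ``None`` (indeterminate, distinct from False) when any of the
    four terminal positions is N.
    """
    if len(element_seq) < 4:
        raise InputError("terminal_signature: sequence shorter than 4 bp")
    if not set(element_seq) <= ALPHABET:
        raise InputError("terminal_signature: non-alphabet characters")
    head, tail = element_seq[:2], element_seq[-2:]
    if "N" in head or "N" in tail:
        return None
    return set(head) <= PURINES and set(tail) <= PYRIMIDINES


def detect_tsd(
    left_flank: str,
    right_flank: str,
    k_min: int = 3,
    k_max: int = 6,
    max_mismatch: int = 0,
) -> Optional[TsdCall]:
    """Longest target-site duplication between two insertion flanks.

    Compares the k-suffix of ``left_flank`` with the k-prefix of
    ``right_flank`` for k from ``k_max`` down to ``k_min``; exact match by
    default (``max_mismatch`` may be set to 1 to tolerate one substitution;
    N never matches).  Returns ``None`` when no k qualifies.
    """
    if k_min > k_max or k_min < 1:
        raise ConfigError("detect_tsd: need 1 <= k_min <= k_max")
    if len(left_flank) < k_max or len(right_flank) < k_max:
        raise InputError("detect_tsd: flanks shorter than k_max")
    for k in range(k_max, k_min - 1, -1):
        suffix = left_flank[-k:]
        prefix = right_flank[:k]
        mism = sum(
            1 for x, y in zip(suffix, prefix) if x != y or x == "N" or y == "N"
        )
        if mism <= max_mismatch:
            return TsdCall(
                tsd=suffix,
                length=k,
                left_pos=Interval("left_flank", len(left_flank) - k, len(left_flank)),
                right_pos=Interval("right_flank", 0, k),
            )
    return None
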