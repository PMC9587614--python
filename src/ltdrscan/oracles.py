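"""Brute-force reference implementations used for cross-validation.

Everything in this module trades speed for transparency: quadratic dynamic
programs, exhaustive enumerations and regular expressions.  They are kept
deliberately independent of the production code paths (biopython / edlib /
the hand-rolled grammar parser) so that agreement between the two routes is
meaningful evidence of correctness.
"""

from __future__ import annotations

import re

from ltdrscan.core import Scoring


def local_alignment_score(a: str, b: str, scoring: Scoring = Scoring()) -> float:
    """Smith-Waterman local score with affine gaps (Gotoh), pure-Python DP.

    Gap convention matches :class:`ltdrscan.core.Scoring`: a gap of length
    L costs ``gap_open + L * gap_extend``.
    """
    n, m = len(a), len(b)
    neg = float("-inf")
    open_cost = scoring.gap_open + scoring.gap_extend
    ext = scoring.gap_extend
    best = 0.0
    # H: best ending in match/mismatch; E: gap in a (consumes b); F: gap in b.
    prev_h = [0.0] * (m + 1)
    prev_e = [neg] * (m + 1)
    for i in range(1, n + 1):
        cur_h = [0.0] * (m + 1)
        cur_e = [neg] * (m + 1)
        f = neg
        for j in range(1, m + 1):
            sub = scoring.match if a[i - 1] == b[j - 1] else scoring.mismatch
            h_diag = max(prev_h[j - 1], 0.0) + sub
            cur_e[j] = max(prev_e[j] + ext, prev_h[j] + open_cost)
            f = max(f + ext, cur_h[j - 1] + open_cost)
            h = max(h_diag, cur_e[j], f, 0.0)
            cur_h[j] = h
            if h > best:
                best = h
        prev_h, prev_e = cur_h, cur_e
    return best


_GRAMMAR = [
    ("SOLO_LTDR", re.compile(r"L")),
    ("SOLO_INT", re.compile(r"I")),
    ("LTDR_INT", re.compile(r"LI")),
    ("INT_LTDR", re.compile(r"IL")),
    ("MONOMER", re.compile(r"LIL")),
    ("MULTIMER_SHARED", re.compile(r"(?:LI){2,}L")),
    ("TANDEM_INT", re.compile(r"LI{2,}L")),
]


def architecture_by_regex(tokens: str) -> tuple[str, int | None, int | None]:
    """Regex oracle for the insertion-architecture grammar.

    ``tokens`` is a string over {L, I}.  Returns (label, n, m) where n is
    the monomer-unit count of a shared-LTDR multimer and m the abutted-INT
    count of a tandem-INT array; anything matching no rule is COMPLEX.
    """
    if not tokens or set(tokens) - {"L", "I"}:
        raise ValueError(f"bad token string {tokens!r}")
    for label, pattern in _GRAMMAR:
        if pattern.fullmatch(tokens):
            if label == "MULTIMER_SHARED":
                return label, tokens.count("I"), None
            if label == "TANDEM_INT":
                return label, None, tokens.count("I")
            return label, None, None
    return "COMPLEX", None, None


def tir_by_enumeration(
    seq: str, min_len: int, max_len: int, max_mismatch: int
) -> int:
    """Longest qualifying TIR arm by checking every arm length explicitly."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "?"}
    best = 0
    for length in range(min_len, min(max_len, len(seq) // 2) + 1):
        mism = 0
        for i in range(length):
            if seq[i] != comp[seq[len(seq) - 1 - i]]:
                mism += 1
        if mism <= max_mismatch:
            best = length
    return best


def tsd_by_scan(
    left: str, right: str, k_min: int, k_max: int
) -> str | None:
    """Longest exact suffix/prefix duplication by scanning every k."""
    best = None
    for k in range(k_min, k_max + 1):
        if "N" not in left[-k:] and left[-k:] == right[:k]:
            best = left[-k:]
    return best
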