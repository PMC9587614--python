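"""Seed-and-extend scanner: find all copies of LTDR/INT part consensi.

The scanner replaces a general-purpose repeat search with a focused
two-stage strategy: exact ``word_size``-mer seeding (both strands, numpy
rolling hash) followed by alignment extension of the part consensus
against each seeded window.  Extension is glocal when the copy looks
full-length and local otherwise, so truncated copies surface as hits with
low ``query_coverage`` rather than going missing.  Windows that could hold
several abutted copies (shared-LTDR multimers, tandem INTs) are searched
recursively: after each accepted hit the flanking sub-windows are
re-searched until nothing qualifies.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import edlib
import numpy as np
import pandas as pd

from ltdrscan.core import (
    GenomeSequence,
    Interval,
    Scoring,
    align_pair,
    reverse_complement,
)
from ltdrscan.errors import ConfigError, InputError

#: Identity floor shared with the consensus-building cluster step.
DEFAULT_MIN_IDENTITY = 0.75

_SCAN_SCORING = Scoring(match=2, mismatch=-3, gap_open=-5, gap_extend=-2)


@dataclass(frozen=True)
class Hit:
    """One scanner match of a part consensus on a contig."""

    interval: Interval
    part: str
    family_id: str
    identity: float
    query_coverage: float
    columns: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.identity <= 1.0 and 0.0 <= self.query_coverage <= 1.0):
            raise InputError("identity and coverage must be fractions")


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    table = np.full(256, 4, dtype=np.uint8)
    for i, base in enumerate(b"ACGT"):
        table[base] = i
    return table[arr]


def _rolling_hashes(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Base-4 hashes of all k-windows plus a validity mask (no N)."""
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=bool)
    h = np.zeros(n, dtype=np.uint64)
    valid = np.ones(n, dtype=bool)
    codes64 = codes.astype(np.uint64)
    for i in range(k):
        h = h * np.uint64(4) + codes64[i : n + i]
        valid &= codes[i : n + i] < 4
    return h, valid


def parse_part_id(record_id: str) -> tuple[str, str]:
    """Split a part-library header of the form ``family:PART``."""
    family, sep, part = record_id.rpartition(":")
    if not sep or part not in ("LTDR", "INT"):
        raise InputError(
            f"part-library id {record_id!r} must look like 'family:LTDR' or 'family:INT'"
        )
    return family, part


def _seed_windows(
    seed_positions: np.ndarray, qlen: int, word_size: int, contig_len: int
) -> list[tuple[int, int]]:
    """Group nearby seed positions and pad each group by one query length."""
    windows = []
    if seed_positions.size == 0:
        return windows
    group_start = prev = int(seed_positions[0])
    for pos in seed_positions[1:]:
        pos = int(pos)
        if pos - prev > qlen:
            windows.append(
                (max(0, group_start - qlen - 50), min(contig_len, prev + word_size + qlen + 50))
            )
            group_start = pos
        prev = pos
    windows.append(
        (max(0, group_start - qlen - 50), min(contig_len, prev + word_size + qlen + 50))
    )
    return windows


def _extend_in_window(
    query: str,
    contig: GenomeSequence,
    wstart: int,
    wend: int,
    part: str,
    family_id: str,
    strand: str,
    min_identity: float,
    min_coverage: float,
    out: list[Hit],
) -> None:
    qlen = len(query)
    if wend - wstart < max(12, int(min_coverage * qlen * 0.8)):
        return
    wseq = contig.seq[wstart:wend]
    located = edlib.align(query, wseq, mode="HW", task="locations", k=-1)
    if not located["locations"]:
        return
    s, e = located["locations"][0]
    if s is None:
        s = 0
    sub_start = max(0, s - 40)
    sub = wseq[sub_start : e + 1 + 40]
    if not sub:
        return
    aln = align_pair(query, sub, mode="local", scoring=_SCAN_SCORING)
    qs, qe = aln.a_span
    coverage = (qe - qs) / qlen
    if coverage >= 0.9:
        # Looks full length: force the whole query in so terminal
        # mismatches cannot shave the element boundaries.
        aln = align_pair(query, sub, mode="glocal", scoring=_SCAN_SCORING)
        coverage = 1.0
    identity = aln.identity
    ts, te = aln.b_span
    if te <= ts:
        return
    columns = max(len(aln.aligned_a.strip("-")), te - ts)
    if identity >= min_identity and coverage >= min_coverage:
        hit_start = wstart + sub_start + ts
        hit_end = wstart + sub_start + te
        out.append(
            Hit(
                interval=Interval(contig.contig_id, hit_start, hit_end, strand),
                part=part,
                family_id=family_id,
                identity=round(identity, 4),
                query_coverage=round(coverage, 4),
                columns=columns,
            )
        )
        _extend_in_window(
            query, contig, wstart, hit_start, part, family_id, strand,
            min_identity, min_coverage, out,
        )
        _extend_in_window(
            query, contig, hit_end, wend, part, family_id, strand,
            min_identity, min_coverage, out,
        )


def _dedupe(hits: list[Hit]) -> list[Hit]:
    """Merge overlapping same-part same-family hits, keeping higher identity."""
    hits = sorted(
        hits, key=lambda h: (h.interval.contig_id, h.part, h.family_id, h.interval.start)
    )
    kept: list[Hit] = []
    for hit in hits:
        if kept:
            last = kept[-1]
            same = (
                last.part == hit.part
                and last.family_id == hit.family_id
                and last.interval.contig_id == hit.interval.contig_id
            )
            if same and last.interval.overlaps(hit.interval):
                overlap = min(last.interval.end, hit.interval.end) - max(
                    last.interval.start, hit.interval.start
                )
                shorter = min(len(last.interval), len(hit.interval))
                if overlap >= 0.5 * shorter:
                    if hit.identity > last.identity:
                        kept[-1] = hit
                    continue
        kept.append(hit)
    return kept


def scan(
    genomes: Sequence[GenomeSequence] | GenomeSequence,
    part_library: Sequence[GenomeSequence],
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_coverage: float = 0.5,
    word_size: int = 12,
) -> list[Hit]:
    """Find every locus where a part consensus matches at ``min_identity``.

    Hits are reported on both strands and sorted by (contig, start, part).
    """
    if isinstance(genomes, GenomeSequence):
        genomes = [genomes]
    if not part_library:
        raise ConfigError("empty part library")
    if word_size < 8:
        raise ConfigError("word_size must be >= 8")
    for rec in part_library:
        if len(rec.seq) < word_size:
            raise ConfigError(f"part {rec.contig_id!r} shorter than word_size")
    hits: list[Hit] = []
    for contig in genomes:
        codes = _encode(contig.seq)
        g_hashes, g_valid = _rolling_hashes(codes, word_size)
        if g_hashes.size == 0:
            continue
        for rec in part_library:
            family_id, part = parse_part_id(rec.contig_id)
            for strand in ("+", "-"):
                query = rec.seq if strand == "+" else reverse_complement(rec.seq)
                q_hashes, q_valid = _rolling_hashes(_encode(query), word_size)
                q_set = np.unique(q_hashes[q_valid])
                seed_mask = np.isin(g_hashes, q_set) & g_valid
                seeds = np.nonzero(seed_mask)[0]
                part_hits: list[Hit] = []
                for wstart, wend in _seed_windows(seeds, len(query), word_size, len(contig.seq)):
                    _extend_in_window(
                        query, contig, wstart, wend, part, family_id, strand,
                        min_identity, min_coverage, part_hits,
                    )
                hits.extend(part_hits)
    hits = _dedupe(hits)
    hits.sort(key=lambda h: (h.interval.contig_id, h.interval.start, h.part))
    return hits


def merge_hits(hits: Sequence[Hit], max_gap: int = 30) -> list[Hit]:
    """Join same-part, same-strand fragments separated by at most ``max_gap``.

    Only fragments of one broken-up copy are joined: two pieces whose
    query coverages sum beyond ~one full consensus are genuinely distinct
    abutted copies (tandem INTs, shared LTDRs) and stay separate.  The
    merged identity is the alignment-column-weighted mean of the
    fragments; query coverage is summed (capped at 1).
    """
    merged: list[Hit] = []
    for hit in sorted(hits, key=lambda h: (h.interval.contig_id, h.interval.start)):
        if merged:
            last = merged[-1]
            if (
                last.part == hit.part
                and last.family_id == hit.family_id
                and last.interval.contig_id == hit.interval.contig_id
                and last.interval.strand == hit.interval.strand
                and 0 <= hit.interval.start - last.interval.end <= max_gap
                and last.query_coverage + hit.query_coverage <= 1.1
            ):
                total_cols = last.columns + hit.columns
                merged[-1] = replace(
                    last,
                    interval=Interval(
                        last.interval.contig_id,
                        last.interval.start,
                        hit.interval.end,
                        last.interval.strand,
                    ),
                    identity=round(
                        (last.identity * last.columns + hit.identity * hit.columns)
                        / total_cols,
                        4,
                    ),
                    query_coverage=min(1.0, round(last.query_coverage + hit.query_coverage, 4)),
                    columns=total_cols,
                )
                continue
        merged.append(hit)
    return merged


def hits_to_frame(hits: Sequence[Hit]) -> pd.DataFrame:
    """Tabular view of a hit list (0-based half-open coordinates)."""
    return pd.DataFrame(
        [
            {
                "contig_id": h.interval.contig_id,
                "start": h.interval.start,
                "end": h.interval.end,
                "strand": h.interval.strand,
                "family_id": h.family_id,
                "part": h.part,
                "identity": h.identity,
                "query_coverage": h.query_coverage,
            }
            for h in hits
        ],
        columns=[
            "contig_id", "start", "end", "strand",
            "family_id", "part", "identity", "query_coverage",
        ],
    )


def hits_to_bed_rows(hits: Sequence[Hit]) -> list[tuple[Interval, str, float]]:
    return [(h.interval, f"{h.family_id}:{h.part}", h.identity) for h in hits]
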