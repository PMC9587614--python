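"""Rebuild family consensi from genomic copies.

The reconstruction pipeline mirrors classical repeat-library curation:
greedy 75 %/75 % clustering, star alignment of the cluster members onto a
seed copy, a 50 %-majority-rule consensus, iterative re-extraction with
long flanks so the consensus can grow until it reaches the true element
termini, and finally terminus calling from three independent lines of
evidence (RR..YY signature, TIR, member TSDs).

The flank-extension trick relies on the flanking sequence of distinct
insertion loci being mutually unrelated: within the element, copies agree
and per-column support is high; outside it, support collapses to
background base frequencies.  The element boundary is declared where
support first stays below threshold for a sustained run of columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from ltdrscan.core import (
    GenomeSequence,
    Interval,
    Scoring,
    align_pair,
    detect_tsd,
    find_tir,
    reverse_complement,
    terminal_signature,
)
from ltdrscan.errors import InputError

_SCORING = Scoring(match=2, mismatch=-3, gap_open=-5, gap_extend=-2)

MISSING = "."
GAP = "-"


@dataclass
class ConsensusModel:
    """A consensus sequence with per-column support and called termini.

    ``support`` is, per consensus column, the fraction of non-missing
    members agreeing with the emitted base.  ``termini`` are offsets into
    ``seq`` once called; the three evidence flags say which terminus tests
    passed (RR..YY signature, TIR, member TSDs).
    """

    seq: str
    support: list[float]
    tie_columns: list[int] = field(default_factory=list)
    termini: Optional[tuple[int, int]] = None
    evidence: dict = field(default_factory=dict)
    low_confidence: bool = False

    def called_seq(self) -> str:
        if self.termini is None:
            return self.seq
        return self.seq[self.termini[0] : self.termini[1]]


def greedy_cluster(
    seqs: Sequence[GenomeSequence],
    min_identity: float = 0.75,
    min_coverage: float = 0.75,
) -> list[list[GenomeSequence]]:
    """Greedy single-linkage clustering at identity/coverage thresholds.

    Seeds with the longest unassigned sequence and joins any sequence
    whose local alignment to the seed reaches ``min_identity`` with
    coverage ``min_coverage`` of the shorter sequence.  Deterministic:
    candidates are processed by (length descending, id lexicographic).
    """
    if not seqs:
        raise InputError("greedy_cluster: no sequences")
    pending = sorted(seqs, key=lambda r: (-len(r.seq), r.contig_id))
    clusters: list[list[GenomeSequence]] = []
    while pending:
        seed = pending.pop(0)
        members = [seed]
        rest = []
        for cand in pending:
            short, long_ = (cand, seed) if len(cand.seq) <= len(seed.seq) else (seed, cand)
            aln = align_pair(short.seq, long_.seq, "local", _SCORING)
            coverage = (aln.a_span[1] - aln.a_span[0]) / len(short.seq)
            if aln.identity >= min_identity and coverage >= min_coverage:
                members.append(cand)
            else:
                rest.append(cand)
        pending = rest
        clusters.append(members)
    return clusters


def star_msa(
    copies: Sequence[str],
    seed_seq: str,
    min_identity: float = 0.5,
) -> tuple[list[str], list[int]]:
    """Star alignment of copies onto a seed; one shared coordinate system.

    Each copy is aligned pairwise to the seed and the columns are merged:
    one block per seed position, preceded by an insertion block wide
    enough for the longest insertion any member carries there.  Positions
    a member does not span are marked '.', deletions '-'.  Returns
    (rows, kept_indices); members below the identity floor are excluded.
    """
    if not copies:
        raise InputError("star_msa: no copies")
    per_copy = []
    kept = []
    for idx, copy in enumerate(copies):
        aln = align_pair(copy, seed_seq, "local", _SCORING)
        if aln.identity < min_identity:
            continue
        kept.append(idx)
        # bases[j] = member base at seed position j; ins[j] = member bases
        # inserted immediately before seed position j.
        bases: dict[int, str] = {}
        ins: dict[int, str] = {}
        seed_pos = aln.b_span[0]
        for x, y in zip(aln.aligned_a, aln.aligned_b):
            if y == GAP:
                ins[seed_pos] = ins.get(seed_pos, "") + x
            elif x == GAP:
                bases[seed_pos] = GAP
                seed_pos += 1
            else:
                bases[seed_pos] = x
                seed_pos += 1
        per_copy.append((aln.b_span, bases, ins))
    if not per_copy:
        raise InputError("star_msa: every member fell below the identity floor")
    ins_width = [0] * (len(seed_seq) + 1)
    for _, _, ins in per_copy:
        for j, s in ins.items():
            ins_width[j] = max(ins_width[j], len(s))
    rows = []
    for (lo, hi), bases, ins in per_copy:
        chunks = []
        for j in range(len(seed_seq) + 1):
            if ins_width[j]:
                s = ins.get(j, "")
                pad = MISSING if (j < lo or j > hi) else GAP
                chunks.append(s + pad * (ins_width[j] - len(s)))
            if j < len(seed_seq):
                if lo <= j < hi:
                    chunks.append(bases.get(j, GAP))
                else:
                    chunks.append(MISSING)
        rows.append("".join(chunks))
    return rows, kept


def majority_consensus(rows: Sequence[str], threshold: float = 0.5) -> ConsensusModel:
    """Majority-rule consensus of an aligned matrix.

    Per column the plurality symbol among non-missing entries is emitted
    when its fraction reaches ``threshold`` (below it the plurality winner
    is still emitted but carries its sub-threshold support); gap-majority
    columns are deleted.  Ties break by whole-matrix base frequency, then
    alphabetically, and are flagged.
    """
    if not rows:
        raise InputError("majority_consensus: empty matrix")
    width = len(rows[0])
    if any(len(r) != width for r in rows):
        raise InputError("majority_consensus: ragged matrix")
    overall: dict[str, int] = {}
    for row in rows:
        for ch in row:
            if ch not in (MISSING, "N"):
                overall[ch] = overall.get(ch, 0) + 1
    seq_chars: list[str] = []
    support: list[float] = []
    ties: list[int] = []
    for col in range(width):
        counts: dict[str, int] = {}
        total = 0
        for row in rows:
            ch = row[col]
            if ch in (MISSING, "N"):
                continue
            counts[ch] = counts.get(ch, 0) + 1
            total += 1
        if total == 0:
            continue
        top = max(counts.values())
        winners = sorted(
            (ch for ch, c in counts.items() if c == top),
            key=lambda ch: (-overall.get(ch, 0), ch),
        )
        winner = winners[0]
        if winner == GAP:
            continue
        if len(winners) > 1:
            ties.append(len(seq_chars))
        seq_chars.append(winner)
        support.append(top / total)
    return ConsensusModel(seq="".join(seq_chars), support=support, tie_columns=ties)


@dataclass
class ExtendedConsensus:
    """Result of flank extension: consensus plus per-member placements.

    ``full_seq``/``full_support`` include the low-support flank margins;
    ``boundaries`` delimit the supported element within them.  ``model``
    is the trimmed consensus.  ``member_intervals`` give each member's
    element span on its contig after extension.
    """

    model: ConsensusModel
    full_seq: str
    full_support: list[float]
    boundaries: tuple[int, int]
    member_intervals: list[Interval]
    over_extended: bool = False


def _oriented_slices(genome: GenomeSequence, iv: Interval, flank: int) -> tuple[str, str, str]:
    """(left_flank, core, right_flank) in element orientation."""
    gl = genome.seq[max(0, iv.start - flank) : iv.start]
    core = genome.seq[iv.start : iv.end]
    gr = genome.seq[iv.end : iv.end + flank]
    if iv.strand == "-":
        return reverse_complement(gr), reverse_complement(core), reverse_complement(gl)
    return gl, core, gr


def extend_to_termini(
    genomes: Sequence[GenomeSequence],
    copy_intervals: Sequence[Interval],
    flank: int = 5000,
    max_rounds: int = 10,
    max_copies: int = 10,
    support_threshold: float = 0.7,
    drop_run: int = 20,
) -> ExtendedConsensus:
    """Grow a copy-set consensus until it spans the element termini.

    Copies are re-extracted with ``flank`` bases of genomic context (the
    caller supplies them in preference order; only the first
    ``max_copies`` are used), star-aligned, and consensus support is
    scanned outward from the core: the element ends where support stays
    below ``support_threshold`` for ``drop_run`` consecutive columns.
    Iterates until member placements converge or ``max_rounds``.

    A single copy cannot terminate (no disagreement in its flanks): the
    result is returned un-extended and flagged low-confidence.  If support
    never drops before the extracted window ends, the consensus is flagged
    ``over_extended`` (e.g. copies inserted into near-identical host
    repeats).
    """
    by_id = {g.contig_id: g for g in genomes}
    intervals = list(copy_intervals)[:max_copies]
    if not intervals:
        raise InputError("extend_to_termini: no copies")
    if len(intervals) < 2:
        genome = by_id[intervals[0].contig_id]
        _, core, _ = _oriented_slices(genome, intervals[0], 0)
        model = ConsensusModel(seq=core, support=[1.0] * len(core), low_confidence=True)
        return ExtendedConsensus(
            model=model,
            full_seq=core,
            full_support=[1.0] * len(core),
            boundaries=(0, len(core)),
            member_intervals=intervals,
            over_extended=False,
        )
    over_extended = False
    for _ in range(max_rounds):
        slices = [
            _oriented_slices(by_id[iv.contig_id], iv, flank) for iv in intervals
        ]
        cores = [core for _, core, _ in slices]
        seed_idx = max(range(len(cores)), key=lambda i: len(cores[i]))
        core_rows, kept = star_msa(cores, cores[seed_idx])
        slices = [slices[i] for i in kept]
        intervals = [intervals[i] for i in kept]
        lw = max(len(lf) for lf, _, _ in slices)
        rw = max(len(rf) for _, _, rf in slices)
        rows = []
        for (lf, _, rf), core_row in zip(slices, core_rows):
            rows.append(
                MISSING * (lw - len(lf)) + lf + core_row + rf + MISSING * (rw - len(rf))
            )
        cons = majority_consensus(rows)
        # Map matrix columns to consensus positions and member base counts.
        width = len(rows[0])
        core_lo, core_hi = lw, width - rw
        col_support, col_winner_kept = _column_profile(rows, cons)
        left_b, hit_left_edge = _walk_boundary(
            col_support, start=core_lo, step=-1, stop=-1,
            threshold=support_threshold, drop_run=drop_run,
        )
        right_b, hit_right_edge = _walk_boundary(
            col_support, start=core_hi - 1, step=+1, stop=width,
            threshold=support_threshold, drop_run=drop_run,
        )
        # Sticky across rounds: hitting the window edge in any round means
        # the copies agreed beyond a full flank of context.
        over_extended = over_extended or hit_left_edge or hit_right_edge
        new_intervals = []
        for iv, row in zip(intervals, rows):
            n_left = sum(1 for ch in row[:left_b] if ch not in (MISSING, GAP))
            n_span = sum(1 for ch in row[left_b : right_b + 1] if ch not in (MISSING, GAP))
            lf_len = len(_oriented_slices(by_id[iv.contig_id], iv, flank)[0])
            if iv.strand == "+":
                start = iv.start - lf_len + n_left
                new_intervals.append(
                    Interval(iv.contig_id, start, start + n_span, iv.strand)
                )
            else:
                end = iv.end + lf_len - n_left
                new_intervals.append(
                    Interval(iv.contig_id, end - n_span, end, iv.strand)
                )
        converged = new_intervals == intervals
        intervals = new_intervals
        if converged:
            break
    # Final consensus over the converged members, trimmed to boundaries.
    full_seq = cons.seq
    full_support = cons.support
    bl = _matrix_to_consensus_index(col_winner_kept, left_b)
    br = _matrix_to_consensus_index(col_winner_kept, right_b + 1)
    model = ConsensusModel(
        seq=full_seq[bl:br],
        support=full_support[bl:br],
        low_confidence=False,
    )
    return ExtendedConsensus(
        model=model,
        full_seq=full_seq,
        full_support=full_support,
        boundaries=(bl, br),
        member_intervals=intervals,
        over_extended=over_extended,
    )


def _column_profile(rows: Sequence[str], cons: ConsensusModel) -> tuple[list[float], list[int]]:
    """Per matrix column: support of the plurality symbol, and the mapping
    from matrix column to consensus index (-1 for deleted columns)."""
    width = len(rows[0])
    support = [0.0] * width
    mapping = [-1] * width
    cons_idx = 0
    for col in range(width):
        counts: dict[str, int] = {}
        total = 0
        for row in rows:
            ch = row[col]
            if ch in (MISSING, "N"):
                continue
            counts[ch] = counts.get(ch, 0) + 1
            total += 1
        if total == 0:
            continue
        top_ch = max(counts, key=lambda ch: counts[ch])
        support[col] = counts[top_ch] / total
        if top_ch != GAP:
            mapping[col] = cons_idx
            cons_idx += 1
    return support, mapping


def _matrix_to_consensus_index(mapping: list[int], col: int) -> int:
    for c in range(col, len(mapping)):
        if mapping[c] >= 0:
            return mapping[c]
    valid = [m for m in mapping if m >= 0]
    return (valid[-1] + 1) if valid else 0


def _walk_boundary(
    support: list[float], start: int, step: int, stop: int,
    threshold: float, drop_run: int,
) -> tuple[int, bool]:
    """Walk outward from the core while columns still look element-like.

    A column belongs to the element while the mean support over the next
    ``drop_run`` columns (looking outward) stays at or above
    ``threshold``; inside the element that mean sits near 1, in unrelated
    flank sequence it collapses to the background base-frequency maximum.
    Returns (boundary column, hit_matrix_edge)."""
    boundary = start
    col = start
    while col != stop:
        window = []
        probe = col
        for _ in range(drop_run):
            if probe == stop:
                break
            window.append(support[probe])
            probe += step
        if not window or sum(window) / len(window) < threshold:
            return boundary, False
        boundary = col
        col += step
    return boundary, True


def call_termini(
    genomes: Sequence[GenomeSequence],
    extended: ExtendedConsensus,
    search: int = 10,
    tir_min: int = 8,
    tsd_k_min: int = 3,
    tsd_k_max: int = 6,
) -> ConsensusModel:
    """Refine and annotate element termini with three evidence tests.

    Candidate cut pairs within ``search`` columns of the support
    boundaries are scored by (1) the RR..YY terminal signature of the
    candidate consensus, (2) a TIR across the candidate element, and
    (3) member-flank TSDs at the candidate cut.  The candidate passing the
    most tests (TSD-supporting member count breaks ties) wins; if no
    candidate passes any test the support boundaries stand, flagged
    low-confidence.
    """
    by_id = {g.contig_id: g for g in genomes}
    bl, br = extended.boundaries
    full = extended.full_seq
    members = extended.member_intervals
    best = None
    for dl in range(-search, search + 1):
        start = bl + dl
        if start < 0:
            continue
        for dr in range(-search, search + 1):
            end = br + dr
            if end > len(full) or end - start < 50:
                continue
            candidate = full[start:end]
            sig = terminal_signature(candidate) is True
            tir = find_tir(candidate, min_len=tir_min).length >= tir_min
            tsd_votes = 0
            for iv in members:
                genome = by_id[iv.contig_id]
                flanks = _member_flanks(genome, iv, dl, dr, tsd_k_max)
                if flanks is None:
                    continue
                left, right = flanks
                if detect_tsd(left, right, k_min=tsd_k_min, k_max=tsd_k_max) is not None:
                    tsd_votes += 1
            tsd = tsd_votes >= max(1, (len(members) + 1) // 2)
            score = (int(sig) + int(tir) + int(tsd), tsd_votes, -(abs(dl) + abs(dr)), -dl, -dr)
            if best is None or score > best[0]:
                best = (score, dl, dr, sig, tir, tsd)
    model = extended.model
    if best is None or best[0][0] == 0:
        return ConsensusModel(
            seq=model.seq,
            support=model.support,
            termini=(0, len(model.seq)),
            evidence={"signature": False, "tir": False, "tsd": False},
            low_confidence=True,
        )
    _, dl, dr, sig, tir, tsd = best
    seq = full[bl + dl : br + dr]
    support = extended.full_support[bl + dl : br + dr]
    return ConsensusModel(
        seq=seq,
        support=support,
        termini=(0, len(seq)),
        evidence={"signature": sig, "tir": tir, "tsd": tsd},
        low_confidence=False,
    )


def _member_flanks(
    genome: GenomeSequence, iv: Interval, dl: int, dr: int, k: int
) -> Optional[tuple[str, str]]:
    """Member flanks (element orientation) at a shifted candidate cut."""
    if iv.strand == "+":
        es, ee = iv.start + dl, iv.end + dr
        if es - k < 0 or ee + k > len(genome.seq):
            return None
        return genome.seq[es - k : es], genome.seq[ee : ee + k]
    es_g, ee_g = iv.start - dr, iv.end - dl
    if es_g - k < 0 or ee_g + k > len(genome.seq):
        return None
    left = reverse_complement(genome.seq[ee_g : ee_g + k])
    right = reverse_complement(genome.seq[es_g - k : es_g])
    return left, right


def split_ltdr_int(consensus: str, min_repeat: int = 100, min_identity: float = 0.9) -> Optional[tuple[str, str]]:
    """Split an element consensus into its LTDR and INT portions.

    Looks for the longest terminal direct repeat: a prefix of length k
    matching the suffix of length k at ``min_identity`` (ungapped).
    Returns (ltdr, int) or None when no repeat of at least ``min_repeat``
    is found.
    """
    best = 0
    for k in range(min_repeat, len(consensus) // 2 + 1):
        prefix = consensus[:k]
        suffix = consensus[-k:]
        matches = sum(1 for x, y in zip(prefix, suffix) if x == y and x != "N")
        if matches / k >= min_identity:
            best = k
    if not best:
        return None
    return consensus[:best], consensus[best : len(consensus) - best]
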