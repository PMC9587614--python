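"""Group hits into loci, parse architectures, gate on TSDs, build censuses.

The architecture vocabulary covers every insertion pattern reported for
LTDR-composite elements:

====================  =====================================================
label                 token pattern (L = LTDR copy, I = INT copy)
====================  =====================================================
SOLO_LTDR             L
SOLO_INT              I
LTDR_INT              L I          (right LTDR lost)
INT_LTDR              I L          (left LTDR lost)
MONOMER               L I L
MULTIMER_SHARED(n)    (L I)^n L, n >= 2   - consecutive monomers sharing
                      abutted LTDRs
TANDEM_INT(m)         L I^m L, m >= 2     - LTDR missing between INTs
COMPLEX               anything else; a best-effort segmentation into the
                      prototype chunks is recorded rather than forcing a
                      label
====================  =====================================================

Census counting follows the convention that only insertions with a
recognizable TSD are counted, and that a dimer (n = 2) is a multimer.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from fractions import Fraction
from typing import Optional, Sequence

import pandas as pd

from ltdrscan.core import (
    GenomeSequence,
    Interval,
    Scoring,
    TsdCall,
    align_pair,
    detect_tsd,
    reverse_complement,
    terminal_signature,
)
from ltdrscan.errors import InputError
from ltdrscan.io import Gff3Feature
from ltdrscan.scanner import Hit

LABELS = (
    "SOLO_LTDR",
    "MONOMER",
    "MULTIMER_SHARED",
    "TANDEM_INT",
    "LTDR_INT",
    "INT_LTDR",
    "SOLO_INT",
    "COMPLEX",
)

_ALIGN_SCORING = Scoring(match=2, mismatch=-3, gap_open=-5, gap_extend=-2)


@dataclass
class LocusCluster:
    """One insertion locus: an ordered run of nearby same-family hits.

    ``tokens``, ``part_seqs``, ``seq`` and the flanks are all given in
    element orientation (reverse-complemented for minus-strand loci).
    """

    contig_id: str
    family_id: str
    hits: list[Hit]
    outer: Interval
    strand: str
    tokens: str
    part_seqs: list[str]
    seq: str
    left_flank: str
    right_flank: str
    flank_truncated: bool = False


@dataclass
class ArchitectureCall:
    """Parsed structural label of one insertion locus."""

    label: str
    n: Optional[int] = None
    m: Optional[int] = None
    tsd: Optional[TsdCall] = None
    junction_microdels: list[Optional[int]] = field(default_factory=list)
    segmentation: list[str] = field(default_factory=list)
    accepted: Optional[bool] = None


@dataclass
class FamilyCensus:
    """Per-family counts of accepted insertions by architecture label."""

    family_id: str
    counts: dict[str, int]
    dimer_count: int
    diversity: Optional[float] = None

    @property
    def multimer_count(self) -> int:
        return self.counts.get("MULTIMER_SHARED", 0)

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def group_hits(
    hits: Sequence[Hit],
    genomes: Sequence[GenomeSequence],
    locus_gap: int = 200,
    flank_len: int = 50,
) -> list[LocusCluster]:
    """Cluster hits into loci: maximal runs with inter-hit gaps <= locus_gap.

    Minus-strand runs are reverse-complement-normalized so tokens read in
    element orientation.  Flanks shorter than ``flank_len`` (contig edge)
    are truncated and flagged.
    """
    by_contig = {g.contig_id: g for g in genomes}
    clusters: list[LocusCluster] = []
    keyed: dict[tuple[str, str], list[Hit]] = {}
    for hit in hits:
        keyed.setdefault((hit.interval.contig_id, hit.family_id), []).append(hit)
    for (contig_id, family_id), group in sorted(keyed.items()):
        genome = by_contig.get(contig_id)
        if genome is None:
            raise InputError(f"hits reference unknown contig {contig_id!r}")
        group.sort(key=lambda h: h.interval.start)
        run: list[Hit] = []
        for hit in group:
            if run and hit.interval.start - run[-1].interval.end > locus_gap:
                clusters.append(_make_cluster(run, genome, family_id, flank_len))
                run = []
            run.append(hit)
        if run:
            clusters.append(_make_cluster(run, genome, family_id, flank_len))
    clusters.sort(key=lambda c: (c.contig_id, c.outer.start))
    return clusters


def _make_cluster(
    run: list[Hit], genome: GenomeSequence, family_id: str, flank_len: int
) -> LocusCluster:
    start = min(h.interval.start for h in run)
    end = max(h.interval.end for h in run)
    minus = sum(1 for h in run if h.interval.strand == "-")
    strand = "-" if minus * 2 > len(run) else "+"
    tokens = "".join("L" if h.part == "LTDR" else "I" for h in run)
    part_seqs = [genome.seq[h.interval.start : h.interval.end] for h in run]
    seq = genome.seq[start:end]
    gl = genome.seq[max(0, start - flank_len) : start]
    gr = genome.seq[end : end + flank_len]
    truncated = len(gl) < flank_len or len(gr) < flank_len
    if strand == "-":
        tokens = tokens[::-1]
        part_seqs = [reverse_complement(s) for s in reversed(part_seqs)]
        seq = reverse_complement(seq)
        gl, gr = reverse_complement(gr), reverse_complement(gl)
    return LocusCluster(
        contig_id=genome.contig_id,
        family_id=family_id,
        hits=run,
        outer=Interval(genome.contig_id, start, end, strand),
        strand=strand,
        tokens=tokens,
        part_seqs=part_seqs,
        seq=seq,
        left_flank=gl,
        right_flank=gr,
        flank_truncated=truncated,
    )


def parse_architecture(tokens: str | Sequence[str]) -> ArchitectureCall:
    """Parse an ordered L/I token string into its architecture label.

    Strings matching no prototype become COMPLEX with a greedy
    left-to-right segmentation into non-overlapping prototype chunks.
    """
    s = "".join(tokens)
    if not s:
        raise InputError("empty token sequence")
    if set(s) - {"L", "I"}:
        raise InputError(f"unknown tokens in {s!r}")
    if s == "L":
        return ArchitectureCall("SOLO_LTDR")
    if s == "I":
        return ArchitectureCall("SOLO_INT")
    if s == "LI":
        return ArchitectureCall("LTDR_INT")
    if s == "IL":
        return ArchitectureCall("INT_LTDR")
    if s == "LIL":
        return ArchitectureCall("MONOMER")
    if len(s) >= 5 and len(s) % 2 == 1 and s[0] == "L" and s[-1] == "L":
        if all(s[i] == ("L" if i % 2 == 0 else "I") for i in range(len(s))):
            return ArchitectureCall("MULTIMER_SHARED", n=len(s) // 2)
    if len(s) >= 4 and s[0] == "L" and s[-1] == "L" and set(s[1:-1]) == {"I"}:
        return ArchitectureCall("TANDEM_INT", m=len(s) - 2)
    return ArchitectureCall("COMPLEX", segmentation=_segment(s))


def _segment(s: str) -> list[str]:
    """Greedy left-to-right split into the longest prototype chunk each step."""
    chunks = []
    i = 0
    while i < len(s):
        chunk = _longest_prototype(s, i)
        chunks.append(chunk)
        i += len(chunk)
    return chunks


def _longest_prototype(s: str, i: int) -> str:
    best = s[i]
    if s[i] == "L":
        # alternating (LI)^k L
        j = i
        while j + 2 < len(s) and s[j + 1] == "I" and s[j + 2] == "L":
            j += 2
        if j > i:
            best = s[i : j + 1]
        # L I^j L
        j = i + 1
        while j < len(s) and s[j] == "I":
            j += 1
        if j > i + 1 and j < len(s) and s[j] == "L" and j - i > len(best) - 1:
            cand = s[i : j + 1]
            if len(cand) > len(best):
                best = cand
    elif i + 1 < len(s) and s[i + 1] == "L":
        best = s[i : i + 2]  # IL
    return best


def gate_by_tsd(
    cluster: LocusCluster,
    call: ArchitectureCall,
    k_min: int = 3,
    k_max: int = 6,
    max_mismatch: int = 0,
) -> ArchitectureCall:
    """Populate the call's TSD and decide acceptance.

    A locus is accepted iff its outer flanks carry a duplication of at
    least ``k_min`` bases; solo-LTDR loci must additionally show the
    RR..YY terminal signature (guarding against stray LTDR-like matches).
    """
    gated = replace(call)
    if len(cluster.left_flank) < k_max or len(cluster.right_flank) < k_max:
        gated.tsd = None
        gated.accepted = False
        return gated
    tsd = detect_tsd(
        cluster.left_flank, cluster.right_flank, k_min=k_min, k_max=k_max,
        max_mismatch=max_mismatch,
    )
    if tsd is not None and cluster.strand == "-":
        # Flanks were normalized to element orientation; report the TSD
        # string on the forward genomic strand.
        tsd = replace(tsd, tsd=reverse_complement(tsd.tsd))
    gated.tsd = tsd
    accepted = tsd is not None
    if accepted and call.label == "SOLO_LTDR":
        accepted = terminal_signature(cluster.seq) is True
    gated.accepted = accepted
    return gated


def call_junction_microdeletion(
    cluster: LocusCluster,
    int_consensus: str,
    min_identity: float = 0.6,
) -> list[Optional[int]]:
    """Consensus bases covered by neither copy at each INT-INT junction.

    For every pair of abutted INT copies, both copies are glocally aligned
    to the INT consensus; the micro-deletion is the number of consensus
    bases missing between the end of the upstream copy's span and the
    start of the downstream copy's span (tail gap + head gap).  A junction
    whose copies fail the identity floor is reported as None
    (unresolvable).
    """
    out: list[Optional[int]] = []
    doubled = int_consensus + int_consensus
    for i in range(len(cluster.tokens) - 1):
        if cluster.tokens[i] != "I" or cluster.tokens[i + 1] != "I":
            continue
        # The split point between two abutted copies is ambiguous wherever
        # the shared edge motif could belong to either copy, so align the
        # combined region against a doubled consensus: the consensus bases
        # missing at the junction surface as the length deficit of the
        # aligned spans.
        combined = cluster.part_seqs[i] + cluster.part_seqs[i + 1]
        aln = align_pair(combined, doubled, "glocal", _ALIGN_SCORING)
        if aln.identity < min_identity:
            out.append(None)
            continue
        target_span = aln.b_span[1] - aln.b_span[0]
        query_span = aln.a_span[1] - aln.a_span[0]
        out.append(max(0, target_span - query_span))
    return out


def tabulate(
    calls: Sequence[ArchitectureCall],
    family_id: str,
    accepted_only: bool = True,
    diversity: Optional[float] = None,
) -> FamilyCensus:
    """Per-label census of one family's calls; COMPLEX is counted, not dropped."""
    counts = {label: 0 for label in LABELS}
    dimers = 0
    for call in calls:
        if accepted_only and call.accepted is not True:
            continue
        counts[call.label] += 1
        if call.label == "MULTIMER_SHARED" and call.n == 2:
            dimers += 1
    return FamilyCensus(
        family_id=family_id, counts=counts, dimer_count=dimers, diversity=diversity
    )


def dimer_fraction(dimer_count: int, multimer_count: int) -> Optional[int]:
    """Percentage of dimers among multimers, rounded half-up to an integer.

    Returns None (undefined) when there are no multimers.
    """
    if dimer_count < 0 or multimer_count < dimer_count:
        raise InputError("need multimer_count >= dimer_count >= 0")
    if multimer_count == 0:
        return None
    return int(Fraction(100 * dimer_count, multimer_count) + Fraction(1, 2))


def family_diversity(
    copies: Sequence[str],
    consensus: str,
    min_identity: float = 0.75,
) -> Optional[float]:
    """Mean percent divergence of copies from their consensus, to one decimal.

    Copies aligning below ``min_identity`` are excluded; None when no copy
    qualifies.
    """
    divergences = []
    for copy in copies:
        if not copy:
            continue
        aln = align_pair(copy, consensus, "glocal", _ALIGN_SCORING)
        if aln.identity >= min_identity:
            divergences.append(100.0 * (1.0 - aln.identity))
    if not divergences:
        return None
    return round(sum(divergences) / len(divergences), 1)


def ltdr_length_class(
    ltdr_len: int,
    band_450: tuple[int, int] = (400, 550),
    band_660: tuple[int, int] = (600, 720),
) -> str:
    """Assign an LTDR length to one of the two observed length classes."""
    if ltdr_len <= 0:
        raise InputError("ltdr_len must be positive")
    if band_450[0] <= ltdr_len <= band_450[1]:
        return "class_450"
    if band_660[0] <= ltdr_len <= band_660[1]:
        return "class_660"
    return "other"


_CENSUS_COLUMNS = [
    "family_id",
    "diversity_pct",
    "monomer",
    "solo_ltdr",
    "multimer",
    "dimer",
    "ltdr_int",
    "int_ltdr",
    "solo_int",
    "tandem_int",
    "complex",
    "dimer_fraction_pct",
]


def census_frame(censuses: Sequence[FamilyCensus]) -> pd.DataFrame:
    """Census table in the familiar column order (one family per row)."""
    rows = []
    for c in censuses:
        frac = dimer_fraction(c.dimer_count, c.multimer_count)
        rows.append(
            {
                "family_id": c.family_id,
                "diversity_pct": "" if c.diversity is None else c.diversity,
                "monomer": c.counts.get("MONOMER", 0),
                "solo_ltdr": c.counts.get("SOLO_LTDR", 0),
                "multimer": c.counts.get("MULTIMER_SHARED", 0),
                "dimer": c.dimer_count,
                "ltdr_int": c.counts.get("LTDR_INT", 0),
                "int_ltdr": c.counts.get("INT_LTDR", 0),
                "solo_int": c.counts.get("SOLO_INT", 0),
                "tandem_int": c.counts.get("TANDEM_INT", 0),
                "complex": c.counts.get("COMPLEX", 0),
                "dimer_fraction_pct": "" if frac is None else frac,
            }
        )
    return pd.DataFrame(rows, columns=_CENSUS_COLUMNS)


def calls_to_gff3(
    clusters: Sequence[LocusCluster], calls: Sequence[ArchitectureCall]
) -> list[Gff3Feature]:
    """One parent feature per insertion plus one child feature per part.

    Rejected loci are kept (attribute ``rejected=true``) so nothing is
    silently dropped; census tables count accepted loci only.
    """
    features = []
    for i, (cluster, call) in enumerate(zip(clusters, calls)):
        parent_id = f"locus{i:05d}"
        attrs = {
            "ID": parent_id,
            "family": cluster.family_id,
            "label": call.label,
        }
        if call.n is not None:
            attrs["n"] = call.n
        if call.m is not None:
            attrs["m"] = call.m
        if call.tsd is not None:
            attrs["tsd"] = call.tsd.tsd
        if call.accepted is not True:
            attrs["rejected"] = "true"
        if call.segmentation:
            attrs["segmentation"] = ",".join(call.segmentation)
        if call.junction_microdels:
            attrs["junction_microdel"] = ",".join(
                "NA" if d is None else str(d) for d in call.junction_microdels
            )
        features.append(
            Gff3Feature(
                cluster.contig_id, "ltdrscan", "transposon_insertion",
                cluster.outer.start, cluster.outer.end, None, cluster.strand, attrs,
            )
        )
        for j, hit in enumerate(cluster.hits):
            features.append(
                Gff3Feature(
                    cluster.contig_id, "ltdrscan",
                    "repeat_region",
                    hit.interval.start, hit.interval.end, hit.identity,
                    hit.interval.strand,
                    {
                        "ID": f"{parent_id}.{j}",
                        "Parent": parent_id,
                        "part": hit.part,
                        "family": hit.family_id,
                    },
                )
            )
    return features
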