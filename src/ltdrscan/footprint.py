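"""Excision footprints: reconstruct empty sites and infer flank deletions.

When a partial insertion (LTDR-INT, INT-LTDR or solo INT) sits inside a
copy of *another* repeat family, the pre-insertion ("empty") state of the
locus can be restored from that host family's consensus.  Comparing the
observed junctions against the reconstructed empty site then reveals the
excision footprint: LTDR excision removes the LTDR plus 0-5 flanking
bases from exactly one side, so one TSD copy (or its neighbourhood) comes
up short.

Ambiguity is first-class here.  Whenever the deleted bases happen to be
identical to their neighbours, several (TSD length, deleted bp)
combinations explain the junctions equally well; all consistent
candidates are reported, ranked so the most parsimonious
(fewest-deleted-bases) reading at the family's dominant TSD length comes
first.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from ltdrscan.classify import LocusCluster
from ltdrscan.core import Scoring, align_pair
from ltdrscan.errors import InputError

_SCORING = Scoring(match=2, mismatch=-3, gap_open=-5, gap_extend=-2)

PARTIAL_LABELS = ("LTDR_INT", "INT_LTDR", "SOLO_INT")


@dataclass(frozen=True)
class FootprintCandidate:
    """One (side, deleted bp, TSD) reading consistent with the junctions."""

    deleted_side: str  # left / right / none
    deleted_bp: int
    tsd_len: int
    tsd: str


@dataclass
class FootprintCall:
    """Inferred excision footprint at one partial-insertion locus."""

    reconstructed_empty: str
    deleted_side: str
    deleted_bp: int
    overlap: int
    candidates: list[FootprintCandidate] = field(default_factory=list)
    complex_footprint: bool = False


def reconstruct_empty_site(
    cluster: LocusCluster,
    host_consensus: str,
    min_identity: float = 0.75,
    min_flank_cover: float = 0.5,
) -> Optional[str]:
    """Restore the pre-insertion sequence of a locus from a host consensus.

    Both flanks of the locus are locally aligned to the host consensus
    (both orientations are tried, since cluster flanks read in element
    orientation); when they map collinearly (left before right, same
    orientation) the host segment spanning both matches is the inferred
    pre-insertion target, returned in element orientation.  Returns None
    when the flanks do not map compatibly (different host families,
    rearranged locus...).
    """
    for host in (host_consensus, None):
        if host is None:
            from ltdrscan.core import reverse_complement

            host = reverse_complement(host_consensus)
        empty = _reconstruct_oriented(cluster, host, min_identity, min_flank_cover)
        if empty is not None:
            return empty
    return None


def _reconstruct_oriented(
    cluster: LocusCluster,
    host_consensus: str,
    min_identity: float,
    min_flank_cover: float,
) -> Optional[str]:
    if len(cluster.left_flank) < 10 or len(cluster.right_flank) < 10:
        return None
    left = align_pair(cluster.left_flank, host_consensus, "local", _SCORING)
    right = align_pair(cluster.right_flank, host_consensus, "local", _SCORING)
    for aln, flank in ((left, cluster.left_flank), (right, cluster.right_flank)):
        cover = (aln.a_span[1] - aln.a_span[0]) / len(flank)
        if aln.identity < min_identity or cover < min_flank_cover:
            return None
    # Host coordinates of the full flanks, extrapolated from the aligned
    # cores (the unaligned flank tips are the interesting junction bases).
    left_end = left.b_span[1] + (len(cluster.left_flank) - left.a_span[1])
    right_start = right.b_span[0] - right.a_span[0]
    left_start = left.b_span[0] - left.a_span[0]
    right_end = right.b_span[1] + (len(cluster.right_flank) - right.a_span[1])
    if not (0 <= left_start < left_end <= len(host_consensus)):
        return None
    if not (left_start < right_end <= len(host_consensus)):
        return None
    if right_start < left_start or right_end <= left_end:
        return None
    return host_consensus[left_start:right_end]


def _common_prefix(a: str, b: str) -> int:
    n = 0
    for x, y in zip(a, b):
        if x != y or x == "N":
            break
        n += 1
    return n


def infer_excision_footprint(
    cluster: LocusCluster,
    reconstructed_empty: str,
    k_min: int = 3,
    k_max: int = 6,
    dominant_tsd_len: Optional[int] = None,
    max_deleted: int = 5,
) -> FootprintCall:
    """Infer which side of an excised LTDR lost how many flanking bases.

    The locus string (left flank + element remnant + right flank, element
    orientation) is matched against the reconstructed empty site from
    both ends.  With breakpoints ``t_L`` (how far the locus matches the
    empty site from the left) and ``t_R`` (mirror from the right), an
    intact insertion shows ``t_L - t_R`` equal to the TSD length; a
    one-sided deletion of d bases reduces that overlap by d.  Which side
    was hit follows from the architecture (LTDR_INT lost its right LTDR,
    INT_LTDR its left; solo INT could be either).  All (side, d, k)
    readings consistent with the junctions are enumerated; deletions
    beyond ``max_deleted`` mark the footprint COMPLEX.
    """
    if cluster is not None and hasattr(cluster, "tokens"):
        from ltdrscan.classify import parse_architecture

        label = parse_architecture(cluster.tokens).label
        if label not in PARTIAL_LABELS:
            raise InputError(f"footprint inference needs a partial architecture, got {label}")
    else:  # pragma: no cover - defensive
        label = "SOLO_INT"
    observed = cluster.left_flank + cluster.seq + cluster.right_flank
    empty = reconstructed_empty
    t_left = _common_prefix(observed, empty)
    t_right = len(empty) - _common_prefix(observed[::-1], empty[::-1])
    overlap = t_left - t_right
    if label == "LTDR_INT":
        sides = ["right"]
    elif label == "INT_LTDR":
        sides = ["left"]
    else:
        sides = ["left", "right"]
    candidates: list[FootprintCandidate] = []
    for k in range(k_min, k_max + 1):
        d_floor = max(0, k - overlap)
        if d_floor == 0:
            # Junctions compatible with an intact TSD of length k.
            t = t_left - k
            if 0 <= t and t + k <= len(empty):
                candidates.append(
                    FootprintCandidate("none", 0, k, empty[t : t + k])
                )
        # One-sided deletion readings; d may exceed the minimum forced by
        # the overlap when deleted bases happened to equal their
        # neighbours (the chance-match ambiguity of Fig.-2B-style cases).
        for side in sides:
            for d in range(max(1, d_floor), max_deleted + 1):
                t = (t_left - k) if side == "right" else t_right
                if t < 0 or t + k > len(empty):
                    continue
                candidates.append(
                    FootprintCandidate(side, d, k, empty[t : t + k])
                )

    def rank(c: FootprintCandidate):
        dominant_miss = 0 if (dominant_tsd_len is None or c.tsd_len == dominant_tsd_len) else 1
        return (dominant_miss, c.deleted_bp, -c.tsd_len, c.deleted_side)

    candidates.sort(key=rank)
    # No reading with <= max_deleted deleted bases explains the junctions:
    # outside the one-sided 0-5-bp excision model.
    complex_fp = not candidates
    if complex_fp:
        best_side, best_d = "none", 0
    else:
        best = candidates[0]
        best_side, best_d = best.deleted_side, best.deleted_bp
    return FootprintCall(
        reconstructed_empty=empty,
        deleted_side=best_side,
        deleted_bp=best_d,
        overlap=overlap,
        candidates=candidates,
        complex_footprint=complex_fp,
    )
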