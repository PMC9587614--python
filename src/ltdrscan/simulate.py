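"""Synthetic genomes with planted LTDR-composite insertions and ground truth.

The generator emulates the structural repertoire reported for KolobokP-like
families: elements whose ~450-bp or ~660-bp LTDRs carry 11-18-bp TIRs and
5'-RR..YY-3' termini, target site duplications of 3-5 bp, solo LTDRs,
monomers, shared-LTDR multimers, tandem-INT arrays with 3-4-bp junction
micro-deletions, directly planted partial forms, per-copy substitution
divergence, and LTDR excisions that delete 0-5 flanking bases on exactly
one side.  Every planted event is described by a machine-readable
TruthRecord so downstream detectors can be scored without any external
genome.

Background sequence is i.i.d. with a configurable GC content - real host
genomes have isochores, genes, and other repeats, none of which is
simulated here.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ltdrscan.core import (
    GenomeSequence,
    Interval,
    find_tir,
    reverse_complement,
    terminal_signature,
)
from ltdrscan.errors import ConfigError, InputError, PlacementError
from ltdrscan.io import write_fasta

ARCHITECTURES = (
    "SOLO_LTDR",
    "MONOMER",
    "MULTIMER_SHARED",
    "TANDEM_INT",
    "LTDR_INT",
    "INT_LTDR",
    "SOLO_INT",
)

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class ElementModel:
    """Generative description of one LTDR-composite family.

    ``ltdr_seq`` satisfies the terminal signature and carries a perfect
    TIR of at least ``tir_len``; ``int_seq`` begins and ends with
    ``int_edge_motif`` (the motif that appears only once at the junction
    of two abutted INTs after a micro-deletion).
    """

    family_id: str
    ltdr_seq: str
    int_seq: str
    tir_len: int
    tsd_len: int
    int_edge_motif: str = "TATA"

    def __post_init__(self) -> None:
        if terminal_signature(self.ltdr_seq) is not True:
            raise ConfigError(f"{self.family_id}: LTDR lacks the RR..YY signature")
        tir = find_tir(self.ltdr_seq, min_len=min(8, self.tir_len), max_mismatch=0)
        if tir.length < self.tir_len:
            raise ConfigError(f"{self.family_id}: LTDR TIR shorter than declared")
        motif = self.int_edge_motif
        if not (self.int_seq.startswith(motif) and self.int_seq.endswith(motif)):
            raise ConfigError(f"{self.family_id}: INT does not carry the edge motif")

    @property
    def monomer_len(self) -> int:
        return 2 * len(self.ltdr_seq) + len(self.int_seq)

    def monomer_seq(self) -> str:
        return self.ltdr_seq + self.int_seq + self.ltdr_seq


@dataclass(frozen=True)
class PlantRequest:
    """One requested insertion event.

    ``junction_microdel`` applies only to TANDEM_INT and removes that many
    bases at each INT-INT junction from the tip named by
    ``junction_tip`` ('left' = tail of the upstream INT, 'right' = head of
    the downstream INT).
    """

    architecture: str
    n: Optional[int] = None
    m: Optional[int] = None
    divergence: float = 0.0
    locus: int | str = "random"
    strand: str = "+"
    junction_microdel: int = 4
    junction_tip: str = "right"

    def __post_init__(self) -> None:
        if self.architecture not in ARCHITECTURES:
            raise ConfigError(f"unknown architecture {self.architecture!r}")
        if self.architecture == "MULTIMER_SHARED" and (self.n is None or self.n < 2):
            raise ConfigError("MULTIMER_SHARED requires n >= 2")
        if self.architecture == "TANDEM_INT" and (self.m is None or self.m < 2):
            raise ConfigError("TANDEM_INT requires m >= 2")
        if not (0.0 <= self.divergence <= 0.2):
            raise ConfigError("divergence must be within [0, 0.2]")
        if self.strand not in ("+", "-"):
            raise ConfigError("strand must be '+' or '-'")
        if self.junction_tip not in ("left", "right"):
            raise ConfigError("junction_tip must be 'left' or 'right'")


@dataclass
class TruthRecord:
    """Ground truth for one planted (and possibly later excised) event.

    ``start``/``end`` span the element itself; the TSD copies sit
    immediately outside on both sides in the emitted genome
    (pre-excision).  ``parts`` are (label, start, end) triples in genomic
    position order; on the minus strand the element reads right to left.
    """

    event_id: str
    family_id: str
    contig_id: str
    architecture: str
    n: Optional[int]
    m: Optional[int]
    start: int
    end: int
    strand: str
    tsd: str
    divergence: float
    parts: list[tuple[str, int, int]]
    junctions: list[tuple[int, str]] = field(default_factory=list)
    excised_which: Optional[str] = None
    excised_flank_bp: Optional[int] = None
    excised_flank_side: Optional[str] = None

    def outer(self) -> Interval:
        return Interval(self.contig_id, self.start, self.end, self.strand)

    def tokens(self) -> str:
        """Part labels in element orientation, as L/I token string."""
        letters = "".join("L" if p[0] == "LTDR" else "I" for p in self.parts)
        return letters[::-1] if self.strand == "-" else letters


def make_background(length: int, gc: float, seed: int) -> GenomeSequence:
    """I.i.d. background contig with P(G) + P(C) = gc."""
    if length < 1:
        raise ConfigError("background length must be >= 1")
    if not (0.0 < gc < 1.0):
        raise ConfigError("gc must be in (0, 1)")
    rng = np.random.default_rng(seed)
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    draws = rng.choice(4, size=length, p=probs)
    seq = _BASES[draws].tobytes().decode("ascii")
    return GenomeSequence(contig_id="bg", seq=seq)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode("ascii")


def make_element(
    family_id: str,
    ltdr_len: int = 473,
    int_len: int = 1691,
    tir_len: int = 14,
    tsd_len: int = 4,
    int_edge_motif: str = "TATA",
    seed: int = 0,
) -> ElementModel:
    """Construct a family model satisfying every structural invariant.

    The defaults give a nonautonomous-scale monomer of 473 + 1691 + 473 =
    2637 bp; autonomous-scale families (monomers of roughly 4.0-4.7 kb)
    are obtained by raising ``int_len``.
    """
    if not (11 <= tir_len <= 30):
        raise ConfigError("tir_len outside the supported 11-30 bp range")
    if ltdr_len < 2 * tir_len + 4:
        raise ConfigError("ltdr_len too short for the requested TIR")
    if int_len < 2 * len(int_edge_motif):
        raise ConfigError("int_len shorter than two edge motifs")
    if not (3 <= tsd_len <= 6):
        raise ConfigError("tsd_len outside the supported 3-6 bp range")
    rng = np.random.default_rng(seed)
    # Left TIR arm starting with two purines; the right arm is its exact
    # reverse complement, which automatically ends the LTDR with two
    # pyrimidines (RR..YY).
    purines = "AG"
    arm = (
        purines[rng.integers(0, 2)]
        + purines[rng.integers(0, 2)]
        + _random_seq(rng, tir_len - 2)
    )
    middle = _random_seq(rng, ltdr_len - 2 * tir_len)
    ltdr = arm + middle + reverse_complement(arm)
    motif = int_edge_motif.upper()
    int_seq = motif + _random_seq(rng, int_len - 2 * len(motif)) + motif
    return ElementModel(
        family_id=family_id,
        ltdr_seq=ltdr,
        int_seq=int_seq,
        tir_len=tir_len,
        tsd_len=tsd_len,
        int_edge_motif=motif,
    )


def diverge(
    seq: str,
    rate: float,
    rng: np.random.Generator,
    indel_rate: float = 0.0,
    max_indel: int = 2,
) -> str:
    """Apply i.i.d. substitutions (and optionally short indels) to a copy.

    Substitutions always change the base.  Indels, when enabled, are
    insertions or deletions of at most ``max_indel`` bp at one-tenth the
    substitution density by default.
    """
    if rate == 0.0 and indel_rate == 0.0:
        return seq
    chars = list(seq)
    if rate > 0.0:
        hits = np.nonzero(rng.random(len(chars)) < rate)[0]
        for i in hits:
            current = chars[i]
            options = [b for b in "ACGT" if b != current]
            chars[i] = options[rng.integers(0, len(options))]
    if indel_rate > 0.0:
        out = []
        for c in chars:
            if rng.random() < indel_rate:
                size = int(rng.integers(1, max_indel + 1))
                if rng.random() < 0.5:
                    out.append(_random_seq(rng, size) + c)
                # deletion: drop this base (size > 1 handled approximately)
            else:
                out.append(c)
        chars = out
    return "".join(chars)


def _build_insert(
    model: ElementModel, request: PlantRequest, rng: np.random.Generator
) -> tuple[str, list[tuple[str, int, int]], list[tuple[int, str]]]:
    """Assemble the insert sequence, per-part offsets, and junction metadata."""

    def copy(part_seq: str) -> str:
        return diverge(part_seq, request.divergence, rng)

    L, I = model.ltdr_seq, model.int_seq
    arch = request.architecture
    pieces: list[tuple[str, str]] = []
    junctions: list[tuple[int, str]] = []
    if arch == "SOLO_LTDR":
        pieces = [("LTDR", copy(L))]
    elif arch == "MONOMER":
        pieces = [("LTDR", copy(L)), ("INT", copy(I)), ("LTDR", copy(L))]
    elif arch == "MULTIMER_SHARED":
        for _ in range(request.n):
            pieces += [("LTDR", copy(L)), ("INT", copy(I))]
        pieces.append(("LTDR", copy(L)))
    elif arch == "TANDEM_INT":
        d = request.junction_microdel
        if not (0 <= d <= len(model.int_edge_motif)):
            raise ConfigError("junction_microdel must be within the edge motif length")
        ints = [copy(I) for _ in range(request.m)]
        for j in range(1, request.m):
            if request.junction_tip == "right":
                ints[j] = ints[j][d:] if d else ints[j]
            else:
                ints[j - 1] = ints[j - 1][: len(ints[j - 1]) - d] if d else ints[j - 1]
            junctions.append((d, request.junction_tip))
        pieces = [("LTDR", copy(L))] + [("INT", s) for s in ints] + [("LTDR", copy(L))]
    elif arch == "LTDR_INT":
        pieces = [("LTDR", copy(L)), ("INT", copy(I))]
    elif arch == "INT_LTDR":
        pieces = [("INT", copy(I)), ("LTDR", copy(L))]
    elif arch == "SOLO_INT":
        pieces = [("INT", copy(I))]
    seq = "".join(s for _, s in pieces)
    parts = []
    offset = 0
    for label, s in pieces:
        parts.append((label, offset, offset + len(s)))
        offset += len(s)
    if request.strand == "-":
        seq = reverse_complement(seq)
        total = len(seq)
        parts = [(lab, total - e, total - s) for lab, s, e in reversed(parts)]
    return seq, parts, junctions


_EVENT_COUNTER = [0]


def plant(
    genome: GenomeSequence,
    model: ElementModel,
    request: PlantRequest,
    seed: int,
    occupied: Optional[Sequence[Interval]] = None,
    event_id: Optional[str] = None,
) -> tuple[GenomeSequence, TruthRecord]:
    """Insert one element copy, duplicating the target site.

    The ``tsd_len`` bases immediately 3' of the cut are duplicated so the
    element ends up flanked by identical copies (standard cut-and-paste
    convention).  ``occupied`` intervals (current-genome coordinates) are
    refused; a fixed colliding locus raises :class:`PlacementError`, a
    random one is re-drawn.
    """
    rng = np.random.default_rng(seed)
    k = model.tsd_len
    glen = len(genome.seq)
    if glen < 2 * k + 2:
        raise InputError("genome too short to accept an insertion")

    def collides(pos: int) -> bool:
        if occupied is None:
            return False
        probe = Interval(genome.contig_id, max(0, pos - 1), pos + k + 1)
        return any(probe.overlaps(iv) for iv in occupied)

    if request.locus == "random":
        pos = None
        for _ in range(1000):
            cand = int(rng.integers(k, glen - k))
            if not collides(cand):
                pos = cand
                break
        if pos is None:
            raise PlacementError("could not place insertion after 1000 draws")
    else:
        pos = int(request.locus)
        if not (k <= pos <= glen - k):
            raise InputError("locus leaves less than tsd_len bases on one side")
        if collides(pos):
            raise PlacementError(f"locus {pos} collides with an existing insertion")

    insert, rel_parts, junctions = _build_insert(model, request, rng)
    tsd = genome.seq[pos : pos + k]
    new_seq = genome.seq[: pos + k] + insert + genome.seq[pos:]
    elem_start = pos + k
    if event_id is None:
        _EVENT_COUNTER[0] += 1
        event_id = f"ev{_EVENT_COUNTER[0]:04d}"
    truth = TruthRecord(
        event_id=event_id,
        family_id=model.family_id,
        contig_id=genome.contig_id,
        architecture=request.architecture,
        n=request.n,
        m=request.m,
        start=elem_start,
        end=elem_start + len(insert),
        strand=request.strand,
        tsd=tsd,
        divergence=request.divergence,
        parts=[(lab, elem_start + s, elem_start + e) for lab, s, e in rel_parts],
        junctions=junctions,
    )
    return GenomeSequence(genome.contig_id, new_seq), truth


def shift_record(truth: TruthRecord, at: int, delta: int) -> TruthRecord:
    """Shift all coordinates at or beyond ``at`` by ``delta``."""
    if truth.start < at:
        return truth
    new = dataclasses.replace(truth)
    new.start += delta
    new.end += delta
    new.parts = [(lab, s + delta, e + delta) for lab, s, e in truth.parts]
    return new


def excise_ltdr(
    genome: GenomeSequence,
    truth: TruthRecord,
    which: str,
    flank_deleted_bp: int = 0,
    side: str = "outer",
    others: Sequence[TruthRecord] = (),
) -> tuple[GenomeSequence, TruthRecord, list[TruthRecord]]:
    """Remove one terminal LTDR plus 0-5 bases from exactly one adjacent side.

    ``which`` names the LTDR in element orientation ('left' = the 5' LTDR
    of the element).  ``side`` says where the extra bases come from:
    'outer' eats into the flank/TSD, 'inner' into the element interior.
    Unrelated records on the same contig are returned coordinate-shifted.
    """
    if which not in ("left", "right"):
        raise ConfigError("which must be 'left' or 'right'")
    if side not in ("inner", "outer"):
        raise ConfigError("side must be 'inner' or 'outer'")
    if not (0 <= flank_deleted_bp <= 5):
        raise ConfigError("flank_deleted_bp must be within 0-5")
    # Map element orientation onto genomic order.
    genomic_which = which if truth.strand == "+" else ("right" if which == "left" else "left")
    idx = 0 if genomic_which == "left" else len(truth.parts) - 1
    label, ps, pe = truth.parts[idx]
    if label != "LTDR":
        raise InputError(f"part at the {which} end is {label}, not LTDR")
    rs, re_ = ps, pe
    # 'outer'/'inner' are element-oriented; convert to genomic direction.
    eats_left = (genomic_which == "left") == (side == "outer")
    if flank_deleted_bp:
        if eats_left:
            rs -= flank_deleted_bp
        else:
            re_ += flank_deleted_bp
    if rs < 0 or re_ > len(genome.seq):
        raise ConfigError("flank deletion runs off the contig")
    delta = -(re_ - rs)
    new_seq = genome.seq[:rs] + genome.seq[re_:]

    def adjust(x: int) -> int:
        if x >= re_:
            return x + delta
        if x > rs:
            return rs
        return x

    new_parts = []
    for lab, s, e in truth.parts:
        if (lab, s, e) == (label, ps, pe):
            continue
        s2, e2 = adjust(s), adjust(e)
        if e2 > s2:
            new_parts.append((lab, s2, e2))
    new = dataclasses.replace(truth)
    new.parts = new_parts
    if new_parts:
        new.start = min(s for _, s, _ in new_parts)
        new.end = max(e for _, _, e in new_parts)
    else:
        new.start, new.end = rs, rs + 1
        new.architecture = "NONE"
    new.excised_which = which
    new.excised_flank_bp = flank_deleted_bp
    new.excised_flank_side = side if flank_deleted_bp else None
    if new_parts:
        from ltdrscan.classify import parse_architecture

        call = parse_architecture(new.tokens())
        new.architecture, new.n, new.m = call.label, call.n, call.m
    shifted = [shift_record(t, re_, delta) if t.start >= re_ else t for t in others]
    return GenomeSequence(genome.contig_id, new_seq), new, shifted


_TRUTH_COLUMNS = [
    "event_id",
    "family_id",
    "contig_id",
    "architecture",
    "n",
    "m",
    "start",
    "end",
    "strand",
    "tsd",
    "divergence",
    "parts",
    "junctions",
    "excised_which",
    "excised_flank_bp",
    "excised_flank_side",
]


def _parts_to_str(parts: list[tuple[str, int, int]]) -> str:
    return ";".join(f"{lab}:{s}-{e}" for lab, s, e in parts)


def _parts_from_str(text: str) -> list[tuple[str, int, int]]:
    out = []
    for item in str(text).split(";"):
        if not item:
            continue
        lab, _, span = item.partition(":")
        s, _, e = span.partition("-")
        out.append((lab, int(s), int(e)))
    return out


def write_dataset(
    genomes: Sequence[GenomeSequence],
    truths: Sequence[TruthRecord],
    models: Sequence[ElementModel],
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write genome FASTA, truth TSV, and the part-library FASTA.

    The part library holds the undiverged model sequences, one record per
    part, headed ``<family>:LTDR`` / ``<family>:INT``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": out / "genome.fasta",
        "truth": out / "truth.tsv",
        "parts": out / "parts.fasta",
    }
    write_fasta(genomes, paths["genome"])
    rows = []
    for t in truths:
        rows.append(
            {
                "event_id": t.event_id,
                "family_id": t.family_id,
                "contig_id": t.contig_id,
                "architecture": t.architecture,
                "n": "" if t.n is None else t.n,
                "m": "" if t.m is None else t.m,
                "start": t.start,
                "end": t.end,
                "strand": t.strand,
                "tsd": t.tsd,
                "divergence": t.divergence,
                "parts": _parts_to_str(t.parts),
                "junctions": ";".join(f"{d}:{tip}" for d, tip in t.junctions),
                "excised_which": t.excised_which or "",
                "excised_flank_bp": "" if t.excised_flank_bp is None else t.excised_flank_bp,
                "excised_flank_side": t.excised_flank_side or "",
            }
        )
    pd.DataFrame(rows, columns=_TRUTH_COLUMNS).to_csv(paths["truth"], sep="\t", index=False)
    part_records = []
    for model in models:
        part_records.append(GenomeSequence(f"{model.family_id}:LTDR", model.ltdr_seq))
        part_records.append(GenomeSequence(f"{model.family_id}:INT", model.int_seq))
    write_fasta(part_records, paths["parts"])
    return paths


def read_truth(path: str | Path) -> list[TruthRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    records = []
    for _, row in df.iterrows():
        records.append(
            TruthRecord(
                event_id=row["event_id"],
                family_id=row["family_id"],
                contig_id=row["contig_id"],
                architecture=row["architecture"],
                n=int(row["n"]) if row["n"] else None,
                m=int(row["m"]) if row["m"] else None,
                start=int(row["start"]),
                end=int(row["end"]),
                strand=row["strand"],
                tsd=row["tsd"],
                divergence=float(row["divergence"]),
                parts=_parts_from_str(row["parts"]),
                junctions=[
                    (int(item.split(":")[0]), item.split(":")[1])
                    for item in row["junctions"].split(";")
                    if item
                ],
                excised_which=row["excised_which"] or None,
                excised_flank_bp=int(row["excised_flank_bp"]) if row["excised_flank_bp"] else None,
                excised_flank_side=row["excised_flank_side"] or None,
            )
        )
    return records


def simulate_excision_study(
    n_events: int = 100,
    seed: int = 0,
    divergence: float = 0.0,
    host_len: int = 600,
    contig_len: int = 3_000,
    model: Optional[ElementModel] = None,
) -> tuple[list[GenomeSequence], list[TruthRecord], str, ElementModel]:
    """One-sided LTDR excisions inside a host repeat, one contig per event.

    Each contig carries one copy of a host repeat consensus with a monomer
    planted inside it, after which one LTDR is excised together with 1-5
    bases from its outer flank - the configuration that lets the
    pre-insertion state be reconstructed from the host consensus and the
    footprint be read off the junctions.  Returns (contigs, truths,
    host_consensus, element_model).
    """
    rng = np.random.default_rng(seed)
    if model is None:
        model = make_element("FAM450", seed=int(rng.integers(2**31)))
    host = make_background(host_len, 0.36, seed=int(rng.integers(2**31))).seq
    contigs: list[GenomeSequence] = []
    truths: list[TruthRecord] = []
    host_at = contig_len // 3
    for i in range(n_events):
        bg = make_background(contig_len, 0.36, seed=int(rng.integers(2**31)))
        carrier = GenomeSequence(
            f"fp{i:03d}", bg.seq[:host_at] + host + bg.seq[host_at:]
        )
        locus = host_at + int(rng.integers(100, host_len - 100))
        request = PlantRequest(
            architecture="MONOMER",
            divergence=divergence,
            locus=locus,
            strand="+-"[int(rng.integers(0, 2))],
        )
        planted, truth = plant(
            carrier, model, request, seed=int(rng.integers(2**31)), event_id=f"fp{i:03d}"
        )
        which = "left" if rng.integers(0, 2) else "right"
        deleted = int(rng.integers(1, 6))
        excised, truth, _ = excise_ltdr(
            planted, truth, which=which, flank_deleted_bp=deleted, side="outer"
        )
        contigs.append(excised)
        truths.append(truth)
    return contigs, truths, host, model


@dataclass
class SimulationConfig:
    """Study conditions for one simulated dataset.

    The default architecture mix plants 100 insertions spanning all seven
    structural labels on a 2-Mb background, split across two families that
    mirror the two reported LTDR length classes (473-bp LTDR / 2637-bp
    monomer and 664-bp LTDR / 2453-bp monomer).
    """

    genome_length: int = 2_000_000
    gc: float = 0.36
    divergence: float = 0.02
    min_spacing: int = 2_000
    counts: dict = field(
        default_factory=lambda: {
            "MONOMER": 25,
            "SOLO_LTDR": 30,
            "MULTIMER_SHARED": 15,
            "TANDEM_INT": 6,
            "LTDR_INT": 10,
            "INT_LTDR": 10,
            "SOLO_INT": 4,
        }
    )
    multimer_n_max: int = 4
    random_strand: bool = True


def default_families(seed: int) -> list[ElementModel]:
    """The two family models used throughout the simulated studies."""
    return [
        make_element("FAM450", ltdr_len=473, int_len=1691, tir_len=14, tsd_len=4, seed=seed * 2 + 11),
        make_element("FAM660", ltdr_len=664, int_len=1125, tir_len=12, tsd_len=5, seed=seed * 2 + 12),
    ]


def simulate_dataset(
    config: SimulationConfig,
    seed: int,
    models: Optional[Sequence[ElementModel]] = None,
) -> tuple[list[GenomeSequence], list[TruthRecord], list[ElementModel]]:
    """Plant the configured architecture mix on a fresh background.

    All randomness flows from ``seed``; identical config + seed give
    byte-identical genomes.
    """
    rng = np.random.default_rng(seed)
    if models is None:
        models = default_families(seed)
    genome = make_background(config.genome_length, config.gc, seed=int(rng.integers(2**31)))
    requests = []
    for arch, count in config.counts.items():
        for _ in range(count):
            n = int(rng.integers(2, config.multimer_n_max + 1)) if arch == "MULTIMER_SHARED" else None
            m = int(rng.integers(2, 4)) if arch == "TANDEM_INT" else None
            strand = "+-"[int(rng.integers(0, 2))] if config.random_strand else "+"
            requests.append(
                PlantRequest(
                    architecture=arch,
                    n=n,
                    m=m,
                    divergence=config.divergence,
                    strand=strand,
                    junction_microdel=int(rng.integers(3, 5)),
                    junction_tip="left" if rng.integers(0, 2) else "right",
                )
            )
    order = rng.permutation(len(requests))
    truths: list[TruthRecord] = []
    occupied: list[Interval] = []
    margin = config.min_spacing
    # Largest insert the requested mix can produce, used to pad occupied
    # intervals so the next insertion point cannot land within ``margin``.
    lmax = max(len(m.ltdr_seq) for m in models)
    imax = max(len(m.int_seq) for m in models)
    max_insert = lmax
    for req in requests:
        if req.architecture == "MULTIMER_SHARED":
            size = req.n * (lmax + imax) + lmax
        elif req.architecture == "TANDEM_INT":
            size = 2 * lmax + req.m * imax
        else:
            size = 2 * lmax + imax
        max_insert = max(max_insert, size)
    for i, idx in enumerate(order):
        request = requests[idx]
        model = models[int(rng.integers(0, len(models)))]
        for attempt in range(200):
            try:
                genome2, truth = plant(
                    genome,
                    model,
                    request,
                    seed=int(rng.integers(2**31)),
                    occupied=occupied,
                    event_id=f"ev{i:04d}",
                )
            except PlacementError:
                continue
            break
        else:
            raise PlacementError("genome too crowded for the requested event count")
        delta = (truth.end - truth.start) + len(truth.tsd)
        truths = [shift_record(t, truth.start - len(truth.tsd), delta) for t in truths]
        occupied = [
            Interval(iv.contig_id, iv.start + delta, iv.end + delta, iv.strand)
            if iv.start >= truth.start - len(truth.tsd)
            else iv
            for iv in occupied
        ]
        # Pad the left side by the largest possible insert so the next
        # insertion point cannot start within ``margin`` of this locus.
        occupied.append(
            Interval(
                genome2.contig_id,
                max(0, truth.start - margin - max_insert),
                min(len(genome2.seq), truth.end + margin),
            )
        )
        genome = genome2
        truths.append(truth)
    truths.sort(key=lambda t: t.start)
    return [genome], truths, list(models)
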