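"""End-to-end stage drivers shared by the CLI and by validation scripts.

Each function takes in-memory objects plus a :class:`RunConfig` and wires
the per-module operations into one stage of the annotation workflow:
scan -> group -> parse -> gate -> tabulate (annotate), scan -> cluster ->
extend -> call termini (consensus), and empty-site reconstruction +
footprint inference (footprint).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from ltdrscan.classify import (
    ArchitectureCall,
    FamilyCensus,
    LocusCluster,
    call_junction_microdeletion,
    family_diversity,
    gate_by_tsd,
    group_hits,
    parse_architecture,
    tabulate,
)
from ltdrscan.config import RunConfig
from ltdrscan.consensus import (
    ConsensusModel,
    ExtendedConsensus,
    call_termini,
    extend_to_termini,
    greedy_cluster,
    split_ltdr_int,
)
from ltdrscan.core import GenomeSequence
from ltdrscan.footprint import (
    PARTIAL_LABELS,
    FootprintCall,
    infer_excision_footprint,
    reconstruct_empty_site,
)
from ltdrscan.scanner import Hit, merge_hits, scan


@dataclass
class AnnotateResult:
    hits: list[Hit]
    clusters: list[LocusCluster]
    calls: list[ArchitectureCall]
    censuses: list[FamilyCensus]


def annotate(
    genomes: Sequence[GenomeSequence],
    part_library: Sequence[GenomeSequence],
    cfg: RunConfig = RunConfig(),
) -> AnnotateResult:
    """Full structural annotation of a genome against a part library."""
    hits = scan(
        genomes,
        part_library,
        min_identity=cfg.scan_min_identity,
        min_coverage=cfg.scan_min_coverage,
        word_size=cfg.scan_word_size,
    )
    hits = merge_hits(hits, max_gap=cfg.merge_max_gap)
    clusters = group_hits(hits, genomes, locus_gap=cfg.locus_gap, flank_len=cfg.flank_len)
    parts = {rec.contig_id: rec.seq for rec in part_library}
    calls = []
    for cluster in clusters:
        call = parse_architecture(cluster.tokens)
        call = gate_by_tsd(
            cluster, call, k_min=cfg.tsd_k_min, k_max=cfg.tsd_k_max,
            max_mismatch=cfg.tsd_max_mismatch,
        )
        if "II" in cluster.tokens:
            int_cons = parts.get(f"{cluster.family_id}:INT")
            if int_cons:
                call.junction_microdels = call_junction_microdeletion(cluster, int_cons)
        calls.append(call)
    censuses = []
    for family_id in sorted({c.family_id for c in clusters}):
        fam_calls = [call for cluster, call in zip(clusters, calls) if cluster.family_id == family_id]
        copies = []
        for cluster in clusters:
            if cluster.family_id != family_id:
                continue
            for hit, seq in zip(cluster.hits, cluster.part_seqs):
                copies.append((hit.part, seq))
        diversities = []
        for part in ("LTDR", "INT"):
            cons = parts.get(f"{family_id}:{part}")
            part_copies = [s for p, s in copies if p == part]
            if cons and part_copies:
                d = family_diversity(part_copies, cons)
                if d is not None:
                    diversities.append((d, len(part_copies)))
        diversity = None
        if diversities:
            total = sum(n for _, n in diversities)
            diversity = round(sum(d * n for d, n in diversities) / total, 1)
        censuses.append(tabulate(fam_calls, family_id, diversity=diversity))
    return AnnotateResult(hits=hits, clusters=clusters, calls=calls, censuses=censuses)


@dataclass
class FamilyConsensus:
    family_id: str
    model: ConsensusModel
    extended: ExtendedConsensus
    ltdr_seq: Optional[str] = None
    int_seq: Optional[str] = None


def build_consensus(
    genomes: Sequence[GenomeSequence],
    part_library: Sequence[GenomeSequence],
    cfg: RunConfig = RunConfig(),
) -> list[FamilyConsensus]:
    """Rebuild each family's element consensus from its genomic copies.

    Copies are whole insertion loci (scanner hits grouped as in
    ``annotate``); they enter extension in decreasing mean-identity order
    and only the first ``consensus_max_copies`` are used.
    """
    result = annotate(genomes, part_library, cfg)
    out = []
    for family_id in sorted({c.family_id for c in result.clusters}):
        fam = [
            (cluster, call)
            for cluster, call in zip(result.clusters, result.calls)
            if cluster.family_id == family_id
        ]
        # Monomer loci span the whole element and are the natural copy set
        # for consensus building; fall back to all loci only when fewer
        # than two monomers exist.  Within the pool, rank by scanner
        # identity (descending) - extension uses the first max_copies.
        def mean_identity(cluster: LocusCluster) -> float:
            return sum(h.identity for h in cluster.hits) / len(cluster.hits)

        monomers = [pair for pair in fam if pair[1].label == "MONOMER"]
        pool = monomers if monomers else fam
        ranked = sorted(pool, key=lambda pair: -mean_identity(pair[0]))
        # Guard the copy set with the 75 %/75 % clustering step: keep the
        # cluster containing the best-ranked locus.
        pool_cap = ranked[: 3 * cfg.consensus_max_copies]
        seqs = [
            GenomeSequence(f"copy{i:03d}", cluster.seq)
            for i, (cluster, _) in enumerate(pool_cap)
        ]
        clusters75 = greedy_cluster(
            seqs,
            min_identity=cfg.cluster_min_identity,
            min_coverage=cfg.cluster_min_coverage,
        )
        best_id = "copy000"
        chosen = next(
            (cl for cl in clusters75 if any(s.contig_id == best_id for s in cl)),
            clusters75[0],
        )
        chosen_ids = {s.contig_id for s in chosen}
        intervals = [
            cluster.outer
            for i, (cluster, _) in enumerate(pool_cap)
            if f"copy{i:03d}" in chosen_ids
        ]
        extended = extend_to_termini(
            genomes,
            intervals,
            flank=cfg.consensus_flank,
            max_rounds=cfg.consensus_max_rounds,
            max_copies=cfg.consensus_max_copies,
            support_threshold=cfg.consensus_support_threshold,
            drop_run=cfg.consensus_drop_run,
        )
        model = call_termini(
            genomes, extended,
            search=cfg.termini_search,
            tsd_k_min=cfg.tsd_k_min,
            tsd_k_max=cfg.tsd_k_max,
        )
        split = split_ltdr_int(model.called_seq())
        out.append(
            FamilyConsensus(
                family_id=family_id,
                model=model,
                extended=extended,
                ltdr_seq=split[0] if split else None,
                int_seq=split[1] if split else None,
            )
        )
    return out


@dataclass
class FootprintRow:
    cluster: LocusCluster
    label: str
    call: Optional[FootprintCall]


def footprints(
    clusters: Sequence[LocusCluster],
    calls: Sequence[ArchitectureCall],
    host_consensus: str,
    cfg: RunConfig = RunConfig(),
    dominant_tsd_len: Optional[int] = None,
) -> list[FootprintRow]:
    """Excision-footprint inference for every partial-architecture locus.

    ``dominant_tsd_len`` is normally the modal TSD length of the family's
    accepted full insertions; when None, candidates are ranked purely by
    parsimony.
    """
    rows = []
    for cluster, call in zip(clusters, calls):
        if call.label not in PARTIAL_LABELS:
            continue
        empty = reconstruct_empty_site(cluster, host_consensus)
        fp = None
        if empty is not None:
            fp = infer_excision_footprint(
                cluster, empty,
                k_min=cfg.tsd_k_min, k_max=cfg.tsd_k_max,
                dominant_tsd_len=dominant_tsd_len,
                max_deleted=cfg.footprint_max_deleted,
            )
        rows.append(FootprintRow(cluster=cluster, label=call.label, call=fp))
    return rows


def dominant_tsd_length(calls: Sequence[ArchitectureCall]) -> Optional[int]:
    """Modal TSD length among accepted calls (ties -> longer)."""
    lengths: dict[int, int] = {}
    for call in calls:
        if call.accepted and call.tsd is not None:
            lengths[call.tsd.length] = lengths.get(call.tsd.length, 0) + 1
    if not lengths:
        return None
    return max(lengths, key=lambda k: (lengths[k], k))
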