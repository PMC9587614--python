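"""Clustering, star alignment, majority consensus, extension, termini."""

import itertools
import random

import pytest

from ltdrscan.core import GenomeSequence, Interval, reverse_complement
from ltdrscan.consensus import (
    call_termini,
    extend_to_termini,
    greedy_cluster,
    majority_consensus,
    split_ltdr_int,
    star_msa,
)
from ltdrscan.simulate import SimulationConfig, make_background, make_element, simulate_dataset


def _random_seq(rng, n):
    return "".join(rng.choice("ACGT") for _ in range(n))


class TestGreedyCluster:
    def test_identical_copies_one_cluster(self):
        seqs = [GenomeSequence(f"s{i}", "ACGTACGTAC" * 30) for i in range(5)]
        clusters = greedy_cluster(seqs)
        assert len(clusters) == 1 and len(clusters[0]) == 5

    def test_unrelated_families_split(self):
        rng = random.Random(1)
        a = _random_seq(rng, 300)
        b = _random_seq(rng, 300)
        seqs = [GenomeSequence("a1", a), GenomeSequence("a2", a), GenomeSequence("b1", b)]
        clusters = greedy_cluster(seqs)
        assert sorted(len(c) for c in clusters) == [1, 2]

    def test_matches_bruteforce_single_linkage_to_seed(self):
        """Greedy seed-joining equals explicit pairwise threshold checks."""
        rng = random.Random(7)
        base_a, base_b = _random_seq(rng, 200), _random_seq(rng, 200)

        def mutate(s, k):
            chars = list(s)
            for pos in rng.sample(range(len(s)), k):
                chars[pos] = rng.choice([c for c in "ACGT" if c != chars[pos]])
            return "".join(chars)

        seqs = [GenomeSequence(f"a{i}", mutate(base_a, 10)) for i in range(6)]
        seqs += [GenomeSequence(f"b{i}", mutate(base_b, 10)) for i in range(4)]
        clusters = greedy_cluster(seqs)
        families = [sorted(s.contig_id[0] for s in c) for c in clusters]
        assert sorted(len(c) for c in clusters) == [4, 6]
        for fam in families:
            assert len(set(fam)) == 1  # no mixed cluster


class TestStarMsa:
    def test_identical_copies_gapless(self):
        seed = "ACGTACGTACGTACGTACGT" * 3
        rows, kept = star_msa([seed, seed, seed], seed)
        assert kept == [0, 1, 2]
        assert all(row == seed for row in rows)

    def test_two_bp_deletion_gives_gap_in_that_row_only(self):
        seed = "ACGTAACCGGTTACGTAACCGGTTACGT"
        member = seed[:10] + seed[12:]
        rows, _ = star_msa([seed, member], seed)
        assert rows[0].count("-") == 0
        assert rows[1].count("-") == 2

    def test_column_count_is_seed_plus_insertions(self):
        seed = "ACGTAACCGGTTACGTAACCGGTTACGT"
        member = seed[:10] + "TTT" + seed[10:]
        rows, _ = star_msa([seed, member], seed)
        assert len(rows[0]) == len(seed) + 3


class TestMajorityConsensus:
    def test_plurality_column(self):
        rows = ["A", "A", "A", "G"]
        model = majority_consensus(rows)
        assert model.seq == "A" and model.support == [0.75]

    def test_tie_breaks_deterministically_and_flags(self):
        rows = ["AA", "AA", "GC", "GC"]
        model = majority_consensus(rows)
        # column 0 ties A/G; overall counts equal -> alphabetical winner
        assert model.seq[0] == "A"
        assert 0 in model.tie_columns
        # invariant under row permutation
        for perm in itertools.permutations(rows):
            assert majority_consensus(list(perm)).seq == model.seq

    def test_single_row_identity(self):
        assert majority_consensus(["ACGTACGT"]).seq == "ACGTACGT"

    def test_gap_majority_columns_deleted(self):
        rows = ["A-C", "A-C", "AGC"]
        assert majority_consensus(rows).seq == "AC"

    def test_missing_entries_ignored(self):
        rows = ["..A", "CCA", "CCA"]
        model = majority_consensus(rows)
        assert model.seq == "CCA"
        assert model.support[-1] == 1.0


def _plant_copies(model, n, seed, divergence=0.0, glen=200_000):
    cfg = SimulationConfig(
        genome_length=glen, divergence=divergence, min_spacing=1500,
        counts={"MONOMER": n},
    )
    genomes, truths, _ = simulate_dataset(cfg, seed=seed, models=[model])
    ivs = [Interval(t.contig_id, t.start, t.end, t.strand) for t in truths]
    return genomes, ivs


class TestExtensionAndTermini:
    def test_divergence_zero_roundtrip_exact(self, small_model):
        genomes, ivs = _plant_copies(small_model, 8, seed=13)
        ext = extend_to_termini(genomes, ivs, flank=400)
        called = call_termini(genomes, ext)
        assert called.seq == small_model.monomer_seq()
        assert called.evidence == {"signature": True, "tir": True, "tsd": True}
        assert not called.low_confidence

    def test_truncated_cores_are_extended_to_true_termini(self, small_model):
        genomes, ivs = _plant_copies(small_model, 8, seed=14)
        shrunk = [Interval(iv.contig_id, iv.start + 60, iv.end - 60, iv.strand) for iv in ivs]
        ext = extend_to_termini(genomes, shrunk, flank=400)
        called = call_termini(genomes, ext)
        assert called.seq == small_model.monomer_seq()

    def test_signature_ablated_model_recovered_via_tir_and_tsd(self):
        """Element starting YY..: signature fails, TIR + TSD still place termini."""
        rng = random.Random(5)
        arm = "TT" + _random_seq(rng, 12)
        ltdr = arm + _random_seq(rng, 400) + reverse_complement(arm)
        elem = ltdr + "TATA" + _random_seq(rng, 800) + "TATA" + ltdr
        genomes, ivs = [], []
        for i in range(6):
            bg = make_background(4000, 0.4, 500 + i).seq
            pos = 1500
            tsd = bg[pos : pos + 4]
            seq = bg[: pos + 4] + elem + bg[pos:]
            genomes.append(GenomeSequence(f"c{i}", seq))
            ivs.append(Interval(f"c{i}", pos + 4, pos + 4 + len(elem)))
        ext = extend_to_termini(genomes, ivs, flank=300)
        called = call_termini(genomes, ext)
        assert called.seq == elem
        assert called.evidence["signature"] is False
        assert called.evidence["tir"] is True
        assert called.evidence["tsd"] is True

    def test_single_copy_flagged_low_confidence(self, small_model):
        genomes, ivs = _plant_copies(small_model, 1, seed=15, glen=40_000)
        ext = extend_to_termini(genomes, ivs, flank=400)
        assert ext.model.low_confidence is True

    def test_near_identical_host_repeats_flag_over_extension(self, small_model):
        """Two copies in the same host context: flank support never drops."""
        rng = random.Random(9)
        host = _random_seq(rng, 1200)
        elem = small_model.monomer_seq()
        genomes, ivs = [], []
        for i in range(2):
            bg = make_background(4000, 0.4, 700 + i).seq
            pos = 600  # inside the shared host copy
            carrier = host[:pos] + "TTAA" + elem + host[pos : pos + 4] + host[pos + 4 :]
            seq = bg[:1000] + carrier + bg[1000:]
            genomes.append(GenomeSequence(f"h{i}", seq))
            start = 1000 + pos + 4
            ivs.append(Interval(f"h{i}", start, start + len(elem)))
        ext = extend_to_termini(genomes, ivs, flank=250)
        assert ext.over_extended is True

    def test_boundary_support_profile(self, small_model):
        """Support ~1 inside the element, background-level outside, 2 % divergence."""
        genomes, ivs = _plant_copies(small_model, 10, seed=16, divergence=0.02)
        ext = extend_to_termini(genomes, ivs, flank=300)
        bl, br = ext.boundaries
        inside = ext.full_support[bl + 10 : br - 10]
        outside = ext.full_support[: max(1, bl - 20)] + ext.full_support[br + 20 :]
        assert sum(inside) / len(inside) >= 0.9
        assert sum(outside) / len(outside) <= 0.6


def test_split_ltdr_int(small_model):
    split = split_ltdr_int(small_model.monomer_seq())
    assert split is not None
    ltdr, internal = split
    assert ltdr == small_model.ltdr_seq
    assert internal == small_model.int_seq


def test_split_ltdr_int_absent_for_random_sequence():
    rng = random.Random(3)
    assert split_ltdr_int(_random_seq(rng, 1000)) is None
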