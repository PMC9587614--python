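"""Architecture grammar, TSD gating, censuses and summary statistics."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ltdrscan.classify import (
    dimer_fraction,
    family_diversity,
    gate_by_tsd,
    ltdr_length_class,
    parse_architecture,
    tabulate,
)
from ltdrscan.errors import InputError
from ltdrscan.oracles import architecture_by_regex
from ltdrscan.pipeline import annotate
from ltdrscan.config import RunConfig


def test_grammar_agrees_with_regex_oracle_up_to_length_seven():
    """Exhaustive check of every L/I token string of length <= 7."""
    count = 0
    for length in range(1, 8):
        for tokens in itertools.product("LI", repeat=length):
            s = "".join(tokens)
            call = parse_architecture(s)
            assert (call.label, call.n, call.m) == architecture_by_regex(s), s
            count += 1
    assert count == 254


@pytest.mark.parametrize(
    "tokens,label,n,m",
    [
        ("LILIL", "MULTIMER_SHARED", 2, None),
        ("LIIL", "TANDEM_INT", None, 2),
        ("LIILIL", "COMPLEX", None, None),
        ("L", "SOLO_LTDR", None, None),
        ("LIL", "MONOMER", None, None),
    ],
)
def test_grammar_examples(tokens, label, n, m):
    call = parse_architecture(tokens)
    assert (call.label, call.n, call.m) == (label, n, m)


def test_complex_records_segmentation():
    call = parse_architecture("LIILIL")
    assert call.label == "COMPLEX"
    assert "".join(call.segmentation) == "LIILIL"
    assert len(call.segmentation) >= 2


def test_unknown_token_rejected():
    with pytest.raises(InputError):
        parse_architecture("LIX")
    with pytest.raises(InputError):
        parse_architecture("")


@pytest.fixture(scope="module")
def annotated(mixed_dataset):
    genomes, truths, models, parts = mixed_dataset
    return annotate(genomes, parts, RunConfig()), truths


class TestEndToEndGrouping:
    """Round trips from the mixed divergence-0 dataset."""

    def test_one_cluster_per_truth_locus(self, annotated):
        result, truths = annotated
        assert len(result.clusters) == len(truths)

    def test_labels_and_tsds_match_truth(self, annotated):
        result, truths = annotated
        for cluster, call, truth in zip(result.clusters, result.calls, truths):
            assert call.label == truth.architecture
            assert (call.n, call.m) == (truth.n, truth.m)
            assert call.accepted is True
            assert call.tsd.tsd == truth.tsd

    def test_minus_strand_normalization(self, annotated):
        result, truths = annotated
        minus = [
            (cluster, truth)
            for cluster, truth in zip(result.clusters, truths)
            if truth.strand == "-"
        ]
        assert minus, "dataset should contain minus-strand events"
        for cluster, truth in minus:
            assert cluster.tokens == truth.tokens()

    def test_junction_microdeletions_recovered(self, annotated, mixed_dataset):
        result, truths = annotated
        _, _, models, _ = mixed_dataset
        consensi = {m.family_id: m.int_seq for m in models}
        from ltdrscan.classify import call_junction_microdeletion

        checked = 0
        for cluster, truth in zip(result.clusters, truths):
            if truth.architecture != "TANDEM_INT":
                continue
            dels = call_junction_microdeletion(cluster, consensi[truth.family_id])
            assert dels == [d for d, _ in truth.junctions]
            checked += 1
        assert checked >= 1

    def test_randomized_flanks_rejected(self, annotated):
        result, _ = annotated
        cluster = result.clusters[0]
        # overwrite flanks with unrelated sequence: the gate must refuse
        cluster2 = type(cluster)(
            contig_id=cluster.contig_id,
            family_id=cluster.family_id,
            hits=cluster.hits,
            outer=cluster.outer,
            strand=cluster.strand,
            tokens=cluster.tokens,
            part_seqs=cluster.part_seqs,
            seq=cluster.seq,
            left_flank="A" * 50,
            right_flank="C" * 50,
        )
        call = parse_architecture(cluster2.tokens)
        gated = gate_by_tsd(cluster2, call)
        assert gated.accepted is False


class TestCensus:
    def test_tabulate_counts_and_conservation(self):
        calls = [parse_architecture(t) for t in ["LIL", "LIL", "LIL", "L"] + ["L"] * 19]
        for c in calls:
            c.accepted = True
        census = tabulate(calls, "fam")
        assert census.counts["MONOMER"] == 3
        assert census.counts["SOLO_LTDR"] == 20
        assert census.total == len(calls)

    def test_empty_census(self):
        census = tabulate([], "fam")
        assert census.total == 0 and census.dimer_count == 0

    def test_rejected_calls_excluded(self):
        a = parse_architecture("LIL")
        a.accepted = True
        b = parse_architecture("LIL")
        b.accepted = False
        assert tabulate([a, b], "fam").total == 1

    def test_dimer_count(self):
        calls = [parse_architecture("LILIL"), parse_architecture("LILILIL")]
        for c in calls:
            c.accepted = True
        census = tabulate(calls, "fam")
        assert census.multimer_count == 2 and census.dimer_count == 1


class TestDimerFraction:
    @pytest.mark.parametrize("d,m,expected", [(5, 24, 21), (7, 30, 23), (0, 10, 0), (1, 2, 50)])
    def test_examples(self, d, m, expected):
        assert dimer_fraction(d, m) == expected

    def test_undefined_for_zero_multimers(self):
        assert dimer_fraction(0, 0) is None

    def test_error_when_dimers_exceed_multimers(self):
        with pytest.raises(InputError):
            dimer_fraction(3, 2)

    @given(st.integers(0, 50), st.integers(1, 50), st.integers(2, 5))
    @settings(max_examples=60, derandomize=True)
    def test_scale_free(self, d, extra, k):
        m = d + extra
        assert dimer_fraction(d, m) == dimer_fraction(k * d, k * m)

    def test_rounding_is_half_up(self):
        assert dimer_fraction(1, 8) == 13  # 12.5 rounds up
        assert dimer_fraction(1, 40) == 3  # 2.5 rounds up


class TestFamilyDiversity:
    def test_identical_copies(self):
        cons = "ACGT" * 50
        assert family_diversity([cons, cons, cons], cons) == 0.0

    def test_two_substitutions_per_hundred(self):
        cons = "A" * 48 + "CC" + "A" * 50
        copy = "A" * 48 + "GG" + "A" * 50
        assert family_diversity([copy] * 10, cons) == 2.0

    def test_adding_identical_copy_never_increases(self):
        cons = "ACGTACGTAC" * 20
        copy = "ACGTACGTAC" * 19 + "ACGTACGTAG"
        before = family_diversity([copy], cons)
        after = family_diversity([copy, cons], cons)
        assert after <= before

    def test_no_qualifying_copies_flagged(self):
        assert family_diversity(["TTTT" * 30], "ACGG" * 30) is None


@pytest.mark.parametrize(
    "length,expected",
    [(473, "class_450"), (664, "class_660"), (575, "other"), (400, "class_450"), (720, "class_660")],
)
def test_ltdr_length_class(length, expected):
    assert ltdr_length_class(length) == expected
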