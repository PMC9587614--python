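"""The synthetic-genome generator and its ground truth."""

import math

import pytest

from ltdrscan.core import find_tir, reverse_complement, terminal_signature
from ltdrscan.errors import ConfigError, PlacementError
from ltdrscan.simulate import (
    PlantRequest,
    excise_ltdr,
    make_background,
    make_element,
    plant,
    read_truth,
    simulate_dataset,
    write_dataset,
)


class TestMakeBackground:
    def test_deterministic(self):
        assert make_background(1000, 0.5, 7).seq == make_background(1000, 0.5, 7).seq

    def test_gc_within_three_standard_errors(self):
        seq = make_background(10_000, 0.4, 1).seq
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        se = math.sqrt(0.4 * 0.6 / len(seq))
        assert abs(gc - 0.4) < 3 * se

    def test_single_base(self):
        assert len(make_background(1, 0.5, 0).seq) == 1

    def test_bad_gc(self):
        with pytest.raises(ConfigError):
            make_background(10, 1.5, 0)


class TestMakeElement:
    def test_tir_and_signature_by_construction(self):
        m = make_element("f", ltdr_len=473, tir_len=14, seed=1)
        assert find_tir(m.ltdr_seq, max_mismatch=0).length >= 14
        assert terminal_signature(m.ltdr_seq) is True

    def test_long_ltdr_class(self):
        m = make_element("f", ltdr_len=664, int_len=1125, tir_len=18, seed=2)
        assert terminal_signature(m.ltdr_seq) is True
        assert len(m.ltdr_seq) == 664

    def test_deterministic(self):
        a = make_element("f", seed=3)
        b = make_element("f", seed=3)
        assert (a.ltdr_seq, a.int_seq) == (b.ltdr_seq, b.int_seq)

    def test_edge_motif_present(self):
        m = make_element("f", seed=4, int_edge_motif="TATA")
        assert m.int_seq.startswith("TATA") and m.int_seq.endswith("TATA")

    def test_impossible_geometry(self):
        with pytest.raises(ConfigError):
            make_element("f", ltdr_len=20, tir_len=14)


@pytest.fixture()
def background():
    return make_background(20_000, 0.4, 99)


class TestPlant:
    def test_monomer_roundtrip(self, background, small_model):
        req = PlantRequest("MONOMER", locus=10_000)
        genome, truth = plant(background, small_model, req, seed=1)
        elem = genome.seq[truth.start : truth.end]
        assert elem == small_model.monomer_seq()
        left = genome.seq[truth.start - 10 : truth.start]
        right = genome.seq[truth.end : truth.end + 10]
        assert left.endswith(truth.tsd) and right.startswith(truth.tsd)
        assert len(genome.seq) == len(background.seq) + len(elem) + small_model.tsd_len

    def test_tandem_int_single_edge_motif(self, background, small_model):
        req = PlantRequest("TANDEM_INT", m=2, locus=10_000, junction_microdel=4)
        genome, truth = plant(background, small_model, req, seed=2)
        ints = [(s, e) for lab, s, e in truth.parts if lab == "INT"]
        junction = genome.seq[ints[0][1] - 8 : ints[1][0] + 8]
        assert junction.count("TATA") == 1

    def test_multimer_part_counts(self, background, small_model):
        req = PlantRequest("MULTIMER_SHARED", n=4, locus=10_000)
        _, truth = plant(background, small_model, req, seed=3)
        labels = [lab for lab, _, _ in truth.parts]
        assert labels.count("LTDR") == 5 and labels.count("INT") == 4

    def test_divergence_zero_parts_reproduce_model(self, background, small_model):
        req = PlantRequest("MULTIMER_SHARED", n=2, locus=9_000)
        genome, truth = plant(background, small_model, req, seed=4)
        for lab, s, e in truth.parts:
            expected = small_model.ltdr_seq if lab == "LTDR" else small_model.int_seq
            assert genome.seq[s:e] == expected

    def test_minus_strand_parts(self, background, small_model):
        req = PlantRequest("LTDR_INT", locus=9_000, strand="-")
        genome, truth = plant(background, small_model, req, seed=5)
        assert truth.tokens() == "LI"
        lab, s, e = truth.parts[0]
        assert lab == "INT"
        assert reverse_complement(genome.seq[s:e]) == small_model.int_seq

    def test_collision_raises(self, background, small_model):
        from ltdrscan.core import Interval

        occupied = [Interval("bg", 8_000, 12_000)]
        req = PlantRequest("SOLO_LTDR", locus=10_000)
        with pytest.raises(PlacementError):
            plant(background, small_model, req, seed=6, occupied=occupied)


class TestExciseLtdr:
    @pytest.fixture()
    def monomer(self, background, small_model):
        req = PlantRequest("MONOMER", locus=10_000)
        return plant(background, small_model, req, seed=10)

    def test_left_excision_leaves_int_ltdr(self, monomer, small_model):
        genome, truth = monomer
        genome2, truth2, _ = excise_ltdr(genome, truth, "left", 0)
        assert truth2.architecture == "INT_LTDR"
        right = genome2.seq[truth2.end : truth2.end + small_model.tsd_len]
        assert right == truth.tsd  # right TSD copy intact

    def test_outer_deletion_shortens_tsd_copy(self, monomer, small_model):
        genome, truth = monomer
        k = small_model.tsd_len
        genome2, truth2, _ = excise_ltdr(genome, truth, "left", 4, side="outer")
        left = genome2.seq[truth2.start - k : truth2.start]
        # 4 of the k TSD bases are gone; what remains is upstream sequence
        # followed by the TSD tail.
        assert left[k - (k - 4):] == truth.tsd[4:] if k > 4 else True
        assert truth2.excised_flank_bp == 4

    def test_sequential_excision_yields_solo_int(self, monomer):
        genome, truth = monomer
        genome2, truth2, _ = excise_ltdr(genome, truth, "left", 0)
        genome3, truth3, _ = excise_ltdr(genome2, truth2, "right", 0)
        assert truth3.architecture == "SOLO_INT"
        assert [lab for lab, _, _ in truth3.parts] == ["INT"]

    def test_too_many_deleted_bases(self, monomer):
        genome, truth = monomer
        with pytest.raises(ConfigError):
            excise_ltdr(genome, truth, "left", 6)


class TestDataset:
    def test_write_read_roundtrip(self, tmp_path, mixed_dataset):
        genomes, truths, models, _ = mixed_dataset
        paths = write_dataset(genomes, truths, models, tmp_path)
        back = read_truth(paths["truth"])
        assert len(back) == len(truths)
        for a, b in zip(truths, back):
            assert (a.event_id, a.architecture, a.start, a.end, a.tsd) == (
                b.event_id, b.architecture, b.start, b.end, b.tsd,
            )
            assert a.parts == b.parts

    def test_empty_dataset(self, tmp_path):
        genome = make_background(100, 0.5, 0)
        paths = write_dataset([genome], [], [], tmp_path)
        assert read_truth(paths["truth"]) == []

    def test_seed_determinism(self):
        from ltdrscan.simulate import SimulationConfig

        cfg = SimulationConfig(genome_length=50_000, counts={"MONOMER": 2}, min_spacing=1000)
        g1, t1, _ = simulate_dataset(cfg, seed=8)
        g2, t2, _ = simulate_dataset(cfg, seed=8)
        assert g1[0].seq == g2[0].seq
        assert [t.start for t in t1] == [t.start for t in t2]

    def test_truth_tsd_flanks_planted_events(self, mixed_dataset):
        genomes, truths, models, _ = mixed_dataset
        genome = genomes[0]
        for t in truths:
            k = len(t.tsd)
            assert genome.seq[t.start - k : t.start] == t.tsd
            assert genome.seq[t.end : t.end + k] == t.tsd
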