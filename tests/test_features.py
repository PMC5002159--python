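"""Feature encoders: conservation sums, motif counting, property means."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bfadbp import (
    MOTIF_TRIPLES,
    N_FEATURES,
    PhysicochemicalTable,
    ProteinRecord,
    PSSMProfile,
    SSProbMatrix,
    assemble,
    assign_ss_labels,
    conservation_features,
    default_table,
    encode_protein,
    feature_names,
    motif_features,
    physicochemical_features,
    read_feature_csv,
    segment,
    triple_objects,
    write_feature_csv,
)
from bfadbp.features import ContractError, logistic
from bfadbp.profile_io import STANDARD_AA, ValidationError


def make_pssm(record, scores):
    return PSSMProfile(record_id=record.id, scores=scores, columns=STANDARD_AA)


class TestConservation:
    def test_all_zero_pssm_gives_neutral_half(self):
        record = ProteinRecord(id="t", sequence="ACDEFG")
        feats = conservation_features(record, make_pssm(record, np.zeros((6, 20), int)))
        np.testing.assert_allclose(feats, 0.5)

    def test_hand_evaluated_sum_and_logistic(self):
        # sequence AA with A-column entries (1, 2): P_A = 3 -> logistic(3)
        record = ProteinRecord(id="t", sequence="AA")
        scores = np.zeros((2, 20), int)
        scores[0, 0], scores[1, 0] = 1, 2
        feats = conservation_features(record, make_pssm(record, scores))
        assert feats[0] == pytest.approx(1.0 / (1.0 + np.exp(-3.0)), abs=1e-10)
        assert feats[0] == pytest.approx(0.95257, abs=1e-5)
        # every amino acid absent from the sequence has an empty sum
        np.testing.assert_allclose(feats[1:], 0.5)

    def test_only_matching_positions_count(self):
        # the A column also has a score at the C position; it must not count
        record = ProteinRecord(id="t", sequence="AC")
        scores = np.zeros((2, 20), int)
        scores[0, 0] = 5  # A at an A position: counts
        scores[1, 0] = 7  # A column at a C position: ignored
        feats = conservation_features(record, make_pssm(record, scores))
        assert feats[0] == pytest.approx(logistic(5.0))

    def test_position_permutation_equivariance(self, rng):
        record, pssm, _ = triple_objects(40, seed=9)
        perm = rng.permutation(record.L)
        permuted_record = ProteinRecord(
            id=record.id, sequence="".join(record.sequence[i] for i in perm)
        )
        permuted_pssm = PSSMProfile(
            record_id=record.id, scores=pssm.scores[perm], columns=pssm.columns
        )
        np.testing.assert_allclose(
            conservation_features(record, pssm),
            conservation_features(permuted_record, permuted_pssm),
        )


class TestSecondaryStructure:
    def test_argmax_labels(self):
        ss = SSProbMatrix(
            record_id="t", probs=np.array([[0.8, 0.1, 0.1], [0.1, 0.8, 0.1]])
        )
        assert assign_ss_labels(ss) == "HE"

    def test_tie_broken_by_helix_priority(self):
        ss = SSProbMatrix(record_id="t", probs=np.array([[0.4, 0.4, 0.2]]))
        assert assign_ss_labels(ss) == "H"

    def test_all_coil(self):
        ss = SSProbMatrix(record_id="t", probs=np.tile([0.1, 0.1, 0.8], (3, 1)))
        assert assign_ss_labels(ss) == "CCC"

    @pytest.mark.parametrize(
        "labels, expected",
        [
            ("HHHEEECCC", (("H", 3), ("E", 3), ("C", 3))),
            ("HHHH", (("H", 4),)),
            ("HEHE", (("H", 1), ("E", 1), ("H", 1), ("E", 1))),
        ],
    )
    def test_segmentation_is_maximal_run_length_encoding(self, labels, expected):
        segs = segment(labels)
        assert segs.segments == expected
        assert segs.total_length == len(labels)


class TestMotifs:
    def test_twelve_categories_match_independent_enumeration(self):
        oracle = {
            a + b + c
            for a, b, c in itertools.product("HEC", repeat=3)
            if a != b and b != c
        }
        assert set(MOTIF_TRIPLES) == oracle
        assert len(MOTIF_TRIPLES) == 12

    def test_adjacent_equal_triples_structurally_excluded(self):
        assert not any(t[0] == t[1] or t[1] == t[2] for t in MOTIF_TRIPLES)

    def test_single_window(self):
        feats = motif_features(segment("HHHEEECCC"))
        assert feats[MOTIF_TRIPLES.index("HEC")] == 1.0
        assert feats.sum() == 1.0

    def test_two_windows_each_half(self):
        feats = motif_features(segment("HECH"))
        assert feats[MOTIF_TRIPLES.index("HEC")] == 0.5
        assert feats[MOTIF_TRIPLES.index("ECH")] == 0.5

    def test_fewer_than_three_segments_all_zero(self):
        np.testing.assert_array_equal(motif_features(segment("HHHH")), 0.0)
        np.testing.assert_array_equal(motif_features(segment("HHEE")), 0.0)

    def test_raw_counts_exposed(self):
        feats = motif_features(segment("HECHEC"), normalize=False)
        assert feats.sum() == 4  # 6 segments -> 4 windows

    @given(st.text(alphabet="HEC", min_size=1, max_size=50))
    @settings(max_examples=100, derandomize=True)
    def test_normalized_counts_sum_to_one_or_zero(self, labels):
        segs = segment(labels)
        total = motif_features(segs).sum()
        if len(segs.segments) >= 3:
            assert total == pytest.approx(1.0)
        else:
            assert total == 0.0


class TestPhysicochemical:
    @staticmethod
    def toy_table(values_for_a=0.2, values_for_g=0.4):
        names = default_table().property_names
        scales = {
            name: {aa: values_for_a if aa == "A" else values_for_g for aa in STANDARD_AA}
            for name in names
        }
        return PhysicochemicalTable(scales=scales, version="toy", standardize=False)

    def test_homopolymer_mean_equals_residue_value(self):
        record = ProteinRecord(id="t", sequence="AAAA")
        feats = physicochemical_features(record, self.toy_table())
        np.testing.assert_allclose(feats, 0.2)

    def test_two_residue_mean(self):
        record = ProteinRecord(id="t", sequence="AG")
        feats = physicochemical_features(record, self.toy_table(0.2, 0.4))
        np.testing.assert_allclose(feats, 0.3)

    def test_shipped_table_pins_version_and_names(self):
        table = default_table()
        assert table.version == "synthetic-1.0"
        assert len(table.property_names) == 14
        assert "net charge" in table.property_names
        assert "pKa of side chain" in table.property_names

    def test_incomplete_scale_is_configuration_error(self):
        scales = {name: dict(s) for name, s in default_table().scales.items()}
        del scales["net charge"]["A"]
        with pytest.raises(ValidationError, match="net charge"):
            PhysicochemicalTable(scales=scales, version="broken")


class TestAssemble:
    def test_lengths_and_interval(self):
        fv = assemble(np.full(20, 0.5), np.zeros(12), np.zeros(14), record_id="t")
        assert fv.values.shape == (N_FEATURES,)
        assert np.all((fv.values >= 0) & (fv.values <= 1))

    def test_raw_physchem_zero_maps_to_half(self):
        fv = assemble(np.full(20, 0.5), np.zeros(12), np.zeros(14))
        np.testing.assert_allclose(fv.physicochemical, 0.5)

    def test_wrong_block_length_is_contract_error(self):
        with pytest.raises(ContractError):
            assemble(np.full(19, 0.5), np.zeros(12), np.zeros(14))

    def test_block_boundaries(self):
        fv = assemble(np.full(20, 0.25), np.full(12, 1.0 / 12), np.zeros(14))
        np.testing.assert_allclose(fv.conservation, 0.25)
        np.testing.assert_allclose(fv.motifs, 1.0 / 12)
        np.testing.assert_allclose(fv.physicochemical, 0.5)


class TestEndToEnd:
    def test_encode_protein_is_deterministic(self):
        record, pssm, ss = triple_objects(50, seed=11)
        first = encode_protein(record, pssm, ss)
        second = encode_protein(record, pssm, ss)
        np.testing.assert_array_equal(first.values, second.values)
        assert first.record_id == record.id

    def test_feature_names_align_with_vector(self):
        names = feature_names()
        assert len(names) == N_FEATURES
        assert names[0] == "cons_A" and names[20].startswith("motif_")

    def test_csv_round_trip(self, tmp_path):
        record, pssm, ss = triple_objects(50, seed=11)
        fv = encode_protein(record, pssm, ss)
        path = tmp_path / "features.csv"
        write_feature_csv(path, [fv], labels=[1])
        ids, X, labels = read_feature_csv(path)
        assert ids == [record.id]
        np.testing.assert_allclose(X[0], fv.values, atol=1e-12)
        assert labels.tolist() == [1]
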