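import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from m6age.data_io import RnaSample, SampleSet
from m6age.sequence_features import (BpbModel, FeatureBlock, NPSParams,
                                     PseKNCParams, encode_bpb, encode_ctd,
                                     encode_eiip, encode_ncp_nd, encode_npps,
                                     encode_nps, encode_pseknc, fit_bpb,
                                     fit_npps, fuse_features,
                                     standardized_property_matrix)
from m6age.synthetic_data import SynthConfig, generate_dataset

from conftest import make_set


def random_set(n, L, seed, labels=None):
    rng = np.random.default_rng(seed)
    seqs = ["".join(rng.choice(list("ACGU"), size=L)) for _ in range(n)]
    if labels is None:
        labels = rng.integers(0, 2, size=n)
        labels[:2] = [0, 1]  # both classes always present
    return make_set(seqs, labels)


class TestCTD:
    def test_homopolymer_descriptors(self):
        block = encode_ctd(make_set(["AAAA"]))
        row = dict(zip(block.columns, block.matrix[0]))
        assert row["comp_A"] == 1.0 and row["comp_C"] == 0.0
        assert all(row[c] == 0.0 for c in block.columns if c.startswith("trans"))
        np.testing.assert_allclose(
            [row[f"dist_A_{t}"] for t in ("first", "q25", "q50", "q75", "last")],
            [0.25, 0.25, 0.50, 0.75, 1.00])
        assert all(row[c] == 0.0 for c in block.columns
                   if c.startswith("dist") and "_A_" not in c)

    def test_alternating_transition(self):
        block = encode_ctd(make_set(["ACAC"]))
        row = dict(zip(block.columns, block.matrix[0]))
        assert row["trans_AC"] == 1.0
        assert sum(v for c, v in row.items() if c.startswith("trans")) == 1.0

    def test_composition_sums_to_one(self, random_sequences):
        block = encode_ctd(random_sequences)
        comp = block.matrix[:, :4]
        np.testing.assert_allclose(comp.sum(axis=1), 1.0)

    def test_width_is_30(self, small_balanced):
        assert encode_ctd(small_balanced).n_features == 30


class TestPseKNC:
    def test_property_table_standardized(self):
        P = standardized_property_matrix()
        np.testing.assert_allclose(P.mean(axis=1), 0.0, atol=1e-12)
        np.testing.assert_allclose(P.var(axis=1), 1.0, atol=1e-12)

    def test_lambda_zero_is_kmer_frequencies(self):
        data = random_set(10, 15, seed=1)
        block = encode_pseknc(data, PseKNCParams(k=2, lam=0))
        assert block.n_features == 16
        # with no tiers the vector is exactly the normalized 2-mer counts
        for s, seq in zip(block.matrix, data.sequences):
            kmers = [seq[i:i + 2] for i in range(len(seq) - 1)]
            row = dict(zip(block.columns, s))
            for km in set(kmers):
                assert row[km] == pytest.approx(kmers.count(km) / len(kmers))

    def test_components_sum_to_one(self):
        data = random_set(20, 21, seed=2)
        for k, lam, w in [(1, 1, 0.1), (2, 3, 0.5), (3, 2, 0.1), (2, 0, 1.0)]:
            block = encode_pseknc(data, PseKNCParams(k=k, lam=lam, w=w))
            assert block.n_features == 4 ** k + lam
            np.testing.assert_allclose(block.matrix.sum(axis=1), 1.0)

    def test_homopolymer_tiers_vanish(self):
        block = encode_pseknc(make_set(["A" * 15]), PseKNCParams(k=2, lam=3))
        thetas = block.matrix[0, -3:]
        np.testing.assert_allclose(thetas, 0.0, atol=1e-15)

    def test_lambda_too_large_rejected(self):
        data = make_set(["ACGUA"])
        with pytest.raises(ValueError, match="lambda"):
            encode_pseknc(data, PseKNCParams(k=1, lam=4))


class TestNPS:
    def test_dimension_48(self, small_balanced):
        block = encode_nps(small_balanced, NPSParams(d_max=3))
        assert block.n_features == 48

    def test_single_pair_enumeration(self):
        block = encode_nps(make_set(["AAAA"]), NPSParams(d_max=1))
        row = dict(zip(block.columns, block.matrix[0]))
        assert row["k1_AA"] == 1.0  # positions (1,3) and (2,4), over 2 slots
        assert sum(row.values()) == 1.0

    def test_per_k_frequencies_sum_to_one(self, random_sequences):
        block = encode_nps(random_sequences, NPSParams(d_max=3))
        for k in range(3):
            np.testing.assert_allclose(
                block.matrix[:, 16 * k: 16 * (k + 1)].sum(axis=1), 1.0)


class TestNPPS:
    def test_fit_single_positive_sequence(self):
        train = make_set(["ACG", "ACG", "UUU"], labels=[1, 1, 0])
        model = fit_npps(train, k=1)
        # frequency of G at position 3 in positives is 1
        np.testing.assert_allclose(model.Fs_pos[:, 2], [0, 0, 1, 0])

    def test_fd_columns_sum_to_one(self):
        train = random_set(50, 15, seed=3)
        model = fit_npps(train, k=2)
        np.testing.assert_allclose(model.Fd_pos.sum(axis=0), 1.0)
        np.testing.assert_allclose(model.Fd_neg.sum(axis=0), 1.0)
        np.testing.assert_allclose(model.Fs_pos.sum(axis=0), 1.0)

    def test_pair_frequency_counting(self):
        train = make_set(["ACG", "ACA", "UUU", "GGG"], labels=[1, 1, 0, 0])
        model = fit_npps(train, k=1)
        # pair A{1}G starting at position 1: one of the two positives
        ag = 0 * 4 + 2  # row index of pair (A, G)
        assert model.Fd_pos[ag, 0] == 0.5

    def test_output_width(self):
        data = random_set(5, 25, seed=4)
        block = encode_npps(data, fit_npps(data, k=1))
        assert block.n_features == 23

    def test_identical_classes_give_zero(self):
        seqs = ["ACGUA", "GGAUC", "ACGUA", "GGAUC"]
        train = make_set(seqs, labels=[1, 1, 0, 0])
        block = encode_npps(train, fit_npps(train, k=1))
        np.testing.assert_allclose(block.matrix, 0.0)

    def test_hand_worked_single_column(self):
        train = make_set(["ACG", "UCG"], labels=[1, 0])
        model = fit_npps(train, k=1)
        block = encode_npps(make_set(["ACG"]), model)
        # p3+ = Fd+(AG,1)/Fs+(G,3) = 1/1; p3- = Fd-(AG,1)/Fs-(G,3) = 0/1
        np.testing.assert_allclose(block.matrix, [[1.0]])

    def test_range_bounded(self):
        train = random_set(100, 21, seed=5)
        test = random_set(50, 21, seed=6)
        for k in (1, 2):
            block = encode_npps(test, fit_npps(train, k=k))
            assert block.matrix.min() >= -1.0 and block.matrix.max() <= 1.0

    def test_single_class_training_rejected(self):
        train = make_set(["ACGUA", "GGGAG"], labels=[1, 1])
        with pytest.raises(ValueError, match="both classes"):
            fit_npps(train, k=1)


class TestNcpNd:
    def test_chemical_bits(self):
        block = encode_ncp_nd(make_set(["AUCG" + "A"]))
        row = block.matrix[0]
        np.testing.assert_allclose(row[0:3], [1, 1, 1])   # A
        np.testing.assert_allclose(row[4:7], [0, 1, 0])   # U
        np.testing.assert_allclose(row[8:11], [0, 0, 1])  # C
        np.testing.assert_allclose(row[12:15], [1, 0, 0])  # G

    def test_homopolymer_density(self):
        block = encode_ncp_nd(make_set(["AAAA"]))
        densities = block.matrix[0, 3::4]
        np.testing.assert_allclose(densities, 1.0)

    def test_prefix_density(self):
        block = encode_ncp_nd(make_set(["AU"]))
        assert block.matrix[0, 7] == 0.5  # U at position 2: 1 of first 2

    def test_width_4L(self, small_balanced):
        assert encode_ncp_nd(small_balanced).n_features == 4 * 21


class TestEIIP:
    def test_constants(self):
        block = encode_eiip(make_set(["ACGU"]))
        np.testing.assert_allclose(block.matrix[0],
                                   [0.1260, 0.0806, 0.1335, 0.1340])

    def test_homopolymer_constant(self):
        block = encode_eiip(make_set(["AAAA"]))
        np.testing.assert_allclose(block.matrix[0], 0.1260)

    @pytest.mark.parametrize("L", [21, 25, 41, 101])
    def test_width_equals_length(self, L):
        data = random_set(3, L, seed=7)
        assert encode_eiip(data).n_features == L


class TestBPB:
    def test_fit_counting(self):
        train = make_set(["AC", "AU", "GG", "GG"], labels=[1, 1, 0, 0])
        model = fit_bpb(train)
        assert model.f_pos[0, 0] == 1.0   # A at position 1 in all positives
        assert model.f_pos[1, 1] == 0.5   # C at position 2 in half

    def test_tables_column_stochastic(self):
        model = fit_bpb(random_set(80, 21, seed=8))
        np.testing.assert_allclose(model.f_pos.sum(axis=0), 1.0)
        np.testing.assert_allclose(model.f_neg.sum(axis=0), 1.0)

    def test_identical_classes_symmetric(self):
        seqs = ["ACGUA", "GGAUC"]
        train = make_set(seqs + seqs, labels=[1, 1, 0, 0],
                         prefix="b")
        model = fit_bpb(train)
        np.testing.assert_allclose(model.f_pos, model.f_neg)

    def test_encode_interleaving(self):
        train = make_set(["AC", "AU", "GC", "GU"], labels=[1, 1, 0, 0])
        model = fit_bpb(train)
        block = encode_bpb(make_set(["AC"]), model)
        np.testing.assert_allclose(block.matrix[0], [1.0, 0.0, 0.5, 0.5])

    def test_width_2L(self):
        data = random_set(4, 41, seed=9)
        block = encode_bpb(data, fit_bpb(data))
        assert block.n_features == 82

    def test_symmetric_model_pairs_equal(self):
        data = random_set(30, 15, seed=10)
        model = fit_bpb(data)
        sym = BpbModel(model.L, model.f_pos, model.f_pos)
        block = encode_bpb(data, sym)
        np.testing.assert_array_equal(block.matrix[:, 0::2],
                                      block.matrix[:, 1::2])

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            fit_bpb(make_set(["ACGUA", "UGCAU"], labels=[0, 0]))


class TestFusion:
    def test_widths_concatenate(self, small_balanced):
        ctd = encode_ctd(small_balanced)
        nps = encode_nps(small_balanced)
        fused = fuse_features([ctd, nps])
        assert fused.n_features == 78

    def test_single_block_identity(self, small_balanced):
        ctd = encode_ctd(small_balanced)
        assert fuse_features([ctd]) is ctd

    def test_column_labels_traceable(self, small_balanced):
        fused = fuse_features([encode_ctd(small_balanced),
                               encode_nps(small_balanced)])
        assert "NPS_k1_AA" in fused.columns
        assert all(c.split("_", 1)[0] in ("CTD", "NPS") for c in fused.columns)

    def test_row_mismatch_rejected(self, small_balanced):
        ctd = encode_ctd(small_balanced)
        other = encode_ctd(small_balanced.subset(range(10)))
        with pytest.raises(ValueError, match="rows"):
            fuse_features([ctd, other])


@pytest.fixture(scope="module")
def bulk():
    return random_set(500, 21, seed=100)


class TestProperties:
    """Bulk property checks over 500 random sequences."""

    def test_frequency_outputs_in_unit_interval(self, bulk):
        for block in (encode_nps(bulk), encode_bpb(bulk, fit_bpb(bulk))):
            assert block.matrix.min() >= 0.0 and block.matrix.max() <= 1.0

    def test_pseknc_normalization_bulk(self, bulk):
        block = encode_pseknc(bulk, PseKNCParams(k=3, lam=2, w=0.1))
        np.testing.assert_allclose(block.matrix.sum(axis=1), 1.0)

    def test_npps_range_bulk(self, bulk):
        block = encode_npps(bulk, fit_npps(bulk, k=1))
        assert block.matrix.min() >= -1.0 and block.matrix.max() <= 1.0

    def test_encoders_are_pure(self, bulk):
        sub = bulk.subset(range(50))
        a = encode_pseknc(sub).matrix
        b = encode_pseknc(sub).matrix
        np.testing.assert_array_equal(a, b)

    def test_no_leakage_from_held_out_samples(self):
        """Deleting any held-out sample and refitting the class-conditional
        encoders must leave every other held-out encoding unchanged."""
        data = generate_dataset(SynthConfig(n_pos=30, n_neg=30, L=21, seed=13))
        train = data.subset(range(0, 40))
        test = data.subset(range(40, 60))
        bpb_before = encode_bpb(test, fit_bpb(train)).matrix
        npps_before = encode_npps(test, fit_npps(train, 1)).matrix
        smaller = test.subset(range(0, 19))  # drop one held-out sample
        np.testing.assert_array_equal(
            encode_bpb(smaller, fit_bpb(train)).matrix, bpb_before[:19])
        np.testing.assert_array_equal(
            encode_npps(smaller, fit_npps(train, 1)).matrix, npps_before[:19])


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.lists(st.sampled_from("ACGU"), min_size=9, max_size=9),
       st.integers(1, 3), st.integers(0, 3))
def test_pseknc_sum_invariant_hypothesis(letters, k, lam):
    """PseKNC components sum to 1 for arbitrary sequences and parameters."""
    data = make_set(["".join(letters)])
    block = encode_pseknc(data, PseKNCParams(k=k, lam=lam, w=0.5))
    assert block.matrix.sum() == pytest.approx(1.0)
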