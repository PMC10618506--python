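import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from seqfunnel.encoders import (
    DESCRIPTOR_SCHEMES,
    Descriptor,
    EncodingError,
    EncodingSpec,
    SCHEMES,
    Signal,
    cgr_trajectory,
    descriptor_batch,
    encode,
    moment_descriptor,
)
from seqfunnel.seqio import SequenceRecord, SequenceSet

dna = st.text(alphabet="ACGT", min_size=12, max_size=60)


def rec(seq, rid="s"):
    return SequenceRecord(rid, seq)


class TestFixedMaps:
    @pytest.mark.parametrize(
        "scheme, expected",
        [
            ("eiip", [0.1260, 0.1340, 0.0806, 0.1335]),
            ("atomic", [70, 58, 78, 66]),
            ("molmass", [134, 110, 150, 125]),
            ("freq", [0.24300, 0.27215, 0.27909, 0.20576]),
            ("pam", [-1.5, 0.5, -0.5, 1.5]),
            ("integer", [2, 0, 3, 1]),
        ],
    )
    def test_acgt_values(self, scheme, expected):
        sig = encode(EncodingSpec(scheme), rec("ACGT"))
        np.testing.assert_allclose(sig.channels[0], expected)

    def test_n_gets_channel_mean(self):
        sig = encode(EncodingSpec("atomic"), rec("N"))
        assert sig.channels[0][0] == pytest.approx((70 + 58 + 78 + 66) / 4)


class TestVoss:
    def test_single_base_indicator(self):
        sig = encode(EncodingSpec("voss"), rec("A"))
        np.testing.assert_array_equal(sig.channels, [[1], [0], [0], [0]])

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(dna)
    def test_channels_sum_to_one(self, seq):
        sig = encode(EncodingSpec("voss"), rec(seq))
        np.testing.assert_allclose(sig.channels.sum(axis=0), 1.0)


class TestKmer:
    def test_worked_k2_example(self):
        d = encode(EncodingSpec("kmer", {"k": 2}), rec("ATCGAT"))
        names = [a + b for a in "ACGT" for b in "ACGT"]
        counts = dict(zip(names, d.values * 5))  # 5 overlapping 2-mers
        nonzero = {k: v for k, v in counts.items() if v}
        assert nonzero == {"AT": 2, "TC": 1, "CG": 1, "GA": 1}

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(dna, st.integers(1, 3))
    def test_frequencies_sum_to_one(self, seq, k):
        d = encode(EncodingSpec("kmer", {"k": k}), rec(seq))
        assert len(d) == 4**k
        assert d.values.sum() == pytest.approx(1.0)

    def test_windows_with_n_dropped(self):
        d = encode(EncodingSpec("kmer", {"k": 2}), rec("ANAT"))
        # only the AT window is N-free
        assert d.values.sum() == pytest.approx(1.0)
        names = [a + b for a in "ACGT" for b in "ACGT"]
        assert d.values[names.index("AT")] == pytest.approx(1.0)


class TestKmerNaturalVector:
    def test_homopolymer_hand_values(self):
        # A occupies slots 1..4: count 4, mean 2.5,
        # D2 = (1.5^2*2 + 0.5^2*2) / (4*4) = 5/16
        d = encode(EncodingSpec("kmernv", {"k": 1}), rec("AAAA"))
        counts, mu, d2 = d.values[:4], d.values[4:8], d.values[8:]
        assert counts[0] == 4 and mu[0] == pytest.approx(2.5)
        assert d2[0] == pytest.approx(5 / 16)
        assert counts[1:].sum() == 0

    def test_singleton_kmer_moment_zero(self):
        d = encode(EncodingSpec("kmernv", {"k": 1}), rec("ACGT"))
        counts, mu, d2 = d.values[:4], d.values[4:8], d.values[8:]
        np.testing.assert_array_equal(counts, [1, 1, 1, 1])
        np.testing.assert_allclose(mu, [1, 2, 3, 4])
        np.testing.assert_array_equal(d2, 0.0)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(dna, st.integers(1, 3))
    def test_counts_sum_to_slots(self, seq, k):
        d = encode(EncodingSpec("kmernv", {"k": k}), rec(seq))
        assert d.values[: 4**k].sum() == len(seq) - k + 1


class TestCgrDft:
    def test_first_step_midpoints(self):
        # one step of the iterated map from (1/2, 1/2) toward each corner
        expected = {"A": (0.25, 0.25), "C": (0.25, 0.75),
                    "G": (0.75, 0.75), "T": (0.75, 0.25)}
        for base, point in expected.items():
            traj = cgr_trajectory(rec(base))
            np.testing.assert_allclose(traj[0], point)

    def test_trajectory_stays_in_unit_square(self):
        traj = cgr_trajectory(rec("ACGTACGGTTAC" * 5))
        assert np.all(traj >= 0) and np.all(traj <= 1)

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(dna)
    def test_parseval_with_dc(self, seq):
        sig = encode(EncodingSpec("cgrdft", {"keep_dc": True}), rec(seq))
        codes = {"A": 0 + 0j, "C": 0 + 1j, "G": 1 + 1j, "T": 1 + 0j}
        # recompute trajectory independently
        x, pts = 0.5 + 0.5j, []
        for c in seq:
            x = 0.5 * (x + codes[c])
            pts.append(x)
        n = len(pts)
        assert sig.channels[0].sum() == pytest.approx(
            n * sum(abs(p) ** 2 for p in pts), rel=1e-9
        )

    def test_dc_excluded_by_default(self):
        seq = "ACGTACGTACGT"
        with_dc = encode(EncodingSpec("cgrdft", {"keep_dc": True}), rec(seq))
        without = encode(EncodingSpec("cgrdft"), rec(seq))
        assert with_dc.channels.shape[1] == without.channels.shape[1] + 1
        np.testing.assert_allclose(with_dc.channels[0][1:], without.channels[0])


class TestFps:
    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(dna)
    def test_parseval_per_channel(self, seq):
        sig = encode(EncodingSpec("fps", {"keep_dc": True}), rec(seq))
        n = len(seq)
        for base, ch in zip("ACGT", sig.channels):
            indicator = np.array([1.0 if c == base else 0.0 for c in seq])
            assert ch.sum() == pytest.approx(n * (indicator**2).sum(), rel=1e-9)

    def test_four_channels_length_n_minus_1(self):
        sig = encode(EncodingSpec("fps"), rec("ACGTACGT"))
        assert sig.channels.shape == (4, 7)


class TestEntropy:
    def test_constant_window_zero_entropy(self):
        sig = encode(EncodingSpec("minentropy", {"window": 4}), rec("AAAA"))
        np.testing.assert_allclose(sig.channels[0], [0.0])

    def test_uniform_window_two_bits(self):
        sig = encode(EncodingSpec("minentropy", {"window": 4}), rec("ACGT"))
        np.testing.assert_allclose(sig.channels[0], [2.0])

    def test_signal_length(self):
        sig = encode(EncodingSpec("minentropy", {"window": 5}), rec("ACGTACGTAC"))
        assert sig.channels.shape == (1, 6)


class TestOtherSchemes:
    def test_dinucleotide_on_unit_circle(self):
        sig = encode(EncodingSpec("dinucleotide"), rec("ACGTAC"))
        assert sig.channels.shape == (2, 5)
        radii = np.hypot(sig.channels[0], sig.channels[1])
        np.testing.assert_allclose(radii, 1.0)

    def test_dinucleotide_angles_lexicographic(self):
        # AA is angle 0; AC is 2*pi/16
        sig = encode(EncodingSpec("dinucleotide"), rec("AAC"))
        np.testing.assert_allclose(sig.channels[:, 0], [1.0, 0.0], atol=1e-12)
        theta = 2 * np.pi / 16
        np.testing.assert_allclose(sig.channels[:, 1], [np.cos(theta), np.sin(theta)])

    def test_triplet_and_iching_lexicographic_rank(self):
        # AAA=0, AAC=1, TTT=63; frame-1 non-overlapping reading
        for scheme in ("triplet", "iching"):
            sig = encode(EncodingSpec(scheme), rec("AAAAACTTT"))
            np.testing.assert_array_equal(sig.channels[0], [0, 1, 63])

    def test_triplet_drops_trailing_partial_codon(self):
        sig = encode(EncodingSpec("triplet"), rec("ACGTACGT"))
        assert sig.channels.shape == (1, 2)

    def test_internucleotide_distances(self):
        # A T A A: next same base at offsets 2, 0, 1, 0
        sig = encode(EncodingSpec("internucleotide"), rec("ATAA"))
        np.testing.assert_array_equal(sig.channels[0], [2, 0, 1, 0])

    def test_thermo_reverse_complement_symmetric_table(self):
        from seqfunnel.encoders import NN_ENTHALPY

        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        for dd, dh in NN_ENTHALPY.items():
            rc = comp[dd[1]] + comp[dd[0]]
            assert NN_ENTHALPY[rc] == dh

    def test_thermo_signal(self):
        sig = encode(EncodingSpec("thermo"), rec("ATG"))
        np.testing.assert_allclose(sig.channels[0], [-7.2, -8.5])


class TestErrors:
    @pytest.mark.parametrize(
        "scheme, seq",
        [("dinucleotide", "A"), ("triplet", "AC"), ("kmer", "AC"),
         ("minentropy", "ACG"), ("fps", "A")],
    )
    def test_too_short_names_scheme(self, scheme, seq):
        params = {"k": 3} if scheme == "kmer" else {}
        if scheme == "minentropy":
            params = {"window": 4}
        with pytest.raises(EncodingError, match=scheme):
            encode(EncodingSpec(scheme, params), rec(seq))

    def test_unknown_scheme_rejected(self):
        with pytest.raises(EncodingError, match="unknown scheme"):
            EncodingSpec("fourier")


class TestMomentDescriptor:
    def test_constant_channel_convention(self):
        sig = Signal(np.array([[5.0, 5.0, 5.0]]), ("x",), "s")
        d = moment_descriptor(sig, J=4)
        np.testing.assert_array_equal(d.values, [5.0, 0.0, 0.0, 0.0])

    def test_population_mean_and_sd(self):
        sig = Signal(np.array([[0.0, 0.0, 3.0, 3.0]]), ("x",), "s")
        d = moment_descriptor(sig, J=2)
        np.testing.assert_allclose(d.values, [1.5, 1.5])

    def test_dimension_is_channels_times_j(self):
        sig = Signal(np.array([[1.0, 2.0], [3.0, 4.0]]), ("a", "b"), "s")
        assert len(moment_descriptor(sig, J=4)) == 8

    def test_standardized_moments_scale_invariant(self):
        x = np.array([[1.0, 4.0, 2.0, 8.0, 3.0]])
        d1 = moment_descriptor(Signal(x, ("x",), "s"), J=4)
        d2 = moment_descriptor(Signal(x * 7.0, ("x",), "s"), J=4)
        np.testing.assert_allclose(d1.values[2:], d2.values[2:], rtol=1e-12)


class TestDescriptorBatch:
    @pytest.fixture
    def seqs(self, rng):
        recs = [
            SequenceRecord(f"s{i}", "".join(rng.choice(list("ACGT"), size=60)))
            for i in range(3)
        ]
        return SequenceSet(recs)

    @pytest.mark.parametrize("scheme", SCHEMES)
    def test_uniform_descriptor_length(self, seqs, scheme):
        descs = descriptor_batch(EncodingSpec(scheme), seqs, J=4)
        assert len(descs) == 3
        assert len({len(d) for d in descs}) == 1

    def test_moment_length_bookkeeping(self, seqs):
        assert len(descriptor_batch(EncodingSpec("eiip"), seqs, J=4)[0]) == 4
        assert len(descriptor_batch(EncodingSpec("kmer", {"k": 3}), seqs)[0]) == 64
        assert len(descriptor_batch(EncodingSpec("kmernv", {"k": 2}), seqs)[0]) == 48

    def test_spectrum_resampling_descriptor(self, seqs):
        descs = descriptor_batch(EncodingSpec("cgrdft"), seqs, m=16)
        assert all(len(d) == 16 for d in descs)

    def test_error_names_offending_sequence(self, seqs):
        bad = SequenceSet(list(seqs.records) + [SequenceRecord("tiny", "AC")])
        with pytest.raises(EncodingError, match="tiny"):
            descriptor_batch(EncodingSpec("kmer", {"k": 3}), bad)

    @pytest.mark.parametrize("scheme", SCHEMES)
    def test_determinism_and_duplicate_distance_zero(self, seqs, scheme):
        a = descriptor_batch(EncodingSpec(scheme), seqs, J=4)
        b = descriptor_batch(EncodingSpec(scheme), seqs, J=4)
        for da, db in zip(a, b):
            np.testing.assert_array_equal(da.values, db.values)
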