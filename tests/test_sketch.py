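"""Sketch construction, FASTA/FASTQ input, and signature round-trips."""

import gzip
import json

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from fraccos.hashing import HashConfig, InvalidKmerError, canonical_kmer, murmur64
from fraccos.sketch import (
    SequenceRecord,
    SignatureFormatError,
    Sketch,
    max_hash_for_scale,
    read_sequences,
    read_signature,
    sketch_element_set,
    sketch_sequences,
    write_signature,
)


def brute_force_kmer_hashes(sequences, ksize, seed=42):
    """Oracle: explicit window scan + canonicalisation + reference hash."""
    out = set()
    for seq in sequences:
        seq = seq.upper()
        for i in range(len(seq) - ksize + 1):
            window = seq[i : i + ksize]
            try:
                canon = canonical_kmer(window)
            except InvalidKmerError:
                continue
            out.add(murmur64(canon.encode(), seed))
    return out


class TestSketchSequences:
    def test_scale_one_keeps_every_distinct_canonical_kmer(self):
        records = [SequenceRecord("r", "ACGTACGT")]
        sk = sketch_sequences(records, ksize=4, scale=1.0)
        expected = brute_force_kmer_hashes(["ACGTACGT"], 4)
        assert set(int(h) for h in sk.hashes) == expected

    def test_scale_zero_retains_nothing(self):
        sk = sketch_sequences([SequenceRecord("r", "ACGTACGT")], ksize=4, scale=0.0)
        assert sk.num_hashes == 0

    def test_filtering_matches_brute_force_at_intermediate_scale(self, rng):
        seq = "".join(rng.choice(list("ACGT"), 500))
        sk = sketch_sequences([SequenceRecord("r", seq)], ksize=7, scale=0.25)
        threshold = max_hash_for_scale(0.25)
        expected = {
            h for h in brute_force_kmer_hashes([seq], 7) if h <= threshold
        }
        assert set(int(h) for h in sk.hashes) == expected

    def test_duplicate_kmers_collapse(self):
        once = sketch_sequences([SequenceRecord("r", "ACGTACG")], 4, 1.0)
        many = sketch_sequences([SequenceRecord("r", "ACGTACG" * 30)], 4, 1.0)
        # repeated sequence adds junction k-mers but each hash appears once
        assert len(set(map(int, many.hashes))) == many.num_hashes
        assert set(map(int, once.hashes)) <= set(map(int, many.hashes))

    def test_short_records_and_empty_stream(self):
        assert sketch_sequences([SequenceRecord("r", "ACG")], 4, 1.0).num_hashes == 0
        assert sketch_sequences([], 4, 1.0).num_hashes == 0

    def test_invalid_ksize_rejected(self):
        with pytest.raises(ValueError):
            sketch_sequences([], 0, 1.0)

    def test_non_acgt_windows_skipped_not_fatal(self):
        sk = sketch_sequences([SequenceRecord("r", "ACGTNACGT")], 4, 1.0)
        expected = brute_force_kmer_hashes(["ACGT"], 4)
        assert set(map(int, sk.hashes)) == expected

    @given(st.integers(0, 2**31 - 1))
    def test_subset_monotonicity_in_scale(self, seed):
        """FRAC_s1(A) is a subset of FRAC_s2(A) whenever s1 <= s2."""
        rng = np.random.default_rng(seed)
        elements = rng.integers(0, 10**6, 300, dtype=np.uint64)
        s1, s2 = sorted(rng.uniform(0, 1, 2))
        sk1 = sketch_element_set(elements, s1, replicate_seed=5)
        sk2 = sketch_element_set(elements, s2, replicate_seed=5)
        assert set(map(int, sk1.hashes)) <= set(map(int, sk2.hashes))

    def test_union_compatibility(self, rng):
        a = rng.integers(0, 10**6, 400, dtype=np.uint64)
        b = rng.integers(0, 10**6, 400, dtype=np.uint64)
        sk_a = sketch_element_set(a, 0.5, 3)
        sk_b = sketch_element_set(b, 0.5, 3)
        sk_union = sketch_element_set(np.union1d(a, b), 0.5, 3)
        assert set(map(int, sk_union.hashes)) == set(map(int, sk_a.hashes)) | set(
            map(int, sk_b.hashes)
        )


class TestSketchElementSet:
    def test_empty_set(self):
        assert sketch_element_set([], 1.0, 0).num_hashes == 0

    def test_scale_one_is_bijective_on_small_sets(self):
        elements = np.arange(10**4, dtype=np.uint64)
        sk = sketch_element_set(elements, 1.0, 0)
        assert sk.num_hashes == elements.size

    def test_sketch_size_in_binomial_band(self):
        """|FRAC_s(A)| ~ Binomial(|A|, s): check the three-sigma band."""
        n, s = 10**5, 0.01
        sk = sketch_element_set(np.arange(n, dtype=np.uint64), s, replicate_seed=7)
        assert abs(sk.num_hashes - n * s) < 3 * np.sqrt(n * s * (1 - s))

    def test_ksize_recorded_as_zero(self):
        assert sketch_element_set([1, 2, 3], 0.5, 0).ksize == 0


class TestSketchInvariants:
    def test_unsorted_hashes_rejected(self):
        with pytest.raises(ValueError):
            Sketch(ksize=0, scale=1.0, seed=0, hashes=np.array([3, 1], dtype=np.uint64))

    def test_hash_above_threshold_rejected(self):
        with pytest.raises(ValueError):
            Sketch(
                ksize=0,
                scale=1e-12,
                seed=0,
                hashes=np.array([2**63], dtype=np.uint64),
            )


class TestSequenceReading:
    def test_fasta_plain_and_gzip_agree(self, tiny_fasta, tmp_path):
        gz = tmp_path / "toy.fasta.gz"
        gz.write_bytes(gzip.compress(tiny_fasta.read_bytes()))
        plain = list(read_sequences(tiny_fasta))
        zipped = list(read_sequences(gz))
        assert plain == zipped
        assert plain[0].id == "seq1" and len(plain) == 2

    def test_fastq_detected_and_parsed(self, tmp_path):
        fq = tmp_path / "toy.fastq"
        fq.write_text("@read1\nACGTACGTAC\n+\nIIIIIIIIII\n")
        (rec,) = read_sequences(fq)
        assert rec == SequenceRecord("read1", "ACGTACGTAC")

    def test_fasta_and_fastq_same_sequence_same_sketch(self, tmp_path):
        fa = tmp_path / "x.fasta"
        fa.write_text(">r\nACGTACGTACGTACGT\n")
        fq = tmp_path / "x.fastq"
        fq.write_text("@r\nACGTACGTACGTACGT\n+\n" + "I" * 16 + "\n")
        sk_fa = sketch_sequences(read_sequences(fa), 5, 1.0)
        sk_fq = sketch_sequences(read_sequences(fq), 5, 1.0)
        assert np.array_equal(sk_fa.hashes, sk_fq.hashes)

    def test_unrecognised_format_raises(self, tmp_path):
        bad = tmp_path / "bad.txt"
        bad.write_text("not a sequence file\n")
        with pytest.raises(SignatureFormatError):
            list(read_sequences(bad))


class TestSignatureIO:
    @pytest.mark.parametrize("scale", [1.0, 0.5, 0.001])
    def test_round_trip_identity(self, tmp_path, rng, scale):
        hashes = np.unique(
            rng.integers(0, max_hash_for_scale(scale), 50, dtype=np.uint64)
        )
        sk = Sketch(ksize=21, scale=scale, seed=42, hashes=hashes, name="sample-1")
        path = tmp_path / "s.sig"
        write_signature(sk, path)
        assert read_signature(path) == sk

    def test_round_trip_nonintegral_reciprocal_scale_warns(self, tmp_path):
        sk = Sketch(
            ksize=0,
            scale=0.1293,
            seed=42,
            hashes=np.array([10, 20], dtype=np.uint64),
            name="",
        )
        path = tmp_path / "s.sig"
        with pytest.warns(UserWarning, match="non-integral reciprocal"):
            write_signature(sk, path)
        assert read_signature(path) == sk

    def test_sourmash_layout_fields_present(self, tmp_path):
        sk = Sketch(
            ksize=21,
            scale=0.001,
            seed=42,
            hashes=np.array([5], dtype=np.uint64),
            name="x",
        )
        write_signature(sk, tmp_path / "s.sig")
        doc = json.loads((tmp_path / "s.sig").read_text())
        entry = doc[0]["signatures"][0]
        assert doc[0]["hash_function"] == "0.murmur64"
        assert entry["scaled"] == 1000
        assert entry["mins"] == [5]

    def test_unsorted_mins_rejected(self, tmp_path):
        path = tmp_path / "bad.sig"
        path.write_text(
            json.dumps(
                [{"name": "", "signatures": [{"ksize": 0, "seed": 0, "scaled": 1,
                                              "mins": [9, 3]}]}]
            )
        )
        with pytest.raises(SignatureFormatError, match="mins"):
            read_signature(path)

    def test_malformed_json_rejected(self, tmp_path):
        path = tmp_path / "bad.sig"
        path.write_text("{not json")
        with pytest.raises(SignatureFormatError, match="JSON"):
            read_signature(path)

    def test_missing_field_named_in_error(self, tmp_path):
        path = tmp_path / "bad.sig"
        path.write_text(json.dumps([{"signatures": [{"seed": 0, "mins": []}]}]))
        with pytest.raises(SignatureFormatError, match="ksize"):
            read_signature(path)
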