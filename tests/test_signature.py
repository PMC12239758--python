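"""FASTQ streaming, signature extraction and feature-table I/O."""

import numpy as np
import pytest

from kmersig import (
    build_feature_table,
    enumerate_kmers,
    extract_sample_signature,
    read_feature_table,
    stream_reads,
    write_feature_table,
)
from kmersig.signature import canonicalize_table, read_manifest
from kmersig.errors import (
    EmptySampleError,
    FastqFormatError,
    MetadataError,
    TableFormatError,
)

from conftest import random_dna


class TestStreamReads:
    def test_yields_sequence_lines_in_order(self, write_fastq):
        path = write_fastq(["ACGT", "TTAA"])
        assert list(stream_reads(path)) == ["ACGT", "TTAA"]

    def test_gzip_transparency(self, write_fastq):
        seqs = ["ACGTACGT", "GGGCCC", "ATATAT"]
        plain = write_fastq(seqs, name="a.fastq")
        gz = write_fastq(seqs, name="b.fastq", gz=True)
        assert list(stream_reads(plain)) == list(stream_reads(gz))

    def test_paired_files_pool_reads(self, write_fastq):
        r1 = write_fastq(["AAA", "CCC", "GGG"], name="r1.fastq")
        r2 = write_fastq(["TTT", "ACG", "CGT"], name="r2.fastq")
        assert len(list(stream_reads([r1, r2]))) == 6

    def test_lowercase_is_uppercased(self, write_fastq):
        path = write_fastq(["acgt"])
        assert list(stream_reads(path)) == ["ACGT"]

    def test_truncated_record_raises_with_index(self, write_fastq, tmp_path):
        path = write_fastq(["ACGT", "TTAA"])
        text = path.read_text().splitlines(keepends=True)
        bad = tmp_path / "trunc.fastq"
        bad.write_text("".join(text[:-1]))  # drop the last quality line
        with pytest.raises(FastqFormatError, match="record 1"):
            list(stream_reads(bad))

    def test_missing_file(self, tmp_path):
        with pytest.raises(OSError):
            list(stream_reads(tmp_path / "nope.fastq"))

    def test_batch_size_independence(self, write_fastq, rng):
        seqs = [random_dna(rng, int(rng.integers(20, 80))) for _ in range(100)]
        path = write_fastq(seqs)
        ref = list(stream_reads(path, batch_lines=128))
        for bl in (4, 12, 400):
            assert list(stream_reads(path, batch_lines=bl)) == ref


class TestExtractSignature:
    def test_single_read_all_mass_on_one_kmer(self, write_fastq, spec3):
        path = write_fastq(["AAAA"])
        sig = extract_sample_signature("s1", path, spec3)
        assert sig.frequencies[spec3.index["AAA"]] == 1.0
        assert sig.frequencies.sum() == 1.0
        assert sig.counts_total == 2
        assert sig.n_reads == 1

    def test_two_reads_split_mass(self, write_fastq, spec3):
        path = write_fastq(["AAA", "TTT"])
        sig = extract_sample_signature("s1", path, spec3)
        assert sig.frequencies[spec3.index["AAA"]] == 0.5
        assert sig.frequencies[spec3.index["TTT"]] == 0.5

    def test_empty_sample_raises(self, write_fastq, spec3):
        path = write_fastq(["NN", "A"])  # no valid 3-mer window anywhere
        with pytest.raises(EmptySampleError, match="s_empty"):
            extract_sample_signature("s_empty", path, spec3)

    def test_worker_count_does_not_change_signature(self, write_fastq, spec3, rng):
        path = write_fastq([random_dna(rng, 60) for _ in range(20)])
        a = extract_sample_signature("s", path, spec3, workers=1)
        b = extract_sample_signature("s", path, spec3, workers=4)
        assert np.array_equal(a.frequencies, b.frequencies)

    def test_read_order_permutation_invariance(self, write_fastq, spec3, rng):
        seqs = [random_dna(rng, 50) for _ in range(30)]
        a = extract_sample_signature("s", write_fastq(seqs, name="fwd.fastq"), spec3)
        perm = [seqs[i] for i in rng.permutation(len(seqs))]
        b = extract_sample_signature("s", write_fastq(perm, name="perm.fastq"), spec3)
        assert np.array_equal(a.frequencies, b.frequencies)

    def test_window_count_identity(self, write_fastq, spec3, rng):
        """counts_total == Σ per-read (len − k + 1) − skipped windows, exactly."""
        seqs = [random_dna(rng, int(rng.integers(2, 40)), "ACGTN") for _ in range(50)]
        sig = extract_sample_signature("s", write_fastq(seqs), spec3)
        total_windows = sum(max(0, len(s) - 3 + 1) for s in seqs)
        assert sig.counts_total == total_windows - sig.n_skipped_windows
        assert abs(sig.frequencies.sum() - 1.0) < 1e-9


class TestFeatureTable:
    def _signatures(self, write_fastq, spec3, n=3):
        sigs = []
        for i, seq in enumerate(["AAAA", "ACGTACG", "TTTTT"][:n]):
            p = write_fastq([seq], name=f"s{i}.fastq")
            sigs.append(extract_sample_signature(f"s{i}", p, spec3))
        return sigs

    def test_build_shape_and_order(self, write_fastq, spec3):
        sigs = self._signatures(write_fastq, spec3)
        table = build_feature_table(sigs, {"s0": "NC", "s1": "CD", "s2": "UC"})
        assert table.matrix.shape == (3, 64)
        assert table.sample_ids == ["s0", "s1", "s2"]
        assert table.feature_names == list(spec3.vocabulary)
        assert table.labels == ["NC", "CD", "UC"]

    def test_missing_label_names_sample(self, write_fastq, spec3):
        sigs = self._signatures(write_fastq, spec3)
        with pytest.raises(MetadataError, match="s2"):
            build_feature_table(sigs, {"s0": "NC", "s1": "CD"})

    def test_duplicate_sample_id(self, write_fastq, spec3):
        sigs = self._signatures(write_fastq, spec3, n=2)
        sigs[1].sample_id = "s0"
        with pytest.raises(MetadataError, match="duplicate"):
            build_feature_table(sigs, {"s0": "NC"})

    def test_mixed_k_rejected(self, write_fastq, spec3):
        sigs = self._signatures(write_fastq, spec3, n=2)
        sigs[1].k = 5
        with pytest.raises(MetadataError, match="mix"):
            build_feature_table(sigs, {"s0": "NC", "s1": "CD"})

    def test_tsv_round_trip(self, write_fastq, spec3, tmp_path):
        sigs = self._signatures(write_fastq, spec3)
        table = build_feature_table(sigs, {"s0": "NC", "s1": "CD", "s2": "UC"})
        path = tmp_path / "table.tsv"
        write_feature_table(table, path)
        back = read_feature_table(path)
        assert back.sample_ids == table.sample_ids
        assert back.feature_names == table.feature_names
        assert back.labels == table.labels
        np.testing.assert_allclose(back.matrix, table.matrix, rtol=1e-12, atol=0)

    def test_empty_table_write_rejected(self, tmp_path):
        from kmersig.signature import FeatureTable

        empty = FeatureTable(sample_ids=[], feature_names=["AA"], matrix=np.zeros((0, 1)), labels=[])
        with pytest.raises(TableFormatError):
            write_feature_table(empty, tmp_path / "t.tsv")

    def test_na_cell_rejected(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("sample_id\tAA\tAC\tlabel\ns0\t0.5\tNA\tNC\n")
        with pytest.raises(TableFormatError, match="line 2"):
            read_feature_table(p)

    def test_ragged_row_rejected(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("sample_id\tAA\tAC\tlabel\ns0\t0.5\tNC\n")
        with pytest.raises(TableFormatError, match="line 2"):
            read_feature_table(p)

    def test_canonicalization_folds_reverse_complements(self, write_fastq, spec3):
        sigs = self._signatures(write_fastq, spec3)
        table = build_feature_table(sigs, {"s0": "NC", "s1": "CD", "s2": "UC"})
        folded = canonicalize_table(table)
        assert folded.n_features == 32  # 64 3-mers → 32 canonical pairs (no palindromes at odd k)
        np.testing.assert_allclose(folded.matrix.sum(axis=1), 1.0, atol=1e-9)
        # AAA and TTT collapse onto the canonical AAA column
        j = folded.feature_names.index("AAA")
        i_aaa = table.feature_names.index("AAA")
        i_ttt = table.feature_names.index("TTT")
        np.testing.assert_allclose(
            folded.matrix[:, j], table.matrix[:, i_aaa] + table.matrix[:, i_ttt]
        )


class TestManifest:
    def test_round_trip_single_end(self, tmp_path):
        m = tmp_path / "manifest.tsv"
        m.write_text("sample_id\tpath1\tlabel\ns0\ta.fastq\tNC\ns1\tb.fastq\tCD\n")
        rows = read_manifest(m)
        assert [r[0] for r in rows] == ["s0", "s1"]
        assert rows[0][2] == "NC"

    def test_paired_end_columns(self, tmp_path):
        m = tmp_path / "manifest.tsv"
        m.write_text("sample_id\tpath1\tpath2\tlabel\ns0\ta_1.fastq\ta_2.fastq\tNC\n")
        rows = read_manifest(m)
        assert len(rows[0][1]) == 2

    def test_bad_header(self, tmp_path):
        m = tmp_path / "manifest.tsv"
        m.write_text("id\tpath\tlabel\n")
        with pytest.raises(TableFormatError):
            read_manifest(m)
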