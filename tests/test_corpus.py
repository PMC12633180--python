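"""Window construction, filtering rules, fold balancing, shard round trips."""

import numpy as np
import pandas as pd
import pytest

from mycolm import corpus, io as mio
from mycolm.corpus import Contig, GenomeWindow


def _seq(n, base="A"):
    return base * n


def _window(seq, species=0, chrom="chr1", start=0, **kw):
    return GenomeWindow(species, chrom, start, start + len(seq), seq, **kw)


class TestPrepareContigs:
    def test_lm_minimum_contig_boundary(self):
        fasta = {"keep": _seq(32_768), "drop": _seq(32_767)}
        out = corpus.prepare_contigs(fasta, "lm")
        assert [c.chrom for c in out] == ["keep"]

    def test_supervised_trim_drops_short_piece(self):
        # 18,000 - 2*1,024 = 15,952 < 16,384 -> dropped
        out = corpus.prepare_contigs({"c": _seq(18_000)}, "supervised")
        assert out == []

    def test_supervised_long_contig_split_in_half(self):
        # 800,000 - 2,048 = 797,952 > 786,432 -> two halves of 398,976
        out = corpus.prepare_contigs({"c": _seq(800_000)}, "supervised")
        assert [len(c) for c in out] == [398_976, 398_976]
        assert [c.offset for c in out] == [1_024, 1_024 + 398_976]

    def test_supervised_splits_at_mask_intervals(self):
        mask = pd.DataFrame({"chrom": ["c"], "start": [40_000],
                             "end": [41_000]})
        out = corpus.prepare_contigs({"c": _seq(80_000)}, "supervised",
                                     mask_bed=mask)
        assert [len(c) for c in out] == [40_000 - 2_048, 39_000 - 2_048]
        assert out[1].offset == 41_000 + 1_024

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            corpus.prepare_contigs({"c": "ACGT"}, "other")


class TestSegmentWindows:
    @pytest.mark.parametrize("length,expected_starts", [
        (32_768, [0, 4_096, 8_192, 12_288, 16_384]),
        (16_383, []),
        (16_384, [0]),
    ])
    def test_window_starts_match_enumeration_oracle(self, length,
                                                    expected_starts):
        contig = Contig(0, "c", 0, _seq(length))
        wins = corpus.segment_windows([contig], window=16_384, stride=4_096)
        assert [w.start for w in wins] == expected_starts
        # oracle: exhaustive enumeration of fully contained strided windows
        oracle = [s for s in range(0, length + 1, 4_096)
                  if s + 16_384 <= length]
        assert [w.start for w in wins] == oracle

    def test_offset_contigs_emit_genome_coordinates(self):
        contig = Contig(0, "c", 5_000, _seq(2_048))
        wins = corpus.segment_windows([contig], window=1_024, stride=1_024)
        assert [w.start for w in wins] == [5_000, 6_024]


class TestRepeatFilter:
    @pytest.mark.parametrize("n_lower,kept", [
        (1_146, True),      # 6.9946% <= 7%
        (1_147, False),     # 7.0007% > 7%, strictly greater removes
        (0, True),
    ])
    def test_seven_percent_boundary_is_strict(self, n_lower, kept):
        seq = "a" * n_lower + "A" * (16_384 - n_lower)
        out = corpus.repeat_fraction_filter([_window(seq)])
        assert bool(out) == kept
        assert (n_lower / 16_384 > 0.07) != kept

    def test_fraction_matches_brute_force_count(self, small_windows):
        for w in small_windows:
            brute = sum(ch.islower() for ch in w.seq) / w.length
            assert w.repeat_fraction == pytest.approx(brute)


class TestPositionMasks:
    def _gtf(self, rows):
        text = mio.format_gtf(rows)
        return mio.read_gtf(text)

    def test_exon_chewed_two_bp_each_side(self):
        gtf = self._gtf([("chr1", "t", "exon", 100, 200, "+",
                          'gene_id "g"; transcript_id "t";')])
        w = corpus.build_position_masks(_window(_seq(1_024)), gtf)
        assert w.exon_mask[102:198].all()
        assert not w.exon_mask[:102].any() and not w.exon_mask[198:].any()

    def test_exonic_and_repeat_weight_assigned_once(self):
        seq = "A" * 100 + "a" * 100 + "A" * 824    # repeat inside the exon
        gtf = self._gtf([("chr1", "t", "exon", 51, 250, "+",
                          'gene_id "g"; transcript_id "t";')])
        w = corpus.build_position_masks(_window(seq), gtf)
        assert w.loss_weights[150] == pytest.approx(0.1)   # both -> 0.1 once

    def test_no_annotation_gives_unit_weights(self):
        gtf = self._gtf([("chr9", "t", "exon", 1, 50, "+",
                          'gene_id "g"; transcript_id "t";')])
        w = corpus.build_position_masks(_window(_seq(1_024)), gtf)
        assert np.all(w.loss_weights == 1.0)

    def test_n_bases_get_zero_weight(self):
        seq = "A" * 100 + "N" * 10 + "A" * 914
        w = corpus.build_position_masks(_window(seq), mio.read_gtf(
            mio.format_gtf([("chrX", "t", "exon", 1, 5, "+",
                             'gene_id "g"; transcript_id "t";')])))
        assert np.all(w.loss_weights[100:110] == 0.0)


class TestHomologyFilter:
    def _paf(self, qname, matches, qlen, block):
        line = "\t".join([qname, str(qlen), "0", "100", "+", "t", "1000",
                          "0", "100", str(matches), str(block), "60"])
        return mio.read_paf(line + "\n")

    def test_no_alignment_keeps_window(self):
        w = _window(_seq(16_384))
        kept, removed = corpus.filter_homologous_windows([w], mio.read_paf(""))
        assert kept == [w] and removed == []

    def test_coverage_and_identity_both_above_thresholds_removes(self):
        w = _window(_seq(16_384))
        paf = self._paf(w.window_id, matches=900, qlen=16_384, block=2_000)
        kept, removed = corpus.filter_homologous_windows([w], paf)
        assert removed == [w]
        assert 900 / 16_384 >= 0.05 and 900 / 2_000 >= 0.30

    def test_high_identity_low_coverage_kept(self):
        w = _window(_seq(16_384))
        paf = self._paf(w.window_id, matches=500, qlen=16_384, block=600)
        kept, removed = corpus.filter_homologous_windows([w], paf)
        assert kept == [w]
        assert 500 / 16_384 < 0.05 <= 500 / 600

    def test_short_paf_line_rejected(self):
        with pytest.raises(ValueError, match="fields"):
            mio.read_paf("q\t1\t2\n")


class TestFoldAssignment:
    def test_umap_clip_removes_majority_unmappable(self):
        unmap = np.zeros(1_024, dtype=bool)
        unmap[:615] = True                        # 60% unmappable
        bad = _window(_seq(1_024), unmap_mask=unmap)
        good = [_window(_seq(1_024), start=(i + 1) * 2_000) for i in range(8)]
        split = corpus.assign_folds(good + [bad], n_folds=8, seed=0)
        assert bad.window_id not in split.folds
        assert len(split.folds) == 8

    def test_eight_equal_windows_one_per_fold(self):
        wins = [_window(_seq(1_024), start=i * 2_000) for i in range(8)]
        split = corpus.assign_folds(wins, n_folds=8, seed=1)
        assert sorted(split.folds.values()) == list(range(8))

    def test_sixteen_equal_windows_perfectly_balanced(self):
        wins = [_window(_seq(1_024), start=i * 2_000) for i in range(16)]
        split = corpus.assign_folds(wins, n_folds=8, seed=2)
        totals = np.zeros(8)
        for w in wins:
            totals[split.folds[w.window_id]] += w.length
        assert totals.max() - totals.min() == 0

    def test_more_folds_than_windows_rejected(self):
        with pytest.raises(ValueError):
            corpus.assign_folds([_window(_seq(1_024))], n_folds=2)


class TestShards:
    def test_shard_count_is_ceiling_division(self, tmp_path, small_windows):
        wins = small_windows[:33]
        paths = corpus.write_shards(wins, tmp_path, shard_size=32)
        assert len(paths) == 2

    def test_round_trip_is_identity(self, tmp_path, small_windows):
        wins = small_windows[:5]
        paths = corpus.write_shards(wins, tmp_path, shard_size=3)
        back = corpus.read_shards(paths)
        assert len(back) == len(wins)
        for a, b in zip(wins, back):
            assert a.seq == b.seq and a.species == b.species
            assert a.start == b.start and a.chrom == b.chrom
            np.testing.assert_array_equal(a.exon_mask, b.exon_mask)
            np.testing.assert_array_equal(a.repeat_mask, b.repeat_mask)
            np.testing.assert_allclose(a.loss_weights, b.loss_weights)

    def test_empty_list_writes_no_shards(self, tmp_path):
        assert corpus.write_shards([], tmp_path) == []

    def test_corrupt_shard_fails_checksum(self, tmp_path, small_windows):
        import h5py

        paths = corpus.write_shards(small_windows[:2], tmp_path)
        with h5py.File(paths[0], "a") as fh:
            fh.attrs["checksum"] = 12345
        with pytest.raises(IOError, match="checksum"):
            corpus.read_shards(paths)


def test_split_train_eval_restricts_eval_species(small_windows):
    train, val, test = corpus.split_train_eval(
        small_windows, eval_species=0, val_chroms=("chr2",), test_chroms=())
    assert all(w.chrom == "chr2" for w in val)
    assert all(w.chrom != "chr2" for w in train)
    assert len(train) + len(val) == len(small_windows)
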