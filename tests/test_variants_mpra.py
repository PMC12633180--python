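"""Variant scoring, matched negatives, classification metrics, MPRA harness."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mycolm import coverage as cov
from mycolm import variants_mpra as vm
from mycolm.lm_core import LmConfig

TINY = LmConfig(L=512, tower_widths=(8, 12), n_transformer_blocks=1,
                n_heads=2, key_dim=4, seed=3)


@pytest.fixture(scope="module")
def small_cov_model():
    # bin width 2^(2-1) = 2 bp, 256 positions, crop 8 -> 240 bins
    return cov.CoverageModel(TINY, n_tracks=2, decoder_stages=1, crop_bins=8)


@pytest.fixture(scope="module")
def scoring_context(small_cov_model):
    rng = np.random.default_rng(4)
    contig = "".join(rng.choice(list("ACGT"), 2_048))
    exons = pd.DataFrame([{"gene_id": "g1", "chrom": "chr1",
                           "start": 900, "end": 1_100}])
    return contig, exons


class TestCisTrans:
    @pytest.mark.parametrize("vpos,gpos,vchrom,gchrom,expected", [
        (10_000, 18_000, "chr1", "chr1", "cis"),     # distance exactly 8,000
        (10_000, 18_001, "chr1", "chr1", "trans"),   # one past the boundary
        (10, 20, "chr1", "chr2", "trans"),           # different chromosomes
    ])
    def test_inclusive_distance_rule(self, vpos, gpos, vchrom, gchrom,
                                     expected):
        assert vm.classify_cis_trans(vchrom, vpos, gchrom, gpos) == expected


class TestScoreVariant:
    def test_degenerate_alt_scores_zero(self, small_cov_model,
                                        scoring_context):
        contig, exons = scoring_context
        ref = contig[1_000]
        s = vm.score_variant(small_cov_model, contig, "chr1", 1_001, ref, ref,
                             exons)
        assert s.log2fc == 0.0

    def test_allele_swap_flips_sign_exactly(self, small_cov_model,
                                            scoring_context):
        contig, exons = scoring_context
        ref = contig[1_000].upper()
        alt = "A" if ref != "A" else "C"
        fwd = vm.score_variant(small_cov_model, contig, "chr1", 1_001, ref,
                               alt, exons)
        swapped_contig = contig[:1_000] + alt + contig[1_001:]
        rev = vm.score_variant(small_cov_model, swapped_contig, "chr1", 1_001,
                               alt, ref, exons)
        assert fwd.log2fc == pytest.approx(-rev.log2fc, abs=1e-6)
        assert fwd.cov_ref == pytest.approx(rev.cov_alt, abs=1e-4)

    def test_reference_mismatch_is_hard_error(self, small_cov_model,
                                              scoring_context):
        contig, exons = scoring_context
        ref = contig[1_000].upper()
        wrong = "G" if ref != "G" else "T"
        with pytest.raises(ValueError, match="reference mismatch"):
            vm.score_variant(small_cov_model, contig, "chr1", 1_001, wrong,
                             "A", exons)


class TestMatchedNegatives:
    def _tables(self):
        positives = pd.DataFrame([
            {"chrom": "chr1", "pos": 100, "ref": "A", "alt": "C",
             "af": 0.3, "tss_dist": -150},
        ])
        candidates = pd.DataFrame([
            {"chrom": "chr1", "pos": 500, "ref": "G", "alt": "T", "af": 0.2,
             "tss_dist": -250, "coding": False},     # off by 100 -> primary
            {"chrom": "chr1", "pos": 600, "ref": "G", "alt": "T", "af": 0.2,
             "tss_dist": -300, "coding": False},     # off by 150 -> fallback
            {"chrom": "chr1", "pos": 700, "ref": "G", "alt": "T", "af": 0.04,
             "tss_dist": -150, "coding": False},     # AF below threshold
        ])
        return positives, candidates

    def test_primary_window_inclusive_at_100(self):
        positives, candidates = self._tables()
        sets = vm.sample_matched_negatives(positives, candidates, n_sets=1,
                                           seed=0)
        assert sets[0].iloc[0]["matched"]
        assert sets[0].iloc[0]["pos"] == 500

    def test_fallback_window_used_when_primary_empty(self):
        positives, candidates = self._tables()
        candidates = candidates.drop(index=0)
        sets = vm.sample_matched_negatives(positives, candidates, n_sets=1,
                                           seed=0)
        assert sets[0].iloc[0]["matched"]
        assert sets[0].iloc[0]["pos"] == 600

    def test_low_af_candidate_never_selected(self):
        positives, candidates = self._tables()
        candidates = candidates.drop(index=[0, 1])
        sets = vm.sample_matched_negatives(positives, candidates, n_sets=1,
                                           seed=0)
        assert not sets[0].iloc[0]["matched"]

    def test_sets_satisfy_every_constraint(self, small_genome):
        from mycolm.fixtures import simulate_eqtls
        _, _, _, truth = small_genome
        positives, candidates = simulate_eqtls(truth, n_pos=5, seed=0,
                                               n_candidates=200)
        sets = vm.sample_matched_negatives(positives, candidates, n_sets=4,
                                           seed=1)
        assert len(sets) == 4
        pos_keys = set(zip(positives["chrom"], positives["pos"]))
        for s in sets:
            matched = s[s["matched"]]
            assert (matched["af"] >= 0.05).all()
            assert not any(k in pos_keys
                           for k in zip(matched["chrom"], matched["pos"]))
            # distance tolerance (fallback bound) and uniqueness per set
            paired = matched.merge(positives, left_on="positive_pos",
                                   right_on="pos", suffixes=("", "_pos"))
            assert ((paired["tss_dist"].abs()
                     - paired["tss_dist_pos"].abs()).abs() <= 200).all()
            assert matched["pos"].is_unique


class TestClassificationMetrics:
    def test_perfect_separation(self):
        assert vm.auroc([5, 6, 7], [1, 2, 3]) == 1.0
        assert vm.auprc([5, 6, 7], [1, 2, 3]) == pytest.approx(1.0)

    def test_random_scores_near_half(self, rng):
        aurocs = [vm.auroc(rng.random(40), rng.random(40)) for _ in range(30)]
        assert abs(np.mean(aurocs) - 0.5) < 0.05

    def test_auroc_equals_mann_whitney_pairwise_oracle(self, rng):
        pos = rng.normal(1.0, 1.0, 13)
        neg = rng.normal(0.0, 1.0, 17)
        wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
        assert vm.auroc(pos, neg) == pytest.approx(
            wins / (len(pos) * len(neg)), abs=1e-12)

    def test_per_bin_metrics_missing_when_class_empty(self):
        pos = pd.DataFrame({"log2fc": [2.0], "tss_dist": [500]})
        neg = pd.DataFrame({"log2fc": [0.1], "tss_dist": [3_000]})
        out = vm.eqtl_classification_eval(pos, neg)
        assert out["bins"]["0-1000"] is None
        assert out["auroc"] == 1.0


class TestMpraDesign:
    def test_eleven_offsets_by_default(self):
        designs = vm.mpra_insertion_design(10_000, "+", "A" * 80)
        assert len(designs) == 11

    def test_forward_window_arithmetic(self):
        d = [x for x in vm.mpra_insertion_design(10_000, "+", "A" * 80)
             if x.offset == 150][0]
        assert (d.window_start, d.window_end) == (9_795, 9_905)

    def test_reverse_strand_midpoint(self):
        d = [x for x in vm.mpra_insertion_design(10_000, "-", "A" * 80)
             if x.offset == 150][0]
        assert d.midpoint == 10_150

    def test_window_off_contig_rejected(self):
        with pytest.raises(ValueError, match="off contig"):
            vm.mpra_insertion_design(120, "+", "A" * 80)

    def test_offset_below_minimum_rejected(self):
        with pytest.raises(ValueError):
            vm.mpra_insertion_design(10_000, "+", "A" * 80, offsets=(50,))


class TestDreamFormat:
    def test_output_is_110_bp_with_fixed_flanks(self):
        core = "ACGT" * 20
        out = vm.dream_format(core)
        assert len(out) == 110
        assert out.startswith("TGCATTTTTTTCACATC")
        assert out.endswith("GGTTACGGCTGTT")
        assert out[17:97] == core

    def test_non_acgt_rejected(self):
        with pytest.raises(ValueError):
            vm.dream_format("N" * 80)


class TestMpraScore:
    # gene exon close enough to the insertion that both fit in the 512-bp
    # scoring window (bins cover [16, 496) around the insertion midpoint)
    @pytest.fixture()
    def mpra_context(self, scoring_context):
        contig, _ = scoring_context
        exons = pd.DataFrame([{"gene_id": "g1", "chrom": "chr1",
                               "start": 350, "end": 470}])
        return contig, exons

    def test_native_construct_scores_zero(self, small_cov_model,
                                          mpra_context):
        contig, exons = mpra_context
        native_core = contig[195:305]       # the exact native 110-bp window
        c = vm.MpraConstruct(gene_id="g1", strand="+", offset=700,
                             midpoint=250, window_start=195, window_end=305,
                             sequence=native_core.upper())
        score = vm.mpra_score(small_cov_model,
                              contig.upper(), [c], exons, "chr1")
        assert score.log2fc_single == pytest.approx(0.0, abs=1e-7)

    def test_dual_with_identical_alleles_scores_zero(self, small_cov_model,
                                                     mpra_context):
        contig, exons = mpra_context
        c = vm.MpraConstruct(gene_id="g1", strand="+", offset=700,
                             midpoint=250, window_start=195, window_end=305,
                             sequence=vm.dream_format("ACGT" * 20))
        score = vm.mpra_score(small_cov_model, contig, [c], exons, "chr1",
                              alt_constructs=[c])
        assert score.delta_log2fc_dual == pytest.approx(0.0, abs=1e-9)

    def test_insertion_overlapping_exons_rejected(self, small_cov_model,
                                                  mpra_context):
        contig, exons = mpra_context
        c = vm.MpraConstruct(gene_id="g1", strand="+", offset=100,
                             midpoint=400, window_start=345, window_end=455,
                             sequence=vm.dream_format("ACGT" * 20))
        with pytest.raises(ValueError, match="overlaps"):
            vm.mpra_score(small_cov_model, contig, [c], exons, "chr1")
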