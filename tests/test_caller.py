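"""Caller checks: candidate-region seeding and merging, window planning
arithmetic, haplotype-to-reference variant extraction (validated by a
reconstruction oracle), majority-vote merging against an exhaustive tally,
and feature annotation."""

import itertools

import numpy as np
import pytest

from haplocall.caller import (CandidateRegion, WindowCall,
                              find_candidate_regions, plan_windows,
                              extract_variants, merge_window_calls,
                              annotate_cis_trans, assign_phase_sets,
                              UnalignableHaplotype)
from haplocall.encoder import GenomicWindow
from haplocall.variants import (Variant, HET_HAP0, HET_HAP1, HOM,
                                apply_variants_to_reference,
                                trim_and_left_align)
from tests.test_encoder import make_bam


class TestCandidateRegions:
    def _bam_with_mismatches(self, tmp_path, n_reads, pos=100, ref_len=1000):
        # reference is all-A; reads carry a C at `pos`
        reads = []
        for i in range(n_reads):
            start = pos - 20
            seq = "A" * 20 + "C" + "A" * 19
            reads.append((f"m{i}", start, "40M", seq))
        for i in range(5):
            reads.append((f"c{i}", pos - 30, "60M", "A" * 60))
        return make_bam(tmp_path / "cand.bam", reads, ref_len=ref_len)

    def test_two_supporting_reads_is_no_region(self, tmp_path,
                                               string_reference):
        bam = self._bam_with_mismatches(tmp_path, 2)
        ref = string_reference(chr1="A" * 1000)
        assert find_candidate_regions(bam, ref, "chr1") == []

    def test_three_supporting_reads_padded_region(self, tmp_path,
                                                  string_reference):
        bam = self._bam_with_mismatches(tmp_path, 3)
        ref = string_reference(chr1="A" * 1000)
        regions = find_candidate_regions(bam, ref, "chr1")
        assert len(regions) == 1
        assert (regions[0].start, regions[0].end) == (96, 105)
        assert regions[0].seeds == [100]

    def test_nearby_seeds_merge(self, tmp_path, string_reference):
        reads = []
        for i in range(3):
            reads.append((f"a{i}", 80, "40M", "A" * 20 + "C" + "A" * 19))
            reads.append((f"b{i}", 130, "40M", "A" * 20 + "G" + "A" * 19))
        bam = make_bam(tmp_path / "merge.bam", reads)
        ref = string_reference(chr1="A" * 1000)
        regions = find_candidate_regions(bam, ref, "chr1")
        assert len(regions) == 1
        assert regions[0].seeds == [100, 150]

    def test_empty_input(self, tmp_path, string_reference):
        bam = make_bam(tmp_path / "empty.bam", [("r", 0, "10M", "A" * 10)])
        ref = string_reference(chr1="A" * 1000)
        assert find_candidate_regions(bam, ref, "chr1") == []

    def test_indel_reads_flag_positions(self, tmp_path, string_reference):
        reads = [(f"d{i}", 80, "20M5D20M", "A" * 40) for i in range(3)]
        bam = make_bam(tmp_path / "indel.bam", reads)
        ref = string_reference(chr1="A" * 1000)
        regions = find_candidate_regions(bam, ref, "chr1")
        assert len(regions) == 1
        assert 100 in regions[0].seeds


class TestPlanWindows:
    def test_single_seed_spacing(self):
        region = CandidateRegion("chr1", 996, 1005, seeds=[1000])
        starts = [w.start for w in plan_windows(region)]
        assert starts == [900, 925, 950, 975, 1000]

    def test_near_origin_clamps_to_zero(self):
        region = CandidateRegion("chr1", 46, 55, seeds=[50])
        starts = [w.start for w in plan_windows(region)]
        assert starts[0] == 0
        assert 50 in starts

    def test_step_configurable(self):
        region = CandidateRegion("chr1", 996, 1005, seeds=[1000])
        starts = [w.start for w in plan_windows(region, step=50)]
        assert starts == [900, 950, 1000]

    def test_all_windows_fixed_width(self):
        region = CandidateRegion("chr1", 196, 280, seeds=[200, 275])
        for w in plan_windows(region):
            assert w.width == 150


class TestExtractVariants:
    def _window(self, ref):
        return GenomicWindow("chr1", 0, len(ref))

    def test_identity_haplotype_is_empty(self):
        ref = "ACGTACGTAC"
        assert extract_variants(ref, ref, self._window(ref)) == []

    def test_snv(self):
        ref = "ACGTACGTAC"
        hap = "ACGAACGTAC"
        out = extract_variants(hap, ref, self._window(ref))
        assert len(out) == 1
        v, prob, offset = out[0]
        assert (v.pos, v.ref, v.alt) == (3, "T", "A")
        assert offset == 3

    def test_insertion_left_normalized(self):
        ref = "ACGTACGT"
        hap = "ACGTTTACGT"
        out = extract_variants(hap, ref, self._window(ref))
        assert len(out) == 1
        v = out[0][0]
        assert v.pos + 1 > 0 and len(v.alt) - len(v.ref) == 2
        # re-normalizing is a fixed point
        renorm = trim_and_left_align(v.chrom, v.pos, v.ref, v.alt,
                                     lambda a, b: ref[a:b])
        assert renorm == v

    def test_deletion(self):
        ref = "ACGTGTACCCGTACAAAC"
        hap = "ACGTGTACGTACAAAC"
        out = extract_variants(hap, ref, self._window(ref))
        assert len(out) == 1
        v = out[0][0]
        assert len(v.ref) - len(v.alt) == 2

    def test_kmer_probability_attached(self):
        ref = "A" * 40
        hap = "A" * 20 + "C" + "A" * 19
        probs = np.linspace(0.5, 0.9, 10)
        out = extract_variants(hap, ref, self._window(ref), token_probs=probs)
        v, prob, _ = out[0]
        assert prob == pytest.approx(probs[20 // 4])

    def test_unalignable_haplotype_raises(self):
        ref = "A" * 60
        hap = "CGTCGT" * 10
        with pytest.raises(UnalignableHaplotype):
            extract_variants(hap, ref, self._window(ref))

    def test_reconstruction_oracle_random_edits(self):
        """Applying the extracted variants back to the reference reproduces
        the haplotype (20 random multi-edit cases)."""
        rng = np.random.default_rng(5)
        for _ in range(20):
            core = "".join(rng.choice(list("ACGT"), size=60))
            flank = "".join(rng.choice(list("ACGT"), size=15))
            hap = list(core)
            for _ in range(int(rng.integers(1, 4))):
                op = rng.choice(["sub", "ins", "del"])
                p = int(rng.integers(5, len(hap) - 5))
                if op == "sub":
                    hap[p] = str(rng.choice([b for b in "ACGT"
                                             if b != hap[p]]))
                elif op == "ins":
                    hap.insert(p, str(rng.choice(list("ACGT"))))
                else:
                    del hap[p]
            hap = "".join(hap)
            ref_slice = flank + core + flank
            window = GenomicWindow("chr1", 15, 15 + 60)
            out = extract_variants(hap, ref_slice, window, ref_slice_start=0)
            rebuilt = apply_variants_to_reference(
                ref_slice, 0, [v for v, _, _ in out])
            assert rebuilt == flank + hap + flank


def _wc(variant, genotype, prob=0.9, offset=40, window_index=0):
    return WindowCall(variant=variant, genotype=genotype, kmer_prob=prob,
                      offset=offset, window_index=window_index)


V = Variant("chr1", 500, "A", "G")


class TestMergeWindowCalls:
    def test_majority_het_over_hom(self):
        calls = [[_wc(V, HET_HAP0, window_index=0)],
                 [_wc(V, HET_HAP0, window_index=1)],
                 [_wc(V, HOM, window_index=2)]]
        merged = merge_window_calls(calls)
        assert len(merged) == 1
        assert merged[0].is_het
        assert merged[0].features.het_votes == 2
        assert merged[0].features.hom_votes == 1

    def test_unanimous_unchanged(self):
        calls = [[_wc(V, HOM, window_index=i)] for i in range(3)]
        assert merge_window_calls(calls)[0].genotype == HOM

    def test_tie_breaks_toward_het(self):
        calls = [[_wc(V, HET_HAP1, window_index=0)],
                 [_wc(V, HOM, window_index=1)]]
        assert merge_window_calls(calls)[0].is_het

    def test_single_window_idempotent(self):
        calls = [[_wc(V, HET_HAP1, prob=0.7, offset=30)]]
        merged = merge_window_calls(calls)
        assert merged[0].genotype == HET_HAP1
        assert merged[0].features.window_count == 1
        assert merged[0].features.min_kmer_prob == pytest.approx(0.7)

    def test_kmer_prob_summary_is_min_and_mean(self):
        calls = [[_wc(V, HOM, prob=0.6, window_index=0)],
                 [_wc(V, HOM, prob=0.9, window_index=1)]]
        merged = merge_window_calls(calls)[0]
        assert merged.features.min_kmer_prob == pytest.approx(0.6)
        assert merged.features.mean_kmer_prob == pytest.approx(0.75)

    def test_matches_exhaustive_tally_oracle(self):
        """All genotype-vote configurations of up to 6 windows agree with an
        independent tally (het wins ties; hap0 wins het sub-ties)."""
        labels = [None, HET_HAP0, HET_HAP1, HOM]
        for n_windows in range(1, 7):
            for config in itertools.product(range(4), repeat=n_windows):
                if not any(config):
                    continue
                calls = [[_wc(V, labels[c], window_index=i)] if c else []
                         for i, c in enumerate(config)]
                merged = merge_window_calls(calls)
                het = sum(1 for c in config if c in (1, 2))
                hom = sum(1 for c in config if c == 3)
                if het >= hom:
                    hap0 = sum(1 for c in config if c == 1)
                    hap1 = sum(1 for c in config if c == 2)
                    expected = HET_HAP0 if hap0 >= hap1 else HET_HAP1
                else:
                    expected = HOM
                assert merged[0].genotype == expected, config
                assert merged[0].features.window_count == het + hom


class TestAnnotation:
    def test_cis_trans_symmetry_and_counts(self):
        a = Variant("chr1", 100, "A", "G")
        b = Variant("chr1", 120, "C", "T")
        c = Variant("chr1", 140, "G", "A")
        calls = [
            [_wc(a, HET_HAP0, window_index=0), _wc(b, HET_HAP0, window_index=0),
             _wc(c, HET_HAP1, window_index=0)],
            [_wc(a, HET_HAP0, window_index=1), _wc(b, HET_HAP0, window_index=1)],
        ]
        merged = merge_window_calls(calls)
        annotate_cis_trans(merged, calls)
        by_pos = {m.variant.pos: m for m in merged}
        assert by_pos[100].features.n_cis == 1      # b
        assert by_pos[100].features.n_trans == 1    # c
        assert by_pos[120].features.n_cis == 1
        assert by_pos[140].features.n_trans == 2
        # symmetry: a cis b <=> b cis a
        assert by_pos[120].features.n_trans == 1

    def test_hom_counts_as_cis(self):
        a = Variant("chr1", 100, "A", "G")
        b = Variant("chr1", 120, "C", "T")
        calls = [[_wc(a, HOM, window_index=0), _wc(b, HET_HAP1,
                                                   window_index=0)]]
        merged = merge_window_calls(calls)
        annotate_cis_trans(merged, calls)
        assert all(m.features.n_cis == 1 for m in merged)

    def test_phase_sets_group_het_calls_sharing_windows(self):
        a = Variant("chr1", 100, "A", "G")
        b = Variant("chr1", 120, "C", "T")
        far = Variant("chr1", 5000, "G", "C")
        calls = [
            [_wc(a, HET_HAP0, window_index=0), _wc(b, HET_HAP1,
                                                   window_index=0)],
            [_wc(far, HET_HAP0, window_index=7)],
        ]
        merged = merge_window_calls(calls)
        assign_phase_sets(merged, calls)
        by_pos = {m.variant.pos: m for m in merged}
        assert by_pos[100].phase_set == by_pos[120].phase_set == 101
        assert by_pos[5000].phase_set is None
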