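"""Training-engine checks: labeling precedence, target construction,
read-backed phase resolution against exhaustive enumeration, the
permutation-minimizing loss against a brute-force oracle, and the LR
schedule endpoints."""

import numpy as np
import pytest

from haplocall import nn
from haplocall.encoder import GenomicWindow
from haplocall.model import detokenize, tokenize
from haplocall.training import (LRScheduleConfig, lr_at_step, classify_window,
                                label_regions, build_targets, resolve_phase,
                                permutation_min_loss, RegionDiscarded,
                                PhaseUnresolvableError, TARGET_LENGTH)
from haplocall.variants import Variant, HET_HAP0, HET_HAP1, HOM


def _w(start=0, width=150, chrom="chr1"):
    return GenomicWindow(chrom, start, start + width)


class TestSchedule:
    def test_warmup_reaches_max(self):
        sch = LRScheduleConfig(warmup_steps=100, total_steps=1000)
        assert lr_at_step(100, sch) == pytest.approx(5e-5)

    def test_cosine_ends_at_min(self):
        sch = LRScheduleConfig(warmup_steps=100, total_steps=1000)
        assert lr_at_step(1000, sch) == pytest.approx(1e-5)
        assert lr_at_step(5000, sch) == pytest.approx(1e-5)

    def test_warmup_is_linear_from_near_zero(self):
        sch = LRScheduleConfig(warmup_steps=100, total_steps=1000)
        assert lr_at_step(0, sch) == 0.0
        assert lr_at_step(50, sch) == pytest.approx(2.5e-5)

    def test_fine_tune_endpoints(self):
        sch = LRScheduleConfig.fine_tune(warmup_steps=10, total_steps=100)
        assert lr_at_step(10, sch) == pytest.approx(1e-5)
        assert lr_at_step(100, sch) == pytest.approx(1e-6)

    def test_monotone_decay_after_warmup(self):
        sch = LRScheduleConfig(warmup_steps=10, total_steps=200)
        rates = [lr_at_step(s, sch) for s in range(10, 201)]
        assert all(a >= b for a, b in zip(rates, rates[1:]))


class TestLabeling:
    def test_snv_window(self):
        v = Variant("chr1", 50, "A", "G")
        assert classify_window(_w(), [v]) == "snv"

    def test_two_deletions_is_multi_indel(self):
        vs = [Variant("chr1", 30, "AT", "A"), Variant("chr1", 90, "GC", "G")]
        assert classify_window(_w(), vs) == "multi_indel"

    def test_true_negative(self):
        assert classify_window(_w(), []) == "true_negative"

    def test_precedence_insertion_over_snv(self):
        vs = [Variant("chr1", 30, "A", "G"), Variant("chr1", 90, "G", "GC")]
        assert classify_window(_w(), vs) == "insertion"

    def test_stratification_takes_precedence_below_multi_indel(self):
        vs = [Variant("chr1", 30, "A", "G")]
        assert classify_window(_w(), vs, in_stratification=True) == \
            "low_complexity_or_poor_mappability"

    def test_label_regions_confident_filter(self):
        truth = [(Variant("chr1", 50, "A", "G"), HOM)]
        windows = [_w(0), _w(300)]
        labeled = label_regions(windows, truth,
                                confident_bed=[("chr1", 0, 200)])
        assert len(labeled) == 1
        assert labeled[0][1] == "snv"


class TestBuildTargets:
    def test_no_variants_gives_reference_prefix(self, string_reference):
        ref = string_reference(chr1="ACGT" * 100)
        t0, t1 = build_targets(ref, _w(0), [])
        assert t0 == t1 == ("ACGT" * 100)[:TARGET_LENGTH]

    def test_phased_het_snv_lands_on_its_haplotype(self, string_reference):
        seq = "A" * 400
        ref = string_reference(chr1=seq)
        v = Variant("chr1", 10, "A", "G")
        t0, t1 = build_targets(ref, _w(0), [(v, HET_HAP1)])
        assert t0[10] == "A" and t1[10] == "G"
        assert len(t0) == len(t1) == TARGET_LENGTH

    def test_homozygous_variant_on_both(self, string_reference):
        ref = string_reference(chr1="A" * 400)
        v = Variant("chr1", 10, "A", "C")
        t0, t1 = build_targets(ref, _w(0), [(v, HOM)])
        assert t0[10] == t1[10] == "C"

    def test_deletion_reextends_from_downstream_reference(self,
                                                          string_reference):
        seq = "ACGT" * 100
        ref = string_reference(chr1=seq)
        v = Variant("chr1", 20, seq[20:24], seq[20])  # 3 bp deletion
        t0, t1 = build_targets(ref, _w(0), [(v, HET_HAP0)])
        expected = seq[:21] + seq[24:]
        assert t0 == expected[:TARGET_LENGTH]
        assert t1 == seq[:TARGET_LENGTH]
        assert len(t0) == TARGET_LENGTH

    def test_overlapping_variants_discard_region(self, string_reference):
        ref = string_reference(chr1="A" * 400)
        vs = [(Variant("chr1", 10, "AAAA", "A"), HET_HAP0),
              (Variant("chr1", 12, "A", "C"), HET_HAP0)]
        with pytest.raises(RegionDiscarded):
            build_targets(ref, _w(0), vs)

    def test_straddling_variant_discards_region(self, string_reference):
        ref = string_reference(chr1="A" * 600)
        v = Variant("chr1", 98, "A" * 5, "A")
        with pytest.raises(RegionDiscarded):
            build_targets(ref, _w(100), [(v, HOM)])


def _exhaustive_phase_oracle(ref_seq, span_start, variants, reads, sw_score):
    """Independent enumeration: best total read score over all assignments."""
    from haplocall.variants import apply_variants_to_reference
    best_score, best_assign = None, None
    n = len(variants)
    for code in range(2 ** n):
        assign = [(code >> i) & 1 for i in range(n)]
        h0 = apply_variants_to_reference(
            ref_seq, span_start, [v for v, a in zip(variants, assign) if not a])
        h1 = apply_variants_to_reference(
            ref_seq, span_start, [v for v, a in zip(variants, assign) if a])
        total = sum(max(sw_score(r, h0), sw_score(r, h1)) for r in reads)
        if best_score is None or total > best_score:
            best_score, best_assign = total, assign
    return best_score


def _simple_sw(query, target, match=2, mismatch=-4, gap_open=-6, gap_ext=-1):
    """Plain affine-gap Smith-Waterman, row-vectorized."""
    n, m = len(query), len(target)
    neg = -1e9
    h = np.zeros(m + 1)
    e = np.full(m + 1, neg)
    best = 0.0
    t = np.frombuffer(target.encode(), dtype=np.uint8)
    for i in range(1, n + 1):
        q = query[i - 1].encode()[0]
        sub = np.where(t == q, match, mismatch)
        f = np.full(m + 1, neg)
        h_new = np.zeros(m + 1)
        e = np.maximum(h + gap_open, e + gap_ext)
        diag = h[:-1] + sub
        for j in range(1, m + 1):
            f[j] = max(h_new[j - 1] + gap_open, f[j - 1] + gap_ext)
            h_new[j] = max(0.0, diag[j - 1], e[j], f[j])
        h = h_new
        best = max(best, h.max())
    return best


class TestResolvePhase:
    def test_single_het_assigned_to_hap1(self, string_reference):
        ref = string_reference(chr1="ACGT" * 50)
        v = Variant("chr1", 40, "A", "G")
        assert resolve_phase(ref, _w(0), [v], []) == [(v, HET_HAP1)]

    def test_cis_reads_give_cis_assignment(self, string_reference):
        seq = "ACGTGGCATCGATCAGGCTAACGGTTACGATCAGGATCCAGTTACGGAT" * 3
        ref = string_reference(chr1=seq)
        v1, v2 = Variant("chr1", 20, seq[20], "T"), \
            Variant("chr1", 40, seq[40], "C")
        both = seq[10:20] + "T" + seq[21:40] + "C" + seq[41:60]
        neither = seq[10:60]
        reads = [both] * 6 + [neither] * 6
        phased = dict(resolve_phase(ref, _w(0), [v1, v2], reads))
        assert phased[v1] == phased[v2]

    def test_trans_reads_give_trans_assignment(self, string_reference):
        seq = "ACGTGGCATCGATCAGGCTAACGGTTACGATCAGGATCCAGTTACGGAT" * 3
        ref = string_reference(chr1=seq)
        v1, v2 = Variant("chr1", 20, seq[20], "T"), \
            Variant("chr1", 40, seq[40], "C")
        only1 = seq[10:20] + "T" + seq[21:60]
        only2 = seq[10:40] + "C" + seq[41:60]
        reads = [only1] * 6 + [only2] * 6
        phased = dict(resolve_phase(ref, _w(0), [v1, v2], reads))
        assert phased[v1] != phased[v2]

    def test_distance_limit_raises(self, string_reference):
        ref = string_reference(chr1="A" * 600)
        vs = [Variant("chr1", 10, "A", "G"), Variant("chr1", 250, "A", "C")]
        with pytest.raises(PhaseUnresolvableError):
            resolve_phase(ref, _w(0, width=400), vs, [])

    def test_too_many_unphased_raises(self, string_reference):
        ref = string_reference(chr1="ACGT" * 100)
        vs = [Variant("chr1", 10 + 4 * i, "A", "G") for i in range(5)]
        with pytest.raises(PhaseUnresolvableError):
            resolve_phase(ref, _w(0), vs, [])

    @pytest.mark.parametrize("n_variants", [2, 3])
    def test_matches_exhaustive_enumeration(self, string_reference,
                                            n_variants):
        """resolve_phase attains the same optimal total alignment score as an
        independent exhaustive 2^n enumeration (independent SW scorer)."""
        from haplocall.variants import apply_variants_to_reference
        rng = np.random.default_rng(123 + n_variants)
        for trial in range(25):
            seq = "".join(rng.choice(list("ACGT"), size=90))
            positions = sorted(rng.choice(np.arange(10, 80), size=n_variants,
                                          replace=False).tolist())
            if min(np.diff(positions), default=10) < 3:
                continue
            variants = []
            for p in positions:
                alt = rng.choice([b for b in "ACGT" if b != seq[p]])
                variants.append(Variant("chr1", int(p), seq[p], str(alt)))
            truth_assign = rng.integers(0, 2, size=n_variants)
            h0 = apply_variants_to_reference(
                seq, 0, [v for v, a in zip(variants, truth_assign) if not a])
            h1 = apply_variants_to_reference(
                seq, 0, [v for v, a in zip(variants, truth_assign) if a])
            reads = []
            for hap in (h0, h1):
                for _ in range(4):
                    s = int(rng.integers(0, 30))
                    reads.append(hap[s:s + 55])
            ref = string_reference(chr1=seq)
            phased = dict(resolve_phase(ref, _w(0, width=90), variants, reads))
            got_assign = [1 if phased[v] == HET_HAP1 else 0 for v in variants]
            # compare achieved score against the independent oracle optimum
            g0 = apply_variants_to_reference(
                seq, 0, [v for v, a in zip(variants, got_assign) if not a])
            g1 = apply_variants_to_reference(
                seq, 0, [v for v, a in zip(variants, got_assign) if a])
            got_score = sum(max(_simple_sw(r, g0), _simple_sw(r, g1))
                            for r in reads)
            oracle = _exhaustive_phase_oracle(seq, 0, variants, reads,
                                              _simple_sw)
            assert got_score == pytest.approx(oracle)


class TestPermutationMinLoss:
    def _brute_force(self, l0, l1, t0, t1):
        def ce(lg, tt):
            lg = lg - lg.max(axis=-1, keepdims=True)
            logp = lg - np.log(np.exp(lg).sum(axis=-1, keepdims=True))
            return -logp[np.arange(len(tt)), tt].sum()
        return min(ce(l0, t0) + ce(l1, t1), ce(l0, t1) + ce(l1, t0))

    def test_perfect_swapped_prediction_has_near_zero_loss(self):
        t0 = np.array([3, 7, 200])
        t1 = np.array([9, 0, 31])
        l0 = np.full((3, 256), -30.0)
        l1 = np.full((3, 256), -30.0)
        l0[np.arange(3), t1] = 30.0   # decoder 0 predicts target 1
        l1[np.arange(3), t0] = 30.0
        loss = permutation_min_loss(l0, l1, t0, t1)
        assert loss.item() < 1e-3

    def test_identical_targets_give_equal_configurations(self):
        rng = np.random.default_rng(0)
        l0, l1 = rng.normal(size=(2, 5, 256))
        t = rng.integers(0, 256, size=5)
        a = permutation_min_loss(l0, l1, t, t).item()
        b = permutation_min_loss(l1, l0, t, t).item()
        assert a == pytest.approx(b, rel=1e-5)

    def test_matches_brute_force_on_random_inputs(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            T = int(rng.integers(1, 12))
            l0, l1 = rng.normal(size=(2, T, 256)) * 3
            t0, t1 = rng.integers(0, 256, size=(2, T))
            got = permutation_min_loss(l0, l1, t0, t1).item()
            expect = self._brute_force(l0, l1, t0, t1)
            assert got == pytest.approx(expect, rel=1e-4)

    def test_target_order_invariance(self):
        rng = np.random.default_rng(21)
        for _ in range(200):
            T = int(rng.integers(1, 12))
            l0, l1 = rng.normal(size=(2, T, 256)) * 3
            t0, t1 = rng.integers(0, 256, size=(2, T))
            a = permutation_min_loss(l0, l1, t0, t1).item()
            b = permutation_min_loss(l0, l1, t1, t0).item()
            assert a == pytest.approx(b, rel=1e-5)

    def test_gradients_flow_only_through_minimizing_pairing(self):
        t0 = np.array([[3, 7]])
        t1 = np.array([[9, 0]])
        l0 = nn.Tensor(np.zeros((1, 2, 256), dtype=np.float32),
                       requires_grad=True)
        l1 = nn.Tensor(np.random.default_rng(0).normal(
            size=(1, 2, 256)).astype(np.float32))
        l1.data[0, np.arange(2), t0[0]] = 25.0  # l1 matches t0 strongly
        l1.requires_grad = True
        loss = permutation_min_loss(l0, l1, t0, t1)
        loss.backward()
        # chosen configuration must be the swap: l0 paired with t1
        g = l0.grad[0, 0]
        assert g[9] < 0              # pulls towards t1's first token
        assert g[3] > 0 or abs(g[3]) < abs(g[9])


def test_resume_from_checkpoint_reproduces_training(sim_sample, tmp_path):
    """Resuming from a checkpoint reproduces the continued run's losses bit
    for bit (model, optimizer and RNG state all round-trip)."""
    from haplocall.model import HaplotypeTransformer, PRESETS
    from haplocall.simulator import make_region_suite
    from haplocall.training import train

    examples = make_region_suite(sim_sample, {"true_negative": 12},
                                 max_reads=32, seed=2)
    sched_full = LRScheduleConfig(warmup_steps=2, total_steps=4,
                                  batch_size=4, max_rate=1e-3, min_rate=1e-4)
    straight = train(HaplotypeTransformer(PRESETS["tiny"], seed=9),
                     examples, sched_full, seed=5, eval_every=1)
    sched_half = LRScheduleConfig(warmup_steps=2, total_steps=2,
                                  batch_size=4, max_rate=1e-3, min_rate=1e-4)
    model = HaplotypeTransformer(PRESETS["tiny"], seed=9)
    train(model, examples, sched_half, seed=5, eval_every=1,
          checkpoint_dir=str(tmp_path))
    resumed = train(HaplotypeTransformer(PRESETS["tiny"], seed=1),
                    examples, sched_full, seed=5, eval_every=1,
                    resume_from=str(tmp_path / "checkpoint_0000002.npz"))
    assert [m["train_loss"] for m in straight[2:]] == \
        [m["train_loss"] for m in resumed]
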