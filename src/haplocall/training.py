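"""Training: region labeling, target construction, phase resolution and the
permutation-minimizing loss.

Targets are built by editing each haplotype's truth alleles into the window's
reference sequence and trimming/extending with downstream reference to
exactly 148 bases (37 4-mer tokens).  Because the two haplotypes are an
unordered pair, the loss for a batch is computed for both prediction-target
pairings and only the cheaper pairing receives gradients.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .alignment import local_score
from .encoder import EncodedRegion, GenomicWindow
from .model import (HaplotypeTransformer, tokenize, detokenize,
                    MAX_OUTPUT_TOKENS, KMER_SIZE)
from .variants import (Variant, HET_HAP0, HET_HAP1, HOM,
                       apply_variants_to_reference)

REGION_LABELS = ("snv", "deletion", "insertion", "multi_indel",
                 "low_complexity_or_poor_mappability", "true_negative")

TARGET_LENGTH = MAX_OUTPUT_TOKENS * KMER_SIZE  # 148 bp

PHASE_DISTANCE_LIMIT = 100   # bp; farther apart -> region discarded
MAX_UNPHASED_HETS = 4


class RegionDiscarded(ValueError):
    """Raised when a window cannot yield a consistent training target."""


class PhaseUnresolvableError(RegionDiscarded):
    pass


@dataclass
class TrainingExample:
    region: EncodedRegion
    target0: np.ndarray          # 37 token ids
    target1: np.ndarray
    label: str
    sample_id: str = ""
    ref_seq: str = ""            # window reference (for validation metrics)
    variants: list = field(default_factory=list)  # [(Variant, genotype)]


@dataclass
class LRScheduleConfig:
    """Linear warmup from ~0 to ``max_rate`` then cosine decay to ``min_rate``."""

    warmup_steps: int = 1000
    max_rate: float = 5e-5
    min_rate: float = 1e-5
    total_steps: int = 100_000
    batch_size: int = 512
    adamw_betas: tuple[float, float] = (0.9, 0.99)
    weight_decay: float = 0.01

    def __post_init__(self):
        if self.min_rate >= self.max_rate:
            raise ValueError("min_rate must be below max_rate")

    @classmethod
    def fine_tune(cls, **kw) -> "LRScheduleConfig":
        kw.setdefault("max_rate", 1e-5)
        kw.setdefault("min_rate", 1e-6)
        return cls(**kw)


def lr_at_step(step: int, schedule: LRScheduleConfig) -> float:
    if step < 0:
        raise ValueError("step must be non-negative")
    if step < schedule.warmup_steps:
        return schedule.max_rate * step / max(1, schedule.warmup_steps)
    if step >= schedule.total_steps:
        return schedule.min_rate
    span = max(1, schedule.total_steps - schedule.warmup_steps)
    frac = (step - schedule.warmup_steps) / span
    return schedule.min_rate + 0.5 * (schedule.max_rate - schedule.min_rate) \
        * (1.0 + math.cos(math.pi * frac))


# ---------------------------------------------------------------------------
# region labeling

def classify_window(window: GenomicWindow,
                    variants: list[Variant],
                    in_stratification: bool = False) -> str:
    """Label one window from the truth variants it overlaps."""
    n_indels = sum(1 for v in variants if not v.is_snv)
    if n_indels >= 2:
        return "multi_indel"
    if variants and in_stratification:
        return "low_complexity_or_poor_mappability"
    if any(v.is_insertion for v in variants):
        return "insertion"
    if any(v.is_deletion for v in variants):
        return "deletion"
    if variants:
        return "snv"
    return "true_negative"


def _overlaps(window: GenomicWindow, v: Variant) -> bool:
    return v.chrom == window.chrom and v.pos < window.end \
        and v.pos + len(v.ref) > window.start


def label_regions(windows: list[GenomicWindow],
                  truth: list[tuple[Variant, str]],
                  stratification_beds: list[list[tuple[str, int, int]]] | None = None,
                  confident_bed: list[tuple[str, int, int]] | None = None
                  ) -> list[tuple[GenomicWindow, str]]:
    """Label windows by truth-variant content with the fixed precedence
    multi_indel > low_complexity > insertion > deletion > snv > true_negative.

    Windows not fully inside ``confident_bed`` (when given) are excluded.
    """
    strat = []
    for bed in (stratification_beds or []):
        strat.extend(bed)
    out = []
    for w in windows:
        if confident_bed is not None:
            if not any(c == w.chrom and s <= w.start and w.end <= e
                       for c, s, e in confident_bed):
                continue
        vs = [v for v, _ in truth if _overlaps(w, v)]
        in_strat = any(c == w.chrom and s < w.end and e > w.start
                       for c, s, e in strat) if strat else False
        out.append((w, classify_window(w, vs, in_strat and bool(vs))))
    return out


# ---------------------------------------------------------------------------
# target construction

def build_targets(reference, window: GenomicWindow,
                  phased_variants: list[tuple[Variant, str]],
                  target_length: int = TARGET_LENGTH) -> tuple[str, str]:
    """Build the two 148 bp target haplotype sequences for a window.

    Each haplotype is the reference from ``window.start`` with that
    haplotype's alleles applied, trimmed or extended with downstream
    reference so both targets are exactly ``target_length`` bases.
    Variants straddling the window start, or overlapping on one haplotype,
    discard the region.
    """
    slack = target_length + 80
    ref_seq = reference.fetch(window.chrom, window.start,
                              window.start + slack).upper()
    if len(ref_seq) < target_length:
        raise RegionDiscarded("window too close to the contig end")
    haps = []
    for hap_gts in ((HOM, HET_HAP0), (HOM, HET_HAP1)):
        vs = []
        for v, gt in phased_variants:
            if gt not in hap_gts:
                continue
            if v.pos < window.start and v.pos + len(v.ref) > window.start:
                raise RegionDiscarded(
                    f"variant {v.chrom}:{v.pos} straddles the window start")
            if v.pos < window.start or v.pos >= window.start + slack - 30:
                continue
            vs.append(v)
        try:
            edited = apply_variants_to_reference(ref_seq, window.start, vs)
        except ValueError as exc:
            raise RegionDiscarded(str(exc)) from exc
        if len(edited) < target_length:
            raise RegionDiscarded("deletions exhaust the reference slack")
        haps.append(edited[:target_length])
    return haps[0], haps[1]


# ---------------------------------------------------------------------------
# phase resolution

def resolve_phase(reference, window: GenomicWindow,
                  unphased: list[Variant],
                  read_sequences: list[str],
                  max_unphased: int = MAX_UNPHASED_HETS
                  ) -> list[tuple[Variant, str]]:
    """Assign unphased het variants to haplotypes by read support.

    All 2^n assignments are enumerated; for each, the two candidate
    haplotypes are built and every read is scored against both by
    Smith-Waterman, keeping its best score.  The assignment maximizing the
    total score wins; ties break toward the lexicographically smallest
    (hap0, hap1) sequence pair.  A single het variant is assigned to
    haplotype 1 by convention.
    """
    unphased = sorted(unphased, key=lambda v: v.pos)
    if not unphased:
        return []
    if len(unphased) > max_unphased:
        raise PhaseUnresolvableError(
            f"{len(unphased)} ambiguous het variants exceed the limit")
    for a, b in zip(unphased, unphased[1:]):
        if b.pos - a.pos >= PHASE_DISTANCE_LIMIT:
            raise PhaseUnresolvableError(
                f"variants {a.pos} and {b.pos} are >= "
                f"{PHASE_DISTANCE_LIMIT} bp apart")
    if len(unphased) == 1:
        return [(unphased[0], HET_HAP1)]

    span_start = max(0, unphased[0].pos - 30)
    span_end = unphased[-1].pos + len(unphased[-1].ref) + 30
    ref_seq = reference.fetch(window.chrom, span_start, span_end).upper()

    best = None
    n = len(unphased)
    for code in range(2 ** n):
        assign = [(code >> i) & 1 for i in range(n)]
        hap_vs = ([v for v, a in zip(unphased, assign) if a == 0],
                  [v for v, a in zip(unphased, assign) if a == 1])
        try:
            h0 = apply_variants_to_reference(ref_seq, span_start, hap_vs[0])
            h1 = apply_variants_to_reference(ref_seq, span_start, hap_vs[1])
        except ValueError:
            continue
        total = sum(max(local_score(r, h0), local_score(r, h1))
                    for r in read_sequences)
        key = (-total, h0, h1, assign[0] == 0)
        if best is None or key < best[0]:
            best = (key, assign)
    if best is None:
        raise PhaseUnresolvableError("no consistent haplotype pair")
    return [(v, HET_HAP1 if a else HET_HAP0)
            for v, a in zip(unphased, best[1])]


def examples_from_files(bam_path: str, fasta_path: str, vcf_path: str,
                        confident_bed: list[tuple[str, int, int]] | None = None,
                        max_reads: int = 32, window_size: int = 150,
                        limit: int | None = None, seed: int = 0,
                        sample_id: str = "") -> list[TrainingExample]:
    """Build labeled training examples from standard files.

    Contigs are tiled at ``window_size``; windows are labeled against the
    truth VCF, targets are built from the phased truth (unphased het variants
    are resolved by read-backed enumeration), and the pileup is encoded.
    Windows whose targets cannot be built consistently are skipped.
    """
    import pysam

    from .encoder import encode_region
    from .variants import load_truth_vcf, HET_UNPHASED

    rng = np.random.default_rng(seed)
    truth = load_truth_vcf(vcf_path)
    bam = pysam.AlignmentFile(bam_path)
    ref = pysam.FastaFile(fasta_path)
    examples: list[TrainingExample] = []
    for chrom in bam.references:
        length = bam.get_reference_length(chrom)
        windows = [GenomicWindow(chrom, s, s + window_size)
                   for s in range(0, length - window_size + 1, window_size)]
        for window, label in label_regions(windows, truth,
                                           confident_bed=confident_bed):
            if limit is not None and len(examples) >= limit:
                break
            overlapping = [(v, gt) for v, gt in truth
                           if _overlaps(window, v)]
            unphased = [v for v, gt in overlapping if gt == HET_UNPHASED]
            phased = [(v, gt) for v, gt in overlapping if gt != HET_UNPHASED]
            try:
                if unphased:
                    reads = [r.query_sequence for r in
                             bam.fetch(chrom, window.start, window.end)
                             if r.query_sequence]
                    phased.extend(resolve_phase(ref, window, unphased, reads))
                t0, t1 = build_targets(ref, window, phased)
            except RegionDiscarded:
                continue
            enc = encode_region(bam, ref, window, max_reads=max_reads,
                                seed=int(rng.integers(0, 2 ** 31 - 1)))
            examples.append(TrainingExample(
                region=enc, target0=tokenize(t0), target1=tokenize(t1),
                label=label, sample_id=sample_id,
                ref_seq=ref.fetch(chrom, window.start,
                                  window.start + TARGET_LENGTH + 30),
                variants=phased))
    bam.close()
    ref.close()
    return examples


# ---------------------------------------------------------------------------
# loss

def _seq_ce(logits: nn.Tensor, targets: np.ndarray) -> nn.Tensor:
    b, t, v = logits.shape
    per_tok = nn.cross_entropy_logits(logits.reshape(b * t, v),
                                      np.asarray(targets).reshape(-1))
    return per_tok.reshape(b, t).sum(axis=1)    # [B]


def permutation_min_loss(logits0, logits1, target0, target1) -> nn.Tensor:
    """Order-invariant haplotype-pair loss.

    For each example, cross-entropy is computed for both pairings of the two
    predictions with the two targets and the cheaper pairing is kept:
    ``min(CE(P0,T0)+CE(P1,T1), CE(P0,T1)+CE(P1,T0))``.  Gradients flow only
    through the minimizing configuration.  Returns the batch mean.
    """
    logits0 = logits0 if isinstance(logits0, nn.Tensor) else nn.Tensor(logits0)
    logits1 = logits1 if isinstance(logits1, nn.Tensor) else nn.Tensor(logits1)
    t0 = np.asarray(target0, dtype=np.int64)
    t1 = np.asarray(target1, dtype=np.int64)
    if t0.ndim == 1:
        t0, t1 = t0[None], t1[None]
    if logits0.data.ndim == 2:
        logits0 = logits0.reshape(1, *logits0.shape)
        logits1 = logits1.reshape(1, *logits1.shape)
    if logits0.shape[:2] != t0.shape or logits1.shape[:2] != t1.shape:
        raise ValueError("logit/target shape mismatch")
    straight = _seq_ce(logits0, t0) + _seq_ce(logits1, t1)
    swapped = _seq_ce(logits0, t1) + _seq_ce(logits1, t0)
    pick = (straight.data <= swapped.data).astype(np.float32)
    loss = straight * nn.Tensor(pick) + swapped * nn.Tensor(1.0 - pick)
    return loss.mean()


# ---------------------------------------------------------------------------
# training loop

def _stack(examples: list[TrainingExample], idx) -> tuple[np.ndarray, ...]:
    regions = np.stack([examples[i].region.array for i in idx])
    t0 = np.stack([examples[i].target0 for i in idx])
    t1 = np.stack([examples[i].target1 for i in idx])
    return regions, t0, t1


def evaluate_examples(model: HaplotypeTransformer,
                      examples: list[TrainingExample],
                      max_regions: int = 64) -> dict:
    """Single-window validation metrics: mean base-error rate plus SNV/indel
    sensitivity and precision (a variant counts as found when it appears in
    either decoded haplotype)."""
    from .caller import extract_variants  # deferred: caller imports encoder

    examples = examples[:max_regions]
    if not examples:
        return {}
    regions = np.stack([ex.region.array for ex in examples])
    preds = model.greedy_decode_batch(regions)
    base_errors = []
    tp = {"snv": 0, "indel": 0}
    fp = {"snv": 0, "indel": 0}
    fn = {"snv": 0, "indel": 0}
    for ex, pred in zip(examples, preds):
        t0, t1 = detokenize(ex.target0), detokenize(ex.target1)
        p0, p1 = pred.hap0, pred.hap1
        straight = sum(a != b for a, b in zip(p0, t0)) \
            + sum(a != b for a, b in zip(p1, t1))
        swapped = sum(a != b for a, b in zip(p0, t1)) \
            + sum(a != b for a, b in zip(p1, t0))
        base_errors.append(min(straight, swapped) / (len(t0) + len(t1)))
        truth_keys = {v.key() for v, _ in ex.variants}
        found: set = set()
        for hap in (p0, p1):
            try:
                for var, _prob, _off in extract_variants(
                        hap, ex.ref_seq, ex.region.window,
                        token_probs=None):
                    found.add(var.key())
            except Exception:
                # an unalignable decode finds nothing in this window
                continue
        for k in truth_keys | found:
            klass = "snv" if len(k[2]) == 1 and len(k[3]) == 1 else "indel"
            if k in truth_keys and k in found:
                tp[klass] += 1
            elif k in found:
                fp[klass] += 1
            else:
                fn[klass] += 1
    out = {"base_error_rate": float(np.mean(base_errors))}
    for klass in ("snv", "indel"):
        denom_s = tp[klass] + fn[klass]
        denom_p = tp[klass] + fp[klass]
        out[f"{klass}_sensitivity"] = tp[klass] / denom_s if denom_s else None
        out[f"{klass}_precision"] = tp[klass] / denom_p if denom_p else None
    return out


def train(model: HaplotypeTransformer,
          examples: list[TrainingExample],
          schedule: LRScheduleConfig,
          seed: int = 0,
          val_examples: list[TrainingExample] | None = None,
          eval_every: int | None = None,
          checkpoint_dir: str | None = None,
          metrics_path: str | None = None,
          clip_norm: float = 1.0,
          resume_from: str | None = None) -> list[dict]:
    """Train ``model`` with AdamW and the warmup/cosine schedule.

    Deterministic given ``seed``: batch order, dropout and initialization all
    derive from fixed generators whose states are saved in checkpoints, so a
    resumed run reproduces the original step for step.  Raises on NaN loss.
    """
    if not examples:
        raise ValueError("no training examples")
    opt = nn.AdamW(model.parameters(), lr=schedule.max_rate,
                   betas=schedule.adamw_betas,
                   weight_decay=schedule.weight_decay)
    shuffle_rng = np.random.default_rng(seed)
    step = 0
    perm = np.empty(0, dtype=np.int64)
    pos = 0
    if resume_from:
        step, perm, pos = _load_checkpoint(resume_from, model, opt,
                                           shuffle_rng)
    metrics: list[dict] = []
    log_fh = open(metrics_path, "a") if metrics_path else None
    model.train_mode(True)
    try:
        while step < schedule.total_steps:
            if pos >= len(perm):
                perm = shuffle_rng.permutation(len(examples))
                pos = 0
            idx = perm[pos:pos + schedule.batch_size]
            pos += schedule.batch_size
            regions, t0, t1 = _stack(examples, idx)
            lr = lr_at_step(step, schedule)
            opt.lr = lr
            memory = model.encoder_forward(regions)
            logits0 = model.decoder_forward(memory, 0, t0)
            logits1 = model.decoder_forward(memory, 1, t1)
            # optimize the per-token mean (a pure rescale of the pair loss)
            # so gradient magnitudes are independent of sequence length
            loss = permutation_min_loss(logits0, logits1, t0, t1) \
                * nn.Tensor(1.0 / (2.0 * t0.shape[1]))
            loss_val = loss.item()
            if not math.isfinite(loss_val):
                raise RuntimeError(
                    f"NaN/inf loss at step {step} (lr={lr:.2e}); aborting")
            model.zero_grad()
            loss.backward()
            nn.clip_grad_norm(model.parameters(), clip_norm)
            opt.step()
            step += 1
            record = {"step": step, "lr": lr, "train_loss": loss_val}
            if eval_every and (step % eval_every == 0
                               or step >= schedule.total_steps):
                model.train_mode(False)
                if val_examples:
                    record.update(evaluate_examples(model, val_examples))
                model.train_mode(True)
                if checkpoint_dir:
                    os.makedirs(checkpoint_dir, exist_ok=True)
                    path = os.path.join(checkpoint_dir,
                                        f"checkpoint_{step:07d}.npz")
                    _save_checkpoint(path, model, opt, shuffle_rng, step,
                                     perm, pos)
                    record["checkpoint"] = path
                metrics.append(record)
                if log_fh:
                    log_fh.write(json.dumps(record) + "\n")
                    log_fh.flush()
    finally:
        model.train_mode(False)
        if log_fh:
            log_fh.close()
    return metrics


def _save_checkpoint(path, model, opt, shuffle_rng, step, perm, pos) -> None:
    state = model.state_dict()
    for i, (m, v) in enumerate(zip(opt.m, opt.v)):
        state[f"__adam_m_{i}__"] = m
        state[f"__adam_v_{i}__"] = v
    state["__perm__"] = np.asarray(perm, dtype=np.int64)
    state["__meta__"] = np.frombuffer(json.dumps({
        "step": step, "adam_t": opt.t, "pos": int(pos),
        "shuffle_state": shuffle_rng.bit_generator.state,
        "dropout_state": model._train_rng.bit_generator.state,
        "config": model.config.to_json(),
    }).encode(), dtype=np.uint8)
    np.savez(path, **state)


def _load_checkpoint(path, model, opt, shuffle_rng
                     ) -> tuple[int, np.ndarray, int]:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        model.load_state_dict({k: data[k] for k in data.files
                               if not k.startswith("__")})
        for i in range(len(opt.m)):
            opt.m[i] = data[f"__adam_m_{i}__"].copy()
            opt.v[i] = data[f"__adam_v_{i}__"].copy()
        perm = data["__perm__"].copy()
    opt.t = meta["adam_t"]
    shuffle_rng.bit_generator.state = meta["shuffle_state"]
    model._train_rng.bit_generator.state = meta["dropout_state"]
    return meta["step"], perm, meta["pos"]
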