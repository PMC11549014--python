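"""Accuracy accounting: call matching, per-class summaries and distance-binned
phase precision.

Matching is exact over normalized (chrom, pos, ref, alt): a truth record is a
true positive only when the genotype also agrees; a correct allele with the
wrong genotype is tallied separately as a genotype mismatch.  Phase precision
compares the relative phase (cis/trans) of adjacent same-phase-set het pairs
against the truth, binned by inter-variant distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

from .variants import Variant, VariantCall, HET_HAP0, HET_HAP1, HOM

VARIANT_CLASSES = ("snv", "insertion", "deletion")
INDEL_SIZE_BINS = ((1, 5), (6, 15), (16, None))
PHASE_DISTANCE_BINS = ((1, 24), (25, 49), (50, 100), (101, None))


def genotypes_equivalent(a: str, b: str) -> bool:
    """Genotype equality up to haplotype order (het-hap0 matches het-hap1)."""
    return (a == HOM) == (b == HOM)


def variant_class(v: Variant) -> str:
    if v.is_snv:
        return "snv"
    return "insertion" if v.is_insertion else "deletion"


def indel_size_bin(v: Variant) -> str | None:
    if v.is_snv:
        return None
    size = v.size_change
    for lo, hi in INDEL_SIZE_BINS:
        if size >= lo and (hi is None or size <= hi):
            return f"{lo}-{hi}" if hi is not None else f">{lo - 1}"
    return None


@dataclass
class ClassCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0
    genotype_mismatch: int = 0

    @property
    def sensitivity(self) -> float | None:
        d = self.tp + self.fn
        return self.tp / d if d else None

    @property
    def precision(self) -> float | None:
        d = self.tp + self.fp
        return self.tp / d if d else None

    @property
    def f1(self) -> float | None:
        s, p = self.sensitivity, self.precision
        if s is None or p is None or (s + p) == 0:
            return None
        return 2 * s * p / (s + p)

    def as_dict(self) -> dict:
        return {"tp": self.tp, "fp": self.fp, "fn": self.fn,
                "genotype_mismatch": self.genotype_mismatch,
                "sensitivity": self.sensitivity,
                "precision": self.precision, "f1": self.f1}


@dataclass
class MatchSummary:
    by_class: dict[str, ClassCounts] = field(default_factory=dict)
    by_size: dict[str, ClassCounts] = field(default_factory=dict)
    overall: ClassCounts = field(default_factory=ClassCounts)

    def as_dict(self) -> dict:
        return {"overall": self.overall.as_dict(),
                "by_class": {k: v.as_dict() for k, v in self.by_class.items()},
                "by_size": {k: v.as_dict() for k, v in self.by_size.items()}}


def _in_bed(v: Variant, bed) -> bool:
    return bed is None or any(c == v.chrom and s <= v.pos < e
                              for c, s, e in bed)


def match_calls(calls: list[VariantCall],
                truth: list[tuple[Variant, str]],
                confident_bed: list[tuple[str, int, int]] | None = None
                ) -> MatchSummary:
    """Genotype-aware exact matching of calls against truth records."""
    summary = MatchSummary(
        by_class={k: ClassCounts() for k in VARIANT_CLASSES},
        by_size={f"{lo}-{hi}" if hi else f">{lo - 1}": ClassCounts()
                 for lo, hi in INDEL_SIZE_BINS})

    truth_in = [(v, gt) for v, gt in truth if _in_bed(v, confident_bed)]
    calls_in = [c for c in calls if _in_bed(c.variant, confident_bed)]
    truth_by_key = {v.key(): gt for v, gt in truth_in}
    matched_keys = set()

    def tallies(v: Variant):
        out = [summary.overall, summary.by_class[variant_class(v)]]
        sb = indel_size_bin(v)
        if sb is not None:
            out.append(summary.by_size[sb])
        return out

    for call in calls_in:
        key = call.variant.key()
        gt = truth_by_key.get(key)
        for t in tallies(call.variant):
            if gt is None:
                t.fp += 1
            elif genotypes_equivalent(call.genotype, gt):
                t.tp += 1
            else:
                # wrong genotype: the call is an FP and the truth record
                # stays unmatched (FN), with the mismatch tallied separately
                t.genotype_mismatch += 1
                t.fp += 1
        if gt is not None and genotypes_equivalent(call.genotype, gt):
            matched_keys.add(key)
    for v, _gt in truth_in:
        if v.key() not in matched_keys:
            for t in tallies(v):
                t.fn += 1
    return summary


# ---------------------------------------------------------------------------
# phase precision

@dataclass
class PhaseBinStats:
    bin_label: str
    correct: int = 0
    incorrect: int = 0

    @property
    def precision_percent(self) -> float | None:
        n = self.correct + self.incorrect
        return 100.0 * self.correct / n if n else None

    def as_dict(self) -> dict:
        return {"bin": self.bin_label, "correct": self.correct,
                "incorrect": self.incorrect,
                "precision_percent": self.precision_percent}


def phase_bin_label(distance: int) -> str | None:
    for lo, hi in PHASE_DISTANCE_BINS:
        if distance >= lo and (hi is None or distance <= hi):
            return f"{lo}-{hi}" if hi is not None else f">{lo - 1}"
    return None


def phase_precision_from_counts(correct: int, incorrect: int) -> float:
    """The phase-precision statistic: 100 * correct / (correct + incorrect)."""
    return PhaseBinStats("", correct, incorrect).precision_percent


def _relative_phase(gt_a: str, gt_b: str) -> str | None:
    """cis when both alts sit on the same haplotype, else trans."""
    if HOM in (gt_a, gt_b):
        return None
    return "cis" if gt_a == gt_b else "trans"


def phase_precision(calls: list[VariantCall],
                    truth: list[tuple[Variant, str]],
                    min_quality: float = 10.0) -> list[PhaseBinStats]:
    """Distance-binned concordance of predicted vs truth relative phase.

    Calls below ``min_quality`` are discarded first.  For each adjacent pair
    of het calls in the same phase set, the predicted relative phase
    (cis/trans) is compared to the truth phasing; pairs lacking truth phase
    or with a genotype conflict are discarded.  Bins with no pairs are
    omitted from the result.
    """
    truth_by_key = {v.key(): gt for v, gt in truth}
    stats: dict[str, PhaseBinStats] = {}
    kept = [c for c in calls
            if c.quality >= min_quality and c.is_het
            and c.phase_set is not None]
    by_ps: dict[tuple, list[VariantCall]] = {}
    for c in kept:
        by_ps.setdefault((c.variant.chrom, c.phase_set), []).append(c)
    for members in by_ps.values():
        members.sort(key=lambda c: c.variant.pos)
        for a, b in zip(members, members[1:]):
            gt_a = truth_by_key.get(a.variant.key())
            gt_b = truth_by_key.get(b.variant.key())
            if gt_a is None or gt_b is None:
                continue
            if gt_a == HOM or gt_b == HOM:
                continue  # genotype conflicts with a het call
            pred = _relative_phase(a.genotype, b.genotype)
            ref = _relative_phase(gt_a, gt_b)
            if pred is None or ref is None:
                continue
            distance = b.variant.pos - a.variant.pos
            label = phase_bin_label(max(1, distance))
            if label is None:
                continue
            st = stats.setdefault(label, PhaseBinStats(label))
            if pred == ref:
                st.correct += 1
            else:
                st.incorrect += 1
    order = [f"{lo}-{hi}" if hi else f">{lo - 1}"
             for lo, hi in PHASE_DISTANCE_BINS]
    return [stats[k] for k in order if k in stats]


def evaluation_report(calls, truth, confident_bed=None,
                      min_quality: float = 10.0) -> dict:
    summary = match_calls(calls, truth, confident_bed)
    bins = phase_precision(calls, truth, min_quality=min_quality)
    return {"match": summary.as_dict(),
            "phase": [b.as_dict() for b in bins]}
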