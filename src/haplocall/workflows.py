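"""Desk-scale end-to-end study: simulate, train, calibrate, call, evaluate.

This module wires the whole pipeline together at a size one CPU can handle
in minutes: a ``tiny`` model is trained on a few thousand simulated regions
(50x coverage, 0.1% base error, homozygous SNVs), the quality forest is
calibrated on raw calls from a noisier calibration contig, and accuracy is
measured on a held-out contig through the full six-step calling pipeline at
the default Q10 threshold.
"""

from __future__ import annotations

import logging
import os
import time
from dataclasses import dataclass, field

import numpy as np
import pysam

from .caller import call
from .evaluation import match_calls
from .model import HaplotypeTransformer, PRESETS
from .quality import VariantQualityModel, build_training_set, fit_classifier
from .simulator import SimConfig, SimulatedSample, simulate, make_region_suite
from .training import LRScheduleConfig, train

logger = logging.getLogger(__name__)

#: study conditions for the scaled-down benchmark: 150 bp reads at 50x with
#: 0.1% substitution error and homozygous SNVs at human-like density
TRAIN_SIM = dict(snv_rate=2e-3, ins_rate=0.0, del_rate=0.0,
                 het_fraction=0.0, mean_depth=50.0, base_error_rate=1e-3)
#: calibration uses one contig at the study's own error rate (true calls
#: distributed like the evaluation sample) plus contigs at higher error
#: rates until false-positive raw calls exist for the forest's negative
#: class
CALIBRATION_ERROR_RATES = (TRAIN_SIM["base_error_rate"], 8e-3, 1.5e-2,
                           2.5e-2)

TRAIN_REF_LENGTH = 30_000
HOLDOUT_REF_LENGTH = 20_000
CALIBRATION_REF_LENGTH = 20_000
N_TRAIN_REGIONS = {"snv": 2000, "true_negative": 1000}
TINY_SCHEDULE = dict(warmup_steps=100, total_steps=1200, batch_size=32,
                     max_rate=2e-3, min_rate=2e-4)
#: warm-restart extension rounds when the validation base-error rate has not
#: converged (the copy-circuit bootstrap step varies between runs); bounded
#: so total training time stays predictable
EXTENSION_SCHEDULE = dict(warmup_steps=50, total_steps=700, batch_size=32,
                          max_rate=1.5e-3, min_rate=1.5e-4)
MAX_EXTENSION_ROUNDS = 2
CONVERGED_BASE_ERROR = 0.15


@dataclass
class StudyResult:
    model: HaplotypeTransformer
    classifier: VariantQualityModel
    train_metrics: list[dict]
    holdout: SimulatedSample
    calls_by_quality: dict[float, list] = field(default_factory=dict)
    metrics: dict = field(default_factory=dict)


def _derived_seed(seed: int, salt: int) -> int:
    return int((seed * 1_000_003 + salt) % (2 ** 31 - 1))


def train_tiny_model(workdir: str, seed: int,
                     schedule_overrides: dict | None = None,
                     region_counts: dict[str, int] | None = None
                     ) -> tuple[HaplotypeTransformer, list[dict]]:
    """Simulate a training contig and train a ``tiny`` model on it."""
    cfg = SimConfig(ref_length=TRAIN_REF_LENGTH, seed=_derived_seed(seed, 1),
                    **TRAIN_SIM)
    sample = simulate(cfg)
    sample.write(os.path.join(workdir, "train_sample"))
    counts = dict(region_counts or N_TRAIN_REGIONS)
    examples = make_region_suite(sample, counts, max_reads=32,
                                 seed=_derived_seed(seed, 2))
    logger.info("built %d training regions from %d truth variants",
                len(examples), len(sample.truth))
    val = examples[::15]
    train_set = [e for i, e in enumerate(examples) if i % 15]
    model = HaplotypeTransformer(PRESETS["tiny"], seed=_derived_seed(seed, 3))
    sched = dict(TINY_SCHEDULE)
    sched.update(schedule_overrides or {})
    schedule = LRScheduleConfig(**sched)
    metrics = train(model, train_set, schedule, seed=_derived_seed(seed, 4),
                    val_examples=val[:48],
                    eval_every=max(1, schedule.total_steps // 5))
    rounds = 0
    while metrics[-1].get("base_error_rate", 1.0) > CONVERGED_BASE_ERROR \
            and rounds < MAX_EXTENSION_ROUNDS:
        logger.info("validation base error %.3f after %d rounds; extending",
                    metrics[-1]["base_error_rate"], rounds)
        ext = LRScheduleConfig(**EXTENSION_SCHEDULE)
        metrics += train(model, train_set, ext,
                         seed=_derived_seed(seed, 20 + rounds),
                         val_examples=val[:48],
                         eval_every=max(1, ext.total_steps // 2))
        rounds += 1
    return model, metrics


def calibrate_classifier(model: HaplotypeTransformer, workdir: str,
                         seed: int) -> VariantQualityModel:
    """Fit the quality forest on raw calls from noisy calibration contigs.

    Calibration needs both true and false raw calls; if one contig does not
    supply both classes (a very clean or very broken call set), further
    contigs at increasing error rates are added before giving up.
    """
    raw: list = []
    truth: list = []
    for round_idx, err in enumerate(CALIBRATION_ERROR_RATES):
        sim = dict(TRAIN_SIM, base_error_rate=err)
        cfg = SimConfig(ref_length=CALIBRATION_REF_LENGTH,
                        seed=_derived_seed(seed, 5 + 10 * round_idx), **sim)
        sample = simulate(cfg)
        paths = sample.write(os.path.join(workdir,
                                          f"calibration_sample_{round_idx}"))
        with pysam.AlignmentFile(paths.bam) as bam, \
                pysam.FastaFile(paths.fasta) as fasta:
            raw.extend(call(bam, fasta, sample.chrom, model, classifier=None,
                            min_quality=None,
                            seed=_derived_seed(seed, 6 + 10 * round_idx)))
        truth.extend(sample.truth)
        logger.info("calibration round %d: %d raw calls, %d truth variants",
                    round_idx, len(raw), len(truth))
        X, y = build_training_set(raw, truth)
        # keep adding contigs until both classes are present (round 0 is at
        # the study's own error rate and may legitimately contain no FPs)
        if round_idx >= 1 and len(np.unique(y)) == 2:
            return VariantQualityModel(seed=_derived_seed(seed, 7)).fit(X, y)
    return fit_classifier(raw, truth, seed=_derived_seed(seed, 7))


def run_study(workdir: str, seed: int = 1,
              quality_thresholds: tuple[float, ...] = (0.0, 10.0, 20.0, 30.0),
              schedule_overrides: dict | None = None) -> StudyResult:
    """The full scaled-down benchmark.

    Returns per-threshold call sets on the held-out contig plus a metrics
    dictionary with SNV sensitivity/precision at Q10, the quality-sweep
    results and the training trajectory.
    """
    t0 = time.time()
    model, train_metrics = train_tiny_model(
        workdir, seed, schedule_overrides=schedule_overrides)
    t1 = time.time()
    classifier = calibrate_classifier(model, workdir, seed)
    t2 = time.time()

    holdout_cfg = SimConfig(ref_length=HOLDOUT_REF_LENGTH,
                            seed=_derived_seed(seed, 8), **TRAIN_SIM)
    holdout = simulate(holdout_cfg)
    paths = holdout.write(os.path.join(workdir, "holdout_sample"))

    result = StudyResult(model=model, classifier=classifier,
                         train_metrics=train_metrics, holdout=holdout)
    with pysam.AlignmentFile(paths.bam) as bam, \
            pysam.FastaFile(paths.fasta) as fasta:
        scored = call(bam, fasta, holdout.chrom, model,
                      classifier=classifier, min_quality=None,
                      seed=_derived_seed(seed, 9))
    sweep = {}
    for q in sorted(quality_thresholds):
        kept = [c for c in scored if c.quality >= q]
        result.calls_by_quality[q] = kept
        summary = match_calls(kept, holdout.truth)
        snv = summary.by_class["snv"]
        sweep[q] = {"n_calls": len(kept),
                    "snv_sensitivity": snv.sensitivity,
                    "snv_precision": snv.precision,
                    "snv_f1": snv.f1}
    q10 = sweep.get(10.0, {})
    result.metrics = {
        "n_truth_snvs": sum(1 for v, _ in holdout.truth if v.is_snv),
        "quality_sweep": sweep,
        "snv_sensitivity_q10": q10.get("snv_sensitivity"),
        "snv_precision_q10": q10.get("snv_precision"),
        "snv_f1_q10": q10.get("snv_f1"),
        "final_val_base_error": train_metrics[-1].get("base_error_rate"),
        "timing_s": {"train": round(t1 - t0, 1),
                     "calibrate": round(t2 - t1, 1),
                     "call_eval": round(time.time() - t2, 1)},
    }
    return result
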