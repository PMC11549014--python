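"""Diploid short-read simulator for desk-scale testing and training.

Generates a random reference contig, plants phased SNVs and indels to form
two haplotypes, draws error-bearing fixed-length reads from both haplotypes,
and emits standard files: FASTA (+.fai), VCF (phased GT) and a
coordinate-sorted, indexed BAM whose CIGARs are exact compositions of the
read-to-haplotype and haplotype-to-reference alignments.

The defaults emulate the data regime the caller targets: 150 bp reads at
~50x depth with ~0.1% substitution error, human-like variant density and a
geometric indel length distribution.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pysam

from .variants import (Variant, HET_HAP0, HET_HAP1, HOM,
                       trim_and_left_align, apply_variants_to_reference)

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimConfig:
    """Simulation parameters; rates are per reference base pair."""

    ref_length: int = 20_000
    gc_fraction: float = 0.5
    snv_rate: float = 1e-3
    ins_rate: float = 1e-4
    del_rate: float = 1e-4
    indel_geom_p: float = 0.5     # geometric length distribution parameter
    max_indel: int = 15
    het_fraction: float = 0.5
    read_length: int = 150
    mean_depth: float = 50.0
    base_error_rate: float = 1e-3
    read_indel_rate: float = 0.0  # per-base read insertion/deletion error
    chrom: str = "sim1"
    seed: int = 0

    def __post_init__(self):
        for name in ("snv_rate", "ins_rate", "del_rate", "base_error_rate",
                     "read_indel_rate", "het_fraction", "gc_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")


@dataclass
class SimRead:
    name: str
    haplotype: int
    ref_start: int
    cigartuples: list[tuple[int, int]]
    sequence: str
    qualities: np.ndarray
    reverse: bool


@dataclass
class SamplePaths:
    fasta: str
    vcf: str
    bam: str


@dataclass
class SimulatedSample:
    """A simulated diploid sample held in memory until written to disk."""

    config: SimConfig
    reference: str
    truth: list[tuple[Variant, str]]          # (variant, genotype label)
    haplotypes: tuple[str, str]
    hap_ops: tuple[list, list]                # ref<->hap alignment op lists
    reads: list[SimRead] = field(default_factory=list)
    paths: SamplePaths | None = None

    @property
    def chrom(self) -> str:
        return self.config.chrom

    def truth_variants(self) -> list[Variant]:
        return [v for v, _ in self.truth]

    def write(self, outdir: str) -> SamplePaths:
        os.makedirs(outdir, exist_ok=True)
        fasta = os.path.join(outdir, "ref.fa")
        with open(fasta, "w") as fh:
            fh.write(f">{self.chrom}\n")
            for i in range(0, len(self.reference), 80):
                fh.write(self.reference[i:i + 80] + "\n")
        pysam.faidx(fasta)

        vcf = os.path.join(outdir, "truth.vcf")
        header = pysam.VariantHeader()
        header.add_line(f"##contig=<ID={self.chrom},length={len(self.reference)}>")
        header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,'
                        'Description="Genotype">')
        header.add_sample("SIM")
        with pysam.VariantFile(vcf, "w", header=header) as out:
            for v, gt in sorted(self.truth, key=lambda t: t[0].pos):
                rec = out.new_record(contig=v.chrom, start=v.pos,
                                     alleles=(v.ref, v.alt))
                if gt == HOM:
                    rec.samples["SIM"]["GT"] = (1, 1)
                elif gt == HET_HAP0:
                    rec.samples["SIM"]["GT"] = (1, 0)
                else:
                    rec.samples["SIM"]["GT"] = (0, 1)
                rec.samples["SIM"].phased = True
                out.write(rec)
        vcf_gz = vcf + ".gz"
        pysam.tabix_index(vcf, preset="vcf", force=True)

        bam = os.path.join(outdir, "reads.bam")
        unsorted = os.path.join(outdir, "reads.unsorted.bam")
        header = {"HD": {"VN": "1.6"},
                  "SQ": [{"SN": self.chrom, "LN": len(self.reference)}]}
        with pysam.AlignmentFile(unsorted, "wb", header=header) as out:
            for read in self.reads:
                a = pysam.AlignedSegment()
                a.query_name = read.name
                a.query_sequence = read.sequence
                a.flag = 16 if read.reverse else 0
                a.reference_id = 0
                a.reference_start = read.ref_start
                a.mapping_quality = 60
                a.cigartuples = read.cigartuples
                a.query_qualities = pysam.qualitystring_to_array(
                    "".join(chr(q + 33) for q in read.qualities))
                a.set_tag("HP", read.haplotype)
                out.write(a)
        pysam.sort("-o", bam, unsorted)
        os.remove(unsorted)
        pysam.index(bam)
        self.paths = SamplePaths(fasta=fasta, vcf=vcf_gz, bam=bam)
        return self.paths


# ---------------------------------------------------------------------------
# variant planting

def _random_reference(length: int, gc: float, rng: np.random.Generator) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(_BASES[rng.choice(4, size=length, p=p)])


def _plant_variants(ref: str, cfg: SimConfig,
                    rng: np.random.Generator) -> list[tuple[Variant, str]]:
    length = len(ref)
    occupied = np.zeros(length, dtype=bool)
    occupied[:2] = True
    occupied[-cfg.max_indel - 2:] = True

    def fetch(a, b):
        return ref[a:b]

    def geom_len():
        return int(min(cfg.max_indel, rng.geometric(cfg.indel_geom_p)))

    planted: list[tuple[Variant, str]] = []
    for kind, rate in (("snv", cfg.snv_rate), ("ins", cfg.ins_rate),
                       ("del", cfg.del_rate)):
        n = rng.binomial(length, rate)
        for _ in range(n):
            for _attempt in range(200):
                pos = int(rng.integers(2, length - cfg.max_indel - 2))
                if kind == "snv":
                    span = (pos, pos + 1)
                    refbase = ref[pos]
                    alt = str(rng.choice([b for b in "ACGT" if b != refbase]))
                    raw = (pos, refbase, alt)
                elif kind == "ins":
                    ins = "".join(rng.choice(list("ACGT"), size=geom_len()))
                    raw = (pos, ref[pos], ref[pos] + ins)
                    span = (pos, pos + 1)
                else:
                    ln = geom_len()
                    raw = (pos, ref[pos:pos + 1 + ln], ref[pos])
                    span = (pos, pos + 1 + ln)
                v = trim_and_left_align("", raw[0], raw[1], raw[2], fetch)
                v = Variant(cfg.chrom, v.pos, v.ref, v.alt)
                # pad by 1 bp so anchored representations never touch
                lo = min(span[0], v.pos) - 1
                hi = max(span[1], v.pos + len(v.ref)) + 1
                if not occupied[lo:hi].any():
                    occupied[lo:hi] = True
                    u = rng.random()
                    if u < 1 - cfg.het_fraction:
                        gt = HOM
                    else:
                        gt = HET_HAP0 if rng.random() < 0.5 else HET_HAP1
                    planted.append((v, gt))
                    break
    planted.sort(key=lambda t: t[0].pos)
    return planted


# ---------------------------------------------------------------------------
# haplotype construction and alignment-op bookkeeping
#
# op lists are CIGAR-like tuples over (reference, haplotype):
#   ('M', n) consumes both, ('I', n) haplotype only, ('D', n) reference only.

def _hap_ops(ref: str, variants: list[Variant]) -> tuple[str, list]:
    ops: list[tuple[str, int]] = []
    seq: list[str] = []
    cursor = 0

    def emit(op, n):
        if n <= 0:
            return
        if ops and ops[-1][0] == op:
            ops[-1] = (op, ops[-1][1] + n)
        else:
            ops.append((op, n))

    for v in variants:
        emit("M", v.pos - cursor)
        seq.append(ref[cursor:v.pos])
        a, b = len(v.ref), len(v.alt)
        common = min(a, b)
        emit("M", common)
        seq.append(v.alt[:common])
        if b > a:
            emit("I", b - a)
            seq.append(v.alt[common:])
        elif a > b:
            emit("D", a - b)
        cursor = v.pos + a
    emit("M", len(ref) - cursor)
    seq.append(ref[cursor:])
    return "".join(seq), ops


def _ref_pos_at_hap(ops: list, hap_pos: int) -> tuple[int, int, int]:
    """Locate hap coordinate: returns (ref_pos, op_index, offset_into_op)."""
    ref_pos = 0
    hp = 0
    for i, (op, n) in enumerate(ops):
        consumes_hap = op in ("M", "I")
        consumes_ref = op in ("M", "D")
        if consumes_hap and hp + n > hap_pos:
            off = hap_pos - hp
            return ref_pos + (off if consumes_ref else 0), i, off
        if consumes_hap:
            hp += n
        if consumes_ref:
            ref_pos += n
    raise ValueError("haplotype position beyond alignment")


def _compose(read_ops: list, hap_ops: list, hap_start: int
             ) -> tuple[int, list[tuple[int, int]]]:
    """Compose read->haplotype ops with haplotype->reference ops.

    Returns (reference start, pysam cigartuples).  Read ops: ('M', n) consumes
    read+hap, ('I', n) read only, ('D', n) hap only.
    """
    ref_start, hi, hoff = _ref_pos_at_hap(hap_ops, hap_start)
    # remaining part of current hap op
    hop, hn = hap_ops[hi]
    hn -= hoff
    out: list[tuple[str, int]] = []

    def emit(op, n):
        if n <= 0:
            return
        if out and out[-1][0] == op:
            out[-1] = (op, out[-1][1] + n)
        else:
            out.append((op, n))

    def next_hop():
        nonlocal hi, hop, hn
        hi += 1
        if hi < len(hap_ops):
            hop, hn = hap_ops[hi]
        else:
            hop, hn = "M", 10 ** 9  # pad; reads never run past contig end

    # if the read starts inside a hap insertion, leading bases align to
    # nothing in the reference
    for rop, rn in read_ops:
        if rop == "I":
            emit("I", rn)
            continue
        while rn > 0:
            if hn == 0:
                next_hop()
                continue
            if hop == "D":
                # reference bases absent from the haplotype
                emit("D", hn)
                hn = 0
                continue
            take = min(rn, hn)
            if rop == "M":
                emit("M" if hop == "M" else "I", take)
            else:  # read deletion error: hap consumed, read not
                if hop == "M":
                    emit("D", take)
                # hap insertion skipped by a read deletion: nothing in ref
            rn -= take
            hn -= take
    # trim alignment-invalid leading/trailing ops
    while out and out[0][0] in ("D", "I"):
        op, n = out.pop(0)
        if op == "D":
            ref_start += n
        else:
            out.insert(0, ("S", n))
            break
    while out and out[-1][0] == "D":
        out.pop()
    if out and out[-1][0] == "I":
        out[-1] = ("S", out[-1][1])
    codes = {"M": 0, "I": 1, "D": 2, "S": 4}
    return ref_start, [(codes[op], n) for op, n in out]


def _draw_read(hap_seq: str, hap_start: int, cfg: SimConfig,
               rng: np.random.Generator) -> tuple[str, list, np.ndarray]:
    """Emit read bases walking the haplotype, injecting sequencing errors."""
    seq: list[str] = []
    ops: list[tuple[str, int]] = []

    def emit(op, n=1):
        if ops and ops[-1][0] == op:
            ops[-1] = (op, ops[-1][1] + n)
        else:
            ops.append((op, n))

    hp = hap_start
    while len(seq) < cfg.read_length and hp < len(hap_seq):
        if cfg.read_indel_rate and rng.random() < cfg.read_indel_rate:
            if rng.random() < 0.5:
                seq.append(str(rng.choice(list("ACGT"))))
                emit("I")
            else:
                emit("D")
                hp += 1
            continue
        base = hap_seq[hp]
        if cfg.base_error_rate and rng.random() < cfg.base_error_rate:
            base = str(rng.choice([b for b in "ACGT" if b != base]))
        seq.append(base)
        emit("M")
        hp += 1
    qual_phred = 40 if cfg.base_error_rate <= 0 else int(round(
        -10 * np.log10(cfg.base_error_rate)))
    quals = np.clip(rng.normal(qual_phred, 2, size=len(seq)).round(), 2,
                    60).astype(np.int64)
    return "".join(seq), ops, quals


def simulate(config: SimConfig) -> SimulatedSample:
    """Generate a full diploid sample per ``config`` (deterministic in seed)."""
    rng = np.random.default_rng(config.seed)
    ref = _random_reference(config.ref_length, config.gc_fraction, rng)
    truth = _plant_variants(ref, config, rng)

    hap_variants = (
        [v for v, gt in truth if gt in (HOM, HET_HAP0)],
        [v for v, gt in truth if gt in (HOM, HET_HAP1)],
    )
    hap0, ops0 = _hap_ops(ref, hap_variants[0])
    hap1, ops1 = _hap_ops(ref, hap_variants[1])
    haps = (hap0, hap1)
    hap_ops = (ops0, ops1)

    n_total = int(round(config.mean_depth * config.ref_length
                        / config.read_length))
    reads: list[SimRead] = []
    for i in range(n_total):
        hap_id = int(rng.integers(0, 2))
        hseq = haps[hap_id]
        max_start = max(1, len(hseq) - config.read_length)
        start = int(rng.integers(0, max_start))
        seq, read_ops, quals = _draw_read(hseq, start, config, rng)
        if len(seq) < 30:
            continue
        ref_start, cigar = _compose(read_ops, hap_ops[hap_id], start)
        if not any(op == 0 for op, _ in cigar):
            continue
        reads.append(SimRead(name=f"read{i:06d}", haplotype=hap_id,
                             ref_start=ref_start, cigartuples=cigar,
                             sequence=seq, qualities=quals,
                             reverse=bool(rng.random() < 0.5)))
    return SimulatedSample(config=config, reference=ref, truth=truth,
                           haplotypes=haps, hap_ops=hap_ops, reads=reads)


# ---------------------------------------------------------------------------
# training-region emission

def make_region_suite(sample: SimulatedSample,
                      counts: dict[str, int],
                      max_reads: int = 32,
                      window_size: int = 150,
                      seed: int = 0,
                      sample_id: str = "sim") -> list:
    """Emit labeled training examples from a written simulated sample.

    ``counts`` maps region labels to the number of examples requested, e.g.
    ``{"snv": 800, "true_negative": 800}``.  Variant-bearing windows are
    anchored on truth variants with a random in-window offset; the same
    window can be re-emitted with a fresh read downsampling, so high-coverage
    sites yield many distinct examples.  Windows whose targets cannot be
    built consistently are skipped.
    """
    import pysam

    from .encoder import GenomicWindow, encode_region
    from .model import tokenize
    from .training import (TrainingExample, build_targets, classify_window,
                           RegionDiscarded, TARGET_LENGTH)

    if sample.paths is None:
        raise ValueError("sample must be written to disk first "
                         "(call sample.write(outdir))")
    rng = np.random.default_rng(seed)
    bam = pysam.AlignmentFile(sample.paths.bam)
    ref = pysam.FastaFile(sample.paths.fasta)
    length = len(sample.reference)
    chrom = sample.chrom

    def overlapping(w):
        return [(v, gt) for v, gt in sample.truth
                if v.pos < w.end and v.pos + len(v.ref) > w.start]

    # pool of candidate windows per label
    pool: dict[str, list[GenomicWindow]] = {label: [] for label in counts}
    variant_positions = [v.pos for v, _ in sample.truth]
    for pos in variant_positions:
        for _ in range(4):
            off = int(rng.integers(15, TARGET_LENGTH - 20))
            s = min(max(0, pos - off), length - window_size)
            w = GenomicWindow(chrom, s, s + window_size)
            label = classify_window(w, [v for v, _ in overlapping(w)])
            if label in pool:
                pool[label].append(w)
    if "true_negative" in counts:
        tries = 0
        while len(pool["true_negative"]) < max(
                counts["true_negative"], 1) and tries < 20000:
            tries += 1
            s = int(rng.integers(0, length - window_size))
            w = GenomicWindow(chrom, s, s + window_size)
            if not overlapping(w):
                pool["true_negative"].append(w)

    examples = []
    for label, n in counts.items():
        windows = pool.get(label, [])
        if not windows:
            continue
        i = 0
        emitted = 0
        attempts = 0
        while emitted < n and attempts < 5 * n:
            attempts += 1
            w = windows[i % len(windows)]
            i += 1
            sub_seed = int(rng.integers(0, 2 ** 31 - 1))
            try:
                t0, t1 = build_targets(ref, w, overlapping(w))
            except RegionDiscarded:
                continue
            enc = encode_region(bam, ref, w, max_reads=max_reads,
                                seed=sub_seed)
            examples.append(TrainingExample(
                region=enc, target0=tokenize(t0), target1=tokenize(t1),
                label=label, sample_id=sample_id,
                ref_seq=ref.fetch(chrom, w.start,
                                  w.start + TARGET_LENGTH + 30),
                variants=overlapping(w)))
            emitted += 1
    bam.close()
    ref.close()
    return examples
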