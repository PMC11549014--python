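"""Variant records and VCF-style left normalization.

Positions are 0-based half-open everywhere inside the package; they become
1-based only when records are written to or read from VCF.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

#: genotype labels used throughout the caller
HET_HAP0 = "het-hap0"   # alt on decoded/target haplotype 0
HET_HAP1 = "het-hap1"
HET_UNPHASED = "het"
HOM = "hom"


@dataclass(frozen=True, order=True)
class Variant:
    """A normalized small variant; ``pos`` is 0-based."""

    chrom: str
    pos: int
    ref: str
    alt: str

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def is_insertion(self) -> bool:
        return len(self.alt) > len(self.ref)

    @property
    def is_deletion(self) -> bool:
        return len(self.alt) < len(self.ref)

    @property
    def size_change(self) -> int:
        return abs(len(self.alt) - len(self.ref))

    def key(self) -> tuple:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class CallFeatures:
    """Per-call evidence summaries feeding the quality classifier."""

    window_count: int = 0
    total_windows: int = 0
    n_cis: int = 0
    n_trans: int = 0
    min_kmer_prob: float = 0.0
    mean_kmer_prob: float = 0.0
    mean_window_offset: float = 0.0   # mean |position_in_window - 75|
    het_votes: int = 0
    hom_votes: int = 0
    depth: int = 0
    alt_support: int = 0


@dataclass
class VariantCall:
    """A merged, normalized call ready for VCF emission."""

    variant: Variant
    genotype: str                   # HET_HAP0 / HET_HAP1 / HOM
    features: CallFeatures = field(default_factory=CallFeatures)
    quality: float = 0.0
    phase_set: int | None = None

    @property
    def is_het(self) -> bool:
        return self.genotype != HOM

    def gt_string(self) -> str:
        if self.genotype == HOM:
            return "1|1" if self.phase_set is not None else "1/1"
        if self.phase_set is None:
            return "0/1"
        return "1|0" if self.genotype == HET_HAP0 else "0|1"


def trim_and_left_align(chrom: str, pos: int, ref: str, alt: str,
                        fetch: Callable[[int, int], str]) -> Variant:
    """Normalize a variant: trim shared bases and left-align indels.

    ``fetch(start, end)`` must return reference sequence for ``chrom`` over a
    0-based half-open interval.  The returned record keeps the usual VCF
    anchor-base convention for indels (ref and alt never empty).
    """
    if ref == alt:
        raise ValueError("ref and alt identical; not a variant")
    ref, alt = ref.upper(), alt.upper()
    while True:
        if ref and alt and ref[-1] == alt[-1] \
                and not (len(ref) == 1 and len(alt) == 1):
            ref, alt = ref[:-1], alt[:-1]
            continue
        if (not ref or not alt) and pos > 0:
            base = fetch(pos - 1, pos).upper()
            ref, alt = base + ref, base + alt
            pos -= 1
            continue
        break
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    if not ref or not alt:
        # variant at contig start with nothing to anchor on the left;
        # anchor on the right base instead (rare, VCF-legal)
        base = fetch(pos + len(ref), pos + len(ref) + 1).upper()
        ref, alt = ref + base, alt + base
    return Variant(chrom=chrom, pos=pos, ref=ref, alt=alt)


def normalize_variant(v: Variant, fetch: Callable[[int, int], str]) -> Variant:
    return trim_and_left_align(v.chrom, v.pos, v.ref, v.alt, fetch)


def apply_variants_to_reference(ref_seq: str, ref_start: int,
                                variants: list[Variant]) -> str:
    """Apply non-overlapping variants (0-based, sorted) to a reference slice.

    ``ref_seq`` covers [ref_start, ref_start + len(ref_seq)); variants outside
    the slice are ignored, variants straddling its edge raise.
    """
    out = []
    cursor = 0
    end = ref_start + len(ref_seq)
    for v in sorted(variants, key=lambda x: x.pos):
        if v.pos + len(v.ref) <= ref_start or v.pos >= end:
            continue
        if v.pos < ref_start or v.pos + len(v.ref) > end:
            raise ValueError(f"variant {v} straddles the slice boundary")
        off = v.pos - ref_start
        if off < cursor:
            raise ValueError(f"overlapping variants at {v.chrom}:{v.pos}")
        out.append(ref_seq[cursor:off])
        out.append(v.alt)
        cursor = off + len(v.ref)
    out.append(ref_seq[cursor:])
    return "".join(out)


def load_truth_vcf(path: str) -> list[tuple[Variant, str]]:
    """Read (variant, genotype label) pairs from a single-sample VCF.

    Phased genotypes map 1|0 -> het-hap0 and 0|1 -> het-hap1; unphased
    heterozygotes come back as plain ``het`` for downstream phase resolution.
    """
    import pysam

    out: list[tuple[Variant, str]] = []
    with pysam.VariantFile(path) as vcf:
        sample = list(vcf.header.samples)[0] if list(vcf.header.samples) else None
        for rec in vcf:
            if not rec.alts:
                continue
            alt = rec.alts[0]
            v = Variant(rec.chrom, rec.start, rec.ref.upper(), alt.upper())
            if sample is None:
                out.append((v, HET_UNPHASED))
                continue
            data = rec.samples[sample]
            gt = data.get("GT")
            if gt is None or None in gt:
                continue
            alts = sum(1 for a in gt if a and a > 0)
            if alts == 0:
                continue
            if alts == len(gt):
                out.append((v, HOM))
            elif data.phased:
                out.append((v, HET_HAP0 if gt[0] else HET_HAP1))
            else:
                out.append((v, HET_UNPHASED))
    return out


def load_calls_vcf(path: str) -> list["VariantCall"]:
    """Read emitted calls back (genotype, quality, phase set; features from
    INFO when present)."""
    import pysam

    out: list[VariantCall] = []
    with pysam.VariantFile(path) as vcf:
        samples = list(vcf.header.samples)
        sample = samples[0] if samples else None
        known_info = set(vcf.header.info.keys())

        def info_get(info, key, default):
            # pysam raises on keys absent from the header (e.g. a VCF not
            # produced by this package)
            return info.get(key, default) if key in known_info else default

        for rec in vcf:
            if not rec.alts:
                continue
            v = Variant(rec.chrom, rec.start, rec.ref.upper(),
                        rec.alts[0].upper())
            genotype = HET_UNPHASED
            phase_set = None
            if sample is not None:
                data = rec.samples[sample]
                gt = data.get("GT")
                if gt and None not in gt:
                    alts = sum(1 for a in gt if a and a > 0)
                    if alts == len(gt):
                        genotype = HOM
                    elif data.phased:
                        genotype = HET_HAP0 if gt[0] else HET_HAP1
                phase_set = data.get("PS")
            info = rec.info
            features = CallFeatures(
                window_count=info_get(info, "WC", 0),
                total_windows=info_get(info, "TW", 0),
                n_cis=info_get(info, "NCIS", 0),
                n_trans=info_get(info, "NTRANS", 0),
                min_kmer_prob=info_get(info, "KPMIN", 0.0),
                mean_kmer_prob=info_get(info, "KPMEAN", 0.0),
                mean_window_offset=info_get(info, "WOFF", 0.0),
                het_votes=info_get(info, "HETV", 0),
                hom_votes=info_get(info, "HOMV", 0),
                depth=info_get(info, "DP", 0),
                alt_support=info_get(info, "ALTC", 0))
            out.append(VariantCall(variant=v, genotype=genotype,
                                   features=features,
                                   quality=rec.qual or 0.0,
                                   phase_set=phase_set))
    return out
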