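"""The six-step variant detection pipeline.

1. Scan alignments for candidate positions (>=3 reads differing from the
   reference), pad by 4 bp and merge regions closer than 100 bp.
2. Plan overlapping 150 bp model windows at a 25 bp step, starting 100 bases
   upstream of the first candidate position.
3. Greedily decode two haplotypes per window and align each to the reference;
   mismatches and gaps become normalized variant calls.
4. Merge per-window calls with a majority-rules genotype vote.
5. Annotate evidence features (window counts, cis/trans, token probabilities,
   window offsets, depth and allele support).
6. Score each call with the quality classifier and filter on phred quality.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .alignment import align_glocal, MATCH
from .encoder import GenomicWindow, encode_region, DEFAULT_WINDOW_SIZE
from .variants import (Variant, VariantCall, CallFeatures,
                       HET_HAP0, HET_HAP1, HOM, trim_and_left_align)

logger = logging.getLogger(__name__)

MIN_SEED_SUPPORT = 3
SEED_PADDING = 4
REGION_MERGE_DISTANCE = 100
WINDOW_STEP = 25
UPSTREAM_OFFSET = 100
REFERENCE_SLACK = 30
DEFAULT_MIN_QUALITY = 10.0


class UnalignableHaplotype(ValueError):
    pass


@dataclass
class CandidateRegion:
    chrom: str
    start: int
    end: int
    seeds: list[int] = field(default_factory=list)


@dataclass
class WindowCall:
    """One variant observed in one decoded window."""

    variant: Variant
    genotype: str           # HET_HAP0 / HET_HAP1 / HOM
    kmer_prob: float
    offset: int             # variant position within the window
    window_index: int = 0


# ---------------------------------------------------------------------------
# step 1: candidate regions

def find_candidate_regions(alignment_source, reference, chrom: str,
                           start: int = 0, end: int | None = None,
                           min_support: int = MIN_SEED_SUPPORT,
                           padding: int = SEED_PADDING,
                           merge_distance: int = REGION_MERGE_DISTANCE
                           ) -> list[CandidateRegion]:
    """Flag positions where >= ``min_support`` reads differ from the reference
    (mismatch or indel), pad seeds and merge nearby seeds into regions."""
    if end is None:
        end = alignment_source.get_reference_length(chrom)
    counts = np.zeros(end - start, dtype=np.int32)
    ref_cache: dict[tuple[int, int], str] = {}

    def ref_slice(a, b):
        key = (a, b)
        if key not in ref_cache:
            ref_cache[key] = reference.fetch(chrom, a, b).upper()
        return ref_cache[key]

    def bump(pos):
        if start <= pos < end:
            counts[pos - start] += 1

    for read in alignment_source.fetch(chrom, start, end):
        if read.is_unmapped or read.is_secondary or read.is_supplementary \
                or not read.cigartuples:
            continue
        seq = read.query_sequence or ""
        rp, qp = read.reference_start, 0
        for op, n in read.cigartuples:
            if op in (0, 7, 8):
                ref = ref_slice(rp, rp + n)
                for k in range(n):
                    if k < len(ref) and seq[qp + k].upper() != ref[k]:
                        bump(rp + k)
                rp += n
                qp += n
            elif op == 1:       # insertion: flag the anchor position
                bump(rp - 1)
                qp += n
            elif op in (2, 3):  # deletion: flag every deleted position
                for k in range(n):
                    bump(rp + k)
                rp += n
            elif op == 4:
                qp += n
    seeds = (np.nonzero(counts >= min_support)[0] + start).tolist()
    if not seeds:
        return []
    regions: list[CandidateRegion] = []
    for seed in seeds:
        lo = max(0, seed - padding)
        hi = seed + padding + 1
        if regions and lo - regions[-1].end < merge_distance:
            regions[-1].end = max(regions[-1].end, hi)
            regions[-1].seeds.append(seed)
        else:
            regions.append(CandidateRegion(chrom, lo, hi, [seed]))
    return regions


# ---------------------------------------------------------------------------
# step 2: window planning

def plan_windows(region: CandidateRegion,
                 window_size: int = DEFAULT_WINDOW_SIZE,
                 step: int = WINDOW_STEP,
                 upstream: int = UPSTREAM_OFFSET) -> list[GenomicWindow]:
    """Overlapping windows covering the region: the first starts ``upstream``
    bases before the first seed, subsequent starts advance by ``step`` until a
    start passes the last seed.  Starts clamp to 0."""
    if not region.seeds:
        raise ValueError("candidate region has no seed positions")
    first, last = min(region.seeds), max(region.seeds)
    starts = []
    s = first - upstream
    while s <= last:
        starts.append(max(0, s))
        s += step
    seen = set()
    out = []
    for s in starts:
        if s not in seen:
            seen.add(s)
            out.append(GenomicWindow(region.chrom, s, s + window_size))
    return out


# ---------------------------------------------------------------------------
# step 3: haplotype-to-reference variant extraction

def extract_variants(hap_seq: str, ref_slice: str, window: GenomicWindow,
                     token_probs: np.ndarray | None = None,
                     ref_slice_start: int | None = None,
                     min_score_fraction: float = 0.3
                     ) -> list[tuple[Variant, float, int]]:
    """Align a decoded haplotype to the reference and harvest variants.

    Returns (normalized variant, probability of the 4-mer token containing
    the variant bases, position within the window) triples.  Raises
    ``UnalignableHaplotype`` when the alignment score falls below
    ``min_score_fraction`` of a perfect match.
    """
    if ref_slice_start is None:
        ref_slice_start = window.start
    core_start = window.start - ref_slice_start
    if core_start < 0:
        raise ValueError("reference slice must not begin after the window")
    hap_seq = hap_seq.upper()
    ref_slice = ref_slice.upper()
    # the decoded haplotype starts at the window's first column, so the
    # alignment target starts there too; the wider slice provides left
    # context for indel anchoring and normalization only
    core = ref_slice[core_start:]
    if hap_seq == core[:len(hap_seq)]:
        return []
    aln = align_glocal(hap_seq, core)
    if aln.score < min_score_fraction * MATCH * len(hap_seq):
        raise UnalignableHaplotype(
            f"haplotype aligns at score {aln.score:.0f} in window "
            f"{window.chrom}:{window.start}")

    def fetch(a, b):
        return ref_slice[a:b]

    def tok_prob(q_pos):
        if token_probs is None:
            return 1.0
        idx = min(q_pos // 4, len(token_probs) - 1)
        return float(token_probs[idx])

    out: list[tuple[Variant, float, int]] = []
    for event in aln.walk():
        if event[0] == "X":
            _, t_pos, q_pos = event
            p = t_pos + core_start
            raw = (p, ref_slice[p], hap_seq[q_pos])
            prob = tok_prob(q_pos)
        elif event[0] == "I":
            _, t_pos, q_start, q_end = event
            p = t_pos + core_start
            if p == 0:
                logger.debug("dropping unanchorable insertion at slice start")
                continue
            raw = (p - 1, ref_slice[p - 1],
                   ref_slice[p - 1] + hap_seq[q_start:q_end])
            prob = tok_prob(q_start)
        else:  # deletion
            _, t_start, t_end, q_pos = event
            p = t_start + core_start
            if p == 0:
                logger.debug("dropping unanchorable deletion at slice start")
                continue
            raw = (p - 1, ref_slice[p - 1:t_end + core_start],
                   ref_slice[p - 1])
            prob = tok_prob(min(q_pos, len(hap_seq) - 1))
        norm = trim_and_left_align(window.chrom, raw[0], raw[1], raw[2], fetch)
        variant = Variant(window.chrom, norm.pos + ref_slice_start,
                          norm.ref, norm.alt)
        out.append((variant, prob, variant.pos - window.start))
    return out


def window_calls_from_prediction(prediction, window: GenomicWindow,
                                 ref_slice: str, ref_slice_start: int,
                                 window_index: int = 0) -> list[WindowCall]:
    """Convert a two-haplotype prediction into per-window calls.

    A variant present on one decoded haplotype is a heterozygous observation
    for that haplotype; present on both, a homozygous one.
    """
    per_hap: list[dict] = []
    for hap_seq, probs in ((prediction.hap0, prediction.token_probs0),
                           (prediction.hap1, prediction.token_probs1)):
        found = {}
        for variant, prob, offset in extract_variants(
                hap_seq, ref_slice, window, token_probs=probs,
                ref_slice_start=ref_slice_start):
            found[variant.key()] = (variant, prob, offset)
        per_hap.append(found)
    calls = []
    for key in sorted(set(per_hap[0]) | set(per_hap[1])):
        in0, in1 = key in per_hap[0], key in per_hap[1]
        variant, prob, offset = per_hap[0].get(key) or per_hap[1].get(key)
        if in0 and in1:
            genotype = HOM
            prob = min(per_hap[0][key][1], per_hap[1][key][1])
        else:
            genotype = HET_HAP0 if in0 else HET_HAP1
        calls.append(WindowCall(variant=variant, genotype=genotype,
                                kmer_prob=prob, offset=offset,
                                window_index=window_index))
    return calls


# ---------------------------------------------------------------------------
# steps 4-5: merging and feature annotation

def merge_window_calls(per_window_calls: list[list[WindowCall]],
                       windows: list[GenomicWindow] | None = None
                       ) -> list[VariantCall]:
    """Merge calls across overlapping windows by majority genotype vote.

    Ties between heterozygous and homozygous votes break toward
    heterozygous.  Variants seen in a minority of their covering windows are
    retained; the vote counts land in the call's features for the quality
    classifier to weigh.
    """
    by_key: dict[tuple, list[WindowCall]] = {}
    for calls in per_window_calls:
        for c in calls:
            by_key.setdefault(c.variant.key(), []).append(c)
    merged = []
    for key in sorted(by_key):
        obs = by_key[key]
        variant = obs[0].variant
        het_votes = sum(1 for c in obs if c.genotype != HOM)
        hom_votes = sum(1 for c in obs if c.genotype == HOM)
        if het_votes >= hom_votes:
            hap0 = sum(1 for c in obs if c.genotype == HET_HAP0)
            hap1 = sum(1 for c in obs if c.genotype == HET_HAP1)
            genotype = HET_HAP0 if hap0 >= hap1 else HET_HAP1
        else:
            genotype = HOM
        probs = [c.kmer_prob for c in obs]
        offsets = [abs(c.offset - 75) for c in obs]
        total = len(per_window_calls)
        if windows is not None:
            total = sum(1 for w in windows
                        if w.start <= variant.pos < w.end)
        features = CallFeatures(
            window_count=len(obs), total_windows=max(total, len(obs)),
            min_kmer_prob=float(min(probs)),
            mean_kmer_prob=float(np.mean(probs)),
            mean_window_offset=float(np.mean(offsets)),
            het_votes=het_votes, hom_votes=hom_votes)
        merged.append(VariantCall(variant=variant, genotype=genotype,
                                  features=features))
    return merged


def _haps_of(call: WindowCall) -> set[int]:
    if call.genotype == HOM:
        return {0, 1}
    return {0} if call.genotype == HET_HAP0 else {1}


def annotate_cis_trans(merged: list[VariantCall],
                       per_window_calls: list[list[WindowCall]]) -> None:
    """Count, for each merged call, other region variants in cis and trans
    from co-occurrence on the same or opposite decoded haplotype."""
    presence: dict[tuple, dict[int, set[int]]] = {}
    for calls in per_window_calls:
        for c in calls:
            presence.setdefault(c.variant.key(), {})[c.window_index] = _haps_of(c)
    keys = [m.variant.key() for m in merged]
    for i, call in enumerate(merged):
        n_cis = n_trans = 0
        mine = presence.get(keys[i], {})
        for j, other in enumerate(merged):
            if i == j:
                continue
            theirs = presence.get(keys[j], {})
            shared = set(mine) & set(theirs)
            if not shared:
                continue
            cis_votes = sum(1 for w in shared if mine[w] & theirs[w])
            trans_votes = len(shared) - cis_votes
            if cis_votes >= trans_votes:
                n_cis += 1
            else:
                n_trans += 1
        call.features.n_cis = n_cis
        call.features.n_trans = n_trans


def assign_phase_sets(merged: list[VariantCall],
                      per_window_calls: list[list[WindowCall]]) -> None:
    """Group het calls that share a window into phase sets.

    Variants in a shared phase set carry phased genotypes (1|0 / 0|1 by their
    majority haplotype assignment); the set id is the 1-based position of the
    group's first variant, following VCF PS convention.
    """
    windows_of: dict[tuple, set[int]] = {}
    for calls in per_window_calls:
        for c in calls:
            windows_of.setdefault(c.variant.key(), set()).add(c.window_index)
    hets = [m for m in merged if m.is_het]
    # union-find over shared windows
    comp: dict[int, int] = {i: i for i in range(len(hets))}

    def find(i):
        while comp[i] != i:
            comp[i] = comp[comp[i]]
            i = comp[i]
        return i

    for i in range(len(hets)):
        for j in range(i + 1, len(hets)):
            if windows_of.get(hets[i].variant.key(), set()) \
                    & windows_of.get(hets[j].variant.key(), set()):
                comp[find(i)] = find(j)
    groups: dict[int, list[VariantCall]] = {}
    for i, m in enumerate(hets):
        groups.setdefault(find(i), []).append(m)
    for members in groups.values():
        if len(members) < 2:
            continue
        ps = min(m.variant.pos for m in members) + 1
        for m in members:
            m.phase_set = ps


def annotate_support(merged: list[VariantCall], alignment_source) -> None:
    """Fill read depth and alt-supporting read counts from the pileup."""
    for call in merged:
        v = call.variant
        depth = 0
        support = 0
        for read in alignment_source.fetch(v.chrom, v.pos, v.pos + 1):
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            depth += 1
            seq = read.query_sequence or ""
            rp, qp = read.reference_start, 0
            for op, n in read.cigartuples or []:
                if op in (0, 7, 8):
                    if rp <= v.pos < rp + n:
                        if v.is_snv and seq[qp + v.pos - rp].upper() == v.alt:
                            support += 1
                        elif not v.is_snv:
                            # indel support: an I/D adjacent to the anchor
                            pass
                    rp += n
                    qp += n
                elif op == 1:
                    if v.is_insertion and rp - 1 == v.pos:
                        support += 1
                    qp += n
                elif op in (2, 3):
                    if v.is_deletion and rp - 1 == v.pos:
                        support += 1
                    rp += n
                elif op == 4:
                    qp += n
        call.features.depth = depth
        call.features.alt_support = support


# ---------------------------------------------------------------------------
# step 6 + orchestration

def call_region(alignment_source, reference, region: CandidateRegion,
                model, seed: int = 0, decode_batch: int = 64
                ) -> list[VariantCall]:
    """Steps 2-5 for one candidate region (no quality filtering)."""
    cfg = model.config
    windows = plan_windows(region, window_size=cfg.window_size)
    arrays = []
    slices = []
    for w in windows:
        enc = encode_region(alignment_source, reference, w,
                            max_reads=cfg.max_reads, seed=seed)
        arrays.append(enc.array)
        s0 = max(0, w.start - REFERENCE_SLACK)
        slices.append((reference.fetch(w.chrom, s0,
                                       w.end + REFERENCE_SLACK), s0))
    preds = []
    for i in range(0, len(arrays), decode_batch):
        preds.extend(model.greedy_decode_batch(np.stack(arrays[i:i + decode_batch])))
    per_window_calls: list[list[WindowCall]] = []
    for wi, (w, pred, (ref_slice, s0)) in enumerate(zip(windows, preds, slices)):
        try:
            per_window_calls.append(window_calls_from_prediction(
                pred, w, ref_slice, s0, window_index=wi))
        except UnalignableHaplotype as exc:
            logger.warning("skipping window: %s", exc)
            per_window_calls.append([])
    merged = merge_window_calls(per_window_calls, windows=windows)
    annotate_cis_trans(merged, per_window_calls)
    assign_phase_sets(merged, per_window_calls)
    annotate_support(merged, alignment_source)
    return merged


def call(alignment_source, reference, chrom: str, model,
         classifier=None, min_quality: float | None = DEFAULT_MIN_QUALITY,
         start: int = 0, end: int | None = None, seed: int = 0
         ) -> list[VariantCall]:
    """Run the full six-step pipeline over one contig span.

    Without a classifier, raw (unfiltered, quality-0) calls are returned —
    the form consumed by classifier calibration.  A failing region is logged
    and skipped; it never aborts the run.
    """
    regions = find_candidate_regions(alignment_source, reference, chrom,
                                     start=start, end=end)
    out: list[VariantCall] = []
    for region in regions:
        try:
            out.extend(call_region(alignment_source, reference, region,
                                   model, seed=seed))
        except Exception:
            logger.exception("region %s:%d-%d failed; skipping",
                             region.chrom, region.start, region.end)
    # windows of adjacent regions can overlap: keep one record per variant,
    # preferring the better-supported observation
    best: dict[tuple, VariantCall] = {}
    for c in out:
        key = c.variant.key()
        if key not in best or c.features.window_count > \
                best[key].features.window_count:
            best[key] = c
    out = list(best.values())
    if classifier is not None:
        for c in out:
            p = classifier.score(c)
            c.quality = classifier.prob_to_phred(p)
    if min_quality is not None and classifier is not None:
        out = [c for c in out if c.quality >= min_quality]
    out.sort(key=lambda c: (c.variant.chrom, c.variant.pos, c.variant.ref,
                            c.variant.alt))
    return out


# ---------------------------------------------------------------------------
# VCF output

VCF_INFO_FIELDS = [
    ("WC", "Integer", "Windows containing the call"),
    ("TW", "Integer", "Windows covering the site"),
    ("NCIS", "Integer", "Other region variants in cis"),
    ("NTRANS", "Integer", "Other region variants in trans"),
    ("KPMIN", "Float", "Minimum k-mer token probability"),
    ("KPMEAN", "Float", "Mean k-mer token probability"),
    ("WOFF", "Float", "Mean |window offset - 75|"),
    ("HETV", "Integer", "Heterozygous genotype votes"),
    ("HOMV", "Integer", "Homozygous genotype votes"),
    ("DP", "Integer", "Read depth at the site"),
    ("ALTC", "Integer", "Alt-supporting reads"),
]


def write_vcf(calls: list[VariantCall], reference, path: str,
              sample_name: str = "SAMPLE") -> str:
    import pysam

    header = pysam.VariantHeader()
    header.add_line("##source=haplocall")
    for contig, length in zip(reference.references, reference.lengths):
        header.add_line(f"##contig=<ID={contig},length={length}>")
    for name, typ, desc in VCF_INFO_FIELDS:
        header.add_line(f'##INFO=<ID={name},Number=1,Type={typ},'
                        f'Description="{desc}">')
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_line('##FORMAT=<ID=PS,Number=1,Type=Integer,'
                    'Description="Phase set">')
    header.add_sample(sample_name)
    with pysam.VariantFile(path, "w", header=header) as out:
        for c in sorted(calls, key=lambda c: (c.variant.chrom, c.variant.pos)):
            v = c.variant
            rec = out.new_record(contig=v.chrom, start=v.pos,
                                 alleles=(v.ref, v.alt))
            rec.qual = round(float(c.quality), 2)
            f = c.features
            rec.info.update({
                "WC": f.window_count, "TW": f.total_windows,
                "NCIS": f.n_cis, "NTRANS": f.n_trans,
                "KPMIN": f.min_kmer_prob, "KPMEAN": f.mean_kmer_prob,
                "WOFF": f.mean_window_offset, "HETV": f.het_votes,
                "HOMV": f.hom_votes, "DP": f.depth, "ALTC": f.alt_support,
            })
            sample = rec.samples[sample_name]
            if c.genotype == HOM:
                sample["GT"] = (1, 1)
                sample.phased = c.phase_set is not None
            elif c.phase_set is not None:
                sample["GT"] = (1, 0) if c.genotype == HET_HAP0 else (0, 1)
                sample.phased = True
                sample["PS"] = c.phase_set
            else:
                sample["GT"] = (0, 1)
                sample.phased = False
            out.write(rec)
    return path
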