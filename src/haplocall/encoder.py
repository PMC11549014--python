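"""Encode aligned reads over a genomic window into the model's input tensor.

Each window of ``window_size`` (default 150) reference positions becomes an
array of shape [g, r, 10]: g positions, r read rows with the reference in
row 0, and a 10-feature vector per (position, read) cell:

    one-hot base (4) | base qual / 100 | consumes-reference | consumes-read |
    reverse strand | clipped read | mapping qual / 100

Cells with no aligned base stay all-zero.  The reference row carries a base
quality of 1.0 (phred 100 scaled) and no flags.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

N_FEATURES = 10
DEFAULT_WINDOW_SIZE = 150
DEFAULT_MAX_READS = 150
_BASE_CODES = {"A": 0, "C": 1, "G": 2, "T": 3}


class ContigNotFoundError(KeyError):
    pass


class EncodingError(ValueError):
    pass


@dataclass(frozen=True, order=True)
class GenomicWindow:
    """A 0-based half-open reference interval of fixed width."""

    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if self.start < 0:
            raise ValueError("window start must be >= 0")
        if self.end <= self.start:
            raise ValueError("window end must exceed start")

    @property
    def width(self) -> int:
        return self.end - self.start


@dataclass
class ReadEvent:
    """One CIGAR-derived per-column event of a read."""

    kind: str               # 'aligned' | 'deletion' | 'insertion'
    base: str | None        # None for deletions
    base_qual: int
    reverse: bool
    clipped: bool
    mapq: int


@dataclass
class EncodedRegion:
    window: GenomicWindow
    array: np.ndarray                       # [g, r, 10] float32
    read_ids: list[str] = field(default_factory=list)


def base_features(event: ReadEvent) -> np.ndarray:
    """Encode one read event as the 10-feature vector."""
    out = np.zeros(N_FEATURES, dtype=np.float32)
    if event.kind not in ("aligned", "deletion", "insertion"):
        raise EncodingError(f"unknown event kind {event.kind!r}")
    if event.kind != "deletion":
        base = (event.base or "").upper()
        if base in _BASE_CODES:
            out[_BASE_CODES[base]] = 1.0
        elif base != "N":
            raise EncodingError(f"unsupported base {base!r}")
        # N: one-hot left all-zero, flags still set
        out[4] = min(event.base_qual, 100) / 100.0
    out[5] = 1.0 if event.kind in ("aligned", "deletion") else 0.0  # consumes ref
    out[6] = 1.0 if event.kind in ("aligned", "insertion") else 0.0  # consumes read
    out[7] = 1.0 if event.reverse else 0.0
    out[8] = 1.0 if event.clipped else 0.0
    out[9] = min(event.mapq, 100) / 100.0
    return out


def reference_row(ref_seq: str, width: int) -> np.ndarray:
    """Feature rows for the reference: quality 1.0, no flags set."""
    row = np.zeros((width, N_FEATURES), dtype=np.float32)
    for i, base in enumerate(ref_seq[:width].upper()):
        code = _BASE_CODES.get(base)
        if code is not None:
            row[i, code] = 1.0
        row[i, 4] = 1.0
    # positions past the fetched reference (contig end) stay all-zero
    row[len(ref_seq):, 4] = 0.0
    return row


def _window_rng(window: GenomicWindow, seed: int) -> np.random.Generator:
    return np.random.default_rng(
        [seed & 0x7FFFFFFF, zlib.crc32(window.chrom.encode()) & 0x7FFFFFFF,
         window.start, window.end])


def extract_reads(alignment_source, window: GenomicWindow,
                  max_reads: int = DEFAULT_MAX_READS, seed: int = 0) -> list:
    """Fetch reads overlapping ``window``, sorted by first aligned position.

    If more than ``max_reads - 1`` reads overlap (row 0 is the reference),
    they are uniformly downsampled with an RNG keyed by (window, seed), so
    repeated calls are reproducible.  Unmapped and secondary records are
    skipped.
    """
    if window.chrom not in alignment_source.references:
        raise ContigNotFoundError(window.chrom)
    if not alignment_source.has_index():
        raise OSError("alignment source must be indexed")
    reads = [r for r in alignment_source.fetch(window.chrom, window.start,
                                               window.end)
             if not r.is_unmapped and not r.is_secondary
             and not r.is_supplementary and r.cigartuples]
    reads.sort(key=lambda r: (r.reference_start, r.query_name))
    cap = max_reads - 1
    if len(reads) > cap:
        rng = _window_rng(window, seed)
        keep = np.sort(rng.choice(len(reads), size=cap, replace=False))
        reads = [reads[i] for i in keep]
    return reads


def read_events_by_column(read, window: GenomicWindow) -> dict[int, ReadEvent]:
    """Walk a read's CIGAR and produce one event per window column.

    Per column the read either contributes an aligned base or a deletion
    mark; when an insertion immediately follows a column, the event for that
    column is replaced by the insertion's first base (consumes-reference=0) —
    the generative decoder reconstructs the full inserted sequence from
    context.  Soft-clipped bases are never placed in columns, but their
    presence sets the clipped flag on every encoded base of the read.
    """
    seq = read.query_sequence or ""
    quals = read.query_qualities
    clipped = any(op in (4, 5) for op, _ in read.cigartuples)
    reverse = read.is_reverse
    mapq = read.mapping_quality
    events: dict[int, ReadEvent] = {}
    ref_pos = read.reference_start
    read_pos = 0

    def col(p):
        c = p - window.start
        return c if 0 <= c < window.width else None

    for op, length in read.cigartuples:
        if op in (0, 7, 8):  # M, =, X
            for k in range(length):
                c = col(ref_pos + k)
                if c is not None:
                    q = quals[read_pos + k] if quals is not None else 30
                    events[c] = ReadEvent("aligned", seq[read_pos + k], q,
                                          reverse, clipped, mapq)
            ref_pos += length
            read_pos += length
        elif op == 2 or op == 3:  # D, N
            for k in range(length):
                c = col(ref_pos + k)
                if c is not None:
                    events[c] = ReadEvent("deletion", None, 0,
                                          reverse, clipped, mapq)
            ref_pos += length
        elif op == 1:  # I — anchor the first inserted base on the previous column
            c = col(ref_pos - 1)
            if c is not None and read_pos < len(seq):
                q = quals[read_pos] if quals is not None else 30
                events[c] = ReadEvent("insertion", seq[read_pos], q,
                                      reverse, clipped, mapq)
            read_pos += length
        elif op == 4:  # S
            read_pos += length
        # H (5) and P (6) consume nothing encoded here
    return events


def encode_region(alignment_source, reference, window: GenomicWindow,
                  max_reads: int = DEFAULT_MAX_READS, seed: int = 0
                  ) -> EncodedRegion:
    """Build the [g, r, 10] input tensor for one window.

    ``reference`` is a ``pysam.FastaFile`` (or any object with a matching
    ``fetch``).  Windows extending past the contig end are clipped and
    zero-padded with a logged warning.
    """
    g = window.width
    array = np.zeros((g, max_reads, N_FEATURES), dtype=np.float32)
    ref_seq = reference.fetch(window.chrom, window.start, window.end)
    if len(ref_seq) < g:
        logger.warning("window %s:%d-%d extends past the contig end; "
                       "zero-padding %d columns", window.chrom, window.start,
                       window.end, g - len(ref_seq))
    array[:, 0, :] = reference_row(ref_seq, g)
    reads = extract_reads(alignment_source, window, max_reads=max_reads,
                          seed=seed)
    read_ids = []
    for row, read in enumerate(reads, start=1):
        for c, event in read_events_by_column(read, window).items():
            array[c, row, :] = base_features(event)
        read_ids.append(read.query_name)
    return EncodedRegion(window=window, array=array, read_ids=read_ids)
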