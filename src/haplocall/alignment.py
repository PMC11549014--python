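"""Pairwise alignment helpers shared by phase resolution and variant extraction.

All alignments use one affine-gap scoring scheme tuned for ~150 bp short-read
sequences: match +2, mismatch -4, gap open -6, gap extend -1.  Modes:

* ``glocal`` — the query (a decoded haplotype) aligns end to end against a
  target (reference slice) whose RIGHT end may be left unaligned for free;
  the left edges of query and target are pinned together, matching the
  contract that a decoded haplotype starts at its window's first column.
  Unaligned target bases at the left edge are therefore real deletions.
* ``local`` — classic Smith-Waterman, used for read-vs-haplotype scoring.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio import Align

MATCH = 2
MISMATCH = -4
GAP_OPEN = -6
GAP_EXTEND = -1


def make_aligner(mode: str = "glocal") -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.match_score = MATCH
    aligner.mismatch_score = MISMATCH
    aligner.open_gap_score = GAP_OPEN
    aligner.extend_gap_score = GAP_EXTEND
    if mode == "glocal":
        aligner.mode = "global"
        # free gap over the target's tail only ("deletion" = target letters
        # without a query counterpart); every other gap pays full price
        aligner.open_right_deletion_score = 0
        aligner.extend_right_deletion_score = 0
    elif mode == "local":
        aligner.mode = "local"
    elif mode == "global":
        aligner.mode = "global"
    else:
        raise ValueError(f"unknown alignment mode {mode!r}")
    return aligner


_GLOCAL = make_aligner("glocal")
_LOCAL = make_aligner("local")


def glocal_score(query: str, target: str) -> float:
    """Score of the best left-pinned, right-end-free alignment."""
    if not query or not target:
        return 0.0
    return float(_GLOCAL.score(target, query))


def local_score(query: str, target: str) -> float:
    if not query or not target:
        return 0.0
    return float(_LOCAL.score(target, query))


@dataclass
class AlignedPair:
    """One query/target alignment expressed as matched coordinate blocks."""

    score: float
    target_blocks: list[tuple[int, int]]
    query_blocks: list[tuple[int, int]]
    target: str
    query: str

    def walk(self):
        """Per-difference events in target/query coordinates.

        ('X', t_pos, q_pos)              substitution
        ('I', t_pos, q_start, q_end)     query insertion before target t_pos
        ('D', t_start, t_end, q_pos)     deletion of target[t_start:t_end]

        The unaligned target TAIL (free right end gap) is not reported; an
        unaligned target HEAD is a real deletion under the left-pinned
        contract.  Unaligned query letters at either end are insertions.
        """
        events = []
        tb, qb = self.target_blocks, self.query_blocks
        if not tb:
            return events
        for (ts, te), (qs, qe) in zip(tb, qb):
            for k in range(te - ts):
                if self.target[ts + k] != self.query[qs + k]:
                    events.append(("X", ts + k, qs + k))
        for i in range(len(tb) - 1):
            t_gap = (tb[i][1], tb[i + 1][0])
            q_gap = (qb[i][1], qb[i + 1][0])
            if q_gap[1] > q_gap[0] and t_gap[1] == t_gap[0]:
                events.append(("I", t_gap[0], q_gap[0], q_gap[1]))
            elif t_gap[1] > t_gap[0] and q_gap[1] == q_gap[0]:
                events.append(("D", t_gap[0], t_gap[1], q_gap[0]))
            else:
                # mixed gap: deletion then insertion at the same anchor
                if t_gap[1] > t_gap[0]:
                    events.append(("D", t_gap[0], t_gap[1], q_gap[0]))
                if q_gap[1] > q_gap[0]:
                    events.append(("I", t_gap[1], q_gap[0], q_gap[1]))
        # left edge: unaligned target head is a deletion, unaligned query
        # head an insertion
        head = []
        if tb[0][0] > 0:
            head.append(("D", 0, tb[0][0], 0))
        if qb[0][0] > 0:
            head.append(("I", 0, 0, qb[0][0]))
        events = head + events
        # right edge: query overhang only (the target tail is free)
        if qb[-1][1] < len(self.query):
            events.append(("I", tb[-1][1], qb[-1][1], len(self.query)))
        return events


def align_glocal(query: str, target: str) -> AlignedPair:
    """Best glocal alignment of ``query`` against ``target``.

    Ties between co-optimal alignments resolve to Biopython's first
    enumerated alignment, which is deterministic for fixed inputs.
    """
    alns = _GLOCAL.align(target, query)
    aln = alns[0]
    t_blocks, q_blocks = aln.aligned
    return AlignedPair(score=float(aln.score),
                       target_blocks=[(int(a), int(b)) for a, b in t_blocks],
                       query_blocks=[(int(a), int(b)) for a, b in q_blocks],
                       target=target, query=query)
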