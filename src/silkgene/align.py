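"""Shared pairwise-alignment and percent-identity conventions.

Every module in the package that reports a percent identity uses the same
definition: matching columns / alignment columns x 100, where internal gap
columns count against identity and terminal (overhanging) gap columns are
excluded.  The scoring scheme is fixed (match +1, mismatch -1, gap open -4,
gap extend -1) so results are deterministic; for the near-identical
sequences this package compares, identities are insensitive to the scheme,
but a fixed one guarantees reproducibility.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import edlib
from Bio.Align import PairwiseAligner

MATCH = 1
MISMATCH = -1
GAP_OPEN = -4
GAP_EXTEND = -1


@lru_cache(maxsize=4)
def _aligner(mode: str) -> PairwiseAligner:
    aligner = PairwiseAligner(
        match_score=MATCH,
        mismatch_score=MISMATCH,
        open_gap_score=GAP_OPEN,
        extend_gap_score=GAP_EXTEND,
        mode=mode,
    )
    return aligner


@dataclass(frozen=True)
class AlignmentStats:
    """Column tally of one pairwise alignment, terminal gaps excluded."""

    matches: int
    mismatches: int
    internal_gap_columns: int
    #: gap events (maximal runs of gap columns) of length 1-2 nt
    short_gap_events: int
    #: 1-based inclusive span of the aligned (non-overhang) region on seq a
    span_a: tuple[int, int]
    #: 1-based inclusive span on seq b
    span_b: tuple[int, int]

    @property
    def columns(self) -> int:
        return self.matches + self.mismatches + self.internal_gap_columns

    @property
    def identity_pct(self) -> float:
        if self.columns == 0:
            return 0.0
        return 100.0 * self.matches / self.columns


def _stats_from_alignment(alignment, a: str, b: str) -> AlignmentStats:
    """Column tally from an alignment's coordinate path.

    Segments where both sequences advance are aligned blocks; one-sided
    segments are gaps.  Gaps before the first or after the last aligned
    block are terminal and excluded (local alignments have none).
    """
    ta, qa = alignment.coordinates
    segments: list[tuple[str, int, int, int]] = []  # (kind, len, ta0, qa0)
    for k in range(len(ta) - 1):
        dt, dq = int(ta[k + 1] - ta[k]), int(qa[k + 1] - qa[k])
        if dt and dq:
            segments.append(("M", dt, int(ta[k]), int(qa[k])))
        elif dt or dq:
            segments.append(("G", max(dt, dq), int(ta[k]), int(qa[k])))
    aligned_idx = [i for i, s in enumerate(segments) if s[0] == "M"]
    if not aligned_idx:
        return AlignmentStats(0, 0, 0, 0, (1, 0), (1, 0))
    first, last = aligned_idx[0], aligned_idx[-1]
    matches = mismatches = gap_cols = short_gaps = 0
    for kind, length, t0, q0 in segments[first : last + 1]:
        if kind == "M":
            m = sum(a[t0 + i] == b[q0 + i] for i in range(length))
            matches += m
            mismatches += length - m
        else:
            gap_cols += length
            if length <= 2:
                short_gaps += 1
    ta0, qa0 = segments[first][2], segments[first][3]
    kind_l, len_l, tl, ql = segments[last]
    ta1 = tl + len_l
    qa1 = ql + len_l  # last segment is 'M': both advance
    return AlignmentStats(
        matches=matches,
        mismatches=mismatches,
        internal_gap_columns=gap_cols,
        short_gap_events=short_gaps,
        span_a=(ta0 + 1, ta1),
        span_b=(qa0 + 1, qa1),
    )


def align_stats(a: str, b: str, mode: str = "global") -> AlignmentStats:
    """Align two sequences and tally columns under the package convention.

    mode 'global' for whole-sequence comparisons (unit vs unit, clone vs
    clone); mode 'local' for segment discovery against a longer target.
    """
    if not a or not b:
        raise ValueError("cannot align empty sequences")
    alignment = _aligner(mode).align(a, b)[0]
    return _stats_from_alignment(alignment, a, b)


def percent_identity(a: str, b: str) -> float:
    """Global-alignment percent identity (terminal gaps excluded).

    Equal-length inputs take a Hamming fast path: with the package's
    scoring, the optimal global alignment of near-identical equal-length
    sequences is gapless, so column-wise comparison is exact and much
    faster.  Sequences of very different length always go through the
    aligner.
    """
    if len(a) == len(b):
        if a == b:
            return 100.0
        ham = sum(x == y for x, y in zip(a, b))
        # only trust the gapless path when the sequences really are
        # near-identical; otherwise a gapped alignment could score better
        if ham >= 0.9 * len(a):
            return 100.0 * ham / len(a)
    return align_stats(a, b, mode="global").identity_pct


def edit_alignment(query: str, target: str, mode: str = "NW") -> dict:
    """Edit-distance alignment with path, via edlib.

    Used where unit-cost indel placement is what matters (frameshift
    resolution, unit chaining); scored comparisons use align_stats.
    """
    result = edlib.align(query, target, task="path", mode=mode)
    if result["editDistance"] < 0:
        raise RuntimeError("edlib alignment failed")
    return result


def cigar_ops(cigar: str):
    """Yield (length, op) pairs from an edlib cigar string."""
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            yield int(num), ch
            num = ""
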