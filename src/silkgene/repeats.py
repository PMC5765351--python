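"""Tandem-repeat decomposition of spidroin coding sequences.

The repetitive region of a spidroin CDS is an array of near-identical,
in-frame units flanked by nonrepetitive terminal-coding blocks.  This module
finds the unit period and phase by self-comparison, chains unit boundaries
through the array (tolerating the occasional single-base indel left by
sequencing artifacts), quantifies homogenization as all-vs-all pairwise
identity, builds the majority-rule consensus unit, and resolves isolated
frameshift artifacts against that consensus — the operation used to repair
raw assemblies whose repeat region carries a handful of spurious 1-nt indels.

Percent identity here and everywhere in the package is matching columns /
alignment columns x 100 with terminal gaps excluded (see ``silkgene.align``).
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field

import numpy as np

from .align import cigar_ops, edit_alignment, percent_identity
from .annotate import translate

__all__ = [
    "RepeatDecomposition",
    "FrameshiftEvent",
    "FrameshiftReport",
    "detect_repeats",
    "identity_matrix",
    "consensus_repeat",
    "resolve_frameshifts",
    "apply_events",
]


@dataclass
class RepeatDecomposition:
    """Units are 1-based inclusive CDS-relative intervals, numbered 5'->3'."""

    cds: str
    units: list[tuple[int, int]]
    unit_len_nt: int
    consensus: str
    identity_mat: np.ndarray  # full-length units only
    mean_identity_nt: float
    mean_identity_aa: float
    #: mean pairwise nt identity including the truncated unit, aligned-span only
    mean_identity_nt_all: float

    @property
    def n_units(self) -> int:
        return len(self.units)

    @property
    def repeat_region(self) -> tuple[int, int]:
        return (self.units[0][0], self.units[-1][1])

    @property
    def nterm_interval(self) -> tuple[int, int]:
        return (1, self.units[0][0] - 1)

    @property
    def cterm_interval(self) -> tuple[int, int]:
        return (self.units[-1][1] + 1, len(self.cds))

    def unit_seq(self, i: int) -> str:
        lo, hi = self.units[i]
        return self.cds[lo - 1 : hi]

    def unit_seqs(self) -> list[str]:
        return [self.unit_seq(i) for i in range(self.n_units)]

    def full_length_indices(self) -> list[int]:
        return [i for i, (lo, hi) in enumerate(self.units) if hi - lo + 1 == self.unit_len_nt]


@dataclass
class FrameshiftEvent:
    #: 1-based position on the input sequence; an addition inserts `bases`
    #: before this position, a deletion removes len(bases) bases starting here
    position: int
    kind: str  # 'insertion_needed' | 'deletion_needed'
    bases: str
    unit_index: int  # 0-based index of the unit the artifact sits in


@dataclass
class FrameshiftReport:
    events: list[FrameshiftEvent] = field(default_factory=list)
    corrected_sequence: str = ""
    n_additions: int = 0
    n_deletions: int = 0


# ---------------------------------------------------------------------------
# period and phase discovery


def _kmer_period(seq: str, min_unit: int, max_unit: int, k: int = 12) -> int | None:
    """Modal spacing between recurrences of shared k-mers, restricted to the
    allowed period range."""
    positions: dict[str, list[int]] = defaultdict(list)
    for i in range(len(seq) - k + 1):
        positions[seq[i : i + k]].append(i)
    votes: Counter[int] = Counter()
    for pos_list in positions.values():
        for a, b in zip(pos_list, pos_list[1:]):
            d = b - a
            if min_unit <= d <= max_unit:
                votes[d] += 1
    if not votes:
        return None
    return votes.most_common(1)[0][0]


def _coarse_region(seq: str, period: int, floor_frac: float) -> tuple[int, int] | None:
    """Longest stretch where seq[i] == seq[i+period] at high density.

    Returns (a, b) on the match-array domain: the array spans roughly
    [a, b + period) on the sequence.
    """
    n = len(seq) - period
    if n <= 0:
        return None
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    m = (arr[:n] == arr[period:]).astype(float)
    w = min(30, max(5, period // 4))
    density = np.convolve(m, np.ones(w) / w, mode="same")
    marked = density >= max(0.6, floor_frac - 0.1)
    if not marked.any():
        return None
    # longest contiguous marked run
    best_len = best_start = 0
    run_start = None
    for i, flag in enumerate(np.append(marked, False)):
        if flag and run_start is None:
            run_start = i
        elif not flag and run_start is not None:
            if i - run_start > best_len:
                best_len, best_start = i - run_start, run_start
            run_start = None
    if best_len < period // 2:
        return None
    return best_start, best_start + best_len


def _hamming_pct(a: str, b: str) -> float:
    return 100.0 * sum(x == y for x, y in zip(a, b)) / len(a)


def _medoid(windows: list[str]) -> str:
    scores = [sum(_hamming_pct(w, v) for v in windows) for w in windows]
    return windows[int(np.argmax(scores))]


#: per-base penalty in the boundary score (matches - penalty * length).
#: Must exceed the chance per-base match rate between repeat sequence and
#: the similarly codon-biased flanks (~1/3) by a solid margin while staying
#: under the in-repeat match rate at the divergences handled (>= 0.98).
BOUNDARY_PENALTY = 0.75


def _penalized_argmax(v: list[bool]) -> int:
    """Boundary estimate: c maximizing matches(c) - penalty*c over prefixes
    of the in-array indicator v."""
    best_c, best_score, cum = 0, 0.0, 0.0
    for c in range(1, len(v) + 1):
        cum += 1.0 if v[c - 1] else 0.0
        score = cum - BOUNDARY_PENALTY * c
        if score > best_score:
            best_score, best_c = score, c
    return best_c


def _trimmed_boundary(v: list[bool], max_trim: int = 3) -> int:
    """Penalized-argmax boundary, then pull inward (at most ``max_trim``
    steps) until the two outermost steps both match.

    The trim stops a lone chance match just outside the array from dragging
    the boundary outward; capping it keeps an interior mutation near the
    true boundary from dragging it inward instead.
    """
    c0 = _penalized_argmax(v)
    c = c0
    while c > 0 and c0 - c < max_trim and not (v[c - 1] and (c < 2 or v[c - 2])):
        c -= 1
    if c0 - c >= max_trim and not (v[c - 1] and (c < 2 or v[c - 2])):
        return c0
    return c


def _left_step(seq: str, pos: int, unit: str) -> int:
    """One leftward walk of at most a period against the unit's tail."""
    P = len(unit)
    limit = min(P, pos)
    v = [seq[pos - e] == unit[P - e] for e in range(1, limit + 1)]
    return _trimmed_boundary(v)


def _rot_right(unit: str, k: int) -> str:
    k %= len(unit)
    return unit[-k:] + unit[:-k] if k else unit


def _shift_continuation(seq: str, pos: int, unit: str, window: int = 16,
                        min_frac: float = 0.7) -> tuple[int, int] | None:
    """Does the lattice continue left of `pos` after a 1-2 nt indel?

    Returns (raw_shift, unit_shift): skipping `raw_shift` sequence bases
    (an inserted artifact) or `unit_shift` unit bases (a deleted one) makes
    the window left of the junction match the unit's tail again.  None means
    no continuation — `pos` is the true array start.
    """
    for rshift, ushift in ((1, 0), (0, 1), (2, 0), (0, 2)):
        lo = pos - rshift - window
        if lo < 0:
            continue
        frag = seq[lo : pos - rshift]
        ref = unit[len(unit) - ushift - window : len(unit) - ushift]
        if sum(a == b for a, b in zip(frag, ref)) / window >= min_frac:
            return rshift, ushift
    return None


def _find_array_start(seq: str, anchor: int, unit: str) -> tuple[int, str]:
    """Walk from a clean unit occurrence at `anchor` to the array's 5' end.

    Clean periods are crossed whole; a stalled walk is either the true start
    (no lattice continuation to the left) or an artifact indel, which is
    crossed by shifting the sequence or unit cursor by the indel length.
    Returns the start position and the unit template rotated into phase with
    it.
    """
    P = len(unit)
    pos = anchor
    for _ in range(8 * (len(seq) // P + 2)):
        e = _left_step(seq, pos, unit)
        pos -= e
        unit = _rot_right(unit, e)
        if e == P and pos >= P:
            continue  # clean period crossed; keep walking
        shift = _shift_continuation(seq, pos, unit)
        if shift is None:
            break
        rshift, ushift = shift
        pos -= rshift
        unit = _rot_right(unit, ushift)
        if rshift == 0 and ushift == 0:  # defensive: cannot happen
            break
    return pos, unit


def _truncated_tail(seq: str, pos: int, unit: str,
                    min_len: int = 12) -> tuple[int, float]:
    """(length, quality) of a 3'-truncated final unit starting at `pos`.

    The truncation point maximizes matches(T) - penalty*T against the unit
    prefix (inside the unit matches accrue near 1/site, past it near 1/3),
    then gets the two-sided contrast polish.  Length 0 means no credible
    truncated unit here.
    """
    P = len(unit)
    limit = min(P, len(seq) - pos)
    if limit <= 0:
        return 0, -1e9
    v = [seq[pos + t] == unit[t] for t in range(limit)]
    best_t = _trimmed_boundary(v)
    quality = sum(v[:best_t]) - BOUNDARY_PENALTY * best_t
    if best_t < min_len or quality < 3.0:
        return 0, quality
    return best_t, quality


def _head_confirmed(seq: str, start: int, unit: str, window: int | None = None,
                    min_frac: float = 0.6, max_shift: int = 2) -> bool:
    """Mirror of _tail_confirmed for backward chaining: the sequence just
    after `start` must match the unit's 5' end."""
    P = len(unit)
    w = window or min(30, max(12, P // 3))
    ref = unit[:w]
    best = 0.0
    for shift in range(-max_shift, max_shift + 1):
        lo = start + shift
        if lo < 0 or lo + w > len(seq):
            continue
        frag = seq[lo : lo + w]
        best = max(best, sum(a == b for a, b in zip(frag, ref)) / w)
    return best >= min_frac


def _tail_confirmed(seq: str, end: int, unit: str, window: int | None = None,
                    min_frac: float = 0.6, max_shift: int = 2) -> bool:
    """True if the sequence just before `end` matches the unit's 3' end.

    Guards chain acceptance: a unit is only full-length if its tail really is
    repeat sequence (checked by Hamming identity, tolerating a +-2 nt shift
    from an internal artifact indel).  Without this, an edit-distance
    alignment can stretch a truncated final unit across the C-terminal flank
    and stay under the identity floor.
    """
    P = len(unit)
    w = window or min(30, max(12, P // 3))
    ref = unit[P - w :]
    best = 0.0
    for shift in range(-max_shift, max_shift + 1):
        lo = end - w + shift
        if lo < 0 or lo + w > len(seq):
            continue
        frag = seq[lo : lo + w]
        best = max(best, sum(a == b for a, b in zip(frag, ref)) / w)
    return best >= min_frac


def detect_repeats(cds: str, min_unit_nt: int = 30, max_unit_nt: int | None = None,
                   identity_floor: float = 80.0) -> RepeatDecomposition | None:
    """Decompose a CDS into tandem repeat units plus nonrepetitive flanks.

    Finds the period by k-mer self-comparison, the phase by anchoring a
    representative unit and extending to the true array start, then chains
    unit boundaries 5'->3' with an edit-distance aligner so units carrying
    isolated 1-nt indels keep correct boundaries.  Returns None when no
    period yields a repeat array at ``identity_floor`` mean unit identity.
    """
    seq = cds.upper()
    if max_unit_nt is None:
        max_unit_nt = max(min_unit_nt, len(seq) // 2)
    if not 3 <= min_unit_nt <= max_unit_nt <= max(3, len(seq) // 2):
        raise ValueError("require 3 <= min_unit_nt <= max_unit_nt <= len(cds)/2")
    period = _kmer_period(seq, min_unit_nt, max_unit_nt)
    if period is None:
        return None
    coarse = _coarse_region(seq, period, identity_floor / 100.0)
    if coarse is None:
        return None
    a, b = coarse

    # representative unit from rigid slices inside the coarse region
    windows = [seq[p : p + period] for p in range(a, b + 1 - period, period)]
    windows = [w for w in windows if len(w) == period]
    if len(windows) < 1:
        return None
    medoid = _medoid(windows) if len(windows) > 1 else windows[0]

    # anchor the representative near the region start
    win_lo = max(0, a - period - 16)
    win_hi = min(len(seq), a + 2 * period + 16)
    hit = edit_alignment(medoid, seq[win_lo:win_hi], mode="HW")
    s_anchor = win_lo + hit["locations"][0][0]

    # Two passes: the first uses the medoid window as unit template; the
    # second rebuilds the template as the majority consensus of the units
    # just chained, which cancels the medoid copy's private mutations and
    # sharpens both array-edge boundaries.
    units: list[tuple[int, int]] = []
    template = medoid
    anchor = s_anchor
    for _ in range(2):
        start, phase0 = _find_array_start(seq, anchor, template)
        units = _chain_units(seq, start, phase0, period, identity_floor)
        if not units:
            return None
        # rebuild the template from units of exactly the lattice period, so
        # boundary wobble cannot drift the period itself
        full = [seq[lo:hi] for lo, hi in units if hi - lo == period]
        if len(full) < 2:
            break
        template = consensus_repeat(full)
        anchor = units[0][0] + period  # start of the second lattice period

    modal = Counter(hi - lo for lo, hi in units).most_common(1)[0][0]
    unit_seqs = [seq[lo:hi] for lo, hi in units]
    full = [u for u in unit_seqs if len(u) == modal]
    if len(full) >= 2:
        consensus = consensus_repeat(full)
    else:
        consensus = full[0] if full else unit_seqs[0]

    mat, mean_nt = identity_matrix(full)
    if mean_nt < identity_floor:
        return None
    mean_aa = _mean_aa_identity(full)
    mean_all = _mean_pairwise(unit_seqs) if len(unit_seqs) > 1 else 100.0

    return RepeatDecomposition(
        cds=seq,
        units=[(lo + 1, hi) for lo, hi in units],
        unit_len_nt=modal,
        consensus=consensus,
        identity_mat=mat,
        mean_identity_nt=mean_nt,
        mean_identity_aa=mean_aa,
        mean_identity_nt_all=mean_all,
    )


def _chain_units(seq: str, start: int, phase0: str, period: int,
                 identity_floor: float) -> list[tuple[int, int]]:
    """Walk unit boundaries 5'->3' from `start` (0-based half-open output).

    Full units are located with a prefix edit alignment so isolated artifact
    indels shift the next boundary correctly; a 3'-truncated final unit is
    appended by prefix matching, allowing the preceding chain end to be off
    by a base or two at nonzero divergence.
    """
    slack = max(8, period // 50)
    units: list[tuple[int, int]] = []
    pos = start
    while len(seq) - pos >= period - slack:
        target = seq[pos : pos + period + slack]
        res = edit_alignment(phase0, target, mode="SHW")
        dist = res["editDistance"]
        end = pos + res["locations"][0][1] + 1
        if 100.0 * (1.0 - dist / period) < identity_floor:
            break
        # an edit path can tie a substitution against an indel at the unit
        # edge and wobble the boundary; when plain mismatch counting does as
        # well as the edit alignment there is no indel evidence, so step
        # exactly one period
        if pos + period <= len(seq):
            ham = sum(a != b for a, b in zip(phase0, seq[pos : pos + period]))
            if ham <= dist + 2:
                end = pos + period
        if not _tail_confirmed(seq, end, phase0):
            break  # truncated final unit, handled below
        units.append((pos, end))
        pos = end
    if not units:
        return []

    best = (0, -1e9, 0)  # (tail_len, quality, delta)
    for delta in (-2, -1, 0, 1, 2):
        p2 = pos + delta
        if p2 <= units[-1][0] or p2 > len(seq):
            continue
        t, q = _truncated_tail(seq, p2, phase0)
        if t and q > best[1]:
            best = (t, q, delta)
    if best[0]:
        t, _, delta = best
        if delta:
            units[-1] = (units[-1][0], pos + delta)
        units.append((pos + delta, pos + delta + t))
    return units


def _mean_pairwise(seqs: list[str]) -> float:
    vals = [
        percent_identity(seqs[i], seqs[j])
        for i in range(len(seqs))
        for j in range(i + 1, len(seqs))
    ]
    return float(np.mean(vals)) if vals else 100.0


def _mean_aa_identity(units: list[str]) -> float:
    translatable = [u for u in units if len(u) % 3 == 0]
    if len(translatable) < 2:
        return float("nan")
    prots = [translate(u) for u in translatable]
    return _mean_pairwise(prots)


def identity_matrix(units: list[str]) -> tuple[np.ndarray, float]:
    """All-vs-all pairwise percent identity; mean over unordered pairs."""
    n = len(units)
    mat = np.full((n, n), 100.0)
    vals = []
    for i in range(n):
        for j in range(i + 1, n):
            pid = percent_identity(units[i], units[j])
            mat[i, j] = mat[j, i] = pid
            vals.append(pid)
    return mat, (float(np.mean(vals)) if vals else 100.0)


def consensus_repeat(units: list[str]) -> str:
    """Majority-rule consensus over a column-wise alignment of units.

    Column ties are broken by the most 5' unit's base.  Units of equal length
    are stacked directly; otherwise each is projected onto the first unit's
    coordinates through an edit-distance alignment.
    """
    if len(units) < 2:
        raise ValueError("consensus requires at least 2 units")
    if len(set(map(len, units))) == 1:
        rows = units
    else:
        anchor = units[0]
        rows = [anchor]
        for unit in units[1:]:
            res = edit_alignment(unit, anchor, mode="NW")
            row = []
            qi = ti = 0
            for length, op in cigar_ops(res["cigar"]):
                if op in "=X":
                    row.append(unit[qi : qi + length])
                    qi += length
                    ti += length
                elif op == "D":  # anchor has extra columns
                    row.append("-" * length)
                    ti += length
                elif op == "I":  # unit insertion relative to anchor: dropped
                    qi += length
            rows.append("".join(row))
    out = []
    for col in range(len(rows[0])):
        counts: Counter[str] = Counter(row[col] for row in rows)
        top = max(counts.values())
        # earliest (most 5') unit among the tied states wins
        winner = next(row[col] for row in rows if counts[row[col]] == top)
        if winner != "-":
            out.append(winner)
    return "".join(out)


# ---------------------------------------------------------------------------
# frameshift resolution


def resolve_frameshifts(raw: str, decomposition: RepeatDecomposition | None = None,
                        max_indel_nt: int = 2) -> FrameshiftReport:
    """Correct isolated short indels in the repeat array against the
    majority-rule consensus unit.

    Each unit is aligned to the consensus; indels of <= ``max_indel_nt`` nt
    private to a single unit are treated as sequencing artifacts and reverted
    to the consensus state (an *addition* inserts the consensus base the unit
    lacks, a *deletion* removes the unit's extra base).  Indels shared by at
    least half the units at the same consensus column are genuine sequence
    and left alone, as are longer indels and whole-unit loss.
    """
    seq = raw.upper()
    if decomposition is None:
        decomposition = detect_repeats(seq)
        if decomposition is None:
            raise ValueError("no detectable repeat region in input")
    consensus = decomposition.consensus
    n_units = decomposition.n_units

    candidates = []  # (consensus_col, kind, raw_pos_1based, bases, unit_idx)
    for idx, (lo, hi) in enumerate(decomposition.units):
        unit = seq[lo - 1 : hi]
        # truncated final unit aligns to a consensus *prefix* (SHW leaves the
        # consensus tail free) so the 3' truncation is not read as a deletion
        truncated = len(unit) < decomposition.unit_len_nt - max_indel_nt
        res = edit_alignment(unit, consensus, mode="SHW" if truncated else "NW")
        ci = ui = 0  # consensus / unit cursors
        for length, op in cigar_ops(res["cigar"]):
            if op in "=X":
                ci += length
                ui += length
            elif op == "D":  # unit lacks consensus bases -> addition needed
                if length <= max_indel_nt:
                    candidates.append((ci, "insertion_needed", lo + ui,
                                       consensus[ci : ci + length], idx))
                ci += length
            elif op == "I":  # unit has extra bases -> deletion needed
                if length <= max_indel_nt:
                    candidates.append((ci, "deletion_needed", lo + ui,
                                       unit[ui : ui + length], idx))
                ui += length

    # shared indels (same column, same kind, in >= half the units) are biology
    by_site: Counter[tuple[int, str]] = Counter((c[0], c[1]) for c in candidates)
    events = [
        FrameshiftEvent(position=pos, kind=kind, bases=bases, unit_index=idx)
        for col, kind, pos, bases, idx in candidates
        if by_site[(col, kind)] < max(2, (n_units + 1) // 2)
    ]
    events.sort(key=lambda e: e.position)
    events = _cancel_boundary_pairs(events)

    corrected = apply_events(seq, events)
    return FrameshiftReport(
        events=events,
        corrected_sequence=corrected,
        n_additions=sum(len(e.bases) for e in events if e.kind == "insertion_needed"),
        n_deletions=sum(len(e.bases) for e in events if e.kind == "deletion_needed"),
    )


def _cancel_boundary_pairs(events: list[FrameshiftEvent],
                           max_gap: int = 3) -> list[FrameshiftEvent]:
    """Drop complementary event pairs that cancel at a unit boundary.

    Two spurious patterns cancel pairwise.  A chained boundary landing a base
    off makes the unit on one side show an extra base and its neighbor a
    missing one (same bases, adjacent positions; applying both is a no-op).
    And two nearby substitutions inside one unit can tie with an
    insertion+deletion path in the edit alignment — real divergence, not an
    artifact — recognized as an opposite-kind pair within the same unit.
    """
    keep = list(events)
    changed = True
    while changed:
        changed = False
        for i in range(len(keep) - 1):
            a, b = keep[i], keep[i + 1]
            if a.kind == b.kind:
                continue
            boundary_pair = (a.bases == b.bases
                             and abs(b.position - a.position) <= max_gap)
            mimicry_pair = (a.unit_index == b.unit_index
                            and abs(b.position - a.position) <= 2 * max_gap)
            if boundary_pair or mimicry_pair:
                del keep[i + 1], keep[i]
                changed = True
                break
    return keep


def apply_events(seq: str, events: list[FrameshiftEvent]) -> str:
    """Apply frameshift corrections to a sequence (positions refer to the
    uncorrected input, so application proceeds right to left)."""
    chars = list(seq)
    for ev in sorted(events, key=lambda e: e.position, reverse=True):
        i = ev.position - 1
        if ev.kind == "insertion_needed":
            chars[i:i] = list(ev.bases)
        elif ev.kind == "deletion_needed":
            if "".join(chars[i : i + len(ev.bases)]) != ev.bases:
                raise ValueError(f"event at {ev.position} does not match the sequence")
            del chars[i : i + len(ev.bases)]
        else:
            raise ValueError(f"unknown event kind {ev.kind!r}")
    return "".join(chars)
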