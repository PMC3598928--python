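"""Paired-end pairing and windowed Smith-Waterman mate rescue.

Each end of a pair is first aligned independently.  Pairing then handles
three cases: (1) both ends have hits — cross the hit lists and keep
combinations in forward/reverse orientation whose outer distance (leftmost
base of the left end to rightmost base of the right end) lies within
``D +/- k*sd``; (2)/(3) only one end has hits — the mapped end anchors a
windowed local Smith-Waterman search for its mate, in both orientations,
over the genome interval the insert-size model implies.  One best pair is
reported per read pair.
"""

from __future__ import annotations

import dataclasses

from Bio import Align

from .aligncore import AlignmentResult
from .seqio import Sequence

__all__ = [
    "PairParams",
    "PairedAlignment",
    "EndInput",
    "pair_both_mapped",
    "sw_rescue",
    "pair_reads",
]

FORWARD = "forward"
REVERSE = "reverse"

_COMP = str.maketrans("ACGTN", "TGCAN")


def _revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


@dataclasses.dataclass(frozen=True)
class PairParams:
    """Insert-size model and rescue scoring.

    ``outer_distance``/``std_dev`` describe the fragment span; the proper-
    pair window is ``k = window_sigmas`` standard deviations wide (3 sigma
    captures ~99.7% of normally distributed inserts).  Rescue uses unit
    local-alignment scores (+1/-1/-1) so the identity cutoff stays
    interpretable: a read aligned at identity f scores about
    ``(2f - 1) * read_len``.
    """

    outer_distance: int = 200
    std_dev: int = 20
    window_sigmas: int = 3
    sw_match: int = 1
    sw_mismatch: int = -1
    sw_gap: int = -1
    rescue_min_identity: float = 0.90

    def __post_init__(self):
        if self.outer_distance <= 0 or self.std_dev < 0 or self.window_sigmas < 1:
            raise ValueError("need D > 0, sd >= 0, k >= 1")

    @property
    def slack(self) -> int:
        return self.window_sigmas * self.std_dev


@dataclasses.dataclass
class PairedAlignment:
    read_pair_id: str
    p1: int
    p2: int
    strand1: str
    strand2: str
    combined_score: int
    insert: int
    source: str  # both_mapped | rescued_end1 | rescued_end2


@dataclasses.dataclass
class EndInput:
    """One end's read and its threshold-passing single-end hits."""

    read: Sequence
    hits: list


def _span(hit: AlignmentResult, read_len: int) -> tuple[int, int]:
    return hit.ref_start, hit.ref_start + read_len


def pair_both_mapped(hits1: list, hits2: list, params: PairParams,
                     len1: int, len2: int) -> list[tuple]:
    """Proper-pair combinations of two hit lists, best first.

    A combination qualifies when the ends lie on opposite strands, the
    forward end is leftmost, and the outer distance falls inside
    ``D +/- k*sd``.  Returned tuples are
    (combined_score, |insert - D|, p1, hit1, hit2, insert) sorted ascending.
    """
    out = []
    D, slack = params.outer_distance, params.slack
    for h1 in hits1:
        for h2 in hits2:
            if h1.strand == h2.strand:
                continue
            fwd, rev = (h1, h2) if h1.strand == FORWARD else (h2, h1)
            fwd_len = len1 if fwd is h1 else len2
            rev_len = len2 if rev is h2 else len1
            if rev.ref_start < fwd.ref_start:
                continue
            insert = (rev.ref_start + rev_len) - fwd.ref_start
            if abs(insert - D) > slack:
                continue
            combined = h1.score + h2.score
            out.append((combined, abs(insert - D), h1.ref_start, h1, h2, insert))
    out.sort(key=lambda t: t[:3])
    return out


def _sw_aligner(params: PairParams) -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "local"
    a.match_score = params.sw_match
    a.mismatch_score = params.sw_mismatch
    a.open_gap_score = params.sw_gap
    a.extend_gap_score = params.sw_gap
    return a


def sw_rescue(read_bases: str, genome: Sequence, anchor_pos: int,
              anchor_strand: str, anchor_len: int,
              params: PairParams) -> tuple[int, str, int] | None:
    """Search the insert-size window for an unmapped mate.

    The window is placed where the mate's fragment end should lie given
    the anchor: right of a forward anchor, left of a reverse anchor, with
    ``k*sd`` slack on both sides (clipped to the genome).  Both the read
    and its reverse complement are searched; the best local alignment is
    accepted when its score reaches ``(2*identity - 1) * read_len``.
    Returns (genome position of the mate's leftmost base, strand,
    SW score), or None.
    """
    L = len(read_bases)
    D, slack = params.outer_distance, params.slack
    if anchor_strand == FORWARD:
        lo = anchor_pos + D - slack - L
        hi = anchor_pos + D + slack
    else:
        anchor_end = anchor_pos + anchor_len
        lo = anchor_end - D - slack
        hi = anchor_end - D + slack + L
    lo = max(lo, 0)
    hi = min(hi, genome.length)
    if hi - lo < L:
        return None
    window = genome.bases[lo:hi]
    aligner = _sw_aligner(params)
    min_score = params.sw_match * L * (2 * params.rescue_min_identity - 1)
    best = None
    for strand, query in ((FORWARD, read_bases), (REVERSE, _revcomp(read_bases))):
        alns = aligner.align(window, query)
        if len(alns) == 0:
            continue
        aln = alns[0]
        if aln.score < min_score:
            continue
        tgt_blocks, qry_blocks = aln.aligned
        # genome position the read's first base maps back to
        pos = lo + int(tgt_blocks[0][0]) - int(qry_blocks[0][0])
        if best is None or aln.score > best[2]:
            best = (max(pos, 0), strand, int(aln.score))
    return best


def _rescue_pair(mapped: AlignmentResult, mapped_len: int, mate: Sequence,
                 genome: Sequence, params: PairParams,
                 pair_id: str, mapped_is_end1: bool) -> PairedAlignment | None:
    res = sw_rescue(mate.bases, genome, mapped.ref_start, mapped.strand,
                    mapped_len, params)
    if res is None:
        return None
    mate_pos, mate_strand, sw = res
    if mate_strand == mapped.strand:
        return None
    mate_len = mate.length
    fwd_pos, fwd_len = ((mapped.ref_start, mapped_len)
                        if mapped.strand == FORWARD else (mate_pos, mate_len))
    rev_pos, rev_len = ((mate_pos, mate_len)
                        if mapped.strand == FORWARD else (mapped.ref_start, mapped_len))
    insert = (rev_pos + rev_len) - fwd_pos
    if rev_pos < fwd_pos or abs(insert - params.outer_distance) > params.slack:
        return None
    rescue_edit = max(0, (mate_len - sw + 1) // 2)  # unit scores: ~errors
    combined = mapped.score + rescue_edit
    if mapped_is_end1:
        return PairedAlignment(pair_id, mapped.ref_start, mate_pos,
                               mapped.strand, mate_strand, combined, insert,
                               "rescued_end2")
    return PairedAlignment(pair_id, mate_pos, mapped.ref_start,
                           mate_strand, mapped.strand, combined, insert,
                           "rescued_end1")


def _pair_id(name: str) -> str:
    return name[:-2] if name.endswith(("/1", "/2")) else name


def pair_reads(ends1: list[EndInput], ends2: list[EndInput],
               genome: Sequence, params: PairParams = PairParams()
               ) -> list[PairedAlignment]:
    """Pair per-end hit lists, rescuing unmapped mates; one pair per read pair.

    Case 1 crosses the two hit lists; when no combination satisfies the
    insert window (including when one end has no hits at all), the best
    hit of the mapped end anchors a rescue for its mate.  Ties are broken
    by insert deviation and then leftmost position of end 1.
    """
    if len(ends1) != len(ends2):
        raise ValueError("paired inputs differ in length")
    out: list[PairedAlignment] = []
    for e1, e2 in zip(ends1, ends2):
        pid = _pair_id(e1.read.id)
        best: PairedAlignment | None = None
        if e1.hits and e2.hits:
            combos = pair_both_mapped(e1.hits, e2.hits, params,
                                      e1.read.length, e2.read.length)
            if combos:
                _, _, _, h1, h2, insert = combos[0]
                best = PairedAlignment(pid, h1.ref_start, h2.ref_start,
                                       h1.strand, h2.strand,
                                       h1.score + h2.score, insert,
                                       "both_mapped")
        if best is None:
            candidates = []
            if e1.hits:
                h1 = min(e1.hits, key=lambda h: (h.score, h.ref_start))
                r = _rescue_pair(h1, e1.read.length, e2.read, genome, params,
                                 pid, mapped_is_end1=True)
                if r:
                    candidates.append(r)
            if e2.hits:
                h2 = min(e2.hits, key=lambda h: (h.score, h.ref_start))
                r = _rescue_pair(h2, e2.read.length, e1.read, genome, params,
                                 pid, mapped_is_end1=False)
                if r:
                    candidates.append(r)
            if candidates:
                best = min(candidates,
                           key=lambda p: (p.combined_score,
                                          abs(p.insert - params.outer_distance),
                                          p.p1))
        if best is not None:
            out.append(best)
    return out
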