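"""Seeding: turn each read into candidate reference diagonals.

Every seed-length window of the read (both orientations) is looked up in
the index; a hit at genome position ``p`` for the seed at read offset ``q``
votes for the diagonal ``p - q`` — the genome position the read's first
base would occupy.  Votes are merged per (read, strand, diagonal), since
duplicate seeds on one diagonal would only repeat the same extension work.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np

from .index import SeedIndex, pack_kmers
from .seqio import EncodedRead, Sequence

__all__ = [
    "SeedingConfig",
    "CandidatePair",
    "extract_seeds",
    "generate_candidates",
    "fetch_window",
]

logger = logging.getLogger(__name__)

FORWARD = "forward"
REVERSE = "reverse"


@dataclasses.dataclass(frozen=True)
class SeedingConfig:
    """Seed placement within reads.

    ``stride`` spaces successive seed offsets; the final offset
    ``read_len - seed_len`` is always included so the read's 3' end is
    covered.  ``max_candidates_per_read`` caps the merged candidate list
    (0 = unlimited), keeping the diagonals with the most supporting seeds.
    """

    stride: int = 1
    max_candidates_per_read: int = 0

    def __post_init__(self):
        if self.stride < 1:
            raise ValueError("stride must be >= 1")


@dataclasses.dataclass
class CandidatePair:
    """One (read, strand, reference diagonal) extension task."""

    read_id: str
    strand: str
    window_start: int
    supporting_offsets: frozenset


def extract_seeds(read: EncodedRead, strand: str,
                  config: SeedingConfig = SeedingConfig(),
                  seed_len: int = 15) -> list[tuple[int, np.ndarray]]:
    """Seed (offset, k-mer codes) list for one strand of a read."""
    codes = read.fwd if strand == FORWARD else read.rc
    n = len(codes)
    if n < seed_len:
        logger.warning("read %s shorter than the seed length; no seeds", read.id)
        return []
    last = n - seed_len
    offsets = list(range(0, last + 1, config.stride))
    if offsets[-1] != last:
        offsets.append(last)
    return [(q, codes[q : q + seed_len]) for q in offsets]


def generate_candidates(index: SeedIndex, read: EncodedRead,
                        config: SeedingConfig = SeedingConfig()) -> list[CandidatePair]:
    """All merged candidate diagonals of a read, both strands.

    The reverse strand queries the read's reverse-complement codes against
    the forward-only index, so ``window_start`` is always a forward-strand
    genome coordinate.  Diagonals starting left of the genome are clamped
    to 0 (the extension engine charges the missing coverage itself).
    """
    k = index.config.seed_len
    out: list[CandidatePair] = []
    for strand in (FORWARD, REVERSE):
        seeds = extract_seeds(read, strand, config, k)
        if not seeds:
            continue
        votes: dict[int, set] = {}
        offsets = np.array([q for q, _ in seeds], dtype=np.int64)
        codes = read.fwd if strand == FORWARD else read.rc
        packed_all = pack_kmers(codes, k)
        slots = index.slots_of(packed_all[offsets])
        for q, slot in zip(offsets.tolist(), slots.tolist()):
            for p in index.positions_at(slot):
                diag = max(int(p) - q, 0)
                votes.setdefault(diag, set()).add(q)
        cands = [
            CandidatePair(read.id, strand, diag, frozenset(qs))
            for diag, qs in sorted(votes.items())
        ]
        if config.max_candidates_per_read and len(cands) > config.max_candidates_per_read:
            cands.sort(key=lambda c: (-len(c.supporting_offsets), c.window_start))
            cands = sorted(cands[: config.max_candidates_per_read],
                           key=lambda c: c.window_start)
        out.extend(cands)
    return out


def fetch_window(genome: Sequence | np.ndarray, cand: CandidatePair,
                 read_len: int) -> tuple[str, str, str | None]:
    """The two engine windows and the extra right base of a candidate.

    ``window_normal`` starts at the candidate diagonal, ``window_shifted``
    one base left; ``right_extra_base`` is the base just past the normal
    window.  Positions outside the genome are absent, never fabricated, so
    windows at the genome edges may be short and the extra base ``None``.
    """
    if isinstance(genome, Sequence):
        bases = genome.bases
    else:
        from .seqio import decode_bases

        bases = decode_bases(genome)
    ws = cand.window_start
    glen = len(bases)
    normal = bases[max(ws, 0): min(ws + read_len, glen)]
    shifted = bases[max(ws - 1, 0): min(ws + read_len - 1, glen)]
    extra = bases[ws + read_len] if 0 <= ws + read_len < glen else None
    return normal, shifted, extra
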