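"""Banded semi-global alignment and its block-wise parallel decomposition.

The extension stage scores a read against a candidate reference window with
a unit-cost semi-global Needleman-Wunsch restricted to a band of width one
around the main diagonal: matches cost 0, mismatches and indels cost 1, the
read is aligned end to end, and leading/trailing reference gaps are free
(the optimum is the minimum over the last DP column).

Within the band each read column touches three cells — the upper (u), main
(m) and lower (l) diagonals.  The band is cut into consecutive,
non-overlapping v-shaped blocks; each block reduces to a 3 x w
match/mismatch matrix and is scored independently, yielding a
``BlockScore`` triple (S_u, S_m, S_l) annotated with the entry diagonal(s)
that achieve each exit score.  Block scores are then concatenated over a
balanced tree, pruning any partial score above the error threshold to the
sentinel x.

Two concatenation modes are provided.  The *heuristic* mode carries one
score per exit diagonal plus its start labels, exactly as the hardware
formulation does; when the minimizing entry diagonals of different
continuations diverge this can overestimate.  The *exact* mode (default)
carries the full 3 x 3 min-plus transfer matrix per block, which composes
associatively and reproduces the conventional banded computation bit for
bit; it is the mode the pipeline runs.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f

__all__ = [
    "INF",
    "X",
    "ScoringScheme",
    "BandedParams",
    "BlockScore",
    "TransferBlock",
    "AlignmentResult",
    "banded_nw",
    "full_nw",
    "partition_blocks",
    "align_block_initial",
    "align_block_later",
    "transfer_block",
    "compose",
    "concatenate",
    "finalize",
    "block_align",
    "dual_engine_align",
    "error_threshold",
    "estimate_cycles",
]

INF = 1 << 40  # absorbing cost of the pruned/unreachable sentinel
X = INF  # alias: a score printed as "x"

U, M, L = 0, 1, 2
_DIAG_NAMES = "uml"


@dataclasses.dataclass(frozen=True)
class ScoringScheme:
    """Unit edit costs: 0 per match, 1 per mismatch, 1 per indel."""

    match: int = 0
    mismatch: int = 1
    indel: int = 1


@dataclasses.dataclass(frozen=True)
class BandedParams:
    """Geometry of the block engine.

    The production engine is fixed at band width one (net indel budget of
    one base); the head block covers the first four read columns and the
    remaining columns are cut into blocks of eight, so twelve blocks extend
    a 100 bp read.  The 12 bp illustration geometry (no head, three 4-wide
    blocks) is obtained by setting ``head_width=0, block_width=4``.
    """

    band_width: int = 1
    block_width: int = 8
    head_width: int = 4
    max_read_len: int = 100

    def __post_init__(self):
        if self.band_width != 1:
            raise ValueError("the block engine supports band width 1 only")


@dataclasses.dataclass
class BlockScore:
    """Per-exit-diagonal block costs with their achieving entry labels.

    ``scores[k]`` is the best within-block path cost exiting on diagonal k
    (order u, m, l; ``INF`` encodes the pruned sentinel x) and ``starts[k]``
    the set of entry diagonals achieving it (frozenset over {"u","m","l"}).
    """

    scores: tuple
    starts: tuple

    def __repr__(self):
        def s(v):
            return "x" if v >= INF else str(v)

        def lab(st):
            return "".join(c for c in _DIAG_NAMES if c in st) or "-"

        return (f"BlockScore(({s(self.scores[0])}, {s(self.scores[1])}, "
                f"{s(self.scores[2])}), ({lab(self.starts[0])}, "
                f"{lab(self.starts[1])}, {lab(self.starts[2])}))")


@dataclasses.dataclass
class TransferBlock:
    """Full 3x3 min-plus element: cost[entry][exit] within one block."""

    cost: tuple  # 3x3 nested tuples


@dataclasses.dataclass
class AlignmentResult:
    read_id: str
    strand: str  # "forward" | "reverse"
    ref_start: int
    score: int
    engine: str  # "normal" | "shifted"
    passed: bool


def error_threshold(read_len: int, identity_fraction: float = 0.90) -> int:
    """Maximum edit cost admitted for a read of ``read_len`` bases.

    ``floor(read_len * (1 - identity))``: a 36 bp read at 90% identity may
    carry at most three errors, at most one of which is an indel (the
    band-width-one engine cannot realize more than one net indel anyway).
    """
    if not 0 < identity_fraction < 1:
        raise ValueError("identity_fraction must be in (0, 1)")
    # guard against float droop on exact multiples (e.g. 100 * 0.1)
    return int(math.floor(read_len * (1 - identity_fraction) + 1e-9))


def estimate_cycles(read_len: int, block_width: int, mode: str = "parallel") -> int:
    """Time steps of the cost model: blocks in lockstep plus a log-depth tree.

    Sequential scoring needs one step per read column; the parallel scheme
    needs ``block_width`` steps of block alignment plus ``ceil(log2(B))``
    concatenation steps for ``B = ceil(read_len / block_width)`` blocks
    (12 bp in three 4 bp blocks: 4 + 2 = 6).
    """
    if not read_len >= block_width >= 1:
        raise ValueError("need read_len >= block_width >= 1")
    if mode == "sequential":
        return read_len
    if mode != "parallel":
        raise ValueError(f"unknown mode {mode!r}")
    blocks = -(-read_len // block_width)
    return block_width + math.ceil(math.log2(blocks)) if blocks > 1 else block_width


# ---------------------------------------------------------------------------
# Conventional DP oracles


def _as_codes(seq) -> np.ndarray:
    from .seqio import encode_bases

    if isinstance(seq, str):
        return encode_bases(seq)
    return np.asarray(seq, dtype=np.uint8)


def banded_nw(read, ref, d: int = 1,
              scheme: ScoringScheme = ScoringScheme()) -> int:
    """Banded semi-global NW score; the oracle the block engine must match.

    Cells are restricted to ``|i - j| <= d`` (i indexes the reference, j the
    read).  Initialization: S(i,0) = 0 (free leading reference gaps),
    S(0,j) = j.  Returns the minimum over the last read column, or ``INF``
    when no in-band cell of the last column exists.
    """
    r = _as_codes(read)
    w = _as_codes(ref)
    n, m = len(r), len(w)
    if n == 0:
        raise ValueError("empty read")
    S = [[INF] * (n + 1) for _ in range(m + 1)]
    for i in range(m + 1):  # leading reference gaps are free
        S[i][0] = 0
    for j in range(1, n + 1):
        S[0][j] = j if j <= d else INF
    for i in range(1, m + 1):
        lo = max(1, i - d)
        hi = min(n, i + d)
        for j in range(lo, hi + 1):
            delta = scheme.match if w[i - 1] == r[j - 1] else scheme.mismatch
            best = S[i - 1][j - 1] + delta
            if S[i - 1][j] + scheme.indel < best:
                best = S[i - 1][j] + scheme.indel
            if S[i][j - 1] + scheme.indel < best:
                best = S[i][j - 1] + scheme.indel
            S[i][j] = best
    in_band = [S[i][n] for i in range(m + 1) if abs(i - n) <= d]
    result = min(in_band) if in_band else INF
    return result if result < INF else INF


def full_nw(read, ref, scheme: ScoringScheme = ScoringScheme()) -> int:
    """Unbanded semi-global NW score (band width = infinity)."""
    r = _as_codes(read)
    w = _as_codes(ref)
    return banded_nw(r, w, d=max(len(r), len(w)), scheme=scheme)


# ---------------------------------------------------------------------------
# Block decomposition
#
# Diagonal coordinates: read column j (1-based) touches rows i = j - 1 (u),
# j (m), j + 1 (l).  Row i consumes reference base ``start + i - 1`` of the
# genome; row 0 is the alignment origin's boundary row (no base).  A cell
# whose reference base does not exist is unreachable (x); the u cell of
# column 1 is the valid boundary cell S(0,1).


@dataclasses.dataclass
class BlockSubmatrix:
    """One block's 3 x w substitution matrix with cell validity."""

    first_col: int  # 1-based read column of the block's first column
    delta: np.ndarray  # int64 (3, w): 0 match, 1 mismatch, INF no diagonal entry
    valid: np.ndarray  # bool (3, w): cell exists


def _build_submatrix(read: np.ndarray, genome: np.ndarray, start: int,
                     first_col: int, width: int) -> BlockSubmatrix:
    glen = len(genome)
    delta = np.full((3, width), INF, dtype=np.int64)
    valid = np.zeros((3, width), dtype=bool)
    for t in range(width):
        j = first_col + t
        for k, off in ((U, -1), (M, 0), (L, 1)):
            i = j + off
            if i == 0:
                valid[k, t] = True  # boundary row: reachable, no diagonal move
                continue
            pos = start + i - 1
            if 0 <= pos < glen:
                valid[k, t] = True
                delta[k, t] = 0 if genome[pos] == read[j - 1] else 1
    return BlockSubmatrix(first_col, delta, valid)


def partition_blocks(read, window, params: BandedParams = BandedParams(),
                     start: int = 0) -> tuple[BlockSubmatrix | None, list[BlockSubmatrix]]:
    """Cut the banded search space into the head block and 3 x w blocks.

    ``window`` is the reference the band runs over; ``start`` offsets it
    (row i consumes ``window[start + i - 1]``), which lets a caller address
    candidate windows inside a whole genome without copying.  The head
    covers the first ``head_width`` read columns (possibly none); the rest
    is cut into blocks of ``block_width``, the last possibly partial.
    """
    r = _as_codes(read)
    g = _as_codes(window)
    n = len(r)
    if n > params.max_read_len:
        raise ValueError(f"read longer than max_read_len={params.max_read_len}")
    hw = min(params.head_width, n)
    head = _build_submatrix(r, g, start, 1, hw) if hw else None
    blocks = []
    col = hw + 1
    while col <= n:
        w = min(params.block_width, n - col + 1)
        blocks.append(_build_submatrix(r, g, start, col, w))
        col += w
    return head, blocks


def _sweep(sub: BlockSubmatrix, entry: tuple) -> tuple:
    """Run the three-diagonal column recurrence across one block.

    ``entry`` is the (u, m, l) state at the column before the block; the
    update order within a column is u, then m (vertical from u), then l
    (vertical from m), matching the move structure of the band.
    """
    u, m, l = entry
    delta, valid = sub.delta, sub.valid
    for t in range(delta.shape[1]):
        nu = min(u + delta[U, t], m + 1) if valid[U, t] else INF
        nm = min(m + delta[M, t], l + 1, nu + 1) if valid[M, t] else INF
        nl = min(l + delta[L, t], nm + 1) if valid[L, t] else INF
        u, m, l = min(nu, INF), min(nm, INF), min(nl, INF)
    return u, m, l


def align_block_initial(sub: BlockSubmatrix, l_entry_cost: int = 1) -> BlockScore:
    """Score the first block from the alignment origin.

    All paths start at the origin, so every start label is m.  The lower
    diagonal can still be entered at column 0 through a vertical move from
    the origin (one leading reference gap, ``l_entry_cost``); an all-match
    block therefore scores (1, 0, 1) — each off-diagonal exit forces
    exactly one indel.
    """
    scores = _sweep(sub, (INF, 0, l_entry_cost))
    only_m = frozenset("m")
    return BlockScore(tuple(min(s, INF) for s in scores),
                      (only_m, only_m, only_m))


def transfer_block(sub: BlockSubmatrix) -> TransferBlock:
    """Full 3x3 entry-to-exit cost table of one block."""
    rows = []
    for e in range(3):
        entry = [INF, INF, INF]
        entry[e] = 0
        rows.append(tuple(min(s, INF) for s in _sweep(sub, tuple(entry))))
    return TransferBlock(tuple(rows))


def align_block_later(sub: BlockSubmatrix) -> BlockScore:
    """Score a later block over its three possible entry diagonals.

    For each exit diagonal, the best cost over all entries is kept together
    with the label set of every minimizing entry (ties keep all labels).
    """
    t = transfer_block(sub).cost
    scores, starts = [], []
    for x in range(3):
        best = min(t[e][x] for e in range(3))
        scores.append(best)
        if best >= INF:
            starts.append(frozenset())
        else:
            starts.append(frozenset(
                _DIAG_NAMES[e] for e in range(3) if t[e][x] == best))
    return BlockScore(tuple(scores), tuple(starts))


def compose(left: TransferBlock, right: TransferBlock) -> TransferBlock:
    """Min-plus composition of two transfer blocks (associative)."""
    rows = []
    for e in range(3):
        rows.append(tuple(
            min(INF, min(left.cost[e][k] + right.cost[k][x] for k in range(3)))
            for x in range(3)))
    return TransferBlock(tuple(rows))


def concatenate(left: BlockScore, right: BlockScore,
                threshold: int = INF) -> BlockScore:
    """Chain two block scores through the right block's start labels.

    For each exit x of the right block the new score is
    ``right.scores[x] + min over d in right.starts[x] of left.scores[d]``
    and the new label set is the union of ``left.starts[d]`` over the
    minimizing d.  Scores above ``threshold`` are pruned to x.
    """
    scores, starts = [], []
    for x in range(3):
        rs = right.scores[x]
        if rs >= INF or not right.starts[x]:
            scores.append(INF)
            starts.append(frozenset())
            continue
        cands = [(left.scores[_DIAG_NAMES.index(d)], d) for d in right.starts[x]]
        best = min(c for c, _ in cands)
        total = rs + best
        if total > threshold or total >= INF:
            scores.append(INF)
            starts.append(frozenset())
            continue
        labels: frozenset = frozenset()
        for c, d in cands:
            if c == best:
                labels |= left.starts[_DIAG_NAMES.index(d)]
        scores.append(total)
        starts.append(labels)
    return BlockScore(tuple(scores), tuple(starts))


def finalize(blockscore: BlockScore) -> int:
    """Final alignment score: minimum over the three exit diagonals (or x)."""
    return min(blockscore.scores)


def _tree_fold(items: list, combine):
    """Balanced-tree reduction (pairs adjacent elements each round)."""
    while len(items) > 1:
        nxt = []
        for i in range(0, len(items) - 1, 2):
            nxt.append(combine(items[i], items[i + 1]))
        if len(items) % 2:
            nxt.append(items[-1])
        items = nxt
    return items[0]


# Entry state of the whole banded matrix: the origin (m) costs 0, and the
# semi-global free leading reference gap admits the l diagonal at cost 0
# when its row exists; the u diagonal does not exist before column 1.

def _entry_state(genome: np.ndarray, start: int) -> tuple:
    l0 = 0 if 0 <= start < len(genome) else INF
    return (INF, 0, l0)


def block_align(read, window, params: BandedParams = BandedParams(),
                threshold: int = INF, mode: str = "exact",
                start: int = 0) -> int:
    """Score a candidate window with the block-decomposed banded engine.

    ``mode="exact"`` composes full transfer blocks and equals
    :func:`banded_nw` with d=1 on the same window; ``mode="heuristic"``
    reproduces the single-score-per-exit hardware formulation (never lower
    than the exact score).  Returns ``INF`` (x) when every exit is pruned.
    """
    r = _as_codes(read)
    g = _as_codes(window)
    head, blocks = partition_blocks(r, g, params, start=start)
    subs = ([head] if head is not None else []) + blocks
    if mode == "exact":
        transfers = [transfer_block(s) for s in subs]
        folded = _tree_fold(transfers, compose)
        e = _entry_state(g, start)
        score = min(
            min(INF, e[k] + folded.cost[k][x]) for k in range(3) for x in range(3)
        )
        return score if score <= threshold else INF
    if mode != "heuristic":
        raise ValueError(f"unknown mode {mode!r}")
    l_entry = 1 if 0 <= start < len(g) else INF
    scores = [align_block_initial(subs[0], l_entry)]
    scores += [align_block_later(s) for s in subs[1:]]
    folded = _tree_fold(scores, lambda a, b: concatenate(a, b, threshold))
    out = finalize(folded)
    return out if out <= threshold and out < INF else INF


# ---------------------------------------------------------------------------
# Fast production kernel: the same recurrence as the exact block mode,
# swept column by column over the genome without materializing windows.


@njit(cache=True)
def _band1_kernel(read, genome, start):  # pragma: no cover - jit-compiled
    n = len(read)
    glen = len(genome)
    big = INF
    u = big
    m = 0
    l = 0 if 0 <= start < glen else big
    for j in range(1, n + 1):
        # u cell: row j-1
        i = j - 1
        if i == 0:
            nu = m + 1
        else:
            pos = start + i - 1
            if 0 <= pos < glen:
                du = 0 if genome[pos] == read[j - 1] else 1
                nu = min(u + du, m + 1)
            else:
                nu = big
        # m cell: row j
        pos = start + j - 1
        if 0 <= pos < glen:
            dm = 0 if genome[pos] == read[j - 1] else 1
            nm = min(m + dm, l + 1, nu + 1)
        else:
            nm = big
        # l cell: row j+1
        pos = start + j
        if 0 <= pos < glen:
            dl = 0 if genome[pos] == read[j - 1] else 1
            nl = min(l + dl, nm + 1)
        else:
            nl = big
        u = nu if nu < big else big
        m = nm if nm < big else big
        l = nl if nl < big else big
    return min(u, m, l)


def band1_score(read_codes: np.ndarray, genome_codes: np.ndarray, start: int) -> int:
    """Exact band-1 semi-global score of a read at a genome diagonal.

    Equivalent to ``block_align(read, genome, mode="exact", start=start)``
    with an unbounded threshold; rows beyond either genome end are
    unreachable, which also covers the extra right base of the candidate
    window (row n+1) without special-casing.
    """
    return int(_band1_kernel(read_codes, genome_codes, start))


def dual_engine_align(read_codes: np.ndarray, genome_codes: np.ndarray,
                      window_start: int, threshold: int,
                      params: BandedParams = BandedParams(),
                      mode: str = "exact",
                      read_id: str = "", strand: str = "forward") -> AlignmentResult:
    """Score a candidate with the normal and the left-shifted engine.

    The normal engine runs the band at ``window_start``; the shifted engine
    one base to the left, recovering alignments that need one reference
    base outside the normal window.  The lower-diagonal exit consumes one
    base right of the window; a base that does not exist on the genome
    leaves that exit unreachable rather than inventing a base.  The better
    of the two engines is reported (ties favour the normal engine).
    """
    if mode == "exact":
        s_norm = band1_score(read_codes, genome_codes, window_start)
        s_shift = band1_score(read_codes, genome_codes, window_start - 1)
    else:
        s_norm = block_align(read_codes, genome_codes, params, threshold,
                             mode=mode, start=window_start)
        s_shift = block_align(read_codes, genome_codes, params, threshold,
                              mode=mode, start=window_start - 1)
    if s_shift < s_norm:
        score, engine, ref_start = s_shift, "shifted", window_start - 1
    else:
        score, engine, ref_start = s_norm, "normal", window_start
    return AlignmentResult(read_id, strand, ref_start, int(score), engine,
                           passed=score <= threshold)
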