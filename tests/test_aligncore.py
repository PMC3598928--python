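import itertools
import random

import numpy as np
import pytest
from hypothesis import given, strategies as st

from bandmap.aligncore import (
    INF,
    BandedParams,
    BlockScore,
    align_block_initial,
    align_block_later,
    band1_score,
    banded_nw,
    block_align,
    compose,
    concatenate,
    dual_engine_align,
    error_threshold,
    estimate_cycles,
    finalize,
    full_nw,
    partition_blocks,
    transfer_block,
)
from bandmap.seqio import encode_bases
from bandmap.simulate import random_genome

from conftest import brute_force_banded

ILLUSTRATION = BandedParams(head_width=0, block_width=4)  # 12 bp, 3 blocks of 4


def rand_seq(rng, n, alphabet="ACGT"):
    return "".join(rng.choice(alphabet) for _ in range(n))


class TestOracles:
    def test_identity_scores_zero(self):
        assert banded_nw("ACGTACGTACGT", "ACGTACGTACGT") == 0
        assert full_nw("ACGTACGTACGT", "ACGTACGTACGT") == 0

    def test_free_flanking_reference(self):
        assert banded_nw("ACGT", "AACGTT", d=1) == 0

    def test_forced_read_gap(self):
        assert full_nw("AC", "A") == 1

    def test_brute_force_agreement(self):
        rng = random.Random(7)
        for _ in range(120):
            n, m = rng.randint(1, 6), rng.randint(1, 6)
            r, w = rand_seq(rng, n, "AC"), rand_seq(rng, m, "AC")
            for d in (1, 2, 6):
                got = banded_nw(r, w, d)
                assert (got if got < INF else None) == \
                    brute_force_banded(r, w, d), (r, w, d)

    def test_band_restricts_paths(self):
        rng = random.Random(8)
        for _ in range(60):
            r, w = rand_seq(rng, 8), rand_seq(rng, 8)
            assert full_nw(r, w) <= banded_nw(r, w, d=1)

    def test_full_nw_matches_edlib(self):
        edlib = pytest.importorskip("edlib")
        rng = random.Random(9)
        for _ in range(80):
            r = rand_seq(rng, rng.randint(1, 40))
            w = rand_seq(rng, rng.randint(1, 60))
            assert full_nw(r, w) == edlib.align(r, w, mode="HW")["editDistance"]


class TestPartition:
    def test_illustration_geometry(self):
        head, blocks = partition_blocks("A" * 12, "A" * 12, ILLUSTRATION)
        assert head is None and [b.delta.shape[1] for b in blocks] == [4, 4, 4]

    def test_hardware_geometry_100bp(self):
        head, blocks = partition_blocks("A" * 100, "A" * 100, BandedParams())
        assert head.delta.shape[1] == 4
        assert len(blocks) == 12 and all(b.delta.shape[1] == 8 for b in blocks)

    def test_partial_final_block(self):
        head, blocks = partition_blocks("A" * 20, "A" * 20, BandedParams())
        assert [b.delta.shape[1] for b in blocks] == [8, 8]

    def test_columns_cover_read_exactly(self):
        head, blocks = partition_blocks("A" * 57, "A" * 57, BandedParams())
        cols = head.delta.shape[1] + sum(b.delta.shape[1] for b in blocks)
        assert cols == 57


def submatrix(deltas):
    """A fully-valid interior block from a 3 x w delta table."""
    from bandmap.aligncore import BlockSubmatrix

    d = np.array(deltas, dtype=np.int64)
    return BlockSubmatrix(2, d, np.ones(d.shape, dtype=bool))


class TestBlockScores:
    def test_initial_all_match(self):
        # window long enough that all three exit rows exist
        head, blocks = partition_blocks("AAAA", "AAAAA", ILLUSTRATION)
        s = align_block_initial(blocks[0])
        assert s.scores == (1, 0, 1)  # off-diagonal exits force one indel
        assert s.starts == (frozenset("m"),) * 3

    def test_later_all_match_stays_on_diagonal(self):
        s = align_block_later(submatrix([[0] * 4] * 3))
        assert s.scores == (0, 0, 0)
        assert s.starts == (frozenset("u"), frozenset("m"), frozenset("l"))

    def test_later_is_entrywise_min_of_transfer(self):
        rng = random.Random(11)
        for _ in range(50):
            sub = submatrix([[rng.randint(0, 1) for _ in range(4)] for _ in range(3)])
            t = transfer_block(sub).cost
            s = align_block_later(sub)
            for x in range(3):
                assert s.scores[x] == min(t[e][x] for e in range(3))

    def test_block_vs_banded_on_realized_fragment(self):
        """The initial block from real sequences scores like the brute-force
        banded oracle started at the alignment origin."""
        rng = random.Random(12)
        for _ in range(40):
            r = rand_seq(rng, 4)
            w = rand_seq(rng, 6)
            head, blocks = partition_blocks(r, w, BandedParams(head_width=4))
            s = align_block_initial(head)
            got = min(s.scores)
            oracle = brute_force_banded(r, w[:5], d=1, free_start=False)
            assert (got if got < INF else None) == oracle


class TestConcatenation:
    S1 = BlockScore((1, 0, 1), (frozenset("m"),) * 3)
    S2 = BlockScore((1, 2, 2), (frozenset("m"),) * 3)
    S3 = BlockScore((1, 2, 3), (frozenset("u"), frozenset("u"), frozenset("ul")))

    def test_printed_chain(self):
        s23 = concatenate(self.S2, self.S3, threshold=3)
        assert s23.scores == (2, 3, INF)
        assert s23.starts[:2] == (frozenset("m"), frozenset("m"))
        s123 = concatenate(self.S1, s23, threshold=3)
        assert s123.scores == (2, 3, INF)
        assert finalize(s123) == 2

    def test_neutral_element(self):
        e = BlockScore((0, 0, 0), (frozenset("u"), frozenset("m"), frozenset("l")))
        for bs in (self.S1, self.S2, self.S3):
            out = concatenate(e, bs)
            assert out.scores == bs.scores and out.starts == bs.starts

    def test_finalize(self):
        assert finalize(BlockScore((2, 3, INF), (frozenset("m"),) * 3)) == 2
        assert finalize(BlockScore((INF,) * 3, (frozenset(),) * 3)) == INF

    def test_transfer_composition_associative(self):
        rng = random.Random(13)
        for _ in range(40):
            subs = [submatrix([[rng.randint(0, 1) for _ in range(3)]
                               for _ in range(3)]) for _ in range(4)]
            ts = [transfer_block(s) for s in subs]
            left = compose(compose(compose(ts[0], ts[1]), ts[2]), ts[3])
            right = compose(ts[0], compose(ts[1], compose(ts[2], ts[3])))
            tree = compose(compose(ts[0], ts[1]), compose(ts[2], ts[3]))
            assert left.cost == right.cost == tree.cost


class TestBlockAlign:
    @pytest.mark.parametrize("params", [BandedParams(), ILLUSTRATION,
                                        BandedParams(head_width=2, block_width=3)])
    def test_exact_equals_banded(self, params):
        rng = random.Random(14)
        for _ in range(200):
            n = rng.randint(1, 12)
            m = rng.randint(max(1, n - 2), n + 2)
            r, w = rand_seq(rng, n), rand_seq(rng, m)
            assert block_align(r, w, params) == banded_nw(r, w, d=1)

    def test_heuristic_dominates_exact(self):
        rng = random.Random(15)
        for _ in range(200):
            n = rng.randint(1, 12)
            r, w = rand_seq(rng, n, "AC"), rand_seq(rng, n, "AC")
            assert block_align(r, w, mode="heuristic") >= banded_nw(r, w, d=1)

    def test_identical_is_zero_both_modes(self):
        s = "ACGTTGCA" * 4
        assert block_align(s, s) == 0
        assert block_align(s, s, mode="heuristic") == 0

    def test_kernel_matches_block_exact_at_offsets(self):
        rng = random.Random(16)
        g = rand_seq(rng, 200)
        gc = encode_bases(g)
        for _ in range(150):
            n = rng.randint(1, 20)
            r = rand_seq(rng, n)
            s = rng.randint(-2, 200)
            assert band1_score(encode_bases(r), gc, s) == \
                block_align(r, g, start=s)

    def test_threshold_pruning_preserves_passing_scores(self):
        rng = random.Random(17)
        for _ in range(100):
            n = rng.randint(4, 16)
            r, w = rand_seq(rng, n, "AC"), rand_seq(rng, n, "AC")
            t = error_threshold(n) if n >= 10 else 2
            free = block_align(r, w, threshold=INF)
            capped = block_align(r, w, threshold=t)
            if free <= t:
                assert capped == free
            else:
                assert capped == INF


class TestDualEngine:
    def test_leading_base_outside_window(self):
        """A read needing one reference base left of the window is recovered
        by the shifted engine at a strictly lower score."""
        g = random_genome(400, rng_seed=21)
        gc = encode_bases(g.bases)
        w, L = 200, 30
        read = g.bases[w - 1] + g.bases[w : w + L - 1]
        rc = encode_bases(read)
        norm = band1_score(rc, gc, w)
        shift = band1_score(rc, gc, w - 1)
        assert shift == 0 < norm
        res = dual_engine_align(rc, gc, w, threshold=error_threshold(L))
        assert res.engine == "shifted" and res.score == 0
        assert res.ref_start == w - 1
        # the widened-region oracle agrees
        assert banded_nw(read, g.bases[w - 1 : w + L]) == 0

    def test_exact_window_prefers_normal_engine(self):
        g = random_genome(400, rng_seed=22)
        gc = encode_bases(g.bases)
        read = g.bases[100:130]
        res = dual_engine_align(encode_bases(read), gc, 100, threshold=3)
        assert res.engine == "normal" and res.score == 0 and res.ref_start == 100

    def test_trailing_deletion_uses_extra_base(self):
        """A 1-base deletion makes the alignment consume one base past the
        window; the lower-diagonal exit picks it up via the extra base."""
        g = random_genome(400, rng_seed=23)
        gc = encode_bases(g.bases)
        w, L = 150, 30
        read = g.bases[w : w + 10] + g.bases[w + 11 : w + L + 1]  # deletion
        assert len(read) == L
        score = band1_score(encode_bases(read), gc, w)
        assert score == 1
        assert banded_nw(read, g.bases[w : w + L + 1]) == 1

    def test_absent_right_base_cannot_fake_a_match(self):
        """At the genome end the extra base does not exist; the score equals
        the banded oracle on the true, truncated region."""
        g = random_genome(200, rng_seed=24)
        gc = encode_bases(g.bases)
        L = 30
        w = g.length - L
        read = g.bases[w : w + 10] + g.bases[w + 11 :] + "A"  # wants a base past the end
        assert len(read) == L
        assert band1_score(encode_bases(read), gc, w) == \
            banded_nw(read, g.bases[w:], d=1)

    def test_simulated_error_reads_match_widened_oracle(self):
        """Best dual-engine score equals the banded oracle on the widened
        region for reads with <= 1 indel and a few substitutions."""
        rng = random.Random(25)
        g = random_genome(2_000, rng_seed=25)
        gc = encode_bases(g.bases)
        L = 40
        for _ in range(60):
            p = rng.randint(2, g.length - L - 2)
            bases = list(g.bases[p : p + L + 1])
            kind = rng.choice(["none", "sub", "del", "ins"])
            if kind == "sub":
                i = rng.randrange(L)
                bases[i] = rng.choice([b for b in "ACGT" if b != bases[i]])
            elif kind == "del":
                del bases[rng.randrange(L)]
            elif kind == "ins":
                bases.insert(rng.randrange(L), rng.choice("ACGT"))
            read = "".join(bases)[:L]
            rc = encode_bases(read)
            best = min(band1_score(rc, gc, p), band1_score(rc, gc, p - 1))
            oracle = banded_nw(read, g.bases[p - 1 : p + L + 1], d=2)
            assert best >= oracle  # band-1 engines cannot beat the wide oracle
            assert best <= 2  # and never miss the planted error budget


class TestConstants:
    @pytest.mark.parametrize("read_len,expected", [(36, 3), (100, 10), (76, 7)])
    def test_error_threshold(self, read_len, expected):
        assert error_threshold(read_len) == expected

    @pytest.mark.parametrize("args,expected", [
        ((12, 4, "parallel"), 6),
        ((12, 4, "sequential"), 12),
        ((96, 8, "parallel"), 12),
    ])
    def test_estimate_cycles(self, args, expected):
        assert estimate_cycles(*args) == expected

    def test_parallel_beats_sequential_for_long_reads(self):
        for L in (24, 48, 96):
            assert estimate_cycles(L, 8, "parallel") < estimate_cycles(L, 8, "sequential")
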