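"""Constant-seed bucket-hash index of the reference genome.

Every 15-mer of the forward genome strand is stored in a two-level table.
The packed 30-bit seed is split into a 16-bit prefix, which selects a
bucket, and a 14-bit suffix, which is hashed to 12 bits with a per-bucket
function from the H3 family (XOR of random matrix rows selected by the set
bits of the suffix).  Prefix and hash together address a primary table of
2^28 slots; a slot holding a single genome position stores it inline, a
slot holding two or more positions (a repeated seed, or distinct seeds that
collide within the bucket) points into a secondary collision table.

The primary table is kept as a sparse mapping with the same semantics as
the dense 2^28-slot layout: a dense array of that geometry would cost 1 GiB
regardless of genome size, while the sparse map scales with the number of
distinct seeds actually present.  Each occupied entry still packs into the
canonical 32-bit word ``c:1 | count:7 | ptr:24``.

Because the table stores no seed value, a lookup may return positions of
*other* seeds that hash-collided into the same slot; those false candidates
are eliminated by the extension stage, never by the index.
"""

from __future__ import annotations

import dataclasses
import io
import logging
import struct

import numpy as np

from .seqio import Sequence, encode_bases

__all__ = [
    "IndexConfig",
    "PrimaryEntry",
    "SeedIndex",
    "pack_kmer",
    "split_prefix_suffix",
    "h3_matrices",
    "h3_hash",
    "table_address",
    "build_index",
    "lookup",
    "pack_entry",
    "unpack_entry",
    "save_index",
    "load_index",
]

logger = logging.getLogger(__name__)

_MAGIC = b"SBIX"
_VERSION = 1

MAX_GENOME_LEN = 1 << 24  # Ptr/Pos are 24-bit fields


@dataclasses.dataclass(frozen=True)
class IndexConfig:
    """Geometry of the seed index.

    The default geometry (15 bp seeds, 16-bit prefix, 12-bit hash) yields
    2^28 addressable primary slots — a 64 K x 4 K table.  Scaled geometries
    (smaller prefix/hash) behave identically and are used in tests.
    """

    seed_len: int = 15
    prefix_bits: int = 16
    hash_bits: int = 12
    count_cap: int = 127
    rng_seed: int = 0

    @property
    def suffix_bits(self) -> int:
        return 2 * self.seed_len - self.prefix_bits

    @property
    def n_slots(self) -> int:
        return 1 << (self.prefix_bits + self.hash_bits)

    def __post_init__(self):
        if self.suffix_bits < 1:
            raise ValueError("prefix_bits must leave at least one suffix bit")
        if not 1 <= self.count_cap <= 127:
            raise ValueError("count_cap must fit the 7-bit Count field")


@dataclasses.dataclass
class PrimaryEntry:
    """One occupied 32-bit primary-table entry.

    ``c=0``: ``ptr`` is the single genome position of the slot's seed.
    ``c=1``: ``ptr`` is the start of ``count`` positions in the collision
    table.
    """

    c: int
    count: int
    ptr: int


def pack_entry(entry: PrimaryEntry) -> int:
    """Pack an entry into its 32-bit word: c:1 | count:7 | ptr:24."""
    if not (0 <= entry.count < 128 and 0 <= entry.ptr < (1 << 24)):
        raise ValueError("entry fields out of range")
    return (entry.c << 31) | (entry.count << 24) | entry.ptr


def unpack_entry(word: int) -> PrimaryEntry:
    return PrimaryEntry((word >> 31) & 1, (word >> 24) & 0x7F, word & 0xFFFFFF)


def pack_kmer(bases_or_codes, seed_len: int | None = None) -> int:
    """Pack a k-mer into a ``2k``-bit integer, leftmost base most significant.

    Accepts a string or an array of 2-bit codes.  A 15 bp seed packs into
    30 bits.
    """
    if isinstance(bases_or_codes, str):
        codes = encode_bases(bases_or_codes)
    else:
        codes = np.asarray(bases_or_codes, dtype=np.uint8)
    if seed_len is not None and len(codes) != seed_len:
        raise ValueError(f"expected a {seed_len}-mer, got length {len(codes)}")
    value = 0
    for c in codes:
        value = (value << 2) | int(c)
    return value


def pack_kmers(codes: np.ndarray, seed_len: int) -> np.ndarray:
    """Vectorized packing of every k-mer start position of a code array."""
    if len(codes) < seed_len:
        return np.empty(0, dtype=np.int64)
    win = np.lib.stride_tricks.sliding_window_view(codes, seed_len).astype(np.int64)
    weights = 1 << (2 * np.arange(seed_len - 1, -1, -1, dtype=np.int64))
    return win @ weights


def split_prefix_suffix(packed: int, config: IndexConfig) -> tuple[int, int]:
    """Split a packed seed into (prefix, suffix); top bits form the prefix."""
    suffix_mask = (1 << config.suffix_bits) - 1
    return packed >> config.suffix_bits, packed & suffix_mask


def h3_matrices(config: IndexConfig) -> np.ndarray:
    """Per-bucket H3 matrices, deterministic under ``config.rng_seed``.

    Shape ``(2^prefix_bits, suffix_bits)``; row ``i`` of a bucket's matrix
    is a ``hash_bits``-wide random word.
    """
    rng = np.random.default_rng(config.rng_seed)
    return rng.integers(
        0, 1 << config.hash_bits,
        size=(1 << config.prefix_bits, config.suffix_bits),
        dtype=np.uint32,
    )


def h3_hash(suffix: int, matrix: np.ndarray) -> int:
    """H3 hash: XOR of matrix rows selected by the set bits of ``suffix``.

    Bit ``i`` of the suffix (LSB first) selects row ``i``.
    """
    h = 0
    i = 0
    while suffix:
        if suffix & 1:
            h ^= int(matrix[i])
        suffix >>= 1
        i += 1
    return h


def _h3_hash_vec(suffixes: np.ndarray, prefixes: np.ndarray, matrices: np.ndarray,
                 config: IndexConfig) -> np.ndarray:
    h = np.zeros(len(suffixes), dtype=np.uint32)
    for bit in range(config.suffix_bits):
        sel = ((suffixes >> bit) & 1).astype(bool)
        if sel.any():
            h[sel] ^= matrices[prefixes[sel], bit]
    return h


def table_address(prefix: int, h: int, config: IndexConfig) -> int:
    """Primary-table slot index: prefix selects the bucket, hash the slot."""
    return (prefix << config.hash_bits) | h


@dataclasses.dataclass
class SeedIndex:
    """The two-level seed index plus the coded reference it was built from."""

    config: IndexConfig
    primary: dict  # slot index -> PrimaryEntry
    collision: np.ndarray  # uint32 genome positions
    genome_id: str
    genome_len: int
    refcodes: np.ndarray  # 2-bit codes of the (N-resolved) genome
    overflowed_slots: set = dataclasses.field(default_factory=set)

    def __post_init__(self):
        self._matrices = h3_matrices(self.config)

    def slot_of(self, packed: int) -> int:
        prefix, suffix = split_prefix_suffix(packed, self.config)
        return table_address(prefix, h3_hash(suffix, self._matrices[prefix]), self.config)

    def slots_of(self, packed: np.ndarray) -> np.ndarray:
        packed = np.asarray(packed, dtype=np.int64)
        prefixes = (packed >> self.config.suffix_bits).astype(np.int64)
        suffixes = packed & ((1 << self.config.suffix_bits) - 1)
        h = _h3_hash_vec(suffixes, prefixes, self._matrices, self.config)
        return (prefixes << self.config.hash_bits) | h

    def positions_at(self, slot: int) -> np.ndarray:
        entry = self.primary.get(slot)
        if entry is None:
            return np.empty(0, dtype=np.uint32)
        if entry.c == 0:
            return np.array([entry.ptr], dtype=np.uint32)
        return self.collision[entry.ptr : entry.ptr + entry.count]


def build_index(genome: Sequence, config: IndexConfig | None = None) -> SeedIndex:
    """Index every k-mer start position of the forward genome strand.

    Positions are 0-based; only the forward strand is indexed (reads are
    queried in both orientations).  Slots whose occupancy exceeds
    ``count_cap`` keep their first ``count_cap`` positions and are flagged
    in the build log.
    """
    config = config or IndexConfig()
    k = config.seed_len
    if genome.length < k:
        raise ValueError(f"genome shorter than the seed length ({k})")
    if genome.length > MAX_GENOME_LEN:
        raise ValueError(
            "genome exceeds the 24-bit position space "
            f"({MAX_GENOME_LEN} bases); this build supports desk-scale genomes only"
        )
    codes = encode_bases(genome.bases)
    packed = pack_kmers(codes, k)
    idx = SeedIndex(config, {}, np.empty(0, dtype=np.uint32),
                    genome.id, genome.length, codes)
    slots = idx.slots_of(packed)

    order = np.argsort(slots, kind="stable")
    sorted_slots = slots[order]
    uniq, starts, counts = np.unique(sorted_slots, return_index=True, return_counts=True)

    primary: dict[int, PrimaryEntry] = {}
    collision_parts: list[np.ndarray] = []
    coll_len = 0
    overflowed: set[int] = set()
    for slot, start, count in zip(uniq.tolist(), starts.tolist(), counts.tolist()):
        positions = order[start : start + count]
        if count == 1:
            primary[slot] = PrimaryEntry(0, 1, int(positions[0]))
            continue
        if count > config.count_cap:
            overflowed.add(slot)
            positions = positions[: config.count_cap]
            count = config.count_cap
        primary[slot] = PrimaryEntry(1, count, coll_len)
        collision_parts.append(positions.astype(np.uint32))
        coll_len += count
    if overflowed:
        logger.warning(
            "%d slot(s) exceeded count_cap=%d; extra positions dropped",
            len(overflowed), config.count_cap,
        )
    idx.primary = primary
    idx.collision = (np.concatenate(collision_parts).astype(np.uint32)
                     if collision_parts else np.empty(0, dtype=np.uint32))
    idx.overflowed_slots = overflowed
    return idx


def lookup(index: SeedIndex, kmer) -> set[int]:
    """All genome positions stored at the k-mer's slot.

    The result is a superset of the k-mer's true positions: bucket-internal
    hash collisions may contribute positions of other seeds.
    """
    packed = pack_kmer(kmer, index.config.seed_len)
    return set(int(p) for p in index.positions_at(index.slot_of(packed)))


# ---------------------------------------------------------------------------
# Serialization: little-endian 32-bit words throughout.
# Header: magic, version, seed_len, prefix_bits, hash_bits, count_cap,
# rng_seed, genome_len, |genome_id|, genome_id, n_primary, n_collision.
# Primary block: (slot, packed entry word) pairs in slot order.
# Collision block: 24-bit positions in 32-bit words.
# Genome block: 2-bit codes packed four to a byte.

def save_index(index: SeedIndex, path) -> None:
    buf = io.BytesIO()
    gid = index.genome_id.encode()
    cfg = index.config
    buf.write(_MAGIC)
    buf.write(struct.pack(
        "<7I", _VERSION, cfg.seed_len, cfg.prefix_bits, cfg.hash_bits,
        cfg.count_cap, cfg.rng_seed & 0xFFFFFFFF, index.genome_len,
    ))
    buf.write(struct.pack("<I", len(gid)))
    buf.write(gid)
    buf.write(struct.pack("<2I", len(index.primary), len(index.collision)))
    slots = np.fromiter(sorted(index.primary), dtype=np.uint32, count=len(index.primary))
    words = np.fromiter(
        (pack_entry(index.primary[int(s)]) for s in slots),
        dtype=np.uint32, count=len(slots),
    )
    inter = np.empty(2 * len(slots), dtype="<u4")
    inter[0::2] = slots
    inter[1::2] = words
    buf.write(inter.tobytes())
    buf.write(index.collision.astype("<u4").tobytes())
    codes = index.refcodes
    padded = np.zeros(-(-len(codes) // 4) * 4, dtype=np.uint8)
    padded[: len(codes)] = codes
    packed_genome = (padded[0::4] | (padded[1::4] << 2)
                     | (padded[2::4] << 4) | (padded[3::4] << 6))
    buf.write(packed_genome.tobytes())
    with open(path, "wb") as fh:
        fh.write(buf.getvalue())


def load_index(path) -> SeedIndex:
    with open(path, "rb") as fh:
        data = fh.read()
    view = memoryview(data)
    if data[:4] != _MAGIC:
        raise ValueError("not a bandmap index file (bad magic number)")
    try:
        version, seed_len, prefix_bits, hash_bits, count_cap, rng_seed, genome_len = (
            struct.unpack_from("<7I", view, 4)
        )
        if version != _VERSION:
            raise ValueError(f"unsupported index version {version}")
        off = 4 + 28
        (gid_len,) = struct.unpack_from("<I", view, off)
        off += 4
        gid = bytes(view[off : off + gid_len]).decode()
        off += gid_len
        n_primary, n_collision = struct.unpack_from("<2I", view, off)
        off += 8
        inter = np.frombuffer(view, dtype="<u4", count=2 * n_primary, offset=off)
        off += 8 * n_primary
        collision = np.frombuffer(view, dtype="<u4", count=n_collision, offset=off).astype(np.uint32)
        off += 4 * n_collision
        n_bytes = -(-genome_len // 4)
        packed_genome = np.frombuffer(view, dtype=np.uint8, count=n_bytes, offset=off)
    except (struct.error, ValueError) as exc:
        if "unsupported index version" in str(exc):
            raise
        raise ValueError(f"truncated or corrupt index file: {exc}") from exc
    codes = np.empty(n_bytes * 4, dtype=np.uint8)
    codes[0::4] = packed_genome & 3
    codes[1::4] = (packed_genome >> 2) & 3
    codes[2::4] = (packed_genome >> 4) & 3
    codes[3::4] = (packed_genome >> 6) & 3
    config = IndexConfig(seed_len, prefix_bits, hash_bits, count_cap, rng_seed)
    primary = {
        int(inter[2 * i]): unpack_entry(int(inter[2 * i + 1])) for i in range(n_primary)
    }
    return SeedIndex(config, primary, collision, gid, genome_len, codes[:genome_len])
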