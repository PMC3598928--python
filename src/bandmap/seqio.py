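"""Sequence I/O, 2-bit base coding and chunked read staging.

The aligner works on 2-bit coded bases (A=0, C=1, G=2, T=3).  The mapping is
chosen so that the complement of a code is ``code XOR 3``, which makes
reverse complementation branch-free.  Each read is staged together with its
reverse complement, so a chunk of ``n`` reads of length ``L`` occupies
``n * L * 2 * 2`` bits.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Iterator, Sequence as TSequence

import numpy as np
from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator

__all__ = [
    "Sequence",
    "EncodedRead",
    "ReadChunk",
    "encode_bases",
    "decode_bases",
    "reverse_complement",
    "resolve_ns",
    "chunk_reads",
    "chunk_storage_bits",
    "read_fasta",
    "read_fastq",
    "encode_read",
    "write_sam",
]

BASES = "ACGT"

# 256-entry lookup: byte value of base -> 2-bit code, 255 marks invalid.
_CODE_LUT = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _CODE_LUT[ord(_b)] = _i
    _CODE_LUT[ord(_b.lower())] = _i

_DECODE = np.frombuffer(BASES.encode(), dtype=np.uint8)


@dataclasses.dataclass
class Sequence:
    """A named nucleotide string over {A, C, G, T, N}."""

    id: str
    bases: str

    @property
    def length(self) -> int:
        return len(self.bases)


@dataclasses.dataclass
class EncodedRead:
    """A read staged for alignment: forward and reverse-complement codes."""

    id: str
    fwd: np.ndarray
    rc: np.ndarray

    @property
    def length(self) -> int:
        return len(self.fwd)


@dataclasses.dataclass
class ReadChunk:
    reads: list
    capacity: int = 1000


def encode_bases(bases: str) -> np.ndarray:
    """Encode an A/C/G/T string into 2-bit codes (A=0, C=1, G=2, T=3).

    Raises ``ValueError`` naming the position of the first non-ACGT character.
    """
    raw = np.frombuffer(bases.encode("ascii"), dtype=np.uint8)
    codes = _CODE_LUT[raw]
    bad = np.nonzero(codes == 255)[0]
    if bad.size:
        pos = int(bad[0])
        raise ValueError(
            f"non-ACGT character {bases[pos]!r} at position {pos}"
        )
    return codes


def decode_bases(codes: np.ndarray) -> str:
    """Inverse of :func:`encode_bases`."""
    return _DECODE[np.asarray(codes, dtype=np.uint8)].tobytes().decode()


def reverse_complement(codes: np.ndarray) -> np.ndarray:
    """Reverse-complement an array of 2-bit codes (complement = XOR 3)."""
    return (codes[::-1] ^ 3).astype(np.uint8)


def resolve_ns(seq: Sequence, rng_seed: int) -> Sequence:
    """Replace every N with a random base drawn uniformly from ACGT.

    The replacement stream is deterministic under ``rng_seed`` so that an
    index built from the resolved genome is reproducible.  Lowercase bases
    are uppercased; non-N positions are otherwise unchanged.
    """
    bases = seq.bases.upper()
    if "N" not in bases:
        return Sequence(seq.id, bases)
    arr = np.frombuffer(bases.encode("ascii"), dtype=np.uint8).copy()
    ns = np.nonzero(arr == ord("N"))[0]
    rng = np.random.default_rng(rng_seed)
    arr[ns] = _DECODE[rng.integers(0, 4, size=ns.size)]
    return Sequence(seq.id, arr.tobytes().decode())


def encode_read(seq: Sequence) -> EncodedRead:
    fwd = encode_bases(seq.bases)
    return EncodedRead(seq.id, fwd, reverse_complement(fwd))


def chunk_reads(reads: TSequence[EncodedRead], capacity: int = 1000) -> list[ReadChunk]:
    """Partition reads, in order, into chunks of at most ``capacity``."""
    if capacity < 1:
        raise ValueError("chunk capacity must be >= 1")
    reads = list(reads)
    return [
        ReadChunk(reads[i : i + capacity], capacity)
        for i in range(0, len(reads), capacity)
    ]


def chunk_storage_bits(n_reads: int, read_len: int) -> int:
    """Bits needed to stage ``n_reads`` coded reads of ``read_len`` bases.

    Two bits per base, times two strands (forward + reverse complement):
    1,000 reads of 100 bp occupy 400,000 bits.
    """
    if n_reads < 0 or read_len < 0:
        raise ValueError("n_reads and read_len must be non-negative")
    return n_reads * read_len * 2 * 2


def read_fasta(path) -> list[Sequence]:
    """Read a (multi-record, line-wrapped) FASTA file."""
    return [Sequence(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def read_fastq(path) -> list[Sequence]:
    """Read a 4-line-record FASTQ file; base qualities are ignored.

    A malformed record raises ``ValueError`` naming the approximate line.
    """
    out: list[Sequence] = []
    with open(path) as fh:
        it = FastqGeneralIterator(fh)
        n = 0
        while True:
            try:
                title, bases, _qual = next(it)
            except StopIteration:
                break
            except ValueError as exc:
                raise ValueError(
                    f"malformed FASTQ record near line {4 * n + 1}: {exc}"
                ) from exc
            out.append(Sequence(title.split()[0], bases.upper()))
            n += 1
    return out


def sam_header(genome_id: str, genome_len: int, extra_comments: Iterable[str] = ()) -> dict:
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": genome_id, "LN": int(genome_len)}],
        "PG": [{"ID": "bandmap", "PN": "bandmap"}],
    }
    comments = list(extra_comments)
    if comments:
        header["CO"] = comments
    return header


def write_sam(records: Iterator, path, genome_id: str, genome_len: int,
              extra_comments: Iterable[str] = ()) -> None:
    """Write pysam ``AlignedSegment`` records as a SAM text file."""
    import pysam

    header = pysam.AlignmentHeader.from_dict(
        sam_header(genome_id, genome_len, extra_comments)
    )
    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        for rec in records:
            fh.write(rec)
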