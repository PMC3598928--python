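"""End-to-end single-end and paired-end mapping pipelines.

Reads are staged in chunks (1,000 by default), seeded against the index on
both strands, extended with the dual banded engine, filtered against the
identity threshold, deduplicated and emitted as SAM.  Results do not
depend on the chunk size; chunking only bounds the working set, mirroring
the host/aligner handshake of the accelerator the method was designed for.
"""

from __future__ import annotations

import dataclasses
import logging

from . import pairing, seqio
from .aligncore import AlignmentResult, BandedParams, dual_engine_align, error_threshold
from .index import SeedIndex
from .pairing import EndInput, PairParams
from .seedengine import SeedingConfig, generate_candidates
from .seqio import Sequence, chunk_reads, encode_read

__all__ = ["RunConfig", "align_reads", "align_pairs", "sam_records_single",
           "sam_records_paired", "results_from_sam"]

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class RunConfig:
    """Aligner parameters; serializable to a plain key=value text file."""

    seed_len: int = 15
    identity: float = 0.90
    max_indels: int = 1
    band: int = 1
    chunk_size: int = 1000
    max_read_len: int = 100
    align_mode: str = "exact"  # exact | heuristic
    stride: int = 1
    trim_to_max: bool = False
    best_only: bool = False
    rng_seed: int = 0
    pair: PairParams = dataclasses.field(default_factory=PairParams)

    def to_text(self) -> str:
        lines = []
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if f.name == "pair":
                for pf in dataclasses.fields(PairParams):
                    lines.append(f"pair.{pf.name}={getattr(v, pf.name)}")
            else:
                lines.append(f"{f.name}={v}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "RunConfig":
        cfg = cls()
        pair_kw = {}
        casts = {f.name: f for f in dataclasses.fields(cls)}
        pair_casts = {f.name: f for f in dataclasses.fields(PairParams)}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, val = line.partition("=")
            key, val = key.strip(), val.strip()
            if key.startswith("pair."):
                pk = key[5:]
                if pk not in pair_casts:
                    raise ValueError(f"unknown config key {key!r}")
                pair_kw[pk] = _cast(pair_casts[pk].type, val)
            elif key in casts and key != "pair":
                setattr(cfg, key, _cast(casts[key].type, val))
            else:
                raise ValueError(f"unknown config key {key!r}")
        if pair_kw:
            cfg.pair = PairParams(**{**dataclasses.asdict(cfg.pair), **pair_kw})
        return cfg


def _cast(typename, val: str):
    t = str(typename)
    if "bool" in t:
        return val.lower() in ("1", "true", "yes")
    if "int" in t:
        return int(val)
    if "float" in t:
        return float(val)
    return val


def _prepare(reads: list[Sequence], config: RunConfig) -> list[Sequence]:
    out = []
    for r in reads:
        if r.length > config.max_read_len:
            if not config.trim_to_max:
                raise ValueError(
                    f"read {r.id} is {r.length} bp, longer than "
                    f"max_read_len={config.max_read_len} (use trim_to_max to 3'-trim)"
                )
            r = Sequence(r.id, r.bases[: config.max_read_len])
        out.append(r)
    return out


def align_reads(index: SeedIndex, reads: list[Sequence],
                config: RunConfig = RunConfig()) -> dict[str, list[AlignmentResult]]:
    """Map reads single-end; returns read id -> threshold-passing hits.

    Hits are deduplicated per (strand, position) keeping the minimum
    score, and sorted by (score, position, strand); the first hit is the
    primary one.  Reads with no passing hit map to an empty list.
    """
    reads = _prepare(reads, config)
    if index.config.seed_len != config.seed_len:
        raise ValueError("index and run configuration disagree on seed length")
    genome_codes = index.refcodes
    seeding = SeedingConfig(stride=config.stride)
    params = BandedParams(band_width=config.band)
    results: dict[str, list[AlignmentResult]] = {}
    n_aligned = 0
    chunks = chunk_reads([encode_read(r) for r in reads], config.chunk_size)
    for ci, chunk in enumerate(chunks):
        for er in chunk.reads:
            threshold = error_threshold(er.length, config.identity)
            best: dict[tuple, AlignmentResult] = {}
            for cand in generate_candidates(index, er, seeding):
                res = dual_engine_align(
                    er.fwd if cand.strand == "forward" else er.rc,
                    genome_codes, cand.window_start, threshold,
                    params, config.align_mode, er.id, cand.strand)
                if not res.passed:
                    continue
                key = (res.strand, res.ref_start)
                if key not in best or res.score < best[key].score:
                    best[key] = res
            hits = sorted(best.values(),
                          key=lambda h: (h.score, h.ref_start, h.strand))
            if config.best_only and hits:
                hits = [h for h in hits if h.score == hits[0].score]
            results[er.id] = hits
            n_aligned += bool(hits)
        logger.info("chunk %d: %d reads processed", ci, len(chunk.reads))
    if reads:
        logger.info("aligned %d/%d reads (%.1f%%)",
                    n_aligned, len(reads), 100 * n_aligned / len(reads))
    return results


def align_pairs(index: SeedIndex, reads1: list[Sequence], reads2: list[Sequence],
                config: RunConfig = RunConfig()):
    """Map both ends single-end, then pair with rescue.

    Returns (pairs, results1, results2).
    """
    if len(reads1) != len(reads2):
        raise ValueError("mate files differ in read count")
    results1 = align_reads(index, reads1, config)
    results2 = align_reads(index, reads2, config)
    genome = Sequence(index.genome_id, seqio.decode_bases(index.refcodes))
    ends1 = [EndInput(r, results1[r.id]) for r in _prepare(reads1, config)]
    ends2 = [EndInput(r, results2[r.id]) for r in _prepare(reads2, config)]
    pairs = pairing.pair_reads(ends1, ends2, genome, config.pair)
    return pairs, results1, results2


# ---------------------------------------------------------------------------
# SAM emission.  The engine reports positions and edit costs, not
# tracebacks, so the CIGAR is <read_len>M and the cost rides in the NM tag;
# MAPQ is 255 (unavailable).


def _segment(header, read: Sequence, hit: AlignmentResult | None,
             secondary: bool = False):
    import pysam

    seg = pysam.AlignedSegment(header)
    seg.query_name = read.id
    seg.mapping_quality = 255
    if hit is None:
        seg.flag = 4
        seg.query_sequence = read.bases
        return seg
    flag = 16 if hit.strand == "reverse" else 0
    if secondary:
        flag |= 256
    seg.flag = flag
    seg.reference_id = 0
    seg.reference_start = hit.ref_start
    seg.cigarstring = f"{read.length}M"
    seg.query_sequence = (read.bases if hit.strand == "forward"
                          else read.bases.translate(_RC)[::-1])
    seg.set_tag("NM", hit.score)
    seg.set_tag("AS", -hit.score)
    return seg


_RC = str.maketrans("ACGTN", "TGCAN")


def sam_records_single(reads, results, genome_id, genome_len, best_only=False):
    import pysam

    header = pysam.AlignmentHeader.from_dict(
        seqio.sam_header(genome_id, genome_len))
    for read in reads:
        hits = results.get(read.id, [])
        if not hits:
            yield _segment(header, read, None)
            continue
        for i, hit in enumerate(hits):
            yield _segment(header, read, hit, secondary=i > 0)
            if best_only:
                break


def sam_records_paired(reads1, reads2, pairs, results1, results2,
                       genome_id, genome_len):
    """Paired SAM: one record per end, mate fields filled for proper pairs."""
    import pysam

    header = pysam.AlignmentHeader.from_dict(
        seqio.sam_header(genome_id, genome_len))
    by_id = {p.read_pair_id: p for p in pairs}
    for r1, r2 in zip(reads1, reads2):
        pid = pairing._pair_id(r1.id)
        pair = by_id.get(pid)
        for end, read, mate_read in ((1, r1, r2), (2, r2, r1)):
            results = results1 if end == 1 else results2
            if pair is not None:
                pos = pair.p1 if end == 1 else pair.p2
                strand = pair.strand1 if end == 1 else pair.strand2
                hit = AlignmentResult(read.id, strand, pos, 0, "normal", True)
                own = [h for h in results.get(read.id, [])
                       if h.ref_start == pos and h.strand == strand]
                hit.score = own[0].score if own else 0
                seg = _segment(header, read, hit)
                seg.flag |= 1 | 2 | (64 if end == 1 else 128)
                mate_strand = pair.strand2 if end == 1 else pair.strand1
                if mate_strand == "reverse":
                    seg.flag |= 32
                seg.next_reference_id = 0
                seg.next_reference_start = pair.p2 if end == 1 else pair.p1
                left = min(pair.p1, pair.p2)
                seg.template_length = pair.insert if pos == left else -pair.insert
                yield seg
            else:
                hits = results.get(read.id, [])
                hit = hits[0] if hits else None
                seg = _segment(header, read, hit)
                seg.flag |= 1 | (64 if end == 1 else 128)
                mate_hits = (results2 if end == 1 else results1).get(mate_read.id, [])
                if not mate_hits:
                    seg.flag |= 8
                yield seg


def results_from_sam(path) -> dict:
    """Primary alignments of a SAM file as read id -> (pos, strand) | None."""
    import pysam

    out: dict = {}
    with pysam.AlignmentFile(str(path), "r") as fh:
        for rec in fh:
            if rec.is_secondary or rec.is_supplementary:
                continue
            if rec.is_unmapped:
                out.setdefault(rec.query_name, None)
            else:
                out[rec.query_name] = (
                    rec.reference_start,
                    "reverse" if rec.is_reverse else "forward",
                )
    return out
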