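"""Synthetic genomes, wgsim-style reads with ground truth, and evaluation.

The generator emulates the sampling scheme of the SAMtools ``wgsim``
utility: read start positions uniform over the genome, strands uniform,
i.i.d. per-base substitution errors, and at most one single-base indel per
read (the band-width-one extension engine cannot align reads with more
than one net indel, so the simulator operates in the same regime).
Paired mode draws the fragment's outer distance from Normal(D, sd) and
emits forward/reverse-oriented ends.  Ground truth (position, strand,
error counts) is carried in a TSV sidecar rather than encoded in read
names; a parser for wgsim-style names is provided for real wgsim output.

Evaluation follows the +/-5 bp rule: a reported alignment is correct when
its strand matches the truth and its position is within ``tolerance``
bases of the true position.
"""

from __future__ import annotations

import dataclasses
import re

import numpy as np
import pandas as pd

from .seqio import BASES, Sequence

__all__ = [
    "SimConfig",
    "TruthRecord",
    "EvalReport",
    "random_genome",
    "simulate_reads",
    "evaluate",
    "f_score",
    "write_truth",
    "read_truth",
    "parse_wgsim_name",
]

_BASE_ARR = np.frombuffer(BASES.encode(), dtype=np.uint8)


@dataclasses.dataclass(frozen=True)
class SimConfig:
    """Study conditions for read simulation.

    Defaults follow the simulation regime of the evaluation this package
    targets: 4% per-base substitution error, paired outer distance
    200 +/- 20.  ``indel_prob`` is the fraction of reads receiving exactly
    one 1 bp indel; the default 0.01 matches wgsim's default mutation rate
    (0.001 per base, 15% of mutations indels) at 76-100 bp read lengths.
    """

    genome_len: int = 100_000
    n_reads: int = 10_000
    read_len: int = 76
    err_rate: float = 0.04
    indel_prob: float = 0.01
    paired: bool = False
    outer_distance: int = 200
    std_dev: int = 20
    rng_seed: int = 0

    def __post_init__(self):
        if not 0 <= self.err_rate < 1:
            raise ValueError("err_rate must be in [0, 1)")
        if not 0 <= self.indel_prob <= 1:
            raise ValueError("indel_prob must be in [0, 1]")
        if self.read_len > self.genome_len:
            raise ValueError("read_len cannot exceed genome_len")


@dataclasses.dataclass
class TruthRecord:
    read_id: str
    true_pos: int  # 0-based leftmost genome base covered by the read
    true_strand: str  # "forward" | "reverse"
    n_subs: int
    n_indels: int


@dataclasses.dataclass
class EvalReport:
    n_reads: int
    n_aligned: int
    n_true: int

    @property
    def sensitivity(self) -> float:
        return self.n_aligned / self.n_reads if self.n_reads else 0.0

    @property
    def accuracy(self) -> float:
        return self.n_true / self.n_aligned if self.n_aligned else 0.0

    precision = accuracy

    @property
    def recall(self) -> float:
        return self.n_true / self.n_reads if self.n_reads else 0.0

    @property
    def f(self) -> float:
        return f_score(self.accuracy, self.recall)

    def as_dict(self) -> dict:
        return {
            "n_reads": self.n_reads,
            "n_aligned": self.n_aligned,
            "n_true": self.n_true,
            "sensitivity": self.sensitivity,
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f_score": self.f,
        }


def f_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall (0 when both are 0)."""
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def random_genome(length: int, rng_seed: int = 0, name: str = "synthetic") -> Sequence:
    """An i.i.d.-uniform ACGT genome, deterministic under the seed."""
    if length < 1:
        raise ValueError("genome length must be >= 1")
    rng = np.random.default_rng(rng_seed)
    return Sequence(name, _BASE_ARR[rng.integers(0, 4, size=length)].tobytes().decode())


_COMP = str.maketrans("ACGT", "TGCA")


def _revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


def _mutate(template: str, read_len: int, want_indel: bool, err_rate: float,
            rng: np.random.Generator) -> tuple[str, int, int]:
    """Apply at most one 1 bp indel, then i.i.d. substitutions.

    ``template`` carries ``read_len + 1`` bases so a deletion still yields
    a full-length read; without an indel the extra base is dropped.
    Returns (read bases, n_subs, n_indels).
    """
    n_indels = 0
    if want_indel:
        n_indels = 1
        if rng.random() < 0.5 and len(template) > read_len:  # deletion
            cut = int(rng.integers(0, read_len))
            read = template[:cut] + template[cut + 1 : read_len + 1]
        else:  # insertion
            at = int(rng.integers(0, read_len))
            ins = BASES[rng.integers(0, 4)]
            read = template[:at] + ins + template[at : read_len - 1]
    else:
        read = template[:read_len]
    arr = np.frombuffer(read.encode(), dtype=np.uint8).copy()
    subs = np.nonzero(rng.random(read_len) < err_rate)[0]
    for i in subs:
        old = chr(arr[i])
        choices = [b for b in BASES if b != old]
        arr[i] = ord(choices[rng.integers(0, 3)])
    return arr.tobytes().decode(), len(subs), n_indels


def simulate_reads(genome: Sequence, config: SimConfig
                   ) -> tuple[list[Sequence], list[TruthRecord]]:
    """Sample reads (or read pairs) with ground truth.

    Single-end mode emits ``n_reads`` reads named ``simread_<i>``.  Paired
    mode emits ``n_reads`` pairs named ``simread_<i>/1`` and ``/2`` in an
    interleaved list; ends are forward/reverse oriented and which end of
    the fragment becomes /1 is decided by a fair coin, as wgsim does.
    True positions are 0-based leftmost covered genome bases.
    """
    rng = np.random.default_rng(config.rng_seed)
    L = config.read_len
    g = genome.bases
    reads: list[Sequence] = []
    truth: list[TruthRecord] = []

    def one_end(name: str, pos: int, reverse: bool) -> None:
        template = g[pos : pos + L + 1]
        want_indel = rng.random() < config.indel_prob and len(template) > L
        bases, n_subs, n_indels = _mutate(template, L, want_indel, config.err_rate, rng)
        if reverse:
            bases = _revcomp(bases)
        reads.append(Sequence(name, bases))
        truth.append(TruthRecord(name, pos, "reverse" if reverse else "forward",
                                 n_subs, n_indels))

    if not config.paired:
        positions = rng.integers(0, genome.length - L + 1, size=config.n_reads)
        strands = rng.random(config.n_reads) < 0.5
        for i in range(config.n_reads):
            one_end(f"simread_{i}", int(positions[i]), bool(strands[i]))
        return reads, truth

    D, sd = config.outer_distance, config.std_dev
    for i in range(config.n_reads):
        frag = int(round(rng.normal(D, sd)))
        frag = max(frag, L + 1)
        frag = min(frag, genome.length)
        start = int(rng.integers(0, genome.length - frag + 1))
        left_pos = start
        right_pos = start + frag - L
        flip = rng.random() < 0.5  # which fragment end becomes read /1
        if not flip:
            one_end(f"simread_{i}/1", left_pos, reverse=False)
            one_end(f"simread_{i}/2", right_pos, reverse=True)
        else:
            one_end(f"simread_{i}/1", right_pos, reverse=True)
            one_end(f"simread_{i}/2", left_pos, reverse=False)
    return reads, truth


def write_truth(truth: list[TruthRecord], path) -> None:
    pd.DataFrame(
        [dataclasses.asdict(t) for t in truth],
        columns=["read_id", "true_pos", "true_strand", "n_subs", "n_indels"],
    ).to_csv(path, sep="\t", index=False)


def read_truth(path) -> list[TruthRecord]:
    df = pd.read_csv(path, sep="\t")
    return [TruthRecord(str(r.read_id), int(r.true_pos), str(r.true_strand),
                        int(r.n_subs), int(r.n_indels))
            for r in df.itertuples()]


_WGSIM_RE = re.compile(r"^(?P<ref>.+)_(?P<p1>\d+)_(?P<p2>\d+)_")


def parse_wgsim_name(name: str, read_len: int, end: int = 1) -> tuple[int, str]:
    """Ground truth from a wgsim-encoded read name.

    wgsim names reads ``<ref>_<pos1>_<pos2>_...`` with 1-based positions of
    the two fragment ends; end 1 is the forward (left) end.  Returns the
    0-based leftmost position and strand of the requested end.
    """
    m = _WGSIM_RE.match(name)
    if not m:
        raise ValueError(f"not a wgsim-style read name: {name!r}")
    p1, p2 = int(m.group("p1")), int(m.group("p2"))
    if end == 1:
        return p1 - 1, "forward"
    return p2 - read_len, "reverse"


def evaluate(results, truth: list[TruthRecord], tolerance: int = 5) -> EvalReport:
    """Score mapping output against ground truth with the +/-5 bp rule.

    ``results`` maps read_id -> (position, strand) for aligned reads
    (omit or map to None for unaligned).  A result for an unknown read id
    is an error.  An aligned read counts as true when the strand matches
    and |reported - true| <= tolerance.
    """
    by_id = {t.read_id: t for t in truth}
    unknown = set(results) - set(by_id)
    if unknown:
        raise ValueError(f"results reference unknown read ids: {sorted(unknown)[:5]}")
    n_aligned = 0
    n_true = 0
    for read_id, res in results.items():
        if res is None:
            continue
        pos, strand = res
        n_aligned += 1
        t = by_id[read_id]
        if strand == t.true_strand and abs(pos - t.true_pos) <= tolerance:
            n_true += 1
    return EvalReport(len(truth), n_aligned, n_true)
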