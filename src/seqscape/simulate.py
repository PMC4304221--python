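"""Synthetic genomes with planted exact repeats, reads, and truth alignments.

The generator emulates the study conditions the pipeline is designed for:
a uniform-random nucleotide background carrying a small number of planted
*maximal* exact repeats (the copies are identical but their flanking bases
differ, so the repeated substring cannot be extended), shotgun reads
sampled uniformly from both strands at a chosen fold coverage, and the
ground-truth alignment of every read emitted as SAM so the k-assignment
stage can be exercised without an external aligner.

Default conditions: a 2,000 bp genome with one 40 bp repeat in two copies,
error-free 100 bp reads at 30x. All randomness flows through one seeded
generator; identical spec + seed gives byte-identical output files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil
from pathlib import Path

import numpy as np
import pysam

from .assembly import revcomp

__all__ = ["SimulationSpec", "SimulatedRead", "SimulatedData", "simulate", "write_simulation"]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SimulationSpec:
    genome_len: int = 2000
    repeats: tuple[tuple[int, int], ...] = ((40, 2),)
    read_len: int = 100
    coverage: float = 30.0
    error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        if not 0 <= self.error_rate < 1:
            raise ValueError("error_rate must be in [0, 1)")
        for rl, copies in self.repeats:
            if copies > 4:
                raise ValueError(
                    "at most 4 copies per repeat: maximality requires pairwise "
                    "distinct flanking bases"
                )
            if rl * copies > self.genome_len:
                raise ValueError(
                    f"repeat of {rl} bp x {copies} copies does not fit a "
                    f"{self.genome_len} bp genome"
                )
        if self.read_len > self.genome_len:
            raise ValueError("read_len exceeds genome_len")


@dataclass(frozen=True)
class SimulatedRead:
    read_id: str
    seq: str  # as sequenced (reverse-complemented for minus-strand reads)
    start: int  # 0-based reference start
    is_reverse: bool


@dataclass
class SimulatedData:
    spec: SimulationSpec
    genome: str
    reads: list[SimulatedRead]
    repeat_positions: list[tuple[int, int]] = field(default_factory=list)  # (start, length)

    @property
    def ref_name(self) -> str:
        return "sim_ref"


def _random_genome(rng: np.random.Generator, n: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=n)]


def _place_repeats(rng: np.random.Generator, genome: np.ndarray,
                   repeats: tuple[tuple[int, int], ...],
                   margin: int = 1) -> list[tuple[int, int]]:
    """Plant each repeat's copies at non-overlapping slots; force maximality.

    ``margin`` keeps every copy away from the genome ends so that reads —
    whose coverage ramps down over the terminal ``read_len`` bases — can
    actually span each copy and its flanks.
    """
    n = len(genome)
    occupied: list[tuple[int, int]] = []  # (start, end) with 2 bp padding
    placed: list[tuple[int, int]] = []
    for rl, copies in repeats:
        unit = _random_genome(rng, rl)
        lo = max(1, margin)
        hi = n - rl - max(1, margin)
        if hi <= lo:
            lo, hi = 1, n - rl - 1
        starts: list[int] = []
        for _ in range(copies):
            for _attempt in range(10_000):
                s = int(rng.integers(lo, hi))
                if all(s + rl + 2 <= a or s >= b + 2 for a, b in occupied):
                    break
            else:
                raise ValueError("could not pack the requested repeats into the genome")
            occupied.append((s, s + rl))
            starts.append(s)
            genome[s : s + rl] = unit
        # maximality: left and right flanking bases must differ between copies
        for flank in (-1, rl):
            seen = {genome[starts[0] + flank]}
            for s in starts[1:]:
                while genome[s + flank] in seen:
                    genome[s + flank] = _BASES[rng.integers(0, 4)]
                seen.add(genome[s + flank])
        placed.extend((s, rl) for s in starts)
    return placed


def simulate(spec: SimulationSpec) -> SimulatedData:
    """Generate genome, reads and truth alignments for one specification."""
    rng = np.random.default_rng(spec.seed)
    genome_arr = _random_genome(rng, spec.genome_len)
    placed = _place_repeats(rng, genome_arr, spec.repeats, margin=spec.read_len)
    genome = genome_arr.tobytes().decode()

    num_reads = ceil(spec.coverage * spec.genome_len / spec.read_len)
    starts = rng.integers(0, spec.genome_len - spec.read_len + 1, size=num_reads)
    strands = rng.random(size=num_reads) < 0.5
    reads: list[SimulatedRead] = []
    width = len(str(max(num_reads - 1, 1)))
    for i in range(num_reads):
        s = int(starts[i])
        frag = genome[s : s + spec.read_len]
        if spec.error_rate > 0:
            arr = np.frombuffer(frag.encode(), dtype=np.uint8).copy()
            hits = np.nonzero(rng.random(spec.read_len) < spec.error_rate)[0]
            for j in hits:
                choices = _BASES[_BASES != arr[j]]
                arr[j] = choices[rng.integers(0, len(choices))]
            frag = arr.tobytes().decode()
        seq = revcomp(frag) if strands[i] else frag
        reads.append(SimulatedRead(f"read{i:0{width}d}", seq, s, bool(strands[i])))
    return SimulatedData(spec=spec, genome=genome, reads=reads, repeat_positions=placed)


def write_simulation(data: SimulatedData, out_dir: str | Path) -> dict[str, Path]:
    """Write genome FASTA, reads FASTQ and truth SAM; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": out / "genome.fa",
        "reads": out / "reads.fq",
        "sam": out / "truth.sam",
    }
    with open(paths["genome"], "w") as fh:
        fh.write(f">{data.ref_name} simulated genome length={len(data.genome)}\n")
        for i in range(0, len(data.genome), 70):
            fh.write(data.genome[i : i + 70] + "\n")
    with open(paths["reads"], "w") as fh:
        for r in data.reads:
            fh.write(f"@{r.read_id}\n{r.seq}\n+\n{'I' * len(r.seq)}\n")
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": data.ref_name, "LN": len(data.genome)}],
    }
    with pysam.AlignmentFile(str(paths["sam"]), "w", header=header) as sam:
        for r in data.reads:
            a = pysam.AlignedSegment(sam.header)
            a.query_name = r.read_id
            a.flag = 16 if r.is_reverse else 0
            a.reference_id = 0
            a.reference_start = r.start
            a.mapping_quality = 60
            a.cigarstring = f"{len(r.seq)}M"
            a.query_sequence = revcomp(r.seq) if r.is_reverse else r.seq
            a.query_qualities = pysam.qualitystring_to_array("I" * len(r.seq))
            sam.write(a)
    return paths
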