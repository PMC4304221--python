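"""End-to-end orchestration: landscape -> k assignment -> iterative assembly.

The driver mirrors how the method is meant to be used: build the maximal
sequence landscape for a (phylogenetically close) reference once, annotate
every aligned read with its optimal k, fall back to defaults for repeats
longer than the read and for unaligned reads, then assemble the reads with
the variable-k iterative de Bruijn procedure and report contig statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

from . import io as sio
from .assembly import AssemblyState, partition_reads, run_iterative
from .kselect import KAssignConfig, assign_reads_from_sam, write_k_table
from .landscape import MslIndex, build_msl
from .simulate import SimulationSpec, simulate, write_simulation
from .stats import AssemblyStats, compute_stats
from .suffix import DNA_ALPHABET

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineError", "build_reference_msl", "run_pipeline"]

#: separator pool for concatenation mode; each record boundary gets its own
#: symbol, so no repeated substring can span two records
_SEPARATORS = "!#$%&()*+,-./:;<=>?@[]^_{|}~"


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def build_reference_msl(records: Mapping[str, str], concat: bool = False) -> dict[str, MslIndex]:
    """Landscapes for a multi-record reference.

    Default: each record is treated independently. With ``concat=True`` the
    records are joined with pairwise-distinct separator symbols first, so
    substrings repeated *between* records (plasmid vs. chromosome, say)
    count as repeats; per-record height arrays are then sliced back out.
    """
    if not concat or len(records) == 1:
        return {name: build_msl(seq) for name, seq in records.items()}
    if len(records) - 1 > len(_SEPARATORS):
        raise ValueError("too many records for concatenation mode")
    names = list(records)
    seps = _SEPARATORS[: len(names) - 1]
    joined = ""
    offsets: dict[str, int] = {}
    for i, name in enumerate(names):
        offsets[name] = len(joined)
        joined += records[name]
        if i < len(seps):
            joined += seps[i]
    combined = build_msl(joined, alphabet=DNA_ALPHABET + seps)
    out: dict[str, MslIndex] = {}
    from .suffix import SourceString

    for name in names:
        off, ln = offsets[name], len(records[name])
        src = SourceString(records[name])
        heights = combined.heights[off : off + ln].copy()
        summits = []
        for m in combined.summits[off : off + ln]:
            if m is None:
                summits.append(None)
            else:
                from .landscape import Mountain

                summits.append(Mountain(m.begin - off, m.end - off, m.freq))
        out[name] = MslIndex(source=src, heights=heights, summits=summits)
    return out


@dataclass
class PipelineConfig:
    out_dir: Path
    reference: Path | None = None
    reads: Path | None = None
    sam: Path | None = None
    simulation: SimulationSpec | None = None
    cutoff: int = 5
    k_config: KAssignConfig = field(default_factory=KAssignConfig)
    concat_records: bool = False
    write_summits: bool = False


@dataclass
class PipelineResult:
    msl_by_ref: dict[str, MslIndex]
    assignments: dict | None = None
    contigs: list[str] | None = None
    stats: AssemblyStats | None = None
    assembly_state: AssemblyState | None = None
    paths: dict[str, Path] = field(default_factory=dict)


def _stage(name: str):
    def deco(fn):
        def wrapper(*a, **kw):
            log.info("stage %s: start", name)
            try:
                return fn(*a, **kw)
            except Exception as exc:  # noqa: BLE001 - stage attribution
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return wrapper

    return deco


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Execute the stages the configuration enables; artifacts land in out_dir."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result = PipelineResult(msl_by_ref={})

    if cfg.simulation is not None:
        data = _stage("simulate")(lambda: simulate(cfg.simulation))()
        paths = write_simulation(data, out)
        cfg.reference, cfg.reads, cfg.sam = paths["genome"], paths["reads"], paths["sam"]
        result.paths.update(paths)

    if cfg.reference is None:
        raise PipelineError("stage 'landscape' failed: no reference given "
                            "(pass a FASTA or request simulation)")

    records = _stage("read-reference")(sio.read_fasta)(cfg.reference)
    result.msl_by_ref = _stage("landscape")(build_reference_msl)(records, cfg.concat_records)
    lpath = out / "landscape.tsv"
    sio.write_landscape_tsv(result.msl_by_ref, lpath, summits=cfg.write_summits)
    result.paths["landscape"] = lpath
    if cfg.sam is None and cfg.reads is None:
        return result
    if cfg.sam is None:
        raise PipelineError("stage 'assign-k' failed: reads given without alignments "
                            "(provide a SAM or use simulation)")

    reads = _stage("read-reads")(sio.read_reads)(cfg.reads) if cfg.reads else {}
    lengths = {n: len(s) for n, s in reads.items()}
    result.assignments = _stage("assign-k")(assign_reads_from_sam)(
        cfg.sam, result.msl_by_ref, cfg.k_config, read_lengths=lengths
    )
    kpath = out / "k_assignments.tsv"
    write_k_table(result.assignments, kpath)
    result.paths["k_table"] = kpath
    by_source: dict[str, int] = {}
    for a in result.assignments.values():
        by_source[a.source] = by_source.get(a.source, 0) + 1
    log.info("k assignment sources: %s", by_source)
    if not reads:
        return result

    state = AssemblyState()
    part = _stage("partition")(partition_reads)(result.assignments, reads)
    contigs = _stage("assemble")(run_iterative)(part, cfg.cutoff, state=state)
    result.contigs, result.assembly_state = contigs, state
    cpath = out / "contigs.fa"
    final_k = part.k_max
    cov = {}
    if final_k in state.graphs:
        cov = sio.mean_kmer_coverage(contigs, state.graphs[final_k].counts, final_k)
    sio.write_contigs(contigs, cpath, round_k=final_k, coverage=cov)
    result.paths["contigs"] = cpath

    genome_len = sum(len(s) for s in records.values())
    result.stats = compute_stats(contigs, genome_len)
    spath = out / "stats.txt"
    spath.write_text(result.stats.as_text(genome_len))
    result.paths["stats"] = spath
    return result
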