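"""Iterative variable-k de Bruijn assembly.

Reads are partitioned by their assigned k-mer size and assembled in rounds
of increasing k: round ``k`` builds a de Bruijn graph from every read whose
assigned size is at most ``k`` together with the contigs of the previous
round, so information recovered at small k survives into the larger-k
graphs where repeats shorter than ``k - 1`` no longer branch.

The per-round assembler is deliberately plain: canonical k-mer counting
(a k-mer and its reverse complement are one object), a multiplicity cutoff
for error removal, clipping of dead-end tips shorter than ``2k``, and
condensation of maximal non-branching paths into contigs. Contigs fed
forward from the previous round are exempt from the cutoff — they are
trusted input whose own k-mer multiplicity is 1 by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .kselect import ReadKAssignment

__all__ = [
    "ReadPartition",
    "DeBruijnGraph",
    "AssemblyState",
    "revcomp",
    "canonical",
    "partition_reads",
    "dbg_assemble",
    "run_iterative",
]

log = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

DEFAULT_CUTOFF = 5


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def canonical(seq: str) -> str:
    """Lexicographically smaller of a sequence and its reverse complement."""
    rc = revcomp(seq)
    return seq if seq <= rc else rc


@dataclass
class ReadPartition:
    """Reads grouped by assigned k: bucket k holds the reads with K(r) = k."""

    buckets: dict[int, list[str]]  # k -> read ids, insertion order preserved
    seqs: dict[str, str]  # read id -> sequence as sequenced

    @property
    def k_min(self) -> int:
        return min(self.buckets)

    @property
    def k_max(self) -> int:
        return max(self.buckets)

    @property
    def levels(self) -> list[int]:
        return sorted(self.buckets)


@dataclass
class DeBruijnGraph:
    """Condensed view of one round: surviving canonical k-mers with counts."""

    k: int
    counts: dict[str, int]
    graph: nx.DiGraph = field(repr=False)

    @property
    def num_kmers(self) -> int:
        return len(self.counts)


@dataclass
class AssemblyState:
    """Instrumented trace of the iterative rounds."""

    accumulated_reads: list[str] = field(default_factory=list)
    contigs_by_round: dict[int, list[str]] = field(default_factory=dict)
    reads_per_round: dict[int, int] = field(default_factory=dict)
    graphs: dict[int, DeBruijnGraph] = field(default_factory=dict)


def partition_reads(
    assignments: Mapping[str, ReadKAssignment] | Mapping[str, int],
    reads: Mapping[str, str],
) -> ReadPartition:
    """Group reads into buckets by their assigned k."""
    if not reads:
        raise ValueError("empty read set: nothing to assemble")
    buckets: dict[int, list[str]] = {}
    for name in reads:
        if name not in assignments:
            raise KeyError(f"read {name!r} has no k assignment")
        a = assignments[name]
        k = a if isinstance(a, int) else a.k
        buckets.setdefault(k, []).append(name)
    return ReadPartition(buckets=buckets, seqs=dict(reads))


def _count_kmers(seqs: Iterable[str], k: int) -> tuple[dict[str, int], int]:
    counts: dict[str, int] = {}
    skipped = 0
    for s in seqs:
        s = s.upper()
        if len(s) < k:
            skipped += 1
            continue
        for i in range(len(s) - k + 1):
            km = canonical(s[i : i + k])
            counts[km] = counts.get(km, 0) + 1
    return counts, skipped


def _build_graph(kmers: Iterable[str]) -> nx.DiGraph:
    """Doubled-orientation de Bruijn graph: both strands of every k-mer."""
    g = nx.DiGraph()
    for km in kmers:
        for orient in (km, revcomp(km)):
            g.add_edge(orient[:-1], orient[1:])
    return g


def _unitigs(g: nx.DiGraph) -> list[list[str]]:
    """Maximal non-branching node paths, deterministically ordered.

    A walk never follows an edge with that edge's own reverse complement:
    in the doubled-orientation graph a dead end sitting on a palindromic
    (k-1)-mer would otherwise let the walk turn back onto the opposite
    strand and spell a hairpin chimera W + rc(W).
    """
    def through(v: str) -> bool:
        return g.in_degree(v) == 1 and g.out_degree(v) == 1

    def hairpin(prev: str, mid: str, nxt: str) -> bool:
        return canonical(prev + mid[-1]) == canonical(mid + nxt[-1])

    paths: list[list[str]] = []
    seen: set[tuple[str, str]] = set()

    def walk(u: str, v: str) -> list[str]:
        path = [u, v]
        seen.add((u, v))
        while through(path[-1]):
            nxt = next(iter(g.successors(path[-1])))
            if (path[-1], nxt) in seen or hairpin(path[-2], path[-1], nxt):
                break
            seen.add((path[-1], nxt))
            path.append(nxt)
        return path

    for u in sorted(g.nodes):
        if through(u):
            continue
        for v in sorted(g.successors(u)):
            if (u, v) not in seen:
                paths.append(walk(u, v))
    # leftovers: isolated cycles and hairpin remnants (every node 1-in-1-out)
    for u in sorted(g.nodes):
        for v in sorted(g.successors(u)):
            if (u, v) not in seen:
                paths.append(walk(u, v))
    return paths


def _spell(path: Sequence[str]) -> str:
    return path[0] + "".join(node[-1] for node in path[1:])


def dbg_assemble(
    seqs: Iterable[str],
    k: int,
    cutoff: int = DEFAULT_CUTOFF,
    protected: Iterable[str] = (),
    state: AssemblyState | None = None,
) -> list[str]:
    """Assemble sequences at one k; returns contigs sorted (length desc, lexical).

    ``protected`` sequences contribute k-mers exempt from the multiplicity
    cutoff (contigs fed forward between rounds). Sequences shorter than
    ``k`` are skipped with a logged count. Output contigs are reported in
    canonical orientation and deduplicated across strands.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    counts, skipped = _count_kmers(seqs, k)
    exempt, skipped_p = _count_kmers(protected, k)
    for km, c in exempt.items():
        counts[km] = counts.get(km, 0) + c
    if skipped or skipped_p:
        log.info("k=%d: skipped %d sequences shorter than k", k, skipped + skipped_p)
    if not counts:
        log.warning("k=%d: no sequence reached length k; empty assembly", k)
        return []

    surviving = {km: c for km, c in counts.items() if c >= cutoff or km in exempt}
    if not surviving:
        return []

    g = _build_graph(surviving)
    # clip dead-end tips shorter than 2k, then recondense; a tip goes only
    # when a strictly better-covered sibling edge exists at its junction, so
    # genuine short terminal unitigs severed by an error branch survive
    def edge_count(u: str, v: str) -> int:
        return surviving.get(canonical(u + v[-1]), 0)

    clipped: set[str] = set()
    for path in _unitigs(g):
        seq = _spell(path)
        if len(seq) >= 2 * k:
            continue
        dead_start = g.in_degree(path[0]) == 0
        dead_end = g.out_degree(path[-1]) == 0
        if dead_start == dead_end:  # interior link or isolated contig
            continue
        if dead_start:
            junction, this_edge = path[-1], (path[-2], path[-1])
            siblings = [(u, junction) for u in g.predecessors(junction)]
        else:
            junction, this_edge = path[0], (path[0], path[1])
            siblings = [(junction, v) for v in g.successors(junction)]
        competition = max(
            (edge_count(*e) for e in siblings if e != this_edge), default=0
        )
        tip_cov = max(edge_count(path[i], path[i + 1]) for i in range(len(path) - 1))
        if competition > tip_cov:
            for i in range(len(path) - 1):
                clipped.add(canonical(path[i] + path[i + 1][-1]))
    if clipped:
        surviving = {km: c for km, c in surviving.items() if km not in clipped}
        g = _build_graph(surviving)

    contigs = {canonical(_spell(p)) for p in _unitigs(g)}
    out = sorted(contigs, key=lambda s: (-len(s), s))
    if state is not None:
        state.graphs[k] = DeBruijnGraph(k=k, counts=surviving, graph=g)
    return out


def run_iterative(
    partition: ReadPartition,
    cutoff: int = DEFAULT_CUTOFF,
    state: AssemblyState | None = None,
) -> list[str]:
    """Assemble rounds k_min..k_max over the occupied k levels; returns A_{k_max}.

    Round k assembles the union of buckets up to k plus the previous
    round's contigs. Unoccupied levels between occupied ones are skipped:
    they would re-condense the same input.
    """
    if state is None:
        state = AssemblyState()
    accumulated: list[str] = []  # R' as read ids
    prev_contigs: list[str] = []
    for k in partition.levels:
        accumulated.extend(partition.buckets[k])
        read_seqs = [partition.seqs[r] for r in accumulated]
        state.reads_per_round[k] = len(accumulated)
        prev_contigs = dbg_assemble(read_seqs, k, cutoff, protected=prev_contigs,
                                    state=state)
        state.contigs_by_round[k] = prev_contigs
        log.info("round k=%d: %d reads, %d contigs, %d bp", k, len(accumulated),
                 len(prev_contigs), sum(len(c) for c in prev_contigs))
    state.accumulated_reads = accumulated
    return prev_contigs
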