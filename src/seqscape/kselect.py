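"""Per-read k-mer size selection from reference alignments and the MSL.

For a read of length ``l`` aligned at reference position ``p``, the optimal
k is one more than the tallest landscape summit over the bases the read
covers: ``k* = 1 + max(MSL[p], ..., MSL[p + l - 1])``. A de Bruijn graph
built at that k has no branching vertex inside the read's window provided
the window is unchanged relative to the reference and error-free, because
no substring of length ``k - 1`` inside it is repeated elsewhere.

Every alignment of a read (forward and reverse, primary and secondary)
contributes one ``k*`` to the set ``K*``; the read's k is ``max(K*)``.
Reverse alignments reverse-complement the read sequence handed to
assembly, not the reference window, so the landscape lookup is identical.
Two fallbacks apply: when ``max(K*)`` exceeds the read length (the read
sits inside a repeat longer than itself) a long-repeat default is used
(77); reads with no alignment at all get the unaligned default (55).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pysam

from .landscape import MslIndex

__all__ = [
    "AlignmentRecord",
    "ReadKAssignment",
    "KAssignConfig",
    "kstar",
    "assign_k",
    "read_sam_alignments",
    "assign_reads_from_sam",
    "write_k_table",
    "read_k_table",
]

DEFAULT_K_LONG_REPEAT = 77
DEFAULT_K_UNALIGNED = 55

#: smallest k a de Bruijn graph can be built at
K_MIN_VALID = 2


@dataclass(frozen=True)
class AlignmentRecord:
    """One read-to-reference alignment (0-based leftmost position)."""

    read_id: str
    ref_id: str
    pos: int
    read_len: int
    is_reverse: bool = False
    is_aligned: bool = True

    def __post_init__(self) -> None:
        if self.read_len < 1:
            raise ValueError("read_len must be >= 1")
        if self.is_aligned and self.pos < 0:
            raise ValueError("aligned record needs pos >= 0")


@dataclass(frozen=True)
class KAssignConfig:
    long_repeat_default: int = DEFAULT_K_LONG_REPEAT
    unaligned_default: int = DEFAULT_K_UNALIGNED
    floor: int | None = None
    force_odd: bool = False


@dataclass
class ReadKAssignment:
    """Final k for one read, with the per-alignment K* set and its provenance.

    ``source`` is ``aligned`` (k = max K*), ``default_long_repeat``
    (max K* exceeded the read length) or ``default_unaligned`` (no
    alignments at all).
    """

    read_id: str
    kstars: frozenset[int]
    k: int
    source: str
    read_len: int = 0


def kstar(msl: MslIndex, pos: int, read_len: int) -> int:
    """1 + max summit height over the window [pos, pos + read_len - 1], 0-based.

    Windows running past the record end are clamped to it.
    """
    if read_len < 1:
        raise ValueError("read_len must be >= 1")
    if not 0 <= pos < msl.n:
        raise IndexError(f"alignment position {pos} beyond record end {msl.n}")
    end = min(pos + read_len, msl.n)
    return int(msl.heights[pos:end].max()) + 1


def assign_k(
    read_id: str,
    alignments: Iterable[AlignmentRecord],
    msl_by_ref: Mapping[str, MslIndex],
    cfg: KAssignConfig = KAssignConfig(),
    read_len: int | None = None,
) -> ReadKAssignment:
    """Collect K* over all alignments of one read and apply the default policy."""
    kstars: set[int] = set()
    length = read_len or 0
    for aln in alignments:
        if not aln.is_aligned:
            length = max(length, aln.read_len)
            continue
        if aln.ref_id not in msl_by_ref:
            raise KeyError(f"no landscape built for reference {aln.ref_id!r}")
        kstars.add(kstar(msl_by_ref[aln.ref_id], aln.pos, aln.read_len))
        length = max(length, aln.read_len)

    if not kstars:
        k, source = cfg.unaligned_default, "default_unaligned"
    else:
        k = max(kstars)
        if k > length:
            k, source = cfg.long_repeat_default, "default_long_repeat"
        else:
            source = "aligned"
    k = max(k, K_MIN_VALID)
    if cfg.floor is not None:
        k = max(k, cfg.floor)
    if cfg.force_odd and k % 2 == 0:
        k += 1
    return ReadKAssignment(read_id=read_id, kstars=frozenset(kstars), k=k,
                           source=source, read_len=length)


def read_sam_alignments(sam_path: str | Path) -> dict[str, list[AlignmentRecord]]:
    """Group usable SAM records by read id.

    Primary and secondary alignments are kept; supplementary records are
    skipped. Unmapped reads appear with an unaligned placeholder record so
    they still receive the default k.
    """
    grouped: dict[str, list[AlignmentRecord]] = {}
    lengths: dict[str, int] = {}
    with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_supplementary:
                continue
            name = rec.query_name
            rl = rec.query_length or rec.infer_read_length() or lengths.get(name, 0)
            if rl:
                lengths[name] = rl
            if rec.is_unmapped:
                grouped.setdefault(name, [])
                continue
            grouped.setdefault(name, []).append(
                AlignmentRecord(
                    read_id=name,
                    ref_id=rec.reference_name,
                    pos=rec.reference_start,
                    read_len=rl or 1,
                    is_reverse=rec.is_reverse,
                )
            )
    # backfill lengths on secondary records that carried '*' sequences
    fixed: dict[str, list[AlignmentRecord]] = {}
    for name, alns in grouped.items():
        rl = lengths.get(name, 0)
        fixed[name] = [
            AlignmentRecord(a.read_id, a.ref_id, a.pos, max(a.read_len, rl), a.is_reverse)
            for a in alns
        ]
    return fixed


def assign_reads_from_sam(
    sam_path: str | Path,
    msl_by_ref: Mapping[str, MslIndex],
    cfg: KAssignConfig = KAssignConfig(),
    read_lengths: Mapping[str, int] | None = None,
) -> dict[str, ReadKAssignment]:
    """Assign a k to every read named in the SAM stream."""
    grouped = read_sam_alignments(sam_path)
    out: dict[str, ReadKAssignment] = {}
    for name, alns in grouped.items():
        rl = read_lengths.get(name) if read_lengths else None
        out[name] = assign_k(name, alns, msl_by_ref, cfg, read_len=rl)
    return out


def write_k_table(assignments: Mapping[str, ReadKAssignment], path: str | Path) -> None:
    """TSV: read_id, k, source, max_kstar (0 when K* is empty)."""
    with open(path, "w") as fh:
        fh.write("#read_id\tk\tsource\tmax_kstar\n")
        for name in sorted(assignments):
            a = assignments[name]
            mx = max(a.kstars) if a.kstars else 0
            fh.write(f"{name}\t{a.k}\t{a.source}\t{mx}\n")


def read_k_table(path: str | Path) -> dict[str, int]:
    out: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            out[fields[0]] = int(fields[1])
    return out
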