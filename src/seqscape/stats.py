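"""Contig-set summary statistics (N50 family)."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

log = logging.getLogger(__name__)

__all__ = ["AssemblyStats", "compute_stats"]


@dataclass(frozen=True)
class AssemblyStats:
    num_contigs: int
    total: int
    largest: int
    n50: int
    ng50: int

    def as_text(self, genome_len: int | None = None) -> str:
        lines = [
            f"contigs\t{self.num_contigs}",
            f"total_bp\t{self.total}",
            f"largest_bp\t{self.largest}",
            f"N50\t{self.n50}",
        ]
        if genome_len is not None:
            lines.append(f"NG50\t{self.ng50}\t# 0 when the assembly never reaches half the genome")
        return "\n".join(lines) + "\n"


def compute_stats(contigs: Iterable[str] | Sequence[int], genome_len: int | None = None) -> AssemblyStats:
    """N50/NG50/largest/total over contig sequences or lengths.

    N50 is the largest length L such that contigs of length >= L sum to at
    least half the total assembly; NG50 uses half of ``genome_len`` instead
    and is 0 when the assembly never reaches it.
    """
    lengths = sorted(
        (len(c) if isinstance(c, str) else int(c) for c in contigs), reverse=True
    )
    if not lengths:
        log.warning("empty contig set: all statistics are zero")
        return AssemblyStats(0, 0, 0, 0, 0)
    total = sum(lengths)

    def nx(half: float) -> int:
        acc = 0
        for L in lengths:
            acc += L
            if acc >= half:
                return L
        return 0

    ng50 = nx(genome_len / 2) if genome_len else 0
    return AssemblyStats(
        num_contigs=len(lengths),
        total=total,
        largest=lengths[0],
        n50=nx(total / 2),
        ng50=ng50,
    )
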