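"""Reading and writing the file formats the pipeline touches.

FASTA/FASTQ go through Biopython's SeqIO; SAM through pysam (see
:mod:`seqscape.kselect`). Landscape and k tables are plain TSV with a
one-line header naming the coordinate convention (user-facing coordinates
are 1-based; everything internal is 0-based).
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO

from .landscape import MslIndex

__all__ = [
    "read_fasta",
    "read_reads",
    "write_fasta",
    "write_landscape_tsv",
    "write_contigs",
]


def read_fasta(path: str | Path) -> dict[str, str]:
    """FASTA records as an ordered mapping id -> uppercased sequence."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def read_reads(path: str | Path) -> dict[str, str]:
    """Reads from FASTA or FASTQ (sniffed from the first byte)."""
    p = Path(path)
    with open(p) as fh:
        first = fh.read(1)
    fmt = "fastq" if first == "@" else "fasta"
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(p), fmt)}


def write_fasta(records: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_landscape_tsv(msl_by_ref: Mapping[str, MslIndex], path: str | Path,
                        summits: bool = False) -> None:
    """Per-position summit heights; optional summit spans. 1-based, inclusive."""
    with open(path, "w") as fh:
        cols = "record\tposition\theight" + ("\tsummit_begin\tsummit_end" if summits else "")
        fh.write(f"# 1-based positions, inclusive spans\n{cols}\n")
        for name, msl in msl_by_ref.items():
            for i in range(msl.n):
                row = f"{name}\t{i + 1}\t{int(msl.heights[i])}"
                if summits:
                    m = msl.summits[i]
                    row += f"\t{m.begin + 1}\t{m.end + 1}" if m else "\t.\t."
                fh.write(row + "\n")


def write_contigs(contigs: Iterable[str], path: str | Path, round_k: int | None = None,
                  coverage: Mapping[str, float] | None = None) -> None:
    """Contig FASTA; headers carry assembly round, length and mean k-mer coverage."""
    with open(path, "w") as fh:
        for i, seq in enumerate(contigs, start=1):
            parts = [f"contig_{i:05d}"]
            if round_k is not None:
                parts.append(f"round={round_k}")
            parts.append(f"length={len(seq)}")
            if coverage and seq in coverage:
                parts.append(f"cov={coverage[seq]:.1f}")
            fh.write(">" + " ".join(parts) + "\n")
            for j in range(0, len(seq), 70):
                fh.write(seq[j : j + 70] + "\n")


def mean_kmer_coverage(contigs: Iterable[str], counts: Mapping[str, int], k: int) -> dict[str, float]:
    """Mean multiplicity of a contig's canonical k-mers (for FASTA headers)."""
    from .assembly import canonical

    out: dict[str, float] = {}
    for seq in contigs:
        if len(seq) < k:
            continue
        vals = [counts.get(canonical(seq[i : i + k]), 0) for i in range(len(seq) - k + 1)]
        out[seq] = sum(vals) / len(vals)
    return out
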