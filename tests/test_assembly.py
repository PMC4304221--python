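"""De Bruijn assembly: condensation, cutoff, strand closure, iterative rounds."""

import numpy as np
import pytest

from seqscape import SimulationSpec, revcomp, simulate
from seqscape.assembly import (
    AssemblyState,
    canonical,
    dbg_assemble,
    partition_reads,
    run_iterative,
)
from seqscape.kselect import ReadKAssignment

from conftest import truth_assignments


def contig_set(contigs):
    return {canonical(c) for c in contigs}


def _assignment(name, k):
    return ReadKAssignment(read_id=name, kstars=frozenset({k}), k=k, source="aligned")


class TestPartition:
    def test_groups_by_k(self):
        reads = {"a": "ACGT", "b": "ACGT", "c": "ACGT"}
        assigns = {n: _assignment(n, k) for n, k in [("a", 21), ("b", 21), ("c", 31)]}
        part = partition_reads(assigns, reads)
        assert {k: len(v) for k, v in part.buckets.items()} == {21: 2, 31: 1}
        assert (part.k_min, part.k_max) == (21, 31)
        # disjoint and exhaustive
        ids = [r for b in part.buckets.values() for r in b]
        assert sorted(ids) == sorted(reads)

    def test_single_bucket_degenerates_to_one_round(self):
        reads = {"a": "ACCACCAA", "b": "ACCACCAA"}
        assigns = {n: _assignment(n, 3) for n in reads}
        part = partition_reads(assigns, reads)
        assert run_iterative(part, cutoff=1) == dbg_assemble(list(reads.values()), 3, 1)

    def test_unassigned_read_rejected(self):
        with pytest.raises(KeyError):
            partition_reads({}, {"a": "ACGT"})

    def test_empty_read_set_rejected(self):
        with pytest.raises(ValueError):
            partition_reads({}, {})


class TestDbgAssemble:
    # A/C-only sequences: their reverse complements (G/T) share no node with
    # the forward strand, so the doubled graph keeps the two strands separate.
    def test_linear_sequence_condenses_to_itself(self):
        assert contig_set(dbg_assemble(["ACCAA"], 3, cutoff=1)) == {canonical("ACCAA")}

    def test_tiling_reads_above_cutoff_recover_the_sequence(self):
        target = "CACCCCAAAACCACCA"  # all 5-mers distinct: no branch at k = 6
        reads = [target[i : i + 8] for i in range(9)] * 10
        assert contig_set(dbg_assemble(reads, 6, cutoff=5)) == {canonical(target)}

    def test_cutoff_removes_singletons(self):
        assert dbg_assemble(["ACCAA"], 3, cutoff=2) == []

    def test_protected_sequences_survive_cutoff(self):
        out = dbg_assemble([], 3, cutoff=5, protected=["ACCAA"])
        assert contig_set(out) == {canonical("ACCAA")}

    def test_k_below_two_rejected(self):
        with pytest.raises(ValueError):
            dbg_assemble(["ACGT"], 1, 1)

    def test_all_sequences_shorter_than_k(self):
        assert dbg_assemble(["ACG", "CGT"], 5, 1) == []

    def test_branch_splits_contigs(self):
        # two sequences sharing the middle CCC: a branch on both sides
        seqs = ["AACCCAA", "CACCCAC"]
        out = dbg_assemble(seqs * 3, 3, cutoff=1)
        assert len(out) > 1

    def test_strand_closure(self):
        rng = np.random.default_rng(1)
        seqs = ["".join("ACGT"[c] for c in rng.integers(0, 4, size=60)) for _ in range(20)]
        fwd = dbg_assemble(seqs, 7, cutoff=1)
        rev = dbg_assemble([revcomp(s) for s in seqs], 7, cutoff=1)
        assert contig_set(fwd) == contig_set(rev)

    def test_deterministic_output_order(self):
        rng = np.random.default_rng(2)
        seqs = ["".join("ACGT"[c] for c in rng.integers(0, 4, size=50)) for _ in range(15)]
        a = dbg_assemble(seqs, 5, cutoff=1)
        b = dbg_assemble(list(reversed(seqs)), 5, cutoff=1)
        assert a == b
        assert a == sorted(a, key=lambda s: (-len(s), s))

    def test_kmer_conservation_into_contigs(self):
        """Every surviving canonical k-mer occurs in exactly one contig."""
        rng = np.random.default_rng(3)
        genome = "".join("ACGT"[c] for c in rng.integers(0, 4, size=500))
        reads = [genome[i : i + 60] for i in range(0, 441, 5)] * 6
        k = 21
        state = AssemblyState()
        contigs = dbg_assemble(reads, k, cutoff=5, state=state)
        surviving = set(state.graphs[k].counts)
        from_contigs: list[str] = []
        for c in contigs:
            from_contigs.extend(canonical(c[i : i + k]) for i in range(len(c) - k + 1))
        assert set(from_contigs) == surviving
        assert len(from_contigs) == len(set(from_contigs))

    def test_tip_shorter_than_two_k_is_clipped(self):
        backbone = "CACCCCAAAACCACCA"  # all 5-mers distinct
        reads = [backbone[i : i + 8] for i in range(9)] * 6
        # one erroneous read sprouting a short dead end off the backbone
        tip = backbone[:6] + "T"
        out = dbg_assemble(reads + [tip], 6, cutoff=1)
        assert contig_set(out) == {canonical(backbone)}


class TestIterativeRounds:
    def test_round_input_law(self, sim_data):
        """The reads entering round k are exactly the union of buckets <= k."""
        assigns = truth_assignments(sim_data)
        reads = {r.read_id: r.seq for r in sim_data.reads}
        part = partition_reads(assigns, reads)
        state = AssemblyState()
        run_iterative(part, cutoff=5, state=state)
        expected = 0
        for k in part.levels:
            expected += len(part.buckets[k])
            assert state.reads_per_round[k] == expected
        assert expected == len(reads)

    def test_contigs_are_walks_in_the_final_graph(self, sim_data):
        assigns = truth_assignments(sim_data)
        reads = {r.read_id: r.seq for r in sim_data.reads}
        part = partition_reads(assigns, reads)
        state = AssemblyState()
        contigs = run_iterative(part, cutoff=5, state=state)
        g = state.graphs[part.k_max].graph
        k = part.k_max
        for c in contigs:
            nodes = [c[i : i + k - 1] for i in range(len(c) - k + 2)]
            present = all(g.has_edge(nodes[i], nodes[i + 1]) for i in range(len(nodes) - 1))
            rc = revcomp(c)
            rnodes = [rc[i : i + k - 1] for i in range(len(rc) - k + 2)]
            rpresent = all(g.has_edge(rnodes[i], rnodes[i + 1]) for i in range(len(rnodes) - 1))
            assert present or rpresent

    def test_final_contigs_match_truth_genome(self, sim_data):
        assigns = truth_assignments(sim_data)
        reads = {r.read_id: r.seq for r in sim_data.reads}
        contigs = run_iterative(partition_reads(assigns, reads), cutoff=5)
        g, grc = sim_data.genome, revcomp(sim_data.genome)
        assert contigs, "assembly produced no contigs"
        for c in contigs:
            assert c in g or c in grc, "contig is not an exact genome substring"
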