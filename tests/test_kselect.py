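"""k-mer size assignment: window maximum, default policies, SAM ingestion."""

import numpy as np
import pytest

from seqscape import build_msl
from seqscape.kselect import (
    AlignmentRecord,
    KAssignConfig,
    assign_k,
    assign_reads_from_sam,
    kstar,
    read_k_table,
    write_k_table,
)


@pytest.fixture(scope="module")
def msl_map(catcat_msl):
    return {"ref": catcat_msl}


class TestKstar:
    def test_window_over_tt_region(self, catcat_msl):
        # heights [3,3,3,3,3,3,2,2,0]; window positions 7-9 (1-based)
        assert kstar(catcat_msl, 6, 3) == 3

    def test_whole_reference_window(self, catcat_msl):
        assert kstar(catcat_msl, 0, 9) == 4

    def test_all_zero_heights_gives_one(self):
        msl = build_msl("ACGT")
        assert kstar(msl, 0, 4) == 1

    def test_window_clamped_at_record_end(self, catcat_msl):
        assert kstar(catcat_msl, 6, 100) == 3

    def test_position_beyond_end_rejected(self, catcat_msl):
        with pytest.raises(IndexError):
            kstar(catcat_msl, 9, 1)

    def test_monotone_in_window_size(self, catcat_msl):
        for pos in range(9):
            vals = [kstar(catcat_msl, pos, L) for L in range(1, 10 - pos)]
            assert vals == sorted(vals)


class TestAssignPolicy:
    def test_aligned_takes_max_of_kstar_set(self, msl_map):
        alns = [
            AlignmentRecord("r", "ref", 0, 9),  # k* = 4
            AlignmentRecord("r", "ref", 6, 3),  # k* = 3
        ]
        a = assign_k("r", alns, msl_map)
        assert a.kstars == frozenset({3, 4})
        assert a.k == 4 and a.source == "aligned"

    def test_long_repeat_default_when_kstar_exceeds_read(self, msl_map):
        a = assign_k("r", [AlignmentRecord("r", "ref", 0, 2)], msl_map)
        assert a.k == 77 and a.source == "default_long_repeat"
        assert max(a.kstars) == 4 > 2

    def test_unaligned_default(self, msl_map):
        a = assign_k("r", [], msl_map, read_len=100)
        assert a.k == 55 and a.source == "default_unaligned" and a.kstars == frozenset()

    def test_reverse_alignment_uses_same_window(self, msl_map):
        fwd = assign_k("r", [AlignmentRecord("r", "ref", 0, 9)], msl_map)
        rev = assign_k("r", [AlignmentRecord("r", "ref", 0, 9, is_reverse=True)], msl_map)
        assert fwd.k == rev.k == 4

    def test_configurable_defaults_floor_and_parity(self, msl_map):
        cfg = KAssignConfig(long_repeat_default=99, unaligned_default=33,
                            floor=11, force_odd=True)
        assert assign_k("r", [], msl_map, cfg).k == 33
        a = assign_k("r", [AlignmentRecord("r", "ref", 0, 9)], msl_map, cfg)
        assert a.k == 11  # floor beats k* = 4; already odd

    def test_force_odd_rounds_up(self):
        msl = build_msl("CATCATTTG")
        cfg = KAssignConfig(force_odd=True)
        a = assign_k("r", [AlignmentRecord("r", "ref", 0, 9)], {"ref": msl}, cfg)
        assert a.k == 5  # k* = 4 rounded up

    def test_k_never_below_two(self):
        msl = build_msl("ACGT")
        a = assign_k("r", [AlignmentRecord("r", "ref", 0, 4)], {"ref": msl})
        assert a.k == 2  # k* = 1 floored to the smallest usable graph order

    def test_missing_reference_landscape(self, msl_map):
        with pytest.raises(KeyError, match="other"):
            assign_k("r", [AlignmentRecord("r", "other", 0, 5)], msl_map)


class TestSamIngestion:
    def test_truth_sam_round_trip(self, sim_data, sim_files, tmp_path):
        msl = {sim_data.ref_name: build_msl(sim_data.genome)}
        assignments = assign_reads_from_sam(sim_files["sam"], msl)
        # totality: every simulated read gets exactly one k
        assert set(assignments) == {r.read_id for r in sim_data.reads}
        by_source = {}
        for a in assignments.values():
            by_source[a.source] = by_source.get(a.source, 0) + 1
        assert sum(by_source.values()) == len(sim_data.reads)
        assert by_source.get("aligned", 0) == len(sim_data.reads)  # error-free truth
        # reads spanning the planted 40 bp repeat get k = 41
        heights = msl[sim_data.ref_name].heights
        for r in sim_data.reads:
            window_max = int(heights[r.start : r.start + len(r.seq)].max())
            assert assignments[r.read_id].k == max(window_max + 1, 2)
        # table round-trip
        path = tmp_path / "k.tsv"
        write_k_table(assignments, path)
        assert read_k_table(path) == {n: a.k for n, a in assignments.items()}

    def test_unmapped_records_get_default(self, tmp_path):
        sam = tmp_path / "u.sam"
        sam.write_text(
            "@HD\tVN:1.6\tSO:unsorted\n"
            "@SQ\tSN:ref\tLN:9\n"
            "mapped\t0\tref\t1\t60\t5M\t*\t0\t0\tCATCA\tIIIII\n"
            "lost\t4\t*\t0\t0\t*\t*\t0\t0\tACGTA\tIIIII\n"
        )
        msl = {"ref": build_msl("CATCATTTG")}
        out = assign_reads_from_sam(sam, msl)
        assert out["lost"].source == "default_unaligned" and out["lost"].k == 55
        assert out["mapped"].source == "aligned"


def test_branch_free_guarantee_at_assigned_k():
    """Reads tiling a region whose tallest repeat has its second copy elsewhere,
    assembled at the assigned k, build a de Bruijn graph with no branching
    vertex: k exceeds every repeat length, so no (k-1)-mer of the region is
    repeated within it."""
    import networkx as nx

    from conftest import random_dna

    rng = np.random.default_rng(77)
    repeat = random_dna(rng, 20)
    region = random_dna(rng, 300) + repeat + random_dna(rng, 300)
    genome = region + random_dna(rng, 200) + repeat + random_dna(rng, 200)
    msl = build_msl(genome)
    k = kstar(msl, 0, len(region))
    # the planted repeat dominates (chance flank matches may extend it slightly)
    assert 21 <= k <= 25
    reads = [region[i : i + 100] for i in range(0, len(region) - 99, 10)]
    g = nx.DiGraph()
    for rd in reads:
        for i in range(len(rd) - k + 1):
            km = rd[i : i + k]
            g.add_edge(km[:-1], km[1:])
    internal = [v for v in g if g.in_degree(v) >= 1 and g.out_degree(v) >= 1]
    assert all(g.in_degree(v) == 1 and g.out_degree(v) == 1 for v in internal)
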