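"""Building blocks, junction graph, enumeration (vs brute force), scoring."""

from itertools import product

import numpy as np
import pytest

from mitoforms import isoforms as iso_mod
from mitoforms.isoforms import (
    BuildingBlock,
    build_graph,
    building_blocks,
    enumerate_isoforms,
    score_isoforms,
)
from mitoforms.model import (
    IsoformModel,
    OrientedUnit,
    canonical_block,
    canonicalize_isoform,
    parse_arrangement,
)


def _blocks_from_arrangements(arrangements, repeats, support=5):
    """Derive the block set perfect reads over these circles would yield."""
    paths = []
    for arr in arrangements:
        doubled = arr + arr[:3]
        paths.extend([doubled] * support)
    return building_blocks(paths, repeats, min_support=support)


class TestBuildingBlocks:
    def test_orientation_merge(self):
        a = parse_arrangement("A+,B+")
        b = parse_arrangement("B-,A-")
        blocks = building_blocks([a, b], repeats=set(), min_support=2)
        assert len(blocks) == 1
        assert blocks[0].support == 2

    def test_min_support_drops_rare_blocks(self):
        a = parse_arrangement("A+,B+")
        blocks = building_blocks([a], repeats=set(), min_support=2)
        assert blocks == []

    def test_repeat_triples_extracted(self):
        path = parse_arrangement("K+,R+,P+,T+,Q+")
        blocks = building_blocks([path, path], repeats={"R", "T"})
        triples = {b.units for b in blocks if len(b.units) == 3}
        assert canonical_block(tuple(parse_arrangement("K+,R+,P+"))) in triples
        assert canonical_block(tuple(parse_arrangement("P+,T+,Q+"))) in triples

    def test_saligna_hinge_blocks_match_published_sets(self, saligna_run):
        blocks = saligna_run["blocks"]
        got_t = {b.units for b in blocks if len(b.units) == 3 and b.units[1].unit == "T"}
        got_r = {b.units for b in blocks if len(b.units) == 3 and b.units[1].unit == "R"}
        exp_t = {
            canonical_block(tuple(parse_arrangement(s)))
            for s in ("P+,T+,Q+", "P+,T+,L+", "K+,T+,L+", "K+,T+,Q+")
        }
        exp_r = {
            canonical_block(tuple(parse_arrangement(s)))
            for s in ("Z+,R+,P+", "Z+,R+,U+", "L+,R+,U+", "L+,R+,P+")
        }
        assert got_t == exp_t
        assert got_r == exp_r


class TestBuildGraph:
    def test_hinge_connects_to_both_exits(self, sativa_even):
        graph = sativa_even["graph"]
        nxt = {ou.unit for ou in graph.allowed_next(OrientedUnit("R", "+"))}
        assert {"P", "U"} <= nxt

    def test_simple_cycle_graph(self):
        arr = parse_arrangement("A+,B+,C+")
        blocks = _blocks_from_arrangements([arr], repeats=set())
        graph = build_graph(blocks, {"A": 1, "B": 1, "C": 1})
        assert len(graph.adjacencies) == 3
        assert graph.constraints == {}

    def test_empty_blocks_no_adjacencies(self):
        graph = build_graph([], {"A": 1})
        assert graph.adjacencies == {}

    def test_unknown_unit_raises(self):
        blocks = [BuildingBlock(tuple(parse_arrangement("A+,B+")), 3)]
        with pytest.raises(ValueError, match="absent"):
            build_graph(blocks, {"A": 1})


# ---------------------------------------------------------------------------
# Brute-force enumeration oracle
# ---------------------------------------------------------------------------

def brute_force_isoforms(graph):
    """All circular arrangements by exhaustive extension of oriented unit
    instances filtered by observed adjacency, with block constraints checked
    on the complete circle; canonical and deduplicated."""
    instances = sorted(
        u for u, c in graph.copy_numbers.items() for _ in range(c)
    )
    total = len(instances)
    results = set()

    def valid_circle(arr):
        n = len(arr)
        for i in range(n):
            if not graph.has_adjacency(arr[i], arr[(i + 1) % n]):
                return False
        if n >= 3:
            for i in range(n):
                if not graph.triple_ok(arr[i - 1], arr[i], arr[(i + 1) % n]):
                    return False
        return True

    def extend(path, remaining):
        if len(path) == total:
            if valid_circle(path):
                iso = canonicalize_isoform(IsoformModel(tuple(path)))
                results.add(iso.arrangement)
            return
        for u in sorted(set(remaining)):
            for strand in "+-":
                nxt = OrientedUnit(u, strand)
                if not graph.has_adjacency(path[-1], nxt):
                    continue
                rest = list(remaining)
                rest.remove(u)
                extend(path + [nxt], rest)

    first = instances[0]
    rest = list(instances)
    rest.remove(first)
    extend([OrientedUnit(first, "+")], rest)
    # the fixed start orientation misses circles only reachable from the
    # reflected start; add them by symmetry
    for arr in list(results):
        refl = canonicalize_isoform(
            IsoformModel(tuple(ou.reverse() for ou in reversed(arr)))
        )
        results.add(refl.arrangement)
    return results


def _random_graph(seed):
    """A graph induced by 1-2 random circular arrangements of <= 8 instances."""
    rng = np.random.default_rng(seed)
    n_units = int(rng.integers(3, 6))
    names = [chr(ord("A") + i) for i in range(n_units)]
    repeat = names[int(rng.integers(0, n_units))]
    copy_numbers = {u: (2 if u == repeat else 1) for u in names}
    instances = [u for u, c in copy_numbers.items() for _ in range(c)]
    arrangements = []
    for _ in range(int(rng.integers(1, 3))):
        perm = list(rng.permutation(instances))
        strands = ["+" if rng.random() < 0.8 else "-" for _ in perm]
        arrangements.append(tuple(OrientedUnit(u, s) for u, s in zip(perm, strands)))
    blocks = _blocks_from_arrangements(arrangements, {repeat})
    return build_graph(blocks, copy_numbers), arrangements


class TestEnumerateIsoforms:
    def test_sativa_two_major_isoforms(self, sativa_even):
        enum = sativa_even["enum"]
        assert len(enum.isoforms) == 2
        assert not enum.truncated
        arrs = [iso.arrangement for iso in enum.isoforms]
        truth = sativa_even["truth"]
        expected = {
            canonicalize_isoform(truth.isoforms[0]).arrangement,
            canonicalize_isoform(truth.isoforms[1]).arrangement,
        }
        assert set(arrs) == expected
        # the two differ exactly by the P/U exchange between R and T
        diff = [
            (a.unit, b.unit)
            for a, b in zip(*arrs)
            if a != b
        ]
        assert {frozenset(d) for d in diff} == {frozenset({"P", "U"})}

    def test_three_unit_cycle_single_isoform(self):
        arr = parse_arrangement("A+,B+,C+")
        graph = build_graph(
            _blocks_from_arrangements([arr], set()), {"A": 1, "B": 1, "C": 1}
        )
        enum = enumerate_isoforms(graph)
        assert len(enum.isoforms) == 1
        assert enum.isoforms[0].arrangement == tuple(parse_arrangement("A+,B+,C+"))

    def test_unsatisfiable_graph_reports_diagnostic(self):
        graph = build_graph([], {"A": 1, "B": 1})
        enum = enumerate_isoforms(graph)
        assert enum.isoforms == []
        assert "no observed junction" in enum.diagnostics

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_on_small_graphs(self, seed):
        graph, arrangements = _random_graph(seed)
        enum = enumerate_isoforms(graph)
        got = {iso.arrangement for iso in enum.isoforms}
        expected = brute_force_isoforms(graph)
        assert got == expected
        # every generating arrangement is recovered
        for arr in arrangements:
            assert canonicalize_isoform(IsoformModel(arr)).arrangement in got

    def test_spec_toy_hinge_pattern(self):
        """Units A,B,C 1x + repeat R 2x arranged A-R-B ... C-R-(A): the
        enumeration agrees with brute force."""
        arr = parse_arrangement("A+,R+,B+,C+,R+")
        graph = build_graph(
            _blocks_from_arrangements([arr], {"R"}),
            {"A": 1, "B": 1, "C": 1, "R": 2},
        )
        enum = enumerate_isoforms(graph)
        assert {i.arrangement for i in enum.isoforms} == brute_force_isoforms(graph)
        assert canonicalize_isoform(IsoformModel(arr)).arrangement in {
            i.arrangement for i in enum.isoforms
        }


class TestScoreIsoforms:
    def _alpha_beta(self):
        alpha = IsoformModel(parse_arrangement("A+,R+,P+,T+,Q+,R+,U+,T+"), label="alpha")
        beta = IsoformModel(parse_arrangement("A+,R+,U+,T+,Q+,R+,P+,T+"), label="beta")
        return alpha, beta

    def _supports(self, isoforms, freqs, scale=400):
        # occurrence-weighted supports for all blocks of the union
        supports = {}
        blocks = set()
        for iso in isoforms:
            arr = iso.arrangement + iso.arrangement[:3]
            blocks |= {b.units for b in building_blocks([arr], {"R", "T"}, 1)}
        for b in blocks:
            supports[b] = round(
                scale * sum(
                    f * iso_mod.block_occurrences(iso, b)
                    for f, iso in zip(freqs, isoforms)
                )
            )
        return supports

    def test_pure_mixture(self):
        alpha, beta = self._alpha_beta()
        supports = self._supports([alpha, beta], [1.0, 0.0])
        res = score_isoforms([alpha, beta], supports)
        assert res.frequencies["alpha"] == pytest.approx(1.0, abs=0.05)
        assert res.frequencies["beta"] == pytest.approx(0.0, abs=0.05)

    def test_even_and_skewed_mixtures(self):
        alpha, beta = self._alpha_beta()
        for f in (0.5, 0.8):
            supports = self._supports([alpha, beta], [f, 1 - f])
            res = score_isoforms([alpha, beta], supports)
            assert res.frequencies["alpha"] == pytest.approx(f, abs=0.05)

    def test_degenerate_design_flagged_and_tied(self):
        # two rotations of the same circle: identical block profiles
        a = IsoformModel(parse_arrangement("A+,B+,C+"), label="x")
        b = IsoformModel(parse_arrangement("B+,C+,A+"), label="y")
        supports = {canonical_block(tuple(parse_arrangement("A+,B+"))): 10,
                    canonical_block(tuple(parse_arrangement("B+,C+"))): 10,
                    canonical_block(tuple(parse_arrangement("C+,A+"))): 10}
        res = score_isoforms([a, b], supports)
        assert res.degenerate
        assert res.frequencies["x"] == pytest.approx(res.frequencies["y"])
        assert res.tied_groups == [["x", "y"]]

    def test_isoform_sequences_materialization(self):
        from mitoforms.isoforms import isoform_sequences
        from mitoforms.model import revcomp

        unit_seqs = {"A": "ACGTACGTAA", "B": "GGGTTTCCCA"}
        iso = IsoformModel(parse_arrangement("A+,B-"), label="x")
        ((label, seq, coords),) = isoform_sequences([iso], unit_seqs)
        assert label == "x"
        assert seq == unit_seqs["A"] + revcomp(unit_seqs["B"])
        assert coords == [("A", "+", 0, 10), ("B", "-", 10, 20)]

    def test_no_shared_blocks_raises(self):
        a = IsoformModel(parse_arrangement("A+,B+"), label="x")
        supports = {canonical_block(tuple(parse_arrangement("C+,D+"))): 5}
        with pytest.raises(ValueError):
            score_isoforms([a], supports)
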