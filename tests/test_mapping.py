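"""Tiling, the seeded local aligner (against a DP oracle), read selection,
plastid filtering, and unit-path reconstruction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitoforms import mapping, simulate
from mitoforms.mapping import AlignmentHit, make_tiling
from mitoforms.model import SequenceRecord, revcomp

from conftest import toy_config


def _random_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


# ---------------------------------------------------------------------------
# Tiling
# ---------------------------------------------------------------------------

class TestMakeTiling:
    def test_exact_multiple(self):
        frags = make_tiling([("u", "A" * 3000)], 2000, 1000)
        assert [(f.start, f.end) for f in frags] == [(0, 2000), (1000, 3000)]

    def test_tail_window_added(self):
        # a 3,552 bp unit: regular windows then one flush-right tail window
        frags = make_tiling([("t", "A" * 3552)], 2000, 1000)
        assert [(f.start, f.end) for f in frags] == [(0, 2000), (1000, 3000), (1552, 3552)]

    def test_short_unit_single_fragment(self):
        frags = make_tiling([("s", "A" * 1200)], 2000, 1000)
        assert [(f.start, f.end) for f in frags] == [(0, 1200)]

    def test_empty_unit_list_raises(self):
        with pytest.raises(ValueError):
            make_tiling([])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.integers(min_value=1, max_value=9000),
        st.integers(min_value=2, max_value=2000),
        st.integers(min_value=1, max_value=2000),
    )
    def test_fragments_cover_unit_exactly(self, L, window, step):
        if step > window:
            window, step = step, window
        frags = make_tiling([("u", "A" * L)], window, step)
        covered = np.zeros(L, dtype=bool)
        for f in frags:
            assert 0 <= f.start < f.end <= L
            assert len(f) == min(window, L)
            covered[f.start : f.end] = True
        assert covered.all()


# ---------------------------------------------------------------------------
# Local aligner vs full Smith-Waterman oracle
# ---------------------------------------------------------------------------

def smith_waterman(query, target, match=1, mismatch=-1, gap=-1):
    """Plain DP local alignment; returns (score, q_interval, t_interval)."""
    n, m = len(query), len(target)
    H = np.zeros((n + 1, m + 1))
    for i in range(1, n + 1):
        sub = np.where(
            np.frombuffer(target.encode(), dtype=np.uint8)
            == query[i - 1].encode()[0],
            match, mismatch,
        )
        for j in range(1, m + 1):
            H[i, j] = max(0, H[i - 1, j - 1] + sub[j - 1], H[i - 1, j] + gap, H[i, j - 1] + gap)
    score = H.max()
    i, j = np.unravel_index(np.argmax(H), H.shape)
    # traceback for start
    qi, tj = i, j
    while H[qi, tj] > 0:
        diag = H[qi - 1, tj - 1]
        up = H[qi - 1, tj]
        left = H[qi, tj - 1]
        step = H[qi, tj]
        if qi > 0 and tj > 0 and step == diag + (match if query[qi - 1] == target[tj - 1] else mismatch):
            qi, tj = qi - 1, tj - 1
        elif qi > 0 and step == up + gap:
            qi -= 1
        elif tj > 0 and step == left + gap:
            tj -= 1
        else:
            break
    return score, (qi, i), (tj, j)


class TestAlignLocal:
    def test_exact_substring(self):
        rng = np.random.default_rng(0)
        target = _random_seq(rng, 6000)
        query = target[1500:3500]
        hits = mapping.align_local(query, target)
        assert len(hits) == 1
        h = hits[0]
        assert h.identity == 1.0
        assert (h.read_start, h.read_end) == (1500, 3500)
        assert h.aln_len == 2000
        assert h.strand == "+"

    def test_reverse_complement_hit(self):
        rng = np.random.default_rng(1)
        target = _random_seq(rng, 4000)
        query = revcomp(target[500:2500])
        hits = mapping.align_local(query, target)
        assert len(hits) == 1
        assert hits[0].strand == "-"
        assert (hits[0].read_start, hits[0].read_end) == (500, 2500)

    def test_mutated_substring_identity(self):
        rng = np.random.default_rng(2)
        target = _random_seq(rng, 5000)
        sub = list(target[1000:3000])
        # 5% substitutions, kept away from the extremes
        for pos in rng.choice(np.arange(20, 1980), size=100, replace=False):
            sub[pos] = "ACGT"[("ACGT".index(sub[pos]) + 1) % 4]
        hits = mapping.align_local("".join(sub), target)
        assert len(hits) == 1
        h = hits[0]
        assert h.identity == pytest.approx(0.95, abs=0.01)
        assert abs(h.read_start - 1000) <= 2 and abs(h.read_end - 3000) <= 2

    def test_no_hit_on_unrelated_sequence(self):
        rng = np.random.default_rng(3)
        assert mapping.align_local(_random_seq(rng, 500), _random_seq(rng, 2000)) == []

    def test_empty_sequence_raises(self):
        with pytest.raises(ValueError):
            mapping.align_local("", "ACGT")

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4, 5])
    def test_agrees_with_dp_oracle(self, seed):
        """On instances <= 300 bp the seeded aligner matches full DP:
        interval within +-2 bp, identity within 0.02."""
        rng = np.random.default_rng(seed + 100)
        target = _random_seq(rng, 300)
        lo, hi = 40, 40 + int(rng.integers(120, 200))
        sub = list(target[lo:hi])
        n_mut = int(rng.integers(0, len(sub) // 25))
        for pos in rng.choice(np.arange(5, len(sub) - 5), size=n_mut, replace=False):
            sub[pos] = "ACGT"[("ACGT".index(sub[pos]) + 1) % 4]
        query = "".join(sub)
        hits = mapping.align_local(query, target, min_len=30)
        assert hits, "aligner missed a planted high-identity instance"
        h = max(hits, key=lambda x: x.aln_len)
        _score, (q0, q1), (t0, t1) = smith_waterman(query, target)
        assert abs(h.read_start - t0) <= 2 and abs(h.read_end - t1) <= 2
        dp_identity = 1 - n_mut / (q1 - q0) if q1 > q0 else 1.0
        assert h.identity == pytest.approx(dp_identity, abs=0.02)


# ---------------------------------------------------------------------------
# Tiling-to-read mapping
# ---------------------------------------------------------------------------

class TestMapTilingToReads:
    def test_error_free_unit_read_hits_in_order(self):
        rng = np.random.default_rng(7)
        unit = _random_seq(rng, 10000)
        frags = make_tiling([("u", unit)])
        read = SequenceRecord("r", unit)
        hits = mapping.map_tiling_to_reads(frags, [read])
        assert len(hits) >= 9
        assert [h.frag_index for h in hits] == sorted(h.frag_index for h in hits)
        assert all(h.strand == "+" for h in hits)

    def test_unrelated_read_no_hits(self):
        rng = np.random.default_rng(8)
        frags = make_tiling([("u", _random_seq(rng, 6000))])
        read = SequenceRecord("r", _random_seq(rng, 8000))
        assert mapping.map_tiling_to_reads(frags, [read]) == []

    def test_junction_read_shows_both_units(self):
        rng = np.random.default_rng(9)
        w = _random_seq(rng, 8000)
        z = _random_seq(rng, 8000)
        frags = make_tiling([("W", w), ("Z", z)])
        read = SequenceRecord("j", w[-5000:] + z[:5000])
        hits = mapping.map_tiling_to_reads(frags, [read])
        units_in_order = [h.unit for h in hits]
        assert set(units_in_order) == {"W", "Z"}
        assert units_in_order == sorted(units_in_order, key=lambda u: u != "W")


class TestSelectInformativeReads:
    def _hits(self, read_id, fragment_ids):
        return [
            AlignmentHit(read_id, fid, 0, 0, 0, 0, "+", 1.0, 2000)
            for fid in fragment_ids
        ]

    def test_threshold_boundary(self):
        hits = self._hits("keep", [f"u.{i:04d}" for i in range(10)]) + self._hits(
            "drop", [f"u.{i:04d}" for i in range(9)]
        )
        assert mapping.select_informative_reads(hits, 10) == {"keep"}

    def test_duplicate_fragments_count_once(self):
        hits = self._hits("r", ["u.0001"] * 5 + ["u.0002"] * 5)
        assert mapping.select_informative_reads(hits, 3) == set()
        assert mapping.select_informative_reads(hits, 2) == {"r"}

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            mapping.select_informative_reads([], 0)


class TestFilterPlastid:
    def test_filtering_rules(self):
        rng = np.random.default_rng(11)
        decoy = SequenceRecord("cp", _random_seq(rng, 20000))
        mito = _random_seq(rng, 5000)
        pairs = [
            # both mates plastid: dropped
            (SequenceRecord("a/1", decoy.seq[500:600]), SequenceRecord("a/2", decoy.seq[2000:2100])),
            # clean mitochondrial pair: kept
            (SequenceRecord("b/1", mito[100:200]), SequenceRecord("b/2", mito[1000:1100])),
            # one plastid mate is enough to drop the pair
            (SequenceRecord("c/1", mito[200:300]), SequenceRecord("c/2", decoy.seq[3000:3100])),
            # chimeric mate matching decoy over only 80% of its length: kept
            (SequenceRecord("d/1", decoy.seq[5000:5080] + mito[0:20]), SequenceRecord("d/2", mito[2000:2100])),
        ]
        kept = mapping.filter_plastid(pairs, decoy)
        assert [p[0].id for p in kept] == ["b/1", "d/1"]


# ---------------------------------------------------------------------------
# Unit paths
# ---------------------------------------------------------------------------

class TestAdapters:
    def test_outfmt6_table_round_trip(self, tmp_path):
        frags = make_tiling([("W", "A" * 4000)])
        tab = tmp_path / "hits.tsv"
        # qseqid sseqid pident length mismatch gapopen qstart qend sstart send evalue bits
        tab.write_text(
            "W.0000\tread1\t98.50\t2000\t30\t0\t1\t2000\t501\t2500\t0.0\t3500\n"
            "W.0001\tread1\t97.00\t1900\t57\t0\t1\t1900\t4400\t2501\t0.0\t3100\n"
        )
        hits = mapping.load_blast_hits(tab, frags)
        assert len(hits) == 2
        plus, minus = hits
        assert (plus.read_start, plus.read_end, plus.strand) == (500, 2500, "+")
        assert plus.identity == pytest.approx(0.985)
        assert plus.unit == "W" and plus.frag_index == 0
        assert (minus.read_start, minus.read_end, minus.strand) == (2500, 4400, "-")

    def test_fasta_round_trip(self, tmp_path):
        from mitoforms.io import read_fasta, write_fasta

        rng = np.random.default_rng(55)
        records = [
            SequenceRecord(f"s{i}", _random_seq(rng, int(rng.integers(10, 200))))
            for i in range(5)
        ]
        path = tmp_path / "x.fasta"
        write_fasta(records, path, width=60)
        back = read_fasta(path)
        assert [(r.id, r.seq) for r in back] == [(r.id, r.seq) for r in records]


class TestUnitPaths:
    def _mk_hits(self, spec, step=1000):
        """spec: list of (unit, frag_index, read_start, strand)."""
        return [
            AlignmentHit("r", f"{u}.{i:04d}", s, s + 2000, 0, 2000, strand, 0.98, 2000,
                         unit=u, frag_index=i)
            for u, i, s, strand in spec
        ]

    def test_junction_path(self):
        hits = self._mk_hits(
            [("W", 50, 0, "+"), ("W", 51, 1000, "+"), ("W", 52, 2000, "+"),
             ("Z", 0, 3000, "+"), ("Z", 1, 4000, "+"), ("Z", 2, 5000, "+")]
        )
        path = mapping.unit_path_from_hits(hits, {"W": 60000, "Z": 20000})
        assert str(path) == "W+,Z+"

    def test_antitone_indices_give_minus_strand(self):
        hits = self._mk_hits([("T", 2, 0, "-"), ("T", 1, 1000, "-"), ("T", 0, 2000, "-")])
        path = mapping.unit_path_from_hits(hits, {"T": 4000})
        assert str(path) == "T-"

    def test_stray_fragment_dropped_by_min_run(self):
        hits = self._mk_hits(
            [("K", 10, 0, "+"), ("K", 11, 1000, "+"),
             ("X", 5, 1500, "+"),  # single stray hit
             ("K", 12, 2000, "+"), ("K", 13, 3000, "+")]
        )
        path = mapping.unit_path_from_hits(hits, {"K": 80000, "X": 50000})
        assert str(path) == "K+"

    def test_short_unit_single_fragment_kept(self):
        hits = self._mk_hits(
            [("K", 10, 0, "+"), ("K", 11, 1000, "+"),
             ("N", 0, 2200, "+"),  # unit shorter than window+step
             ("K2", 0, 4300, "+"), ("K2", 1, 5300, "+")]
        )
        path = mapping.unit_path_from_hits(hits, {"K": 80000, "N": 1500, "K2": 30000})
        assert [str(ou) for ou, _ in path.entries] == ["K+", "N+", "K2+"]

    def test_error_free_paths_match_provenance(self):
        """Every unit path from zero-error reads is a contiguous subpath of
        the generating arrangement (or its reverse complement)."""
        cfg = toy_config(seed=12, coverage=15, sub_rate=0, ins_rate=0, del_rate=0)
        truth = simulate.generate_genome(cfg)
        reads, prov = simulate.sample_long_reads(truth, cfg)
        units = [(n, s) for n, s in truth.unit_seqs.items()]
        hits = mapping.map_tiling_to_reads(mapping.make_tiling(units), reads)
        paths = mapping.unit_paths(hits, {n: len(s) for n, s in units})
        arr = truth.isoforms[0].arrangement
        doubled = arr + arr
        fwd = ",".join(str(ou) for ou in doubled)
        rev = ",".join(str(ou.reverse()) for ou in reversed(doubled))
        assert len(paths) > 10
        for p in paths:
            token = str(p)
            assert token in fwd or token in rev, f"{p.read_id}: {token}"
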