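"""Unit stoichiometry and junction abundance from long-read alignments.

Copy numbers of primary structural units are read off tiling coverage: a
2 kb / 0.5 kb-step fragment library is aligned to the informative read set
and per-fragment hit counts (alignments >= 1.8 kb at >= 80% identity) are
compared between units.  Units at twice the single-copy baseline are large
repeats.  The 1.8 kb length filter keeps alignments caused by dispersed
medium-size repeats (all shorter than 1.2 kb) out of the counts.

Junction abundance uses 2 kb junction-spanning fragments (1 kb of sequence
on either side of the junction): the number of reads carrying an
uninterrupted alignment of such a fragment measures how often that junction
occurs in the molecule pool; the transition from complete (>= 1.8 kb) to
segmented alignments in the sorted-length curve is the breakpoint.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mapping import make_tiling, max_clean_segment, seed_and_align
from .model import OrientedUnit, SequenceRecord, canonical_block, revcomp

__all__ = [
    "CoverageProfile",
    "JunctionModel",
    "unit_coverage",
    "classify_copy_number",
    "junctions_from_paths",
    "junction_library",
    "junction_abundance",
]

COVERAGE_WINDOW = 2000
COVERAGE_STEP = 500
MIN_ALN_LEN = 1800
MIN_IDENTITY = 0.8
JUNCTION_FLANK = 1000


@dataclass
class CoverageProfile:
    """Per-fragment long-read hit counts for one unit."""

    unit: str
    frag_starts: list[int]
    counts: list[int]

    @property
    def mean_interior(self) -> float:
        """Mean count excluding the two terminal fragments on each side,
        which dip because reads must fully contain a fragment to count."""
        inner = self.counts[2:-2] if len(self.counts) > 4 else self.counts
        return float(np.mean(inner)) if inner else 0.0


def unit_coverage(
    units: list[tuple[str, str]],
    reads: list[SequenceRecord],
    window: int = COVERAGE_WINDOW,
    step: int = COVERAGE_STEP,
    min_aln_len: int = MIN_ALN_LEN,
    min_identity: float = MIN_IDENTITY,
) -> list[CoverageProfile]:
    """Count, per coverage-tiling fragment, reads with an alignment of at
    least ``min_aln_len`` contiguous bases at ``min_identity`` identity."""
    if not reads:
        raise ValueError("informative read set is empty")
    fragments = make_tiling(units, window=window, step=step)
    # distance-only verification: at the identity threshold a fragment can
    # only clear min_aln_len through one contiguous alignment
    hits = seed_and_align(
        [(f.id, f.seq) for f in fragments],
        reads,
        stride=10,
        min_identity=min_identity,
        min_len=min_aln_len,
        fast_accept_span=min_aln_len + 50,
    )
    counts: Counter = Counter()
    for h in hits:
        clean = max_clean_segment(h.cigar) if h.cigar else h.aln_len
        if clean >= min_aln_len:
            counts[h.query_id] += 1
    profiles = []
    for unit, _seq in units:
        unit_frags = [f for f in fragments if f.unit == unit]
        profiles.append(
            CoverageProfile(
                unit,
                [f.start for f in unit_frags],
                [counts.get(f.id, 0) for f in unit_frags],
            )
        )
    return profiles


def classify_copy_number(
    profiles: list[CoverageProfile], flag_tolerance: float = 0.25
) -> tuple[dict[str, int], set[str]]:
    """Copy numbers from interior coverage ratios.

    The single-copy baseline is an iterated median: start from the median of
    all unit means, assign provisional integer copy numbers, recompute the
    baseline as the median per-copy coverage, and repeat to convergence.
    Units whose ratio sits more than ``flag_tolerance`` from the nearest
    integer are flagged (sub-stoichiometric repeats are surfaced, not
    silently rounded).
    """
    means = np.array([p.mean_interior for p in profiles], dtype=float)
    names = [p.unit for p in profiles]
    if len(profiles) == 1:
        return {names[0]: 1}, {names[0]}
    if np.all(means == 0):
        raise ValueError("no stable single-copy baseline: all units uncovered")
    baseline = float(np.median(means[means > 0]))
    for _ in range(20):
        cn = np.maximum(1, np.rint(means / baseline))
        new_baseline = float(np.median(means[means > 0] / cn[means > 0]))
        if abs(new_baseline - baseline) < 1e-9:
            break
        baseline = new_baseline
    ratios = means / baseline
    copy_numbers = {}
    flagged = set()
    for name, ratio in zip(names, ratios):
        cn = max(1, int(round(ratio)))
        copy_numbers[name] = cn
        if abs(ratio - round(ratio)) > flag_tolerance or ratio < 0.5:
            flagged.add(name)
    if len(flagged) == len(names):
        raise ValueError("no stable single-copy baseline: every unit flagged")
    return copy_numbers, flagged


@dataclass
class JunctionModel:
    """A 2 kb junction-spanning fragment (1 kb flank each side)."""

    left: OrientedUnit
    right: OrientedUnit
    seq: str
    flank_left: int
    flank_right: int
    support: int = 0

    @property
    def id(self) -> str:
        return f"{self.left}|{self.right}"


def junctions_from_paths(paths) -> Counter:
    """Canonical oriented adjacency counts observed in unit paths (or in
    isoform arrangements, including the circular wrap)."""
    counts: Counter = Counter()
    for p in paths:
        if hasattr(p, "arrangement"):
            arr = tuple(p.arrangement)
            pairs = list(zip(arr, arr[1:]))
            if getattr(p, "topology", "circular") == "circular" and len(arr) > 1:
                pairs.append((arr[-1], arr[0]))
        else:
            arr = p.units if hasattr(p, "units") else tuple(p)
            pairs = list(zip(arr, arr[1:]))
        for a, b in pairs:
            counts[canonical_block((a, b))] += 1
    return counts


def _oriented_seq(unit_seqs: dict[str, str], ou: OrientedUnit) -> str:
    seq = unit_seqs[ou.unit]
    return seq if ou.strand == "+" else revcomp(seq)


def junction_library(
    junctions, unit_seqs: dict[str, str], flank: int = JUNCTION_FLANK
) -> list[JunctionModel]:
    """One junction fragment per distinct oriented junction.

    The fragment takes the terminal ``flank`` bp of the left unit and the
    initial ``flank`` bp of the right unit; a unit shorter than the flank
    contributes its full sequence and the actual flank is recorded.
    Reverse-complement duplicates are merged (canonical orientation).
    """
    if isinstance(junctions, (Counter, dict)):
        pairs = list(junctions)
    else:
        pairs = list(junctions)
    seen = set()
    models = []
    for pair in pairs:
        a, b = canonical_block(tuple(pair))
        if (a, b) in seen:
            continue
        seen.add((a, b))
        left_seq = _oriented_seq(unit_seqs, a)
        right_seq = _oriented_seq(unit_seqs, b)
        fl = min(flank, len(left_seq))
        fr = min(flank, len(right_seq))
        models.append(
            JunctionModel(a, b, left_seq[-fl:] + right_seq[:fr], fl, fr)
        )
    return models


def junction_abundance(
    models: list[JunctionModel],
    reads: list[SequenceRecord],
    threshold: int = MIN_ALN_LEN,
    max_gap: int = 50,
    min_identity: float = MIN_IDENTITY,
) -> tuple[pd.DataFrame, dict[str, list[int]]]:
    """Support counts and sorted-alignment-length curves per junction.

    For each junction fragment, every read's best uninterrupted alignment
    length (no internal indel run above ``max_gap``) is recorded; support is
    the number of reads at or above ``threshold`` (scaled down for
    flank-limited fragments), and the breakpoint index is where the sorted
    curve crosses the threshold.
    """
    if not models:
        return pd.DataFrame(
            columns=["left", "right", "support", "pool_fraction", "breakpoint_index", "n_alignments"]
        ), {}
    hits = seed_and_align(
        [(m.id, m.seq) for m in models],
        reads,
        min_identity=min_identity,
        min_len=300,
        keep_cigar=True,
    )
    best: dict[str, dict[str, int]] = {m.id: {} for m in models}
    for h in hits:
        clean = max_clean_segment(h.cigar, max_gap=max_gap)
        prev = best[h.query_id].get(h.read_id, 0)
        if clean > prev:
            best[h.query_id][h.read_id] = clean
    n_reads = len(reads)
    rows = []
    curves: dict[str, list[int]] = {}
    for m in models:
        lengths = sorted(best[m.id].values(), reverse=True)
        eff_threshold = min(threshold, int(0.9 * len(m.seq)))
        support = sum(1 for x in lengths if x >= eff_threshold)
        m.support = support
        curves[m.id] = lengths
        rows.append(
            (str(m.left), str(m.right), support, support / n_reads, support, len(lengths))
        )
    table = pd.DataFrame(
        rows,
        columns=["left", "right", "support", "pool_fraction", "breakpoint_index", "n_alignments"],
    )
    return table, curves


def breakpoint_index(sorted_lengths: list[int], threshold: int = MIN_ALN_LEN) -> int:
    """Index of the transition from complete to segmented alignments in a
    descending sorted-length vector (equals the support count)."""
    return sum(1 for x in sorted_lengths if x >= threshold)
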