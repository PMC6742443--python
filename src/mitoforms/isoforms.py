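"""Building blocks, the junction graph, and isoform enumeration.

Secondary building blocks are ordered, oriented runs of primary units
observed within single long reads — typically a repeat unit with its two
flanks.  Blocks of length >= 3 phase the passage through a repeat (which
pair-level junctions cannot: around an equally-used hinge the pair sets of
the alternative genome arrangements coincide), so they enter enumeration as
path constraints: a closed walk entering a repeat from X must exit toward
some Y with X-repeat-Y an observed block.

Enumeration finds every circular (or, optionally, linear) arrangement that
uses each unit exactly copy-number times, follows only observed junctions,
and honors the block constraints; results are canonicalized (minimal
rotation / reflection) and deduplicated.  Frequencies of the enumerated
isoforms are then fit to observed block-support fractions by constrained
least squares on the frequency simplex.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .mapping import UnitPath
from .model import IsoformModel, OrientedUnit, canonical_block, canonicalize_isoform

__all__ = [
    "BuildingBlock",
    "JunctionGraph",
    "EnumerationResult",
    "ScoreResult",
    "building_blocks",
    "build_graph",
    "enumerate_isoforms",
    "score_isoforms",
    "block_occurrences",
]


@dataclass(frozen=True)
class BuildingBlock:
    """A canonical oriented unit tuple with its read-support count."""

    units: tuple[OrientedUnit, ...]
    support: int

    def __str__(self) -> str:
        return ",".join(str(u) for u in self.units)

    @property
    def interior(self) -> tuple[str, ...]:
        return tuple(u.unit for u in self.units[1:-1])


def building_blocks(
    paths: list[UnitPath],
    repeats: set[str],
    min_support: int = 2,
) -> list[BuildingBlock]:
    """Extract canonical building blocks from unit paths.

    Every length-2 adjacency is counted, plus the windows that phase the
    hinges: a triple (previous, repeat, next) for every repeat occurrence
    with both neighbors detected — the neighbors themselves may be repeats;
    a read only needs to reach into them, not span them — and the maximal
    repeat-run window (run plus one non-repeat flank on each side) when a
    read traverses a whole run of adjacent repeats.  Blocks with support
    below ``min_support`` are dropped to suppress chimeric or error-driven
    paths.
    """
    counts: Counter = Counter()
    for path in paths:
        units = path.units if isinstance(path, UnitPath) else tuple(path)
        n = len(units)
        for a, b in zip(units, units[1:]):
            counts[canonical_block((a, b))] += 1
        for i in range(1, n - 1):
            if units[i].unit in repeats:
                counts[canonical_block(tuple(units[i - 1 : i + 2]))] += 1
        i = 0
        while i < n:
            if units[i].unit in repeats:
                j = i
                while j < n and units[j].unit in repeats:
                    j += 1
                if i > 0 and j < n and j - i > 1:  # multi-repeat run, flanked
                    counts[canonical_block(tuple(units[i - 1 : j + 1]))] += 1
                i = j
            else:
                i += 1
    blocks = [
        BuildingBlock(units, support)
        for units, support in counts.items()
        if support >= min_support
    ]
    blocks.sort(key=lambda b: (-len(b.units), -b.support, str(b)))
    return blocks


@dataclass
class JunctionGraph:
    """Unit-terminus graph: unit edges with copy-number multiplicity plus
    observed adjacency edges; longer blocks kept as walk constraints."""

    copy_numbers: dict[str, int]
    adjacencies: dict[tuple[OrientedUnit, OrientedUnit], int]
    constraints: dict[str, set[tuple[OrientedUnit, ...]]] = field(default_factory=dict)

    def allowed_next(self, u: OrientedUnit) -> list[OrientedUnit]:
        out = []
        for (a, b), _w in self.adjacencies.items():
            if a == u:
                out.append(b)
            if b.reverse() == u:
                out.append(a.reverse())
        return sorted(set(out))

    def has_adjacency(self, a: OrientedUnit, b: OrientedUnit) -> bool:
        return canonical_block((a, b)) in self.adjacencies

    def triple_ok(self, prev: OrientedUnit, cur: OrientedUnit, nxt: OrientedUnit) -> bool:
        """A walk through repeat ``cur`` must follow an observed block, when
        any block constrains that repeat."""
        allowed = self.constraints.get(cur.unit)
        if not allowed:
            return True
        return canonical_block((prev, cur, nxt)) in allowed


def build_graph(
    blocks: list[BuildingBlock], copy_numbers: dict[str, int]
) -> JunctionGraph:
    """Assemble the junction graph from canonical blocks and copy numbers."""
    adjacencies: dict[tuple[OrientedUnit, OrientedUnit], int] = {}
    constraints: dict[str, set[tuple[OrientedUnit, ...]]] = {}
    for block in blocks:
        for ou in block.units:
            if ou.unit not in copy_numbers:
                raise ValueError(f"block names unit {ou.unit!r} absent from copy numbers")
        for a, b in zip(block.units, block.units[1:]):
            key = canonical_block((a, b))
            adjacencies[key] = adjacencies.get(key, 0) + block.support
        if len(block.units) >= 3:
            for i in range(1, len(block.units) - 1):
                mid = block.units[i]
                if copy_numbers.get(mid.unit, 1) >= 2:
                    triple = canonical_block(tuple(block.units[i - 1 : i + 2]))
                    constraints.setdefault(mid.unit, set()).add(triple)
    # a closed arrangement passes each repeat copy_number times, so fewer
    # observed triples than copies means the hinge was only partially seen
    # (reads too short to phase it) — such a repeat stays unconstrained
    constraints = {
        u: trips for u, trips in constraints.items()
        if len(trips) >= copy_numbers.get(u, 1)
    }
    return JunctionGraph(dict(copy_numbers), adjacencies, constraints)


@dataclass
class EnumerationResult:
    isoforms: list[IsoformModel]
    truncated: bool = False
    diagnostics: str = ""


def enumerate_isoforms(
    graph: JunctionGraph,
    max_results: int = 10000,
    allow_linear: bool = False,
) -> EnumerationResult:
    """Backtracking enumeration of arrangements consistent with the graph.

    Closed walks (circular isoforms) use each unit exactly copy-number
    times, traverse only observed adjacencies, and satisfy every block
    constraint, including across the wrap.  With ``allow_linear`` open walks
    are also emitted (for genomes with a terminal unit).  Results are
    canonical and deduplicated; the search is capped at ``max_results``
    with an explicit truncation flag.
    """
    total = sum(graph.copy_numbers.values())
    if total == 0:
        return EnumerationResult([], diagnostics="empty copy-number map")
    no_adj = [
        u for u in graph.copy_numbers
        if not graph.allowed_next(OrientedUnit(u, "+"))
        and not graph.allowed_next(OrientedUnit(u, "-"))
    ]
    if no_adj and not allow_linear:
        return EnumerationResult(
            [], diagnostics=f"units with no observed junction: {sorted(no_adj)}"
        )

    # start from a single-copy unit when one exists (fixes rotation)
    singles = sorted(u for u, c in graph.copy_numbers.items() if c == 1)
    start_units = [singles[0]] if singles else sorted(graph.copy_numbers)
    found: dict = {}
    truncated = False

    def backtrack(path: list[OrientedUnit], remaining: dict[str, int]):
        nonlocal truncated
        if truncated:
            return
        if len(path) == total:
            first, last = path[0], path[-1]
            if graph.has_adjacency(last, first):
                wrap_ok = True
                if len(path) >= 3:
                    if not graph.triple_ok(path[-2], last, first):
                        wrap_ok = False
                    if wrap_ok and not graph.triple_ok(last, first, path[1]):
                        wrap_ok = False
                if wrap_ok:
                    iso = canonicalize_isoform(
                        IsoformModel(tuple(path), topology="circular")
                    )
                    found.setdefault(iso.arrangement, iso)
                    if len(found) >= max_results:
                        truncated = True
            if allow_linear:
                iso = canonicalize_isoform(IsoformModel(tuple(path), topology="linear"))
                found.setdefault(("linear",) + iso.arrangement, iso)
            return
        cur = path[-1]
        for nxt in graph.allowed_next(cur):
            if remaining.get(nxt.unit, 0) <= 0:
                continue
            if len(path) >= 2 and not graph.triple_ok(path[-2], cur, nxt):
                continue
            remaining[nxt.unit] -= 1
            path.append(nxt)
            backtrack(path, remaining)
            path.pop()
            remaining[nxt.unit] += 1

    for su in start_units:
        remaining = dict(graph.copy_numbers)
        remaining[su] -= 1
        backtrack([OrientedUnit(su, "+")], remaining)
        if singles:
            break

    isoforms = sorted(found.values(), key=lambda i: (i.topology, i.arrangement))
    return EnumerationResult(isoforms, truncated=truncated)


def block_occurrences(iso: IsoformModel, block: tuple[OrientedUnit, ...]) -> int:
    """Occurrences of a canonical block along an isoform (circular wrap
    included; both traversal orientations checked)."""
    arr = iso.arrangement
    m = len(block)
    if m > len(arr):
        return 0
    doubled = arr + arr[: m - 1] if iso.topology == "circular" else arr
    canon = canonical_block(tuple(block))
    count = 0
    for i in range(len(doubled) - m + 1):
        if canonical_block(tuple(doubled[i : i + m])) == canon:
            count += 1
    return count


def isoform_sequences(
    isoforms: list[IsoformModel], unit_seqs: dict[str, str]
) -> list[tuple[str, str, list[tuple[str, str, int, int]]]]:
    """Materialize each arrangement: (label, sequence, unit coordinates).

    Coordinates are 0-based half-open on the emitted sequence (BED
    convention); add one to starts for GFF3.
    """
    from .model import revcomp

    out = []
    for i, iso in enumerate(isoforms):
        label = iso.label or f"iso{i}"
        parts, coords, pos = [], [], 0
        for ou in iso.arrangement:
            seq = unit_seqs[ou.unit]
            if ou.strand == "-":
                seq = revcomp(seq)
            parts.append(seq)
            coords.append((ou.unit, ou.strand, pos, pos + len(seq)))
            pos += len(seq)
        out.append((label, "".join(parts), coords))
    return out


@dataclass
class ScoreResult:
    frequencies: dict[str, float]
    residual: float
    degenerate: bool
    tied_groups: list[list[str]] = field(default_factory=list)


def _block_group(block: tuple[OrientedUnit, ...]) -> tuple:
    """Detectability class of a block: blocks in one class require reads of
    the same span, so their support ratios are free of length bias.  Pairs
    form one class; longer blocks are classed by their interior units."""
    if len(block) == 2:
        return ("pair",)
    return ("block", tuple(sorted(u.unit for u in block[1:-1])))


def score_isoforms(
    isoforms: list[IsoformModel],
    block_supports: dict[tuple[OrientedUnit, ...], int] | list[BuildingBlock],
) -> ScoreResult:
    """Isoform frequencies by least squares on within-class block fractions.

    The read support of block b in a pool with isoform frequencies f is
    s_g * sum_i f_i n_bi, where n_bi counts occurrences of b in isoform i
    and s_g is the detectability of the block's span class (longer spans are
    seen by fewer reads).  Normalizing within each class cancels s_g:
    predicted fractions are p_b = sum_i f_i n_bi / sum_{b' in class} sum_i
    f_i n_b'i, and f is recovered by constrained least squares on the
    simplex (f >= 0, sum f = 1).  Isoforms with identical block profiles
    are inherently indistinguishable: they are flagged and their combined
    frequency is split evenly.
    """
    if isinstance(block_supports, list):
        block_supports = {b.units: b.support for b in block_supports}
    blocks = [canonical_block(tuple(b)) for b in block_supports]
    supports = np.array([block_supports[b] for b in block_supports], dtype=float)
    labels = [iso.label or f"iso{i}" for i, iso in enumerate(isoforms)]
    n = np.array(
        [[block_occurrences(iso, b) for iso in isoforms] for b in blocks], dtype=float
    )
    usable = n.sum(axis=1) > 0
    n = n[usable]
    supports = supports[usable]
    blocks = [b for b, keep in zip(blocks, usable) if keep]
    if n.size == 0 or supports.sum() == 0:
        raise ValueError("no measured block occurs in any candidate isoform")

    # identical columns cannot be separated: merge, solve, split evenly
    merged: list[list[int]] = []
    seen: dict[bytes, int] = {}
    for i in range(n.shape[1]):
        key = n[:, i].tobytes()
        if key in seen:
            merged[seen[key]].append(i)
        else:
            seen[key] = len(merged)
            merged.append([i])
    degenerate = any(len(m) > 1 for m in merged)
    A = np.stack([n[:, m].sum(axis=1) for m in merged], axis=1)
    k = A.shape[1]

    # group rows by detectability class; keep classes with measured support
    class_rows: dict[tuple, list[int]] = {}
    for r, b in enumerate(blocks):
        class_rows.setdefault(_block_group(b), []).append(r)
    groups = [rows for rows in class_rows.values() if supports[rows].sum() > 0]

    def objective(f):
        # classes weighted by their support total (binomial information)
        total = 0.0
        for rows in groups:
            tot_s = supports[rows].sum()
            pred = A[rows] @ f
            denom = pred.sum()
            if denom <= 0:
                total += 1e3
                continue
            total += tot_s * float(
                np.sum((supports[rows] / tot_s - pred / denom) ** 2)
            )
        return total

    from scipy.optimize import minimize

    x0 = np.full(k, 1.0 / k)
    res = minimize(
        objective,
        x0,
        method="SLSQP",
        bounds=[(0.0, 1.0)] * k,
        constraints=[{"type": "eq", "fun": lambda f: f.sum() - 1.0}],
        options={"maxiter": 200, "ftol": 1e-12},
    )
    f_merged = np.clip(res.x, 0, None)
    f_merged = f_merged / f_merged.sum() if f_merged.sum() > 0 else x0
    frequencies = {}
    for mi, members in enumerate(merged):
        for i in members:
            frequencies[labels[i]] = float(f_merged[mi] / len(members))
    residual = float(np.sqrt(objective(f_merged)))
    tied = [[labels[i] for i in m] for m in merged if len(m) > 1]
    return ScoreResult(frequencies, residual, degenerate, tied)
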