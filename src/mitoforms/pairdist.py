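"""2D distance matrices from mate pairs and Hi-C; minor-isoform detection.

Paired reads mapped to a reference isoform populate a symmetric matrix of
1 kb-binned pair distances.  Pairs from the reference arrangement pile up
along the main diagonal at the library insert distance; pairs spanning a
recombinant junction created by crossover at a dispersed repeat appear as
short diagonals displaced from the main one ("double short diagonals", one
per reciprocal junction).  The ratio between the pair flux across such a
junction and the flux across an ordinary reference locus estimates the
recombination frequency.

Hi-C reads carrying the Mbo-I GATC-GATC ligation scar are split into
sub-read pairs at the scar and treated exactly like mate pairs downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import SequenceRecord, revcomp

__all__ = [
    "DistanceMatrix",
    "RecombSignature",
    "map_read_positions",
    "pair_distance_matrix",
    "split_hic_reads",
    "detect_recombination",
    "plot_matrix",
]

MATE_PAIR_SUBSAMPLE = 320_000
HIC_SUBSAMPLE = 640_000
BIN_SIZE = 1000
MIN_PAIR_DISTANCE = 1000

_CODE = np.zeros(256, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


def _codes(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _encode_kmers(codes: np.ndarray, k: int) -> np.ndarray:
    n = codes.size - k + 1
    out = np.zeros(max(n, 0), dtype=np.int64)
    for i in range(k):
        out |= codes[i : i + n].astype(np.int64) << (2 * (k - 1 - i))
    return out


def map_read_positions(
    reads: list[str],
    reference: str,
    circular: bool = True,
    k: int = 13,
    stride: int = 7,
    min_votes: int = 5,
    unique_ratio: float = 0.95,
) -> tuple[np.ndarray, np.ndarray]:
    """Leftmost mapping coordinate of equal-length short reads by seed voting.

    Each read's strided k-mers vote for (strand, diagonal) placements on the
    reference; a read maps if its best placement collects ``min_votes`` and
    is unique (no second placement within ``unique_ratio`` of the best — the
    criterion that discards reads from repeated sequence).  Returns
    (mapped mask, position) arrays.
    """
    L = len(reads[0])
    n = len(reads)
    G = len(reference)
    ref = reference + (reference[: L + k] if circular else "")
    ref_km = _encode_kmers(_codes(ref), k)
    order = np.argsort(ref_km, kind="stable")
    ref_sorted = ref_km[order]
    ref_pos = np.arange(ref_km.size, dtype=np.int64)[order]

    offsets = np.arange(0, L - k + 1, stride)
    all_rows = []
    all_keys = []
    for strand, texts in ((0, reads), (1, [revcomp(r) for r in reads])):
        codes = _CODE[
            np.frombuffer("".join(texts).encode(), dtype=np.uint8)
        ].reshape(n, L)
        # k-mer values at each strided offset, vectorized across reads
        for off in offsets:
            km = np.zeros(n, dtype=np.int64)
            for i in range(k):
                km |= codes[:, off + i].astype(np.int64) << (2 * (k - 1 - i))
            lo = np.searchsorted(ref_sorted, km, side="left")
            hi = np.searchsorted(ref_sorted, km, side="right")
            counts = hi - lo
            nz = np.nonzero(counts)[0]
            if nz.size == 0:
                continue
            c = counts[nz]
            run_starts = np.concatenate(([0], np.cumsum(c)[:-1]))
            pos_idx = np.repeat(lo[nz], c) + (np.arange(int(c.sum())) - np.repeat(run_starts, c))
            diag = ref_pos[pos_idx] - off
            if circular:
                diag %= G
            rows = np.repeat(nz, c)
            all_rows.append(rows)
            all_keys.append(diag * 2 + strand)
    if not all_rows:
        return np.zeros(n, bool), np.zeros(n, np.int64)
    rows = np.concatenate(all_rows)
    keys = np.concatenate(all_keys)
    order = np.lexsort((keys, rows))
    rows, keys = rows[order], keys[order]
    # run-length count of identical (read, placement) pairs
    brk = np.nonzero((np.diff(rows) != 0) | (np.diff(keys) != 0))[0] + 1
    starts = np.concatenate(([0], brk))
    ends = np.concatenate((brk, [rows.size]))
    votes = ends - starts
    vrows = rows[starts]
    vkeys = keys[starts]
    # per read: best and second-best placements
    mapped = np.zeros(n, dtype=bool)
    pos = np.zeros(n, dtype=np.int64)
    order2 = np.lexsort((-votes, vrows))
    vrows, vkeys, votes = vrows[order2], vkeys[order2], votes[order2]
    first = np.concatenate(([True], np.diff(vrows) != 0))
    idx_first = np.nonzero(first)[0]
    for start in idx_first:
        r = vrows[start]
        best = votes[start]
        if best < min_votes:
            continue
        second = votes[start + 1] if start + 1 < vrows.size and vrows[start + 1] == r else 0
        if second >= unique_ratio * best:
            continue
        mapped[r] = True
        pos[r] = vkeys[start] // 2
    return mapped, pos


@dataclass
class DistanceMatrix:
    """Symmetric 1 kb-binned counts of intra-molecule pair distances."""

    reference_id: str
    bin_size: int
    counts: np.ndarray
    total_pairs: int
    circular: bool = True

    @property
    def n_bins(self) -> int:
        return self.counts.shape[0]


def pair_distance_matrix(
    pos1: np.ndarray,
    pos2: np.ndarray,
    reference_length: int,
    reference_id: str = "ref",
    bin_size: int = BIN_SIZE,
    min_distance: int = MIN_PAIR_DISTANCE,
    subsample: int | None = MATE_PAIR_SUBSAMPLE,
    seed: int = 0,
    circular: bool = True,
) -> DistanceMatrix:
    """Bin mapped pair coordinates into a symmetric 2D count matrix.

    Distances are computed from leftmost coordinates (the shorter arc for a
    circular reference); pairs at or under ``min_distance`` are excluded,
    and an optional uniform random subsample of fixed size is taken so
    libraries are comparable.  Each retained pair increments both (i, j)
    and (j, i).
    """
    if reference_length < bin_size:
        raise ValueError("reference shorter than one bin")
    pos1 = np.asarray(pos1, dtype=np.int64)
    pos2 = np.asarray(pos2, dtype=np.int64)
    d = np.abs(pos1 - pos2)
    if circular:
        d = np.minimum(d, reference_length - d)
    keep = d > min_distance
    pos1, pos2 = pos1[keep], pos2[keep]
    if subsample is not None and pos1.size > subsample:
        idx = np.random.default_rng(seed).choice(pos1.size, size=subsample, replace=False)
        pos1, pos2 = pos1[idx], pos2[idx]
    n_bins = (reference_length + bin_size - 1) // bin_size
    b1 = np.clip(pos1 // bin_size, 0, n_bins - 1)
    b2 = np.clip(pos2 // bin_size, 0, n_bins - 1)
    counts = np.zeros((n_bins, n_bins), dtype=np.int64)
    np.add.at(counts, (b1, b2), 1)
    np.add.at(counts, (b2, b1), 1)
    return DistanceMatrix(reference_id, bin_size, counts, int(pos1.size), circular)


def split_hic_reads(
    reads: list[SequenceRecord],
) -> list[tuple[SequenceRecord, SequenceRecord]]:
    """Split reads at GATC-GATC ligation scars into sub-read pairs.

    Each scar is cut at its midpoint so both sub-reads retain one GATC; a
    read with k scars yields k consecutive sub-read pairs.  Reads without
    the dimer are discarded.  Concatenating the sub-reads of a pair restores
    the original sequence around the join.
    """
    out = []
    for read in reads:
        cuts = []
        start = 0
        while True:
            i = read.seq.find("GATCGATC", start)
            if i < 0:
                break
            cuts.append(i + 4)
            start = i + 4
        if not cuts:
            continue
        bounds = [0] + cuts + [len(read.seq)]
        segments = [read.seq[bounds[i] : bounds[i + 1]] for i in range(len(bounds) - 1)]
        for j in range(len(segments) - 1):
            out.append(
                (
                    SequenceRecord(f"{read.id}.s{j}/1", segments[j]),
                    SequenceRecord(f"{read.id}.s{j}/2", segments[j + 1]),
                )
            )
    return out


@dataclass
class RecombSignature:
    """Off-diagonal crossover signature at a dispersed repeat pair."""

    repeat_positions: tuple[int, int]
    repeat_length: int
    observed: dict[str, float]
    baseline: float
    frequency: float
    flag: str = "ok"


def _rect_sum(matrix: DistanceMatrix, rows, cols, exclude_near_diag: int = 1) -> float:
    """Sum of matrix cells over a (circularly wrapped) bin rectangle,
    excluding cells within ``exclude_near_diag`` bins of the main diagonal
    (those fall under the short-distance pair filter)."""
    B = matrix.n_bins
    total = 0.0
    for i in rows:
        bi = i % B
        for j in cols:
            bj = j % B
            off = abs(bi - bj)
            if matrix.circular:
                off = min(off, B - off)
            if off <= exclude_near_diag:
                continue
            total += matrix.counts[bi, bj]
    return total


def _junction_flux(
    matrix: DistanceMatrix, a_bin: int, b_bin: int, span: int, exclude_near_diag: int = 1
) -> float:
    """Pair flux across a junction joining reference position a (upstream
    side) to position b (downstream side): cells (a - u, b + v) with
    u, v >= 0 and u + v <= span — the triangle swept out by pairs whose two
    reads straddle the junction within the library span."""
    B = matrix.n_bins
    total = 0.0
    for u in range(span + 1):
        bi = (a_bin - u) % B
        for v in range(span + 1 - u):
            bj = (b_bin + v) % B
            off = abs(bi - bj)
            if matrix.circular:
                off = min(off, B - off)
            if off <= exclude_near_diag:
                continue
            total += matrix.counts[bi, bj]
    return total


def detect_recombination(
    matrix: DistanceMatrix,
    repeat_positions: tuple[int, int],
    repeat_length: int,
    span: int | None = None,
    n_reference_loci: int = 24,
) -> RecombSignature:
    """Estimate the frequency of crossover at a direct repeat pair.

    Crossover between copies at p1 < p2 creates two reciprocal junctions;
    pairs spanning them land on short diagonals displaced from the main
    diagonal near (p2, p1) and (p1, p2 + repeat).  The estimator sums the
    matrix over the two junction rectangles (each ``span`` bins on a side)
    and divides by the mean pair flux across ordinary reference loci — the
    value "on the main diagonal" at comparable separation.  Copies closer
    than the library span are flagged unestimable (the signature merges into
    the main diagonal).
    """
    p1, p2 = sorted(repeat_positions)
    B = matrix.n_bins
    bs = matrix.bin_size
    G = B * bs
    if span is None:
        # library span from the matrix itself: 98th percentile of the
        # circular pair-distance histogram
        half = B // 2
        hist = np.zeros(half + 1, dtype=np.float64)
        for d in range(1, half + 1):
            h = np.trace(matrix.counts, offset=d)
            if matrix.circular:
                h += np.trace(matrix.counts, offset=d - B)
            hist[d] = h
        cum = np.cumsum(hist)
        # 90th percentile: covers most of the insert distribution while
        # staying robust to off-diagonal signature mass
        span = int(np.searchsorted(cum, 0.90 * cum[-1])) + 1
    sep = min(abs(p2 - p1), G - abs(p2 - p1))
    if sep <= (span + 2) * bs:
        return RecombSignature(
            (p1, p2), repeat_length, {}, 0.0, 0.0, flag="unestimable"
        )
    b1, b2 = p1 // bs, p2 // bs
    rep_bins = max(1, repeat_length // bs)

    # junction A joins (just before p2) to (just after p1 + repeat); the
    # downstream side starts in the bin holding the repeat end (reads inside
    # the repeat itself are removed by the unique-mapping filter)
    obs_a = _junction_flux(matrix, b2, (p1 + repeat_length) // bs, span)
    # junction B joins (just before p1) to (just after p2 + repeat)
    obs_b = _junction_flux(matrix, b1, (p2 + repeat_length) // bs, span)

    # baseline: mean flux across ordinary loci away from the repeat copies
    forbidden = set()
    for center in (b1, b2):
        for d in range(-2 * span - rep_bins, 2 * span + rep_bins + 1):
            forbidden.add((center + d) % B)
    loci = [b for b in range(0, B, max(1, B // n_reference_loci)) if b not in forbidden]
    if not loci:
        return RecombSignature((p1, p2), repeat_length, {}, 0.0, 0.0, flag="unestimable")
    base_fluxes = [_junction_flux(matrix, r, r, span) for r in loci]
    baseline = float(np.mean(base_fluxes))
    if baseline <= 0:
        return RecombSignature((p1, p2), repeat_length, {}, 0.0, 0.0, flag="unestimable")
    freq = float((obs_a + obs_b) / 2.0 / baseline)
    return RecombSignature(
        (p1, p2),
        repeat_length,
        {"junction_a": obs_a, "junction_b": obs_b},
        baseline,
        min(freq, 1.0),
    )


def plot_matrix(matrix: DistanceMatrix, path, vmax: float | None = None) -> None:
    """Write a heat-map PNG of the distance matrix (1 kb bins)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 6))
    ax.imshow(
        matrix.counts,
        origin="lower",
        cmap="viridis",
        vmax=vmax,
        interpolation="nearest",
    )
    ax.set_xlabel(f"bin ({matrix.bin_size} bp)")
    ax.set_ylabel(f"bin ({matrix.bin_size} bp)")
    ax.set_title(matrix.reference_id)
    fig.savefig(path, dpi=120)
    plt.close(fig)
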