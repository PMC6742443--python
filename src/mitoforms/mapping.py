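"""Reverse read mapping: tiling fragments aligned onto long reads.

Instead of mapping reads onto an assembly, each primary structural unit is
cut into overlapping tiling fragments (2 kb windows, 1 kb step) which are
then located on the raw long reads.  The ordered fragment hits along a read
spell out the sequence of oriented units the molecule traverses — including
passes through repeat units that a read-to-assembly mapping would collapse.

The aligner is a seeded chained local aligner: exact k-mer seeds (k = 15 by
default) are bucketed by diagonal per (query, strand), and each chain is
verified with a banded edit-distance alignment (edlib) to produce identity,
intervals and a CIGAR.  An adapter for external tabular (BLAST outfmt-6
style) hit files is provided for users who prefer an external mapper.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import edlib
import numpy as np
import pandas as pd

from .model import OrientedUnit, PrimaryUnit, SequenceRecord, revcomp

__all__ = [
    "TilingFragment",
    "AlignmentHit",
    "UnitPath",
    "make_tiling",
    "align_local",
    "map_tiling_to_reads",
    "select_informative_reads",
    "filter_plastid",
    "unit_path_from_hits",
    "unit_paths",
    "load_blast_hits",
    "hits_to_frame",
]

DEFAULT_WINDOW = 2000
DEFAULT_STEP = 1000
DEFAULT_K = 15
DEFAULT_MIN_IDENTITY = 0.8


@dataclass(frozen=True)
class TilingFragment:
    """One window of a unit: interval [start, end) on the unit sequence."""

    unit: str
    index: int
    start: int
    end: int
    seq: str

    @property
    def id(self) -> str:
        return f"{self.unit}.{self.index:04d}"

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class AlignmentHit:
    """A local alignment of a query (fragment) on a read."""

    read_id: str
    query_id: str
    read_start: int
    read_end: int
    q_start: int
    q_end: int
    strand: str
    identity: float
    aln_len: int
    cigar: str = ""
    unit: str = ""
    frag_index: int = -1


@dataclass
class UnitPath:
    """Ordered oriented units detected along one read."""

    read_id: str
    entries: list[tuple[OrientedUnit, int]]  # (oriented unit, read offset)
    n_distinct_fragments: int = 0
    ambiguous: bool = False

    @property
    def units(self) -> tuple[OrientedUnit, ...]:
        return tuple(ou for ou, _ in self.entries)

    def __str__(self) -> str:
        return ",".join(str(ou) for ou in self.units)


# ---------------------------------------------------------------------------
# Tiling
# ---------------------------------------------------------------------------

def make_tiling(
    units, window: int = DEFAULT_WINDOW, step: int = DEFAULT_STEP
) -> list[TilingFragment]:
    """Sliding windows over each unit; a tail window [L-window, L) is added
    when the last regular window falls short of the unit end, so unit termini
    (where junction evidence lives) are always covered.  Units shorter than
    the window yield a single whole-unit fragment.
    """
    if window < step or step < 1:
        raise ValueError("need window >= step >= 1")
    if not units:
        raise ValueError("empty unit list")
    fragments: list[TilingFragment] = []
    for unit in units:
        name, seq = (unit.name, unit.seq) if isinstance(unit, PrimaryUnit) else unit
        L = len(seq)
        idx = 0
        if L <= window:
            fragments.append(TilingFragment(name, 0, 0, L, seq))
            continue
        last_end = 0
        start = 0
        while start + window <= L:
            fragments.append(TilingFragment(name, idx, start, start + window, seq[start : start + window]))
            last_end = start + window
            idx += 1
            start += step
        if last_end < L:
            fragments.append(TilingFragment(name, idx, L - window, L, seq[L - window : L]))
    return fragments


# ---------------------------------------------------------------------------
# k-mer index + seeded chained alignment engine
# ---------------------------------------------------------------------------

_CODE = np.zeros(256, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


def _codes(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _encode_kmers(codes: np.ndarray, k: int) -> np.ndarray:
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    out = np.zeros(n, dtype=np.int64)
    for i in range(k):
        out |= codes[i : i + n].astype(np.int64) << (2 * (k - 1 - i))
    return out


class KmerIndex:
    """Sorted k-mer table over a set of query sequences (both strands)."""

    def __init__(self, queries: list[tuple[str, str]], k: int = DEFAULT_K):
        self.k = k
        self.ids = [qid for qid, _ in queries]
        self.seqs = [seq for _, seq in queries]
        self.lens = np.array([len(s) for s in self.seqs], dtype=np.int64)
        kmers, qidx, qpos, strand = [], [], [], []
        for qi, seq in enumerate(self.seqs):
            for st, s in ((0, seq), (1, revcomp(seq))):
                km = _encode_kmers(_codes(s), k)
                kmers.append(km)
                qidx.append(np.full(km.size, qi, dtype=np.int32))
                qpos.append(np.arange(km.size, dtype=np.int32))
                strand.append(np.full(km.size, st, dtype=np.int8))
        kmers = np.concatenate(kmers) if kmers else np.empty(0, np.int64)
        order = np.argsort(kmers, kind="stable")
        self.kmers = kmers[order]
        self.qidx = np.concatenate(qidx)[order]
        self.qpos = np.concatenate(qpos)[order]
        self.strand = np.concatenate(strand)[order]


def _match_arrays(index: KmerIndex, read_codes: np.ndarray, stride: int):
    """All (read_pos, query, strand, qpos) seed matches for one read."""
    km = _encode_kmers(read_codes, index.k)
    if km.size == 0:
        return None
    pos = np.arange(0, km.size, stride)
    km = km[pos]
    lo = np.searchsorted(index.kmers, km, side="left")
    hi = np.searchsorted(index.kmers, km, side="right")
    counts = hi - lo
    nz = counts > 0
    if not nz.any():
        return None
    c = counts[nz]
    starts = lo[nz]
    total = int(c.sum())
    run_starts = np.concatenate(([0], np.cumsum(c)[:-1]))
    offsets = np.arange(total) - np.repeat(run_starts, c)
    entry = np.repeat(starts, c) + offsets
    read_pos = np.repeat(pos[nz], c)
    return read_pos, index.qidx[entry], index.strand[entry], index.qpos[entry]


_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


def _parse_cigar(cigar: str):
    return [(int(n), op) for n, op in _CIGAR_RE.findall(cigar)]


def _cigar_identity(cigar: str) -> tuple[float, int]:
    """(identity, alignment columns) from an extended CIGAR."""
    cols = match = 0
    for n, op in _parse_cigar(cigar):
        cols += n
        if op == "=":
            match += n
    return (match / cols if cols else 0.0), cols


def _trim_cigar(cigar: str):
    """Strip leading/trailing non-match runs (local-alignment end polish).

    Returns (runs, q_lead, q_trail, t_lead, t_trail) where the q/t values are
    query/target bases removed from each end.
    """
    runs = list(_parse_cigar(cigar))
    ql = qt = tl = tt = 0
    while runs and runs[0][1] != "=":
        n, op = runs.pop(0)
        if op in ("X", "I"):
            ql += n
        if op in ("X", "D"):
            tl += n
    while runs and runs[-1][1] != "=":
        n, op = runs.pop()
        if op in ("X", "I"):
            qt += n
        if op in ("X", "D"):
            tt += n
    return runs, ql, qt, tl, tt


def max_clean_segment(cigar: str, max_gap: int = 50) -> int:
    """Longest query stretch aligned without any indel run > ``max_gap``.

    This operationalizes an "uninterrupted" alignment: a single chained
    alignment broken wherever an insertion or deletion run exceeds the gap
    allowance; the returned value counts query bases in the best piece.
    """
    best = cur = 0
    for n, op in _parse_cigar(cigar):
        if op in ("I", "D") and n > max_gap:
            best = max(best, cur)
            cur = 0
            continue
        if op in ("=", "X", "I"):
            cur += n
    return max(best, cur)


def _verify_cluster(qseq, read_seq, diag, q_lo, q_hi, pad=80, task="path"):
    """Banded verification of one seed chain with edlib (infix mode).

    ``task='path'`` reconstructs the CIGAR and polishes the ends;
    ``task='locations'`` skips path reconstruction (several-fold faster)
    and estimates identity from the edit distance over the aligned span.
    """
    qlen, rlen = len(qseq), len(read_seq)
    qa = max(0, -diag - pad)
    qb = min(qlen, rlen - diag + pad)
    if qb - qa < 20:
        return None
    wstart = max(0, diag + qa - pad)
    wend = min(rlen, diag + qb + pad)
    res = edlib.align(qseq[qa:qb], read_seq[wstart:wend], mode="HW", task=task)
    if res["editDistance"] < 0 or not res["locations"]:
        return None
    loc = res["locations"][0]
    t0 = loc[0] if loc[0] is not None else 0
    t1 = loc[1]
    if task != "path":
        qspan = qb - qa
        tspan = t1 + 1 - t0
        cols = max(qspan, tspan)
        ident = max(0.0, 1.0 - res["editDistance"] / cols)
        return {
            "q_start": qa,
            "q_end": qb,
            "read_start": wstart + t0,
            "read_end": wstart + t1 + 1,
            "identity": ident,
            "aln_len": cols,
            "cigar": "",
        }
    runs, ql, qt, tl, tt = _trim_cigar(res["cigar"])
    if not runs:
        return None
    cigar = "".join(f"{n}{op}" for n, op in runs)
    ident, cols = _cigar_identity(cigar)
    return {
        "q_start": qa + ql,
        "q_end": qb - qt,
        "read_start": wstart + t0 + tl,
        "read_end": wstart + t1 + 1 - tt,
        "identity": ident,
        "aln_len": cols,
        "cigar": cigar,
    }


def seed_and_align(
    queries: list[tuple[str, str]],
    reads: list[SequenceRecord],
    k: int = DEFAULT_K,
    stride: int = 5,
    band: int = 120,
    min_seeds: int = 3,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_len: int = 100,
    keep_cigar: bool = False,
    fast_accept_span: int | None = None,
) -> list[AlignmentHit]:
    """Map every query onto every read; deterministic given inputs.

    With ``keep_cigar`` the full alignment path is reconstructed and end
    mismatches are trimmed; otherwise a faster distance-only verification
    is used (intervals exact to a few bases, identity estimated from the
    edit distance).  ``fast_accept_span`` short-circuits verification for
    clusters whose exact-seed footprint already covers that many query
    bases at high density — such a cluster can only arise from a long
    high-identity alignment — with identity estimated from the seed rate.
    """
    task = "path" if keep_cigar else "locations"
    index = KmerIndex(queries, k=k)
    hits: list[AlignmentHit] = []
    for read in reads:
        rc = _codes(read.seq)
        m = _match_arrays(index, rc, stride)
        if m is None:
            continue
        read_pos, qidx, strand, qpos = m
        diag = read_pos.astype(np.int64) - qpos
        key = qidx.astype(np.int64) * 2 + strand
        order = np.lexsort((diag, key))
        key, diag = key[order], diag[order]
        read_pos, qpos = read_pos[order], qpos[order]
        # split into clusters where query/strand changes or diagonal jumps
        brk = np.nonzero((np.diff(key) != 0) | (np.diff(diag) > band))[0] + 1
        bounds = np.concatenate(([0], brk, [key.size]))
        for b0, b1 in zip(bounds[:-1], bounds[1:]):
            if b1 - b0 < min_seeds:
                continue
            qi = int(key[b0] // 2)
            st = int(key[b0] % 2)
            qseq = index.seqs[qi] if st == 0 else revcomp(index.seqs[qi])
            d = int(diag[b0 + (b1 - b0) // 2])  # diagonals sorted: median
            # overlap upper bound: skip clusters that cannot reach min_len
            overlap_bound = min(len(qseq), len(read.seq) - d) - max(0, -d) + 160
            if overlap_bound < min_len:
                continue
            q_lo = int(qpos[b0:b1].min())
            q_hi = int(qpos[b0:b1].max()) + k
            res = None
            if fast_accept_span is not None:
                span = q_hi - q_lo
                density = (b1 - b0) * stride / max(span, 1)
                if span >= fast_accept_span and density >= 0.3:
                    # seed rate r ~ (identity)^k for random errors
                    ident_est = min(1.0, min(density, 1.0) ** (1.0 / k))
                    res = {
                        "q_start": q_lo, "q_end": q_hi,
                        "read_start": d + q_lo, "read_end": d + q_hi,
                        "identity": ident_est, "aln_len": span, "cigar": "",
                    }
            if res is None:
                res = _verify_cluster(qseq, read.seq, d, q_lo, q_hi, task=task)
            if res is None:
                continue
            if res["identity"] < min_identity or res["aln_len"] < min_len:
                continue
            qlen = len(index.seqs[qi])
            if st == 1:  # convert to original query coordinates
                q_start = qlen - res["q_end"]
                q_end = qlen - res["q_start"]
            else:
                q_start, q_end = res["q_start"], res["q_end"]
            hits.append(
                AlignmentHit(
                    read_id=read.id,
                    query_id=index.ids[qi],
                    read_start=res["read_start"],
                    read_end=res["read_end"],
                    q_start=q_start,
                    q_end=q_end,
                    strand="+" if st == 0 else "-",
                    identity=res["identity"],
                    aln_len=res["aln_len"],
                    cigar=res["cigar"] if keep_cigar else "",
                )
            )
    return _dedup_hits(hits)


def _dedup_hits(hits: list[AlignmentHit]) -> list[AlignmentHit]:
    """Collapse near-duplicate hits (same read/query/strand, overlapping span)."""
    hits.sort(key=lambda h: (h.read_id, h.query_id, h.strand, h.read_start))
    out: list[AlignmentHit] = []
    for h in hits:
        if out:
            p = out[-1]
            if (
                p.read_id == h.read_id
                and p.query_id == h.query_id
                and p.strand == h.strand
                and h.read_start < p.read_end - 50
            ):
                if h.aln_len > p.aln_len:
                    out[-1] = h
                continue
        out.append(h)
    return out


def align_local(
    query: str,
    target: str,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_len: int = 30,
    k: int = DEFAULT_K,
) -> list[AlignmentHit]:
    """Maximal gap-tolerant local alignments of ``query`` on ``target``,
    both strands.  Zero hits is a valid result.
    """
    if not query or not target:
        raise ValueError("sequences must be non-empty")
    return seed_and_align(
        [("query", query)],
        [SequenceRecord("target", target)],
        k=min(k, max(8, len(query) // 2)),
        stride=1,
        min_seeds=1,
        min_identity=min_identity,
        min_len=min_len,
        keep_cigar=True,
    )


# ---------------------------------------------------------------------------
# Pipeline operations
# ---------------------------------------------------------------------------

def map_tiling_to_reads(
    fragments: list[TilingFragment],
    reads: list[SequenceRecord],
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_len: int = 100,
    stride: int = 5,
    keep_cigar: bool = False,
) -> list[AlignmentHit]:
    """Align tiling fragments to long reads; hits are annotated with the
    owning unit and fragment index and sorted by (read, read offset)."""
    frag_by_id = {f.id: f for f in fragments}
    hits = seed_and_align(
        [(f.id, f.seq) for f in fragments],
        reads,
        stride=stride,
        min_identity=min_identity,
        min_len=min_len,
        keep_cigar=keep_cigar,
    )
    for h in hits:
        f = frag_by_id[h.query_id]
        h.unit = f.unit
        h.frag_index = f.index
    hits.sort(key=lambda h: (h.read_id, h.read_start))
    return hits


def hits_to_frame(hits: list[AlignmentHit]) -> pd.DataFrame:
    """Tab-table form of a hit list (0-based half-open intervals)."""
    return pd.DataFrame(
        [
            (h.read_id, h.query_id, h.unit, h.frag_index, h.read_start, h.read_end,
             h.q_start, h.q_end, h.strand, round(h.identity, 4), h.aln_len)
            for h in hits
        ],
        columns=["read_id", "fragment_id", "unit", "frag_index", "read_start",
                 "read_end", "frag_start", "frag_end", "strand", "identity", "aln_len"],
    )


def select_informative_reads(
    hits: list[AlignmentHit] | pd.DataFrame, min_distinct_fragments: int = 10
) -> set[str]:
    """Reads carrying at least ``min_distinct_fragments`` distinct tiling
    fragments (defaults to 10; 12 was used for the read-poorer species)."""
    if min_distinct_fragments < 1:
        raise ValueError("min_distinct_fragments must be >= 1")
    if isinstance(hits, pd.DataFrame):
        counts = hits.groupby("read_id")["fragment_id"].nunique()
    else:
        frame = pd.DataFrame(
            [(h.read_id, h.query_id) for h in hits], columns=["read_id", "fragment_id"]
        )
        if frame.empty:
            return set()
        counts = frame.groupby("read_id")["fragment_id"].nunique()
    return set(counts.index[counts >= min_distinct_fragments])


def filter_plastid(
    pairs: list[tuple[SequenceRecord, SequenceRecord]],
    decoy: SequenceRecord,
    length_fraction: float = 0.9,
    similarity_fraction: float = 0.9,
) -> list[tuple[SequenceRecord, SequenceRecord]]:
    """Drop read pairs where either mate maps to the plastid decoy over at
    least ``length_fraction`` of its length at ``similarity_fraction``
    identity; the unmapped pairs are returned for mitochondrial analysis."""
    mates: list[tuple[str, str]] = []
    for i, (r1, r2) in enumerate(pairs):
        mates.append((f"p{i}/1", r1.seq))
        mates.append((f"p{i}/2", r2.seq))
    hits = seed_and_align(
        mates,
        [decoy],
        stride=2,
        min_seeds=2,
        min_identity=similarity_fraction,
        min_len=20,
    )
    bad = set()
    for h in hits:
        pair_idx = int(h.query_id[1:].split("/")[0])
        mate_len = len(pairs[pair_idx][0 if h.query_id.endswith("/1") else 1].seq)
        if (h.q_end - h.q_start) >= length_fraction * mate_len:
            bad.add(pair_idx)
    return [p for i, p in enumerate(pairs) if i not in bad]


def unit_path_from_hits(
    read_hits: list[AlignmentHit],
    unit_lengths: dict[str, int],
    window: int = DEFAULT_WINDOW,
    step: int = DEFAULT_STEP,
    min_run: int = 2,
) -> UnitPath:
    """Collapse a read's ordered fragment hits into an oriented unit path.

    Runs of consecutive same-unit fragments with monotone indices become one
    oriented unit ('+' for increasing indices, '-' for decreasing).  Runs
    shorter than ``min_run`` fragments are discarded unless the unit is too
    short to yield more than one fragment.  Two units claiming more than
    half of the same read span mark the read ambiguous.
    """
    if not read_hits:
        return UnitPath("", [])
    hits = sorted(read_hits, key=lambda h: (h.read_start, -h.aln_len))
    read_id = hits[0].read_id
    runs: list[list[AlignmentHit]] = []
    cur: list[AlignmentHit] = [hits[0]]
    for h in hits[1:]:
        p = cur[-1]
        same = h.unit == p.unit and h.strand == p.strand
        if same:
            delta = h.frag_index - p.frag_index
            ok = (0 < delta <= 3) if h.strand == "+" else (-3 <= delta < 0)
            # tail fragments repeat the terminal window; allow a stall
            ok = ok or delta == 0
            if ok and 0 < h.read_start - p.read_start <= window + 2 * step:
                cur.append(h)
                continue
        runs.append(cur)
        cur = [h]
    runs.append(cur)

    kept: list[list[AlignmentHit]] = []
    for run in runs:
        unit = run[0].unit
        short_unit = unit_lengths.get(unit, window + step + 1) <= window + step
        if len(run) < min_run and not short_unit:
            continue
        # a discarded stray may have split one true run in two: rejoin
        if kept:
            p, h = kept[-1][-1], run[0]
            delta = h.frag_index - p.frag_index
            ok = (0 <= delta <= 3) if h.strand == "+" else (-3 <= delta <= 0)
            if (
                h.unit == p.unit and h.strand == p.strand and ok
                and 0 < h.read_start - p.read_start <= window + 2 * step
            ):
                kept[-1].extend(run)
                continue
        kept.append(list(run))

    entries: list[tuple[OrientedUnit, int, int, int]] = []  # ou, offset, span_end
    for run in kept:
        start = run[0].read_start
        end = max(h.read_end for h in run)
        entries.append((OrientedUnit(run[0].unit, run[0].strand), start, end, len(run)))

    # conflicting overlap check: two accepted runs covering >50% of one span
    ambiguous = False
    for i in range(1, len(entries)):
        a, b = entries[i - 1], entries[i]
        overlap = min(a[2], b[2]) - max(a[1], b[1])
        span = min(a[2] - a[1], b[2] - b[1])
        if span > 0 and overlap > 0.5 * span and a[0].unit != b[0].unit:
            ambiguous = True

    distinct = len({(h.unit, h.frag_index) for h in hits})
    return UnitPath(
        read_id,
        [(ou, off) for ou, off, _end, _n in entries],
        n_distinct_fragments=distinct,
        ambiguous=ambiguous,
    )


def unit_paths(
    hits: list[AlignmentHit],
    unit_lengths: dict[str, int],
    read_ids: set[str] | None = None,
    window: int = DEFAULT_WINDOW,
    step: int = DEFAULT_STEP,
    min_run: int = 2,
) -> list[UnitPath]:
    """Unit paths for every (optionally pre-selected) read with hits;
    ambiguous reads are excluded from the returned path set."""
    by_read: dict[str, list[AlignmentHit]] = {}
    for h in hits:
        if read_ids is not None and h.read_id not in read_ids:
            continue
        by_read.setdefault(h.read_id, []).append(h)
    paths = []
    for rid in sorted(by_read):
        path = unit_path_from_hits(by_read[rid], unit_lengths, window, step, min_run)
        if not path.ambiguous and path.entries:
            paths.append(path)
    return paths


def load_blast_hits(path, fragments: list[TilingFragment]) -> list[AlignmentHit]:
    """Adapter: read an outfmt-6-style tab file (qseqid sseqid pident length
    mismatch gapopen qstart qend sstart send evalue bitscore) produced by an
    external mapper, with tiling fragments as queries and reads as subjects.
    Coordinates are converted to 0-based half-open."""
    frag_by_id = {f.id: f for f in fragments}
    cols = ["qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
            "qstart", "qend", "sstart", "send", "evalue", "bitscore"]
    tab = pd.read_csv(path, sep="\t", names=cols, comment="#")
    hits = []
    for row in tab.itertuples(index=False):
        minus = row.sstart > row.send
        s_lo, s_hi = sorted((int(row.sstart), int(row.send)))
        f = frag_by_id.get(row.qseqid)
        hits.append(
            AlignmentHit(
                read_id=str(row.sseqid),
                query_id=str(row.qseqid),
                read_start=s_lo - 1,
                read_end=s_hi,
                q_start=int(row.qstart) - 1,
                q_end=int(row.qend),
                strand="-" if minus else "+",
                identity=float(row.pident) / 100.0,
                aln_len=int(row.length),
                unit=f.unit if f else "",
                frag_index=f.index if f else -1,
            )
        )
    hits.sort(key=lambda h: (h.read_id, h.read_start))
    return hits
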