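"""Junction re-assembly and short-read majority polishing.

Junction sequences are recovered by draft-anchored consensus: reads whose
unit path contains a junction are trimmed to 4-6 kb around it, aligned to a
draft built from the two unit flanks, and voted column by column (majority
base; ties keep the draft — stability over novelty).  The same pileup
machinery polishes contigs with accurate short reads, including simple
indel correction when more than half of the covering reads agree.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import edlib

from .mapping import UnitPath, _parse_cigar, _trim_cigar, seed_and_align
from .model import OrientedUnit, SequenceRecord, canonical_block, revcomp

__all__ = [
    "JunctionWindowReads",
    "trim_junction_reads",
    "consensus_from_reads",
    "polish_with_short_reads",
]


@dataclass
class JunctionWindowReads:
    """Trimmed read segments centered on one junction."""

    junction_id: str
    segments: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.segments)


def trim_junction_reads(
    reads: list[SequenceRecord],
    paths: list[UnitPath],
    junction: tuple[OrientedUnit, OrientedUnit],
    flank: int = 3000,
    min_total: int = 1000,
) -> JunctionWindowReads:
    """Extract up to ``flank`` bp on each side of a junction from every read
    whose unit path contains it; segments shorter than ``min_total`` after
    clipping at read ends are discarded.  Segments observed on the reverse
    strand are flipped so every segment presents the junction in canonical
    orientation.
    """
    canon = canonical_block(tuple(junction))
    reflected = (canon[1].reverse(), canon[0].reverse())
    read_by_id = {r.id: r for r in reads}
    out = JunctionWindowReads(f"{canon[0]}|{canon[1]}")
    for path in paths:
        read = read_by_id.get(path.read_id)
        if read is None:
            continue
        units = path.units
        for i in range(len(units) - 1):
            pair = (units[i], units[i + 1])
            if pair == canon:
                flip = False
            elif pair == reflected:
                flip = True
            else:
                continue
            # junction offset: where the right-hand unit's run begins
            offset = path.entries[i + 1][1]
            lo = max(0, offset - flank)
            hi = min(len(read.seq), offset + flank)
            segment = read.seq[lo:hi]
            if len(segment) < min_total:
                continue
            out.segments.append(revcomp(segment) if flip else segment)
    return out


def _pileup(draft: str, alignments: list[tuple[str, int, str]]):
    """Column votes over a draft from (query_seq, draft_start, cigar) tuples.

    Returns (votes, inserts, coverage): per-column base/'-' counters, the
    insertion-string counters keyed by the column they precede, and the
    per-column spanning-read depth.
    """
    n = len(draft)
    votes = [Counter() for _ in range(n)]
    inserts: dict[int, Counter] = {}
    coverage = [0] * n
    for qseq, t0, cigar in alignments:
        q = 0
        t = t0
        for count, op in _parse_cigar(cigar):
            if op in ("=", "X"):
                for _ in range(count):
                    votes[t][qseq[q]] += 1
                    coverage[t] += 1
                    q += 1
                    t += 1
            elif op == "D":
                for _ in range(count):
                    votes[t]["-"] += 1
                    coverage[t] += 1
                    t += 1
            elif op == "I":
                inserts.setdefault(t, Counter())[qseq[q : q + count]] += 1
                q += count
    return votes, inserts, coverage


def _apply_majority(
    draft: str,
    votes,
    inserts,
    coverage,
    min_depth: int = 2,
):
    """Majority call per column; ties and thin columns keep the draft."""
    out = []
    changes = []
    for i, base in enumerate(draft):
        ins = inserts.get(i)
        if ins:
            n_ins = sum(ins.values())
            if coverage[i] > 0 and n_ins * 2 > coverage[i]:
                text, _ = ins.most_common(1)[0]
                out.append(text)
                changes.append((i, "", text, coverage[i], n_ins))
        if coverage[i] < min_depth or not votes[i]:
            out.append(base)
            continue
        n_win = max(votes[i].values())
        top = sorted(b for b, c in votes[i].items() if c == n_win)
        if base in top or len(top) > 1:
            out.append(base)  # draft wins or tie: keep draft
            continue
        winner = top[0]
        if winner == "-":
            changes.append((i, base, "", coverage[i], n_win))
        else:
            out.append(winner)
            changes.append((i, base, winner, coverage[i], n_win))
    return "".join(out), changes


def _align_to_draft(segment: str, draft: str):
    """Best-strand infix alignment of a segment against a draft."""
    best = None
    for seq in (segment, revcomp(segment)):
        res = edlib.align(seq, draft, mode="HW", task="path")
        if res["editDistance"] >= 0 and (best is None or res["editDistance"] < best[1]["editDistance"]):
            best = (seq, res)
    if best is None:
        return None
    seq, res = best
    runs, ql, qt, tl, tt = _trim_cigar(res["cigar"])
    if not runs:
        return None
    t0 = res["locations"][0][0] + tl
    cigar = "".join(f"{n}{op}" for n, op in runs)
    return seq[ql : len(seq) - qt if qt else len(seq)], t0, cigar


def consensus_from_reads(
    segments: list[str], draft: str, min_depth: int = 2
) -> tuple[str, bool]:
    """Draft-anchored consensus: align each segment to the draft and take
    the per-column majority (ties and columns under ``min_depth`` keep the
    draft).  Returns (consensus, low_confidence_flag); with no segments the
    draft is returned flagged.
    """
    if not segments:
        return draft, True
    alignments = []
    for seg in segments:
        aln = _align_to_draft(seg, draft)
        if aln is not None:
            alignments.append(aln)
    if not alignments:
        return draft, True
    votes, inserts, coverage = _pileup(draft, alignments)
    consensus, _changes = _apply_majority(draft, votes, inserts, coverage, min_depth)
    low_confidence = len(alignments) < 3
    return consensus, low_confidence


def polish_with_short_reads(
    contig: str,
    short_reads: list[SequenceRecord],
    min_depth: int = 3,
    min_identity: float = 0.8,
) -> tuple[str, list[tuple], bool]:
    """Majority-vote polishing of a contig with accurate short reads.

    Reads are located on the contig with the seeded aligner; per-column
    majority substitutions plus indels supported by more than half of the
    covering reads are applied.  Returns (polished, change_log, warning):
    the warning flag is set when more than 10% of columns have depth below
    ``min_depth`` (those columns are left untouched).
    """
    target = SequenceRecord("contig", contig)
    hits = seed_and_align(
        [(r.id, r.seq) for r in short_reads],
        [target],
        stride=3,
        min_seeds=2,
        min_identity=min_identity,
        min_len=30,
        keep_cigar=True,
    )
    read_by_id = {r.id: r.seq for r in short_reads}
    alignments = []
    for h in hits:
        qseq = read_by_id[h.query_id]
        if h.strand == "-":
            qseq = revcomp(qseq)
            q0 = len(qseq) - h.q_end
        else:
            q0 = h.q_start
        alignments.append((qseq[q0:], h.read_start, h.cigar))
    votes, inserts, coverage = _pileup(contig, alignments)
    thin = sum(1 for c in coverage if c < min_depth)
    warning = thin > 0.1 * len(contig)
    polished, changes = _apply_majority(contig, votes, inserts, coverage, min_depth)
    return polished, changes, warning
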