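"""Detection of near-identical repeats within and between sequences.

Repeats are the substrate of mitochondrial genome rearrangement, and only
nearly identical copies recombine productively.  The scan therefore uses
exact 50-mer seeds on both strands with ungapped X-drop extension under a
strongly mismatch-averse score (+1 match, -20 mismatch): a copy diverged by
a few percent cannot sustain a scoring segment, which is precisely the
intended selectivity.  Size classes follow the field's convention: large
(>= 1 kb, the recombining hinges), intermediate (100-999 bp, rarely
recombining), short (< 100 bp).
"""

from __future__ import annotations

from dataclasses import dataclass

from .model import SequenceRecord, revcomp

__all__ = ["RepeatMatch", "find_repeats", "classify_repeats"]

WORD_SIZE = 50
REWARD = 1
PENALTY = -20
MIN_SCORE = 50
XDROP = 40


@dataclass
class RepeatMatch:
    """An ungapped repeat match between two sequence intervals."""

    id_a: str
    start_a: int
    end_a: int
    id_b: str
    start_b: int
    end_b: int
    orientation: str  # direct | inverted
    length: int
    identity: float
    score: int
    size_class: str = ""
    role: str = ""

    def key(self):
        return (self.id_a, self.start_a, self.end_a, self.id_b, self.start_b,
                self.end_b, self.orientation)


def _size_class(length: int) -> str:
    if length >= 1000:
        return "large"
    if length >= 100:
        return "intermediate"
    return "short"


def _extend_ungapped(sa: str, sb: str, pa: int, pb: int, word: int,
                     reward: int, penalty: int, xdrop: int):
    """X-drop extension of an exact seed on one diagonal; returns the
    maximal-score segment (start_a, end_a, start_b, matches, score)."""
    # right extension
    score = word * reward
    best_score = score
    best_right = pa + word
    i, j = pa + word, pb + word
    while i < len(sa) and j < len(sb):
        score += reward if sa[i] == sb[j] else penalty
        if score > best_score:
            best_score = score
            best_right = i + 1
        if score < best_score - xdrop:
            break
        i += 1
        j += 1
    # left extension
    score = best_score
    best_left = pa
    i, j = pa - 1, pb - 1
    while i >= 0 and j >= 0:
        score += reward if sa[i] == sb[j] else penalty
        if score > best_score:
            best_score = score
            best_left = i
        if score < best_score - xdrop:
            break
        i -= 1
        j -= 1
    start_a = best_left
    end_a = best_right
    start_b = pb - (pa - start_a)
    length = end_a - start_a
    seg_a = sa[start_a:end_a]
    seg_b = sb[start_b : start_b + length]
    matches = sum(1 for x, y in zip(seg_a, seg_b) if x == y)
    return start_a, end_a, start_b, matches, best_score


def _seed_positions(seq: str, word: int) -> dict[str, list[int]]:
    table: dict[str, list[int]] = {}
    for i in range(len(seq) - word + 1):
        table.setdefault(seq[i : i + word], []).append(i)
    return table


def _scan_pair(id_a, sa, id_b, sb, orientation, word, reward, penalty,
               min_score, xdrop, self_pair):
    """All maximal ungapped segments between sa and sb (sb already oriented).
    Seeds sharing a diagonal are merged: each (diagonal, segment) reported once."""
    table = _seed_positions(sa, word)
    done: dict[int, list[tuple[int, int]]] = {}  # diagonal -> [(start_a, end_a)]
    out = []
    blen = len(sb)
    for j in range(blen - word + 1):
        seed = sb[j : j + word]
        for i in table.get(seed, ()):
            if self_pair and orientation == "direct" and i == j:
                continue  # trivial self-hit
            diag = i - j
            covered = False
            for s, e in done.get(diag, ()):
                if s <= i and i + word <= e:
                    covered = True
                    break
            if covered:
                continue
            start_a, end_a, start_b, matches, score = _extend_ungapped(
                sa, sb, i, j, word, reward, penalty, xdrop
            )
            done.setdefault(diag, []).append((start_a, end_a))
            if score < min_score:
                continue
            length = end_a - start_a
            end_b = start_b + length
            if orientation == "inverted":
                # map sb interval back to original B coordinates
                start_b, end_b = blen - end_b, blen - start_b
            if self_pair:
                if orientation == "direct" and start_a >= start_b:
                    continue  # keep one of the mirrored pair
                if orientation == "inverted" and start_a > start_b:
                    continue
                if orientation == "inverted" and start_a == start_b and end_a == end_b:
                    # a palindrome matches itself; keep it once
                    pass
            out.append(
                RepeatMatch(
                    id_a, start_a, end_a, id_b, start_b, end_b,
                    orientation, length, matches / length, score,
                    size_class=_size_class(length),
                )
            )
    return out


def find_repeats(
    sequences: list[SequenceRecord] | list[tuple[str, str]],
    word: int = WORD_SIZE,
    reward: int = REWARD,
    penalty: int = PENALTY,
    min_score: int = MIN_SCORE,
    xdrop: int = XDROP,
) -> list[RepeatMatch]:
    """Nearly identical repeats across a set of sequences, both strands.

    Canonical ordering: sequence A precedes B (by input order), and within a
    self-comparison the leftmost interval is A.  Overlapping extensions from
    seeds on the same diagonal are merged (leftmost-longest survives).
    """
    seqs = [
        (s.id, s.seq) if isinstance(s, SequenceRecord) else (s[0], s[1])
        for s in sequences
    ]
    if not seqs:
        raise ValueError("no sequences given")
    matches: dict = {}
    for ai in range(len(seqs)):
        for bi in range(ai, len(seqs)):
            id_a, sa = seqs[ai]
            id_b, sb = seqs[bi]
            for orientation, oriented_b in (("direct", sb), ("inverted", revcomp(sb))):
                for m in _scan_pair(
                    id_a, sa, id_b, oriented_b, orientation, word, reward,
                    penalty, min_score, xdrop, self_pair=(ai == bi)
                ):
                    prev = matches.get(m.key())
                    if prev is None or m.score > prev.score:
                        matches[m.key()] = m
    out = sorted(matches.values(), key=lambda m: m.key())
    return _merge_contained(out)


def _merge_contained(matches: list[RepeatMatch]) -> list[RepeatMatch]:
    """Drop matches wholly contained in a longer match on the same diagonal
    relation (leftmost-longest tie-break)."""
    kept: list[RepeatMatch] = []
    for m in sorted(matches, key=lambda x: (-x.length, x.key())):
        contained = False
        for k in kept:
            if (
                m.id_a == k.id_a and m.id_b == k.id_b and m.orientation == k.orientation
                and k.start_a <= m.start_a and m.end_a <= k.end_a
                and k.start_b <= m.start_b and m.end_b <= k.end_b
            ):
                contained = True
                break
        if not contained:
            kept.append(m)
    kept.sort(key=lambda m: m.key())
    return kept


def classify_repeats(
    matches: list[RepeatMatch],
    copy_numbers: dict[str, int],
    unit_lengths: dict[str, int] | None = None,
) -> list[RepeatMatch]:
    """Attach size classes and hinge/dispersed roles.

    A match covering at least 90% of a 2x unit is a hinge (the repeat IS the
    unit); everything else is a dispersed repeat.
    """
    for m in matches:
        m.size_class = _size_class(m.length)
        role = "dispersed"
        if unit_lengths:
            for sid, lo, hi in ((m.id_a, m.start_a, m.end_a), (m.id_b, m.start_b, m.end_b)):
                L = unit_lengths.get(sid)
                if L and copy_numbers.get(sid, 1) >= 2 and (hi - lo) >= 0.9 * L:
                    role = "hinge"
        m.role = role
    return matches
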