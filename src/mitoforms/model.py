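"""Core domain types for mitochondrial structural-isoform analysis.

Plant mitochondrial genomes are best described not as a single circle but as
a dynamic mixture of arrangements ("isoforms") of a small set of *primary
structural units* — polished contigs that tile the non-redundant genome.
Units present at 2x stoichiometry (large repeats) act as recombination
hinges between isoforms.  This module holds the shared vocabulary: sequence
records, oriented units, genome fixtures (built-in unit-length tables for
*Lactuca sativa* and *L. saligna*), isoform models, and small physical
conversion helpers.

Coordinates are 0-based, half-open throughout the package; exported GFF3 is
1-based inclusive (stated where written).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

__all__ = [
    "SequenceRecord",
    "PrimaryUnit",
    "OrientedUnit",
    "GenomeFixture",
    "IsoformModel",
    "ContourMeasure",
    "KB_PER_UM",
    "load_fixture",
    "isoform_length",
    "um_to_kb",
    "kb_to_um",
    "canonicalize_isoform",
    "revcomp",
    "parse_arrangement",
    "arrangement_str",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: DNA contour-length conversion used for fluorescence-microscopy contour
#: measurements (10 um of stained fiber corresponds to ~30 kb).
KB_PER_UM = 3.0


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (ACGTN, case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SequenceRecord:
    """A named DNA sequence (read or contig)."""

    id: str
    seq: str

    def __post_init__(self):
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if len(self.seq) < 1:
            raise ValueError(f"sequence {self.id!r} is empty")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class PrimaryUnit:
    """A primary structural unit: a polished contig with a copy number.

    Units are named with single/double letter codes (K..Z by convention).
    ``copy_number >= 2`` marks the unit as a large repeat (a hinge).
    """

    name: str
    seq: str
    copy_number: int = 1

    def __post_init__(self):
        if not (1 <= len(self.name) <= 2) or not self.name.isalpha():
            raise ValueError(f"unit name {self.name!r} not a 1-2 letter code")
        if self.copy_number < 1:
            raise ValueError(f"unit {self.name}: copy_number must be >= 1")

    @property
    def is_repeat(self) -> bool:
        return self.copy_number >= 2

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True, order=True)
class OrientedUnit:
    """A unit name with a strand, e.g. ``R+`` or ``T-``."""

    unit: str
    strand: str = "+"

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def reverse(self) -> "OrientedUnit":
        return OrientedUnit(self.unit, "-" if self.strand == "+" else "+")

    def __str__(self) -> str:
        return f"{self.unit}{self.strand}"

    @classmethod
    def parse(cls, token: str) -> "OrientedUnit":
        token = token.strip()
        if token[-1] in "+-":
            return cls(token[:-1], token[-1])
        return cls(token, "+")


def parse_arrangement(text: str) -> tuple[OrientedUnit, ...]:
    """Parse ``"M+,N+,K-"`` (or ``"M-N-K"`` with bare names) into oriented units."""
    sep = "," if "," in text else "-" if text[-1] not in "+-" and "-" in text else ","
    return tuple(OrientedUnit.parse(t) for t in text.split(sep) if t.strip())


def arrangement_str(arrangement) -> str:
    return ",".join(str(u) for u in arrangement)


@dataclass(frozen=True)
class GenomeFixture:
    """A species' unit-length table: ordered (name, length) rows plus repeat flags."""

    species: str
    units: tuple[tuple[str, int], ...]
    repeats: frozenset[str]

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self.units)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(n for n, _ in self.units)

    def total_length(self) -> int:
        return sum(length for _, length in self.units)

    def copy_numbers(self) -> dict[str, int]:
        return {n: (2 if n in self.repeats else 1) for n, _ in self.units}


# Unit lengths (bp) of the L. sativa and L. saligna mitochondrial genomes.
# Repeat flags: coverage analysis showed M, R and T at 2x in both species;
# in L. sativa the short unit N travels with M (the MN repeat) and is also 2x.
_SATIVA_UNITS = (
    ("K", 78272),
    ("L", 44054),
    ("W", 53983),
    ("U", 38613),
    ("M", 30580),
    ("P", 20468),
    ("Z", 19295),
    ("Q", 11283),
    ("R", 10430),
    ("N", 4116),
    ("T", 3552),
)
_SALIGNA_UNITS = (
    ("K", 79109),
    ("L", 43583),
    ("UV", 90023),
    ("M", 30534),
    ("P", 20420),
    ("Z", 19278),
    ("Q", 11083),
    ("R", 10433),
    ("S", 14743),
    ("T", 4048),
)

_FIXTURES = {
    "sativa": GenomeFixture("sativa", _SATIVA_UNITS, frozenset({"M", "N", "R", "T"})),
    "saligna": GenomeFixture("saligna", _SALIGNA_UNITS, frozenset({"M", "R", "T"})),
}

# For simulation, the long saligna UV unit may be split into U and V parts
# (U corresponds to sativa's U; V to the shared part of sativa's W), which is
# how the repeat-flanking blocks are named.  Lengths are a constructed split.
_SALIGNA_SPLIT_UNITS = tuple(
    row for name_len in _SALIGNA_UNITS
    for row in ([name_len] if name_len[0] != "UV" else [("U", 38613), ("V", 51410)])
)
_FIXTURES["saligna-split"] = GenomeFixture(
    "saligna-split", _SALIGNA_SPLIT_UNITS, frozenset({"M", "R", "T"})
)


def load_fixture(species: str) -> GenomeFixture:
    """Return the built-in unit-length table for ``sativa`` or ``saligna``.

    ``saligna-split`` is a simulation variant with UV split into U and V.
    """
    try:
        return _FIXTURES[species]
    except KeyError:
        valid = ", ".join(sorted(_FIXTURES))
        raise ValueError(f"unknown species {species!r}; valid labels: {valid}") from None


def isoform_length(fixture: GenomeFixture, copy_numbers: dict[str, int]) -> int:
    """Genome length of an isoform: sum of unit length x copy number."""
    lengths = fixture.lengths
    unknown = set(copy_numbers) - set(lengths)
    if unknown:
        raise ValueError(f"units not in {fixture.species} fixture: {sorted(unknown)}")
    return sum(lengths[u] * n for u, n in copy_numbers.items())


def um_to_kb(length_um: float) -> float:
    """Convert a DNA contour length in micrometres to kilobases (3.0 kb/um)."""
    if length_um < 0:
        raise ValueError("length must be >= 0")
    return KB_PER_UM * length_um


def kb_to_um(length_kb: float) -> float:
    """Inverse of :func:`um_to_kb`."""
    if length_kb < 0:
        raise ValueError("length must be >= 0")
    return length_kb / KB_PER_UM


@dataclass(frozen=True)
class ContourMeasure:
    """A molecule contour measured in micrometres with its kb equivalent."""

    length_um: float
    length_kb: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.length_kb is None:
            object.__setattr__(self, "length_kb", um_to_kb(self.length_um))


@dataclass(frozen=True)
class IsoformModel:
    """One full arrangement of oriented primary units (circular or linear)."""

    arrangement: tuple[OrientedUnit, ...]
    topology: str = "circular"
    total_length: int = 0
    frequency: float = 0.0
    label: str = ""

    def __post_init__(self):
        if self.topology not in ("circular", "linear"):
            raise ValueError(f"topology must be circular|linear, got {self.topology!r}")
        if not self.arrangement:
            raise ValueError("arrangement must be non-empty")
        if not 0.0 <= self.frequency <= 1.0:
            raise ValueError("frequency must be in [0, 1]")

    def multiplicities(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for ou in self.arrangement:
            counts[ou.unit] = counts.get(ou.unit, 0) + 1
        return counts

    def __str__(self) -> str:
        return arrangement_str(self.arrangement)


def _reflect(arrangement: tuple[OrientedUnit, ...]) -> tuple[OrientedUnit, ...]:
    """Traversal of the same molecule on the opposite strand."""
    return tuple(ou.reverse() for ou in reversed(arrangement))


def _min_rotation(arr: tuple[OrientedUnit, ...]) -> tuple[OrientedUnit, ...]:
    # Lexicographically minimal rotation via the doubled-sequence scan.
    n = len(arr)
    doubled = arr + arr
    best = arr
    for i in range(1, n):
        cand = doubled[i : i + n]
        if cand < best:
            best = cand
    return best


def canonicalize_isoform(iso: IsoformModel) -> IsoformModel:
    """Reduce an isoform to its canonical arrangement.

    Circular isoforms are invariant under rotation and under traversal of the
    opposite strand; the canonical form is the lexicographically minimal
    arrangement over all rotations of both traversals.  Linear isoforms are
    reduced to min(self, reflected traversal).  Idempotent.
    """
    arr = iso.arrangement
    if iso.topology == "circular":
        canonical = min(_min_rotation(arr), _min_rotation(_reflect(arr)))
    else:
        canonical = min(arr, _reflect(arr))
    if canonical == arr:
        return iso
    return replace(iso, arrangement=canonical)


def canonical_block(block: tuple[OrientedUnit, ...]) -> tuple[OrientedUnit, ...]:
    """Canonical form of a linear oriented-unit tuple (min of self / reflection)."""
    return min(tuple(block), _reflect(tuple(block)))
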