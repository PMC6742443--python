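"""Synthetic recombining mitochondrial genomes with ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: a small set of primary structural units, large repeat units at 2x
stoichiometry acting as recombination hinges, a mixture of full-length
circular isoforms at configured frequencies, and read sets drawn from that
mixture — long reads (lognormal lengths, configurable sub/ins/del error),
Illumina-style mate pairs (Normal insert sizes, substitution errors only),
and Hi-C chimeras carrying the GATC-GATC ligation scar.

Every stage draws from a named substream of a single seed so that genome,
long-read, mate-pair and Hi-C sampling are independently reproducible.

Default conditions follow the real study where stated: ~250x long-read
coverage, 100 nt paired reads, mate-pair inserts of 2.5/5/10 kb.  The
long-read error rate defaults to 1% per class (real CLR error is higher;
kept low so the built-in seeded aligner is comfortably sufficient — a
documented knob, not a claim about PacBio chemistry).
"""

from __future__ import annotations

import math
import re
from collections import Counter
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .model import (
    IsoformModel,
    OrientedUnit,
    SequenceRecord,
    canonical_block,
    load_fixture,
    revcomp,
)

__all__ = [
    "SimulationConfig",
    "MatePairLibrary",
    "PlantedRepeat",
    "Molecule",
    "GroundTruth",
    "default_isoforms",
    "generate_genome",
    "sample_long_reads",
    "sample_mate_pairs",
    "sample_hic_pairs",
    "crossover_products",
    "apply_errors",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = np.zeros(256, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


def _seq_to_codes(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _codes_to_seq(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode()


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return _codes_to_seq(rng.integers(0, 4, size=n, dtype=np.uint8))


# Substream ids: all randomness flows from (seed, stream) pairs.
_STREAMS = {"genome": 11, "longreads": 23, "matepairs": 37, "hic": 53}


def _rng(seed: int, stream: str, salt: int = 0) -> np.random.Generator:
    return np.random.default_rng([seed & 0x7FFFFFFF, _STREAMS[stream], salt])


@dataclass(frozen=True)
class MatePairLibrary:
    """One paired library: Normal(insert_mean, insert_sd) outer distance."""

    insert_mean: float
    insert_sd: float
    n_pairs: int
    read_len: int = 100
    error_rate: float = 0.001  # substitutions only

    def __post_init__(self):
        if self.insert_mean <= 2 * self.read_len:
            raise ValueError("insert mean must exceed twice the read length")


@dataclass(frozen=True)
class PlantedRepeat:
    """Copy ``length`` bp from one unit location into another (a dispersed repeat)."""

    source_unit: str
    source_start: int
    dest_unit: str
    dest_start: int
    length: int
    inverted: bool = False


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic genome and its read sets."""

    units: tuple[tuple[str, int], ...]
    isoforms: tuple[IsoformModel, ...]
    seed: int = 0
    planted_repeats: tuple[PlantedRepeat, ...] = ()
    coverage: float = 250.0
    read_length_mean: float = 15000.0
    read_length_sigma: float = 0.35  # sigma of the underlying Normal
    min_read_length: int = 1000
    sub_rate: float = 0.01
    ins_rate: float = 0.01
    del_rate: float = 0.01
    mate_pair_libraries: tuple[MatePairLibrary, ...] = ()
    hic_pairs: int = 0
    hic_exponent: float = 1.5
    hic_flank: int = 96
    unit_seqs: dict = field(default_factory=dict)  # optional user-supplied sequences

    def __post_init__(self):
        total = sum(iso.frequency for iso in self.isoforms)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"isoform frequencies sum to {total}, expected 1")
        for rate in (self.sub_rate, self.ins_rate, self.del_rate):
            if not 0.0 <= rate <= 0.2:
                raise ValueError("error rates must be in [0, 0.2]")
        if self.coverage <= 0:
            raise ValueError("coverage must be > 0")
        known = {name for name, _ in self.units}
        for iso in self.isoforms:
            missing = {ou.unit for ou in iso.arrangement} - known
            if missing:
                raise ValueError(
                    f"isoform {iso.label or '?'} references unknown units {sorted(missing)}"
                )

    @classmethod
    def for_species(cls, species: str, seed: int = 0, **kwargs) -> "SimulationConfig":
        fixture = (
            load_fixture("saligna-split") if species == "saligna" else load_fixture(species)
        )
        return cls(
            units=fixture.units,
            isoforms=default_isoforms(species),
            seed=seed,
            **kwargs,
        )


@dataclass(frozen=True)
class Molecule:
    """One molecule species in the simulated pool."""

    label: str
    seq: str
    topology: str = "circular"
    frequency: float = 1.0


@dataclass
class GroundTruth:
    """Everything the pipeline is later asked to recover."""

    unit_seqs: dict[str, str]
    isoforms: tuple[IsoformModel, ...]
    molecules: tuple[Molecule, ...]
    unit_coords: dict[str, list[tuple[str, str, int, int]]]
    junctions: Counter
    copy_numbers: dict[str, int]

    def molecule(self, label: str) -> Molecule:
        for mol in self.molecules:
            if mol.label == label:
                return mol
        raise KeyError(label)


# ---------------------------------------------------------------------------
# Built-in isoform models
# ---------------------------------------------------------------------------

def _iso(label: str, text: str, freq: float, topology: str = "circular") -> IsoformModel:
    arr = tuple(OrientedUnit(t, "+") for t in text.split())
    return IsoformModel(arr, topology=topology, frequency=freq, label=label)


def default_isoforms(species: str) -> tuple[IsoformModel, ...]:
    """Constructed full-genome arrangements consistent with the published
    unit order constraints (M-N-K-M-N-W-Z; R and T each joined to both P and
    U; the saligna M-S-M, M-V and V-Z junctions).  The deposited arrangements
    are not fully stated anywhere, so these are models, not transcriptions.

    For sativa, alpha and beta differ by the exchange of P and U between the
    R and T repeats.  For saligna, a single pair of circles cannot carry the
    complementary half of the eight observed repeat-flanking blocks (the
    pairing Z-R-U / L-R-P / P-T-L / K-T-Q closes a 4-cycle L-R-P-T), so the
    default mixture is one full circle plus its two recombination products.
    """
    if species == "sativa":
        return (
            _iso("alpha", "M N K M N W Z R P T Q L R U T", 0.5),
            _iso("beta", "M N K M N W Z R U T Q L R P T", 0.5),
        )
    if species in ("saligna", "saligna-split"):
        return (
            _iso("A", "M S M V Z R P T Q K T L R U", 0.5),
            _iso("B1", "L R P T", 0.25),
            _iso("B2", "M S M V Z R U K T Q", 0.25),
        )
    raise ValueError(f"no default isoforms for species {species!r}")


# ---------------------------------------------------------------------------
# Genome generation
# ---------------------------------------------------------------------------

def generate_genome(config: SimulationConfig) -> GroundTruth:
    """Build unit sequences, plant repeats, and assemble the isoform mixture.

    Unit sequences are i.i.d. uniform bases (seeded) unless supplied in
    ``config.unit_seqs``.  Identical seeds give byte-identical output.
    """
    rng = _rng(config.seed, "genome")
    unit_seqs: dict[str, str] = {}
    for name, length in config.units:
        if name in config.unit_seqs:
            seq = config.unit_seqs[name].upper()
            if len(seq) != length:
                raise ValueError(f"supplied sequence for {name} has wrong length")
            unit_seqs[name] = seq
        else:
            unit_seqs[name] = _random_seq(rng, length)

    for rep in config.planted_repeats:
        src = unit_seqs[rep.source_unit][rep.source_start : rep.source_start + rep.length]
        if len(src) != rep.length:
            raise ValueError("planted repeat source out of bounds")
        if rep.inverted:
            src = revcomp(src)
        dest = unit_seqs[rep.dest_unit]
        if rep.dest_start + rep.length > len(dest):
            raise ValueError("planted repeat destination out of bounds")
        unit_seqs[rep.dest_unit] = (
            dest[: rep.dest_start] + src + dest[rep.dest_start + rep.length :]
        )

    molecules = []
    unit_coords: dict[str, list[tuple[str, str, int, int]]] = {}
    junctions: Counter = Counter()
    isoforms = []
    for iso in config.isoforms:
        parts = []
        coords = []
        pos = 0
        for ou in iso.arrangement:
            seq = unit_seqs[ou.unit]
            if ou.strand == "-":
                seq = revcomp(seq)
            parts.append(seq)
            coords.append((ou.unit, ou.strand, pos, pos + len(seq)))
            pos += len(seq)
        full = "".join(parts)
        isoforms.append(replace(iso, total_length=len(full)))
        molecules.append(Molecule(iso.label, full, iso.topology, iso.frequency))
        unit_coords[iso.label] = coords
        arr = iso.arrangement
        pairs = list(zip(arr, arr[1:]))
        if iso.topology == "circular" and len(arr) > 1:
            pairs.append((arr[-1], arr[0]))
        for a, b in pairs:
            junctions[canonical_block((a, b))] += 1

    # True copy numbers: multiplicities within the longest (full) isoform.
    full_iso = max(isoforms, key=lambda i: i.total_length)
    copy_numbers = {name: 0 for name, _ in config.units}
    copy_numbers.update(full_iso.multiplicities())

    return GroundTruth(
        unit_seqs=unit_seqs,
        isoforms=tuple(isoforms),
        molecules=tuple(molecules),
        unit_coords=unit_coords,
        junctions=junctions,
        copy_numbers=copy_numbers,
    )


# ---------------------------------------------------------------------------
# Error model
# ---------------------------------------------------------------------------

def apply_errors(
    seq: str,
    rng: np.random.Generator,
    sub_rate: float,
    ins_rate: float,
    del_rate: float,
) -> str:
    """Apply per-base substitutions, deletions, then insertions."""
    if sub_rate == ins_rate == del_rate == 0:
        return seq
    codes = _seq_to_codes(seq).copy()
    n = len(codes)
    r = rng.random(n)
    sub_idx = np.nonzero(r < sub_rate)[0]
    if sub_idx.size:
        shift = rng.integers(1, 4, size=sub_idx.size, dtype=np.uint8)
        codes[sub_idx] = (codes[sub_idx] + shift) % 4
    # the same uniform draw decides deletion on the non-substituted mass
    del_mask = (r >= sub_rate) & (r < sub_rate + del_rate)
    codes = codes[~del_mask]
    if ins_rate > 0 and codes.size:
        ins_mask = rng.random(codes.size) < ins_rate
        ins_pos = np.nonzero(ins_mask)[0]
        if ins_pos.size:
            ins_val = rng.integers(0, 4, size=ins_pos.size, dtype=np.uint8)
            codes = np.insert(codes, ins_pos, ins_val)
    return _codes_to_seq(codes)


# ---------------------------------------------------------------------------
# Long reads
# ---------------------------------------------------------------------------

def _molecule_probs(molecules) -> np.ndarray:
    w = np.array([m.frequency * len(m.seq) for m in molecules], dtype=float)
    return w / w.sum()


def sample_long_reads(
    truth: GroundTruth, config: SimulationConfig
) -> tuple[list[SequenceRecord], pd.DataFrame]:
    """Draw long reads until total bases reach coverage x mean molecule length.

    Molecules are chosen proportional to frequency x length; circular
    molecules are sampled with wrap-around via the doubled-sequence trick
    (reads never exceed one full molecule length).
    """
    molecules = truth.molecules
    mean_len = sum(m.frequency * len(m.seq) for m in molecules)
    for m in molecules:
        if m.topology == "linear" and config.read_length_mean > len(m.seq):
            raise ValueError(
                f"mean read length {config.read_length_mean} exceeds linear "
                f"molecule {m.label} ({len(m.seq)} bp)"
            )
    target = config.coverage * mean_len
    probs = _molecule_probs(molecules)
    doubled = [
        m.seq + m.seq if m.topology == "circular" else m.seq for m in molecules
    ]
    mu = math.log(config.read_length_mean) - config.read_length_sigma**2 / 2

    rng = _rng(config.seed, "longreads")
    reads: list[SequenceRecord] = []
    prov_rows = []
    total = 0
    i = 0
    while total < target:
        k = int(rng.choice(len(molecules), p=probs))
        mol = molecules[k]
        mol_len = len(mol.seq)
        length = int(rng.lognormal(mu, config.read_length_sigma))
        length = max(config.min_read_length, min(length, mol_len))
        if mol.topology == "circular":
            start = int(rng.integers(0, mol_len))
        else:
            start = int(rng.integers(0, mol_len - length + 1))
        segment = doubled[k][start : start + length]
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            segment = revcomp(segment)
        read_seq = apply_errors(
            segment, rng, config.sub_rate, config.ins_rate, config.del_rate
        )
        rid = f"lr{i:06d}"
        reads.append(SequenceRecord(rid, read_seq))
        prov_rows.append((rid, mol.label, start, strand, length))
        total += length
        i += 1
    prov = pd.DataFrame(
        prov_rows, columns=["read_id", "isoform", "start", "strand", "length"]
    )
    return reads, prov


# ---------------------------------------------------------------------------
# Mate pairs
# ---------------------------------------------------------------------------

def sample_mate_pairs(
    truth: GroundTruth, config: SimulationConfig, library_index: int = 0
) -> tuple[list[SequenceRecord], list[SequenceRecord], pd.DataFrame]:
    """Sample one mate-pair library: two ``read_len`` reads whose outer
    distance is Normal(insert_mean, insert_sd) truncated above 2 x read_len.

    Returns (reads1, reads2, provenance); read 2 is the reverse complement
    of the distal end (FR layout).  Pairs spanning the circular origin wrap.
    """
    lib = config.mate_pair_libraries[library_index]
    molecules = truth.molecules
    probs = _molecule_probs(molecules)
    rng = _rng(config.seed, "matepairs", library_index)
    n = lib.n_pairs
    mol_idx = rng.choice(len(molecules), size=n, p=probs)
    inserts = rng.normal(lib.insert_mean, lib.insert_sd, size=n)
    if lib.insert_sd > 0:
        bad = inserts <= 2 * lib.read_len
        while bad.any():
            inserts[bad] = rng.normal(lib.insert_mean, lib.insert_sd, size=int(bad.sum()))
            bad = inserts <= 2 * lib.read_len
    inserts = np.rint(inserts).astype(int)

    doubled = {}
    for k, m in enumerate(molecules):
        doubled[k] = m.seq + m.seq if m.topology == "circular" else m.seq

    reads1, reads2, rows = [], [], []
    for i in range(n):
        k = int(mol_idx[i])
        mol = molecules[k]
        mol_len = len(mol.seq)
        ins = int(min(inserts[i], mol_len))
        if mol.topology == "circular":
            start = int(rng.integers(0, mol_len))
        else:
            start = int(rng.integers(0, max(1, mol_len - ins + 1)))
        seq = doubled[k]
        r1 = seq[start : start + lib.read_len]
        r2 = revcomp(seq[start + ins - lib.read_len : start + ins])
        pid = f"mp{library_index}_{i:06d}"
        reads1.append(SequenceRecord(pid + "/1", r1))
        reads2.append(SequenceRecord(pid + "/2", r2))
        rows.append((pid, mol.label, start, (start + ins - lib.read_len) % mol_len, ins))
    if lib.error_rate > 0:
        reads1 = _mutate_short(reads1, rng, lib.error_rate)
        reads2 = _mutate_short(reads2, rng, lib.error_rate)
    prov = pd.DataFrame(rows, columns=["pair_id", "isoform", "pos1", "pos2", "insert"])
    return reads1, reads2, prov


def _mutate_short(reads, rng, rate):
    """Vectorized substitution-only errors over equal-length short reads."""
    arr = np.frombuffer("".join(r.seq for r in reads).encode(), dtype=np.uint8)
    codes = _CODE[arr].copy()
    mask = rng.random(codes.size) < rate
    idx = np.nonzero(mask)[0]
    if idx.size:
        codes[idx] = (codes[idx] + rng.integers(1, 4, size=idx.size, dtype=np.uint8)) % 4
    text = _codes_to_seq(codes)
    out = []
    pos = 0
    for r in reads:
        out.append(SequenceRecord(r.id, text[pos : pos + len(r.seq)]))
        pos += len(r.seq)
    return out


# ---------------------------------------------------------------------------
# Hi-C chimeras
# ---------------------------------------------------------------------------

def sample_hic_pairs(
    truth: GroundTruth, config: SimulationConfig
) -> tuple[list[SequenceRecord], pd.DataFrame]:
    """Emit single chimeric reads joining two GATC-bounded loci of one molecule.

    Mbo-I Hi-C ligation creates a GATC-GATC scar; each emitted read is
    leftFlank+GATC + GATC+rightFlank with the join offset recorded.  Locus
    separation follows a power law with the configured decay exponent.
    """
    molecules = truth.molecules
    probs = _molecule_probs(molecules)
    sites = {}
    for k, m in enumerate(molecules):
        sites[k] = np.array([s.start() for s in re.finditer("GATC", m.seq)], dtype=int)
    if all(s.size == 0 for s in sites.values()):
        raise ValueError("no GATC sites in the simulated genome")
    rng = _rng(config.seed, "hic")
    alpha = config.hic_exponent
    flank = config.hic_flank
    dmin = 1000.0
    reads, rows = [], []
    n = config.hic_pairs
    i = 0
    while i < n:
        k = int(rng.choice(len(molecules), p=probs))
        ss = sites[k]
        if ss.size < 2:
            continue
        mol = molecules[k]
        mol_len = len(mol.seq)
        a = int(ss[rng.integers(0, ss.size)])
        d = dmin * rng.random() ** (-1.0 / (alpha - 1.0)) if alpha > 1 else dmin
        d = min(d, mol_len / 2)
        sign = 1 if rng.random() < 0.5 else -1
        target = (a + sign * int(d)) % mol_len
        j = int(ss[np.argmin(np.minimum(np.abs(ss - target), mol_len - np.abs(ss - target)))])
        if j == a:
            continue
        seq2 = mol.seq + mol.seq
        left = seq2[max(0, a - flank) : a + 4] if a >= flank else seq2[a + mol_len - flank : a + mol_len + 4]
        right = seq2[j : j + flank + 4]
        read_seq = left + right
        join = len(left) - 4
        dist = min(abs(a - j), mol_len - abs(a - j))
        rid = f"hic{i:06d}"
        reads.append(SequenceRecord(rid, read_seq))
        rows.append((rid, mol.label, a, j, join, dist))
        i += 1
    prov = pd.DataFrame(
        rows, columns=["read_id", "isoform", "pos_left", "pos_right", "join_offset", "distance"]
    )
    return reads, prov


# ---------------------------------------------------------------------------
# Crossover products (minor recombinant isoforms)
# ---------------------------------------------------------------------------

def crossover_products(
    reference: Molecule, p1: int, p2: int, repeat_length: int
) -> tuple[Molecule, Molecule]:
    """The two circles produced by crossover at a direct repeat.

    ``p1 < p2`` are the start coordinates of the two repeat copies on the
    circular reference.  Recombination between direct copies resolves the
    circle into two subcircles, each retaining one repeat copy: the arc
    [p1, p2) and the arc [p2, p1) (wrapping).
    """
    if reference.topology != "circular":
        raise ValueError("crossover_products expects a circular reference")
    seq = reference.seq
    if not (0 <= p1 < p2 < len(seq)):
        raise ValueError("need 0 <= p1 < p2 < genome length")
    prod_a = seq[p1:p2]
    prod_b = seq[p2:] + seq[:p1]
    return (
        Molecule(reference.label + ".xA", prod_a, "circular", 0.0),
        Molecule(reference.label + ".xB", prod_b, "circular", 0.0),
    )


def mix_molecules(major: Molecule, products: tuple[Molecule, Molecule], fraction: float):
    """Molecule pool after a ``fraction`` of major circles have crossed over.

    Each crossover event converts one major circle into BOTH products, so
    molecule counts are {major: 1-f, productA: f, productB: f}, renormalized.
    """
    if not 0 <= fraction < 1:
        raise ValueError("fraction must be in [0, 1)")
    a, b = products
    norm = (1 - fraction) + 2 * fraction
    return (
        replace(major, frequency=(1 - fraction) / norm),
        replace(a, frequency=fraction / norm),
        replace(b, frequency=fraction / norm),
    )
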