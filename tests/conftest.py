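"""Shared simulation fixtures.

The heavy full-genome simulations are session-scoped and cached so that
several tests can interrogate one run (mapping, stoichiometry, blocks,
enumeration, scoring).  Problem sizes are chosen to keep the whole suite
within a normal CI run while leaving the statistical checks comfortable.
"""

from __future__ import annotations

import functools
from dataclasses import replace

import numpy as np
import pytest

from mitoforms import isoforms as iso_mod
from mitoforms import mapping, pairdist, simulate
from mitoforms.model import IsoformModel, OrientedUnit

SATIVA_COVERAGE = 150
SATIVA_READ_MEAN = 18000


@functools.lru_cache(maxsize=None)
def sativa_pipeline(f_alpha: float, seed: int):
    """Simulate the two-major-isoform mixture and run the long-read stages."""
    isos = simulate.default_isoforms("sativa")
    isos = (
        replace(isos[0], frequency=f_alpha),
        replace(isos[1], frequency=round(1 - f_alpha, 12)),
    )
    cfg = simulate.SimulationConfig(
        units=simulate.SimulationConfig.for_species("sativa").units,
        isoforms=isos,
        seed=seed,
        coverage=SATIVA_COVERAGE,
        read_length_mean=SATIVA_READ_MEAN,
    )
    truth = simulate.generate_genome(cfg)
    reads, prov = simulate.sample_long_reads(truth, cfg)
    units = [(n, s) for n, s in truth.unit_seqs.items()]
    unit_lengths = {n: len(s) for n, s in units}
    hits = mapping.map_tiling_to_reads(mapping.make_tiling(units), reads)
    informative = mapping.select_informative_reads(hits, 10)
    paths = mapping.unit_paths(hits, unit_lengths, informative)
    blocks = iso_mod.building_blocks(paths, {"M", "N", "R", "T"})
    graph = iso_mod.build_graph(blocks, truth.copy_numbers)
    enum = iso_mod.enumerate_isoforms(graph)
    score = iso_mod.score_isoforms(enum.isoforms, blocks) if enum.isoforms else None
    return {
        "config": cfg,
        "truth": truth,
        "reads": reads,
        "provenance": prov,
        "units": units,
        "hits": hits,
        "informative": informative,
        "paths": paths,
        "blocks": blocks,
        "graph": graph,
        "enum": enum,
        "score": score,
    }


@pytest.fixture(scope="session")
def sativa_even():
    return sativa_pipeline(0.5, 11)


@pytest.fixture(scope="session")
def saligna_run():
    """The wild-species model (Fig-2B-style mixture) at 100x with 15 kb reads."""
    cfg = simulate.SimulationConfig.for_species("saligna", seed=5, coverage=100)
    truth = simulate.generate_genome(cfg)
    reads, prov = simulate.sample_long_reads(truth, cfg)
    units = [(n, s) for n, s in truth.unit_seqs.items()]
    hits = mapping.map_tiling_to_reads(mapping.make_tiling(units), reads)
    informative = mapping.select_informative_reads(hits, 12)
    paths = mapping.unit_paths(hits, {n: len(s) for n, s in units}, informative)
    blocks = iso_mod.building_blocks(paths, {"M", "R", "T"})
    return {"truth": truth, "reads": reads, "paths": paths, "blocks": blocks}


# ---------------------------------------------------------------------------
# Mate-pair crossover simulations (minor-isoform detection)
# ---------------------------------------------------------------------------

CROSSOVER_GENOME = 100_000
CROSSOVER_P1, CROSSOVER_P2 = 20_000, 50_000
CROSSOVER_REPEAT = 500
CROSSOVER_PAIRS = 80_000


@functools.lru_cache(maxsize=None)
def crossover_estimate(fraction: float, seed: int = 7):
    """Plant a 500 bp direct repeat, mix the crossover products at the given
    fraction, simulate 5 kb + 10 kb mate-pair libraries, and run the
    off-diagonal estimator against the major reference."""
    cfg = simulate.SimulationConfig(
        units=(("G", CROSSOVER_GENOME),),
        isoforms=(IsoformModel((OrientedUnit("G", "+"),), frequency=1.0, label="ref"),),
        seed=seed,
        planted_repeats=(
            simulate.PlantedRepeat("G", CROSSOVER_P1, "G", CROSSOVER_P2, CROSSOVER_REPEAT),
        ),
        mate_pair_libraries=(
            simulate.MatePairLibrary(5000, 400, CROSSOVER_PAIRS),
            simulate.MatePairLibrary(10000, 800, CROSSOVER_PAIRS),
        ),
    )
    truth = simulate.generate_genome(cfg)
    major = truth.molecules[0]
    if fraction > 0:
        products = simulate.crossover_products(
            major, CROSSOVER_P1, CROSSOVER_P2, CROSSOVER_REPEAT
        )
        truth = replace(truth, molecules=simulate.mix_molecules(major, products, fraction))
    pos1, pos2 = [], []
    for lib in range(2):
        r1, r2, _ = simulate.sample_mate_pairs(truth, cfg, lib)
        m1, p1 = pairdist.map_read_positions([r.seq for r in r1], major.seq)
        m2, p2 = pairdist.map_read_positions([r.seq for r in r2], major.seq)
        both = m1 & m2
        pos1.append(p1[both])
        pos2.append(p2[both])
    matrix = pairdist.pair_distance_matrix(
        np.concatenate(pos1), np.concatenate(pos2), CROSSOVER_GENOME, subsample=None
    )
    sig = pairdist.detect_recombination(
        matrix, (CROSSOVER_P1, CROSSOVER_P2), CROSSOVER_REPEAT
    )
    return matrix, sig


# ---------------------------------------------------------------------------
# Small toy genome (one isoform, one 2x unit)
# ---------------------------------------------------------------------------

def toy_config(seed: int = 0, **kwargs) -> simulate.SimulationConfig:
    units = (("A", 12000), ("B", 8000), ("C", 12000), ("D", 12000))
    arr = tuple(OrientedUnit(u, "+") for u in ["A", "B", "C", "B", "D"])
    defaults = dict(
        units=units,
        isoforms=(IsoformModel(arr, frequency=1.0, label="toy"),),
        seed=seed,
        coverage=40,
        read_length_mean=8000,
        read_length_sigma=0.3,
        min_read_length=1000,
    )
    defaults.update(kwargs)
    return simulate.SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def toy_run():
    cfg = toy_config(seed=2)
    truth = simulate.generate_genome(cfg)
    reads, prov = simulate.sample_long_reads(truth, cfg)
    units = [(n, s) for n, s in truth.unit_seqs.items()]
    hits = mapping.map_tiling_to_reads(mapping.make_tiling(units), reads)
    informative = mapping.select_informative_reads(hits, 5)
    paths = mapping.unit_paths(hits, {n: len(s) for n, s in units}, informative)
    return {
        "config": cfg,
        "truth": truth,
        "reads": reads,
        "provenance": prov,
        "units": units,
        "hits": hits,
        "informative": informative,
        "paths": paths,
    }
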