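"""Shared fixtures: a reduced 60 Mb genome with proportional read depth.

Everything is generated programmatically at session scope so the expensive
pieces (panel simulation, LOESS, PCA fit) are paid once.
"""

import numpy as np
import pytest

from plasmacnv.genomes import proportional_umr, toy_chrom_sizes
from plasmacnv.normalization import fit_reference_panel, loess_gc_correct
from plasmacnv.simulate import (
    SimulationConfig,
    simulate_genome,
    simulate_panel,
)

TOY_SIZES = toy_chrom_sizes()
TOY_UMR = proportional_umr(TOY_SIZES)


@pytest.fixture(scope="session")
def toy_genome_shared():
    """Cohort-shared toy genome (binning, GC field, artifacts, dropouts)."""
    return simulate_genome(TOY_SIZES, seed=11)


@pytest.fixture(scope="session")
def toy_base_config(toy_genome_shared):
    return SimulationConfig(total_umr=TOY_UMR, seed=12, genome=toy_genome_shared)


@pytest.fixture(scope="session")
def toy_panel_raw(toy_base_config):
    return simulate_panel(12, toy_base_config)


@pytest.fixture(scope="session")
def toy_panel_gc(toy_panel_raw):
    return [loess_gc_correct(p) for p in toy_panel_raw]


@pytest.fixture(scope="session")
def toy_panel(toy_panel_gc):
    return fit_reference_panel(toy_panel_gc)


def toy_config(genome, **kw):
    """Convenience constructor for a sample config on the shared toy genome."""
    kw.setdefault("total_umr", TOY_UMR)
    kw.setdefault("genome", genome)
    return SimulationConfig(**kw)
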