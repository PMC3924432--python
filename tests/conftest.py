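"""Shared fixtures: synthetic studies and the processed pipeline bundle."""

import pytest

from retsplice.events import classify_all
from retsplice.genes import chain_novel_genes, coding_potential
from retsplice.junctions import partition
from retsplice.orf import GenomeSource
from retsplice.simulate import SimConfig, simulate

STUDY_SEED = 11


@pytest.fixture(scope="session")
def sim():
    """Default-condition synthetic study (full planted-event load)."""
    return simulate(SimConfig(seed=STUDY_SEED))


@pytest.fixture(scope="session")
def small_sim():
    """Reduced synthetic study for cheaper unit-level checks."""
    cfg = SimConfig(seed=5, n_genes=30, chrom_len=700_000,
                    n_internal_exons=24, n_terminal_exons=6, n_skips=12,
                    n_alt3=8, n_alt5=8, n_novel_genes=4)
    return simulate(cfg)


class Study:
    """Fully processed pipeline state over a simulation result."""

    def __init__(self, res):
        self.res = res
        self.nrt = res.nrt()
        self.genome = GenomeSource(res.genome)
        self.annotated, self.novel = partition(res.junctions, self.nrt)
        self.events = classify_all(self.novel, self.nrt, res.coverage)
        cand = self.events.unanchored_exons + [
            t for t in self.events.terminal_exons if not t.host_transcripts]
        self.genes = chain_novel_genes(cand, self.novel, res.coverage, self.nrt)
        for g in self.genes:
            coding_potential(g, self.genome)


@pytest.fixture(scope="session")
def study(sim):
    return Study(sim)


@pytest.fixture(scope="session")
def small_study(small_sim):
    return Study(small_sim)
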