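import numpy as np
import pytest

from allelepaint.model import DiagnosticSite, DiagnosticSiteSet
from allelepaint.simulate import (
    LineageSpec,
    SimulationConfig,
    simulate_panel,
)


@pytest.fixture(scope="session")
def default_panel():
    """Default V1R2-like panel: 942-nt CDS, 11 nonsynonymous diagnostic
    sites, Figure-2-like lineage frequencies, no recombinants."""
    cfg = SimulationConfig(seed=11)
    return cfg, simulate_panel(cfg)


@pytest.fixture(scope="session")
def mosaic_panel():
    """V1R6-like panel: 13 diagnostic sites and crossover mosaics."""
    cfg = SimulationConfig(
        n_codons=314,
        n_diagnostic=13,
        nonsyn_fraction=8 / 13,
        lineages=[
            LineageSpec("LakeVictoria", 80, 0.5),
            LineageSpec("UpperNile", 20, 0.3),
        ],
        recombinant_fraction=0.15,
        seed=13,
    )
    return cfg, simulate_panel(cfg)


def make_sites(columns, anc="A", der="G"):
    """Minimal diagnostic-site set with uniform states, for painting tests."""
    sites = [
        DiagnosticSite(
            column=c,
            state_ancestral=anc,
            state_derived=der,
            codon=(c - 1) // 3 + 1,
            aa_ancestral="?",
            aa_derived="?",
            is_nonsynonymous=True,
        )
        for c in columns
    ]
    return DiagnosticSiteSet(gene="toy", sites=sites)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
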