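"""Shared fixtures and simulation helpers for the test suite."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import rhmscan as r

settings.register_profile("suite", deadline=None, derandomize=True,
                          max_examples=25)
settings.load_profile("suite")


def seed_stream(master: int, n: int) -> list[int]:
    """n reproducible child seeds below 2**31."""
    return [int(c.generate_state(1)[0] % 2**31)
            for c in np.random.SeedSequence(master).spawn(n)]


def three_pop_designs(sizes=(200, 200, 200), divergence=0.15):
    """Desk-scale analogue of the three study populations."""
    return [
        r.PopulationDesign("POP1", "double_backcross", 10, sizes[0],
                           founder_freq_divergence=divergence),
        r.PopulationDesign("POP2", "backcross", 20, sizes[1],
                           founder_freq_divergence=divergence),
        r.PopulationDesign("POP3", "backcross", 4, sizes[2],
                           founder_freq_divergence=divergence),
    ]


def null_study(seed, sizes=(200, 200, 200), n_chromosomes=6, snps_per_chrom=300,
               polygenic_h2=0.25):
    """Three-population study with polygenic background and no QTL."""
    return r.simulate_study(
        seed, designs=three_pop_designs(sizes),
        gmap=r.default_map(n_chromosomes, snps_per_chrom),
        trait=r.TraitModel(polygenic_h2=polygenic_h2, repeatability=0.5))


def latent_response(truth, seed, residual_var):
    """Genetic value plus Gaussian residual on the latent scale."""
    g = truth["genetic_value"].to_numpy()
    rng = np.random.default_rng(seed)
    return g + rng.normal(0.0, np.sqrt(residual_var), len(g))


def population_design_matrix(panel):
    """Intercept plus population indicator contrasts."""
    cols = [np.ones(panel.n_animals)]
    for pop in pd.unique(panel.populations)[1:]:
        cols.append((panel.populations == pop).astype(float))
    return np.column_stack(cols)


@pytest.fixture(scope="session")
def study():
    """Three small populations, 6 chromosomes x 300 SNPs, polygenic trait."""
    panel, records, truth = null_study(20240901)
    return {"panel": panel, "records": records, "truth": truth}


@pytest.fixture(scope="session")
def tiny_panel():
    """One 60-animal backcross over 2 chromosomes x 60 SNPs."""
    designs = [r.PopulationDesign("TINY", "backcross", 4, 60,
                                  founder_freq_divergence=0.1)]
    gmap = r.GenomeMap([(1, 60, 80.0), (2, 60, 80.0)])
    panel, records, truth = r.simulate_study(77, designs=designs, gmap=gmap)
    return panel
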