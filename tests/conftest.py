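import numpy as np
import pandas as pd
import pytest

from apomixkit import core, synth
from apomixkit.introgression import TrioSpec


@pytest.fixture(scope="session")
def small_cohort():
    """Three drift-structured populations plus outgroup, no planted flow."""
    cfg = synth.SynthConfig(seed=42, n_pops=3, samples_per_pop=12, n_variants=6000)
    vt, gm, truth = synth.simulate_structured_genotypes(cfg)
    pm = synth.population_map(truth, roles={"outgroup": "outgroup"})
    vt = core.polarize_by_outgroup(vt, gm, pm)
    return cfg, vt, gm, pm, truth


@pytest.fixture(scope="session")
def small_freqs(small_cohort):
    cfg, vt, gm, pm, truth = small_cohort
    aft = core.derived_freqs(gm, vt, pm, ["pop1", "pop2", "pop3", "outgroup"])
    return aft


@pytest.fixture
def trio():
    return TrioSpec("pop1", "pop2", "pop3", "outgroup")


def freq_table(p1, p2, p3, po, spacing=1000):
    """Build an AlleleFreqTable from explicit per-site frequencies."""
    n = len(p1)
    sites = pd.DataFrame({"chrom": ["chr1"] * n,
                          "pos": np.arange(n) * spacing})
    freq = pd.DataFrame({"pop1": p1, "pop2": p2, "pop3": p3, "outgroup": po},
                        dtype=float)
    n_alleles = pd.DataFrame(10, index=freq.index, columns=freq.columns)
    return core.AlleleFreqTable(freq, n_alleles, sites)
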