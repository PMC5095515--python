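import numpy as np
import pandas as pd
import pytest

from crowscape import simdata
from crowscape.variantio import MISSING, PopulationMap, VariantMatrix


def make_variant_matrix(genotypes, pops, pos=None, scaffold="s1",
                        ancestral=None, scaffold_length=None):
    """Build a VariantMatrix from an (n_sites, n_samples) genotype array and
    a list of population labels, one per sample column."""
    g = np.asarray(genotypes, dtype=np.int8)
    n_sites, n_samples = g.shape
    assert len(pops) == n_samples
    samples = [f"ind{i}" for i in range(n_samples)]
    popmap = PopulationMap(pd.DataFrame({
        "individual": samples, "population": pops,
        "lat": [0.0] * n_samples, "lon": [0.0] * n_samples,
    }))
    if pos is None:
        pos = np.arange(1, n_sites + 1) * 100
    anc = np.array(["A"] * n_sites, dtype=object) if ancestral is None \
        else np.asarray(ancestral, dtype=object)
    lengths = {scaffold: scaffold_length} if scaffold_length else {}
    return VariantMatrix(
        scaffold=np.array([scaffold] * n_sites, dtype=object),
        pos=np.asarray(pos, dtype=np.int64),
        ref=np.array(["A"] * n_sites, dtype=object),
        alt=np.array(["T"] * n_sites, dtype=object),
        ancestral=anc,
        genotypes=g,
        samples=samples,
        popmap=popmap,
        scaffold_lengths=lengths,
    )


@pytest.fixture(scope="session")
def small_sim():
    """A compact instance of the study-like scenario, shared across tests."""
    cfg = simdata.default_scenario(seed=42, n_scaffolds=4,
                                   windows_per_scaffold=30)
    return simdata.simulate(cfg)


@pytest.fixture(scope="session")
def small_sim_vm(small_sim):
    vm, windex, popmap = simdata.to_variant_matrix(small_sim)
    return vm, windex, popmap


MISSING = MISSING
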