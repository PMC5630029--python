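import numpy as np
import pytest

import mycflux as mf
from mycflux.kinetics import derive_abundances, estimate_synthesis, pooled_sigma


@pytest.fixture(scope="session")
def small_truth():
    """A small noiseless cohort shared across tests."""
    return mf.generate_ground_truth(n_genes=40, seed=7)


@pytest.fixture(scope="session")
def noiseless_rna(small_truth):
    tabs = mf.simulate_rna_tables(small_truth, mf.NoiseModel(cv=0.0), n_replicates=1)
    return {k: mf.normalize(v) for k, v in tabs.items()}


@pytest.fixture(scope="session")
def noiseless_chip(small_truth):
    tabs = mf.simulate_chip_tables(small_truth, mf.NoiseModel(cv=0.0), n_replicates=1)
    return {k: mf.normalize(v) for k, v in tabs.items()}


def rna_inputs(gt, cv, n_replicates, seed=None):
    """Normalized abundances, synthesis estimates, and pooled weights."""
    tabs = mf.simulate_rna_tables(gt, mf.NoiseModel(cv=cv), n_replicates=n_replicates,
                                  seed=seed)
    te, ti = mf.normalize(tabs["total_exon"]), mf.normalize(tabs["total_intron"])
    ne, ni = mf.normalize(tabs["nascent_exon"]), mf.normalize(tabs["nascent_intron"])
    P, M, flags = derive_abundances(te, ti)
    k1 = estimate_synthesis(ne, ni)
    sigmas = dict(
        sigma_P=pooled_sigma(ti)[0],
        sigma_M=pooled_sigma(te)[0],
        sigma_k1=(pooled_sigma(ne)[0] + pooled_sigma(ni)[0]) / gt.grid.labeling_duration,
    )
    return P, M, k1, sigmas, flags
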