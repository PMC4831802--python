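import numpy as np
import pytest

import germcycle as gc


@pytest.fixture(scope="session")
def wt_params():
    return gc.wildtype_params()


@pytest.fixture(scope="session")
def noiseless_library(wt_params):
    """Template library without measurement noise, shared across tests."""
    return gc.build_template_library(wt_params, n_sim=50_000, seed=99, noise_cv=0.0)


@pytest.fixture(scope="session")
def noisy_library(wt_params):
    """Template library at the generator's default measurement noise."""
    return gc.build_template_library(wt_params, n_sim=50_000, seed=99, noise_cv=0.06)


def observed_pair(gonad, bin_edges):
    """Histogram pair of a GonadSample's measured cells on the library bins."""
    edu = gonad.cells["edu"].to_numpy(dtype=bool)
    content = gonad.cells["dna_content"].to_numpy()
    pos, _ = np.histogram(content[edu], bins=bin_edges)
    neg, _ = np.histogram(content[~edu], bins=bin_edges)
    return gc.HistogramPair(bin_edges, pos, neg)


def cohort_phases(samples, lib):
    """Per-gonad phase estimates, dormant-flagged zones dropped."""
    phases = []
    for g in samples:
        est = gc.match_phase(observed_pair(g, lib.bin_edges), lib, gonad_id=g.gonad_id)
        if not est.dormant:
            phases.append(est.phase)
    return phases
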