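import numpy as np
import pytest

from toplines import (MCMCSettings, SimulationConfig, compute_grm, simulate_markers,
                      simulate_phenotypes, stabilize)


@pytest.fixture(scope="session")
def tiny_dataset():
    """60 lines x 200 markers, one trait/environment, h2 = 0.5."""
    cfg = SimulationConfig(n_lines=60, n_markers=200, n_qtl=30, h2=0.5, seed=12345)
    markers = simulate_markers(cfg)
    phenotypes, truth = simulate_phenotypes(markers, cfg)
    grm = stabilize(compute_grm(markers))
    y = phenotypes.slice("env1", "trait1")["value"].to_numpy()
    return {"cfg": cfg, "markers": markers, "phenotypes": phenotypes,
            "truth": truth, "grm": grm, "y": y}


@pytest.fixture()
def fast_settings():
    """Short chains for structural tests where accuracy is not at stake."""
    def make(seed, n_iter=500, burn_in=100, thin=1):
        return MCMCSettings(n_iter=n_iter, burn_in=burn_in, thin=thin, seed=seed)
    return make


def simulate_slice(seed, n_lines=300, n_markers=500, h2=0.5, n_qtl=50):
    """One simulated (y, G) pair under the standard replicate design."""
    cfg = SimulationConfig(n_lines=n_lines, n_markers=n_markers, n_qtl=n_qtl,
                           h2=h2, seed=seed)
    markers = simulate_markers(cfg)
    phenotypes, truth = simulate_phenotypes(markers, cfg)
    grm = stabilize(compute_grm(markers))
    y = phenotypes.slice("env1", "trait1")["value"].to_numpy()
    return y, grm, truth
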