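import numpy as np
import pytest

from rhmap.likelihood import DIPLOID, HAPLOID
from rhmap.simulate import (example_genome, simulate_fragments,
                            simulate_observations)

# diploid marker retention 0.35 corresponds to per-fragment r of ~0.194
R_FRAGMENT_35 = 1.0 - float(np.sqrt(1.0 - 0.35))


def simulate_chain_vectors(rng, thetas, r, n_clones, model=DIPLOID, eps_fn=0.0,
                           missing_rate=0.0):
    """Directly sample observation vectors from the retention chain.

    Independent oracle for the likelihood code: simulates the Markov chain
    states explicitly rather than going through the fragment simulator."""
    thetas = np.asarray(thetas, dtype=float)
    m = len(thetas) + 1
    copies = 1 if model == HAPLOID else 2
    present = np.zeros((n_clones, m), dtype=bool)
    for _ in range(copies):
        s = rng.random(n_clones) < r
        states = [s]
        for theta in thetas:
            brk = rng.random(n_clones) < theta
            s = np.where(brk, rng.random(n_clones) < r, states[-1])
            states.append(s)
        present |= np.array(states).T
    obs = present.astype(np.int8)
    if eps_fn:
        obs[present & (rng.random((n_clones, m)) < eps_fn)] = 0
    if missing_rate:
        obs[rng.random((n_clones, m)) < missing_rate] = -1
    return obs


@pytest.fixture(scope="session")
def clean_panel():
    """One ~100 cR chromosome, 50 markers, 90 clones, no observation error."""
    spec = example_genome(n_chromosomes=1, n_markers=50, length_bp=3_260_000,
                          seed=101)
    truth = simulate_fragments(spec, n_clones=90, r=R_FRAGMENT_35, seed=102)
    panel = simulate_observations(truth, fnr=0.0, fpr=0.0, missing_rate=0.0,
                                  seed=103)
    return spec, truth, panel


@pytest.fixture(scope="session")
def two_chromosome_panel():
    """Two ~100 cR chromosomes of 50 markers each, clean observations."""
    spec = example_genome(n_chromosomes=2, n_markers=50, length_bp=3_260_000,
                          seed=201)
    truth = simulate_fragments(spec, n_clones=90, r=R_FRAGMENT_35, seed=202)
    panel = simulate_observations(truth, fnr=0.0, fpr=0.0, missing_rate=0.0,
                                  seed=203)
    return spec, truth, panel
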