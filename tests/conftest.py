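import numpy as np
import pytest

from ulvfit import (SimulationConfig, fit_sdt, load_item_bank, score_responses,
                    simulate_responses)


@pytest.fixture(scope="session")
def bank():
    return load_item_bank("canonical")


@pytest.fixture(scope="session")
def m_map(bank):
    return bank.m_of_item()


@pytest.fixture(scope="session")
def default_dataset(bank):
    """One design-matched synthetic study (37 persons, 3 trials/item)."""
    return simulate_responses(bank, SimulationConfig(seed=2024))


@pytest.fixture(scope="session")
def default_fit(default_dataset, m_map):
    scores = score_responses(default_dataset.records)
    return scores, fit_sdt(scores, m_map)


def grid_loglik_2x2(K, N, link_pc, step=0.05, lim=3.0):
    """Independent dense-grid oracle for a 2-person x 2-item fit.

    With mean-zero anchoring the free parameters are t (theta = (t, -t)) and
    the two item locations.  ``link_pc`` maps the offset to a success
    probability using a closed form, independent of the package's quadrature
    path.  Returns (best loglik, (t, b1, b2) at the grid argmax).
    """
    grid = np.arange(-lim, lim + step / 2, step)
    t, b1, b2 = np.meshgrid(grid, grid, grid, indexing="ij")
    theta = np.stack([t, -t])                       # 2 x G x G x G
    b = np.stack([b1, b2])
    ll = np.zeros_like(t)
    eps = 1e-12
    for p in range(2):
        for i in range(2):
            pc = np.clip(link_pc(theta[p] - b[i]), eps, 1 - eps)
            ll += K[p, i] * np.log(pc) + (N[p, i] - K[p, i]) * np.log1p(-pc)
    idx = np.unravel_index(np.argmax(ll), ll.shape)
    return float(ll[idx]), (float(t[idx]), float(b1[idx]), float(b2[idx]))


def refine_grid_loglik_2x2(K, N, link_pc, center, step=0.002, halfwidth=0.06):
    """Fine brute-force pass around a coarse-grid argmax (still enumeration)."""
    t0, b10, b20 = center
    best = -np.inf
    g = np.arange(-halfwidth, halfwidth + step / 2, step)
    t, b1, b2 = np.meshgrid(t0 + g, b10 + g, b20 + g, indexing="ij")
    theta = np.stack([t, -t])
    b = np.stack([b1, b2])
    ll = np.zeros_like(t)
    eps = 1e-12
    for p in range(2):
        for i in range(2):
            pc = np.clip(link_pc(theta[p] - b[i]), eps, 1 - eps)
            ll += K[p, i] * np.log(pc) + (N[p, i] - K[p, i]) * np.log1p(-pc)
    return float(ll.max())
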