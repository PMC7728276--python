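import numpy as np
import pandas as pd
import pytest

from hhci.synthetic import SyntheticConfig, generate_panel


@pytest.fixture(scope="session")
def small_cfg():
    """A 7x7 lattice minus one cell (48 municipalities): fast but large
    enough to exercise every pipeline branch."""
    return SyntheticConfig(n_rows=7, n_cols=7, n_drop=1, seed=7)


@pytest.fixture(scope="session")
def small_panel(small_cfg):
    return generate_panel(small_cfg)


@pytest.fixture(scope="session")
def canonical_panel():
    """The 399-municipality default panel (one seed, shared across tests)."""
    return generate_panel(SyntheticConfig(seed=1))


@pytest.fixture(scope="session")
def canonical_outcomes(canonical_panel):
    from hhci.rates import outcome_series

    p = canonical_panel
    y0, y1 = p.config.years
    return outcome_series(p.deaths, p.population, list(range(y0, y1)), y1 - 1, y1)


# ---------------------------------------------------------------------------
# independent oracles (brute force / textbook formulations)


def brute_morans_i(x, neighbors_weights):
    """Double loop over all (i, j) pairs: I = (n/S0) sum_ij w_ij z_i z_j / sum z^2."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    z = x - x.mean()
    s0 = 0.0
    num = 0.0
    for i in range(n):
        for j, wij in neighbors_weights[i]:
            s0 += wij
            num += wij * z[i] * z[j]
    return n / s0 * num / (z @ z)


def brute_local_moran(x, neighbors_weights):
    x = np.asarray(x, dtype=float)
    n = len(x)
    z = (x - x.mean()) / x.std()
    out = np.zeros(n)
    for i in range(n):
        lag = sum(wij * z[j] for j, wij in neighbors_weights[i])
        out[i] = z[i] * lag
    return out


def brute_marshall_eb(deaths, pops):
    """Textbook Marshall global EB, written as explicit loops."""
    deaths = [float(d) for d in deaths]
    pops = [float(p) for p in pops]
    n = len(pops)
    total_d = sum(deaths)
    total_p = sum(pops)
    b = total_d / total_p
    s2 = sum(pops[i] * (deaths[i] / pops[i] - b) ** 2 for i in range(n)) / total_p
    pbar = total_p / n
    a = s2 - b / pbar
    if a < 0:
        a = 0.0
    out = []
    for i in range(n):
        ri = deaths[i] / pops[i]
        if a == 0.0:
            theta = b
        else:
            wi = a / (a + b / pops[i])
            theta = wi * ri + (1 - wi) * b
        out.append(theta * 1e5)
    return np.array(out)


def brute_2sfca(pops, caps, times, d0):
    """Step-by-step 2SFCA with explicit loops."""
    n, m = times.shape
    R = []
    for j in range(m):
        demand = sum(pops[k] for k in range(n) if times[k, j] <= d0)
        R.append(caps[j] / demand if demand > 0 else 0.0)
    A = np.zeros(n)
    for i in range(n):
        A[i] = sum(R[j] for j in range(m) if times[i, j] <= d0)
    return A


def nw_from_weights(w):
    """Neighbor/weight lists [(j, w_ij), ...] per unit from a SpatialWeights."""
    return [
        list(zip(nbrs.tolist(), wts.tolist()))
        for nbrs, wts in zip(w.neighbors, w.weights)
    ]
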