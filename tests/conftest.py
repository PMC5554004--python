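import numpy as np
import pytest

from pubeeg import electrode_adjacency, gen_montage, make_log_freqs


@pytest.fixture(scope="session")
def layout8():
    return gen_montage(8)


@pytest.fixture(scope="session")
def adjacency8(layout8):
    return electrode_adjacency(layout8)


@pytest.fixture(scope="session")
def small_grid():
    """Reduced analysis grid used by pipeline tests: 8 ch x 5 freqs x 20 times."""
    return {
        "freqs": make_log_freqs(1.0, 60.0, 5),
        "times": np.linspace(-2.0, 1.5, 20),
        "n_channels": 8,
    }


def grid_oracle_fit(phases, y, tau_step=1e-4):
    """Brute-force cosine fit: scan tau over [0, pi) and solve the remaining
    two-parameter linear problem in closed form at each tau.

    Independent of the production linearized solver; returns
    (pub, tau, B, rss) at the best grid tau.
    """
    theta = np.asarray(phases, float).ravel()
    yv = np.asarray(y, float).ravel()
    taus = np.arange(0.0, np.pi, tau_step)
    c = np.cos(theta[None, :] + taus[:, None])  # (n_tau, n)
    cbar = c.mean(axis=1, keepdims=True)
    ybar = yv.mean()
    dc = c - cbar
    dy = yv - ybar
    denom = (dc**2).sum(axis=1)
    num = dc @ dy
    A = np.divide(num, denom, out=np.zeros_like(num), where=denom > 0)
    rss = (dy**2).sum() - A * num
    k = int(np.argmin(rss))
    B = ybar - A[k] * cbar[k, 0]
    return abs(float(A[k])), float(taus[k]), float(B), float(rss[k])
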