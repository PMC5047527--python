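import numpy as np
import pytest

from microase import pipeline, simulate


def brute_bh(p):
    """Definitional step-up BH: padj_(i) = min_{j>=i} m p_(j)/j, capped."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    out = np.empty(m)
    for rank_i, i in enumerate(order, start=1):
        best = np.inf
        for rank_j in range(rank_i, m + 1):
            j = order[rank_j - 1]
            best = min(best, m * p[j] / rank_j)
        out[i] = min(1.0, best)
    return out


def brute_storey(p, lam=0.5):
    p = np.asarray(p, dtype=float)
    m = len(p)
    pi0 = min(1.0, np.sum(p > lam) / (m * (1 - lam)))
    return np.minimum(brute_bh(p) * pi0, 1.0)


def site_index(table):
    """Map simulated panel positions back to 0-based site indices."""
    return table["pos"].to_numpy() // 1000 - 1


@pytest.fixture(scope="session")
def small_run():
    """One deterministic count-path run shared by read-only tests."""
    cfg = simulate.SimConfig(n_sites=1000, coverage_mean=80.0, seed=7)
    return pipeline.run_count_path(cfg)
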