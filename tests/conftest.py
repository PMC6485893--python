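import numpy as np
import pandas as pd
import pytest

from epimsap import ScoreMatrix, SimConfig, simulate


@pytest.fixture
def toy_scores():
    """4 samples x 3 loci all-present HpaII matrix."""
    values = pd.DataFrame(
        np.ones((4, 3)),
        index=[f"s{i}" for i in range(4)],
        columns=["L1", "L2", "L3"],
    )
    return ScoreMatrix("HpaII", "E", values)


@pytest.fixture(scope="session")
def small_sim():
    """One-genotype synthetic study, error-free, shared across tests."""
    cfg = SimConfig(
        n_genotypes=1, n_per_group=12, n_loci=60, msl_fraction=0.7,
        dm_fraction=0.2, dm_effect=0.6, error_rate=0.0, primers=("E",), seed=42,
    )
    return simulate(cfg)


def brute_force_amova(values: np.ndarray, labels: np.ndarray):
    """Independent AMOVA oracle: all sums of squares by explicit double loops.

    ``values`` is the squared-distance matrix; returns (ss_among, ss_within,
    sigma2_a, sigma2_w, phi) computed from the textbook definitions with no
    vectorisation shared with the implementation.
    """
    n = values.shape[0]
    groups = sorted(set(labels))
    ss_total = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            ss_total += values[i, j]
    ss_total /= n
    ss_within = 0.0
    sizes = {}
    for g in groups:
        idx = [i for i in range(n) if labels[i] == g]
        sizes[g] = len(idx)
        acc = 0.0
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                acc += values[idx[a], idx[b]]
        ss_within += acc / len(idx)
    ss_among = ss_total - ss_within
    G = len(groups)
    df_a, df_w = G - 1, n - G
    sigma2_w = ss_within / df_w
    n0 = (n - sum(s * s for s in sizes.values()) / n) / df_a
    sigma2_a = (ss_among / df_a - sigma2_w) / n0
    phi = max(sigma2_a, 0.0) / (max(sigma2_a, 0.0) + sigma2_w) if (max(sigma2_a, 0.0) + sigma2_w) > 0 else 0.0
    return ss_among, ss_within, sigma2_a, sigma2_w, phi
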