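"""Shared fixtures: small synthetic studies and their preprocessed forms.

Everything is generated at test time from fixed seeds; session scope keeps
the expensive study simulations to one per suite run.
"""

import numpy as np
import pandas as pd
import pytest

import adiponet as an


@pytest.fixture(scope="session")
def default_study():
    """The reference study shape: 1,000 genes, 5 modules, hubs, regulators."""
    return an.simulate_study(an.SimulationConfig(seed=0))


@pytest.fixture(scope="session")
def default_expression(default_study):
    """Normalized, gender-corrected, SD-filtered expression of the study."""
    counts = an.filter_low_expression(default_study.counts)
    sf = an.size_factors(counts)
    expr = an.normalize(counts, sf, default_study.phenotypes)
    return an.variance_filter(expr, 0.25)


@pytest.fixture(scope="session")
def diffconn_study():
    """Condition-specific blocks only: the differential-connectivity design."""
    return an.simulate_study(
        an.SimulationConfig(seed=0, module_sizes=(), module_trait_cor=(), n_regulators=0)
    )


def make_block_expression(block_sizes, within_cor, n_samples=36, seed=0, n_noise=0):
    """Direct latent-model expression: correlated blocks plus noise genes."""
    rng = np.random.default_rng(seed)
    rows, labels = [], []
    for b, size in enumerate(block_sizes):
        f = rng.standard_normal(n_samples)
        load = np.sqrt(within_cor)
        for _ in range(size):
            rows.append(load * f + np.sqrt(1 - within_cor) * rng.standard_normal(n_samples))
            labels.append(f"B{b + 1}")
    for _ in range(n_noise):
        rows.append(rng.standard_normal(n_samples))
        labels.append("noise")
    expr = pd.DataFrame(
        rows,
        index=[f"g{i + 1:04d}" for i in range(len(rows))],
        columns=[f"s{j + 1:02d}" for j in range(n_samples)],
    )
    return expr, pd.Series(labels, index=expr.index)
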