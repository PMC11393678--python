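"""Shared fixtures: small deterministic datasets and session-scoped benchmark runs."""

import numpy as np
import pytest

from tipscan.circuits import simulate_emt, simulate_toggle, simulate_trifurcating
from tipscan.windows import SplicingCounts, WindowConfig, scan_lineage


@pytest.fixture
def toy_counts() -> SplicingCounts:
    rng = np.random.default_rng(42)
    n, m = 30, 4
    spliced = rng.uniform(0.5, 3.0, size=(n, m))
    unspliced = 0.8 * spliced + rng.normal(0, 0.05, size=(n, m))
    return SplicingCounts(
        unspliced=np.clip(unspliced, 0, None),
        spliced=spliced,
        gene_names=[f"g{i}" for i in range(m)],
        cell_ids=[f"c{i:02d}" for i in range(n)],
        ordering=np.linspace(0, 1, n),
    )


@pytest.fixture(scope="session")
def toggle_lineage():
    """Stochastic toggle-switch benchmark (2000 cells, ramp over 80 time units)."""
    return simulate_toggle(n_traj=50, n_samples=40, seed=1)


@pytest.fixture(scope="session")
def toggle_profile(toggle_lineage):
    cfg = WindowConfig(width=200, increment=50, n_iterations=10, seed=0)
    return scan_lineage(toggle_lineage.counts, cfg)


@pytest.fixture(scope="session")
def emt_lineage():
    """Stochastic tristable-EMT benchmark (3000 cells, 8 genes)."""
    return simulate_emt(n_traj=60, n_samples=50, seed=1)


@pytest.fixture(scope="session")
def emt_profile(emt_lineage):
    cfg = WindowConfig(width=300, increment=60, n_iterations=10, seed=0)
    return scan_lineage(emt_lineage.counts, cfg)


@pytest.fixture(scope="session")
def trifurcating_lineage():
    """Stochastic trifurcating benchmark with per-cell branch labels."""
    return simulate_trifurcating(n_traj=100, n_samples=50, seed=1)
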