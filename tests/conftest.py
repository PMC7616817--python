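import numpy as np
import pandas as pd
import pytest

from polyshock import simulate


@pytest.fixture(scope="session")
def planted_trio():
    """2000-gene simulation with all five classes planted (10% each)."""
    design = simulate.SimDesign(n_genes=2000, seed=0)
    fractions = {c: 0.10 for c in ("ADD", "ELD1", "ELD2", "UP", "DOWN")}
    counts, sheet, truth = simulate.simulate_counts(design, fractions, effect_size=2.0)
    return counts, sheet, truth


@pytest.fixture(scope="session")
def null_sim():
    """2000-gene null simulation (no planted effects)."""
    design = simulate.SimDesign(n_genes=2000, seed=1)
    return simulate.simulate_counts(design, {}, effect_size=2.0)


@pytest.fixture()
def small_counts():
    """Tiny deterministic count matrix with two identical sample groups."""
    rng = np.random.default_rng(42)
    base = rng.integers(5, 500, size=60)
    data = {
        f"s{j}": rng.poisson(base) for j in range(1, 5)
    }
    counts = pd.DataFrame(data, index=[f"g{i:03d}" for i in range(60)])
    counts.index.name = "gene"
    return counts
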