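import numpy as np
import pandas as pd
import pytest

from ssea import FactorialDataset


def make_2x2_dataset(
    cells: dict[tuple[str, str], list[float]],
    unit: str = "u1",
    context: str = "",
    n_trials: int | None = None,
) -> FactorialDataset:
    """Build a one-unit 2x2 dataset from a {(d1, d2): replicates} mapping."""
    rows = []
    for (d1, d2), values in cells.items():
        for i, v in enumerate(values):
            row = {
                "unit": unit,
                "context": context,
                "driver1": d1,
                "driver2": d2,
                "replicate": f"R{i + 1}",
                "response": v,
            }
            if n_trials is not None:
                row["n_trials"] = n_trials
            rows.append(row)
    return FactorialDataset(pd.DataFrame(rows))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def additive_2x2():
    """Noiseless additive cells (1, 2, 3, 4), three replicates each."""
    return make_2x2_dataset(
        {
            ("0", "0"): [1.0] * 3,
            ("a", "0"): [2.0] * 3,
            ("0", "b"): [3.0] * 3,
            ("a", "b"): [4.0] * 3,
        }
    )


@pytest.fixture
def noisy_2x2(rng):
    """Balanced replicated 2x2 with Gaussian noise around distinct cell means."""
    cells = {
        ("0", "0"): 1.0,
        ("a", "0"): 1.8,
        ("0", "b"): 2.4,
        ("a", "b"): 4.1,
    }
    return make_2x2_dataset(
        {k: list(mu + rng.normal(0, 0.3, size=6)) for k, mu in cells.items()}
    )
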