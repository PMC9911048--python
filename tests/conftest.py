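import numpy as np
import pandas as pd
import pytest

from methylwin import Genome, generate_genome


def make_events(position_signals: dict, sample: str = "native") -> pd.DataFrame:
    """Build an event table directly from {position: array of signals}."""
    pos, rid, sig = [], [], []
    i = 0
    for p, vals in position_signals.items():
        for v in np.atleast_1d(vals):
            pos.append(p)
            rid.append(f"{sample}_r{i}")
            sig.append(float(v))
            i += 1
    return pd.DataFrame(
        {
            "position": np.asarray(pos, dtype=np.int64),
            "read_id": rid,
            "sample": sample,
            "signal": np.asarray(sig, dtype=float),
        }
    )


@pytest.fixture(scope="session")
def genome_100k() -> Genome:
    return generate_genome(100_000, 0.5, seed=3)


@pytest.fixture(scope="session")
def genome_20k() -> Genome:
    return generate_genome(20_000, 0.5, seed=8)
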