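from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from minfluxpair import LocalizationTable


def make_table(rows: list[tuple], metadata: dict | None = None) -> LocalizationTable:
    """Build a LocalizationTable from (trace_id, time, x, y, efo, cfr) tuples."""
    df = pd.DataFrame(rows, columns=["trace_id", "time", "x_nm", "y_nm", "efo_hz", "cfr"])
    df = df.astype({"trace_id": np.int64, "time": float, "x_nm": float,
                    "y_nm": float, "efo_hz": float, "cfr": float})
    return LocalizationTable(df=df, metadata=metadata or {})


def random_table(rng: np.random.Generator, n_traces: int = 50,
                 locs_per_trace: int = 6) -> LocalizationTable:
    rows = []
    t = 0.0
    for tid in range(n_traces):
        m = rng.integers(1, locs_per_trace + 1)
        for _ in range(m):
            rows.append((
                tid, t,
                rng.uniform(0, 1000), rng.uniform(0, 1000),
                rng.uniform(0, 100_000), rng.uniform(0, 1.5),
            ))
            t += 0.001
    return make_table(rows)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20_26)
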