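import numpy as np
import pandas as pd
import pytest

from contestkit.prep import MEASURES
from contestkit.simulate import SimulationConfig, simulate_dataset


def make_dyads(durations, winners=None, losers=None, powers=None):
    """Small hand-built dyad table; powers default to 1.0 everywhere."""
    n = len(durations)
    winners = winners if winners is not None else list(range(100, 100 + n))
    losers = losers if losers is not None else list(range(200, 200 + n))
    columns = (["war_id", "winner_state", "loser_state", "duration_days",
                "winner_entry_year", "loser_entry_year"]
               + [f"{role}_{m}" for role in ("winner", "loser")
                  for m in MEASURES])
    rows = []
    for i in range(n):
        row = {"war_id": i + 1, "winner_state": winners[i],
               "loser_state": losers[i],
               "duration_days": int(durations[i]),
               "winner_entry_year": 1900 + i, "loser_entry_year": 1900 + i}
        for m in MEASURES:
            w, l = (powers[i] if powers else (1.0, 1.0))
            row[f"winner_{m}"] = w
            row[f"loser_{m}"] = l
        rows.append(row)
    return pd.DataFrame(rows, columns=columns)


@pytest.fixture(scope="session")
def woa_dyads():
    cfg = SimulationConfig(mode="WOA", n_contests=200, seed=2024)
    dyads, _ = simulate_dataset(cfg)
    return dyads


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
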