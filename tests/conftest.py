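import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=30,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture
def small_otu_table():
    """Hand-sized OTU table with a clear two-group structure."""
    from rumenferm.community import OTUTable
    rng = np.random.default_rng(42)
    base_a = np.array([40, 30, 15, 10, 3, 2], dtype=float)
    base_b = np.array([5, 10, 15, 20, 25, 25], dtype=float)
    counts, meta = [], []
    for i in range(8):
        base = base_a if i < 4 else base_b
        p = base / base.sum()
        counts.append(rng.multinomial(500, p))
        meta.append({"sample_id": f"S{i}", "forage": "GRA" if i < 4 else "HAY",
                     "vitamin_e": "-" if i % 2 == 0 else "+",
                     "time_point": "4h", "inoculum_animal": f"cow{i % 4 + 1}"})
    counts = pd.DataFrame(counts, index=[m["sample_id"] for m in meta],
                          columns=[f"OTU{j}" for j in range(6)])
    return OTUTable(counts, pd.DataFrame(meta).set_index("sample_id"))
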