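import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from triangmr.gwas_io import SummaryStatsTable

settings.register_profile(
    "suite", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_table(rows, trait_label="trait", trait_type="binary"):
    """Build a SummaryStatsTable from a list of per-variant dicts."""
    defaults = {"chrom": "1", "eaf": 0.3, "n": 50_000, "pvalue": 1e-9}
    full = []
    for i, r in enumerate(rows):
        d = dict(defaults)
        d.setdefault("pos", (i + 1) * 100_000)
        d.update(r)
        full.append(d)
    df = pd.DataFrame(full)
    return SummaryStatsTable(trait_label=trait_label, trait_type=trait_type,
                             data=df)


@pytest.fixture
def mk_table():
    return make_table


@pytest.fixture
def simple_pairs():
    """A small clean harmonized frame with exact proportionality 0.3."""
    bx = np.array([0.10, 0.15, 0.20, 0.12, 0.18])
    return pd.DataFrame({
        "variant_id": [f"rs{i}" for i in range(5)],
        "exposure_beta": bx, "exposure_se": np.full(5, 0.01),
        "exposure_eaf": np.full(5, 0.3),
        "outcome_beta": 0.3 * bx, "outcome_se": np.full(5, 0.02),
        "outcome_eaf": np.full(5, 0.3),
    })
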