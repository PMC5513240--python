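import numpy as np
import pandas as pd
import pytest

from niche_coexist.io import Dataset


@pytest.fixture
def toy_sites() -> pd.DataFrame:
    return pd.DataFrame({
        "site_id": ["S1", "S2", "S3", "S4"],
        "position": [0.0, 1.0, 2.0, 3.0],
        "habitat_type": ["pool", "riffle", "pool", "riffle"],
        "substratum": ["cobble", "gravel", "boulder", "cobble"],
        "depth": [1.4, 0.6, 2.0, 0.8],
    })


@pytest.fixture
def toy_counts() -> pd.DataFrame:
    rows = []
    for sid, a, b in [("S1", 5, 1), ("S2", 0, 4), ("S3", 7, 0), ("S4", 2, 3)]:
        rows.append({"site_id": sid, "species": "A", "count": a})
        rows.append({"site_id": sid, "species": "B", "count": b})
    return pd.DataFrame(rows)


@pytest.fixture
def toy_traits() -> pd.DataFrame:
    return pd.DataFrame({
        "species": ["A", "A", "B", "B"],
        "trait": ["mouth_position", "caudal_peduncle_depth"] * 2,
        "value": ["inferior", "4.3", "terminal", "3.5"],
        "trait_type": ["categorical", "quantitative"] * 2,
    })


@pytest.fixture
def toy_dataset(toy_sites, toy_counts, toy_traits) -> Dataset:
    return Dataset(sites=toy_sites, counts=toy_counts, traits=toy_traits)


def two_species_dataset(n_sites: int, rate_a, rate_b, seed: int) -> Dataset:
    """Dataset with two species whose per-site rates are given scalars or
    callables of (depth, is_pool)."""
    rng = np.random.default_rng(seed)
    depth = np.exp(rng.normal(0, 0.5, n_sites))
    is_pool = depth >= 1.0
    sites = pd.DataFrame({
        "site_id": [f"S{i:02d}" for i in range(n_sites)],
        "position": np.arange(n_sites, dtype=float),
        "habitat_type": np.where(is_pool, "pool", "riffle"),
        "substratum": rng.choice(
            ["sand", "gravel", "cobble", "boulder", "bedrock"], n_sites),
        "depth": depth,
    })
    rows = []
    for sp, rate in (("A", rate_a), ("B", rate_b)):
        for i in range(n_sites):
            lam = rate(depth[i], is_pool[i]) if callable(rate) else rate
            rows.append({"site_id": sites["site_id"].iloc[i], "species": sp,
                         "count": int(rng.poisson(lam))})
    return Dataset(sites=sites, counts=pd.DataFrame(rows))
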