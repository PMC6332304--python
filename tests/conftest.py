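import numpy as np
import pandas as pd
import pytest

from eemscreen import SyntheticConfig, SyntheticLibrary, generate_library
from eemscreen.synthlib import ROLE_ACTIVE, ROLE_POOL


@pytest.fixture(scope="session")
def tiny_config() -> SyntheticConfig:
    return SyntheticConfig(
        n_actives=30,
        n_true_inactives=20,
        n_pool=150,
        n_bits={"fp": 96},
        n_scaffolds=2,
        prototype_density=0.15,
        flip_rate_active=0.03,
        flip_rate_inactive=0.05,
        pool_density=0.15,
        descriptor_match_fraction=0.5,
        ambiguous_fraction=0.1,
        seed=11,
    )


@pytest.fixture(scope="session")
def tiny_library(tiny_config) -> SyntheticLibrary:
    return generate_library(tiny_config)


@pytest.fixture(scope="session")
def separable_config() -> SyntheticConfig:
    """Strongly separable benchmark conditions: tight active clusters."""
    return SyntheticConfig(
        n_actives=100,
        n_true_inactives=100,
        n_pool=400,
        n_bits={"fp": 128},
        n_scaffolds=4,
        prototype_density=0.2,
        flip_rate_active=0.03,
        flip_rate_inactive=0.03,
        pool_density=0.2,
        descriptor_match_fraction=0.5,
        ambiguous_fraction=0.0,
        seed=0,
    )


def make_manual_library(active_fp, pool_fp, active_desc=None, pool_desc=None,
                        n_bits=None):
    """Hand-built library: given active and pool fingerprints/descriptors.

    Potencies make every active-candidate active (Ki 10 nM).  Descriptors
    default to a single shared drug-like row so that every pool compound
    passes the descriptor windows.
    """
    active_fp = np.asarray(active_fp, dtype=np.uint8)
    pool_fp = np.asarray(pool_fp, dtype=np.uint8)
    na, npool = len(active_fp), len(pool_fp)
    ids = pd.Index([f"C{i:06d}" for i in range(na + npool)], name="compound_id")
    default = {"logP": 2.0, "MW": 300.0, "HBA": 3, "HBD": 1, "rotB": 4}
    rows = []
    for i in range(na):
        rows.append(dict(default) if active_desc is None else dict(active_desc[i]))
    for i in range(npool):
        rows.append(dict(default) if pool_desc is None else dict(pool_desc[i]))
    descriptors = pd.DataFrame(rows, index=ids)
    potencies = pd.DataFrame(
        {
            "compound_id": ids[:na],
            "measure": ["Ki"] * na,
            "value_nM": [10.0] * na,
        }
    )
    roles = pd.Series([ROLE_ACTIVE] * na + [ROLE_POOL] * npool, index=ids, name="role")
    return SyntheticLibrary(
        fingerprints={"fp": np.vstack([active_fp, pool_fp])},
        descriptors=descriptors,
        potencies=potencies,
        roles=roles,
    )
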