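"""Shared fixtures: desk-scale synthetic datasets and trained settings.

The expensive training fixtures are session-scoped so the learnability and
federation checks share one run.
"""

from __future__ import annotations

import numpy as np
import pytest

from fedceph.federated import FLConfig
from fedceph.harness import ClientData, SettingConfig, TwoClientData, run_setting
from fedceph.synthetic import SynthConfig, generate_records, records_to_arrays

#: desk-scale study conditions: the default two-client configuration
#: (ratios, standards, 856:400 size ratio) scaled to ~300 images total
DESK_FACTOR = 300 / 1256
DESK_SEED = 0
DESK_EPOCHS = 20
DESK_FL = FLConfig(n_rounds=10, local_epochs=5)


@pytest.fixture(scope="session")
def desk_config() -> SynthConfig:
    return SynthConfig(seed=DESK_SEED).scaled(DESK_FACTOR)


@pytest.fixture(scope="session")
def desk_records(desk_config):
    return generate_records(desk_config)


@pytest.fixture(scope="session")
def desk_data(desk_records) -> TwoClientData:
    clients = []
    for cid in ("dicle", "isbi"):
        xtr, ytr = records_to_arrays(desk_records, "train", cid)
        xte, yte = records_to_arrays(desk_records, "test", cid)
        clients.append(ClientData(cid, xtr, ytr, xte, yte))
    return TwoClientData(clients)


@pytest.fixture(scope="session")
def cl_result(desk_data):
    """Centralized training on the merged synthetic clients, 20 epochs."""
    return run_setting(
        SettingConfig(setting="cl", epochs=DESK_EPOCHS, seed=DESK_SEED), desk_data
    )


@pytest.fixture(scope="session")
def ll_result(desk_data):
    return run_setting(
        SettingConfig(setting="ll", epochs=DESK_EPOCHS, seed=DESK_SEED), desk_data
    )


@pytest.fixture(scope="session")
def fl_result(desk_data):
    return run_setting(
        SettingConfig(setting="fl", fl=DESK_FL, seed=DESK_SEED), desk_data
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
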