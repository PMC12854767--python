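import numpy as np
import pytest

from mpakit.spectra import ExcitedStateRecord, SnapshotRecord
from mpakit.synthetic import ChainConfig, EnsembleConfig, make_chain_trajectory, make_ensemble


def single_state_snapshot(energy_ev, fosc=0.0, delta_tpa=0.0, delta_3pa=0.0, time=0.0):
    return SnapshotRecord(
        snapshot_id=0,
        time=time,
        chromophore="LYR-472",
        states=(
            ExcitedStateRecord(
                state_index=1,
                energy=energy_ev,
                oscillator_strength=fosc,
                delta_tpa=delta_tpa,
                delta_3pa=delta_3pa,
            ),
        ),
    )


@pytest.fixture(scope="session")
def small_ensemble():
    records, sidecar = make_ensemble(EnsembleConfig(n_snapshots=100, seed=11))
    return records, sidecar


@pytest.fixture(scope="session")
def small_chain():
    cfg = ChainConfig(n_frames=25, dihedral_sd=12.0, bond_sd=0.012, seed=7)
    return make_chain_trajectory(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
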