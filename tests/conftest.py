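import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240)


@pytest.fixture(scope="session")
def small_session():
    """A compact single-speed session with clean (uncorrupted) spikes."""
    from mukin import SessionConfig, simulate_session

    cfg = SessionConfig(
        ramp_duration=1.0,
        n_trials=3,
        units_per_pool=8,
        rest_duration=1.0,
        snr_db=20.0,
    )
    return simulate_session(cfg, seed=11)


@pytest.fixture(scope="session")
def sparse_noiseless():
    """Few units, widely spaced non-overlapping discharges, no noise.

    Built directly from simulator primitives so spike-triggered averaging
    must recover the generating templates exactly.
    """
    from mukin.simulator import MotorUnitPool, generate_templates, synthesize_emg
    from mukin.types import SpikeTrainSet

    n_units, length, n_samples = 5, 51, 120_000
    pool = MotorUnitPool(
        recruitment_thresholds=np.linspace(0.1, 0.8, n_units),
        territory_centers=np.array([[1.0, 1.0], [2.0, 5.0], [4.0, 3.0], [6.0, 6.0], [6.0, 1.0]]),
    )
    bank = generate_templates(pool, template_length=length, seed=5)
    rng = np.random.default_rng(5)
    trains = {}
    # interleave units on a coarse lattice so no two templates ever overlap
    slot = 0
    spikes_per_unit = 40
    all_slots = []
    for u in range(n_units):
        starts = []
        for k in range(spikes_per_unit):
            starts.append(200 + (slot * 2 * length))
            slot += 1
        trains[u] = np.array(starts, dtype=np.int64)
        all_slots += starts
    assert max(all_slots) + length < n_samples
    spikes = SpikeTrainSet(trains)
    emg = synthesize_emg(spikes, bank, n_samples=n_samples, noise_snr_db=None)
    return emg, spikes, bank
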