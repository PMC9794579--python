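import numpy as np
import pytest

from tdprisk.cell_sim import ReducedMyocyteModel, PacingProtocol, run_paced


@pytest.fixture(scope="session")
def control_model():
    return ReducedMyocyteModel()


@pytest.fixture(scope="session")
def short_protocol():
    return PacingProtocol(cycle_length=2000.0, n_beats=30, output_dt=1.0)


@pytest.fixture(scope="session")
def control_run(control_model, short_protocol):
    """A 30-beat control run; the surrogate reaches its limit cycle within ~5 beats."""
    return run_paced(control_model, short_protocol)


def make_synthetic_beat(cl=2000.0, dt=1.0, apd=250.0, peak=40.0, rest=-85.0):
    """Smooth synthetic AP-like beat used by biomarker oracles."""
    from tdprisk.cell_sim import BeatTrace

    t = np.arange(0.0, cl + dt / 2, dt)
    vm = np.full_like(t, rest)
    up = 10.0
    rise = (t >= up) & (t < up + 2.0)
    vm[rise] = rest + (peak - rest) * (t[rise] - up) / 2.0
    on = (t >= up + 2.0) & (t < up + apd)
    # smooth cosine repolarization
    phase = (t[on] - up - 2.0) / (apd - 2.0)
    vm[on] = rest + (peak - rest) * 0.5 * (1 + np.cos(np.pi * phase))
    cai = np.full_like(t, 1e-4)
    bump = (t >= up) & (t < up + 400.0)
    cai[bump] += 3e-4 * np.sin(np.pi * (t[bump] - up) / 400.0) ** 2
    currents = {
        name: -np.exp(-((t - 100.0) / 80.0) ** 2) * (i + 1) * 0.1
        for i, name in enumerate(
            ("INa", "INaL", "ICaL", "IKr", "IKs", "IK1", "Ito", "INaCa")
        )
    }
    return BeatTrace(beat=1, t=t, vm=vm, cai=cai, currents=currents)


@pytest.fixture
def synthetic_beat():
    return make_synthetic_beat()


@pytest.fixture(scope="session")
def pool_trained_model():
    """CNN trained on the default synthetic pools.

    Printed hyperparameters with the epoch count reduced to 150; shared
    across the training-accuracy and end-to-end evaluation tests because
    cross-validated training dominates the suite's runtime.
    Returns (trained model, test pool).
    """
    from tdprisk.classifier import CnnConfig, assemble_training_set, train
    from tdprisk.synthetic_data import (
        SyntheticClassSpec,
        fixture_drugs,
        gen_variability_pool,
    )

    drugs = fixture_drugs()
    train_drugs = [d for d in drugs if d.split == "train"]
    test_drugs = [d for d in drugs if d.split == "test"]
    spec = SyntheticClassSpec()
    train_pool = gen_variability_pool(train_drugs, spec, 200, 500, seed=10)
    test_pool = gen_variability_pool(test_drugs, spec, 200, 500, seed=11)
    ts = assemble_training_set(train_pool, train_drugs, 50, seed=12)
    model = train(ts, CnnConfig(epochs=150, folds=10, seed=12))
    return model, test_pool
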