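import numpy as np
import pytest
from hypothesis import settings

import calpop

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def two_event_session():
    """One synthetic session with disjoint A/B ensembles at 2 z.

    Returns (raw traces, events, ground truth, z-scored traces,
    epochs A, epochs B) shared read-only across tests.
    """
    cfg = calpop.SessionConfig(
        n_neurons=60,
        duration=700.0,
        seed=11,
        ensembles=[
            calpop.EnsembleSpec("A", 0.2, 2.0),
            calpop.EnsembleSpec("B", 0.2, 2.0),
        ],
        event_schedule=[
            calpop.ScheduleSpec("A", 8, 25.0, 5.0),
            calpop.ScheduleSpec("B", 8, 25.0, 5.0),
        ],
    )
    traces, events, truth = calpop.generate_session(cfg)
    z = calpop.zscore(calpop.compute_dff(traces))
    ep_a = calpop.extract_epochs(z, events, "A")
    ep_b = calpop.extract_epochs(z, events, "B")
    return traces, events, truth, z, ep_a, ep_b


@pytest.fixture()
def toy_epochs():
    """Small hand-built epoch tensor: 3 neurons x 6 trials x 600 frames.

    Neuron 0 responds in the event window [0, 5), neuron 1 ramps only in
    the pre window [-5, 0), neuron 2 is noise.
    """
    rng = np.random.default_rng(42)
    values = rng.normal(0.0, 0.05, size=(3, 6, 600))
    values[0, :, 300:450] += 1.0  # [0, 5) s at 30 FPS, align 300
    values[1, :, 150:300] += 1.0  # [-5, 0) s
    return calpop.EpochTensor(
        values=values,
        pre_s=10.0,
        post_s=10.0,
        frame_rate=30.0,
        neuron_ids=["post_cell", "pre_cell", "flat"],
        trial_event_ids=np.arange(6),
        label="bout",
    )
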