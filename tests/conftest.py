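import numpy as np
import pytest

import strandkinetics as sk

K_GRID = (1e2, 1e3, 1e4, 1e5, 1e6)


def simulate_normalized(k, cond, noise_sd=0.0, seed=0, k_reporter=None):
    """Simulate one experiment (reporter kept fast) and normalize it."""
    duration, dt = sk.observation_window(k, cond.in0)
    spec = sk.TraceSimulationSpec(
        k_displacement=k,
        k_reporter=k_reporter if k_reporter is not None else max(1e3 * k, 1e6),
        conditions=cond, duration=duration, sampling_interval=dt,
        noise_sd=noise_sd, seed=seed,
    )
    wells = sk.simulate_displacement_wells(spec)
    trace = sk.normalize_trace(wells["reaction"], wells["pre_activated"],
                               wells["negative"], conditions=cond)
    return trace, wells, spec


def replicate_fit(k, cond, seed, n_replicates=3, noise_sd=0.01):
    """Independent noisy replicates of one condition, fitted and summarized."""
    traces = []
    for child in np.random.SeedSequence(seed).spawn(n_replicates):
        tr, _, _ = simulate_normalized(
            k, cond, noise_sd=noise_sd,
            seed=int(child.generate_state(1)[0] % 2**31))
        traces.append(tr)
    return sk.fit_replicates(traces, cond)


@pytest.fixture
def regime_a():
    return sk.regime_a()


@pytest.fixture
def regime_b():
    return sk.regime_b()
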