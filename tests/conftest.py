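import numpy as np
import pytest

from hgalpha.containers import EpochedRecording
from hgalpha.simulate import SimulationParams, simulate_dataset


def tiny_params(**overrides) -> SimulationParams:
    """Small but complete simulation: 2 hemispheres, few trials/contacts."""
    defaults = dict(n_hemispheres=2, n_trials_per_condition=6,
                    n_click_trials_per_rate=8, n_pmhg=2, n_alhg=2, n_other=3,
                    seed=7)
    defaults.update(overrides)
    return SimulationParams(**defaults)


@pytest.fixture(scope="session")
def tiny_dataset():
    return simulate_dataset(tiny_params())


def sinusoid_epochs(freq: float, amps, n_trials: int = 8,
                    sample_rate: float = 1000.0,
                    span: tuple[float, float] = (-1.5, 6.3),
                    noise_sd: float = 0.0, seed: int = 0,
                    phase_fn=None, durations=None) -> EpochedRecording:
    """Single-contact sinusoid trials with a time-varying amplitude profile.

    ``amps`` is either a scalar or a callable t -> amplitude envelope.
    """
    rng = np.random.default_rng(seed)
    n = int(round((span[1] - span[0]) * sample_rate))
    times = span[0] + np.arange(n) / sample_rate
    env = amps(times) if callable(amps) else float(amps)
    trials = []
    for i in range(n_trials):
        phase = phase_fn(i) if phase_fn is not None else rng.uniform(0, 2 * np.pi)
        x = env * np.sin(2 * np.pi * freq * times + phase)
        if noise_sd:
            x = x + noise_sd * rng.standard_normal(n)
        trials.append(x[None, :])
    return EpochedRecording(np.stack(trials), sample_rate, times,
                            np.array(["clear"] * n_trials), np.array(["c0"]),
                            sentence_durations=None if durations is None
                            else np.asarray(durations, float))
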