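import warnings

import numpy as np
import pytest

import driftlearn as dl

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def small_model_a_table():
    """2 subjects x 4 days x 98 trials simulated under the constant model."""
    spec = dl.ModelSpec("A", n_days=4, trials_per_day=98)
    design = dl.generate_design(2, 4, 98, per_level=14, seed=11)
    truth = dl.sample_ground_truth(spec, 2, seed=12,
                                   config=dl.PopulationConfig(contaminant_rate=0.0))
    table = dl.simulate_trials(design, truth, spec, seed=13)
    return spec, truth, table


@pytest.fixture(scope="session")
def param_sets():
    """Plausible Wiener parameter sets spanning the fitting range."""
    rng = np.random.default_rng(7)
    sets = []
    for _ in range(20):
        sets.append((
            float(rng.uniform(-2.5, 2.5)),      # v
            float(rng.uniform(0.6, 2.8)),       # a
            float(rng.uniform(0.2, 0.8)),       # z
            float(rng.uniform(0.05, 0.4)),      # t0
        ))
    return sets
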