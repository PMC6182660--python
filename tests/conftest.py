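import numpy as np
import pytest

import plasmasig as ps


@pytest.fixture(scope="session")
def thresholds():
    return ps.Thresholds()


@pytest.fixture(scope="session")
def cross_study():
    """Default-size cross-sectional study (four cohorts, 163 samples)."""
    return ps.generate_cross_sectional(ps.SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def trial_study():
    """Default-size trial study (54 treated, 20 placebo) with expression."""
    return ps.generate_trial(ps.SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def trial_endpoints(trial_study, thresholds):
    return ps.compute_endpoints(trial_study.clinical, thresholds)


@pytest.fixture(scope="session")
def trial_truth_scores(trial_study):
    """Index scores taken from the planted truth (one per baseline sample)."""
    return [ps.IndexScore(f"{p}_m0", v)
            for p, v in sorted(trial_study.truth.index.items())]


def make_matrix(values, probe_prefix="P", sample_prefix="S"):
    values = np.asarray(values, dtype=float)
    probes = [f"{probe_prefix}{i}" for i in range(values.shape[0])]
    samples = [f"{sample_prefix}{j}" for j in range(values.shape[1])]
    return ps.ExpressionMatrix(probes, samples, values)


@pytest.fixture
def tiny_matrix():
    return make_matrix([[1.0, 2.0], [3.0, 4.0]])
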