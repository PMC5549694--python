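"""Shared fixtures: the frozen synthetic benchmark and its trained pipeline.

Session-scoped so the full-resolution cohort is generated and fitted once.
"""

import numpy as np
import pytest

from lymphospec import synthetic_data as sd
from lymphospec import workflow as wf
from lymphospec.spectra_io import AcquisitionParams


@pytest.fixture(scope="session")
def benchmark_cohort():
    return sd.default_benchmark()


@pytest.fixture(scope="session")
def benchmark_train(benchmark_cohort):
    design = wf.StudyDesign(benchmark_cohort.train_ids, benchmark_cohort.test_ids)
    return wf.run_train(benchmark_cohort.spectra, benchmark_cohort.labels, design)


@pytest.fixture(scope="session")
def benchmark_blinded(benchmark_cohort, benchmark_train):
    report, pred = wf.run_blinded_test(
        benchmark_train,
        benchmark_cohort.spectra,
        benchmark_cohort.labels,
        benchmark_cohort.test_ids,
    )
    return report, pred


@pytest.fixture(scope="session")
def small_acquisition():
    """Reduced-resolution axis for multi-cohort simulations."""
    return AcquisitionParams(n_points=4096)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240915)
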