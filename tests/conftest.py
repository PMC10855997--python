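import pytest

from oculopheno import (DetectionParams, TaskSpec, TraceParams,
                        make_default_config, simulate_cohort,
                        simulate_saccade_trace, zscore_metrics)


@pytest.fixture(scope="session")
def midsize_cohort():
    """A moderate labelled cohort shared across statistical tests."""
    cfg = make_default_config(400, 400, seed=11)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def midsize_zscores(midsize_cohort):
    m = midsize_cohort.metrics
    return zscore_metrics(m[m.group != "control"], m[m.group == "control"])


@pytest.fixture(scope="session")
def clean_vg_trace():
    """Noiseless visually guided recording with a known planted latency."""
    spec = TaskSpec("VG", 6)
    params = TraceParams(latency_ms=200.0, latency_sd=0.0, noise_sd=0.0,
                         fep_frac_sd=0.0)
    return simulate_saccade_trace(spec, params, seed=3)


@pytest.fixture
def exact_detection():
    """Detection without smoothing, for sample-exact round trips."""
    return DetectionParams(smoothing_halfwidth_samples=0)
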