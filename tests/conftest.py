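import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from ferrodecay.core import CountMatrix, ProbeInfo, SampleInfo
from ferrodecay.normalization import (
    NormalizationConfig,
    estimate_attenuation_factor,
    normalize_pipeline,
)
from ferrodecay.simulate import HK_PROBE, DesignSpec, default_panel, simulate_experiment

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


def make_matrix(values, probe_classes=None, treatments=None, times=None,
                plates=None, ref_flags=None, attenuated=None, stage="raw"):
    """Small count-matrix builder for unit tests.

    ``values``: 2-D array (probes x samples).  Per-probe and per-sample
    attributes default to endogenous probes / low-iron ST samples.
    """
    values = np.asarray(values, dtype=float)
    n_probes, n_samples = values.shape
    probe_classes = probe_classes or ["endogenous"] * n_probes
    treatments = treatments or ["low"] * n_samples
    times = times if times is not None else [0.0] * n_samples
    plates = plates or ["P1"] * n_samples
    ref_flags = ref_flags or [False] * n_samples
    attenuated = attenuated or [False] * n_probes
    probes = [
        ProbeInfo(
            probe_id=f"G{i}", gene_name=f"G{i}", probe_class=probe_classes[i],
            attenuated=attenuated[i],
            attenuation_factor=10.0 if attenuated[i] else 1.0,
        )
        for i in range(n_probes)
    ]
    samples = [
        SampleInfo(
            sample_id=f"S{j}", treatment=treatments[j], time_min=float(times[j]),
            experiment="ST", plate=plates[j], lane=f"L{j}", replicate=1,
            is_reference_lane=ref_flags[j],
        )
        for j in range(n_samples)
    ]
    return CountMatrix(
        values=pd.DataFrame(values, index=[p.probe_id for p in probes],
                            columns=[s.sample_id for s in samples]),
        probes=probes, samples=samples, stage=stage,
    )


@pytest.fixture(scope="session")
def sim_run():
    """A default simulated run (seed 7): raw matrix, titration, truth."""
    design = DesignSpec(seed=7)
    return simulate_experiment(design, default_panel())


@pytest.fixture(scope="session")
def normalized_run(sim_run):
    """The simulated run pushed through the full normalization pipeline."""
    matrix, titration, truth = sim_run
    config = NormalizationConfig(
        hk_probe=HK_PROBE,
        attenuation_factors=estimate_attenuation_factor(titration),
    )
    normalized, audit = normalize_pipeline(matrix, config)
    return normalized, audit, truth
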