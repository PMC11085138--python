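import numpy as np
import pytest
from hypothesis import settings

import phycobatch as pb
from phycobatch.growth import BiomassConversion, SegmentationConfig

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

#: Worked-example sensor-correction constants used across the suite.
FIG8_A, FIG8_B = 1.795, 0.934


@pytest.fixture(scope="session")
def fig8_model() -> pb.CalibrationModel:
    return pb.CalibrationModel(a=FIG8_A, b=FIG8_B, label="worked-example")


@pytest.fixture(scope="session")
def mu_batch():
    """Seeded photoautotrophic batch anchored to an initial rate of 0.15/h."""
    spec = pb.load_preset("mu_reference", seed=11)
    return pb.simulate_batch(spec)


def replicate_mean_corrected(batch) -> pb.ODTimeSeries:
    """Correct each sensor replicate and average, as the pipeline does."""
    corr = [pb.correct_od(s.values, batch.spec.calibration) for s in batch.od_sensor]
    return pb.ODTimeSeries(times=batch.times, values=np.mean(corr, axis=0),
                           space="corrected", channel="mean")


@pytest.fixture(scope="session")
def light_scan():
    """Growth estimates of one simulated strain at four incident intensities.

    mu_max is anchored at the reference intensity, so only I0 varies —
    emulating one species measured across the tested light range.
    """
    out = {}
    for I0 in (100.0, 300.0, 500.0, 700.0):
        spec = pb.load_preset("light_scan", seed=3, I0=I0)
        batch = pb.simulate_batch(spec)
        mean = replicate_mean_corrected(batch)
        est = pb.analyze_growth(mean, BiomassConversion(k=spec.conversion_k),
                                SegmentationConfig())
        out[I0] = est
    return out
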