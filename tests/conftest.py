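import numpy as np
import pytest

from ssirchrom import PipelineConfig, SampleRun, build_grid
from ssirchrom.simulate import SimConfig, generate

# Table of printed enrichment outcomes for the 56-cork study: per variable,
# (samples selected by the enriching level, in-class members among them,
# enriched class) with the published p-value.  N=56 samples, 28 per class.
CORK_N, CORK_K = 56, 28
CORK_VARIABLES = {
    1: (29, 27, 1, 1.4e-12),
    2: (33, 28, 1, 3.1e-11),
    3: (23, 23, 1, 3.1e-11),
    4: (23, 23, 1, 3.1e-11),
    5: (29, 25, 1, 9.3e-9),
    6: (16, 16, 1, 7.3e-7),
    7: (43, 28, 1, 2.0e-5),
    8: (41, 27, 1, 7.1e-5),
    9: (11, 11, 1, 1.4e-4),
    10: (11, 11, 1, 1.4e-4),
    11: (10, 10, 1, 3.7e-4),
    12: (10, 10, 0, 3.7e-4),
    13: (13, 12, 0, 4.7e-4),
}


@pytest.fixture(scope="session")
def paper_grid():
    """The default analysis grid: 6-17 min in 20 s steps x 49-170 amu in
    0.5 amu windows."""
    return build_grid(6.0, 17.0, 1.0 / 3.0, 49.0, 170.0, 0.5)


@pytest.fixture(scope="session")
def default_config():
    return PipelineConfig()


@pytest.fixture(scope="session")
def small_sim():
    """One 10+10-sample synthetic dataset with the cork marker preset.

    Ten samples per class is the smallest balanced design on which the
    default 5e-4 threshold is attainable with margin: a perfectly aligned
    node reaches 1/C(20,10) ~ 5.4e-6, whereas with 5 per class the floor is
    1/C(10,5) ~ 4e-3 and nothing could ever be selected.
    """
    config = SimConfig(seed=3)
    runs, manifest = generate(config)
    return config, runs, manifest


def make_run(sample_id="s", times=None, mz=None, intensity=None, label=None):
    times = [7.0] if times is None else times
    mz = [95.0] * len(times) if mz is None else mz
    intensity = [10.0] * len(times) if intensity is None else intensity
    return SampleRun(sample_id, np.asarray(times, float),
                     np.asarray(mz, float), np.asarray(intensity, float),
                     label=label)
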