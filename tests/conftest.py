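import numpy as np
import pytest

import specdx as sd

#: Fixed study-condition seed used by the scenario-level tests.
STUDY_SEED = 2023


@pytest.fixture(scope="session")
def young_masked():
    """Default young-stage scenario (control/N/P/S, 40 each), water bands masked."""
    sc = sd.default_scenario("young", n_per_class=40, seed=STUDY_SEED)
    return sd.apply_band_mask(sd.simulate_dataset(sc))


@pytest.fixture()
def tiny_set():
    """Hand-written 3-sample, 5-band set for I/O and preprocessing tests."""
    grid = sd.WavelengthGrid(np.array([500.0, 501.0, 502.0, 503.0, 504.0]))
    refl = np.array(
        [
            [10.0, 11.0, 12.0, 11.5, 10.5],
            [20.0, 21.0, 22.0, 21.5, 20.5],
            [30.0, 31.0, 32.0, 31.5, 30.5],
        ]
    )
    meta = [
        sd.SampleMeta("s1", sd.Treatment.CONTROL, sd.Maturity.YOUNG, 1),
        sd.SampleMeta("s2", sd.Treatment.N_DEF, sd.Maturity.YOUNG, 4, leaf_index=2),
        sd.SampleMeta("s3", sd.Treatment.N_DEF, sd.Maturity.MATURE, 3, replicate=2, trial=2),
    ]
    return sd.SpectraSet(grid=grid, reflectance=refl, meta=meta)
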