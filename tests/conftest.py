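import numpy as np
import pandas as pd
import pytest

from neurofuse.ivim import shell_average
from neurofuse.synthetic import (
    PhantomSpec,
    build_acquisition_scheme,
    generate_phantom,
    simulate_dwi,
)

#: canonical tri-exponential ground truth used throughout the suite
CANONICAL = {"F_p": 0.1, "F_f": 0.2, "F_s": 0.7, "D_p": 2e-2, "D_s": 7e-4}


@pytest.fixture(scope="session")
def scheme():
    return build_acquisition_scheme()


@pytest.fixture(scope="session")
def clean_shells(scheme):
    """Noise-free shell means of the canonical voxel under the full scheme."""
    sig = simulate_dwi(CANONICAL, scheme, noise_model="none", s0=100.0)
    return shell_average(sig, scheme.b_per_volume)


@pytest.fixture(scope="session")
def small_phantom():
    """One-subject phantom on a small grid with its atlas and truth maps."""
    spec = PhantomSpec(shape=(6, 6, 4), n_regions=12, seed=11)
    design = pd.DataFrame([{"subject": "s1", "group": "HC"}])
    truth, atlas = generate_phantom(spec, design)
    return spec, truth["s1"], atlas


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
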