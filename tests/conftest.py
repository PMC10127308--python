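import numpy as np
import pandas as pd
import pytest

from coneseg.phantom import PhantomSpec, generate_phantom
from coneseg.volio import CONE_COLUMNS, ConeTable


def truth_table(phantom) -> ConeTable:
    """Phantom ground truth as a ConeTable (same convention as pipeline output)."""
    t = phantom.truth
    df = pd.DataFrame({
        "id": t["id"], "cx": t["cx"], "cy": t["cy"], "cz": t["cz"],
        "ax": t["ax"], "ay": t["ay"], "az": t["az"],
        "length": t["length"], "radius": t["radius"],
        "size": 1, "nn_dist": np.nan, "status": "valid",
    })[CONE_COLUMNS]
    return ConeTable(df)


@pytest.fixture(scope="session")
def small_phantom():
    """A quick low-curvature phantom (~150 cones) shared across tests."""
    return generate_phantom(PhantomSpec(eye_radius=150.0, cap_half_angle=50.0, seed=3))


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise-free, skew-free phantom for geometric ground-truth checks."""
    return generate_phantom(PhantomSpec(eye_radius=150.0, cap_half_angle=50.0,
                                        noise_sigma=0.0, skew_max=0.0, seed=4))
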