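import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import hemifit as hf

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def ref_params():
    return hf.default_reference_params(seed=0)


@pytest.fixture(scope="session")
def small_table():
    """Reference-noise panel scaled down to 12 lines for fast unit tests."""
    return hf.simulate(hf.default_reference_params(n_lines=12, seed=101))


@pytest.fixture(scope="session")
def ref_table(ref_params):
    """Full 39-line reference panel."""
    return hf.simulate(ref_params, seed=7)


def make_gaussian_std(n_lines, g, s2_dl, s2_r, seed, days=2, nf=7, nm=5):
    """Vial table drawn from the exact Gaussian observation model (identity
    link, no count noise) -- the world the mixed models assume."""
    from hemifit.data import CELLS, CELL_LABELS
    from hemifit.transforms import StandardizedTable

    rng = np.random.default_rng(seed)
    L = rng.multivariate_normal(np.zeros(6), g, size=n_lines)
    rows = []
    for ci, (sex, ratio) in enumerate(CELLS):
        cell = CELL_LABELS[ci]
        nv = nf if sex == "F" else nm
        for d in range(days):
            day = f"{cell}_d{d + 1}"
            dl = rng.normal(0, np.sqrt(s2_dl), n_lines)
            for k in range(n_lines):
                eps = rng.normal(0, np.sqrt(s2_r), nv)
                for v in range(nv):
                    rows.append(
                        (f"L{k:03d}", sex, ratio, day, str(v + 1),
                         L[k, ci] + dl[k] + eps[v])
                    )
    df = pd.DataFrame(
        rows, columns=["line", "sex", "sex_ratio", "day", "vial", "value"]
    )
    lines = [f"L{k:03d}" for k in range(n_lines)]
    return StandardizedTable(df, "scale_center", lines), L


@pytest.fixture(scope="session")
def gaussian_world():
    return make_gaussian_std
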