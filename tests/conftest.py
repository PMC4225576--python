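import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from vitisnet.io_profiles import ProfileMatrix

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


def profile_from_array(
    values,
    metabolites=None,
    cultivar="Cs",
    treatment="IR",
    days=None,
    platform="GC",
):
    """Small ProfileMatrix with auto-generated metadata for unit tests."""
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    metabolites = metabolites or [f"met{j+1}" for j in range(m)]
    ids = [f"s{i+1}" for i in range(n)]
    days = days if days is not None else [1] * n
    meta = pd.DataFrame(
        dict(
            cultivar=[cultivar] * n,
            treatment=[treatment] * n,
            day=days,
            replicate=np.arange(1, n + 1),
        ),
        index=pd.Index(ids, name="sample_id"),
    )
    frame = pd.DataFrame(values, index=meta.index, columns=metabolites)
    return ProfileMatrix(frame, meta, pd.Series(platform, index=metabolites))


@pytest.fixture
def toy_profile():
    return profile_from_array([[10.0, 1.0, 5.0], [20.0, 2.0, 6.0],
                               [30.0, 3.0, 7.0], [40.0, 4.0, 8.0]])


def two_group_profile(ir_values, d_values, metabolite="met1", day=18, cultivar="Cs"):
    """One-metabolite ProfileMatrix with an IR and a D group on one day."""
    ir = np.asarray(ir_values, float)[:, None]
    d = np.asarray(d_values, float)[:, None]
    n_ir, n_d = len(ir), len(d)
    ids = [f"ir{i}" for i in range(n_ir)] + [f"d{i}" for i in range(n_d)]
    meta = pd.DataFrame(
        dict(
            cultivar=[cultivar] * (n_ir + n_d),
            treatment=["IR"] * n_ir + ["D"] * n_d,
            day=[day] * (n_ir + n_d),
            replicate=list(range(1, n_ir + 1)) + list(range(1, n_d + 1)),
        ),
        index=pd.Index(ids, name="sample_id"),
    )
    frame = pd.DataFrame(np.vstack([ir, d]), index=meta.index, columns=[metabolite])
    return ProfileMatrix(frame, meta, pd.Series("GC", index=[metabolite]))
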