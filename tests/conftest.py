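import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from possum_audit import Cohort, default_cohort_spec, generate

settings.register_profile("reproducible", derandomize=True, database=None)
settings.load_profile("reproducible")


def make_frame(ps, os, urgency, died, directly_admitted=None, data_complete=None,
               specialty=None):
    n = len(ps)
    return pd.DataFrame(
        {
            "ps": ps,
            "os": os,
            "urgency": urgency,
            "specialty": specialty or ["general_surgery"] * n,
            "died_30d": died,
            "directly_admitted": directly_admitted or [1] * n,
            "data_complete": data_complete or [1] * n,
        }
    )


@pytest.fixture
def toy_cohort():
    """Six hand-checkable episodes, two deaths."""
    return Cohort(
        make_frame(
            ps=[12, 20, 30, 40, 25, 18],
            os=[6, 10, 15, 20, 12, 8],
            urgency=["elective", "elective", "non_elective", "non_elective",
                     "elective", "non_elective"],
            died=[0, 0, 1, 1, 0, 0],
        ),
        provenance="toy",
    )


@pytest.fixture(scope="session")
def default_cohort():
    """One draw of the packaged synthetic level 1 care ward cohort."""
    return generate(default_cohort_spec())


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20140)
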