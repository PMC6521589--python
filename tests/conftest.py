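import numpy as np
import pandas as pd
import pytest

from chiralpk.cohort import TABLE2_GROUPS, SamplingSchedule
from chiralpk.model import EnantiomerParams


def group_params(group: str) -> EnantiomerParams:
    """Generating mean parameters of one study age group."""
    g = TABLE2_GROUPS[group]
    return EnantiomerParams(
        V_R=g.V_R[0], Cl_R=g.Cl_R[0], Cl_RtoS=g.Cl_RtoS[0],
        V_S=g.V_S[0], Cl_S=g.Cl_S[0],
        ka_R=g.ka_R[0], ka_S=g.ka_S[0], F_R=g.F_R[0], F_S=g.F_S[0],
    )


def records_from_curves(curves, times) -> pd.DataFrame:
    """Long-format record table from {analyte: concentrations} arrays."""
    frames = [
        pd.DataFrame(
            {"analyte": analyte, "time_min": np.asarray(times, float),
             "conc_ug_per_ml": np.asarray(conc, float)}
        )
        for analyte, conc in curves.items()
    ]
    return pd.concat(frames, ignore_index=True)


@pytest.fixture
def schedule() -> SamplingSchedule:
    return SamplingSchedule()


@pytest.fixture(params=list(TABLE2_GROUPS))
def age_group_params(request) -> tuple[str, EnantiomerParams]:
    return request.param, group_params(request.param)
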