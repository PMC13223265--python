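import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from narrative_encoding.containers import GroupTimecourse, RatingPanel

settings.register_profile(
    "ci", derandomize=True, max_examples=50, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


def make_panel(values: dict, question: str = "social", grid_step: float = 1.0,
               attention=None, first_move=None) -> RatingPanel:
    """Panel from {participant: per-timepoint values} on a uniform grid."""
    rows = []
    for pid, vals in values.items():
        vals = np.asarray(vals, float)
        rows.append(
            pd.DataFrame(
                {
                    "participant": pid,
                    "question": question,
                    "trial": "trial-00",
                    "time_s": np.arange(vals.size) * grid_step,
                    "value": vals,
                }
            )
        )
    return RatingPanel(
        ratings=pd.concat(rows, ignore_index=True),
        attention=attention,
        first_move=first_move,
        grid_step=grid_step,
    )


def make_course(median: np.ndarray, grid_step: float = 0.23,
                valid=None) -> GroupTimecourse:
    median = np.asarray(median, float)
    n = median.size
    valid = np.ones(n, bool) if valid is None else np.asarray(valid, bool)
    return GroupTimecourse(
        time_s=np.arange(n) * grid_step,
        median=median,
        mad=np.zeros(n),
        n_valid=np.full(n, 10),
        valid_flag=valid,
        grid_step=grid_step,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
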