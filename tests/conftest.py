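import numpy as np
import pytest

from cortivar.cohort import Cohort, PigRecord
from cortivar.reference import field_study_summaries


def make_cohort(cells: dict[tuple[str, str], list[float]]) -> Cohort:
    """Build a cohort from a {(farm, batch): [hcc, ...]} mapping."""
    records = []
    for (farm, batch), values in cells.items():
        records.extend(
            PigRecord(farm_id=farm, batch_id=batch, pig_id=f"p{i}", hcc=float(v))
            for i, v in enumerate(values)
        )
    return Cohort(records)


@pytest.fixture
def toy_cohort():
    """2 farms x 2 batches x 2 pigs with hand-picked values."""
    return make_cohort(
        {
            ("F1", "1"): [10.0, 12.0],
            ("F1", "2"): [20.0, 26.0],
            ("F2", "1"): [8.0, 9.0],
            ("F2", "2"): [7.0, 11.0],
        }
    )


@pytest.fixture(scope="session")
def field_summaries():
    """The bundled 20-farm reference summary table."""
    return field_study_summaries()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
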