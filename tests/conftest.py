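import pandas as pd
import pytest

from discstager import ObservationSet, load_default_scheme
from discstager.observations import DiscObservation


@pytest.fixture(scope="session")
def scheme():
    return load_default_scheme()


@pytest.fixture
def obs_csv(tmp_path):
    """Factory writing an observation CSV from (disc_id, cond, t, event,
    gene, stage) rows and returning its path."""

    def _write(rows, name="obs.csv"):
        df = pd.DataFrame(
            rows,
            columns=["disc_id", "condition", "time_h", "event", "gene", "stage"],
        )
        path = tmp_path / name
        df.to_csv(path, index=False)
        return path

    return _write


def make_obs(rows):
    """Build an ObservationSet from (disc_id, cond, t, event, {gene: stage})."""
    return ObservationSet(
        discs=[
            DiscObservation(
                disc_id=i, condition=c, time_h=t, event=e, scored=dict(s)
            )
            for i, c, t, e, s in rows
        ]
    )
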