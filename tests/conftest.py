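import numpy as np
import pandas as pd
import pytest

from soilpte import survey_io as sio
from soilpte.synthetic import default_hailun_scenario, generate_survey


@pytest.fixture(scope="session")
def ref():
    return sio.load_reference()


@pytest.fixture(scope="session")
def scenario():
    return default_hailun_scenario()


@pytest.fixture(scope="session")
def survey304(scenario):
    """One 304-sample draw from the default scenario, with ground truth."""
    return generate_survey(scenario, 304, seed=1)


@pytest.fixture(scope="session")
def study_means():
    summary = sio.load_study_summary()
    return summary.loc[list(sio.ELEMENTS), "mean"]


@pytest.fixture
def make_survey():
    """Build a small in-memory survey from per-element concentration lists."""

    def _make(conc: dict[str, list[float]], **meta) -> sio.SurveyTable:
        n = len(next(iter(conc.values())))
        df = pd.DataFrame({
            "sample_id": meta.get("sample_id", [f"S{i}" for i in range(n)]),
            "x": meta.get("x", np.linspace(0.0, 1000.0, n)),
            "y": meta.get("y", np.linspace(0.0, 1000.0, n)),
            "pH": meta.get("pH", [6.5] * n),
        })
        for el in sio.ELEMENTS:
            df[el] = conc.get(el, [1.0] * n)
        return sio.SurveyTable(df)

    return _make
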