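import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")

from reefkit.survey_records import TAXA  # noqa: E402


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def survey_csv(tmp_path):
    """A tiny raw survey table exercising numerics, symbols, and blanks."""
    rows = [
        {
            "record_id": "r1", "site_id": "site01", "substrate": "artificial",
            "year": 2003, "elevation_lwl_m": -2.0, "slope_deg": 45,
            "method": "quadrat", "total": "10",
            "acropora": "+", "pocillopora": "R", "montipora": "4",
            "porites": "3", "faviidae": "0", "millepora": "", "other_hard": "0",
        },
        {
            "record_id": "r2", "site_id": "site02", "substrate": "natural",
            "year": 2004, "elevation_lwl_m": -5.0, "slope_deg": "",
            "method": "spot_check", "total": "20-30",
            "acropora": "12", "pocillopora": "5", "montipora": "R",
            "porites": "0", "faviidae": "0", "millepora": "0", "other_hard": "8",
        },
        {
            "record_id": "r3", "site_id": "site01", "substrate": "artificial",
            "year": 2005, "elevation_lwl_m": -8.0, "slope_deg": 30,
            "method": "manta", "total": "R",
            "acropora": "0", "pocillopora": "0", "montipora": "0",
            "porites": "R", "faviidae": "0", "millepora": "0", "other_hard": "0",
        },
    ]
    path = tmp_path / "survey.csv"
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def make_cover_frame(rng, n=30):
    """Random strictly-positive closed cover rows (proportions) for ordination."""
    raw = rng.dirichlet(np.ones(len(TAXA) + 1) * 0.8, size=n)
    raw = np.clip(raw, 1e-3, None)
    raw /= raw.sum(axis=1, keepdims=True)
    return pd.DataFrame(raw, columns=list(TAXA) + ["other_benthic"])
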