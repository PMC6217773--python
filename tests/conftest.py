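import pandas as pd
import pytest

from ordtreat import (
    build_design,
    compact_model_spec,
    compact_params,
    simulate_dataset,
)


@pytest.fixture
def raw_survey_frame():
    """Five complete raw-survey rows covering every categorical level."""
    return pd.DataFrame(
        {
            "weight_kg": [50.0, 70.0, 92.0, 85.0, 60.0],
            "height_m": [1.80, 1.75, 1.75, 1.70, 1.65],
            "smoker": [0, 1, 0, 1, 0],
            "ff_wholegrain": [1, 3, 7, 2, 4],
            "ff_white": [5, 1, 2, 7, 3],
            "ff_fruit": [2, 2, 6, 1, 7],
            "ff_veg": [3, 1, 2, 5, 2],
            "ff_meat": [3, 2, 4, 1, 7],
            "ff_fried": [6, 3, 7, 2, 5],
            "ff_confect": [3, 4, 1, 7, 2],
            "gender": ["male", "female", "male", "female", "male"],
            "age_band": ["18-29", "30-60", ">60", "30-60", "18-29"],
            "marital": ["single", "married", "divorced/widowed", "married", "single"],
            "residence": ["town", "big city", "village/rural", "town", "big city"],
            "education": [
                "up to secondary",
                "post-secondary",
                "postgraduate",
                "up to secondary",
                "post-secondary",
            ],
            "smoke_prev": [30.1, 20.5, 29.8, 21.2, 31.0],
        }
    )


@pytest.fixture(scope="session")
def compact_design():
    """Moderate simulated sample under the compact design, rho = -0.5."""
    ds, tp = simulate_dataset(4000, compact_params(rho=-0.5, delta=1.0), seed=321)
    return build_design(ds, compact_model_spec()), tp
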