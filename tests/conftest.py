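import numpy as np
import pandas as pd
import pytest

from manateebci import MorphRecord, default_config, generate_population


@pytest.fixture
def small_csv(tmp_path):
    """Three-row fixture file in meters/kilograms, one missing weight."""
    path = tmp_path / "records.csv"
    path.write_text(
        "id,country,location,habitat,sex,sl,ug,w,field_score,pregnant_late,date\n"
        "A1,Belize,Belize,coastal,F,2.60,1.90,330.1,C3,false,2015-03-02\n"
        "A2,Belize,Belize,coastal,M,2.00,1.45,,C3,false,\n"
        "A3,Colombia,Colombia,riverine,F,1.60,1.05,95.0,unscored,false,\n"
    )
    return path


@pytest.fixture
def make_record():
    def _make(**kwargs):
        base = dict(id="X1", habitat="coastal", sex="F",
                    sl_m=2.5, ug_m=1.8, w_kg=300.0, field_score="C3")
        base.update(kwargs)
        return MorphRecord(**base)
    return _make


@pytest.fixture(scope="session")
def clean_population():
    """Moderate-noise study-condition population, no outliers/missingness."""
    cfg = default_config(seed=11).with_cells(
        outlier_fraction=0.0, p_missing_w=0.0, thin_quantile=0.0,
        obese_quantile=1.0)
    return generate_population(cfg)


@pytest.fixture
def isometric_frame():
    """Noise-free population built by isometric scaling of one reference
    animal (SL0=2.0 m, UG0=1.5 m, W0=200 kg; mass scales as s**3)."""
    s = np.linspace(0.8, 1.6, 50)
    return pd.DataFrame({
        "sl_m": 2.0 * s, "ug_m": 1.5 * s, "w_kg": 200.0 * s ** 3,
        "habitat": "coastal", "sex": "F",
    })
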