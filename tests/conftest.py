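import numpy as np
import pandas as pd
import pytest

import normvol as nv


@pytest.fixture(scope="session")
def default_cohort():
    """Seeded default-size cohort with corrected/capped tables and norms."""
    cfg = nv.GeneratorConfig(n_subjects=1200, seed=42)
    table = nv.generate_normative_cohort(cfg)
    corrected = nv.correct_table(table)
    capped, report = nv.cap_outliers(corrected)
    norms = nv.build_age_norms(capped)
    return {
        "config": cfg,
        "table": table,
        "corrected": corrected,
        "capped": capped,
        "report": report,
        "norms": norms,
    }


@pytest.fixture()
def small_config():
    """Small cohort config for fast unit tests (bins hold ~10 subjects)."""
    return nv.GeneratorConfig(n_subjects=150, min_bin_n=5, seed=123)


@pytest.fixture()
def clean_config():
    """Deterministic config: no noise, no outliers, one site, one sex."""
    return nv.GeneratorConfig(
        n_subjects=60,
        n_sites=1,
        site_offsets=(1.0,),
        sex_ticv_ratio=1.0,
        ticv_noise_sd=0.0,
        male_fraction=0.0,
        outlier_fraction=0.0,
        min_bin_n=1,
        seed=5,
    )


@pytest.fixture()
def clean_presets():
    return nv.default_presets(noise_sd=0.0)


@pytest.fixture()
def toy_subject():
    """One wide-table row with three regions, for phantom construction."""
    return pd.Series(
        {
            "subject_id": "s0",
            "age_years": 12.0,
            "ticv_mm3": 1.0e6,
            "roi_a_mm3": 1200.0,
            "roi_b_mm3": 800.0,
            "roi_c_mm3": 500.0,
        }
    )
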