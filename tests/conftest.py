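import numpy as np
import pytest
from hypothesis import settings

import t1std as t

settings.register_profile("ci", deadline=None, derandomize=True,
                          max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def cps4():
    return t.default_cp_definitions()


@pytest.fixture(scope="session")
def scanner_cp():
    return t.ConfounderDef(
        name="scanner", source="0008,1090", representation="categorical",
        reference_value="A",
    )


@pytest.fixture(scope="session")
def paired_scanner_cohort(scanner_cp):
    """Noise-free paired cohort: every subject scanned on scanner A (ref)
    and B, with B injecting exactly +100 ms."""
    records, truth = t.generate_cohort(
        n_subjects=8,
        cps=[scanner_cp],
        categories={"scanner": ["A", "B"]},
        effects=t.EffectSpec(categorical={"scanner": {"B": ("additive", 100.0)}}),
        noise_pixel_sd=0.0,
        maps_per_subject=2,
        seed=11,
    )
    return records, truth


@pytest.fixture(scope="session")
def clean_cohort(cps4):
    """Noise-free 4-CP cohort with identical subject baselines, so every
    deviation from 1150 ms is injected bias."""
    return t.generate_cohort(24, noise_pixel_sd=0.0, base_sd=0.0, seed=3)


@pytest.fixture(scope="session")
def clean_fit(clean_cohort, cps4):
    records, _ = clean_cohort
    setting = t.PipelineSetting("linear", "absolute", "cascaded")
    return t.fit_pipeline(records, setting, cps4)
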