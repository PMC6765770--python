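import pytest

import vegrisk as vr


@pytest.fixture(scope="session")
def tox():
    return vr.default_tox()


@pytest.fixture(scope="session")
def survey_1k():
    """A seeded synthetic survey large enough for stable moment checks."""
    cfg = vr.default_config(seed=101, n_sites=1000)
    return cfg, vr.generate_survey(cfg), vr.generate_population(cfg)


def make_category_samples(metal: str, category_means: dict[str, list[float]]):
    """Samples whose per-category fresh-weight means are exactly as given."""
    samples = []
    i = 0
    for cat, values in category_means.items():
        for v in values:
            i += 1
            samples.append(
                vr.SampleRecord(
                    site_id=f"T{i:03d}",
                    village="V1",
                    veg_species="test",
                    veg_category=cat,
                    soil_conc={metal: 100.0},
                    veg_conc_fw={metal: v},
                )
            )
    return samples
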