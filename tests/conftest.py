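import pytest
from hypothesis import settings as hypothesis_settings

import sgascreen as sga

hypothesis_settings.register_profile("deterministic", derandomize=True,
                                     deadline=None)
hypothesis_settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def clean_screen():
    """Noiseless, artifact-free full-plate screen with planted interactions."""
    truth = sga.generate_truth(376, 0.1, 0.1, seed=7)
    layouts = sga.layout_plates(truth, controls_per_plate=8, seed=1)
    table = sga.simulate_screen(truth, layouts, sga.ArtifactParams.clean(), seed=2)
    return truth, layouts, table


@pytest.fixture(scope="session")
def noisy_screen():
    """Replicated screen with realistic artifacts and 10% multiplicative noise."""
    truth = sga.generate_truth(
        500, 0.1, 0.1, seed=11, suppressor_high=0.3, enhancer_low=1.7
    )
    layouts = sga.replicate_layouts(
        sga.layout_plates(truth, controls_per_plate=16, seed=11), 16
    )
    table = sga.simulate_screen(truth, layouts, sga.ArtifactParams.realistic(), seed=11)
    return truth, layouts, table


@pytest.fixture(scope="session")
def clean_scores(clean_screen):
    truth, _, table = clean_screen
    result = sga.score_table(sga.normalize_plates(table))
    return truth, result


def planted_classes(truth):
    supp = {g for g, c in truth.gene_class.items() if c == "suppressor"}
    enh = {g for g, c in truth.gene_class.items() if c == "enhancer"}
    neutral = {g for g, c in truth.gene_class.items() if c == "neutral"}
    return supp, enh, neutral
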