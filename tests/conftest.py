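import numpy as np
import pytest

from ctanomaly.phantom import desk_scale_config, generate_exam
from ctanomaly.report_ie import load_lexicon


@pytest.fixture(scope="session")
def lexicon():
    return load_lexicon()


@pytest.fixture(scope="session")
def small_exam_batch(lexicon):
    """Twenty desk-scale phantom exams with elevated lesion prevalence."""
    from ctanomaly.schema import ORGAN_CATEGORIES, TARGET_ORGANS

    cfg = desk_scale_config(
        lesion_prevalence={
            o: {c: 0.5 for c in ORGAN_CATEGORIES[o]} for o in TARGET_ORGANS
        }
    )
    rng = np.random.default_rng(42)
    return cfg, [
        generate_exam(cfg, rng, exam_id=f"exam_{i:05d}", lexicon=lexicon)
        for i in range(20)
    ]
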