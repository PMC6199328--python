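import numpy as np
import pytest

from tedeff import scoring
from tedeff.simulate import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort(tmp_path_factory):
    """A reduced cohort (16 samples, 24 genes) for fast per-module tests."""
    cfg = CohortConfig(
        n_samples=24,
        frac_tedeff=0.25,
        n_genes=32,
        frac_at=0.25,
        frac_class1=0.25,
        frac_class2=0.25,
        seed=11,
    )
    return generate_cohort(cfg, str(tmp_path_factory.mktemp("small_cohort")))


@pytest.fixture(scope="session")
def default_cohort(tmp_path_factory):
    """One cohort at the default study conditions (60 samples, 80 genes)."""
    return generate_cohort(CohortConfig(seed=1), str(tmp_path_factory.mktemp("default_cohort")))


def truth_calls(bundle):
    """TEdeff calls taken from the generator's ground truth."""
    return [
        scoring.TEdeffCall(s, 0.0 if lab == "TEdeff" else -2.0, lab)
        for s, lab in bundle.truth["samples"].items()
    ]


def rng(seed=0):
    return np.random.default_rng(seed)
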