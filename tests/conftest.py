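import numpy as np
import pytest

from bifidoprof import profile, synth


@pytest.fixture(scope="session")
def cohort():
    """A small synthetic cohort shared by read-only tests."""
    sim = synth.simulate_cohort(synth.CohortSpec(n_samples=120, seed=7))
    sim["assignments"] = synth.truth_assignments(sim["zotu_species"])
    sim["profile"] = profile.composite_abundance(
        sim["table"], sim["assignments"], sim["bif16s"]
    )
    return sim


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
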