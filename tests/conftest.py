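import hypothesis
import pytest

from lossscan.synthdata import LocusSpec, consensus_profile, make_locus

hypothesis.settings.register_profile(
    "suite", derandomize=True, max_examples=50, deadline=None
)
hypothesis.settings.load_profile("suite")


@pytest.fixture(scope="session")
def functional_locus():
    """A seeded intact seven-exon locus with its model and ground truth."""
    spec = LocusSpec(seed=11)
    locus, model, truth = make_locus(spec)
    return spec, locus, model, truth


@pytest.fixture(scope="session")
def default_profile():
    return consensus_profile(LocusSpec())
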