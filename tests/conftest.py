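import pytest

from isorewire.simulate import generate_dataset, rewiring_scenario


@pytest.fixture(scope="session")
def scenario_dataset():
    """The planted end-to-end scenario: one divergent novel seed, one
    3'-only variant sharing the annotated seed, background loci."""
    config, loci, templates, offsets = rewiring_scenario(rng_seed=1)
    return generate_dataset(config, loci, templates, offsets)
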