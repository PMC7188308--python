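import pytest

from contextflux import (
    ContextSettings,
    ExampleSpec,
    build_example_model,
    contextualize,
    simulate_transcriptome,
)

#: reactions specific to each branch of the example model (enzyme, dedicated
#: transporters and exchanges); used all over to assert pathway selection
GLYCOLYSIS_BRANCH = {"GLYC", "T_GLC", "EX_glc_e"}
STICKLAND_BRANCH = {"STCK", "T_PRO", "T_GLY", "T_AMV", "EX_pro_e", "EX_gly_e", "EX_amv_e"}


@pytest.fixture
def example_model():
    return build_example_model()


@pytest.fixture
def uniform_table(example_model):
    return simulate_transcriptome(example_model, ExampleSpec("uniform"))


@pytest.fixture
def glycolysis_table(example_model):
    return simulate_transcriptome(example_model, ExampleSpec("glycolysis_high"))


@pytest.fixture
def stickland_table(example_model):
    return simulate_transcriptome(example_model, ExampleSpec("stickland_high"))


@pytest.fixture(scope="session")
def stickland_result():
    """Fully sampled Stickland-context run, shared across read-only tests."""
    model = build_example_model()
    table = simulate_transcriptome(model, ExampleSpec("stickland_high"))
    return contextualize(model, table, ContextSettings(n_samples=100, seed=11))


@pytest.fixture(scope="session")
def glycolysis_result():
    model = build_example_model()
    table = simulate_transcriptome(model, ExampleSpec("glycolysis_high"))
    return contextualize(model, table, ContextSettings(n_samples=100, seed=11))
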