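import pytest

from pbpksim.model import BloodPool, ExposureScenario, ModelMetadata, PBPKModel, Tissue
from pbpksim.physiology import build_reference_model, default_scenario


@pytest.fixture(scope="session")
def man_model():
    return build_reference_model("man")


@pytest.fixture(scope="session")
def woman_model():
    return build_reference_model("woman")


@pytest.fixture(scope="session")
def scenario():
    return default_scenario()


@pytest.fixture(scope="session")
def complete_metadata():
    return ModelMetadata(
        model_name="reference_man",
        code_version="2026-01-15 v0.1.0",
        article_citation="doi:10.0000/example-article",
        code_citation="doi:10.0000/example-code",
        authors=(("A. Modeler", "0000-0000-0000-0000", "a.modeler@example.org"),),
        license="CC-BY-4.0",
        sources=("reference physiology compendium", "exemplar chemical parameters"),
        ai_tools_disclosure="none",
    )


def make_model(n_tissues=2, ER=(0.7, 0.0), PC=(1.5, 3.0), BW=73.0,
               V_blood=5.3, QC=6.5, weights=None, flows=None, initial=None):
    """Hand-rolled consistent model builder for property tests: weights and
    flows are chosen so closure holds exactly by construction."""
    if weights is None:
        rest = BW - V_blood
        weights = [rest / n_tissues] * n_tissues
    if flows is None:
        flows = [QC / n_tissues] * n_tissues
    tissues = tuple(
        Tissue(f"tissue{i}", W=weights[i], Q=flows[i], PC=PC[i], ER=ER[i])
        for i in range(n_tissues)
    )
    return PBPKModel(
        BW=BW,
        blood=BloodPool(V_blood=V_blood, W_blood=V_blood, QC=QC),
        tissues=tissues,
        initial_amounts=tuple(initial) if initial else (0.0,) * (n_tissues + 1),
        closure_rtol=1e-9,
        name="synthetic",
    )


@pytest.fixture
def model_factory():
    return make_model
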