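"""Shared fixtures: case-study materials and one cached changeover run."""

import warnings

import pytest

from tabletpress.blend import BlendComposition
from tabletpress.press import PressConfig
from tabletpress.scenarios import build_case_study, case_study_materials, case_study_strength


@pytest.fixture(autouse=True)
def _quiet_material_warnings():
    # the published A60 Kawakita fit extrapolates above the solid density;
    # the warning is asserted explicitly where it matters
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", category=UserWarning, module="tabletpress.materials")
        yield


@pytest.fixture(scope="session")
def materials():
    return case_study_materials()


@pytest.fixture(scope="session")
def kawakita(materials):
    return {m: s.kawakita for m, s in materials.items()}


@pytest.fixture(scope="session")
def recovery(materials):
    return {m: s.recovery for m, s in materials.items()}


@pytest.fixture(scope="session")
def solids(materials):
    return {m: s.solid_density for m, s in materials.items()}


@pytest.fixture(scope="session")
def strength():
    return case_study_strength()


@pytest.fixture
def config():
    return PressConfig()


@pytest.fixture
def pure_a150():
    return BlendComposition.single("A150", "pre")


@pytest.fixture
def pure_a60():
    return BlendComposition.single("A60", "feed")


@pytest.fixture
def blend_50_50():
    return BlendComposition({("A150", "pre"): 0.5, ("A60", "feed"): 0.5})


@pytest.fixture(scope="session")
def case_scenario():
    return build_case_study()


@pytest.fixture(scope="session")
def case_run(case_scenario):
    """One full 25-minute changeover simulation, shared across tests."""
    return case_scenario.run()


@pytest.fixture(scope="session")
def case_frame(case_run):
    return case_run.to_frame()
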