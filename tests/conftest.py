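from pathlib import Path

import pytest
import yaml

from heatwc import (
    AssessmentConfig,
    ScienceConstants,
    generate_fixture_registry,
    load_default_registry,
)

REPO_ROOT = Path(__file__).resolve().parents[1]
DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def constants() -> ScienceConstants:
    return ScienceConstants()


@pytest.fixture(scope="session")
def registry():
    """The synthetic registry bundled with the package."""
    return load_default_registry()


@pytest.fixture()
def tmp_registry_dir(tmp_path):
    generate_fixture_registry(7, 3, tmp_path)
    return tmp_path


@pytest.fixture(scope="session")
def demo_config() -> AssessmentConfig:
    with open(REPO_ROOT / "examples" / "demo_config.yaml") as fh:
        return AssessmentConfig.from_dict(yaml.safe_load(fh))
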