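import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from shotgunlipids.synthetic_data import (
    GeneratorConfig,
    StudyDesign,
    default_species_panel,
    generate_dataset,
)

settings.register_profile(
    "repro",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def panel() -> pd.DataFrame:
    return default_species_panel()


@pytest.fixture(scope="session")
def small_design() -> StudyDesign:
    return StudyDesign(cell_lines=("SH-SY5Y",), n_biological=3, n_technical=2)


@pytest.fixture(scope="session")
def small_panel(panel) -> pd.DataFrame:
    """Sub-panel with the classes needed by every ratio index."""
    keep = ["PC_AA", "PC_AE", "LYSO_PC", "SM", "CER"]
    return panel[panel["lipid_class"].isin(keep)].reset_index(drop=True)


@pytest.fixture(scope="session")
def small_raw(small_design, small_panel) -> pd.DataFrame:
    return generate_dataset(small_design, GeneratorConfig(seed=42), small_panel)
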