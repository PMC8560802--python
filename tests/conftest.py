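import pytest

from interface_atlas.preprocess import normalize_dataset
from interface_atlas.synthio import SynthConfig, generate_cells, generate_spatial


@pytest.fixture(scope="session")
def default_config():
    return SynthConfig(seed=11)


@pytest.fixture(scope="session")
def spatial_data(default_config):
    """One default synthetic spatial dataset, shared across tests."""
    return generate_spatial(default_config)


@pytest.fixture(scope="session")
def cell_data(default_config):
    return generate_cells(default_config, "cell")


@pytest.fixture(scope="session")
def norm_spots(spatial_data):
    spots, _ = spatial_data
    return normalize_dataset(spots)


@pytest.fixture(scope="session")
def norm_cells(cell_data):
    cells, _ = cell_data
    return normalize_dataset(cells)


@pytest.fixture(scope="session")
def null_grid():
    """A grid with no planted spatial structure (null for calibration)."""
    cfg = SynthConfig(seed=23, effect_log2fc=0.0, tumor_umi_multiplier=1.0)
    spots, truth = generate_spatial(cfg)
    return spots, truth, normalize_dataset(spots)
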