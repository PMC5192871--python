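import pytest

import hedgelines as hl


@pytest.fixture(scope="session")
def clean_land():
    """Noise-free, gap-free landscape: classification must be exact."""
    params = hl.LandscapeParams(
        extent=2, seed=42, noise_sd=0.0, gap_fraction=0.0, tree_prob=0.0,
        ditch_prob=0.0, woodland_frac=0.0, urban_frac=0.0,
    )
    return hl.generate_landscape(params)


@pytest.fixture(scope="session")
def clean_masked(clean_land):
    chm = hl.canopy_height(clean_land.dsm, clean_land.dtm)
    return hl.apply_mask(chm, clean_land.landcover, clean_land.dtm)


@pytest.fixture(scope="session")
def default_land():
    """A landscape under the generator's default (noisy, gappy) conditions."""
    return hl.generate_landscape(hl.LandscapeParams(extent=2, seed=5))
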