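import pytest

from ricb.allometry import (
    CarmeanCoefficients,
    jenkins_table,
    read_carmean_table,
    read_species_reference,
)
from ricb.fixtures import FixtureConfig, generate_landscape, write_landscape
from ricb.tiles import augment_and_build_tiles, write_tiles

SEED = 42
MAX_AGE = 300.0


@pytest.fixture(scope="session")
def landscape():
    """Default synthetic landscape: 60x60 grid, 50 plots, ~2000 trees."""
    return generate_landscape(FixtureConfig(seed=SEED))


@pytest.fixture(scope="session")
def carmean_coeffs(landscape):
    return {
        int(r.e_spgrpcd): CarmeanCoefficients(r.b1, r.b2, r.b3, r.b4, r.b5)
        for r in landscape.carmean.itertuples()
    }


@pytest.fixture(scope="session")
def jenkins_coeffs(landscape):
    return jenkins_table(landscape.species_ref)


@pytest.fixture(scope="session")
def tiles(landscape, jenkins_coeffs, carmean_coeffs):
    return augment_and_build_tiles(
        landscape.trees, landscape.plots, jenkins_coeffs, carmean_coeffs, MAX_AGE
    )


@pytest.fixture(scope="session")
def landscape_dir(tmp_path_factory, landscape, tiles):
    """Landscape bundle written to disk, with prebuilt landis tiles."""
    out = tmp_path_factory.mktemp("landscape")
    paths = write_landscape(landscape, out)
    write_tiles(tiles, out / "landis_tiles")
    paths["tiles_dir"] = out / "landis_tiles"
    # round-trip the coefficient tables through their CSV readers once, so
    # the on-disk contract is exercised by every pipeline test
    read_carmean_table(paths["carmean"])
    read_species_reference(paths["species_ref"])
    return paths
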