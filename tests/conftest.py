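import numpy as np
import pytest

from hgcube.genome import GenomeDef, toy_genome
from hgcube.track_store import TrackLoader
from hgcube import fixtures as fx
from hgcube.hgsuite_format import parse_hgsuite


@pytest.fixture(scope="session")
def genome() -> GenomeDef:
    return toy_genome()


@pytest.fixture(scope="session")
def small_genome() -> GenomeDef:
    """Single 10 kb chromosome: small enough for per-base oracles."""
    return GenomeDef("oracle1", (("chr1", 10_000),))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20230719)


@pytest.fixture(scope="session")
def mouse_dir(tmp_path_factory):
    """Mouse preset fixture set (4 genotypes x 4 mutation types)."""
    d = tmp_path_factory.mktemp("mouse")
    fx.make_preset("mouse", d, seed=11)
    return d


@pytest.fixture(scope="session")
def mouse_suite(mouse_dir):
    return parse_hgsuite(mouse_dir / "mutations.gsuite")


@pytest.fixture(scope="session")
def mouse_loader(mouse_dir, genome):
    return TrackLoader(genome, mouse_dir, "points")


@pytest.fixture(scope="session")
def cancer_dir(tmp_path_factory):
    d = tmp_path_factory.mktemp("cancer")
    fx.make_preset("cancer", d, seed=13)
    return d


@pytest.fixture(scope="session")
def cancer_suite(cancer_dir):
    return parse_hgsuite(cancer_dir / "patients.gsuite")


@pytest.fixture(scope="session")
def region_suite(cancer_dir):
    return parse_hgsuite(cancer_dir / "regions.gsuite")


@pytest.fixture(scope="session")
def cancer_loaders(cancer_dir, genome):
    return (TrackLoader(genome, cancer_dir, "points"),
            TrackLoader(genome, cancer_dir, "segments"))
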