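import numpy as np
import pytest

from isopop import (DemographyConfig, Epoch, GenotypeMatrix, MarkerMap,
                    PhasedPanel, make_marker_map, simulate_gene_dropping)


@pytest.fixture
def tiny_map():
    """5 markers on one chromosome, 1 cM = 1 Mb."""
    return MarkerMap(
        chrom=np.array(["1"] * 5, dtype=object),
        ids=np.array([f"rs{i}" for i in range(5)], dtype=object),
        bp=np.array([1_000_000, 2_000_000, 3_000_000, 4_000_000, 5_000_000]),
        cm=np.array([1.0, 2.0, 3.0, 4.0, 5.0]),
        a1=np.array(list("AACCA"), dtype=object),
        a2=np.array(list("GGTTG"), dtype=object),
    )


@pytest.fixture
def tiny_genotypes(tiny_map):
    dos = np.array([
        [0, 1, 2, 1, 0],
        [2, 1, 0, -1, 1],
        [1, 1, 1, 2, 2],
    ], dtype=np.int8)
    return GenotypeMatrix(dos, np.array(["s1", "s2", "s3"], dtype=object),
                          tiny_map, np.array(["P", "P", "Q"], dtype=object))


@pytest.fixture
def tiny_panel(tiny_map):
    haps = np.array([
        [0, 1, 1, 0, 0],
        [1, 0, 1, 1, 0],
        [0, 1, 1, 0, 1],
        [0, 0, 0, 1, 1],
    ], dtype=np.uint8)
    return PhasedPanel(haps, np.array(["s1", "s2"], dtype=object), tiny_map,
                       np.array(["P", "P"], dtype=object))


@pytest.fixture(scope="session")
def isolate_sim():
    """One scaled bottleneck simulation shared across tests.

    151 founders expanding to 2,000 over 12 generations; 30 sampled
    individuals on a 4 x 60 cM genome with ~45 markers/cM.
    """
    mmap = make_marker_map([60.0] * 4, 11_000, spacing="random", seed=7)
    panel, labeling = simulate_gene_dropping(
        DemographyConfig(151, [Epoch(12, 151, 2000)]), mmap,
        n_sample=30, population_label="ISO", seed=7)
    return panel, labeling


@pytest.fixture(scope="session")
def outbred_sim():
    """Large constant-size control on the same kind of map (20 samples)."""
    mmap = make_marker_map([60.0] * 4, 11_000, spacing="random", seed=8)
    panel, labeling = simulate_gene_dropping(
        DemographyConfig(5000, [Epoch(6, 5000)]), mmap,
        n_sample=20, population_label="CTL", seed=8)
    return panel, labeling
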