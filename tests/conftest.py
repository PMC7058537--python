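import numpy as np
import pytest

from tadsv.config import PipelineConfig
from tadsv.hic import Boundary, BoundarySet, ContactMatrix
from tadsv.synthetic import GenomeSpec, plant_boundaries, simulate_hic


@pytest.fixture(scope="session")
def spec_1chrom() -> GenomeSpec:
    return GenomeSpec({"chr1": 20_000_000}, 25_000)


@pytest.fixture(scope="session")
def planted(spec_1chrom):
    """Evenly spaced truth boundaries (centers every 2 Mb)."""
    return plant_boundaries(spec_1chrom)


@pytest.fixture(scope="session")
def tad_map(spec_1chrom, planted):
    """One simulated block-TAD contact map (tau=1, depth 60)."""
    return simulate_hic(spec_1chrom, planted, alpha=1.0, tau=1.0, depth=60.0,
                        seed=11)["chr1"]


@pytest.fixture()
def cfg() -> PipelineConfig:
    return PipelineConfig()


def constant_matrix(n: int = 100, value: float = 5.0,
                    bin_size: int = 25_000) -> ContactMatrix:
    return ContactMatrix("chrT", bin_size, np.full((n, n), value))


def boundary_at(center_bin: int, bin_size: int = 25_000, chrom: str = "chr1",
                source: str = "t") -> Boundary:
    return Boundary(chrom, (center_bin - 1) * bin_size,
                    (center_bin + 2) * bin_size, 1.0, source)
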