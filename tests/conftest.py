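import pytest

from shatterscan import GenomeModel, ScanConfig


@pytest.fixture(scope="session")
def toy_genome() -> GenomeModel:
    """Twelve equal 10-Mbp chromosomes: partner relabeling is symmetric."""
    return GenomeModel(tuple((str(i), 10_000_000) for i in range(1, 13)))


@pytest.fixture(scope="session")
def micro_genome() -> GenomeModel:
    """Three short chromosomes for window-level arithmetic."""
    return GenomeModel((("1", 1000), ("2", 2000), ("3", 1500)))


@pytest.fixture
def micro_scan_config() -> ScanConfig:
    """Window = 5 bins of 10 bp, stepping one bin."""
    return ScanConfig(bin_size=10, window_size=5)
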