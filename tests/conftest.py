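import numpy as np
import pytest

from hetdom.io_formats import GenotypeMatrix, SNPInfo


def make_genotypes(
    rng: np.random.Generator,
    n: int,
    m: int,
    chrom: str = "1",
    spacing_bp: int = 1_000,
    freq_range: tuple[float, float] = (0.1, 0.9),
    missing_rate: float = 0.0,
) -> GenotypeMatrix:
    """Random HWE genotypes on one chromosome, evenly spaced."""
    p = rng.uniform(*freq_range, size=m)
    dos = rng.binomial(2, p, size=(n, m)).astype(np.int8)
    if missing_rate:
        dos[rng.random((n, m)) < missing_rate] = -1
    snps = [SNPInfo(f"{chrom}_s{j}", chrom, (j + 1) * spacing_bp) for j in range(m)]
    return GenotypeMatrix([f"a{i}" for i in range(n)], snps, dos)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_genotypes(rng):
    return make_genotypes(rng, n=12, m=40)
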