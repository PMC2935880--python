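import numpy as np
import pandas as pd
import pytest

from gwaspower.freq_data import SITE_COLUMNS, FrequencyTable, GenotypeData


def make_table(freqs: dict[str, list[float]], alleles=("A", "G")) -> FrequencyTable:
    """Build a FrequencyTable from {panel: [freq_a per SNP]}."""
    n = len(next(iter(freqs.values())))
    frame = pd.DataFrame(
        {
            "snp_id": [f"s{i}" for i in range(1, n + 1)],
            "chrom": "1",
            "pos": range(1, n + 1),
            "allele_a": alleles[0],
            "allele_b": alleles[1],
        }
    )
    for panel, values in freqs.items():
        frame[panel] = np.asarray(values, dtype=float)
    return FrequencyTable(frame=frame, panels=list(freqs), source="synthetic")


@pytest.fixture
def toy_table() -> FrequencyTable:
    return make_table(
        {
            "CEU": [0.05, 0.10, 0.20, 0.00, 0.30],
            "YRI": [0.20, 0.10, 0.05, 0.00, 0.35],
        }
    )


@pytest.fixture
def toy_genotypes() -> GenotypeData:
    """3 SNPs x 20 samples with a deterministic dosage pattern."""
    rng = np.random.default_rng(11)
    sites = pd.DataFrame(
        {
            "snp_id": ["s1", "s2", "s3"],
            "chrom": "1",
            "pos": [1, 2, 3],
            "allele_a": "A",
            "allele_b": "G",
        }
    )[SITE_COLUMNS]
    dosage = rng.integers(0, 3, size=(3, 20)).astype(np.int8)
    samples = [f"ind{j:02d}" for j in range(20)]
    return GenotypeData(sites=sites, dosage=dosage, samples=samples)


@pytest.fixture
def panel_map_20() -> dict[str, str]:
    return {f"ind{j:02d}": ("P1" if j < 10 else "P2") for j in range(20)}
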