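import numpy as np
import pandas as pd
import pytest

from isgscape import peaks as pk
from isgscape import synthetic as syn


@pytest.fixture(scope="session")
def small_spec():
    return syn.SyntheticSpec(
        seed=11,
        segments=[syn.Segment("segA", 40_000), syn.Segment("segB", 30_000)],
        planted_peaks=[
            syn.PlantedPeak("segA", 8_000, 8_640, 4.0, "STAT1", "induced"),
            syn.PlantedPeak("segA", 20_000, 20_640, 4.0, "IRF1", "induced"),
            syn.PlantedPeak("segB", 5_000, 5_640, 4.0, "both", "induced"),
        ],
        planted_motifs=[
            syn.PlantedMotif("segA", 8_300, "+", "STAT1"),
            syn.PlantedMotif("segA", 20_300, "-", "IRF1"),
        ],
        planted_snps=[syn.PlantedSnp("segA", 20_302, "T", "G", "rs_test")],
        gene_templates=[
            syn.GeneTemplate("G001", "segA", 8_500, "+", "es-indISG", known_isg=True),
            syn.GeneTemplate("G002", "segA", 25_000, "-", "resISG", known_isg=True),
            syn.GeneTemplate("G003", "segB", 6_000, "+", "other"),
        ],
    )


def make_matrix(values, spacing=80, probe_len=50, chrom="c1", normalized=False):
    """IntensityMatrix from a (n_probes, n_samples) array on a regular tiling."""
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    probes = pd.DataFrame(
        {
            "probe_id": [f"p{i:04d}" for i in range(n)],
            "chrom": chrom,
            "start": np.arange(n) * spacing,
            "end": np.arange(n) * spacing + probe_len,
        }
    )
    samples = [f"s{j}" for j in range(values.shape[1])]
    return pk.IntensityMatrix(probes, values, samples, normalized=normalized)


@pytest.fixture
def matrix_factory():
    return make_matrix
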