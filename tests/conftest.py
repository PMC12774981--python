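import numpy as np
import pandas as pd
import pytest

from elitepool import DemographyModel, GenomeSpec, HaplotypePanel


@pytest.fixture
def tiny_spec():
    # mutation rate scaled up so a short chromosome still yields enough
    # segregating sites under the small constant-Ne test demography
    return GenomeSpec(
        n_chromosomes=2, sites_per_chromosome=50, physical_length=1e6,
        mutation_rate=2.5e-6,
    )


@pytest.fixture
def constant_demography():
    return DemographyModel(epochs=((0, 100.0),))


def build_panel(haps: np.ndarray, spec: GenomeSpec | None = None) -> HaplotypePanel:
    """Panel from an explicit (n, 2, S) haplotype array, sites evenly spaced."""
    n, _, total = haps.shape
    spec = spec or GenomeSpec(
        n_chromosomes=1, sites_per_chromosome=total, physical_length=1e6
    )
    per = spec.sites_per_chromosome
    frames = []
    for c in range(spec.n_chromosomes):
        pos = np.linspace(1, spec.physical_length, per).astype(int)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": c + 1,
                    "pos": pos,
                    "gpos": pos / spec.physical_length * spec.genetic_length,
                    "ref": "A",
                    "alt": "T",
                }
            )
        )
    sites = pd.concat(frames, ignore_index=True)
    return HaplotypePanel(
        spec=spec,
        haplotypes=haps.astype(np.int8),
        sites=sites,
        ids=[f"ind_{i}" for i in range(n)],
    )


@pytest.fixture
def random_panel():
    """20 diploids, 1 chromosome x 40 sites, random haplotypes."""
    rng = np.random.default_rng(42)
    return build_panel(rng.integers(0, 2, size=(20, 2, 40)))


@pytest.fixture
def homozygous_pair_panel():
    """Two fully homozygous individuals differing at a known set of sites."""
    S = 30
    a = np.zeros((2, S), dtype=np.int8)
    b = np.zeros((2, S), dtype=np.int8)
    b[:, ::3] = 1  # differ at every third site
    return build_panel(np.stack([a, b]))
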