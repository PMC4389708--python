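import numpy as np
import pytest

from agscensus.ags_core import PipelineConfig
from agscensus.align import get_index
from agscensus.simulate import (
    SyntheticMarkerSpec,
    generate_genome,
    generate_marker_families,
)
from agscensus.train import train_model


@pytest.fixture(scope="session")
def tiny_db():
    """Five 120-aa synthetic families: enough for alignment unit tests."""
    return generate_marker_families(
        SyntheticMarkerSpec(n_families=5, ancestral_protein_length=120, seed=11)
    )


@pytest.fixture(scope="session")
def mini_pipeline():
    """A small trained pipeline shared by the integration/property tests.

    Ten 150-aa families, eight 120-250 kb training genomes, one read length
    (100 bp).  Training runs once per session (~1 min) and the returned dict
    carries everything needed to simulate and estimate fresh communities.
    """
    markers = generate_marker_families(
        SyntheticMarkerSpec(n_families=10, ancestral_protein_length=150, seed=21)
    )
    rng = np.random.default_rng([21, 5])
    genomes = [
        generate_genome(
            markers,
            size=int(rng.integers(120_000, 250_000)),
            divergence=0.03,
            seed=int(rng.integers(0, 2**31 - 1)),
            genome_id=f"train{i:02d}",
        )
        for i in range(8)
    ]
    model = train_model(genomes, markers, read_lengths=[100], coverage=10.0, seed=21)
    return {
        "markers": markers,
        "index": get_index(markers),
        "genomes": genomes,
        "model": model,
        "cfg": PipelineConfig(n_reads=1_000_000, read_length=100),
    }
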