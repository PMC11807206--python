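from pathlib import Path

import pytest

import poolscreen as ps

DATA = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def toy_library() -> ps.LibraryDesign:
    return ps.read_manifest(DATA / "toy_library.tsv")


@pytest.fixture(scope="session")
def toy_fastq() -> Path:
    return DATA / "toy_reads.fastq"


@pytest.fixture(scope="session")
def small_library() -> ps.LibraryDesign:
    """40 genes x 4-5 constructs over 5 pools."""
    return ps.design_library(
        n_genes=40, per_gene_min=4, per_gene_max=5, n_pools=5, seed=2
    )


@pytest.fixture(scope="session")
def small_screen(small_library):
    """A neutral screen on the small library, counts level."""
    cfg = ps.SimulationConfig(sequencing_depth=20_000, dispersion=0.1, seed=3)
    ref, trt = ps.simulate_screen_counts(
        small_library, ps.EffectProfile.neutral(small_library), cfg
    )
    return ps.concat_pools([ref, trt], small_library)
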