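import numpy as np
import pytest

from tipscan.synthetic import SimConfig, simulate_pangenome, simulate_reads, simulate_te_library


@pytest.fixture(scope="session")
def small_pangenome():
    """10 planted loci, 6 accessions, error-free 20x reads: shared by the
    genotyping and pipeline tests."""
    cfg = SimConfig(
        seed=11, genome_length=40_000, n_accessions=6, te_count=10,
        insertion_rate=10, te_length_range=(3000, 6000), error_rate=0.0,
    )
    library = simulate_te_library(cfg.te_count, cfg.te_length_range, seed=cfg.seed + 1)
    pg = simulate_pangenome(cfg, library=library)
    reads = {
        acc: simulate_reads(pg.donors[acc]["chr1"], cfg, seed=1000 + i, prefix=f"{acc}_")
        for i, acc in enumerate(pg.donors)
    }
    return cfg, library, pg, reads


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
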