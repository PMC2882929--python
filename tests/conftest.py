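from types import SimpleNamespace

import numpy as np
import pytest

from polysynt.synthetic_data import (
    SimConfig,
    simulate_polyploid_clones,
    simulate_template,
    soft_mask_template,
)


@pytest.fixture(scope="session")
def small_sim():
    """A small but complete simulated study: 2 chromosomes, 4 clones.

    Gene density is raised relative to the genomic default so fragments of a
    clone carry several gene anchors at this scale.
    """
    cfg = SimConfig(
        n_chromosomes=2,
        chrom_length=150_000,
        insert_size_range=(30_000, 45_000),
        grid=(2, 2),
        coverage=8.0,
        gene_density=1 / 4000,
        seed=5,
    )
    seqs, feats, truth = simulate_template(cfg)
    clones = simulate_polyploid_clones(seqs, truth, cfg)
    masked = soft_mask_template(seqs, truth)
    return SimpleNamespace(
        cfg=cfg, seqs=seqs, feats=feats, truth=truth, clones=clones, masked=masked
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
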