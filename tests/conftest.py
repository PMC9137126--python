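import numpy as np
import pandas as pd
import pytest

import pgscreen as pg


@pytest.fixture(scope="session")
def toy_world():
    """Small genome + annotation shared by design-level tests."""
    cfg = pg.SimConfig(seed=11, pc_genes_per_class=2, lnc_genes_per_class=1)
    genome, models = pg.make_toy_annotation(cfg)
    return cfg, genome, models


@pytest.fixture(scope="session")
def ot_index(toy_world):
    _, genome, _ = toy_world
    return pg.OffTargetIndex(genome)


@pytest.fixture(scope="session")
def small_library():
    return pg.make_random_library(n_targets=12, designs_per_target=5, seed=21)


@pytest.fixture(scope="session")
def clean_screen(small_library, tmp_path_factory):
    """Error-free, spike-free screen: reads on disk plus the truth counts."""
    cfg = pg.SimConfig(seed=21, depth=40, error_rate=0.0)
    outdir = tmp_path_factory.mktemp("clean_screen")
    sheet, truth, folds = pg.make_screen_reads(small_library, cfg, outdir)
    return cfg, sheet, truth, folds


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))
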