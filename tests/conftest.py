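import numpy as np
import pandas as pd
import pytest

import synlet as sl


@pytest.fixture(scope="session")
def small_cohort():
    """A desk-scale cohort with one strongly planted pathway."""
    cfg = sl.CohortSimConfig(
        n_samples=120,
        n_genes=900,
        pathways=(sl.PathwaySpec("PLANT", 30, 0.9),),
        n_null_pathways=6,
        null_pathway_size=15,
        seed=11,
    )
    return sl.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_screen():
    """A small screen with one planted RSL group over background."""
    cfg = sl.ScreenSimConfig(
        n_background_genes=2000,
        groups=(
            sl.ScreenGroup(
                "RSLGRP", 300, (sl.MixtureComponent(1.0, float(np.log(1.34)), 0.10),)
            ),
        ),
        seed=5,
    )
    return sl.simulate_screen(cfg)


@pytest.fixture()
def toy_counts(tmp_path):
    path = tmp_path / "counts.tsv"
    df = pd.DataFrame(
        {"s1": [10, 90, 400], "s2": [30, 270, 1200]},
        index=pd.Index(["g1", "g2", "g3"], name="gene_id"),
    )
    df.to_csv(path, sep="\t")
    return path
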