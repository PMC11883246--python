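import numpy as np
import pandas as pd
import pytest

import screenfate as sf


@pytest.fixture(scope="session")
def small_null_screen():
    """A no-effect screen: knockdown 1.0, no fate effects."""
    config = sf.SimulationConfig(
        n_cells=500,
        n_clusters=6,
        n_target_genes=4,
        guides_per_gene=2,
        n_background_genes=20,
        knockdown_fraction=1.0,
        seed=42,
    )
    dataset, truth = sf.simulate_screen(config)
    return config, dataset, truth


@pytest.fixture(scope="session")
def small_kd_screen():
    """A screen with strong (80%) knockdown of every target."""
    config = sf.SimulationConfig(
        n_cells=500,
        n_clusters=6,
        n_target_genes=4,
        guides_per_gene=2,
        n_background_genes=20,
        knockdown_fraction=0.2,
        seed=7,
    )
    dataset, truth = sf.simulate_screen(config)
    return config, dataset, truth


@pytest.fixture(scope="session")
def null_assignments(small_null_screen):
    _, dataset, _ = small_null_screen
    return sf.filter_ambient(dataset.guide_umi_frame(), dataset.library)


@pytest.fixture
def single_guide_library():
    return sf.GuideLibrary(
        pd.DataFrame(
            {"guide_id": ["g1"], "target_gene": ["GENEA"], "scramble": [False]}
        )
    )


@pytest.fixture
def toy_assignments():
    """Three guides over two clusters with hand-countable occupancy."""
    library = sf.GuideLibrary(
        pd.DataFrame(
            {
                "guide_id": ["g1", "g2", "scr"],
                "target_gene": ["A", "B", None],
                "scramble": [False, False, True],
            }
        )
    )
    cells = [f"c{i}" for i in range(10)]
    umis = np.zeros((10, 3), dtype=int)
    umis[[0, 1], 0] = 50  # g1 in c0, c1 (cluster x)
    umis[[5, 6, 7], 1] = 50  # g2 in c5..c7 (cluster y)
    umis[[0, 5], 2] = 50  # scr in c0, c5
    frame = pd.DataFrame(umis, index=cells, columns=library.guide_ids)
    assignments = sf.filter_ambient(frame, library)
    clusters = pd.Series(
        ["x"] * 5 + ["y"] * 5, index=cells, name="cluster"
    )
    return assignments, clusters
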