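import numpy as np
import pandas as pd
import pytest

import beescape as b

NINE_WEIGHTS = {
    "wind": 0.30, "flowering_annual": 0.15, "grassland": 0.20, "forest": 0.20,
    "perennial_flowering": 0.02, "wetland": 0.04, "suburb": 0.05,
    "city": 0.02, "other": 0.02,
}

MARGINAL = {"grassland": 0.55, "wind": 0.25, "flowering_annual": 0.25}


def make_spec(**overrides) -> b.LandscapeSpec:
    kwargs = dict(n_rows=200, n_cols=200, cell_size=100.0,
                  class_weights=dict(NINE_WEIGHTS),
                  marginal_fraction_by_class=dict(MARGINAL),
                  patchiness=600.0, seed=7)
    kwargs.update(overrides)
    return b.LandscapeSpec(**kwargs)


@pytest.fixture(scope="session")
def landscape() -> b.Landscape:
    return b.generate_landscape(make_spec())


@pytest.fixture(scope="session")
def survey_setup(landscape):
    """Sites, buffer proportions and a survey table on the session landscape."""
    sites = b.generate_sites(landscape, 8, 2000.0, seed=11, edge_margin=1500.0)
    props = b.class_proportions_at_points(landscape, sites, 1500.0)
    surveys = b.generate_surveys(sites, props, b.TruthParams(), seed=11)
    return sites, props, surveys


def surveys_from_matrix(matrix: np.ndarray, sites=None, species=None) -> pd.DataFrame:
    """One-visit survey table realizing an exact site x species count matrix."""
    matrix = np.asarray(matrix)
    sites = sites or [f"S{i + 1:02d}" for i in range(matrix.shape[0])]
    species = species or [f"sp{j + 1}" for j in range(matrix.shape[1])]
    rows = [
        (site, 1, sp, int(matrix[i, j]))
        for i, site in enumerate(sites)
        for j, sp in enumerate(species)
    ]
    return pd.DataFrame(rows, columns=["site_id", "visit", "species", "count"])
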