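import numpy as np
import pandas as pd
import pytest

from batsig import (
    CellTypeSimConfig,
    ExpressionMatrix,
    MarkerGroup,
    TissuePanelSimConfig,
    generate_cell_type_profiles,
    generate_tissue_panel,
)

SMALL_GROUPS = {
    MarkerGroup.WHITE: 5,
    MarkerGroup.BEIGE_ONLY: 5,
    MarkerGroup.COMMON_BROWN: 5,
    MarkerGroup.CLASSICAL_ONLY: 5,
}


@pytest.fixture
def noise_free_profiles():
    """Three-condition matrix with planted groups and no replicate noise."""
    cfg = CellTypeSimConfig(
        n_genes=30, planted_groups=dict(SMALL_GROUPS), fold_effect=10.0,
        noise_cv=0.0, baseline_mean=100.0, seed=11,
    )
    return generate_cell_type_profiles(cfg)


@pytest.fixture
def tissue_panel():
    """15-tissue panel with a strong beige factor (λ=0.9, σ=0.3)."""
    cfg = TissuePanelSimConfig(n_tissues=15, beige_loading=0.9, noise_sd=0.3, seed=5)
    return generate_tissue_panel(cfg)


@pytest.fixture
def tiny_matrix():
    """Hand-built 3-gene, 5-sample matrix for direct arithmetic checks."""
    values = pd.DataFrame(
        {
            f"S{i+1}": col
            for i, col in enumerate(
                np.array(
                    [
                        [1.0, 2.0, 3.0, 4.0, 5.0],
                        [2.0, 4.0, 6.0, 8.0, 10.0],
                        [5.0, 4.0, 3.0, 2.0, 1.0],
                    ]
                ).T
            )
        },
        index=["GA", "GB", "GC"],
    )
    samples = pd.DataFrame(
        {"tissue": ["t"] * 5}, index=pd.Index([f"S{i+1}" for i in range(5)], name="sample_id")
    )
    return ExpressionMatrix(values=values, samples=samples)
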