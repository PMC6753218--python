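import numpy as np
import pandas as pd
import pytest

from epipanel.depth import DepthMatrix, PanelDesign, TargetExon


@pytest.fixture
def toy_design() -> PanelDesign:
    """Three adjacent exons of one gene plus a two-exon second gene."""
    return PanelDesign([
        TargetExon("GENEA", 1, "chr1", 100, 200),
        TargetExon("GENEA", 2, "chr1", 200, 300),
        TargetExon("GENEA", 3, "chr1", 400, 500),
        TargetExon("GENEB", 1, "chr2", 100, 350),
        TargetExon("GENEB", 2, "chr2", 1000, 1500),
    ])


@pytest.fixture
def random_matrix() -> pd.DataFrame:
    """Seeded 8-exon x 5-sample RPKM-like matrix."""
    rng = np.random.default_rng(42)
    return pd.DataFrame(
        rng.uniform(1, 100, size=(8, 5)),
        index=[f"G|{i}" for i in range(1, 9)],
        columns=[f"S{i}" for i in range(1, 6)],
    )


@pytest.fixture
def toy_depth(toy_design) -> DepthMatrix:
    counts = pd.DataFrame(
        {
            "S1": [1000, 500, 200, 50, 0],
            "S2": [900, 450, 180, 40, 10],
        },
        index=toy_design.keys,
    )
    return DepthMatrix(counts, pd.Series({"S1": 10_000_000, "S2": 2_000_000}))
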