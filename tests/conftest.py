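import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from gutnet.abundance import CountTable, TaxonLineage

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")


def make_table(counts: dict[str, list[int]], phyla: dict[str, str] | None = None,
               samples: list[str] | None = None) -> CountTable:
    """Small CountTable helper: genus -> per-sample counts."""
    phyla = phyla or {}
    frame = pd.DataFrame(counts).T
    frame.columns = samples or [f"S{i + 1}" for i in range(frame.shape[1])]
    frame.index.name = "taxon_id"
    lineages = {
        g: TaxonLineage(g, {"kingdom": "Bacteria",
                            "phylum": phyla.get(g, "Firmicutes"),
                            "genus": g})
        for g in counts
    }
    return CountTable(frame, lineages)


@pytest.fixture
def small_table() -> CountTable:
    return make_table(
        {
            "Prevotella": [30, 5, 1],
            "Bacteroides": [5, 40, 2],
            "Faecalibacterium": [10, 10, 20],
            "Oscillospira": [5, 5, 30],
            "Streptococcus": [0, 0, 7],
        },
        phyla={
            "Prevotella": "Bacteroidetes",
            "Bacteroides": "Bacteroidetes",
        },
    )


def random_distance_matrix(n: int, rng: np.random.Generator):
    """Random Euclidean-style distance matrix (symmetric, zero diagonal)."""
    pts = rng.random((n, 3))
    d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
    return d
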