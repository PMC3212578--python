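"""Shared fixtures: tiny hand-built matrices and seeded synthetic datasets."""

import numpy as np
import pandas as pd
import pytest

from arscore import GeneratorConfig, generate
from arscore.containers import GeneSetCollection


@pytest.fixture
def tiny_matrix() -> pd.DataFrame:
    """3 genes x 2 samples with simple integer values."""
    return pd.DataFrame(
        [[1.0, 4.0], [2.0, 5.0], [3.0, 6.0]],
        index=pd.Index(["A", "B", "C"], name="gene_id"),
        columns=["s1", "s2"],
    )


@pytest.fixture
def rank10_sample() -> pd.Series:
    """A 10-gene sample whose values already equal their ranks (1..10)."""
    genes = [f"g{i}" for i in range(1, 11)]
    return pd.Series(np.arange(1.0, 11.0), index=genes)


@pytest.fixture
def small_sets() -> GeneSetCollection:
    return GeneSetCollection(
        {
            "top3": ["g8", "g9", "g10"],
            "bottom3": ["g1", "g2", "g3"],
            "all": [f"g{i}" for i in range(1, 11)],
        }
    )


@pytest.fixture(scope="session")
def default_dataset():
    """One draw from the generator under its default study conditions."""
    return generate(GeneratorConfig(n_genes=1500, n_pathways=30, seed=7))


def make_gmt(tmp_path, lines):
    path = tmp_path / "sets.gmt"
    path.write_text("\n".join(lines) + "\n")
    return path


def null_activity(n_pathways: int, n_samples: int, seed: int) -> pd.DataFrame:
    """Exchangeable-noise activity matrix (no structure at all)."""
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        rng.normal(0.5, 0.05, size=(n_pathways, n_samples)),
        index=[f"PW{i:03d}" for i in range(n_pathways)],
        columns=[f"s{j}" for j in range(n_samples)],
    )
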