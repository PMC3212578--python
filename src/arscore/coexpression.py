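"""Within-pathway gene co-expression.

For each pathway the Spearman correlation is computed for every pair of its
member genes across samples and the m(m-1)/2 coefficients are averaged; the
mean pairwise rho summarizes how tightly a pathway's genes are co-regulated
in a dataset. Comparing the per-pathway means between two datasets with a
paired t-test quantifies global loss (or gain) of within-pathway
co-regulation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import GeneSetCollection
from .errors import ContractError

__all__ = ["pathway_coexpression", "compare_coexpression", "CoexpressionComparison"]


@dataclass
class CoexpressionComparison:
    t: float
    p: float
    n_pathways: int


def pathway_coexpression(
    matrix: pd.DataFrame,
    sets: GeneSetCollection,
    min_samples: int = 3,
) -> pd.DataFrame:
    """Mean pairwise Spearman rho among each pathway's genes.

    Gene pairs are correlated on pairwise-complete samples; pairs with fewer
    than ``min_samples`` complete observations are dropped from the mean
    rather than imputed. Pathways with fewer than two mapped genes are
    skipped and listed in ``table.attrs['skipped']``.

    Returns a table with columns ``mean_rho``, ``n_pairs`` (pairs entering
    the mean) and ``n_genes`` (mapped members).
    """
    if matrix.shape[1] < min_samples:
        raise ContractError(f"need >= {min_samples} samples for pairwise correlations")
    rows = []
    skipped: dict[str, str] = {}
    gene_pool = set(map(str, matrix.index))
    for name, genes in sets.items():
        mapped = [g for g in genes if g in gene_pool]
        if len(mapped) < 2:
            skipped[name] = f"only {len(mapped)} mapped genes"
            continue
        sub = matrix.loc[mapped]
        corr = sub.T.corr(method="spearman", min_periods=min_samples).to_numpy()
        iu = np.triu_indices(len(mapped), k=1)
        vals = corr[iu]
        vals = vals[~np.isnan(vals)]
        rows.append(
            {
                "pathway": name,
                "mean_rho": float(vals.mean()) if len(vals) else float("nan"),
                "n_pairs": int(len(vals)),
                "n_genes": len(mapped),
            }
        )
    if not rows:
        raise ContractError("no pathway had >= 2 genes mapped on the matrix")
    table = pd.DataFrame(rows).set_index("pathway")
    table.attrs["skipped"] = skipped
    return table


def compare_coexpression(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
) -> CoexpressionComparison:
    """Paired t-test of per-pathway mean co-expression between two datasets.

    Positive t: pathways are more internally co-expressed in dataset A.
    """
    common = table_a.index.intersection(table_b.index)
    x = table_a.loc[common, "mean_rho"].to_numpy(dtype=float)
    y = table_b.loc[common, "mean_rho"].to_numpy(dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ContractError("need >= 3 shared pathways with defined mean co-expression")
    if np.array_equal(x, y):
        return CoexpressionComparison(t=0.0, p=1.0, n_pathways=len(x))
    res = stats.ttest_rel(x, y)
    return CoexpressionComparison(t=float(res.statistic), p=float(res.pvalue), n_pathways=len(x))
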