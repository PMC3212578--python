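"""Pathway co-regulation: shared-gene-excluded activity correlations.

Two pathways that overlap in membership would show inflated activity
correlation simply because the same genes enter both scores. For every
unordered pair, the genes shared by the two sets are therefore removed,
AR-score profiles are recomputed from each residual set across all samples,
and the Spearman correlation of the two residual profiles is taken. Pairs
whose residual sets fall below ``min_genes`` mapped members are reported as
not evaluable — an undefined quantity, never coerced to zero.

Thresholding |rho| yields an undirected co-regulation network; comparing the
full coefficient vectors between two datasets (e.g. normal vs tumor)
quantifies global pathway decoupling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .containers import GeneSetCollection
from .errors import ContractError, NotEvaluableError
from .pathway_scores import rank_matrix

__all__ = [
    "PathwayCorrelation",
    "PathwayNetwork",
    "CouplingComparison",
    "corr_pair_excluding_shared",
    "all_pairs",
    "build_network",
    "compare_coupling",
]


@dataclass
class PathwayCorrelation:
    """Symmetric pathway x pathway Spearman matrix with exclusion metadata."""

    matrix: pd.DataFrame  # K x K, diagonal 1, NaN where not evaluable
    n_samples: int
    n_pairs: int  # unordered pairs evaluated: K(K-1)/2
    exclude_shared: bool
    not_evaluable: dict[tuple[str, str], str] = field(default_factory=dict)

    @property
    def n_evaluable(self) -> int:
        return self.n_pairs - len(self.not_evaluable)

    def pair_values(self) -> pd.Series:
        """Upper-triangle coefficients as a Series indexed by (a, b) pairs."""
        names = list(self.matrix.index)
        pairs = list(combinations(names, 2))
        vals = [self.matrix.at[a, b] for a, b in pairs]
        return pd.Series(vals, index=pd.MultiIndex.from_tuples(pairs, names=["a", "b"]))


@dataclass
class PathwayNetwork:
    """Thresholded co-regulation network (undirected, no self-loops)."""

    nodes: dict[str, int | None]  # pathway -> gene count annotation
    edges: list[tuple[str, str, float, str]]  # (a, b, rho, "positive"/"negative")
    tau: float


@dataclass
class CouplingComparison:
    t: float
    p: float
    n_pairs: int
    mode: str
    test: str


def _ar_profile(rank_values: np.ndarray, valid: np.ndarray, rows: np.ndarray) -> np.ndarray:
    """AR-score profile across samples for the gene rows in ``rows``."""
    n_per_sample = valid.sum(axis=0).astype(float)
    sub = rank_values[rows]
    sub_valid = valid[rows]
    counts = sub_valid.sum(axis=0)
    sums = np.where(sub_valid, sub, 0.0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        profile = (sums / counts) / n_per_sample
    profile[counts == 0] = np.nan
    return profile


def corr_pair_excluding_shared(
    genes_a: tuple[str, ...] | list[str],
    genes_b: tuple[str, ...] | list[str],
    matrix: pd.DataFrame,
    min_genes: int = 5,
) -> float:
    """Spearman rho between two pathways' activity profiles, shared genes removed.

    Raises :class:`NotEvaluableError` when either residual set keeps fewer
    than ``min_genes`` genes on the matrix.
    """
    shared = set(genes_a) & set(genes_b)
    pool = set(map(str, matrix.index))
    res_a = [g for g in genes_a if g not in shared and g in pool]
    res_b = [g for g in genes_b if g not in shared and g in pool]
    if len(res_a) < min_genes or len(res_b) < min_genes:
        small = "first" if len(res_a) < min_genes else "second"
        raise NotEvaluableError(
            f"residual {small} set has fewer than min_genes={min_genes} genes "
            f"after removing {len(shared)} shared genes"
        )
    ranks = rank_matrix(matrix)
    r = ranks.to_numpy(dtype=float)
    valid = ~np.isnan(r)
    pos = {g: i for i, g in enumerate(matrix.index)}
    prof_a = _ar_profile(r, valid, np.array([pos[g] for g in res_a]))
    prof_b = _ar_profile(r, valid, np.array([pos[g] for g in res_b]))
    rho, _ = stats.spearmanr(prof_a, prof_b, nan_policy="omit")
    return float(rho)


def all_pairs(
    sets: GeneSetCollection,
    matrix: pd.DataFrame,
    min_genes: int = 5,
    exclude_shared: bool = True,
) -> PathwayCorrelation:
    """Shared-gene-excluded Spearman for every unordered pathway pair.

    K pathways yield K(K-1)/2 evaluated pairs (186 pathways: 17,205). For
    disjoint pairs the exclusion is a no-op, so their full-set profiles are
    correlated directly; overlapping pairs get residual profiles rebuilt.
    """
    names = sets.names
    k = len(names)
    if k < 2:
        raise ContractError("need >= 2 pathways to correlate")
    ranks = rank_matrix(matrix)
    r = ranks.to_numpy(dtype=float)
    valid = ~np.isnan(r)
    pos = {g: i for i, g in enumerate(matrix.index)}
    rows = {
        name: np.array([pos[g] for g in genes if g in pos], dtype=int)
        for name, genes in sets.items()
    }

    # full-set AR profiles, then their sample-wise mid-ranks for Spearman
    profiles = np.vstack([_ar_profile(r, valid, rows[name]) for name in names])
    ranked_profiles = pd.DataFrame(profiles).rank(axis=1, method="average").to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(ranked_profiles)

    not_evaluable: dict[tuple[str, str], str] = {}
    row_sets = {name: set(rows[name].tolist()) for name in names}
    for i, j in combinations(range(k), 2):
        a, b = names[i], names[j]
        if not exclude_shared:
            continue
        shared = row_sets[a] & row_sets[b]
        if not shared:
            continue
        res_a = np.array([g for g in rows[a] if g not in shared], dtype=int)
        res_b = np.array([g for g in rows[b] if g not in shared], dtype=int)
        if len(res_a) < min_genes or len(res_b) < min_genes:
            corr[i, j] = corr[j, i] = np.nan
            not_evaluable[(a, b)] = (
                f"residual sets of size {len(res_a)}/{len(res_b)} below min_genes={min_genes}"
            )
            continue
        rho, _ = stats.spearmanr(
            _ar_profile(r, valid, res_a), _ar_profile(r, valid, res_b), nan_policy="omit"
        )
        corr[i, j] = corr[j, i] = rho
    np.fill_diagonal(corr, 1.0)

    df = pd.DataFrame(corr, index=pd.Index(names, name="pathway"), columns=names)
    return PathwayCorrelation(
        matrix=df,
        n_samples=matrix.shape[1],
        n_pairs=k * (k - 1) // 2,
        exclude_shared=exclude_shared,
        not_evaluable=not_evaluable,
    )


def build_network(
    corr: PathwayCorrelation | pd.DataFrame,
    tau: float = 0.75,
    sizes: dict[str, int] | None = None,
) -> PathwayNetwork:
    """Connect pathway pairs with |rho| strictly greater than ``tau``.

    Isolated pathways are kept as nodes; node annotations carry the pathway
    gene counts when ``sizes`` is given. A pair at exactly |rho| == tau is
    NOT an edge.
    """
    if not 0 < tau < 1:
        raise ValueError("tau must lie in (0, 1)")
    df = corr.matrix if isinstance(corr, PathwayCorrelation) else corr
    names = list(df.index)
    edges = []
    for a, b in combinations(names, 2):
        rho = df.at[a, b]
        if pd.notna(rho) and abs(rho) > tau:
            x, y = sorted((a, b))
            edges.append((x, y, float(rho), "positive" if rho > 0 else "negative"))
    nodes = {name: (sizes or {}).get(name) for name in names}
    return PathwayNetwork(nodes=nodes, edges=sorted(edges), tau=tau)


def compare_coupling(
    corr_a: PathwayCorrelation,
    corr_b: PathwayCorrelation,
    mode: str = "abs",
    test: str = "paired",
) -> CouplingComparison:
    """t-test comparing pathway-pair coefficients between two datasets.

    Positive t means dataset A's coefficients are larger — i.e. pathways are
    more tightly coupled in A. ``mode='abs'`` (default) compares |rho| so
    that strong negative co-regulation also counts as coupling. Pairs not
    evaluable in either dataset are dropped pairwise (never imputed as 0).
    """
    if mode not in ("abs", "signed"):
        raise ValueError(f"unknown mode {mode!r}")
    if test not in ("paired", "two_sample"):
        raise ValueError(f"unknown test {test!r}")
    va = corr_a.pair_values()
    vb = corr_b.pair_values()
    common = va.index.intersection(vb.index)
    if len(common) == 0:
        raise ContractError("the two correlation matrices share no pathway pairs")
    xa = va.loc[common].to_numpy()
    xb = vb.loc[common].to_numpy()
    ok = ~(np.isnan(xa) | np.isnan(xb))
    xa, xb = xa[ok], xb[ok]
    if len(xa) < 3:
        raise ContractError("fewer than 3 jointly evaluable pathway pairs")
    if mode == "abs":
        xa, xb = np.abs(xa), np.abs(xb)
    if test == "paired":
        if np.array_equal(xa, xb):
            t_val, p_val = 0.0, 1.0  # identical vectors: no difference to test
        else:
            res = stats.ttest_rel(xa, xb)
            t_val, p_val = float(res.statistic), float(res.pvalue)
    else:
        res = stats.ttest_ind(xa, xb, equal_var=False)
        t_val, p_val = float(res.statistic), float(res.pvalue)
    return CouplingComparison(t=t_val, p=p_val, n_pairs=len(xa), mode=mode, test=test)
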