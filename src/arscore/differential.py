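"""Differential pathway activity between two sample groups.

Per pathway, activity scores of the two groups are compared with a Welch
t-test (or a Wilcoxon rank-sum test, the natural companion for ES-scores).
Multiple testing is controlled with Storey's q-value: the proportion of true
nulls pi0 is estimated from the flat right tail of the p-value histogram on
a lambda grid and extrapolated to lambda -> 1 with a cubic smoother, and
q_i = min_{j>=i} pi0 * m * p_(j) / j. With pi0 = 1 this reduces exactly to
Benjamini-Hochberg; estimating pi0 < 1 buys power when many pathways are
truly differential. Pathways with q below the chosen FDR (1% in the
reference pipeline) are called differential.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import GeneSetCollection
from .errors import ContractError

__all__ = [
    "t_test_pathways",
    "wilcoxon_pathways",
    "estimate_pi0",
    "storey_qvalue",
    "fraction_upregulated",
    "tscore_consistency",
]

DEFAULT_LAMBDAS = np.round(np.arange(0.05, 0.96, 0.05), 2)


def _resolve_groups(
    activity: pd.DataFrame, labels: pd.Series, groups: tuple[str, str] | None
) -> tuple[str, str, list[str], list[str]]:
    labels = labels.astype(str)
    labels = labels[labels.index.isin(activity.columns)]
    present = sorted(labels.unique())
    if groups is None:
        if len(present) != 2:
            raise ContractError(
                f"expected exactly 2 group labels, found {present}; pass groups=(g1, g2)"
            )
        g1, g2 = present
    else:
        g1, g2 = groups
    s1 = list(labels.index[labels == g1])
    s2 = list(labels.index[labels == g2])
    if len(s1) < 2 or len(s2) < 2:
        raise ContractError(
            f"both groups need >= 2 samples (got {g1!r}: {len(s1)}, {g2!r}: {len(s2)})"
        )
    return g1, g2, s1, s2


def _two_group_table(
    activity: pd.DataFrame,
    labels: pd.Series,
    groups: tuple[str, str] | None,
    stat: str,
    pi0: float | None,
) -> pd.DataFrame:
    g1, g2, s1, s2 = _resolve_groups(activity, labels, groups)
    a = activity[s1].to_numpy(dtype=float)
    b = activity[s2].to_numpy(dtype=float)
    rows = []
    skipped = {}
    for i, pathway in enumerate(activity.index):
        x, y = a[i][~np.isnan(a[i])], b[i][~np.isnan(b[i])]
        if len(x) < 2 or len(y) < 2:
            skipped[pathway] = f"fewer than 2 non-missing scores per group ({len(x)}/{len(y)})"
            continue
        if stat == "t":
            res = stats.ttest_ind(x, y, equal_var=False)
            statistic = float(res.statistic)
        else:
            res = stats.mannwhitneyu(x, y, alternative="two-sided")
            # signed rank-sum statistic: positive when group 1 scores higher
            statistic = float(res.statistic - len(x) * len(y) / 2)
        p = float(res.pvalue)
        if np.isnan(statistic):
            statistic, p = 0.0, 1.0  # both groups constant and equal
        rows.append(
            {
                "pathway": pathway,
                f"mean_{g1}": float(np.mean(x)),
                f"mean_{g2}": float(np.mean(y)),
                "statistic": statistic,
                "p": min(max(p, 0.0), 1.0),
                "direction": "up" if statistic > 0 else ("down" if statistic < 0 else "none"),
            }
        )
    if not rows:
        raise ContractError("no pathway had enough non-missing scores in both groups")
    table = pd.DataFrame(rows).set_index("pathway")
    table["q"] = storey_qvalue(table["p"].to_numpy(), pi0=pi0)
    table = table.sort_values("p", kind="stable")
    table.attrs.update(
        {"group1": g1, "group2": g2, "test": stat, "skipped": skipped}
    )
    if stat == "t":
        table = table.rename(columns={"statistic": "t"})
    return table


def t_test_pathways(
    activity: pd.DataFrame,
    labels: pd.Series,
    groups: tuple[str, str] | None = None,
    pi0: float | None = None,
) -> pd.DataFrame:
    """Welch two-sided t-test per pathway; table sorted by p with Storey q.

    ``direction`` is "up" when the pathway scores higher in group 1 (the
    first of ``groups``, or the lexicographically first label). Pathways
    with fewer than two non-missing scores in a group are skipped and listed
    in ``table.attrs['skipped']``.
    """
    return _two_group_table(activity, labels, groups, stat="t", pi0=pi0)


def wilcoxon_pathways(
    activity: pd.DataFrame,
    labels: pd.Series,
    groups: tuple[str, str] | None = None,
    pi0: float | None = None,
) -> pd.DataFrame:
    """Wilcoxon rank-sum (Mann-Whitney) per pathway; exact p for small ties-free groups."""
    return _two_group_table(activity, labels, groups, stat="w", pi0=pi0)


def estimate_pi0(p_values: np.ndarray, lambdas: np.ndarray = DEFAULT_LAMBDAS) -> float:
    """Estimate the proportion of true null hypotheses (Storey's pi0).

    pi0(lambda) = #{p > lambda} / (m (1 - lambda)) is computed on the grid
    and a least-squares cubic in lambda is evaluated at the largest grid
    point (the smoother extrapolation toward lambda -> 1), then clipped to
    (0, 1]. Deterministic given the p-values.
    """
    p = np.asarray(p_values, dtype=float)
    _check_pvalues(p)
    m = len(p)
    pi0_lambda = np.array([(p > lam).sum() / (m * (1.0 - lam)) for lam in lambdas])
    if np.allclose(pi0_lambda, pi0_lambda[0]):
        pi0 = float(pi0_lambda[0])
    else:
        coeffs = np.polyfit(lambdas, pi0_lambda, deg=3)
        pi0 = float(np.polyval(coeffs, lambdas.max()))
    return float(min(max(pi0, 1.0 / m), 1.0))


def _check_pvalues(p: np.ndarray) -> None:
    if p.ndim != 1 or len(p) == 0:
        raise ContractError("p-values must be a non-empty 1-D array")
    if np.any(np.isnan(p)) or np.any(p < 0) or np.any(p > 1):
        raise ContractError("p-values must lie in [0, 1]")


def storey_qvalue(
    p_values: np.ndarray,
    pi0: float | None = None,
    lambdas: np.ndarray = DEFAULT_LAMBDAS,
) -> np.ndarray:
    """Storey q-values for a vector of p-values (order preserved).

    ``pi0=None`` estimates pi0 from the data; ``pi0=1.0`` reproduces
    Benjamini-Hochberg exactly. Monotonicity in p is enforced by the
    min-over-larger-p step.
    """
    p = np.asarray(p_values, dtype=float)
    _check_pvalues(p)
    if pi0 is None:
        pi0 = estimate_pi0(p, lambdas=lambdas)
    if not 0 < pi0 <= 1:
        raise ContractError(f"pi0 must lie in (0, 1], got {pi0}")
    m = len(p)
    order = np.argsort(p, kind="stable")
    q_sorted = pi0 * m * p[order] / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


@dataclass
class GeneLevelTests:
    """Per-gene Welch t-scores and p-values, computed once and reused."""

    t: pd.Series
    p: pd.Series
    group1: str
    group2: str


def gene_level_ttests(
    matrix: pd.DataFrame,
    labels: pd.Series,
    groups: tuple[str, str] | None = None,
) -> GeneLevelTests:
    """Welch t-test per gene row (group 1 minus group 2)."""
    g1, g2, s1, s2 = _resolve_groups(matrix, labels, groups)
    res = stats.ttest_ind(
        matrix[s1].to_numpy(dtype=float),
        matrix[s2].to_numpy(dtype=float),
        axis=1,
        equal_var=False,
        nan_policy="omit",
    )
    t = pd.Series(np.asarray(res.statistic, dtype=float), index=matrix.index)
    p = pd.Series(np.asarray(res.pvalue, dtype=float), index=matrix.index)
    return GeneLevelTests(t=t, p=p, group1=g1, group2=g2)


def fraction_upregulated(
    matrix: pd.DataFrame,
    labels: pd.Series,
    sets: GeneSetCollection,
    p_cut: float = 0.001,
    groups: tuple[str, str] | None = None,
) -> pd.DataFrame:
    """Per pathway: fraction of member genes up-regulated in group 1.

    Column ``frac_up_all`` is the fraction of mapped member genes with
    gene-level t > 0; ``frac_up_significant`` restricts to genes with
    gene-level p < ``p_cut`` (NaN when no member gene passes the cut).
    A fraction near 1 (or 0) means the pathway's differential genes move
    coherently in one direction.
    """
    tests = gene_level_ttests(matrix, labels, groups)
    rows = []
    for name, genes in sets.items():
        mapped = [g for g in genes if g in tests.t.index]
        t = tests.t.loc[mapped].dropna()
        if t.empty:
            continue
        sig = t[tests.p.loc[t.index] < p_cut]
        rows.append(
            {
                "pathway": name,
                "n_genes": len(t),
                "n_significant": len(sig),
                "frac_up_all": float((t > 0).mean()),
                "frac_up_significant": float((sig > 0).mean()) if len(sig) else float("nan"),
            }
        )
    table = pd.DataFrame(rows).set_index("pathway")
    table.attrs.update({"group1": tests.group1, "group2": tests.group2, "p_cut": p_cut})
    return table


def tscore_consistency(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    column: str = "t",
) -> float:
    """Pearson correlation R of the t-scores shared by two differential tables.

    Works for pathway-level tables and, via gene-level t-score frames, for
    genes; a high pathway-level R relative to gene-level R indicates that
    set-level summaries replicate better across datasets than single genes.
    """
    common = table_a.index.intersection(table_b.index)
    x = table_a.loc[common, column].astype(float)
    y = table_b.loc[common, column].astype(float)
    ok = x.notna() & y.notna()
    if ok.sum() < 3:
        raise ContractError("need >= 3 shared entities with finite t-scores")
    return float(np.corrcoef(x[ok], y[ok])[0, 1])
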