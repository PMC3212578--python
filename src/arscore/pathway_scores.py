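"""Per-sample pathway activity scores.

The AR-score (average-rank score) of a gene set in one sample is the mean
within-sample rank of the set's members divided by the number of ranked
genes:

    AS = (1/m) * sum_i r_i / n,

where ``r_i`` is the mid-rank of member gene *i* among the ``n`` genes with
a measured relative expression level in that sample (rank ``n`` = highest),
and ``m`` is the number of members present. AS lies in
``[(m+1)/(2n), (2n-m+1)/(2n)]`` — strictly inside (0, 1) whenever
``1 < m < n`` — and a higher score means the set's genes are, on average,
more highly expressed in that sample. Because it is rank based, the score is
invariant under any strictly increasing transform of a sample's values and
therefore comparable across samples, platforms and set sizes.

The ES-score is the signed maximum deviation of a Kolmogorov–Smirnov-like
running sum walking the sample's genes from highest to lowest relative
expression: members (hits) increment the sum, non-members (misses) decrement
it. It is the classic single-sample enrichment statistic and is provided as
a comparator; its distribution over samples is bimodal where the AR-score's
is approximately normal.

A variant for two-channel (log-ratio) data ranks genes by |value| so that
strong down-regulation counts like strong up-regulation instead of
cancelling it.
"""

from __future__ import annotations

from collections.abc import Sequence

import numpy as np
import pandas as pd

from .containers import GeneSetCollection
from .errors import ContractError

__all__ = [
    "rank_profile",
    "rank_matrix",
    "ar_score",
    "es_score",
    "activity_matrix",
]

_MODES = ("signed", "absolute")


def rank_matrix(matrix: pd.DataFrame, mode: str = "signed") -> pd.DataFrame:
    """Within-sample mid-ranks for every column; highest value gets rank n.

    Missing entries stay missing and are excluded from each sample's n.
    ``mode='absolute'`` ranks |value| (for log-ratio data where both tails
    are of interest).
    """
    if mode not in _MODES:
        raise ValueError(f"mode must be one of {_MODES}, got {mode!r}")
    data = matrix.abs() if mode == "absolute" else matrix
    return data.rank(axis=0, method="average", na_option="keep", ascending=True)


def rank_profile(column: pd.Series, mode: str = "signed") -> pd.Series:
    """Mid-ranks of one sample's values (rank n = highest relative level)."""
    if mode not in _MODES:
        raise ValueError(f"mode must be one of {_MODES}, got {mode!r}")
    values = column.abs() if mode == "absolute" else column
    if values.notna().sum() < 2:
        raise ContractError("rank profile needs >= 2 non-missing values in the sample")
    return values.rank(method="average", na_option="keep", ascending=True)


def ar_score(ranks: pd.Series, genes: Sequence[str]) -> float:
    """AR-score of one gene set in one sample given its rank profile.

    Returns NaN (score undefined, not zero) when no member of the set has a
    rank in this sample.
    """
    member = ranks.reindex(pd.Index(dict.fromkeys(genes)))
    member = member.dropna()
    if member.empty:
        return float("nan")
    n = int(ranks.notna().sum())
    return float(member.mean() / n)


def es_score(
    values: pd.Series,
    genes: Sequence[str],
    weighting: str = "unweighted",
) -> float:
    """KS-like enrichment score of one gene set in one sample.

    Walk the sample's genes from highest to lowest value; at a member gene
    (hit) the running sum rises, at a non-member (miss) it falls by
    ``1/(n-m)``. Unweighted hits rise by ``1/m`` (classic KS statistic);
    weighted hits rise by ``|v_i| / sum_hits |v_j|``. The score is the
    running-sum value of maximum absolute deviation, signed; when the
    maximum positive and negative deviations tie in magnitude the one
    reached earliest in the walk wins.

    Ties between equal expression values are broken by gene order in
    ``values`` (stable sort), so results are deterministic.
    """
    if weighting not in ("unweighted", "weighted"):
        raise ValueError(f"unknown weighting {weighting!r}")
    vals = values.dropna()
    n = len(vals)
    member_index = pd.Index(dict.fromkeys(genes))
    hit_mask = vals.index.isin(member_index)
    m = int(hit_mask.sum())
    if m == 0:
        return float("nan")
    if m >= n:
        raise ContractError(
            f"ES undefined when the set covers all {n} ranked genes (miss step divides by zero)"
        )
    order = np.argsort(-vals.to_numpy(), kind="stable")
    hits = hit_mask[order]
    v = vals.to_numpy()[order]
    steps = np.empty(n, dtype=float)
    if weighting == "unweighted":
        steps[hits] = 1.0 / m
    else:
        w = np.abs(v[hits])
        total = w.sum()
        if total == 0:
            steps[hits] = 1.0 / m  # all-zero member values: fall back to KS steps
        else:
            steps[hits] = w / total
    steps[~hits] = -1.0 / (n - m)
    running = np.cumsum(steps)
    peak = int(np.argmax(np.abs(np.round(running, 15))))
    return float(running[peak])


def activity_matrix(
    matrix: pd.DataFrame,
    sets: GeneSetCollection,
    score_type: str = "ar",
    es_weighting: str = "unweighted",
) -> pd.DataFrame:
    """Score every (pathway, sample) pair; pathways x samples DataFrame.

    ``score_type`` is ``'ar'`` (signed AR-score on relative levels),
    ``'ar_abs'`` (AR on |value|, for two-channel log-ratios) or ``'es'``.
    The per-sample gene count n is recomputed per column, so samples with
    different missingness are handled correctly. Undefined cells (no set
    member measured) propagate as NaN. The result's ``attrs['score_type']``
    records the score used.
    """
    if score_type not in ("ar", "ar_abs", "es"):
        raise ValueError(f"unknown score_type {score_type!r}")

    gene_index = matrix.index
    membership = np.zeros((len(sets), len(gene_index)), dtype=bool)
    name_list = sets.names
    positions = {g: i for i, g in enumerate(gene_index)}
    for k, (_, genes) in enumerate(sets.items()):
        idx = [positions[g] for g in genes if g in positions]
        membership[k, idx] = True

    if score_type in ("ar", "ar_abs"):
        ranks = rank_matrix(matrix, mode="absolute" if score_type == "ar_abs" else "signed")
        r = ranks.to_numpy(dtype=float)
        valid = ~np.isnan(r)
        n_per_sample = valid.sum(axis=0).astype(float)
        sums = membership @ np.where(valid, r, 0.0)
        counts = membership.astype(np.int64) @ valid.astype(np.int64)
        with np.errstate(invalid="ignore", divide="ignore"):
            scores = (sums / counts) / n_per_sample[None, :]
        scores[counts == 0] = np.nan
    else:
        scores = np.empty((len(sets), matrix.shape[1]), dtype=float)
        for j, sample in enumerate(matrix.columns):
            col = matrix.iloc[:, j]
            for k, name in enumerate(name_list):
                scores[k, j] = es_score(col, sets[name], weighting=es_weighting)

    out = pd.DataFrame(scores, index=pd.Index(name_list, name="pathway"), columns=matrix.columns)
    out.attrs["score_type"] = score_type
    return out
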