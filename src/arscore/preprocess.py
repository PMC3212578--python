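"""Gene-wise standardization and gene-set/matrix alignment.

One-channel array intensities are absolute measurements; ranking them within
a sample would mostly reflect probe brightness, not regulation. Standardizing
each gene to mean 0, sd 1 across samples converts absolute values into
relative expression levels, after which within-sample ranks compare how
unusually high or low each gene is for itself. Two-channel log-ratios are
already relative and skip this step.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import CoverageReport, GeneSetCollection
from .errors import ContractError

__all__ = ["StandardizationResult", "standardize_genewise", "restrict_to_matrix"]


@dataclass
class StandardizationResult:
    """Standardized matrix plus the genes dropped along the way."""

    matrix: pd.DataFrame
    dropped_zero_variance: list[str] = field(default_factory=list)
    dropped_too_few_values: list[str] = field(default_factory=list)


def standardize_genewise(matrix: pd.DataFrame, ddof: int = 1) -> StandardizationResult:
    """Z-score each gene across samples (sample sd, ``ddof=1`` by default).

    Genes with zero variance, or with fewer than two non-missing values, are
    dropped and reported. Missing entries stay missing. The operation is
    idempotent up to floating-point noise.

    Raises
    ------
    ContractError
        If the matrix has fewer than two samples (relative levels are
        undefined for a single sample).
    """
    if matrix.shape[1] < 2:
        raise ContractError(
            "gene-wise standardization needs >= 2 samples; relative levels are "
            "undefined for a single sample"
        )
    values = matrix.to_numpy(dtype=float)
    n_valid = np.sum(~np.isnan(values), axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows, ddof >= n
        means = np.nanmean(values, axis=1)
        sds = np.nanstd(values, axis=1, ddof=ddof)

    too_few = n_valid < 2
    zero_var = (~too_few) & ((sds == 0) | np.isnan(sds))
    keep = ~(too_few | zero_var)

    z = (values[keep] - means[keep, None]) / sds[keep, None]
    out = pd.DataFrame(z, index=matrix.index[keep], columns=matrix.columns)
    return StandardizationResult(
        matrix=out,
        dropped_zero_variance=list(matrix.index[zero_var]),
        dropped_too_few_values=list(matrix.index[too_few]),
    )


def restrict_to_matrix(
    sets: GeneSetCollection,
    matrix: pd.DataFrame,
    min_genes: int = 5,
) -> tuple[GeneSetCollection, CoverageReport]:
    """Intersect each gene set with the matrix's genes; drop tiny remnants.

    Genes absent from the platform cannot be ranked, so each set is reduced
    to its mapped members. Sets with fewer than ``min_genes`` mapped members
    are excluded and listed in the coverage report.

    Raises
    ------
    ContractError
        If *no* set has any gene on the matrix — almost certainly an
        identifier-namespace mismatch (e.g. symbols vs probe ids).
    """
    gene_pool = set(map(str, matrix.index))
    retained: dict[str, list[str]] = {}
    report = CoverageReport(n_input_sets=len(sets), n_retained_sets=0)
    any_overlap = False
    for name, genes in sets.items():
        mapped = [g for g in genes if g in gene_pool]
        report.coverage[name] = len(mapped) / len(genes)
        if mapped:
            any_overlap = True
        if len(mapped) >= min_genes:
            retained[name] = mapped
        else:
            report.excluded[name] = len(mapped)
    if not any_overlap:
        raise ContractError(
            "no gene of any set is present on the expression matrix; "
            "check that gene identifier namespaces match"
        )
    report.n_retained_sets = len(retained)
    descriptions = {n: sets.descriptions.get(n, "") for n in retained}
    return GeneSetCollection(retained, descriptions), report
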