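"""Sample clustering and classification on pathway activity profiles.

Samples are clustered hierarchically (complete linkage, Euclidean distance)
on their activity profiles, and two-group designs are classified with a
linear-kernel support vector machine evaluated by leave-one-out
cross-validation (LOOCV). Pathway pre-selection by two-group t-test can run
either once on all samples (``global``, the historically common but
leakage-prone variant) or inside every fold on training samples only
(``per_fold``, the default); the report records which mode produced it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from sklearn.svm import SVC

from .differential import t_test_pathways
from .errors import ContractError

__all__ = ["ClusterResult", "ClassifierReport", "hier_cluster", "select_pathways", "loocv_classify"]


@dataclass
class ClusterResult:
    linkage: np.ndarray  # scipy linkage matrix
    items: list[str]  # row order matching leaf ids
    labels: pd.Series | None = None  # flat cluster assignment when k is given

    def cut(self, k: int) -> pd.Series:
        flat = hierarchy.fcluster(self.linkage, t=k, criterion="maxclust")
        return pd.Series(flat, index=self.items, name="cluster")


@dataclass
class ClassifierReport:
    accuracy: float
    predictions: pd.DataFrame  # per sample: true, predicted
    selection_mode: str
    p_cut: float | None
    selected: list[str] | None  # global/fixed selection
    per_fold_selected: dict[str, list[str]] = field(default_factory=dict)


def hier_cluster(
    activity: pd.DataFrame,
    on: str = "samples",
    k: int | None = None,
) -> ClusterResult:
    """Complete-linkage hierarchical clustering with Euclidean distances.

    ``on='samples'`` clusters the columns (each sample described by its
    pathway activity profile); ``on='pathways'`` clusters the rows. Constant
    profiles (zero distances) are allowed. scipy's linkage is deterministic;
    tied distances resolve by cluster index order.
    """
    if on not in ("samples", "pathways"):
        raise ValueError(f"on must be 'samples' or 'pathways', got {on!r}")
    data = activity.T if on == "samples" else activity
    if data.shape[0] < 2:
        raise ContractError("need >= 2 items to cluster")
    link = hierarchy.linkage(pdist(data.to_numpy(dtype=float)), method="complete")
    result = ClusterResult(linkage=link, items=list(data.index))
    if k is not None:
        result.labels = result.cut(k)
    return result


def select_pathways(
    activity: pd.DataFrame,
    labels: pd.Series,
    p_cut: float,
    groups: tuple[str, str] | None = None,
) -> list[str]:
    """Pathways whose two-group Welch t-test p-value is below ``p_cut``, by p.

    Raises a ContractError advising a looser cut when nothing is selected.
    """
    table = t_test_pathways(activity, labels, groups=groups)
    selected = list(table.index[table["p"] < p_cut])
    if not selected:
        raise ContractError(
            f"no pathway reaches p < {p_cut}; loosen the selection cut"
        )
    return selected


def loocv_classify(
    activity: pd.DataFrame,
    labels: pd.Series,
    pathways: list[str] | None = None,
    selection_mode: str = "per_fold",
    p_cut: float = 1e-5,
    C: float = 1.0,
    groups: tuple[str, str] | None = None,
) -> ClassifierReport:
    """Leave-one-out linear-SVM classification of a two-group design.

    Each sample in turn is held out, a linear-kernel SVM (regularization
    ``C``) is trained on the rest, and the held-out sample is predicted;
    accuracy is the fraction predicted correctly. Features are activity
    scores as-is (AR-scores are already on a common scale).

    ``pathways`` fixes the feature set explicitly (mode recorded as
    ``fixed``). Otherwise features are t-test-selected at ``p_cut`` — once
    on all samples (``selection_mode='global'``, reproducing the common but
    leakage-prone pre-selection) or within every training fold
    (``'per_fold'``, default; the held-out sample never influences
    selection or training).
    """
    if selection_mode not in ("global", "per_fold"):
        raise ValueError(f"unknown selection_mode {selection_mode!r}")
    labels = labels.astype(str)
    labels = labels[labels.index.isin(activity.columns)]
    counts = labels.value_counts()
    if len(counts) != 2:
        raise ContractError(f"LOOCV classification needs exactly 2 classes, got {list(counts.index)}")
    if counts.min() < 3:
        raise ContractError("need >= 3 samples per class for leave-one-out folds")
    samples = list(labels.index)

    mode = selection_mode
    selected_global: list[str] | None = None
    if pathways is not None:
        mode = "fixed"
        selected_global = list(pathways)
    elif selection_mode == "global":
        selected_global = select_pathways(activity, labels, p_cut, groups=groups)

    per_fold: dict[str, list[str]] = {}
    records = []
    for held_out in samples:
        train = [s for s in samples if s != held_out]
        y_train = labels.loc[train]
        if y_train.nunique() < 2:
            raise ContractError(f"training fold for {held_out!r} contains a single class")
        if mode == "per_fold":
            features = select_pathways(activity[train], y_train, p_cut, groups=groups)
            per_fold[held_out] = features
        else:
            features = selected_global
        x_train = activity.loc[features, train].T.to_numpy(dtype=float)
        x_test = activity.loc[features, [held_out]].T.to_numpy(dtype=float)
        model = SVC(kernel="linear", C=C)
        model.fit(x_train, y_train.to_numpy())
        predicted = model.predict(x_test)[0]
        records.append(
            {"sample": held_out, "true": labels.loc[held_out], "predicted": predicted}
        )

    predictions = pd.DataFrame(records).set_index("sample")
    accuracy = float((predictions["true"] == predictions["predicted"]).mean())
    return ClassifierReport(
        accuracy=accuracy,
        predictions=predictions,
        selection_mode=mode,
        p_cut=None if pathways is not None else p_cut,
        selected=selected_global,
        per_fold_selected=per_fold,
    )
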