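"""Synthetic expression data with known pathway structure.

A Gaussian factor model provides ground truth for every pipeline stage.
Each pathway k has a per-sample latent activity a_k ~ N(0, 1); pathways in
the same coupling block have equicorrelated latents (correlation gamma, the
inter-pathway coupling), and a member gene of pathway k is

    x = sqrt(rho_w) * a_k + sqrt(1 - rho_w) * eps,   eps ~ N(0, noise_sd^2),

so at noise_sd = 1 any two member genes correlate at rho_w (the
within-pathway co-expression) and genes track their pathway's latent.
Background genes are pure noise. Conditions (e.g. "normal" vs "tumor") may
differ in rho_w and gamma — attenuating both emulates the loss of
co-expression and of pathway coupling observed in tumors — and designated
differential pathways shift each member gene by delta (in gene-sd units) in
every condition after the first, giving known positives for differential
testing. Designated pathway pairs share a configured fraction of members to
exercise shared-gene exclusion; a shared gene loads on the average of the
two latents (rescaled to unit variance).

Every statistic downstream is rank- or t-based, so only this correlation
and shift structure matters; marginal Gaussianity is a simplification, not
a claim about microarray noise.
"""

from __future__ import annotations

import math
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import GeneSetCollection
from .errors import ContractError

__all__ = ["GeneratorConfig", "TruthRecord", "SyntheticData", "generate"]


def _per_condition(value: float | Mapping[str, float], conditions: Sequence[str]) -> dict[str, float]:
    if isinstance(value, Mapping):
        missing = [c for c in conditions if c not in value]
        if missing:
            raise ContractError(f"missing per-condition value for {missing}")
        return {c: float(value[c]) for c in conditions}
    return {c: float(value) for c in conditions}


@dataclass
class GeneratorConfig:
    """Study-condition parameters of the synthetic generator.

    Defaults emulate the contrast the method targets: tightly co-regulated,
    strongly coupled pathways in the reference ("normal") condition versus
    attenuated co-expression and coupling plus shifted activity for a
    subset of pathways in the perturbed ("tumor") condition.
    """

    n_genes: int = 2000
    n_samples: Mapping[str, int] = field(
        default_factory=lambda: {"normal": 30, "tumor": 30}
    )
    n_pathways: int = 50
    pathway_size: tuple[int, int] = (10, 40)
    #: within-pathway gene-gene correlation, per condition
    rho_within: float | Mapping[str, float] = field(
        default_factory=lambda: {"normal": 0.8, "tumor": 0.4}
    )
    #: latent-factor correlation between coupled pathways, per condition
    gamma: float | Mapping[str, float] = field(
        default_factory=lambda: {"normal": 0.8, "tumor": 0.3}
    )
    #: pathways form consecutive blocks of this size; latents within a block
    #: are equicorrelated at gamma (PSD for any gamma in [0, 1))
    coupled_block_size: int = 5
    #: indices of differential pathways; None -> first 10% (at least 1)
    differential_pathways: Sequence[int] | None = None
    #: per-gene mean shift, in gene-sd units, added in non-reference conditions
    delta: float = 1.0
    #: number of designated overlapping pathway pairs (consecutive pairs)
    n_overlap_pairs: int = 2
    #: fraction of the smaller set's genes shared within an overlap pair
    overlap_fraction: float = 0.2
    noise_sd: float = 1.0
    seed: int = 0

    @property
    def conditions(self) -> list[str]:
        return list(self.n_samples)

    def validate(self) -> None:
        conds = self.conditions
        if not conds:
            raise ContractError("n_samples must name at least one condition")
        if any(n <= 0 for n in self.n_samples.values()):
            raise ContractError("sample counts must be positive")
        lo, hi = self.pathway_size
        if not (0 < lo <= hi):
            raise ContractError("pathway_size range must satisfy 0 < lo <= hi")
        for name, val in (
            ("rho_within", _per_condition(self.rho_within, conds)),
            ("gamma", _per_condition(self.gamma, conds)),
        ):
            for cond, v in val.items():
                if not 0 <= v < 1:
                    raise ContractError(f"{name}[{cond!r}] must lie in [0, 1), got {v}")
        if not math.isfinite(self.delta):
            raise ContractError("delta must be finite")
        if not 0 <= self.overlap_fraction < 1:
            raise ContractError("overlap_fraction must lie in [0, 1)")
        if self.coupled_block_size < 1:
            raise ContractError("coupled_block_size must be >= 1")
        if self.n_pathways * self.pathway_size[0] > self.n_genes:
            raise ContractError(
                "n_genes too small: pathways at minimal size already exceed the gene pool"
            )
        # latent covariance must be positive semi-definite in every condition
        for cond, g in _per_condition(self.gamma, conds).items():
            try:
                np.linalg.cholesky(self._latent_cov(g))
            except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded by range check
                raise ContractError(
                    f"latent covariance for condition {cond!r} is not PSD"
                ) from exc

    def _latent_cov(self, gamma: float) -> np.ndarray:
        cov = np.eye(self.n_pathways)
        for start in range(0, self.n_pathways, self.coupled_block_size):
            block = slice(start, min(start + self.coupled_block_size, self.n_pathways))
            cov[block, block] = gamma
        np.fill_diagonal(cov, 1.0)
        return cov

    def coupled_pairs(self) -> list[tuple[int, int]]:
        pairs = []
        for start in range(0, self.n_pathways, self.coupled_block_size):
            block = range(start, min(start + self.coupled_block_size, self.n_pathways))
            pairs.extend((i, j) for i in block for j in block if i < j)
        return pairs


@dataclass
class TruthRecord:
    """Ground truth of one generated dataset."""

    conditions: list[str]
    reference_condition: str
    coupled_pairs: list[tuple[str, str]]
    differential: dict[str, float]  # pathway -> delta
    overlap: dict[tuple[str, str], list[str]]  # pair -> shared gene ids
    rho_within: dict[str, float]
    gamma: dict[str, float]


@dataclass
class SyntheticData:
    expression: pd.DataFrame
    sets: GeneSetCollection
    labels: pd.Series
    truth: TruthRecord

    def condition_matrix(self, condition: str) -> pd.DataFrame:
        cols = self.labels.index[self.labels == condition]
        return self.expression[list(cols)]


def generate(config: GeneratorConfig) -> SyntheticData:
    """Draw one dataset from the factor model; bit-identical for a fixed seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    conds = config.conditions
    rho_w = _per_condition(config.rho_within, conds)
    gamma = _per_condition(config.gamma, conds)
    k = config.n_pathways
    lo, hi = config.pathway_size

    sizes = rng.integers(lo, hi + 1, size=k)
    pathway_names = [f"PW{idx:03d}" for idx in range(k)]
    gene_names = [f"G{idx:05d}" for idx in range(config.n_genes)]

    # disjoint member assignment first ...
    members: list[list[int]] = []
    cursor = 0
    for size in sizes:
        members.append(list(range(cursor, cursor + int(size))))
        cursor += int(size)
    if cursor > config.n_genes:
        raise ContractError(
            f"n_genes={config.n_genes} too small for the drawn pathway sizes "
            f"(need {cursor}); raise n_genes or shrink pathway_size"
        )

    # ... then make designated consecutive pairs share a fraction of genes
    overlap: dict[tuple[str, str], list[str]] = {}
    for p in range(config.n_overlap_pairs):
        j, kk = 2 * p, 2 * p + 1
        if kk >= k:
            break
        n_shared = int(round(config.overlap_fraction * min(len(members[j]), len(members[kk]))))
        if n_shared == 0:
            continue
        members[kk][:n_shared] = members[j][:n_shared]
        overlap[(pathway_names[j], pathway_names[kk])] = [
            gene_names[g] for g in members[j][:n_shared]
        ]

    if config.differential_pathways is None:
        diff_idx = list(range(max(1, k // 10)))
    else:
        diff_idx = list(config.differential_pathways)
        if any(i < 0 or i >= k for i in diff_idx):
            raise ContractError("differential pathway index out of range")

    # per-gene pathway memberships (shared genes belong to two pathways)
    owners: dict[int, list[int]] = {}
    for pw, genes in enumerate(members):
        for g in genes:
            owners.setdefault(g, []).append(pw)

    n_total = sum(config.n_samples.values())
    values = np.empty((config.n_genes, n_total))
    sample_ids: list[str] = []
    labels: list[str] = []
    col = 0
    for cond in conds:
        n_s = config.n_samples[cond]
        chol = np.linalg.cholesky(config._latent_cov(gamma[cond]))
        latents = chol @ rng.standard_normal((k, n_s))  # K x n_s
        block = rng.normal(0.0, config.noise_sd, size=(config.n_genes, n_s))
        rw = rho_w[cond]
        for g, pws in owners.items():
            if len(pws) == 1:
                factor = latents[pws[0]]
            else:
                j, kk2 = pws[0], pws[1]
                c = gamma[cond] if _same_block(j, kk2, config.coupled_block_size) else 0.0
                factor = (latents[j] + latents[kk2]) / math.sqrt(2.0 * (1.0 + c))
            block[g] = math.sqrt(rw) * factor + math.sqrt(1.0 - rw) * block[g]
            if cond != conds[0] and any(pw in diff_idx for pw in pws):
                block[g] += config.delta
        values[:, col : col + n_s] = block
        sample_ids.extend(f"{cond}_{i:03d}" for i in range(n_s))
        labels.extend([cond] * n_s)
        col += n_s

    expression = pd.DataFrame(
        values, index=pd.Index(gene_names, name="gene_id"), columns=sample_ids
    )
    sets = GeneSetCollection(
        {name: [gene_names[g] for g in genes] for name, genes in zip(pathway_names, members)}
    )
    label_series = pd.Series(labels, index=pd.Index(sample_ids, name="sample_id"), name="label")
    truth = TruthRecord(
        conditions=conds,
        reference_condition=conds[0],
        coupled_pairs=[(pathway_names[i], pathway_names[j]) for i, j in config.coupled_pairs()],
        differential={pathway_names[i]: config.delta for i in diff_idx},
        overlap=overlap,
        rho_within=rho_w,
        gamma=gamma,
    )
    return SyntheticData(expression=expression, sets=sets, labels=label_series, truth=truth)


def _same_block(i: int, j: int, block_size: int) -> bool:
    return i // block_size == j // block_size
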