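"""In-memory containers shared across the pipeline.

Expression matrices, activity matrices and correlation matrices are plain
:class:`pandas.DataFrame` objects (genes/pathways as rows, samples as
columns); sample group labels are a :class:`pandas.Series` indexed by sample
id. The only bespoke container is :class:`GeneSetCollection`, an ordered,
de-duplicated mapping from pathway name to member gene ids.
"""

from __future__ import annotations

from collections.abc import Iterator, Mapping, Sequence
from dataclasses import dataclass, field

from .errors import FormatError

__all__ = ["GeneSetCollection", "CoverageReport"]


class GeneSetCollection:
    """An ordered collection of named gene sets (e.g. KEGG pathways).

    Within each set, duplicate gene ids are collapsed (first occurrence
    wins); set names must be unique and gene lists non-empty.
    """

    def __init__(
        self,
        sets: Mapping[str, Sequence[str]],
        descriptions: Mapping[str, str] | None = None,
    ) -> None:
        self._sets: dict[str, tuple[str, ...]] = {}
        self.descriptions: dict[str, str] = {}
        for name, genes in sets.items():
            if name in self._sets:
                raise FormatError(f"duplicate gene set name: {name!r}")
            deduped = tuple(dict.fromkeys(genes))
            if not deduped:
                raise FormatError(f"gene set {name!r} is empty")
            self._sets[name] = deduped
            self.descriptions[name] = (descriptions or {}).get(name, "")

    @property
    def names(self) -> list[str]:
        return list(self._sets)

    def __len__(self) -> int:
        return len(self._sets)

    def __iter__(self) -> Iterator[str]:
        return iter(self._sets)

    def __contains__(self, name: object) -> bool:
        return name in self._sets

    def __getitem__(self, name: str) -> tuple[str, ...]:
        return self._sets[name]

    def items(self) -> Iterator[tuple[str, tuple[str, ...]]]:
        return iter(self._sets.items())

    def sizes(self) -> dict[str, int]:
        return {name: len(genes) for name, genes in self._sets.items()}

    def subset(self, names: Sequence[str]) -> "GeneSetCollection":
        return GeneSetCollection(
            {n: self._sets[n] for n in names},
            {n: self.descriptions[n] for n in names},
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"GeneSetCollection({len(self)} sets)"

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneSetCollection):
            return NotImplemented
        return self._sets == other._sets


@dataclass
class CoverageReport:
    """How a gene-set collection mapped onto an expression matrix."""

    n_input_sets: int
    n_retained_sets: int
    excluded: dict[str, int] = field(default_factory=dict)  # name -> mapped size
    coverage: dict[str, float] = field(default_factory=dict)  # name -> mapped fraction
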