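"""Named gene-set (pathway) collections with optional category labels.

A collection maps pathway name -> ordered unique member gene list and
optionally pathway name -> category label (e.g. the 11 KEGG metabolism
classes). It supplies the quantities the pathway activity score needs:
per-pathway size ``m_t``, the gene universe of size ``M``, and per-gene
pathway-membership counts ``c_i`` (whose reciprocals are the score's
gene weights).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .errors import InputError


@dataclass
class GeneSetCollection:
    """Pathway name -> member genes, with optional per-pathway categories.

    Parameters
    ----------
    sets : dict of str -> list of str
        Ordered member gene lists; duplicates within a set are rejected.
    categories : dict of str -> str, optional
        Category label per pathway. When given, must cover every pathway.
    """

    sets: dict[str, list[str]]
    categories: dict[str, str] | None = None
    _counts: Counter = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        if not self.sets:
            raise InputError("gene-set collection is empty")
        for name, genes in self.sets.items():
            if len(genes) == 0:
                raise InputError(f"pathway {name!r} has no member genes")
            if len(set(genes)) != len(genes):
                raise InputError(f"pathway {name!r} contains duplicate genes")
        if self.categories is not None:
            missing = [n for n in self.sets if n not in self.categories]
            if missing:
                raise InputError(
                    f"category labels missing for pathways: {sorted(missing)}"
                )
        self._counts = Counter(g for genes in self.sets.values() for g in genes)

    def __len__(self) -> int:
        return len(self.sets)

    def __contains__(self, pathway: str) -> bool:
        return pathway in self.sets

    @property
    def universe(self) -> list[str]:
        """Union of all member genes, in first-appearance order (size ``M``)."""
        return list(self._counts)

    @property
    def sizes(self) -> dict[str, int]:
        """Member count ``m_t`` per pathway."""
        return {name: len(genes) for name, genes in self.sets.items()}

    def membership_counts(self) -> dict[str, int]:
        """Number of pathways containing each gene (``c_i`` >= 1)."""
        return dict(self._counts)

    def category_of(self, pathway: str) -> str:
        if self.categories is None:
            raise InputError("collection carries no category labels")
        return self.categories[pathway]
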