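"""Ranked taxonomic lineages and lowest-common-ancestor (LCA) logic.

Lineages are written in the common ``rank__Name`` notation, e.g.::

    d__Bacteria;p__Actinobacteria;g__Bifidobacterium;s__Bifidobacterium longum

A lineage is a *path*: an ordered sequence of (rank, name) levels from the
domain down to the finest resolved rank.  Any suffix of ranks may be absent
(a genus-level assignment simply stops at ``g__``).  Paths compare by the
prefix relation, and the LCA of a set of paths is their longest common
prefix.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

#: Rank codes ordered from coarsest to finest.
RANK_CODES: tuple[str, ...] = ("d", "p", "c", "o", "f", "g", "s")

RANK_NAMES: dict[str, str] = {
    "d": "domain",
    "p": "phylum",
    "c": "class",
    "o": "order",
    "f": "family",
    "g": "genus",
    "s": "species",
}

_RANK_INDEX = {code: i for i, code in enumerate(RANK_CODES)}


class LineageError(ValueError):
    """Raised for malformed lineage strings or invalid rank structure."""


@dataclass(frozen=True)
class TaxonomyPath:
    """An ordered ranked lineage.

    Parameters
    ----------
    levels:
        Tuple of ``(rank_code, name)`` pairs with strictly increasing rank
        (coarse to fine).  A species level requires the genus to be present.
    """

    levels: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if not self.levels:
            raise LineageError("empty lineage; use None for an absent taxonomy")
        last = -1
        for code, name in self.levels:
            if code not in _RANK_INDEX:
                raise LineageError(f"unknown rank code {code!r}")
            if not name:
                raise LineageError(f"empty name at rank {code!r}")
            idx = _RANK_INDEX[code]
            if idx <= last:
                raise LineageError("ranks must be strictly ordered coarse to fine")
            last = idx
        if self.name_at("s") is not None and self.name_at("g") is None:
            raise LineageError("species-level lineage requires a genus")

    # -- construction ---------------------------------------------------
    @classmethod
    def from_string(cls, lineage: str) -> "TaxonomyPath":
        """Parse ``rank__Name;rank__Name;...`` (whitespace tolerant)."""
        levels = []
        for token in lineage.strip().split(";"):
            token = token.strip()
            if not token:
                continue
            if "__" not in token:
                raise LineageError(f"malformed lineage token {token!r}")
            code, name = token.split("__", 1)
            code = code.strip()
            name = name.strip()
            if not name:
                # a trailing empty rank (e.g. "s__") marks an unresolved rank
                continue
            levels.append((code, name))
        if not levels:
            raise LineageError(f"no resolvable ranks in {lineage!r}")
        return cls(tuple(levels))

    def to_string(self) -> str:
        return ";".join(f"{c}__{n}" for c, n in self.levels)

    # -- queries --------------------------------------------------------
    @property
    def rank(self) -> str:
        """The finest rank code present."""
        return self.levels[-1][0]

    @property
    def depth(self) -> int:
        return len(self.levels)

    def rank_index(self) -> int:
        """Position of the finest rank in the canonical rank order."""
        return _RANK_INDEX[self.rank]

    def name_at(self, code: str) -> Optional[str]:
        for c, n in self.levels:
            if c == code:
                return n
        return None

    @property
    def genus(self) -> Optional[str]:
        return self.name_at("g")

    @property
    def species(self) -> Optional[str]:
        return self.name_at("s")

    def has_genus(self, genus: str) -> bool:
        return self.genus == genus

    def is_prefix_of(self, other: "TaxonomyPath") -> bool:
        return self.levels == other.levels[: len(self.levels)]

    def finer_than(self, other: "TaxonomyPath") -> bool:
        """True if this path resolves to a strictly finer rank than *other*."""
        return self.rank_index() > other.rank_index()

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.to_string()


def lca(paths: Iterable[TaxonomyPath]) -> Optional[TaxonomyPath]:
    """Longest common lineage prefix of *paths*; None if nothing is shared."""
    paths = list(paths)
    if not paths:
        return None
    common = list(paths[0].levels)
    for p in paths[1:]:
        k = 0
        for a, b in zip(common, p.levels):
            if a != b:
                break
            k += 1
        common = common[:k]
        if not common:
            return None
    return TaxonomyPath(tuple(common))
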