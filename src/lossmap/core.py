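"""Core domain types shared across the pipeline.

Cell states of a :class:`CharacterMatrix` are coded as small integers
(:data:`PRESENT`, :data:`ABSENT`, :data:`UNKNOWN`); unknown is a first-class
third state and is never silently coerced to absence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

PRESENT: int = 1
ABSENT: int = 0
UNKNOWN: int = -1

_STATE_CODES = frozenset({PRESENT, ABSENT, UNKNOWN})

#: TSV cell symbol <-> internal code
CELL_SYMBOLS: Mapping[str, int] = {"1": PRESENT, "0": ABSENT, "?": UNKNOWN}
CODE_SYMBOLS: Mapping[int, str] = {v: k for k, v in CELL_SYMBOLS.items()}


class MatrixError(ValueError):
    """Raised for malformed character matrices."""


@dataclass(frozen=True)
class ReadInterval:
    """A single mapped small-RNA read in 0-based half-open coordinates.

    The 5' end of a plus-strand read is ``start``; the 5' end of a
    minus-strand read is ``end - 1``.
    """

    contig: str
    start: int
    end: int
    strand: str
    name: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.contig!r}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def five_prime(self) -> int:
        return self.start if self.strand == "+" else self.end - 1


@dataclass
class SpeciesSummaryRow:
    """Per-species summary used by the cross-layer regressions."""

    taxon: str
    mirna_losses: int
    core_gene_losses: int
    gene_count: int
    n50: int
    morph_losses: int

    def __post_init__(self) -> None:
        for attr in ("mirna_losses", "core_gene_losses", "gene_count", "morph_losses"):
            if getattr(self, attr) < 0:
                raise ValueError(f"{attr} must be >= 0 for {self.taxon!r}")
        if self.n50 <= 0:
            raise ValueError(f"n50 must be > 0 for {self.taxon!r}")


class CharacterMatrix:
    """Taxa x binary-characters matrix with an explicit unknown state.

    Parameters
    ----------
    taxa : ordered taxon labels (rows)
    characters : ordered character labels (columns)
    values : int array of shape (n_taxa, n_characters) with cells in
        {PRESENT, ABSENT, UNKNOWN}
    """

    def __init__(
        self,
        taxa: Iterable[str],
        characters: Iterable[str],
        values: np.ndarray,
    ) -> None:
        self.taxa: list[str] = list(taxa)
        self.characters: list[str] = list(characters)
        values = np.asarray(values, dtype=np.int8)
        if not self.taxa or not self.characters:
            raise MatrixError("matrix needs at least one taxon and one character")
        if len(set(self.taxa)) != len(self.taxa):
            dup = _first_duplicate(self.taxa)
            raise MatrixError(f"duplicate taxon label {dup!r}")
        if len(set(self.characters)) != len(self.characters):
            dup = _first_duplicate(self.characters)
            raise MatrixError(f"duplicate character label {dup!r}")
        if values.shape != (len(self.taxa), len(self.characters)):
            raise MatrixError(
                f"values shape {values.shape} does not match "
                f"({len(self.taxa)}, {len(self.characters)})"
            )
        bad = set(np.unique(values)) - _STATE_CODES
        if bad:
            raise MatrixError(f"invalid cell codes: {sorted(bad)}")
        self.values = values
        self._taxon_index = {t: i for i, t in enumerate(self.taxa)}
        self._char_index = {c: j for j, c in enumerate(self.characters)}

    # -- access -----------------------------------------------------------
    def cell(self, taxon: str, character: str) -> int:
        return int(self.values[self._taxon_index[taxon], self._char_index[character]])

    def taxon_row(self, taxon: str) -> np.ndarray:
        return self.values[self._taxon_index[taxon]]

    def character_column(self, character: str) -> np.ndarray:
        return self.values[:, self._char_index[character]]

    def has_taxon(self, taxon: str) -> bool:
        return taxon in self._taxon_index

    @property
    def n_unknown(self) -> int:
        return int(np.sum(self.values == UNKNOWN))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CharacterMatrix):
            return NotImplemented
        return (
            self.taxa == other.taxa
            and self.characters == other.characters
            and np.array_equal(self.values, other.values)
        )

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"CharacterMatrix({len(self.taxa)} taxa x "
            f"{len(self.characters)} characters, {self.n_unknown} unknown)"
        )


def _first_duplicate(labels: list[str]) -> str:
    seen: set[str] = set()
    for lab in labels:
        if lab in seen:
            return lab
        seen.add(lab)
    return ""  # pragma: no cover
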