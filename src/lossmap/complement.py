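"""Expected-complement accounting by node of origin, loss fractions, and
precursor hairpin-length summaries."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd


class ComplementError(ValueError):
    pass


@dataclass(frozen=True)
class NodeAssignment:
    """Mapping family -> phylogenetic node of origin.

    ``nodes`` is the declared node vocabulary; it may contain nodes with
    zero assigned families.
    """

    families: Mapping[str, str]
    nodes: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        vocab = frozenset(self.nodes) | frozenset(self.families.values())
        object.__setattr__(self, "nodes", vocab)

    @classmethod
    def from_counts(cls, counts: Mapping[str, int]) -> "NodeAssignment":
        """Build a labeled assignment from per-node expected family counts."""
        families: dict[str, str] = {}
        for node, count in counts.items():
            if count < 0:
                raise ComplementError(f"negative family count for node {node!r}")
            for i in range(count):
                families[f"{node}-fam-{i + 1:02d}"] = node
        return cls(families=families, nodes=frozenset(counts))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "NodeAssignment":
        frame = pd.read_csv(path, sep="\t", header=None, names=["family", "node"])
        families = {str(r.family): str(r.node) for r in frame.itertuples(index=False)}
        if len(families) != len(frame):
            raise ComplementError(f"{path}: duplicate family labels")
        return cls(families=families)

    def node_counts(self) -> dict[str, int]:
        counts = {n: 0 for n in sorted(self.nodes)}
        for node in self.families.values():
            counts[node] += 1
        return counts


def expected_families(assignment: NodeAssignment, path_nodes: Sequence[str]) -> int:
    """Families whose origin node lies on the given root-to-tip path."""
    for node in path_nodes:
        if node not in assignment.nodes:
            raise ComplementError(f"unknown node label {node!r}")
    wanted = set(path_nodes)
    return sum(1 for node in assignment.families.values() if node in wanted)


@dataclass(frozen=True)
class LossFraction:
    percent: float          # full precision, 0..100
    display: int            # rounded for reporting
    losses: int
    expected: int

    def to_payload(self) -> dict:
        return {
            "percent": self.percent,
            "display": self.display,
            "losses": self.losses,
            "expected": self.expected,
        }


def loss_fraction(losses: int, expected: int) -> LossFraction:
    """100 * losses / expected, full precision plus a rounded display value."""
    if expected <= 0:
        raise ComplementError("expected count must be > 0")
    if not 0 <= losses <= expected:
        raise ComplementError(f"losses must be in [0, {expected}], got {losses}")
    percent = 100.0 * losses / expected
    return LossFraction(
        percent=percent, display=int(round(percent)), losses=losses, expected=expected
    )


@dataclass(frozen=True)
class PrecursorAnnotation:
    """One annotated precursor span; hairpin length is the span width."""

    species: str
    contig: str
    start: int  # 1-based inclusive (GFF3)
    end: int    # inclusive
    strand: str

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ComplementError(
                f"invalid span {self.start}..{self.end} on {self.contig!r}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def read_gff3_precursors(
    path: str | Path, default_species: str = "unknown"
) -> list[PrecursorAnnotation]:
    """Read precursor spans from GFF3; a ``species=`` attribute overrides
    *default_species*."""
    out: list[PrecursorAnnotation] = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 9:
            raise ComplementError(f"{path}: malformed GFF3 line: {line!r}")
        contig, _src, _type, start, end, _score, strand, _phase, attrs = fields[:9]
        species = default_species
        for item in attrs.split(";"):
            if item.strip().startswith("species="):
                species = item.strip().split("=", 1)[1]
        out.append(
            PrecursorAnnotation(
                species=species,
                contig=contig,
                start=int(start),
                end=int(end),
                strand=strand,
            )
        )
    return out


@dataclass(frozen=True)
class LengthStats:
    mean: float  # rounded to 1 decimal
    min: int
    max: int
    n: int


def precursor_length_stats(
    annotations: Iterable[PrecursorAnnotation],
) -> dict[str, LengthStats]:
    """Per-species arithmetic mean (1 decimal), min and max hairpin length."""
    by_species: dict[str, list[int]] = {}
    for ann in annotations:
        by_species.setdefault(ann.species, []).append(ann.length)
    if not by_species:
        raise ComplementError("no precursor annotations given")
    return {
        species: LengthStats(
            mean=round(sum(lengths) / len(lengths), 1),
            min=min(lengths),
            max=max(lengths),
            n=len(lengths),
        )
        for species, lengths in sorted(by_species.items())
    }
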