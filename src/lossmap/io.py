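"""Readers/writers for the plain-text formats the pipeline touches.

Matrix TSV dialect: header row of character labels, first column taxon
labels, cells in {0, 1, ?}.  BED is BED6, 0-based half-open.  Reports are
JSON with deterministic key order.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
from pathlib import Path
from typing import Any, Iterable, Mapping

import numpy as np
import pandas as pd

from .core import (
    CELL_SYMBOLS,
    CODE_SYMBOLS,
    CharacterMatrix,
    MatrixError,
    ReadInterval,
    SpeciesSummaryRow,
)
from .tree import PhyloTree

log = logging.getLogger(__name__)


class BedFormatError(ValueError):
    pass


# ---------------------------------------------------------------------------
# character matrices
# ---------------------------------------------------------------------------

def read_matrix(path: str | Path, dialect: str = "tsv") -> CharacterMatrix:
    """Read a taxa x characters matrix from TSV.

    Duplicate row/column labels and cells outside {0,1,?} are hard errors;
    unknown ('?') cells are carried as a third state and counted in the log.
    """
    if dialect != "tsv":
        raise ValueError(f"unsupported dialect {dialect!r}")
    lines = Path(path).read_text().splitlines()
    rows = [line.split("\t") for line in lines if line.strip()]
    if not rows:
        raise MatrixError(f"{path}: empty matrix file")
    characters = rows[0][1:]
    taxa: list[str] = []
    values = np.empty((len(rows) - 1, len(characters)), dtype=np.int8)
    for i, row in enumerate(rows[1:]):
        taxon, cells = row[0], row[1:]
        if taxon in taxa:
            raise MatrixError(f"{path}: duplicate taxon row {taxon!r}")
        if len(cells) != len(characters):
            raise MatrixError(
                f"{path}: row {taxon!r} has {len(cells)} cells, "
                f"expected {len(characters)}"
            )
        for j, cell in enumerate(cells):
            try:
                values[i, j] = CELL_SYMBOLS[cell]
            except KeyError:
                raise MatrixError(
                    f"{path}: invalid cell {cell!r} at row {taxon!r}, "
                    f"column {characters[j]!r}"
                ) from None
        taxa.append(taxon)
    matrix = CharacterMatrix(taxa, characters, values)
    if matrix.n_unknown:
        log.warning("%s: %d unknown ('?') cells", path, matrix.n_unknown)
    return matrix


def write_matrix(matrix: CharacterMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("taxon\t" + "\t".join(matrix.characters) + "\n")
        for i, taxon in enumerate(matrix.taxa):
            cells = "\t".join(CODE_SYMBOLS[int(v)] for v in matrix.values[i])
            fh.write(f"{taxon}\t{cells}\n")


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------

def read_newick(path: str | Path) -> PhyloTree:
    return PhyloTree.from_newick(Path(path).read_text())


def write_newick(tree: PhyloTree, path: str | Path) -> None:
    Path(path).write_text(tree.to_newick() + "\n")


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_bed(path: str | Path) -> list[ReadInterval]:
    """Read BED6 into :class:`ReadInterval` objects, preserving input order."""
    try:
        frame = pd.read_csv(
            path, sep="\t", header=None, comment="#", dtype=str,
            skip_blank_lines=True,
        )
    except pd.errors.EmptyDataError:
        log.warning("%s: empty BED file", path)
        return []
    if frame.shape[1] < 6:
        raise BedFormatError(
            f"{path}: BED6 required (6 columns incl. strand), "
            f"got {frame.shape[1]}"
        )
    reads: list[ReadInterval] = []
    for idx, row in enumerate(frame.itertuples(index=False)):
        contig, start, end, name, _score, strand = row[:6]
        try:
            start_i, end_i = int(start), int(end)
        except ValueError:
            raise BedFormatError(f"{path}: non-integer coordinates on line {idx + 1}")
        if end_i <= start_i:
            raise BedFormatError(
                f"{path}: end <= start ({start_i} >= {end_i}) on line {idx + 1}"
            )
        if strand not in ("+", "-"):
            raise BedFormatError(f"{path}: invalid strand {strand!r} on line {idx + 1}")
        reads.append(ReadInterval(str(contig), start_i, end_i, str(strand), str(name)))
    return reads


def write_bed(reads: Iterable[ReadInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, r in enumerate(reads):
            name = r.name if r.name != "." else f"r{i + 1}"
            fh.write(f"{r.contig}\t{r.start}\t{r.end}\t{name}\t0\t{r.strand}\n")


# ---------------------------------------------------------------------------
# small TSV tables
# ---------------------------------------------------------------------------

def read_genome_table(path: str | Path) -> dict[str, int]:
    """Two-column TSV (contig, length) -> mapping."""
    frame = pd.read_csv(path, sep="\t", header=None, names=["contig", "length"])
    out: dict[str, int] = {}
    for row in frame.itertuples(index=False):
        length = int(row.length)
        if length <= 0:
            raise ValueError(f"{path}: non-positive length for {row.contig!r}")
        out[str(row.contig)] = length
    return out


SPECIES_COLUMNS = [
    "taxon", "mirna_losses", "core_gene_losses", "gene_count", "n50", "morph_losses",
]


def write_species_table(rows: Iterable[SpeciesSummaryRow], path: str | Path) -> None:
    frame = pd.DataFrame([dataclasses.asdict(r) for r in rows])[SPECIES_COLUMNS]
    frame.to_csv(path, sep="\t", index=False)


def read_species_table(path: str | Path) -> list[SpeciesSummaryRow]:
    frame = pd.read_csv(path, sep="\t")
    missing = set(SPECIES_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return [
        SpeciesSummaryRow(
            taxon=str(r.taxon),
            mirna_losses=int(r.mirna_losses),
            core_gene_losses=int(r.core_gene_losses),
            gene_count=int(r.gene_count),
            n50=int(r.n50),
            morph_losses=int(r.morph_losses),
        )
        for r in frame.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# JSON reports
# ---------------------------------------------------------------------------

def _jsonify(obj: Any) -> Any:
    if hasattr(obj, "to_payload"):
        return obj.to_payload()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return dataclasses.asdict(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    raise TypeError(f"cannot serialize {type(obj).__name__}")


def report_text(
    results: Any,
    *,
    seed: int | None = None,
    parameters: Mapping[str, Any] | None = None,
) -> str:
    """Serialize *results* plus run metadata as a deterministic JSON string."""
    from . import __version__

    doc = {
        "metadata": {
            "package": "lossmap",
            "version": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "seed": seed,
            "parameters": dict(parameters or {}),
        },
        "results": results,
    }
    return json.dumps(doc, indent=2, sort_keys=True, default=_jsonify) + "\n"


def write_report(
    results: Any,
    path: str | Path,
    *,
    seed: int | None = None,
    parameters: Mapping[str, Any] | None = None,
) -> None:
    Path(path).write_text(report_text(results, seed=seed, parameters=parameters))
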