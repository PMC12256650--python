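"""Seeded generators for matrices, read sets, and species tables.

The matrix generator plants loss/gain events on named branches such that
the irreversible-event remapping in :mod:`lossmap.dollo` recovers the
planted per-branch counts exactly: losses packed onto one character are
kept pairwise disjoint and validated against a single-character
reconstruction before acceptance.

All generators are pure functions of their explicit seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .core import ABSENT, PRESENT, CharacterMatrix, ReadInterval, SpeciesSummaryRow
from .dollo import PolaritySpec
from .tree import PhyloTree


class SimulationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# branch-event matrices
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BranchEventSpec:
    """Planted (losses, gains) per branch, keyed by child node label."""

    tree: PhyloTree
    events: Mapping[str, tuple[int, int]]
    n_characters: int

    def __post_init__(self) -> None:
        if self.n_characters < 1:
            raise SimulationError("n_characters must be >= 1")
        for branch, (n_loss, n_gain) in self.events.items():
            if branch not in self.tree:
                raise SimulationError(f"unknown branch {branch!r}")
            if branch == self.tree.root.name:
                raise SimulationError("events cannot be planted on the root")
            if n_loss < 0 or n_gain < 0:
                raise SimulationError(f"negative event count on {branch!r}")

    @property
    def loss_events(self) -> list[str]:
        """Loss branches with multiplicity, in deterministic preorder."""
        order = {name: i for i, name in enumerate(n.name for n in self.tree.preorder())}
        out: list[str] = []
        for branch in sorted(self.events, key=order.__getitem__):
            out.extend([branch] * self.events[branch][0])
        return out

    @property
    def gain_events(self) -> list[str]:
        order = {name: i for i, name in enumerate(n.name for n in self.tree.preorder())}
        out: list[str] = []
        for branch in sorted(self.events, key=order.__getitem__):
            out.extend([branch] * self.events[branch][1])
        return out


def _single_char_loss_branches(tree: PhyloTree, absent_tips: set[str]) -> set[str]:
    """Loss edges the reconstruction would place for one ancestrally present
    character absent in exactly *absent_tips* (independent mini-oracle used
    to validate packing)."""
    present: dict[str, bool] = {}
    for node in tree.postorder():
        if node.is_leaf():
            present[node.name] = node.name not in absent_tips
        else:
            present[node.name] = any(present[c.name] for c in node.children)
    present[tree.root.name] = True
    out: set[str] = set()
    stack = [tree.root]
    while stack:
        node = stack.pop()
        for child in node.children:
            if present[child.name]:
                stack.append(child)
            else:
                out.add(child.name)  # type: ignore[arg-type]
    return out


def _disjoint(tree: PhyloTree, a: str, b: str) -> bool:
    return (
        a != b
        and not tree.is_strict_ancestor(a, b)
        and not tree.is_strict_ancestor(b, a)
    )


def _pack_losses(
    tree: PhyloTree, loss_events: list[str], budget: int
) -> list[list[str]]:
    """Assign loss events to characters; one event per character while the
    budget allows, then first-fit packing onto disjoint, remap-valid sets."""
    if budget < 1 and loss_events:
        raise SimulationError("character budget over-subscribed: no room for losses")
    chars = [[b] for b in loss_events[:budget]]
    for branch in loss_events[budget:]:
        for branch_set in chars:
            if not all(_disjoint(tree, branch, x) for x in branch_set):
                continue
            candidate = branch_set + [branch]
            absent = set()
            for b in candidate:
                absent.update(tree.leaves_under(b))
            if _single_char_loss_branches(tree, absent) == set(candidate):
                branch_set.append(branch)
                break
        else:
            raise SimulationError(
                "character budget over-subscribed: cannot place loss on "
                f"branch {branch!r}"
            )
    return chars


def gen_matrix_with_polarity(
    spec: BranchEventSpec, seed: int
) -> tuple[CharacterMatrix, PolaritySpec]:
    """Generate a matrix realizing *spec* plus the polarity needed to remap it.

    A character planted as lost on branch b is absent in exactly the tips
    below b (and any further disjoint branches packed onto it) and present
    elsewhere; a planted gain is present only in the tips below its branch.
    Remaining characters are present in all taxa.  The assignment of planted
    patterns to character columns is drawn with *seed*.
    """
    rng = np.random.default_rng(seed)
    tree = spec.tree
    gain_events = spec.gain_events
    budget = spec.n_characters - len(gain_events)
    if budget < 0:
        raise SimulationError("character budget over-subscribed: too many gains")
    loss_chars = _pack_losses(tree, spec.loss_events, budget)
    n_filler = spec.n_characters - len(gain_events) - len(loss_chars)

    tips = tree.tips
    tip_index = {t: i for i, t in enumerate(tips)}
    patterns: list[np.ndarray] = []
    kinds: list[str] = []
    for branch_set in loss_chars:
        col = np.full(len(tips), PRESENT, dtype=np.int8)
        for b in branch_set:
            for t in tree.leaves_under(b):
                col[tip_index[t]] = ABSENT
        patterns.append(col)
        kinds.append("loss")
    for branch in gain_events:
        col = np.full(len(tips), ABSENT, dtype=np.int8)
        for t in tree.leaves_under(branch):
            col[tip_index[t]] = PRESENT
        patterns.append(col)
        kinds.append("gain")
    for _ in range(n_filler):
        patterns.append(np.full(len(tips), PRESENT, dtype=np.int8))
        kinds.append("filler")

    width = len(str(spec.n_characters))
    characters = [f"char_{i + 1:0{width}d}" for i in range(spec.n_characters)]
    perm = rng.permutation(spec.n_characters)
    values = np.empty((len(tips), spec.n_characters), dtype=np.int8)
    overrides: dict[str, str] = {}
    for pattern_idx, col_idx in enumerate(perm):
        values[:, col_idx] = patterns[pattern_idx]
        if kinds[pattern_idx] == "gain":
            overrides[characters[col_idx]] = "absent"
    matrix = CharacterMatrix(tips, characters, values)
    return matrix, PolaritySpec(mode="root-present", overrides=overrides)


def gen_matrix_from_branch_events(spec: BranchEventSpec, seed: int) -> CharacterMatrix:
    return gen_matrix_with_polarity(spec, seed)[0]


# ---------------------------------------------------------------------------
# presets encoding the syndermatan case study
# ---------------------------------------------------------------------------

SYNDERMATAN_NEWICK = (
    "(Outgroup,(Monogononta,(Bdelloidea,(Seisonidea,Acanthocephala)"
    "Pararotatoria)Hemirotifera)Syndermata)Root;"
)

#: Conserved microRNA-family fixture: shared stem losses 9/2/16 plus
#: terminal residuals chosen to match the per-group tip totals
#: (Monogononta 14, Seisonidea 30, Acanthocephala 37); six novel families
#: gained on the Syndermata stem.
_MIRNA_EVENTS = {
    "Syndermata": (9, 6),
    "Monogononta": (5, 0),
    "Hemirotifera": (2, 0),
    "Pararotatoria": (16, 0),
    "Seisonidea": (3, 0),
    "Acanthocephala": (10, 0),
}

#: Metazoan core-gene fixture: stem losses 54/61/165 and terminal losses
#: 76/148 over 954 characters.
_BUSCO_EVENTS = {
    "Syndermata": (54, 0),
    "Hemirotifera": (61, 0),
    "Pararotatoria": (165, 0),
    "Seisonidea": (76, 0),
    "Acanthocephala": (148, 0),
}

PRESET_NAMES = ("syndermata_mirna", "syndermata_busco")


def preset_spec(name: str) -> BranchEventSpec:
    """Named fixtures for the syndermatan case study."""
    tree = PhyloTree.from_newick(SYNDERMATAN_NEWICK)
    if name == "syndermata_mirna":
        return BranchEventSpec(tree=tree, events=_MIRNA_EVENTS, n_characters=50)
    if name == "syndermata_busco":
        return BranchEventSpec(tree=tree, events=_BUSCO_EVENTS, n_characters=954)
    raise SimulationError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")


# ---------------------------------------------------------------------------
# read sets
# ---------------------------------------------------------------------------

def _default_mixture() -> dict[tuple[int, int], float]:
    return {(22, 22): 0.5, (27, 32): 0.5}


@dataclass(frozen=True)
class ReadSimSpec:
    """Parameters for the interval-level small-RNA read simulator."""

    contig_lengths: Mapping[str, int]
    n_reads: int
    cluster_fraction: float = 0.0
    n_clusters: int = 1
    pingpong_fraction: float = 0.0
    length_mixture: Mapping[tuple[int, int], float] = field(
        default_factory=_default_mixture
    )
    window: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.contig_lengths:
            raise SimulationError("at least one contig required")
        if any(l <= 0 for l in self.contig_lengths.values()):
            raise SimulationError("contig lengths must be positive")
        if self.n_reads < 1:
            raise SimulationError("n_reads must be >= 1")
        for frac, label in (
            (self.cluster_fraction, "cluster_fraction"),
            (self.pingpong_fraction, "pingpong_fraction"),
        ):
            if not 0.0 <= frac <= 1.0:
                raise SimulationError(f"{label} must be in [0, 1]")
        if self.cluster_fraction > 0 and self.n_clusters < 1:
            raise SimulationError("n_clusters must be >= 1 when clustering")
        total = sum(self.length_mixture.values())
        if not np.isclose(total, 1.0):
            raise SimulationError("length mixture probabilities must sum to 1")
        for (lo, hi) in self.length_mixture:
            if not (1 <= lo <= hi):
                raise SimulationError(f"invalid length class ({lo}, {hi})")


def gen_read_set(spec: ReadSimSpec, seed: int | None = None) -> list[ReadInterval]:
    """Simulate mapped reads as intervals, fully determined by the seed.

    ``cluster_fraction`` of reads fall into ``n_clusters`` grid-aligned
    windows of ``window`` bp; ``pingpong_fraction`` of piRNA-length reads
    are emitted as opposite-strand partner pairs constructed so that the
    minus-read 5' end sits exactly 9 nt right of the plus-read 5' end
    (a 10-nt 5' overlap).
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    contigs = sorted(spec.contig_lengths)
    lengths = np.array([spec.contig_lengths[c] for c in contigs], dtype=float)
    contig_probs = lengths / lengths.sum()

    classes = sorted(spec.length_mixture)
    class_probs = np.array([spec.length_mixture[c] for c in classes], dtype=float)
    class_probs = class_probs / class_probs.sum()

    clusters: list[tuple[str, int]] = []
    if spec.cluster_fraction > 0:
        fitting = [c for c in contigs if spec.contig_lengths[c] >= spec.window]
        if not fitting:
            raise SimulationError(
                f"no contig can hold a {spec.window} bp cluster window"
            )
        fit_lengths = np.array([spec.contig_lengths[c] for c in fitting], dtype=float)
        fit_probs = fit_lengths / fit_lengths.sum()
        for _ in range(spec.n_clusters):
            contig = fitting[int(rng.choice(len(fitting), p=fit_probs))]
            n_windows = spec.contig_lengths[contig] // spec.window
            idx = int(rng.integers(0, n_windows))
            clusters.append((contig, idx * spec.window))

    reads: list[ReadInterval] = []
    while len(reads) < spec.n_reads:
        lo, hi = classes[int(rng.choice(len(classes), p=class_probs))]
        read_len = int(rng.integers(lo, hi + 1))
        pingpong = (
            read_len >= 27
            and spec.pingpong_fraction > 0
            and rng.random() < spec.pingpong_fraction
            and spec.n_reads - len(reads) >= 2
        )
        margin = read_len - 10 if pingpong else 0  # keep the partner on-contig
        if spec.cluster_fraction > 0 and rng.random() < spec.cluster_fraction:
            contig, wstart = clusters[int(rng.integers(0, len(clusters)))]
            high = wstart + spec.window - read_len
            start = int(rng.integers(wstart + margin, high + 1))
        else:
            contig = contigs[int(rng.choice(len(contigs), p=contig_probs))]
            high = spec.contig_lengths[contig] - read_len
            if high < margin:
                raise SimulationError(
                    f"contig {contig!r} too short for a {read_len} nt read"
                )
            start = int(rng.integers(margin, high + 1))
        if pingpong:
            reads.append(ReadInterval(contig, start, start + read_len, "+"))
            minus_end = start + 10  # 5' overlap of exactly 10 nt
            reads.append(ReadInterval(contig, minus_end - read_len, minus_end, "-"))
        else:
            strand = "+" if rng.random() < 0.5 else "-"
            reads.append(ReadInterval(contig, start, start + read_len, strand))
    return reads


# ---------------------------------------------------------------------------
# species summary tables
# ---------------------------------------------------------------------------

_RESPONSE_COLUMNS = ("core_gene_losses", "gene_count", "morph_losses")


def gen_species_summary(
    n_taxa: int,
    slope: float,
    intercept: float,
    noise_sd: float,
    seed: int,
    *,
    x_range: tuple[float, float] = (0.0, 40.0),
    response: str = "core_gene_losses",
) -> list[SpeciesSummaryRow]:
    """Species rows with a planted linear relation plus Gaussian noise.

    microRNA-loss values are integers evenly spread over *x_range*; the
    *response* column equals ``slope * x + intercept + N(0, noise_sd)``
    rounded to nonnegative integers.  N50 is drawn independently so it is
    uncorrelated with the losses.
    """
    if n_taxa < 3:
        raise SimulationError("n_taxa must be >= 3")
    if noise_sd < 0:
        raise SimulationError("noise_sd must be >= 0")
    if response not in _RESPONSE_COLUMNS:
        raise SimulationError(f"response must be one of {_RESPONSE_COLUMNS}")
    rng = np.random.default_rng(seed)
    x = np.rint(np.linspace(x_range[0], x_range[1], n_taxa)).astype(int)
    noise = rng.normal(0.0, noise_sd, n_taxa) if noise_sd > 0 else np.zeros(n_taxa)
    y = np.maximum(np.rint(slope * x + intercept + noise), 0).astype(int)
    n50 = rng.integers(10**5, 10**7, n_taxa)
    fillers = {
        "core_gene_losses": rng.integers(0, 400, n_taxa),
        "gene_count": rng.integers(8000, 30000, n_taxa),
        "morph_losses": rng.integers(0, 30, n_taxa),
    }
    rows: list[SpeciesSummaryRow] = []
    for i in range(n_taxa):
        cols = {k: int(v[i]) for k, v in fillers.items()}
        cols[response] = int(y[i])
        rows.append(
            SpeciesSummaryRow(
                taxon=f"taxon_{i + 1:02d}",
                mirna_losses=int(x[i]),
                n50=int(n50[i]),
                **cols,
            )
        )
    return rows
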