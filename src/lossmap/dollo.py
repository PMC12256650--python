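"""Irreversible (single-gain, multiple-loss) event mapping on a fixed tree.

For a character that is ancestrally present, an internal node is scored
present iff at least one descendant tip is definitely present (the root is
forced present); a loss is counted on every branch whose parent is present
and whose child is definitely absent.  This places the minimal number of
loss events consistent with the tip states under irreversibility: losses sit
at the tops of maximal present-free subtrees that contain at least one
definitely absent tip.

For a character that is ancestrally absent, a single gain is placed at the
most recent common ancestor of the possessing tips, with losses mapped below
that node by the same rule.

Unknown tip cells neither generate events nor rescue presence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .core import ABSENT, PRESENT, UNKNOWN, CharacterMatrix
from .tree import PhyloTree, TreeError

log = logging.getLogger(__name__)


class DolloError(ValueError):
    pass


@dataclass(frozen=True)
class PolaritySpec:
    """How to resolve each character's ancestral state at the root.

    mode 'root-present' forces every character ancestrally present unless
    overridden; mode 'outgroup' polarizes from the listed outgroup taxa,
    with disagreement between outgroups resolved as unknown (the character
    is excluded from counting and logged).
    """

    mode: str = "root-present"
    outgroups: tuple[str, ...] = ()
    overrides: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mode not in ("root-present", "outgroup"):
            raise ValueError(f"unknown polarity mode {self.mode!r}")
        if self.mode == "outgroup" and not self.outgroups:
            raise ValueError("outgroup polarity requires at least one outgroup taxon")
        for char, state in self.overrides.items():
            if state not in ("present", "absent"):
                raise ValueError(f"override for {char!r} must be present/absent")


@dataclass
class StateReconstruction:
    """Per-character node states plus event placements."""

    tree: PhyloTree
    characters: list[str]
    node_states: dict[str, dict[str, int]]  # character -> node -> state code
    loss_branches: dict[str, list[str]]     # character -> child labels of loss edges
    gain_nodes: dict[str, str | None]       # character -> gain node (None if ancestral)
    skipped: list[str]                      # characters with unresolved polarity


@dataclass
class BranchEventTable:
    """Per-branch loss/gain counts with per-character event lists.

    Branches are identified by their child node label and listed in
    deterministic preorder; the root row can only carry gains (a gain whose
    placement is the root itself).
    """

    tree: PhyloTree
    branches: list[str]
    losses: dict[str, int]
    gains: dict[str, int]
    loss_characters: dict[str, list[str]]
    gain_characters: dict[str, list[str]]

    @property
    def total_losses(self) -> int:
        return sum(self.losses.values())

    @property
    def total_gains(self) -> int:
        return sum(self.gains.values())

    def to_payload(self) -> dict:
        return {
            "branches": [
                {
                    "branch": b,
                    "losses": self.losses[b],
                    "gains": self.gains[b],
                    "lost_characters": list(self.loss_characters[b]),
                    "gained_characters": list(self.gain_characters[b]),
                }
                for b in self.branches
            ],
            "total_losses": self.total_losses,
            "total_gains": self.total_gains,
        }


# ---------------------------------------------------------------------------
# polarity resolution
# ---------------------------------------------------------------------------

def resolve_polarity(
    matrix: CharacterMatrix, polarity: PolaritySpec
) -> dict[str, int | None]:
    """Ancestral state per character; None means unresolved (tie), skip."""
    out: dict[str, int | None] = {}
    if polarity.mode == "outgroup":
        for og in polarity.outgroups:
            if not matrix.has_taxon(og):
                raise DolloError(f"outgroup taxon {og!r} not in matrix")
    for char in matrix.characters:
        override = polarity.overrides.get(char)
        if override is not None:
            out[char] = PRESENT if override == "present" else ABSENT
            continue
        if polarity.mode == "root-present":
            out[char] = PRESENT
            continue
        states = {
            matrix.cell(og, char)
            for og in polarity.outgroups
            if matrix.cell(og, char) != UNKNOWN
        }
        if len(states) == 1:
            out[char] = states.pop()
        else:
            out[char] = None  # all-unknown or disagreeing outgroups
            log.warning(
                "character %r: outgroup polarity unresolved, excluded", char
            )
    return out


# ---------------------------------------------------------------------------
# reconstruction
# ---------------------------------------------------------------------------

def _tip_state(matrix: CharacterMatrix, taxon: str, char: str) -> int:
    return matrix.cell(taxon, char) if matrix.has_taxon(taxon) else UNKNOWN


def _propagate(
    tree: PhyloTree,
    tip_states: Mapping[str, int],
    subtree_root: str,
) -> dict[str, int]:
    """Three-valued presence below each node of the subtree.

    present if any descendant tip definitely present; absent if none present
    but some definitely absent; unknown if all descendant tips unknown.
    The subtree root is forced present afterwards by the caller.
    """
    states: dict[str, int] = {}
    root_node = tree.node(subtree_root)
    order = []
    stack = [root_node]
    while stack:
        n = stack.pop()
        order.append(n)
        stack.extend(n.children)
    for node in reversed(order):
        if node.is_leaf():
            states[node.name] = tip_states.get(node.name, UNKNOWN)
        else:
            child_states = [states[c.name] for c in node.children]
            if PRESENT in child_states:
                states[node.name] = PRESENT
            elif ABSENT in child_states:
                states[node.name] = ABSENT
            else:
                states[node.name] = UNKNOWN
    return states


def _loss_edges(
    tree: PhyloTree, states: Mapping[str, int], subtree_root: str
) -> list[str]:
    """Child labels of edges with parent present and child definitely absent."""
    out: list[str] = []
    stack = [tree.node(subtree_root)]
    while stack:
        node = stack.pop()
        if states.get(node.name, ABSENT) != PRESENT:
            continue
        for child in reversed(node.children):
            if states[child.name] == ABSENT:
                out.append(child.name)  # type: ignore[arg-type]
            elif states[child.name] == PRESENT:
                stack.append(child)
    return out


def reconstruct_states(
    matrix: CharacterMatrix,
    tree: PhyloTree,
    polarity: PolaritySpec | None = None,
) -> StateReconstruction:
    """Map every character's losses (and single gain, if novel) onto *tree*."""
    polarity = polarity or PolaritySpec()
    for taxon in matrix.taxa:
        if taxon not in tree or not tree.is_tip(taxon):
            raise DolloError(f"matrix taxon {taxon!r} is not a tip of the tree")
    ancestral = resolve_polarity(matrix, polarity)

    node_states: dict[str, dict[str, int]] = {}
    loss_branches: dict[str, list[str]] = {}
    gain_nodes: dict[str, str | None] = {}
    skipped: list[str] = []

    for char in matrix.characters:
        anc = ancestral[char]
        if anc is None:
            skipped.append(char)
            continue
        tip_states = {t: _tip_state(matrix, t, char) for t in tree.tips}
        if anc == PRESENT:
            states = _propagate(tree, tip_states, tree.root.name)
            states[tree.root.name] = PRESENT  # root forced present
            loss_branches[char] = _loss_edges(tree, states, tree.root.name)
            gain_nodes[char] = None
        else:
            possessing = [t for t, s in tip_states.items() if s == PRESENT]
            if not possessing:
                log.warning(
                    "character %r: ancestrally absent with no possessing tips", char
                )
                states = {n.name: ABSENT for n in tree.preorder()}
                loss_branches[char] = []
                gain_nodes[char] = None
                node_states[char] = states
                continue
            gain = tree.mrca(possessing)
            states = {n.name: ABSENT for n in tree.preorder()}
            sub = _propagate(tree, tip_states, gain)
            states.update(sub)
            states[gain] = PRESENT
            loss_branches[char] = _loss_edges(tree, states, gain)
            gain_nodes[char] = gain
        node_states[char] = states

    return StateReconstruction(
        tree=tree,
        characters=[c for c in matrix.characters if c not in set(skipped)],
        node_states=node_states,
        loss_branches=loss_branches,
        gain_nodes=gain_nodes,
        skipped=skipped,
    )


def count_branch_events(recon: StateReconstruction) -> BranchEventTable:
    """Tabulate per-branch losses and gains from a reconstruction."""
    tree = recon.tree
    branches = [tree.root.name] + [child for _p, child in tree.branches()]
    losses = {b: 0 for b in branches}
    gains = {b: 0 for b in branches}
    loss_chars: dict[str, list[str]] = {b: [] for b in branches}
    gain_chars: dict[str, list[str]] = {b: [] for b in branches}
    for char in recon.characters:
        for b in recon.loss_branches[char]:
            losses[b] += 1
            loss_chars[b].append(char)
        g = recon.gain_nodes[char]
        if g is not None:
            gains[g] += 1
            gain_chars[g].append(char)
    return BranchEventTable(
        tree=tree,
        branches=branches,
        losses=losses,
        gains=gains,
        loss_characters=loss_chars,
        gain_characters=gain_chars,
    )


def map_losses(
    matrix: CharacterMatrix,
    tree: PhyloTree,
    polarity: PolaritySpec | None = None,
) -> BranchEventTable:
    """Convenience: reconstruct states and tabulate branch events."""
    return count_branch_events(reconstruct_states(matrix, tree, polarity))


def cumulative_tip_losses(table: BranchEventTable, tip: str) -> int:
    """Sum of loss events on the root-to-tip path."""
    if tip not in table.tree or not table.tree.is_tip(tip):
        raise DolloError(f"unknown tip {tip!r}")
    return sum(table.losses[name] for name in table.tree.path_from_root(tip))


def shared_missing(matrix: CharacterMatrix, taxa: Iterable[str]) -> list[str]:
    """Characters definitely absent in every listed taxon (sorted)."""
    taxa = list(taxa)
    if not taxa:
        raise DolloError("shared_missing requires a nonempty taxon set")
    for t in taxa:
        if not matrix.has_taxon(t):
            raise DolloError(f"unknown taxon {t!r}")
    out = [
        char
        for char in matrix.characters
        if all(matrix.cell(t, char) == ABSENT for t in taxa)
    ]
    return sorted(out)
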