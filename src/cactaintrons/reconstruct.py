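"""Ancestral intron configurations by weighted parsimony.

Each conserved boundary region defines one binary character: a taxon
scores 1 if at least one of its boundaries falls in that region.  On a
rooted tree (multifurcations allowed) the minimal-cost ancestral
labelling per character is found with the Sankoff dynamic program under
asymmetric event costs — by default a gain (0 -> 1) costs 2 and a loss
(1 -> 0) costs 1, encoding that intron loss predominates in this gene
family while a shared clade-specific intron can still be explained by a
single gain rather than many independent losses.  Equal costs degenerate
to unweighted (Fitch) parsimony; a very large gain cost yields Dollo
behaviour (at most one gain per character).

Ties at the root are resolved by the configured policy (default: prefer
presence, i.e. the intron-early reading) and flagged as ambiguous.
The root exon count is the number of characters present at the root
plus one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import dendropy
import numpy as np

GAIN = "gain"
LOSS = "loss"


@dataclass(frozen=True)
class CharacterMatrix:
    """Taxa x characters binary presence/absence matrix.

    ``data[i, j]`` is 1 iff taxon *i* carries an intron in region
    (character) *j*.  ``exon_counts`` optionally carries each taxon's
    observed exon number.
    """

    taxa: tuple[str, ...]
    characters: tuple[str, ...]
    data: np.ndarray
    exon_counts: Optional[dict[str, int]] = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.shape != (len(self.taxa), len(self.characters)):
            raise ValueError(
                f"matrix shape {arr.shape} does not match "
                f"{len(self.taxa)} taxa x {len(self.characters)} characters"
            )
        if not np.isin(arr, (0, 1)).all():
            raise ValueError("character states must be 0 or 1")

    def state(self, taxon: str, character: str) -> int:
        return int(self.data[self.taxa.index(taxon), self.characters.index(character)])

    def row(self, taxon: str) -> tuple[int, ...]:
        return tuple(int(x) for x in self.data[self.taxa.index(taxon)])


def build_character_matrix(
    table,
    region_set,
    taxa: Sequence[str],
    intronless: Sequence[str] = (),
) -> CharacterMatrix:
    """Build the intron presence/absence matrix from region membership.

    Parameters
    ----------
    table : BoundaryTable
        Projected boundary table.
    region_set : RegionSet
        Called regions; each region becomes one character.
    taxa
        All taxa to include (tree tips).  A taxon with no boundaries in
        *table* must be listed in *intronless* (single-exon transposase),
        otherwise it is an error.

    A taxon scores 1 for a region iff at least one of its boundaries is
    a member of that region.
    """
    table_names = set(table.names)
    intronless_set = set(intronless)
    characters = tuple(region.label for region in region_set.regions)
    membership: dict[str, set[str]] = {c: set() for c in characters}
    for region in region_set.regions:
        for rec in region.members:
            membership[region.label].add(rec.name)
    rows = []
    exon_counts: dict[str, int] = {}
    for taxon in taxa:
        if taxon not in table_names:
            if taxon not in intronless_set:
                raise ValueError(
                    f"taxon {taxon!r} has no boundaries and is not declared intronless"
                )
            exon_counts[taxon] = 1
        else:
            exon_counts[taxon] = len(table.for_name(taxon)) + 1
        rows.append([1 if taxon in membership[c] else 0 for c in characters])
    return CharacterMatrix(
        taxa=tuple(taxa),
        characters=characters,
        data=np.array(rows, dtype=np.int8),
        exon_counts=exon_counts,
    )


def clade_consensus_exons(
    tree: dendropy.Tree,
    clade_map: Mapping[str, str],
    exon_counts: Mapping[str, int],
) -> dict[str, tuple[int, bool]]:
    """Majority-rule consensus exon number per clade.

    Returns ``clade -> (consensus, ambiguous)`` where the consensus is
    the modal exon count of the clade's taxa; on a tie the larger count
    wins and the clade is flagged ambiguous.
    """
    tips = {leaf.taxon.label for leaf in tree.leaf_node_iter() if leaf.taxon}
    unassigned = tips - set(clade_map)
    if unassigned:
        raise ValueError(f"taxa not assigned to a clade: {', '.join(sorted(unassigned))}")
    clades: dict[str, list[int]] = {}
    for taxon, clade in clade_map.items():
        clades.setdefault(clade, []).append(exon_counts[taxon])
    out: dict[str, tuple[int, bool]] = {}
    for clade, counts in clades.items():
        if not counts:
            raise ValueError(f"clade {clade!r} is empty")
        freq: dict[int, int] = {}
        for c in counts:
            freq[c] = freq.get(c, 0) + 1
        top = max(freq.values())
        modes = sorted(k for k, v in freq.items() if v == top)
        out[clade] = (modes[-1], len(modes) > 1)
    return out


@dataclass(frozen=True)
class ReconstructionConfig:
    """Event costs and the root tie policy for parsimony reconstruction."""

    gain_cost: float = 2.0
    loss_cost: float = 1.0
    root_tie: str = "presence"  # or "absence"

    def __post_init__(self) -> None:
        if self.gain_cost <= 0 or self.loss_cost <= 0:
            raise ValueError("event costs must be positive")
        if self.root_tie not in ("presence", "absence"):
            raise ValueError(f"unknown root_tie policy {self.root_tie!r}")


@dataclass(frozen=True)
class Event:
    """A state change on the edge above *node* for one character."""

    node: str
    character: str
    kind: str  # gain | loss

    def as_tuple(self) -> tuple[str, str, str]:
        return (self.node, self.character, self.kind)


@dataclass
class Reconstruction:
    """Result of a parsimony reconstruction.

    ``node_states[label][char]`` is the chosen state of each (labelled)
    node; ``state_sets`` holds the set of root states achieving minimal
    cost per character (more than one element marks a root ambiguity).
    """

    tree: dendropy.Tree
    characters: tuple[str, ...]
    node_states: dict[str, dict[str, int]]
    root_state_sets: dict[str, frozenset[int]]
    character_costs: dict[str, float]
    total_cost: float
    events: list[Event]
    config: ReconstructionConfig

    @property
    def root_states(self) -> dict[str, int]:
        root_label = _node_label(self.tree.seed_node)
        return dict(self.node_states[root_label])

    @property
    def root_exon_count(self) -> int:
        """Characters present at the root, plus one."""
        return sum(self.root_states.values()) + 1

    @property
    def ambiguous_root_characters(self) -> tuple[str, ...]:
        return tuple(c for c in self.characters if len(self.root_state_sets[c]) > 1)


def _node_label(node: dendropy.Node) -> str:
    if node.is_leaf() and node.taxon is not None:
        return node.taxon.label
    return node.label


def label_internal_nodes(tree: dendropy.Tree, prefix: str = "N") -> None:
    """Give every unlabelled internal node a stable preorder label."""
    counter = 1
    for node in tree.preorder_node_iter():
        if not node.is_leaf() and not node.label:
            node.label = f"{prefix}{counter}"
        counter += 1


def parsimony_reconstruct(
    tree: dendropy.Tree,
    matrix: CharacterMatrix,
    config: ReconstructionConfig | None = None,
) -> Reconstruction:
    """Weighted small-parsimony (Sankoff) reconstruction per character.

    Runs the bottom-up cost recursion ``S_v(s) = sum_children min_t
    (c(s, t) + S_child(t))`` with ``c(0,1) = gain_cost`` and
    ``c(1,0) = loss_cost``, then traces back deterministically: the root
    takes the cheapest state (ties per ``root_tie`` policy, flagged);
    a child keeps its parent's state whenever that is among the optima,
    preferring presence otherwise.  Multifurcations are handled
    natively.  Raises if a matrix taxon is missing from the tree, or a
    tip lacks a matrix row.
    """
    config = config or ReconstructionConfig()
    label_internal_nodes(tree)
    tips = {leaf.taxon.label for leaf in tree.leaf_node_iter() if leaf.taxon}
    missing = [t for t in matrix.taxa if t not in tips]
    if missing:
        raise ValueError(f"matrix taxa absent from tree: {', '.join(missing)}")
    unscored = sorted(tips - set(matrix.taxa))
    if unscored:
        raise ValueError(f"tree tips without character data: {', '.join(unscored)}")

    cost = [[0.0, config.gain_cost], [config.loss_cost, 0.0]]
    node_states: dict[str, dict[str, int]] = {
        _node_label(node): {} for node in tree.preorder_node_iter()
    }
    root_state_sets: dict[str, frozenset[int]] = {}
    character_costs: dict[str, float] = {}
    events: list[Event] = []

    for j, char in enumerate(matrix.characters):
        tip_state = {t: int(matrix.data[i, j]) for i, t in enumerate(matrix.taxa)}
        S: dict[dendropy.Node, list[float]] = {}
        for node in tree.postorder_node_iter():
            if node.is_leaf():
                s = tip_state[node.taxon.label]
                S[node] = [0.0 if s == 0 else math.inf, 0.0 if s == 1 else math.inf]
            else:
                totals = [0.0, 0.0]
                for child in node.child_nodes():
                    for s in (0, 1):
                        totals[s] += min(cost[s][t] + S[child][t] for t in (0, 1))
                S[node] = totals

        root = tree.seed_node
        best = min(S[root])
        optima = frozenset(s for s in (0, 1) if S[root][s] == best)
        root_state_sets[char] = optima
        character_costs[char] = best
        if len(optima) == 1:
            root_state = next(iter(optima))
        else:
            root_state = 1 if config.root_tie == "presence" else 0

        # top-down traceback
        chosen: dict[dendropy.Node, int] = {root: root_state}
        for node in tree.preorder_node_iter():
            if node is root:
                continue
            ps = chosen[node.parent_node]
            c0 = cost[ps][0] + S[node][0]
            c1 = cost[ps][1] + S[node][1]
            if c0 == c1:
                state = ps  # tie: prefer no event on this edge
            else:
                state = 0 if c0 < c1 else 1
            chosen[node] = state
            if state != ps:
                events.append(
                    Event(node=_node_label(node), character=char, kind=GAIN if state == 1 else LOSS)
                )
        for node, state in chosen.items():
            node_states.setdefault(_node_label(node), {})[char] = state

    return Reconstruction(
        tree=tree,
        characters=matrix.characters,
        node_states=node_states,
        root_state_sets=root_state_sets,
        character_costs=character_costs,
        total_cost=sum(character_costs.values()),
        events=events,
        config=config,
    )


def enumerate_events(
    reconstruction: Reconstruction,
    tree: dendropy.Tree | None = None,
) -> tuple[list[Event], dict]:
    """The event list plus a root summary.

    Returns ``(events, summary)`` where the summary reports the root
    intron configuration, the implied root exon count (present
    characters + 1), per-character costs and any root ambiguities.
    """
    recon = reconstruction
    summary = {
        "root_configuration": {c: s for c, s in recon.root_states.items()},
        "root_introns": sorted(c for c, s in recon.root_states.items() if s == 1),
        "root_exon_count": recon.root_exon_count,
        "total_cost": recon.total_cost,
        "n_gains": sum(1 for e in recon.events if e.kind == GAIN),
        "n_losses": sum(1 for e in recon.events if e.kind == LOSS),
        "ambiguous_root_characters": list(recon.ambiguous_root_characters),
    }
    return list(recon.events), summary


def replay_events(reconstruction: Reconstruction) -> dict[str, dict[str, int]]:
    """Replay the event list from the root; returns resulting tip states.

    Used as an internal consistency check: the replayed tip states must
    equal the observed character matrix.
    """
    recon = reconstruction
    events_by_node: dict[str, list[Event]] = {}
    for e in recon.events:
        events_by_node.setdefault(e.node, []).append(e)
    states: dict[dendropy.Node, dict[str, int]] = {}
    tips: dict[str, dict[str, int]] = {}
    for node in recon.tree.preorder_node_iter():
        if node is recon.tree.seed_node:
            states[node] = dict(recon.root_states)
        else:
            current = dict(states[node.parent_node])
            for e in events_by_node.get(_node_label(node), []):
                current[e.character] = 1 if e.kind == GAIN else 0
            states[node] = current
        if node.is_leaf():
            tips[node.taxon.label] = states[node]
    return tips


def write_events(events: Sequence[Event], path) -> None:
    with open(path, "w") as fh:
        fh.write("node\tcharacter\tevent\n")
        for e in events:
            fh.write(f"{e.node}\t{e.character}\t{e.kind}\n")
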