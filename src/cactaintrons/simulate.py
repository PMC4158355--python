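"""Simulate a transposase family evolving on a tree, with ground truth.

The simulator evolves a root protein along a rooted tree under site
substitutions, insertions/deletions, and intron loss and gain, and emits
everything the pipeline consumes — true alignment, residue confidence
scores, boundary table, tree — together with the full truth (per-node
intron states, event history), so every downstream stage can be scored
against known answers.

Model
-----
* Substitutions: uniform exchangeability over the 20 amino acids;
  the count per branch is Poisson(``sub_rate`` x branch length x
  sequence length).  The pipeline never uses substitution-model detail,
  only alignment and score structure.
* Indels: events are Poisson(``indel_rate`` x branch length x length);
  insertion and deletion are equiprobable, lengths geometric with mean
  ``indel_mean_len``, placement uniform.  Every residue is tagged with a
  homology token at its creation; the true alignment is the global
  order of tokens, so gap structure traces the recorded indel history
  exactly.  Deletions never erase a sequence entirely.
* Introns: each intron is anchored to the token of its boundary
  residue.  Loss happens per intron with probability
  ``1 - exp(-loss_rate x branch length)``; gains are Poisson
  (``gain_rate`` x branch length) per lineage, at a uniform residue,
  creating a new character.  If a deletion removes an anchor token the
  intron re-anchors to the nearest surviving residue.
* Scores: residues in columns untouched by indels score around
  ``score_base``; columns whose token was inserted, or flanks a
  deletion, are depressed by ``score_indel_penalty`` — emulating how
  alignment-confidence methods mark indel-rich columns as unreliable.
  Gaussian noise of width ``score_noise`` is added and scores are
  clipped to [0, 1].

Event sampling order is fixed (tree, then per-branch: substitutions,
indels, losses, gains, then scores) and all randomness flows from a
single seeded generator, so identical configurations give byte-identical
outputs.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import dendropy
import numpy as np

from cactaintrons.io import (
    Alignment,
    BoundaryRecord,
    BoundaryTable,
    ResidueScores,
    parse_newick,
    write_alignment_fasta,
    write_boundary_table,
    write_residue_scores,
)
from cactaintrons.reconstruct import Event, GAIN, LOSS, label_internal_nodes
from cactaintrons.regions import Cluster, ClusterConfig, Region, RegionSet

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class IntronSpec:
    """A root intron: boundary after residue ``position``, length in aa."""

    position: int
    length_aa: int


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of a simulation run.

    Rates are per unit branch length; substitution and indel rates are
    additionally per site.  Defaults describe a moderately diverged
    family of a dozen consensus sequences: a 400-residue protein with
    three ancestral introns whose shortest is 33 aa (so the derived
    clustering threshold is 16), average substitution load of a few
    tens of changes per branch, a light indel load, and loss clearly
    outpacing gain.
    """

    seed: int = 0
    tree: Optional[str] = None  # newick; if None, a pure-birth tree is sampled
    n_tips: int = 12
    birth_rate: float = 1.0
    root_length: int = 400
    root_introns: tuple[IntronSpec, ...] = (
        IntronSpec(100, 45),
        IntronSpec(200, 39),
        IntronSpec(300, 33),
    )
    sub_rate: float = 0.5
    indel_rate: float = 0.02
    indel_mean_len: float = 3.0
    loss_rate: float = 0.3
    gain_rate: float = 0.1
    #: per-branch loss-rate overrides, keyed by the child node's label
    branch_loss_rates: tuple[tuple[str, float], ...] = ()
    gain_length_aa: int = 50
    score_base: float = 0.95
    score_indel_penalty: float = 0.35
    score_noise: float = 0.03

    def __post_init__(self) -> None:
        if self.root_length < 1:
            raise ValueError("root_length must be >= 1 (cannot gain introns into an empty protein)")
        for rate in (self.sub_rate, self.indel_rate, self.loss_rate, self.gain_rate):
            if rate < 0:
                raise ValueError("rates must be >= 0")
        positions = [i.position for i in self.root_introns]
        if positions != sorted(set(positions)):
            raise ValueError("root intron positions must be strictly increasing")
        if positions and (positions[0] < 1 or positions[-1] > self.root_length):
            raise ValueError("root intron positions must lie within the protein")
        if any(i.length_aa < 1 for i in self.root_introns):
            raise ValueError("intron lengths must be positive")


class _Lineage:
    """Mutable per-node sequence state during the tree walk."""

    __slots__ = ("tokens", "chars", "introns")

    def __init__(self, tokens: list[int], chars: list[str], introns: dict[str, int]):
        self.tokens = tokens  # homology token per residue
        self.chars = chars  # amino acid per residue
        self.introns = introns  # character id -> anchor token

    def copy(self) -> "_Lineage":
        return _Lineage(list(self.tokens), list(self.chars), dict(self.introns))


@dataclass
class SimulatedDataset:
    """Everything one simulation run produced, inputs and truth alike."""

    config: SimulationConfig
    tree: dendropy.Tree
    alignment: Alignment
    scores: ResidueScores
    boundaries: BoundaryTable
    tip_sequences: dict[str, str]
    node_states: dict[str, frozenset[str]]
    events: list[Event]
    intron_lengths: dict[str, int]
    indel_affected_columns: frozenset[int]

    @property
    def characters(self) -> tuple[str, ...]:
        return tuple(sorted(self.intron_lengths))

    def true_region_set(self, min_region_size: int = 4) -> RegionSet:
        """Regions straight from the true character labels (one per character)."""
        groups: dict[str, list[BoundaryRecord]] = {}
        for rec in self.boundaries.projected():
            groups.setdefault(rec.region, []).append(rec)
        clusters = tuple(
            Cluster(members=tuple(sorted(g, key=lambda r: (r.msa_col, r.name, r.index))))
            for _, g in sorted(groups.items())
        )
        config = ClusterConfig(threshold=10**9, min_region_size=min_region_size)
        promoted = sorted(
            (c for c in clusters if c.size >= min_region_size), key=lambda c: c.mean_column
        )
        regions = tuple(
            Region(label=f"R{i}", cluster=c) for i, c in enumerate(promoted, start=1)
        )
        return RegionSet(clusters=clusters, regions=regions, config=config)


def _sample_tree(config: SimulationConfig, rng: random.Random) -> dendropy.Tree:
    from dendropy.simulate import treesim

    tree = treesim.birth_death_tree(
        birth_rate=config.birth_rate,
        death_rate=0.0,
        num_extant_tips=config.n_tips,
        rng=rng,
    )
    tree.is_rooted = True
    for i, leaf in enumerate(tree.leaf_node_iter(), start=1):
        leaf.taxon.label = f"T{i}"
    return tree


def simulate_dataset(config: SimulationConfig | None = None, **overrides) -> SimulatedDataset:
    """Run one simulation; fully reproducible from ``config.seed``."""
    if config is None:
        config = SimulationConfig(**overrides)
    elif overrides:
        config = replace(config, **overrides)

    rng = np.random.default_rng(config.seed)
    if config.tree is not None:
        tree = parse_newick(config.tree)
        for edge in tree.preorder_edge_iter():
            if edge.length is None:
                edge.length = 1.0
    else:
        tree = _sample_tree(config, random.Random(int(rng.integers(0, 2**31 - 1))))
    label_internal_nodes(tree)

    next_token = config.root_length + 1
    global_order: list[int] = list(range(1, config.root_length + 1))
    affected: set[int] = set()
    gain_counter = 0
    intron_lengths: dict[str, int] = {}

    root_chars = [AMINO_ACIDS[i] for i in rng.integers(0, len(AMINO_ACIDS), config.root_length)]
    root_introns: dict[str, int] = {}
    for k, spec in enumerate(config.root_introns, start=1):
        char_id = f"c{k}"
        root_introns[char_id] = spec.position  # token ids at root equal positions
        intron_lengths[char_id] = spec.length_aa
    root_state = _Lineage(list(range(1, config.root_length + 1)), root_chars, root_introns)

    events: list[Event] = []
    node_states: dict[str, frozenset[str]] = {}
    lineages: dict[dendropy.Node, _Lineage] = {}

    def node_label(node: dendropy.Node) -> str:
        return node.taxon.label if node.is_leaf() and node.taxon else node.label

    def evolve_branch(state: _Lineage, t: float, child_label: str) -> _Lineage:
        nonlocal next_token, gain_counter
        state = state.copy()
        L = len(state.tokens)

        # 1) substitutions
        n_sub = rng.poisson(config.sub_rate * t * L)
        for _ in range(n_sub):
            site = int(rng.integers(0, L))
            old = state.chars[site]
            choices = AMINO_ACIDS.replace(old, "")
            state.chars[site] = choices[int(rng.integers(0, len(choices)))]

        # 2) indels
        n_indel = rng.poisson(config.indel_rate * t * L)
        for _ in range(n_indel):
            length = int(rng.geometric(1.0 / config.indel_mean_len))
            if rng.random() < 0.5:  # insertion after position i (0..L)
                i = int(rng.integers(0, len(state.tokens) + 1))
                new_tokens = list(range(next_token, next_token + length))
                next_token += length
                new_chars = [
                    AMINO_ACIDS[j] for j in rng.integers(0, len(AMINO_ACIDS), length)
                ]
                if i == 0:
                    gpos = global_order.index(state.tokens[0]) if state.tokens else 0
                else:
                    gpos = global_order.index(state.tokens[i - 1]) + 1
                global_order[gpos:gpos] = new_tokens
                state.tokens[i:i] = new_tokens
                state.chars[i:i] = new_chars
                affected.update(new_tokens)
            else:  # deletion, never erasing the whole sequence
                Lc = len(state.tokens)
                if Lc <= 1:
                    continue
                start = int(rng.integers(0, Lc))
                length = min(length, Lc - start, Lc - 1)
                if length <= 0:
                    continue
                doomed = state.tokens[start : start + length]
                if start > 0:
                    affected.add(state.tokens[start - 1])
                if start + length < Lc:
                    affected.add(state.tokens[start + length])
                del state.tokens[start : start + length]
                del state.chars[start : start + length]
                doomed_set = set(doomed)
                for char_id, anchor in list(state.introns.items()):
                    if anchor in doomed_set:
                        state.introns[char_id] = _reanchor(state, start)

        # 3) intron loss
        loss_rate = dict(config.branch_loss_rates).get(child_label, config.loss_rate)
        p_loss = 1.0 - math.exp(-loss_rate * t)
        for char_id in sorted(state.introns):
            if rng.random() < p_loss:
                del state.introns[char_id]
                events.append(Event(node=child_label, character=char_id, kind=LOSS))

        # 4) intron gain (anchor must not collide with an existing boundary)
        n_gain = rng.poisson(config.gain_rate * t)
        for _ in range(n_gain):
            pos = int(rng.integers(0, len(state.tokens)))
            anchor = _free_anchor(state, pos)
            if anchor is None:
                continue  # every residue already carries a boundary
            gain_counter += 1
            char_id = f"g{gain_counter}"
            state.introns[char_id] = anchor
            intron_lengths[char_id] = config.gain_length_aa
            events.append(Event(node=child_label, character=char_id, kind=GAIN))
        return state

    def _free_anchor(state: _Lineage, pos: int) -> Optional[int]:
        taken = set(state.introns.values())
        for offset in range(len(state.tokens)):
            for idx in (pos + offset, pos - offset):
                if 0 <= idx < len(state.tokens) and state.tokens[idx] not in taken:
                    return state.tokens[idx]
        return None

    def _reanchor(state: _Lineage, deletion_start: int) -> int:
        """Nearest surviving residue token not already anchoring an intron."""
        taken = set(state.introns.values())
        order = []
        for offset in range(len(state.tokens)):
            for idx in (deletion_start - 1 - offset, deletion_start + offset):
                if 0 <= idx < len(state.tokens):
                    order.append(state.tokens[idx])
        for token in order:
            if token not in taken:
                return token
        return state.tokens[0]

    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            lineages[node] = root_state
        else:
            parent_state = lineages[node.parent_node]
            t = node.edge.length if node.edge.length is not None else 1.0
            lineages[node] = evolve_branch(parent_state, t, node_label(node))
        node_states[node_label(node)] = frozenset(lineages[node].introns)

    # assemble the true alignment from tokens surviving in >= 1 tip
    tip_nodes = [n for n in tree.leaf_node_iter()]
    tip_tokens = {node_label(n): lineages[n].tokens for n in tip_nodes}
    used = set().union(*(set(toks) for toks in tip_tokens.values()))
    columns = [tok for tok in global_order if tok in used]
    col_of = {tok: i for i, tok in enumerate(columns, start=1)}

    names, rows = [], []
    tip_sequences: dict[str, str] = {}
    for n in tip_nodes:
        name = node_label(n)
        st = lineages[n]
        pos_of = {tok: i for i, tok in enumerate(st.tokens)}
        row = [
            st.chars[pos_of[tok]] if tok in pos_of else "-" for tok in columns
        ]
        names.append(name)
        rows.append("".join(row))
        tip_sequences[name] = "".join(st.chars)
    alignment = Alignment(names=tuple(names), rows=tuple(rows))

    # residue confidence scores, depressed in indel-affected columns
    score_map: dict[tuple[int, int], float] = {}
    for r, name in enumerate(names, start=1):
        row = rows[r - 1]
        for c, ch in enumerate(row, start=1):
            if ch == "-":
                continue
            base = config.score_base
            if columns[c - 1] in affected:
                base -= config.score_indel_penalty
            noise = float(rng.normal(0.0, config.score_noise))
            score_map[(r, c)] = min(1.0, max(0.0, base + noise))
    scores = ResidueScores(scores=score_map)

    # true boundary table
    records: list[BoundaryRecord] = []
    for name in names:
        n = next(t for t in tip_nodes if node_label(t) == name)
        st = lineages[n]
        pos_of = {tok: i + 1 for i, tok in enumerate(st.tokens)}
        entries = sorted(
            ((pos_of[anchor], char_id) for char_id, anchor in st.introns.items()),
        )
        for idx, (pos, char_id) in enumerate(entries, start=1):
            records.append(
                BoundaryRecord(
                    name=name,
                    index=idx,
                    protein_pos=pos,
                    msa_col=col_of[st.tokens[pos - 1]],
                    region=char_id,
                )
            )
    boundaries = BoundaryTable(records=tuple(records))

    return SimulatedDataset(
        config=config,
        tree=tree,
        alignment=alignment,
        scores=scores,
        boundaries=boundaries,
        tip_sequences=tip_sequences,
        node_states=node_states,
        events=events,
        intron_lengths=dict(intron_lengths),
        indel_affected_columns=frozenset(
            col_of[tok] for tok in affected if tok in col_of
        ),
    )


# ---------------------------------------------------------------------------
# Recovery evaluation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RecoveryReport:
    """How well inference on simulated inputs recovered the truth.

    ``region_recall`` is measured over *eligible* true characters —
    those with at least ``min_region_size`` boundaries among the
    boundaries the clustering actually saw (boundaries trimmed away
    cannot be recovered by construction).  ``region_precision`` is the
    fraction of region-member boundaries that belong to the character
    their region was matched to.  Root-state and event accuracies are
    over matched characters and ``None`` when no reconstruction is
    supplied.
    """

    region_precision: float
    region_recall: float
    root_state_accuracy: Optional[float] = None
    event_accuracy: Optional[float] = None
    matching: dict[str, str] = field(default_factory=dict)  # region label -> character


def evaluate_recovery(
    truth: SimulatedDataset,
    region_set: RegionSet,
    reconstruction=None,
) -> RecoveryReport:
    """Score inferred regions (and optionally a reconstruction) against truth."""
    char_of_boundary = {rec.label: rec.region for rec in truth.boundaries.projected()}
    seen_labels = {lab for cluster in region_set.clusters for lab in cluster.labels}
    min_size = region_set.config.min_region_size

    char_members: dict[str, set[str]] = {}
    for lab, char in char_of_boundary.items():
        if lab in seen_labels:
            char_members.setdefault(char, set()).add(lab)
    eligible = {c for c, members in char_members.items() if len(members) >= min_size}

    region_members = {r.label: set(r.cluster.labels) for r in region_set.regions}

    # greedy maximal-overlap assignment, deterministic order
    pairs = sorted(
        (
            (len(region_members[rl] & char_members.get(ch, set())), rl, ch)
            for rl in region_members
            for ch in char_members
        ),
        key=lambda t: (-t[0], t[1], t[2]),
    )
    matching: dict[str, str] = {}
    used_chars: set[str] = set()
    for overlap, rl, ch in pairs:
        if overlap == 0 or rl in matching or ch in used_chars:
            continue
        matching[rl] = ch
        used_chars.add(ch)

    total_in_regions = sum(len(m) for m in region_members.values())
    correct_in_regions = sum(
        len(region_members[rl] & char_members.get(ch, set())) for rl, ch in matching.items()
    )
    precision = correct_in_regions / total_in_regions if total_in_regions else 1.0

    if eligible:
        recovered = 0
        total = 0
        matched_char_to_region = {ch: rl for rl, ch in matching.items()}
        for ch in eligible:
            members = char_members[ch]
            total += len(members)
            rl = matched_char_to_region.get(ch)
            if rl is not None:
                recovered += len(members & region_members[rl])
        recall = recovered / total
    else:
        recall = 1.0

    root_acc = None
    event_acc = None
    if reconstruction is not None:
        matched = {rl: ch for rl, ch in matching.items() if rl in reconstruction.characters}
        root_states = reconstruction.root_states
        if matched:
            hits = 0
            for rl, ch in matched.items():
                true_state = 1 if ch in truth.node_states[_root_label(truth.tree)] else 0
                if root_states.get(rl) == true_state:
                    hits += 1
            root_acc = hits / len(matched)
        else:
            root_acc = 0.0
        true_events = [
            e for e in truth.events if e.character in {ch for ch in matched.values()}
        ]
        if true_events:
            char_to_region = {ch: rl for rl, ch in matched.items()}
            inferred = {
                (e.node, e.character, e.kind) for e in reconstruction.events
            }
            hits = sum(
                1
                for e in true_events
                if (e.node, char_to_region[e.character], e.kind) in inferred
            )
            event_acc = hits / len(true_events)
        else:
            event_acc = 1.0 if not reconstruction.events else None

    return RecoveryReport(
        region_precision=precision,
        region_recall=recall,
        root_state_accuracy=root_acc,
        event_accuracy=event_acc,
        matching=matching,
    )


def run_recovery(ds: SimulatedDataset, min_region_size: int = 4) -> RecoveryReport:
    """Full inference pass on a simulated dataset, scored against truth.

    Trims the true alignment with the simulated scores, projects the
    true boundaries through the resulting coordinate maps, derives the
    clustering threshold from the true intron lengths, clusters, builds
    the character matrix and reconstructs ancestral states — then scores
    everything against the simulator's ground truth.
    """
    from cactaintrons.annotate import Boundary
    from cactaintrons.project import project_boundaries
    from cactaintrons.reconstruct import build_character_matrix, parsimony_reconstruct
    from cactaintrons.regions import call_regions, cluster_boundaries, derive_threshold
    from cactaintrons.trim import build_coordinate_maps, trim_custom

    trimmed = trim_custom(ds.alignment, ds.scores)
    maps = build_coordinate_maps(ds.alignment, trimmed)
    boundaries = [
        Boundary(name=r.name, index=r.index, protein_pos=r.protein_pos,
                 phase=0, intron_len_aa=ds.intron_lengths[r.region])
        for r in ds.boundaries
    ]
    table = project_boundaries(boundaries, maps)
    threshold = derive_threshold([ds.intron_lengths[c] for c in ds.characters])
    config = ClusterConfig(threshold=threshold, min_region_size=min_region_size)
    clusters = cluster_boundaries(table.projected(), config)
    region_set = call_regions(clusters, config)
    tips = [leaf.taxon.label for leaf in ds.tree.leaf_node_iter()]
    intronless = tuple(t for t in tips if not ds.boundaries.for_name(t))
    matrix = build_character_matrix(table, region_set, tips, intronless=intronless)
    recon = parsimony_reconstruct(ds.tree, matrix)
    return evaluate_recovery(ds, region_set, recon)


def _root_label(tree: dendropy.Tree) -> str:
    root = tree.seed_node
    return root.taxon.label if root.is_leaf() and root.taxon else root.label


def write_dataset(ds: SimulatedDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write msa.fasta, scores.txt, boundaries.tsv, tree.nwk, truth_events.tsv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "msa": out / "msa.fasta",
        "scores": out / "scores.txt",
        "boundaries": out / "boundaries.tsv",
        "tree": out / "tree.nwk",
        "events": out / "truth_events.tsv",
        "node_states": out / "truth_node_states.tsv",
    }
    write_alignment_fasta(ds.alignment, paths["msa"])
    write_residue_scores(ds.scores, paths["scores"])
    write_boundary_table(ds.boundaries, paths["boundaries"])
    with open(paths["tree"], "w") as fh:
        fh.write(
            ds.tree.as_string(schema="newick", suppress_rooting=True).strip() + "\n"
        )
    with open(paths["events"], "w") as fh:
        fh.write("node\tcharacter\tevent\n")
        for e in ds.events:
            fh.write(f"{e.node}\t{e.character}\t{e.kind}\n")
    with open(paths["node_states"], "w") as fh:
        fh.write("node\tintrons\n")
        for label, chars in sorted(ds.node_states.items()):
            fh.write(f"{label}\t{','.join(sorted(chars)) if chars else '.'}\n")
    return paths
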