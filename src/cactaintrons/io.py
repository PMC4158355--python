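"""Readers and writers for the external formats the pipeline touches.

Coordinate conventions
----------------------
All public coordinates are 1-based and inclusive: alignment columns run
from 1 to ``n_columns``, alignment rows from 1 to ``n_rows``, and protein
residue positions from 1 to the ungapped sequence length.  A boundary
whose alignment column was trimmed away is represented in memory by
``None`` (the REMOVED sentinel) and serialized on disk as ``0``.

Gap characters are ``-`` and ``.``; every other character, including
``X`` and other ambiguity letters, counts as a residue and may carry a
confidence score.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Mapping, Optional

import dendropy
import pandas as pd
from Bio import SeqIO

GAP_CHARS = frozenset({"-", "."})

#: in-memory sentinel for a boundary whose column was trimmed away
REMOVED = None


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Alignment:
    """A protein multiple sequence alignment.

    Parameters
    ----------
    names
        Ordered, unique sequence identifiers.
    rows
        Aligned sequences, all of equal length, over the amino-acid
        alphabet plus the gap characters ``-`` and ``.``.
    """

    names: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.names) != len(self.rows):
            raise ValueError("names and rows must have equal length")
        if not self.rows:
            raise FormatError("alignment has no records")
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise FormatError("alignment rows have unequal lengths")
        if len(set(self.names)) != len(self.names):
            dupes = sorted({n for n in self.names if self.names.count(n) > 1})
            raise FormatError(f"duplicate sequence names: {', '.join(dupes)}")
        if self.n_columns < 1:
            raise FormatError("alignment must have at least one column")

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])

    def row_index(self, name: str) -> int:
        """0-based index of the row called *name*."""
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"no sequence named {name!r} in alignment") from None

    def is_gap(self, row: int, col: int) -> bool:
        """Whether the cell at 1-based (*row*, *col*) is a gap."""
        return self.rows[row - 1][col - 1] in GAP_CHARS

    def residue_cells(self) -> Iterator[tuple[int, int]]:
        """Yield 1-based (row, col) for every non-gap cell, row-major."""
        for r, row in enumerate(self.rows, start=1):
            for c, ch in enumerate(row, start=1):
                if ch not in GAP_CHARS:
                    yield r, c

    def ungapped(self, name: str) -> str:
        """Sequence of *name* with gaps stripped."""
        row = self.rows[self.row_index(name)]
        return "".join(ch for ch in row if ch not in GAP_CHARS)

    def column(self, col: int) -> str:
        """The 1-based column *col* as a vertical string."""
        return "".join(row[col - 1] for row in self.rows)


def read_alignment_fasta(path: str | Path) -> Alignment:
    """Read a FASTA multiple sequence alignment.

    Both ``-`` and ``.`` are recognized as gaps.  Records of unequal
    length or duplicate identifiers raise :class:`FormatError` naming the
    offending record.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: no records")
    names = [r.id for r in records]
    rows = [str(r.seq) for r in records]
    width = len(rows[0])
    for i, row in enumerate(rows):
        if len(row) != width:
            raise FormatError(
                f"{path}: record {i + 1} ({names[i]!r}) has length "
                f"{len(row)}, expected {width}"
            )
    seen: set[str] = set()
    for i, name in enumerate(names):
        if name in seen:
            raise FormatError(f"{path}: duplicate record name {name!r} (record {i + 1})")
        seen.add(name)
    return Alignment(names=tuple(names), rows=tuple(rows))


def write_alignment_fasta(alignment: Alignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, row in zip(alignment.names, alignment.rows):
            fh.write(f">{name}\n{row}\n")


# ---------------------------------------------------------------------------
# Residue confidence scores
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ResidueScores:
    """Per-residue alignment confidence scores in [0, 1].

    ``scores`` maps 1-based ``(row, col)`` to the confidence of the
    residue there; the support is exactly the set of non-gap alignment
    cells.
    """

    scores: Mapping[tuple[int, int], float]

    def __getitem__(self, cell: tuple[int, int]) -> float:
        return self.scores[cell]

    def get(self, row: int, col: int) -> Optional[float]:
        return self.scores.get((row, col))

    def __len__(self) -> int:
        return len(self.scores)


def read_residue_scores(path: str | Path, alignment: Alignment) -> ResidueScores:
    """Read a residue-score table (GUIDANCE dialect) against *alignment*.

    The file holds whitespace-delimited ``(column, row, score)`` triplets,
    1-based.  Lines starting with ``#`` are comments; a single leading
    header line of column titles is tolerated.  Every non-gap cell of the
    alignment must be scored; scores on gap cells, out-of-range scores,
    or out-of-bounds indices are errors.
    """
    scores: dict[tuple[int, int], float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if lineno == 1:
                try:
                    float(parts[0])
                except ValueError:
                    continue  # header of column titles
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: expected 'col row score', got {line!r}")
            try:
                col, row = int(parts[0]), int(parts[1])
                score = float(parts[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
            if not (1 <= row <= alignment.n_rows and 1 <= col <= alignment.n_columns):
                raise FormatError(
                    f"{path}:{lineno}: cell (row {row}, col {col}) outside "
                    f"{alignment.n_rows}x{alignment.n_columns} alignment"
                )
            if not 0.0 <= score <= 1.0:
                raise FormatError(f"{path}:{lineno}: score {score} outside [0, 1]")
            if alignment.is_gap(row, col):
                raise FormatError(
                    f"{path}:{lineno}: score given for gap cell (row {row}, col {col})"
                )
            scores[(row, col)] = score
    for row, col in alignment.residue_cells():
        if (row, col) not in scores:
            raise FormatError(
                f"{path}: missing score for residue cell (row {row}, col {col})"
            )
    return ResidueScores(scores=scores)


def write_residue_scores(scores: ResidueScores, path: str | Path) -> None:
    """Write scores as 1-based ``col row score`` triplets at fixed precision."""
    with open(path, "w") as fh:
        fh.write("#COL_NUMBER ROW_NUMBER RESIDUE_SCORE\n")
        for (row, col), s in sorted(scores.scores.items(), key=lambda kv: (kv[0][1], kv[0][0])):
            fh.write(f"{col} {row} {s:.6f}\n")


# ---------------------------------------------------------------------------
# Boundary tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BoundaryRecord:
    """One exon/intron boundary of one transposase.

    ``msa_col`` is the boundary's column on the trimmed alignment, or
    ``None`` if that column was removed by trimming (serialized as 0).
    ``region`` is an optional conserved-region label (serialized as '.').
    """

    name: str
    index: int
    protein_pos: int
    msa_col: Optional[int] = None
    region: Optional[str] = None

    @property
    def label(self) -> str:
        """Boundary name in the 5'-to-3' subscript convention, e.g. ``Baron_1``."""
        return f"{self.name}_{self.index}"

    @property
    def is_removed(self) -> bool:
        return self.msa_col is REMOVED


@dataclass(frozen=True)
class BoundaryTable:
    """All annotated boundaries of a transposase set, Table-1 style."""

    records: tuple[BoundaryRecord, ...]

    def __post_init__(self) -> None:
        seen: set[tuple[str, int]] = set()
        for rec in self.records:
            key = (rec.name, rec.index)
            if key in seen:
                raise FormatError(f"duplicate boundary ({rec.name}, {rec.index})")
            seen.add(key)
        by_name: dict[str, list[BoundaryRecord]] = {}
        for rec in self.records:
            by_name.setdefault(rec.name, []).append(rec)
        for name, group in by_name.items():
            recs = sorted(group, key=lambda r: r.index)
            if [r.index for r in recs] != list(range(1, len(recs) + 1)):
                raise FormatError(f"{name}: boundary indices not consecutive from 1")
            positions = [r.protein_pos for r in recs]
            if any(b <= a for a, b in zip(positions, positions[1:])):
                raise FormatError(f"{name}: protein positions not strictly increasing")

    def __iter__(self) -> Iterator[BoundaryRecord]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def names(self) -> tuple[str, ...]:
        out: list[str] = []
        for rec in self.records:
            if rec.name not in out:
                out.append(rec.name)
        return tuple(out)

    def projected(self) -> tuple[BoundaryRecord, ...]:
        """Records whose boundary survived trimming (non-REMOVED column)."""
        return tuple(r for r in self.records if not r.is_removed)

    def removed(self) -> tuple[BoundaryRecord, ...]:
        return tuple(r for r in self.records if r.is_removed)

    def for_name(self, name: str) -> tuple[BoundaryRecord, ...]:
        return tuple(r for r in self.records if r.name == name)


def read_boundary_table(path: str | Path) -> BoundaryTable:
    """Read a boundary TSV with columns name/index/protein_pos/msa_col/region."""
    df = pd.read_csv(path, sep="\t", dtype={"name": str, "region": str})
    required = ["name", "index", "protein_pos", "msa_col", "region"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    records = []
    for row in df.to_dict("records"):
        col = int(row["msa_col"])
        region = None if pd.isna(row["region"]) or row["region"] == "." else str(row["region"])
        records.append(
            BoundaryRecord(
                name=str(row["name"]),
                index=int(row["index"]),
                protein_pos=int(row["protein_pos"]),
                msa_col=REMOVED if col == 0 else col,
                region=region,
            )
        )
    return BoundaryTable(records=tuple(records))


def write_boundary_table(table: BoundaryTable, path: str | Path) -> None:
    """Write a boundary TSV; REMOVED as 0, absent region as '.'.

    ``read_boundary_table(write_boundary_table(t)) == t`` for any valid table.
    """
    with open(path, "w") as fh:
        fh.write("name\tindex\tprotein_pos\tmsa_col\tregion\n")
        for rec in table.records:
            col = 0 if rec.is_removed else rec.msa_col
            region = rec.region if rec.region is not None else "."
            fh.write(f"{rec.name}\t{rec.index}\t{rec.protein_pos}\t{col}\t{region}\n")


def load_packaged_table1() -> BoundaryTable:
    """The packaged transcription of the published boundary table.

    86 boundaries over 40 multi-exon transposases; 13 boundaries fall in
    trimmed-away columns (serialized 0) and 73 carry trimmed-MSA columns.
    """
    from importlib.resources import files

    return read_boundary_table(files("cactaintrons") / "data" / "table1.tsv")


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------


def read_newick_tree(path: str | Path) -> dendropy.Tree:
    """Read a single rooted Newick tree.

    Tip names must be unique; internal node labels are retained as clade
    names.  Underscores in labels are preserved literally.
    """
    try:
        tree = dendropy.Tree.get(
            path=str(path),
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise FormatError(f"{path}: newick parse error: {exc}") from exc
    tree.is_rooted = True
    tips = [leaf.taxon.label for leaf in tree.leaf_node_iter() if leaf.taxon is not None]
    dupes = sorted({t for t in tips if tips.count(t) > 1})
    if dupes:
        raise FormatError(f"{path}: duplicate tip names: {', '.join(dupes)}")
    return tree


def parse_newick(newick: str) -> dendropy.Tree:
    """Parse a Newick string with the same contract as :func:`read_newick_tree`."""
    try:
        tree = dendropy.Tree.get(
            data=newick,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:
        raise FormatError(f"newick parse error: {exc}") from exc
    tree.is_rooted = True
    tips = [leaf.taxon.label for leaf in tree.leaf_node_iter() if leaf.taxon is not None]
    dupes = sorted({t for t in tips if tips.count(t) > 1})
    if dupes:
        raise FormatError(f"duplicate tip names: {', '.join(dupes)}")
    return tree


def clade_nodes(tree: dendropy.Tree) -> dict[str, dendropy.Node]:
    """Map internal node labels to nodes (named clades)."""
    out: dict[str, dendropy.Node] = {}
    for node in tree.preorder_node_iter():
        if not node.is_leaf() and node.label:
            if node.label in out:
                raise FormatError(f"clade label {node.label!r} used more than once")
            out[node.label] = node
    return out
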