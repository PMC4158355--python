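"""Confidence-score based alignment trimming and coordinate maps.

Two column-removal rules are provided:

``custom``
    Remove a column iff it contains at most one residue, or every
    residue in it scores strictly below the residue threshold
    (default 0.804).  A residue scoring exactly at the threshold saves
    its column.  Single-residue columns are removed regardless of score
    ("not comparable and/or bad aligned").

``guidance_default``
    Remove a column iff its column confidence score is strictly below
    the cutoff (default 0.93).  When no native column-score table is
    supplied, the column score is the arithmetic mean of the residue
    scores in that column.

Trimming operates on columns only; rows are never removed.  The result
carries bidirectional maps between original and trimmed column
coordinates, and :func:`build_coordinate_maps` extends these to
per-sequence residue positions, which is what boundary projection needs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from cactaintrons.io import GAP_CHARS, REMOVED, Alignment, ResidueScores

#: removal reasons
ALL_BELOW = "all_below_threshold"
SINGLE_RESIDUE = "single_residue"
BELOW_CUTOFF = "below_column_cutoff"


@dataclass(frozen=True)
class TrimConfig:
    """Thresholds and mode for alignment trimming.

    ``residue_threshold`` is the custom-rule per-residue score threshold;
    ``default_column_cutoff`` the column-score cutoff of the default
    rule.  Both live in [0, 1].
    """

    residue_threshold: float = 0.804
    default_column_cutoff: float = 0.93
    drop_single_residue_columns: bool = True
    mode: str = "custom"

    def __post_init__(self) -> None:
        if not 0.0 <= self.residue_threshold <= 1.0:
            raise ValueError(f"residue_threshold {self.residue_threshold} outside [0, 1]")
        if not 0.0 <= self.default_column_cutoff <= 1.0:
            raise ValueError(f"default_column_cutoff {self.default_column_cutoff} outside [0, 1]")
        if self.mode not in ("custom", "guidance_default"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass(frozen=True)
class TrimResult:
    """Outcome of a trimming run.

    ``kept_columns`` are original 1-based column indices in increasing
    order; ``removed_columns`` maps each removed original column to its
    removal reason.  ``old_to_new`` maps kept original columns to their
    1-based positions on the trimmed alignment.
    """

    n_columns: int
    kept_columns: tuple[int, ...]
    removed_columns: dict[int, str]

    def __post_init__(self) -> None:
        if set(self.kept_columns) & set(self.removed_columns):
            raise ValueError("kept and removed column sets overlap")
        if len(self.kept_columns) + len(self.removed_columns) != self.n_columns:
            raise ValueError("kept + removed does not cover all columns")

    @property
    def n_kept(self) -> int:
        return len(self.kept_columns)

    @property
    def n_removed(self) -> int:
        return len(self.removed_columns)

    @property
    def old_to_new(self) -> dict[int, int]:
        return {old: new for new, old in enumerate(self.kept_columns, start=1)}

    @property
    def new_to_old(self) -> dict[int, int]:
        return {new: old for new, old in enumerate(self.kept_columns, start=1)}


def column_profile(
    alignment: Alignment, scores: ResidueScores
) -> list[tuple[int, Optional[float]]]:
    """Per-column (residue count, max residue score).

    The count excludes gaps; the max is over residue scores only and is
    ``None`` for all-gap columns.  Returned list is 0-based over the
    alignment's 1-based columns 1..n.
    """
    profile: list[tuple[int, Optional[float]]] = []
    for col in range(1, alignment.n_columns + 1):
        count = 0
        best: Optional[float] = None
        for row in range(1, alignment.n_rows + 1):
            if not alignment.is_gap(row, col):
                count += 1
                s = scores.get(row, col)
                if s is None:
                    raise ValueError(f"missing score for residue cell (row {row}, col {col})")
                if best is None or s > best:
                    best = s
        profile.append((count, best))
    return profile


def trim_custom(
    alignment: Alignment,
    scores: ResidueScores,
    config: TrimConfig | None = None,
) -> TrimResult:
    """Apply the custom residue-score trimming rule.

    A column is removed iff it has at most one residue (when
    ``drop_single_residue_columns``) or every residue in it scores
    strictly below ``residue_threshold``.  All-gap columns carry no
    comparable signal and are always removed (reason ``single_residue``).
    """
    config = config or TrimConfig(mode="custom")
    tau = config.residue_threshold
    kept: list[int] = []
    removed: dict[int, str] = {}
    for col, (count, best) in enumerate(column_profile(alignment, scores), start=1):
        if count == 0 or (count == 1 and config.drop_single_residue_columns):
            removed[col] = SINGLE_RESIDUE
        elif best is not None and best < tau:
            removed[col] = ALL_BELOW
        else:
            kept.append(col)
    return TrimResult(
        n_columns=alignment.n_columns,
        kept_columns=tuple(kept),
        removed_columns=removed,
    )


def trim_default_guidance(
    alignment: Alignment,
    column_scores: Sequence[float] | None = None,
    config: TrimConfig | None = None,
    scores: ResidueScores | None = None,
) -> TrimResult:
    """Apply the default column-score cutoff rule.

    ``column_scores`` holds one score per column (1..n order).  If
    absent, ``scores`` must be given and the column score is the mean of
    the residue scores in the column; all-gap columns then have no score
    and are removed.
    """
    config = config or TrimConfig(mode="guidance_default")
    cutoff = config.default_column_cutoff
    if column_scores is None:
        if scores is None:
            raise ValueError("either column_scores or residue scores must be supplied")
        column_scores = []
        for col in range(1, alignment.n_columns + 1):
            vals = [
                scores.scores[(row, col)]
                for row in range(1, alignment.n_rows + 1)
                if not alignment.is_gap(row, col)
            ]
            column_scores.append(sum(vals) / len(vals) if vals else -1.0)
    if len(column_scores) != alignment.n_columns:
        raise ValueError(
            f"{len(column_scores)} column scores for {alignment.n_columns} columns"
        )
    kept: list[int] = []
    removed: dict[int, str] = {}
    for col, s in enumerate(column_scores, start=1):
        if s < cutoff:
            removed[col] = BELOW_CUTOFF
        else:
            kept.append(col)
    return TrimResult(
        n_columns=alignment.n_columns,
        kept_columns=tuple(kept),
        removed_columns=removed,
    )


def apply_trim(alignment: Alignment, trim: TrimResult) -> Alignment:
    """The trimmed alignment (kept columns only, original row order)."""
    keep = [c - 1 for c in trim.kept_columns]
    rows = tuple("".join(row[i] for i in keep) for row in alignment.rows)
    return Alignment(names=alignment.names, rows=rows)


@dataclass(frozen=True)
class CoordinateMaps:
    """Bidirectional maps: residue position <-> original <-> trimmed column.

    For each sequence, residue *i* (1-based, gaps excluded) sits in the
    original column holding its i-th non-gap character; its trimmed
    column is defined only if that column survived trimming.
    """

    residue_to_original: dict[str, tuple[int, ...]]
    old_to_new: dict[int, int]
    new_to_old: dict[int, int]

    def residue_length(self, name: str) -> int:
        return len(self._row(name))

    def _row(self, name: str) -> tuple[int, ...]:
        try:
            return self.residue_to_original[name]
        except KeyError:
            raise KeyError(f"no sequence named {name!r}") from None

    def original_column(self, name: str, residue_pos: int) -> int:
        row = self._row(name)
        if not 1 <= residue_pos <= len(row):
            raise IndexError(
                f"{name}: residue position {residue_pos} beyond sequence length {len(row)}"
            )
        return row[residue_pos - 1]

    def trimmed_column(self, name: str, residue_pos: int) -> Optional[int]:
        """Trimmed column of a residue, or ``None`` if its column was removed."""
        return self.old_to_new.get(self.original_column(name, residue_pos), REMOVED)


def build_coordinate_maps(alignment: Alignment, trim: TrimResult) -> CoordinateMaps:
    """Build residue <-> column maps for *alignment* under *trim*."""
    if trim.n_columns != alignment.n_columns:
        raise ValueError(
            f"trim result covers {trim.n_columns} columns, alignment has {alignment.n_columns}"
        )
    residue_to_original: dict[str, tuple[int, ...]] = {}
    for name, row in zip(alignment.names, alignment.rows):
        cols = tuple(c for c, ch in enumerate(row, start=1) if ch not in GAP_CHARS)
        residue_to_original[name] = cols
    return CoordinateMaps(
        residue_to_original=residue_to_original,
        old_to_new=trim.old_to_new,
        new_to_old=trim.new_to_old,
    )


def identity_trim(alignment: Alignment) -> TrimResult:
    """A no-op trim (all columns kept), for untrimmed projections."""
    return TrimResult(
        n_columns=alignment.n_columns,
        kept_columns=tuple(range(1, alignment.n_columns + 1)),
        removed_columns={},
    )


def write_column_map(trim: TrimResult, path) -> None:
    """Write the column map TSV: old_col, new_col_or_0, reason ('.') for kept."""
    o2n = trim.old_to_new
    with open(path, "w") as fh:
        fh.write("old_col\tnew_col\treason\n")
        for col in range(1, trim.n_columns + 1):
            if col in o2n:
                fh.write(f"{col}\t{o2n[col]}\t.\n")
            else:
                fh.write(f"{col}\t0\t{trim.removed_columns[col]}\n")


def read_column_map(path) -> TrimResult:
    """Read a column map TSV written by :func:`write_column_map`."""
    kept: list[int] = []
    removed: dict[int, str] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("old_col"):
            raise ValueError(f"{path}: unexpected header {header!r}")
        for line in fh:
            if not line.strip():
                continue
            old, new, reason = line.rstrip("\n").split("\t")
            if int(new) == 0:
                removed[int(old)] = reason
            else:
                kept.append(int(old))
    return TrimResult(
        n_columns=len(kept) + len(removed),
        kept_columns=tuple(sorted(kept)),
        removed_columns=removed,
    )
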