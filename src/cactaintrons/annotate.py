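"""Exon coordinates to amino-acid boundary positions.

A transposase gene is annotated as an ordered list of exon spans on the
coding strand, 1-based inclusive nucleotide intervals.  The boundary
between exon *i* and exon *i+1* is expressed on the protein scale as the
residue whose codon contains, or immediately precedes, the intron:

* ``protein_pos = ceil(cum / 3)`` where *cum* is the cumulative coding
  length (nt) at the end of exon *i* — a boundary falling mid-codon is
  assigned to the split codon's residue;
* ``phase = cum mod 3`` (0: between codons; 1 or 2: that many
  nucleotides into the codon);
* ``intron_len_aa = floor(intron_nt / 3)`` measures the intron on the
  protein scale.

A trailing incomplete codon at the end of the CDS is dropped with a
warning, since consensus sequences may be frame-imperfect.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass
from pathlib import Path
from cactaintrons.io import BoundaryTable


@dataclass(frozen=True)
class ExonModel:
    """Ordered exon spans of one transposase gene.

    Spans are 1-based inclusive nucleotide intervals on the coding
    strand, strictly increasing and non-overlapping, with total coding
    length of at least one codon.
    """

    name: str
    spans: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if not self.spans:
            raise ValueError(f"{self.name}: exon model needs at least one span")
        for start, end in self.spans:
            if start < 1 or end < start:
                raise ValueError(f"{self.name}: invalid span ({start}, {end})")
        for (s1, e1), (s2, e2) in zip(self.spans, self.spans[1:]):
            if s2 <= e1:
                raise ValueError(
                    f"{self.name}: spans ({s1},{e1}) and ({s2},{e2}) overlap or are out of order"
                )
        if self.coding_length < 3:
            raise ValueError(f"{self.name}: total coding length {self.coding_length} < 3")

    @property
    def coding_length(self) -> int:
        return sum(e - s + 1 for s, e in self.spans)

    @property
    def protein_length(self) -> int:
        """Complete codons in the CDS (trailing partial codon dropped)."""
        return self.coding_length // 3


@dataclass(frozen=True)
class Boundary:
    """One exon/intron boundary in protein coordinates.

    ``index`` counts boundaries 1-based in the 5' to 3' direction; the
    first boundary is also the beginning of the first intron.
    """

    name: str
    index: int
    protein_pos: int
    phase: int
    intron_len_aa: int


def exons_to_boundaries(model: ExonModel) -> list[Boundary]:
    """Convert an exon model to its k-1 protein-space boundaries.

    A single-exon model yields an empty list.
    """
    leftover = model.coding_length % 3
    if leftover:
        warnings.warn(
            f"{model.name}: CDS length {model.coding_length} not a multiple of 3; "
            f"dropping trailing {leftover} nt",
            stacklevel=2,
        )
    boundaries: list[Boundary] = []
    cum = 0
    for i, ((s, e), (s_next, _)) in enumerate(zip(model.spans, model.spans[1:]), start=1):
        cum += e - s + 1
        intron_nt = s_next - e - 1
        boundaries.append(
            Boundary(
                name=model.name,
                index=i,
                protein_pos=math.ceil(cum / 3),
                phase=cum % 3,
                intron_len_aa=intron_nt // 3,
            )
        )
    return boundaries


_JOIN_RE = re.compile(r"^(?:join\()?\s*([\d.,\s<>]+?)\)?$")


def parse_exon_spans(name: str, text: str) -> ExonModel:
    """Parse a minimal EMBL-style span expression like ``join(1..90,151..300)``.

    A bare ``a..b`` (single exon) is accepted; ``<`` / ``>`` partiality
    markers are ignored.
    """
    m = _JOIN_RE.match(text.strip())
    if m is None:
        raise ValueError(f"{name}: cannot parse span expression {text!r}")
    spans = []
    for piece in m.group(1).split(","):
        piece = piece.strip().replace("<", "").replace(">", "")
        if not piece:
            continue
        parts = piece.split("..")
        if len(parts) != 2:
            raise ValueError(f"{name}: bad interval {piece!r} in {text!r}")
        spans.append((int(parts[0]), int(parts[1])))
    return ExonModel(name=name, spans=tuple(spans))


def read_exon_models(path: str | Path) -> list[ExonModel]:
    """Read a TSV of exon models: columns ``name`` and ``spans``."""
    models = []
    with open(path) as fh:
        header = fh.readline().strip().split("\t")
        try:
            i_name, i_spans = header.index("name"), header.index("spans")
        except ValueError:
            raise ValueError(f"{path}: header must contain 'name' and 'spans'") from None
        for line in fh:
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            models.append(parse_exon_spans(parts[i_name], parts[i_spans]))
    return models


@dataclass(frozen=True)
class BoundarySummary:
    total: int
    projected: int
    removed: int
    exon_counts: dict[str, int]


def summarize_boundaries(table: BoundaryTable) -> BoundarySummary:
    """Count total/projected/removed boundaries and per-transposase exons.

    ``total == projected + removed``; a transposase with *k* boundaries
    has *k + 1* exons.
    """
    exon_counts = {name: len(table.for_name(name)) + 1 for name in table.names}
    projected = len(table.projected())
    removed = len(table.removed())
    return BoundarySummary(
        total=len(table),
        projected=projected,
        removed=removed,
        exon_counts=exon_counts,
    )
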