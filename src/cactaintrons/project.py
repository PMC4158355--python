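"""Lift boundaries from protein coordinates onto trimmed alignment columns.

Each boundary names a residue of its transposase; projection finds the
alignment column holding that residue and maps it through the trimming
column map.  A boundary whose residue sits in a removed column is
reported with the REMOVED sentinel rather than snapped to the nearest
kept column — clustering must not see fabricated positions.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Optional, Sequence

from cactaintrons.annotate import Boundary
from cactaintrons.io import BoundaryRecord, BoundaryTable
from cactaintrons.trim import CoordinateMaps


def project_boundaries(
    boundaries: Sequence[Boundary] | Iterable[Boundary],
    maps: CoordinateMaps,
    regions: Optional[Mapping[str, str]] = None,
) -> BoundaryTable:
    """Project protein-space boundaries onto trimmed alignment columns.

    Parameters
    ----------
    boundaries
        Protein-space boundaries (one per transposase/index pair).
    maps
        Coordinate maps from :func:`cactaintrons.trim.build_coordinate_maps`.
    regions
        Optional boundary-label -> region-label annotations to attach.

    Returns
    -------
    BoundaryTable
        Table-1-style records; ``msa_col`` is the trimmed column of the
        boundary residue or ``None`` if that column was trimmed away.
        Projection is order-preserving: among the surviving boundaries of
        one transposase, trimmed columns increase with boundary index.
    """
    records = []
    for b in sorted(boundaries, key=lambda b: (b.name, b.index)):
        col = maps.trimmed_column(b.name, b.protein_pos)  # raises on unknown name/pos
        label = f"{b.name}_{b.index}"
        records.append(
            BoundaryRecord(
                name=b.name,
                index=b.index,
                protein_pos=b.protein_pos,
                msa_col=col,
                region=regions.get(label) if regions else None,
            )
        )
    return BoundaryTable(records=tuple(records))
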