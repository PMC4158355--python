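"""Cluster boundary columns on the trimmed alignment into conserved regions.

Boundaries that survived trimming are points on the trimmed-alignment
column axis; the distance between two boundaries is the absolute
difference of their columns.  Clusters are built by diameter-constrained
agglomeration: the closest pair of clusters (nearest-neighbour distance)
is merged first, but a merge is allowed only while the merged cluster's
diameter — its maximum pairwise distance — stays within the threshold.
The threshold itself is derived as half the length of the shortest
annotated intron (floor), the largest shift a boundary could undergo
while staying nearer its own region than a neighbouring one.

The diameter cap, not plain single linkage, is essential: with
boundaries at columns 895, 910 and 920, unconstrained nearest-neighbour
chaining would fuse two distinct regions through the middle point, while
the diameter criterion keeps them apart and leaves the chaining point
unclustered.  "Closer than the threshold" is implemented inclusively
(<=): a region may span exactly the threshold.

Clusters reaching ``min_region_size`` members are promoted to named
regions (R1, R2, ... by increasing mean column); smaller clusters are
classified ``small_cluster`` (2-3 members) or ``singleton``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from cactaintrons.io import BoundaryRecord, BoundaryTable

REGION_MEMBER = "region_member"
SMALL_CLUSTER = "small_cluster"
SINGLETON = "singleton"
NOT_EVALUATED = "not_evaluated"


@dataclass(frozen=True)
class ClusterConfig:
    """Clustering threshold (alignment columns) and region promotion size."""

    threshold: int = 16
    min_region_size: int = 4

    def __post_init__(self) -> None:
        if self.threshold < 0:
            raise ValueError("threshold must be >= 0")
        if self.min_region_size < 1:
            raise ValueError("min_region_size must be >= 1")


def derive_threshold(intron_lengths_aa: Sequence[int]) -> int:
    """Half the shortest annotated intron length (floor), in residues.

    This is the maximal distance at which two boundary columns are still
    considered to mark the same region.
    """
    lengths = list(intron_lengths_aa)
    if not lengths:
        raise ValueError("no intron lengths given; supply a threshold explicitly")
    if min(lengths) <= 0:
        raise ValueError("intron lengths must be positive")
    return min(lengths) // 2


def pairwise_distances(table: BoundaryTable | Sequence[BoundaryRecord]) -> pd.DataFrame:
    """Symmetric matrix of column distances between projected boundaries.

    Rows/columns are labelled ``Name_index``; ``d(i, j) = |col_i - col_j|``.
    Raises if any boundary lacks a trimmed column (REMOVED).
    """
    records = list(table)
    removed = [r.label for r in records if r.is_removed]
    if removed:
        raise ValueError(f"REMOVED boundaries have no column: {', '.join(removed)}")
    labels = [r.label for r in records]
    cols = np.array([r.msa_col for r in records], dtype=int)
    dist = np.abs(cols[:, None] - cols[None, :])
    return pd.DataFrame(dist, index=labels, columns=labels)


@dataclass(frozen=True)
class Cluster:
    """A set of projected boundaries whose pairwise distances fit the threshold."""

    members: tuple[BoundaryRecord, ...]

    @property
    def columns(self) -> tuple[int, ...]:
        return tuple(r.msa_col for r in self.members)

    @property
    def span(self) -> tuple[int, int]:
        cols = self.columns
        return (min(cols), max(cols))

    @property
    def diameter(self) -> int:
        lo, hi = self.span
        return hi - lo

    @property
    def mean_column(self) -> float:
        return float(np.mean(self.columns))

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(r.label for r in self.members)


def _sorted_records(records: Iterable[BoundaryRecord]) -> list[BoundaryRecord]:
    return sorted(records, key=lambda r: (r.msa_col, r.name, r.index))


def cluster_boundaries(
    table: BoundaryTable | Sequence[BoundaryRecord],
    config: ClusterConfig | None = None,
) -> list[Cluster]:
    """Diameter-constrained nearest-neighbour agglomeration.

    Starting from singletons, repeatedly merge the closest pair of
    clusters (smallest nearest-neighbour distance between members)
    whose merged diameter stays within ``config.threshold`` (inclusive).
    Ties are broken by the smallest leftmost column of the merged pair,
    then lexicographically by member labels, so the outcome is invariant
    under permutation of the input.

    Returns clusters sorted by increasing minimum column.
    """
    config = config or ClusterConfig()
    records = _sorted_records(
        r for r in (table if not isinstance(table, BoundaryTable) else table.records)
        if not r.is_removed
    )
    clusters: list[Cluster] = [Cluster(members=(r,)) for r in records]
    while True:
        best = None  # (linkage, min_col_union, labels_union, i, j)
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                a, b = clusters[i], clusters[j]
                lo = min(a.span[0], b.span[0])
                hi = max(a.span[1], b.span[1])
                if hi - lo > config.threshold:
                    continue
                linkage = min(
                    abs(ca - cb) for ca in a.columns for cb in b.columns
                )
                key = (linkage, lo, tuple(sorted(a.labels + b.labels)))
                if best is None or key < best[:3]:
                    best = (*key, i, j)
        if best is None:
            break
        i, j = best[3], best[4]
        merged = Cluster(members=tuple(_sorted_records(clusters[i].members + clusters[j].members)))
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)] + [merged]
    return sorted(clusters, key=lambda c: (c.span[0], c.labels))


@dataclass(frozen=True)
class Region:
    """A promoted cluster with its region label."""

    label: str
    cluster: Cluster

    @property
    def span(self) -> tuple[int, int]:
        return self.cluster.span

    @property
    def members(self) -> tuple[BoundaryRecord, ...]:
        return self.cluster.members


@dataclass(frozen=True)
class RegionSet:
    """All clusters plus the subset promoted to regions."""

    clusters: tuple[Cluster, ...]
    regions: tuple[Region, ...]
    config: ClusterConfig

    def region_of(self, boundary_label: str) -> Optional[str]:
        for region in self.regions:
            if boundary_label in region.cluster.labels:
                return region.label
        return None

    def cluster_of(self, boundary_label: str) -> Optional[Cluster]:
        for cluster in self.clusters:
            if boundary_label in cluster.labels:
                return cluster
        return None


def call_regions(
    clusters: Sequence[Cluster],
    config: ClusterConfig | None = None,
) -> RegionSet:
    """Promote clusters of size >= ``min_region_size`` to labelled regions.

    Regions are labelled R1, R2, ... in increasing mean-column order.
    """
    config = config or ClusterConfig()
    promoted = sorted(
        (c for c in clusters if c.size >= config.min_region_size),
        key=lambda c: c.mean_column,
    )
    regions = tuple(Region(label=f"R{i}", cluster=c) for i, c in enumerate(promoted, start=1))
    return RegionSet(clusters=tuple(clusters), regions=regions, config=config)


def region_gap_stats(
    region_set: RegionSet,
    table: BoundaryTable | Sequence[BoundaryRecord],
) -> dict[str, tuple[Optional[int], Optional[int]]]:
    """Nearest outside-boundary distances per region (upstream, downstream).

    The upstream gap is the region's minimum column minus the largest
    boundary column below it (any projected boundary counts, whether or
    not it belongs to another region); the downstream gap is analogous.
    A side with no outside boundary yields ``None``.
    """
    records = [
        r for r in (table if not isinstance(table, BoundaryTable) else table.records)
        if not r.is_removed
    ]
    all_cols = sorted(r.msa_col for r in records)
    out: dict[str, tuple[Optional[int], Optional[int]]] = {}
    for region in region_set.regions:
        lo, hi = region.span
        below = [c for c in all_cols if c < lo]
        above = [c for c in all_cols if c > hi]
        out[region.label] = (
            lo - max(below) if below else None,
            min(above) - hi if above else None,
        )
    return out


def classify_boundaries(
    region_set: RegionSet,
    table: BoundaryTable | Sequence[BoundaryRecord] | None = None,
) -> dict[str, str]:
    """Label every boundary: region member (conserved), small cluster, or singleton.

    If *table* is given, its REMOVED boundaries are labelled
    ``not_evaluated`` as well.
    """
    out: dict[str, str] = {}
    promoted = {id(r.cluster) for r in region_set.regions}
    for cluster in region_set.clusters:
        if id(cluster) in promoted or cluster.size >= region_set.config.min_region_size:
            label = REGION_MEMBER
        elif cluster.size >= 2:
            label = SMALL_CLUSTER
        else:
            label = SINGLETON
        for member in cluster.labels:
            out[member] = label
    if table is not None:
        records = table if not isinstance(table, BoundaryTable) else table.records
        for r in records:
            if r.is_removed:
                out[r.label] = NOT_EVALUATED
    return out


def write_distance_matrix(distances: pd.DataFrame, path) -> None:
    """Write a lower-triangle distance TSV (matrix rows in label order)."""
    labels = list(distances.index)
    with open(path, "w") as fh:
        fh.write("boundary\t" + "\t".join(labels) + "\n")
        for i, lab in enumerate(labels):
            vals = [str(int(distances.iat[i, j])) if j <= i else "" for j in range(len(labels))]
            fh.write(lab + "\t" + "\t".join(vals) + "\n")


def write_regions(region_set: RegionSet, classification: dict[str, str], path) -> None:
    """Write per-boundary region assignments as TSV."""
    with open(path, "w") as fh:
        fh.write("boundary\tmsa_col\tregion\tclassification\tcluster_span\n")
        for cluster in region_set.clusters:
            for rec in cluster.members:
                region = region_set.region_of(rec.label) or "."
                lo, hi = cluster.span
                fh.write(
                    f"{rec.label}\t{rec.msa_col}\t{region}\t"
                    f"{classification.get(rec.label, '.')}\t{lo}-{hi}\n"
                )
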