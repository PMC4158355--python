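"""Shared fixtures and helpers for the test suite."""

from __future__ import annotations

import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from cactaintrons.io import Alignment, ResidueScores, load_packaged_table1
from cactaintrons.regions import ClusterConfig, call_regions, cluster_boundaries

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_alignment(*rows: str, names=None) -> Alignment:
    names = names or [f"s{i}" for i in range(1, len(rows) + 1)]
    return Alignment(names=tuple(names), rows=tuple(rows))


def uniform_scores(alignment: Alignment, value: float = 1.0, overrides=None) -> ResidueScores:
    """Scores of *value* on every residue cell, with optional (row, col) overrides."""
    overrides = overrides or {}
    scores = {}
    for row, col in alignment.residue_cells():
        scores[(row, col)] = overrides.get((row, col), value)
    return ResidueScores(scores=scores)


@pytest.fixture(scope="session")
def table1():
    """The packaged transcription of the published boundary table."""
    return load_packaged_table1()


@pytest.fixture(scope="session")
def fixture_regions(table1):
    """Regions called on the fixture at threshold 16, min size 4."""
    config = ClusterConfig(threshold=16, min_region_size=4)
    clusters = cluster_boundaries(table1.projected(), config)
    return call_regions(clusters, config)


@pytest.fixture(scope="session")
def clade_fixture():
    """Figure-derived clade-level tree and intron states."""
    from importlib.resources import files

    from cactaintrons.io import read_newick_tree
    from cactaintrons.reconstruct import CharacterMatrix

    data = files("cactaintrons") / "data"
    tree = read_newick_tree(data / "clade_tree_figure_derived.nwk")
    df = pd.read_csv(data / "clade_states_figure_derived.tsv", sep="\t")
    chars = ("G", "I", "II", "III")
    matrix = CharacterMatrix(
        taxa=tuple(df["clade"]),
        characters=chars,
        data=df[list(chars)].to_numpy(),
        exon_counts=dict(zip(df["clade"], df["consensus_exons"])),
    )
    return tree, matrix
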