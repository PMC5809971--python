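"""Shared fixtures: small hand-built trees, random tree generators and a
synthetic population frequency table."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from ylineage.phylogeny import CladeTree, Node
from ylineage.popstats import FrequencyTable


def annotate_counts(tree: CladeTree, counts: dict[int, int]) -> CladeTree:
    """Copy a timed genealogy and set each branch's mutation list to a dummy
    list of the given length (only counts matter for rho arithmetic)."""
    out = tree.copy()
    pos = 1
    for node in out.preorder():
        k = counts.get(node.id, 0)
        node.mutations = list(range(pos, pos + k))
        pos += k
    return out


def random_mutation_tree(rng: np.random.Generator, n_tips: int) -> CladeTree:
    """A random rooted binary tree with random integer branch lengths,
    for formula cross-checks."""
    nodes = [Node(name=f"T{i}") for i in range(n_tips)]
    pos = 1
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = Node()
        for child in (nodes[i], nodes[j]):
            k = int(rng.integers(0, 6))
            child.mutations = list(range(pos, pos + k))
            pos += k
            parent.add(child)
        nodes = [n for k_, n in enumerate(nodes) if k_ not in (i, j)]
        nodes.append(parent)
    nodes[0].mutations = []
    return CladeTree(nodes[0])


@pytest.fixture
def balanced_four_tip_tree() -> CladeTree:
    """((A,B),(C,D)) with one mutation on every internal branch."""
    root = Node(mutations=[])
    left = root.add(Node(mutations=[100]))
    right = root.add(Node(mutations=[200]))
    left.add(Node(name="A", mutations=[]))
    left.add(Node(name="B", mutations=[]))
    right.add(Node(name="C", mutations=[]))
    right.add(Node(name="D", mutations=[]))
    return CladeTree(root)


def synthetic_s5_table() -> FrequencyTable:
    """A small population x lineage count table with the annotations the
    collapsing procedure needs (synthetic stand-in for a genotyping panel:
    regions, a nomadic group, an American admixed group, one singleton
    lineage)."""
    rows = [
        # population, macroregion, family, nomadic, n, then lineage counts
        ("Moroccans", "Northwestern Africa", "Afro-asiatic", False, 50,
         8, 2, 0, 3, 1, 1),
        ("Egyptians", "Northeastern Africa", "Afro-asiatic", False, 40,
         4, 2, 2, 2, 4, 0),
        ("Yoruba", "Western Africa", "Niger-Congo", False, 60,
         5, 20, 10, 6, 2, 0),
        ("Daza", "Central Sahel", "Nilo-Saharan", False, 30,
         2, 6, 8, 3, 1, 0),
        ("Tuareg", "Central Sahel", "Afro-asiatic", True, 30,
         9, 9, 2, 0, 0, 0),
        ("ASW", "American admixed", "Niger-Congo", False, 50,
         4, 18, 8, 5, 3, 0),
    ]
    lineages = ["E-a", "E-b", "E-c", "E-d", "E-e", "E-sing"]
    df = pd.DataFrame(
        rows,
        columns=["population", "macroregion", "linguistic_family", "nomadic",
                 "n", *lineages],
    ).set_index("population")
    return FrequencyTable(
        counts=df[lineages],
        meta=df[["macroregion", "linguistic_family", "nomadic", "n"]],
    )


@pytest.fixture
def s5_table() -> FrequencyTable:
    return synthetic_s5_table()
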