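"""Shared fixtures and small independent oracles used across the suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from its2barcode.barcode import barcodes_from_panel
from its2barcode.synthetic_data import PanelSpec, simulate_barcode_panel

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_panel():
    """One canonical synthetic panel: 7 species, 12 haplotypes, 73 positions."""
    return simulate_barcode_panel(PanelSpec(seed=11))


@pytest.fixture(scope="session")
def default_barcodes(default_panel):
    return barcodes_from_panel(
        default_panel.records, default_panel.structures, default_panel.annotations
    )


def random_additive_tree(rng: np.random.Generator, n_taxa: int):
    """Random binary tree with positive branch lengths, plus its additive
    leaf-to-leaf distance matrix.

    Built by random sequential joins, independent of the neighbor-joining
    code under test: distances are accumulated on explicit leaf-path maps.
    """
    from skbio import TreeNode

    nodes = [TreeNode(name=f"t{i}") for i in range(n_taxa)]
    # leaf -> accumulated distance from every leaf below each live node
    below: list[dict[str, float]] = [{node.name: 0.0} for node in nodes]
    dist: dict[tuple[str, str], float] = {}
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        li, lj = rng.uniform(0.1, 2.0), rng.uniform(0.1, 2.0)
        for a, da in below[i].items():
            for b, db in below[j].items():
                key = (a, b) if a < b else (b, a)
                dist[key] = da + li + db + lj
        parent = TreeNode()
        nodes[i].length, nodes[j].length = li, lj
        parent.append(nodes[i])
        parent.append(nodes[j])
        merged = {a: d + li for a, d in below[i].items()}
        merged.update({b: d + lj for b, d in below[j].items()})
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
        below = [b for k, b in enumerate(below) if k not in (i, j)] + [merged]

    tree = nodes[0]
    names = sorted(t.name for t in tree.tips())
    mat = pd.DataFrame(0.0, index=names, columns=names)
    for (a, b), d in dist.items():
        mat.loc[a, b] = mat.loc[b, a] = d
    return tree, mat
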