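"""Shared fixtures: lineage maps and random support-tree generators."""

from __future__ import annotations

from typing import Optional

import numpy as np
import pytest

from stemkv.io_core import LineageMap, SupportTree
from stemkv.synthetic_data import SPECIES_LINEAGES

ANTHOZOANS = [sp for sp, (lin, _) in SPECIES_LINEAGES.items() if lin == "Anthozoa"]
MEDUSOZOANS = [sp for sp, (lin, _) in SPECIES_LINEAGES.items() if lin == "Medusozoa"]


@pytest.fixture
def lmap() -> LineageMap:
    return LineageMap(dict(SPECIES_LINEAGES))


@pytest.fixture
def lmap_with_outgroup() -> LineageMap:
    entries = dict(SPECIES_LINEAGES)
    entries["Drosophila_melanogaster"] = ("Bilateria", "Insecta")
    return LineageMap(entries)


def make_simple_lmap() -> LineageMap:
    """Tiny two-lineage map for hand-built trees: species 'A*' vs 'M*'."""
    return LineageMap({"A": ("Anthozoa", "Anthozoa"), "M": ("Medusozoa", "Medusozoa"),
                       "B": ("Bilateria", "Bilateria")})


def random_support_tree(rng: np.random.Generator, n_tips: int,
                        species_pool=("A", "M", "B"),
                        support_prob: float = 0.85,
                        polytomy_prob: float = 0.2) -> SupportTree:
    """Random (possibly multifurcating) tree with random supports.

    Tips are ``t<i>|<species>``; each internal node gets a support drawn
    uniformly on [0.5, 1] with probability ``support_prob``, else none.
    """
    nodes = [f"t{i}|{rng.choice(species_pool)}:1" for i in range(n_tips)]
    while len(nodes) > 1:
        k = 3 if (len(nodes) >= 3 and rng.random() < polytomy_prob) else 2
        idx = sorted(rng.choice(len(nodes), size=k, replace=False).tolist())
        chosen = [nodes[i] for i in idx]
        rest = [nodes[i] for i in range(len(nodes)) if i not in set(idx)]
        sup = "" if rng.random() > support_prob else format(rng.uniform(0.5, 1.0), ".3f")
        rest.append("(" + ",".join(chosen) + ")" + sup + ":1")
        nodes = rest
    newick = nodes[0].rsplit(":", 1)[0] + ";"
    tree = SupportTree.from_newick(newick)
    # guarantee at least one annotated node so the group finder can run
    internal = tree.internal_nodes(exclude_root=True)
    if internal and all(nd.support is None for nd in internal):
        internal[int(rng.integers(len(internal)))].support = float(rng.uniform(0.5, 1.0))
    return tree
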