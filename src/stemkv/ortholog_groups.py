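"""Ancestral ortholog-group inference from support-annotated gene trees.

One ancestral gene of the Anthozoa/Medusozoa common ancestor corresponds to
the *smallest* clade in a gene-family phylogeny that contains at least one
tip from each focal lineage and whose node support meets the posterior-
probability threshold (default 0.95, inclusive). Counting these minimal
dual-lineage clades yields the inferred gene count at the focal split.

Policy knobs cover the manual decisions such analyses require: per-clade
threshold overrides (a clade just under the genome-wide cutoff may still
be accepted on other evidence), and merge directives that force a set of
tips to be evaluated only at their joint ancestor when the subclade
structure inside it is unreliable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Set, Tuple

import dendropy

from .io_core import DEFAULT_DELIMITER, LineageMap, SupportTree, species_from_label

logger = logging.getLogger("stemkv")


@dataclass
class ThresholdPolicy:
    """Support-threshold policy for clade acceptance.

    ``theta`` is the default posterior-probability threshold; comparison is
    inclusive (>=) unless ``strict`` is set. ``overrides`` maps a clade
    (identified by its exact tip set) to a local threshold. ``merges`` are
    tip sets whose internal subclades are dissolved, so the set is only
    evaluated at its joint ancestor. ``unannotated_support`` substitutes
    for missing node supports; by default a missing support fails the
    threshold (consensus-tree semantics: unannotated = unresolved).
    """

    theta: float = 0.95
    strict: bool = False
    overrides: Dict[FrozenSet[str], float] = field(default_factory=dict)
    merges: Tuple[FrozenSet[str], ...] = ()
    unannotated_support: Optional[float] = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.theta <= 1.0):
            raise ValueError(f"theta {self.theta} outside [0, 1]")
        self.overrides = {frozenset(k): v for k, v in self.overrides.items()}
        self.merges = tuple(frozenset(m) for m in self.merges)

    def effective_theta(self, tipset: FrozenSet[str]) -> float:
        return self.overrides.get(tipset, self.theta)

    def support_ok(self, support: Optional[float], tipset: FrozenSet[str]) -> bool:
        if support is None:
            support = self.unannotated_support
        if support is None:
            return False
        thr = self.effective_theta(tipset)
        return support > thr if self.strict else support >= thr

    def dissolved(self, tipset: FrozenSet[str]) -> bool:
        """True when the clade is a proper subset of a merge directive."""
        return any(tipset < merge for merge in self.merges)


@dataclass(frozen=True)
class OrthologGroup:
    """A minimal dual-lineage clade: one inferred ancestral gene."""

    label: str
    members: FrozenSet[str]
    support: float
    lineages: FrozenSet[str]
    subfamily: Optional[str] = None

    def __len__(self) -> int:
        return len(self.members)


# ---------------------------------------------------------------------------
# Rooting
# ---------------------------------------------------------------------------

def _bipartition_key(side: FrozenSet[str], all_tips: FrozenSet[str]) -> FrozenSet[FrozenSet[str]]:
    return frozenset({side, all_tips - side})


def _support_by_bipartition(tree: SupportTree) -> Dict[FrozenSet[FrozenSet[str]], float]:
    all_tips = frozenset(tree.tip_labels())
    out: Dict[FrozenSet[FrozenSet[str]], float] = {}
    for nd in tree.internal_nodes(exclude_root=True):
        if nd.support is None:
            continue
        out[_bipartition_key(SupportTree.leafset(nd), all_tips)] = nd.support
    return out


def root_by_outgroup(tree: SupportTree, outgroup: Iterable[str]) -> SupportTree:
    """Root on the branch separating ``outgroup`` tips from everything else.

    Node supports annotate *bipartitions*, which rooting does not change,
    so after rerooting each internal node is reassigned the support of the
    bipartition it now represents.
    """
    outgroup = frozenset(outgroup)
    all_tips = frozenset(tree.tip_labels())
    missing = outgroup - all_tips
    if missing:
        raise ValueError(f"outgroup tips not in tree: {sorted(missing)}")
    if not outgroup or outgroup == all_tips:
        raise ValueError("outgroup must be a nonempty proper subset of the tips")

    bip_support = _support_by_bipartition(tree)

    target_edge = None
    for nd in tree.tree.preorder_node_iter():
        if nd is tree.tree.seed_node:
            continue
        below = SupportTree.leafset(nd)
        if below == outgroup or below == all_tips - outgroup:
            target_edge = nd.edge
            break
    if target_edge is None:
        raise ValueError(
            f"outgroup {sorted(outgroup)} is not one side of any branch "
            "(not monophyletic under any rooting)"
        )

    dtree = tree.tree
    length = target_edge.length
    dtree.reroot_at_edge(
        target_edge,
        length1=None if length is None else length / 2.0,
        length2=None if length is None else length / 2.0,
    )
    rooted = SupportTree.__new__(SupportTree)
    rooted.tree = dtree
    rooted.rooted = True
    # reattach supports to the bipartitions they annotated before rooting
    for nd in dtree.preorder_node_iter():
        if nd.is_leaf():
            nd.support = None
            continue
        if nd is dtree.seed_node:
            nd.support = None
            continue
        key = _bipartition_key(SupportTree.leafset(nd), all_tips)
        nd.support = bip_support.get(key)
    return SupportTree(rooted.tree, rooted=True)


# ---------------------------------------------------------------------------
# Minimal dual-lineage clades
# ---------------------------------------------------------------------------

def _tip_lineage(label: str, lmap: LineageMap, delimiter: str) -> str:
    return lmap.lineage_of(species_from_label(label, delimiter))


def _node_candidates(tree: SupportTree, lmap: LineageMap, policy: ThresholdPolicy,
                     delimiter: str) -> List[Tuple[dendropy.Node, FrozenSet[str], float]]:
    """All clades (any node, including polytomies) passing support + lineage tests."""
    lmap.check_focal()
    focal_a, focal_b = lmap.focal
    root = tree.tree.seed_node

    tips = tree.tip_labels()
    lmap.check_species({species_from_label(t, delimiter) for t in tips})

    if not tree.has_any_support() and policy.unannotated_support is None \
            and len(tree.internal_nodes(exclude_root=True)) > 0:
        raise ValueError(
            "tree carries no node supports; pass unannotated_support "
            "(CLI: --assume-support) to treat unannotated nodes as supported"
        )

    out = []
    for nd in tree.tree.preorder_node_iter():
        if nd.is_leaf():
            continue
        tipset = SupportTree.leafset(nd)
        support = 1.0 if nd is root else nd.support  # root clade: support 1.0
        if not policy.support_ok(support, tipset):
            continue
        if policy.dissolved(tipset):
            continue
        lineages = {_tip_lineage(t, lmap, delimiter) for t in tipset}
        if focal_a in lineages and focal_b in lineages:
            eff = policy.unannotated_support if support is None else support
            out.append((nd, tipset, float(eff)))
    return out


def _label_groups(selected: List[Tuple[dendropy.Node, FrozenSet[str], float]],
                  tree: SupportTree, lmap: LineageMap, delimiter: str,
                  subfamily: Optional[str]) -> List[OrthologGroup]:
    """Stable labels in depth-first (preorder) order of the defining nodes."""
    order = {id(nd): i for i, nd in enumerate(tree.tree.preorder_node_iter())}
    selected = sorted(selected, key=lambda t: order[id(t[0])])
    width = max(2, len(str(len(selected))))
    groups = []
    for i, (nd, tipset, support) in enumerate(selected, start=1):
        lineages = frozenset(_tip_lineage(t, lmap, delimiter) for t in tipset)
        groups.append(OrthologGroup(
            label=f"OG{i:0{width}d}",
            members=tipset,
            support=support,
            lineages=lineages,
            subfamily=subfamily,
        ))
    return groups


def find_ancestral_groups(tree: SupportTree, lmap: LineageMap,
                          policy: Optional[ThresholdPolicy] = None,
                          delimiter: str = DEFAULT_DELIMITER,
                          subfamily: Optional[str] = None) -> List[OrthologGroup]:
    """Minimal well-supported clades containing both focal lineages.

    Candidate clades pass the support threshold, contain at least one tip
    from each focal lineage, and are not dissolved by a merge directive;
    the returned groups are the minimal candidates under containment.
    Because clades of one tree form a laminar family, a candidate is
    minimal exactly when no strict descendant is itself a candidate, and
    the resulting groups are pairwise disjoint.
    """
    policy = policy if policy is not None else ThresholdPolicy()
    candidates = _node_candidates(tree, lmap, policy, delimiter)
    cand_nodes = {id(nd) for nd, _, _ in candidates}

    selected = []
    for nd, tipset, support in candidates:
        has_cand_below = any(
            id(desc) in cand_nodes
            for desc in nd.preorder_iter() if desc is not nd
        )
        if not has_cand_below:
            selected.append((nd, tipset, support))
    return _label_groups(selected, tree, lmap, delimiter, subfamily)


def count_ancestral(groups: Sequence[OrthologGroup]) -> int:
    """Number of inferred ancestral genes = number of groups."""
    return len(groups)


def brute_force_groups(tree: SupportTree, lmap: LineageMap,
                       policy: Optional[ThresholdPolicy] = None,
                       delimiter: str = DEFAULT_DELIMITER,
                       subfamily: Optional[str] = None,
                       max_tips: int = 16) -> List[OrthologGroup]:
    """Testing oracle: explicit enumeration + pairwise containment filtering.

    Enumerates every node's tip set, filters by support and lineage
    content, then keeps the sets minimal under pairwise subset tests.
    Restricted to small trees; must agree exactly with
    :func:`find_ancestral_groups`.
    """
    if tree.leaf_count() > max_tips:
        raise ValueError(f"brute-force oracle limited to {max_tips} tips")
    policy = policy if policy is not None else ThresholdPolicy()
    candidates = _node_candidates(tree, lmap, policy, delimiter)

    selected = []
    for i, (nd, tipset, support) in enumerate(candidates):
        minimal = True
        for j, (_, other, _) in enumerate(candidates):
            if i != j and other < tipset:
                minimal = False
                break
        if minimal:
            selected.append((nd, tipset, support))
    # distinct nodes can share a tip set (unifurcations); dedupe by tip set
    seen: Set[FrozenSet[str]] = set()
    deduped = []
    for nd, tipset, support in selected:
        if tipset not in seen:
            seen.add(tipset)
            deduped.append((nd, tipset, support))
    return _label_groups(deduped, tree, lmap, delimiter, subfamily)
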