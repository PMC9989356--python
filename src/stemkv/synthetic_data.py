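"""Duplication-loss simulator with known ancestral truth.

Gene families evolve by a birth-death (duplication-loss) process along a
species tree: within each species-tree branch every gene lineage waits an
exponential time to its next event (rate lambda + mu), a duplication splits
the lineage in two, a loss terminates it, and a speciation copies every
surviving lineage into both daughter branches. The default species tree is
the eight-species cnidarian phylogeny used throughout the package
(Anthozoa: Acropora, Stylophora, Exaiptasia, Nematostella, Renilla;
Medusozoa: Rhopilema, Sanderia, Hydra) with unit root depth and equal
internal timings. Genes present at the root live at the Anthozoa/Medusozoa
split, so the simulator's bookkeeping — how many root genes leave at least
one surviving descendant in each focal lineage — is exactly the quantity
the ortholog-group counter is supposed to recover.

On top of the trees the simulator emulates the other statistical features
the analysis consumes: Beta-distributed node supports concentrated near 1
with a configurable fraction of deliberately weak nodes, and protein
sequences assembled from family-diagnostic domain blocks (T1 + S1-S6 core
for Kv, PAS + core + C-linker/CNBHD for EAG, core + coiled-coil for KCNQ)
that accumulate substitutions along branches, with forced nonconservative
S6-gate substitutions in tips descending from designated R-subunit genes.

Everything is reproducible from integer seeds.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, FrozenSet, List, Mapping, Optional, Sequence, Set, Tuple

import dendropy
import numpy as np

from .classify import FAMILY_OF_SUBFAMILY, SUBFAMILIES
from .gate_score import ConservationScheme
from .io_core import (AA20, DEFAULT_DELIMITER, LineageMap, SeqEntry, SequenceSet,
                      SupportTree, species_from_label, write_fasta)

AA_LIST = sorted(AA20)

# ---------------------------------------------------------------------------
# Species tree and lineage map
# ---------------------------------------------------------------------------

#: the eight-species cnidarian phylogeny, unit depth, equal internal timings
FIG_SPECIES_NEWICK = (
    "((((Acropora_digitifera:0.25,Stylophora_pistillata:0.25)corals:0.25,"
    "(Exaiptasia_pallida:0.25,Nematostella_vectensis:0.25)anemones:0.25)"
    "Hexacorallia:0.25,Renilla_muelleri:0.75)Anthozoa:0.25,"
    "((Rhopilema_esculentum:0.25,Sanderia_malayensis:0.25)Scyphozoa:0.25,"
    "Hydra_vulgaris:0.5)Medusozoa:0.5)Cnidaria;"
)

SPECIES_LINEAGES: Dict[str, Tuple[str, str]] = {
    "Acropora_digitifera": ("Anthozoa", "Hexacorallia"),
    "Stylophora_pistillata": ("Anthozoa", "Hexacorallia"),
    "Exaiptasia_pallida": ("Anthozoa", "Hexacorallia"),
    "Nematostella_vectensis": ("Anthozoa", "Hexacorallia"),
    "Renilla_muelleri": ("Anthozoa", "Octocorallia"),
    "Rhopilema_esculentum": ("Medusozoa", "Scyphozoa"),
    "Sanderia_malayensis": ("Medusozoa", "Scyphozoa"),
    "Hydra_vulgaris": ("Medusozoa", "Hydrozoa"),
}

#: subfamily composition of the inferred stem-cnidarian channel set
#: (23 Kv = 12 Shaker + 1 Shab + 7 Shaw + 3 Shal, 4 EAG = 1 Eag + 2 Erg
#: + 1 Elk, and 1 KCNQ; 28 genes in total)
STEM_ANCESTRAL_SET: Dict[str, int] = {
    "Shaker": 12, "Shab": 1, "Shaw": 7, "Shal": 3,
    "Eag": 1, "Erg": 2, "Elk": 1, "KCNQ": 1,
}


def default_species_tree() -> dendropy.Tree:
    return dendropy.Tree.get(data=FIG_SPECIES_NEWICK, schema="newick",
                             suppress_internal_node_taxa=True,
                             preserve_underscores=True)


def default_lineage_map() -> LineageMap:
    return LineageMap(dict(SPECIES_LINEAGES))


def species_tree_depth(tree: dendropy.Tree) -> float:
    """Root-to-tip depth (ultrametric trees; max over tips otherwise)."""
    return max(lf.distance_from_root() for lf in tree.leaf_node_iter())


# ---------------------------------------------------------------------------
# Sequence templates
# ---------------------------------------------------------------------------

# Frozen synthetic domain-block templates. Family cores descend from one
# ancestral core (cross-family identity ~75%) and subfamily cores from
# their family core (within-family identity ~88%), so reciprocal best-hit
# classification has realistic contrast; the cytoplasmic domain blocks are
# family-specific and unrelated across families.
_TEMPLATE_SEED = 20230121

T1_LEN, CORE_LEN, PAS_LEN, CNBHD_LEN, CC_LEN = 45, 90, 35, 55, 35
GATE_MOTIF = "PVPVIV"
_GATE_OFFSET = 66  # 0-based position of the gate within the S1-S6 core

#: 1-based inclusive gate columns within the Kv family alignment (T1 + core)
KV_GATE_COLUMNS = (T1_LEN + _GATE_OFFSET + 1, T1_LEN + _GATE_OFFSET + len(GATE_MOTIF))

FAMILY_LENGTHS = {"Kv": T1_LEN + CORE_LEN, "EAG": PAS_LEN + CORE_LEN + CNBHD_LEN,
                  "KCNQ": CORE_LEN + CC_LEN}


@dataclass(frozen=True)
class Template:
    subfamily: str
    family: str
    sequence: str
    blocks: Dict[str, Tuple[int, int]]  # block name -> 1-based inclusive span
    gate_columns: Optional[Tuple[int, int]]  # Kv only


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(AA_LIST, size=length))


def _mutate_fraction(seq: str, fraction: float, rng: np.random.Generator,
                     protect: Sequence[int] = ()) -> str:
    """Substitute a fixed fraction of positions (never into the same residue)."""
    protected = set(protect)
    positions = [i for i in range(len(seq)) if i not in protected]
    k = int(round(fraction * len(positions)))
    chosen = rng.choice(positions, size=k, replace=False)
    out = list(seq)
    for i in chosen:
        alternatives = [aa for aa in AA_LIST if aa != out[i]]
        out[i] = rng.choice(alternatives)
    return "".join(out)


def _build_templates() -> Dict[str, Template]:
    rng = np.random.default_rng(_TEMPLATE_SEED)
    gate_idx = list(range(_GATE_OFFSET, _GATE_OFFSET + len(GATE_MOTIF)))
    ancestral_core = list(_random_seq(rng, CORE_LEN))
    for i, res in zip(gate_idx, GATE_MOTIF):
        ancestral_core[i] = res
    ancestral_core = "".join(ancestral_core)

    family_core = {fam: _mutate_fraction(ancestral_core, 0.25, rng, protect=gate_idx)
                   for fam in ("Kv", "EAG", "KCNQ")}
    t1 = _random_seq(rng, T1_LEN)
    pas = _random_seq(rng, PAS_LEN)
    cnbhd = _random_seq(rng, CNBHD_LEN)
    cc = _random_seq(rng, CC_LEN)

    templates: Dict[str, Template] = {}
    for sub in SUBFAMILIES:
        fam = FAMILY_OF_SUBFAMILY[sub]
        core = _mutate_fraction(family_core[fam], 0.12, rng, protect=gate_idx)
        if fam == "Kv":
            seq = t1 + core
            blocks = {"T1": (1, T1_LEN), "S1S6_core": (T1_LEN + 1, T1_LEN + CORE_LEN)}
            gate = KV_GATE_COLUMNS
        elif fam == "EAG":
            seq = pas + core + cnbhd
            blocks = {"EAG_PAS": (1, PAS_LEN),
                      "S1S6_core": (PAS_LEN + 1, PAS_LEN + CORE_LEN),
                      "CNBHD_Clinker": (PAS_LEN + CORE_LEN + 1, len(pas + core + cnbhd))}
            gate = None
        else:
            seq = core + cc
            blocks = {"S1S6_core": (1, CORE_LEN),
                      "KCNQ_coiledcoil": (CORE_LEN + 1, CORE_LEN + CC_LEN)}
            gate = None
        templates[sub] = Template(subfamily=sub, family=fam, sequence=seq,
                                  blocks=blocks, gate_columns=gate)
    return templates


TEMPLATES: Dict[str, Template] = _build_templates()


def reference_sequence_set() -> Tuple[SequenceSet, Dict[str, Tuple[str, str]]]:
    """The eight subfamily templates as an annotated reference channel set."""
    records, annotation = [], {}
    for sub, tpl in TEMPLATES.items():
        rid = f"REF_{sub}|reference"
        records.append(SeqEntry(id=rid, species="reference", residues=tpl.sequence))
        annotation[rid] = (tpl.family, sub)
    return SequenceSet(records), annotation


def domain_block_alignment(name: str) -> SequenceSet:
    """Aligned reference block for one diagnostic domain, drawn from the templates."""
    records = []
    for sub, tpl in TEMPLATES.items():
        if name in tpl.blocks:
            lo, hi = tpl.blocks[name]
            records.append(SeqEntry(id=f"{name}_{sub}", species=sub,
                                    residues=tpl.sequence[lo - 1:hi]))
    if not records:
        raise ValueError(f"no template carries a block named {name!r}")
    return SequenceSet(records)


# ---------------------------------------------------------------------------
# Simulation configuration and truth bookkeeping
# ---------------------------------------------------------------------------

@dataclass
class SimulationConfig:
    """Parameters of one duplication-loss simulation.

    Rates are events per gene lineage per unit time on the species-tree
    timescale (root depth 1 for the default tree). ``subfamilies`` assigns
    each of the ``n0`` root genes a subfamily (default: all Shaker).
    Supports are Beta draws with the given mean and concentration
    (``concentration=None`` makes every draw exactly the mean, which with
    ``support_mean=1.0`` gives perfect supports); ``weak_fraction`` of the
    internal nodes instead draw uniformly below ``theta``.
    """

    n0: int = 1
    dup_rate: float = 0.0
    loss_rate: float = 0.0
    subfamilies: Optional[Sequence[str]] = None
    species_tree_newick: str = FIG_SPECIES_NEWICK
    support_mean: float = 0.99
    support_concentration: Optional[float] = 200.0
    weak_fraction: float = 0.0
    theta: float = 0.95
    substitution_rate: float = 0.05
    r_subunit_fraction: float = 0.0
    gate_degeneration: bool = True
    gene_prefix: str = "g"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n0 < 1:
            raise ValueError("n0 must be >= 1")
        if self.dup_rate < 0 or self.loss_rate < 0:
            raise ValueError("duplication and loss rates must be nonnegative")
        if self.subfamilies is None:
            self.subfamilies = ["Shaker"] * self.n0
        self.subfamilies = list(self.subfamilies)
        if len(self.subfamilies) != self.n0:
            raise ValueError("subfamilies must assign one subfamily per root gene")
        for sub in self.subfamilies:
            if sub not in FAMILY_OF_SUBFAMILY:
                raise ValueError(f"unknown subfamily {sub!r}")

    def species_tree(self) -> dendropy.Tree:
        return dendropy.Tree.get(data=self.species_tree_newick, schema="newick",
                                 suppress_internal_node_taxa=True,
                                 preserve_underscores=True)

    def content_hash(self) -> str:
        payload = {k: (list(v) if isinstance(v, (list, tuple)) else v)
                   for k, v in vars(self).items()}
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


@dataclass
class SimulatedTruth:
    """Ground truth recorded during simulation.

    ``dual_survivors`` is the number of root (focal-split) genes with at
    least one surviving tip descendant in *each* focal lineage — the
    quantity minimal dual-lineage clade counting is designed to recover.
    """

    n0: int
    focal_total: int
    dual_survivors: int
    node_counts: Dict[str, int]
    gene_subfamily: Dict[str, str]
    gene_tip_count: Dict[str, int]
    gene_dual: Dict[str, bool]
    r_genes: FrozenSet[str]
    tip_gene: Dict[str, str]
    tip_r_flags: Dict[str, bool]
    extinct: bool = False


# ---------------------------------------------------------------------------
# Gene-tree simulation
# ---------------------------------------------------------------------------

def _sim_lineage(rng: np.random.Generator, lam: float, mu: float,
                 sp_node: dendropy.Node, remaining: float,
                 counts: Dict[str, int]) -> Optional[dendropy.Node]:
    """One gene lineage entering a species-tree branch with ``remaining`` time left.

    Returns the surviving gene-subtree node (edge length measured from the
    lineage's entry point) or None on extinction. Pass-through nodes from
    single-survivor duplications/speciations are collapsed on the fly.
    """
    total = lam + mu
    wait = rng.exponential(1.0 / total) if total > 0 else math.inf
    if wait < remaining:
        if rng.random() < (lam / total):  # duplication
            left = _sim_lineage(rng, lam, mu, sp_node, remaining - wait, counts)
            right = _sim_lineage(rng, lam, mu, sp_node, remaining - wait, counts)
            survivors = [c for c in (left, right) if c is not None]
            if not survivors:
                return None
            if len(survivors) == 1:
                survivors[0].edge.length += wait
                return survivors[0]
            nd = dendropy.Node()
            nd.edge.length = wait
            nd.event = "duplication"
            for c in survivors:
                nd.add_child(c)
            return nd
        return None  # loss
    # lineage reaches the end of the branch
    if sp_node.is_leaf():
        tip = dendropy.Node()
        tip.edge.length = remaining
        tip.species = sp_node.taxon.label
        return tip
    counts[sp_node.label] = counts.get(sp_node.label, 0) + 1
    kids = [_sim_lineage(rng, lam, mu, ch, ch.edge.length, counts)
            for ch in sp_node.child_nodes()]
    survivors = [c for c in kids if c is not None]
    if not survivors:
        return None
    if len(survivors) == 1:
        survivors[0].edge.length += remaining
        return survivors[0]
    nd = dendropy.Node()
    nd.edge.length = remaining
    nd.event = "speciation"
    for c in survivors:
        nd.add_child(c)
    return nd


def simulate_gene_tree(cfg: SimulationConfig) -> Tuple[SupportTree, SimulatedTruth]:
    """Simulate ``n0`` independent gene lineages starting at the focal split.

    The returned gene tree joins the surviving per-gene subtrees at a root
    polytomy (representing pre-split divergence among the ancestral
    genes); tips are labeled ``<gene>.<copy>|<species>``. A fully extinct
    simulation returns an empty tree with ``truth.extinct`` set.
    """
    rng = np.random.default_rng(cfg.seed)
    sp_tree = cfg.species_tree()
    sp_root = sp_tree.seed_node
    counts: Dict[str, int] = {sp_root.label or "root": cfg.n0}

    gene_roots: List[Tuple[str, Optional[dendropy.Node]]] = []
    for gi in range(1, cfg.n0 + 1):
        gene_id = f"{cfg.gene_prefix}{gi}"
        kids = [_sim_lineage(rng, cfg.dup_rate, cfg.loss_rate, ch, ch.edge.length, counts)
                for ch in sp_root.child_nodes()]
        survivors = [c for c in kids if c is not None]
        if not survivors:
            gene_roots.append((gene_id, None))
        elif len(survivors) == 1:
            gene_roots.append((gene_id, survivors[0]))
        else:
            nd = dendropy.Node()
            nd.edge.length = 0.0
            nd.event = "speciation"
            for c in survivors:
                nd.add_child(c)
            gene_roots.append((gene_id, nd))

    # R-subunit status per root gene (Kv genes only)
    gene_subfamily = {f"{cfg.gene_prefix}{gi}": sub
                      for gi, sub in enumerate(cfg.subfamilies, start=1)}
    r_genes: Set[str] = set()
    for gene_id in gene_subfamily:
        is_kv = FAMILY_OF_SUBFAMILY[gene_subfamily[gene_id]] == "Kv"
        if is_kv and rng.random() < cfg.r_subunit_fraction:
            r_genes.add(gene_id)

    lmap = default_lineage_map()
    focal_a, focal_b = lmap.focal

    tns = dendropy.TaxonNamespace()
    root = dendropy.Node()
    root.edge.length = None
    tip_gene: Dict[str, str] = {}
    tip_r: Dict[str, bool] = {}
    gene_tip_count: Dict[str, int] = {}
    gene_dual: Dict[str, bool] = {}
    dual = 0
    for gene_id, gnode in gene_roots:
        gene_tip_count[gene_id] = 0
        gene_dual[gene_id] = False
        if gnode is None:
            continue
        lineages: Set[str] = set()
        for k, leaf in enumerate(gnode.leaf_iter(), start=1):
            label = f"{gene_id}.{k}|{leaf.species}"
            leaf.taxon = tns.require_taxon(label)
            tip_gene[label] = gene_id
            tip_r[label] = gene_id in r_genes
            lineages.add(SPECIES_LINEAGES[leaf.species][0])
            gene_tip_count[gene_id] += 1
        if focal_a in lineages and focal_b in lineages:
            dual += 1
            gene_dual[gene_id] = True
        root.add_child(gnode)

    extinct = len(root.child_nodes()) == 0
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=root)
    stree = SupportTree(tree, rooted=True)
    truth = SimulatedTruth(
        n0=cfg.n0, focal_total=cfg.n0, dual_survivors=dual,
        node_counts=counts, gene_subfamily=gene_subfamily,
        gene_tip_count=gene_tip_count, gene_dual=gene_dual,
        r_genes=frozenset(r_genes), tip_gene=tip_gene, tip_r_flags=tip_r,
        extinct=extinct,
    )
    return stree, truth


# ---------------------------------------------------------------------------
# Support model
# ---------------------------------------------------------------------------

def assign_supports(tree: SupportTree, mean: float = 0.99,
                    concentration: Optional[float] = 200.0,
                    weak_fraction: float = 0.0, theta: float = 0.95,
                    seed: int = 0) -> SupportTree:
    """Draw node supports in place: Beta(mean*c, (1-mean)*c) per internal node.

    With ``concentration=None`` every node gets exactly ``mean``. A
    ``weak_fraction`` of the non-root internal nodes instead draw
    uniformly on [0.5, theta), i.e. deliberately below the acceptance
    threshold.
    """
    if not (0.0 < mean <= 1.0):
        raise ValueError("support mean must be in (0, 1]")
    rng = np.random.default_rng(seed)
    internal = tree.internal_nodes(exclude_root=True)
    for nd in internal:
        if concentration is None:
            nd.support = mean
        else:
            a = mean * concentration
            b = max((1.0 - mean) * concentration, 1e-9)
            nd.support = min(1.0, float(rng.beta(a, b)))
    n_weak = int(round(weak_fraction * len(internal)))
    if n_weak > 0:
        weak_idx = rng.choice(len(internal), size=n_weak, replace=False)
        for i in weak_idx:
            internal[i].support = float(rng.uniform(0.5, theta))
    return tree


def perfect_supports(tree: SupportTree) -> SupportTree:
    for nd in tree.internal_nodes(exclude_root=True):
        nd.support = 1.0
    return tree


# ---------------------------------------------------------------------------
# Sequence emission
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SeqLabel:
    family: str
    subfamily: str
    is_r: bool


def _force_nonconservative(res: str, scheme: ConservationScheme,
                           rng: np.random.Generator) -> str:
    """A residue from a different chemical class (and not itself special)."""
    pool = [aa for aa in AA_LIST
            if scheme.class_of(aa) != scheme.class_of(res) and aa not in scheme.special]
    return str(rng.choice(pool))


def emit_sequences(tree: SupportTree, truth: SimulatedTruth,
                   substitution_rate: float = 0.05,
                   gate_degeneration: bool = True,
                   scheme: Optional[ConservationScheme] = None,
                   seed: int = 0) -> Tuple[SequenceSet, Dict[str, SeqLabel]]:
    """Emit protein sequences down the gene tree from subfamily templates.

    Each root gene starts at its subfamily template; along every branch
    each site substitutes with probability ``1 - exp(-rate * length)``
    (substitutions only — all tips of one family stay equal length, so the
    family-wise output is alignment-ready). Tips of R-flagged Kv genes
    additionally receive forced nonconservative substitutions at two S6
    gate positions, emulating R-subunit gate degeneration.
    """
    scheme = scheme if scheme is not None else ConservationScheme()
    rng = np.random.default_rng(seed)
    records: List[SeqEntry] = []
    labels: Dict[str, SeqLabel] = {}

    gate_lo, gate_hi = KV_GATE_COLUMNS
    forced_offsets = (0, 4)  # gate positions hit in R-subunit tips

    def evolve(node: dendropy.Node, parent_seq: str) -> None:
        """Process the edge leading into ``node``, then recurse."""
        length = node.edge.length or 0.0
        p = 1.0 - math.exp(-substitution_rate * length)
        seq = parent_seq
        if p > 0.0:
            arr = list(seq)
            hits = np.nonzero(rng.random(len(arr)) < p)[0]
            for i in hits:
                arr[i] = str(rng.choice([aa for aa in AA_LIST if aa != arr[i]]))
            seq = "".join(arr)
        if node.is_leaf():
            label = node.taxon.label
            gene_id = truth.tip_gene[label]
            sub = truth.gene_subfamily[gene_id]
            fam = FAMILY_OF_SUBFAMILY[sub]
            if gate_degeneration and truth.tip_r_flags.get(label, False) and fam == "Kv":
                arr = list(seq)
                for off in forced_offsets:
                    idx = gate_lo - 1 + off
                    arr[idx] = _force_nonconservative(TEMPLATES[sub].sequence[idx],
                                                      scheme, rng)
                seq = "".join(arr)
            records.append(SeqEntry(id=label, species=species_from_label(label),
                                    residues=seq))
            labels[label] = SeqLabel(family=fam, subfamily=sub,
                                     is_r=truth.tip_r_flags.get(label, False))
        else:
            for child in node.child_nodes():
                evolve(child, seq)

    for gnode in tree.tree.seed_node.child_nodes():
        first_leaf = next(gnode.leaf_iter())
        gene_id = truth.tip_gene[first_leaf.taxon.label]
        template = TEMPLATES[truth.gene_subfamily[gene_id]].sequence
        evolve(gnode, template)

    return SequenceSet(records), labels


# ---------------------------------------------------------------------------
# Benchmark bundles
# ---------------------------------------------------------------------------

def generate_benchmark_bundle(cfg: SimulationConfig, out_dir,
                              force: bool = False) -> Dict[str, object]:
    """Write a complete synthetic input bundle to ``out_dir``.

    One gene tree + family-wise protein 'alignment' per gene family in the
    configuration, plus a combined protein FASTA, the lineage map, a truth
    TSV and a manifest (seed, config hash, truth summary). Re-running with
    the manifest's seed reproduces the truth TSV byte for byte.
    """
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(f"output directory {out} exists and is not empty; use force")
    out.mkdir(parents=True, exist_ok=True)

    families: List[str] = []
    for sub in cfg.subfamilies:
        fam = FAMILY_OF_SUBFAMILY[sub]
        if fam not in families:
            families.append(fam)

    ss = np.random.SeedSequence(cfg.seed)
    fam_seeds = {fam: int(child.generate_state(1)[0] % (2 ** 31))
                 for fam, child in zip(families, ss.spawn(len(families)))}

    all_records: List[SeqEntry] = []
    truth_rows: List[Dict[str, object]] = []
    summary: Dict[str, Dict[str, int]] = {}
    trees: Dict[str, SupportTree] = {}
    truths: Dict[str, SimulatedTruth] = {}

    for fam in families:
        subs = [s for s in cfg.subfamilies if FAMILY_OF_SUBFAMILY[s] == fam]
        fam_cfg = SimulationConfig(
            n0=len(subs), dup_rate=cfg.dup_rate, loss_rate=cfg.loss_rate,
            subfamilies=subs, species_tree_newick=cfg.species_tree_newick,
            support_mean=cfg.support_mean,
            support_concentration=cfg.support_concentration,
            weak_fraction=cfg.weak_fraction, theta=cfg.theta,
            substitution_rate=cfg.substitution_rate,
            r_subunit_fraction=cfg.r_subunit_fraction,
            gate_degeneration=cfg.gate_degeneration,
            gene_prefix=f"{fam}_g", seed=fam_seeds[fam],
        )
        tree, truth = simulate_gene_tree(fam_cfg)
        assign_supports(tree, mean=cfg.support_mean,
                        concentration=cfg.support_concentration,
                        weak_fraction=cfg.weak_fraction, theta=cfg.theta,
                        seed=fam_seeds[fam] + 1)
        seqs, labels = emit_sequences(tree, truth,
                                      substitution_rate=cfg.substitution_rate,
                                      gate_degeneration=cfg.gate_degeneration,
                                      seed=fam_seeds[fam] + 2)
        trees[fam] = tree
        truths[fam] = truth
        if not truth.extinct:
            tree.write(out / f"tree_{fam}.nwk")
            write_fasta(seqs, out / f"aln_{fam}.faa")
        all_records.extend(seqs)
        for gene_id in sorted(truth.gene_subfamily):
            truth_rows.append({
                "gene": gene_id, "family": fam,
                "subfamily": truth.gene_subfamily[gene_id],
                "is_r_subunit": int(gene_id in truth.r_genes),
                "n_tips": truth.gene_tip_count[gene_id],
                "dual_lineage_survivor": int(truth.gene_dual[gene_id]),
            })
        summary[fam] = {"n0": truth.n0, "dual_survivors": truth.dual_survivors}

    write_fasta(SequenceSet(all_records), out / "proteins.faa")

    with open(out / "lineage_map.tsv", "w") as fh:
        fh.write("species\tlineage\tclass\n")
        for sp, (lin, cls) in SPECIES_LINEAGES.items():
            fh.write(f"{sp}\t{lin}\t{cls}\n")

    with open(out / "truth.tsv", "w") as fh:
        cols = ["gene", "family", "subfamily", "is_r_subunit", "n_tips",
                "dual_lineage_survivor"]
        fh.write("\t".join(cols) + "\n")
        for row in truth_rows:
            fh.write("\t".join(str(row[c]) for c in cols) + "\n")

    manifest = {
        "seed": cfg.seed,
        "config_hash": cfg.content_hash(),
        "families": families,
        "truth_summary": summary,
        "total_dual_survivors": sum(s["dual_survivors"] for s in summary.values()),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)

    return {"out_dir": out, "manifest": manifest, "trees": trees, "truths": truths}
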