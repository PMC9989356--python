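"""Readers and writers for the formats the pipeline touches.

Sequence sets are plain FASTA (optionally aligned, i.e. equal-length with
gap characters), gene phylogenies are Newick with numeric internal-node
labels or NEXUS consensus trees with ``[&prob=...]``-style node comments
(the format MrBayes writes in its ``.con.tre`` files), and species metadata
is a three-column TSV mapping each species to a lineage and a class.

Conventions used throughout the package:

* sequence/tip identifiers follow ``geneId|speciesId`` — the part after the
  last ``|`` is the species tag (a regex alternative is available);
* node supports are posterior probabilities in ``[0, 1]``; values parsed as
  percentages (``>1`` and ``<=100``) are rescaled with a warning;
* all user-facing coordinates (alignment columns) are 1-based inclusive.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, Iterator, List, Optional, Sequence, Tuple

import dendropy
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("stemkv")

AA20 = frozenset("ACDEFGHIKLMNPQRSTVWY")
#: letters allowed in a sequence record: the 20 amino acids, X, and gap
SEQ_ALPHABET = AA20 | {"X", "-"}

DEFAULT_DELIMITER = "|"


def species_from_label(label: str, delimiter: str = DEFAULT_DELIMITER,
                       species_regex: Optional[str] = None) -> str:
    """Extract the species tag from a ``geneId|speciesId`` style label.

    With ``species_regex`` the first capture group is used instead. A label
    without the delimiter is its own species tag (single-species inputs).
    """
    if species_regex is not None:
        m = re.search(species_regex, label)
        if m is None:
            raise ValueError(f"label {label!r} does not match species regex {species_regex!r}")
        return m.group(1)
    if delimiter in label:
        return label.rsplit(delimiter, 1)[1]
    return label


@dataclass(frozen=True)
class SeqEntry:
    id: str
    species: str
    residues: str


@dataclass
class SequenceSet:
    """An ordered, id-unique collection of protein sequences."""

    records: List[SeqEntry]
    source_path: str = ""

    def __post_init__(self) -> None:
        seen = set()
        for rec in self.records:
            if rec.id in seen:
                raise ValueError(f"duplicate sequence id: {rec.id!r}")
            seen.add(rec.id)
            bad = set(rec.residues) - SEQ_ALPHABET
            if bad:
                raise ValueError(
                    f"sequence {rec.id!r} contains invalid residue letters: {sorted(bad)}"
                )
        self._index = {rec.id: rec for rec in self.records}

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SeqEntry]:
        return iter(self.records)

    def __contains__(self, seq_id: str) -> bool:
        return seq_id in self._index

    def ids(self) -> List[str]:
        return [rec.id for rec in self.records]

    def get(self, seq_id: str) -> SeqEntry:
        try:
            return self._index[seq_id]
        except KeyError:
            raise KeyError(f"no sequence with id {seq_id!r}") from None

    def aligned_length(self) -> int:
        """Common length of all records; error if the set is ragged."""
        if not self.records:
            raise ValueError("empty sequence set has no aligned length")
        lengths = {len(rec.residues) for rec in self.records}
        if len(lengths) != 1:
            raise ValueError(f"ragged alignment: lengths {sorted(lengths)}")
        return lengths.pop()

    def subset(self, ids: Iterable[str]) -> "SequenceSet":
        keep = set(ids)
        return SequenceSet([r for r in self.records if r.id in keep], self.source_path)


def read_fasta(path, delimiter: str = DEFAULT_DELIMITER,
               species_regex: Optional[str] = None) -> SequenceSet:
    """Read a FASTA file into a :class:`SequenceSet`, preserving order.

    The full header token (up to the first whitespace) is the record id;
    the species tag is derived from it via the delimiter/regex rule.
    """
    path = Path(path)
    records: List[SeqEntry] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(SeqEntry(
            id=rec.id,
            species=species_from_label(rec.id, delimiter, species_regex),
            residues=str(rec.seq).upper(),
        ))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return SequenceSet(records, source_path=str(path))


def write_fasta(sset: SequenceSet, path, wrap: int = 60) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        SeqIO.write(
            (SeqRecord(Seq(rec.residues), id=rec.id, description="") for rec in sset),
            fh, "fasta",
        )


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

class SupportTree:
    """A gene phylogeny with per-internal-node support values in [0, 1].

    Wraps a :class:`dendropy.Tree`; each node carries a ``support``
    attribute (float or ``None``). Tip labels must be unique.
    """

    def __init__(self, tree: dendropy.Tree, rooted: bool = True) -> None:
        self.tree = tree
        self.rooted = rooted
        labels = self.tip_labels()
        if len(labels) != len(set(labels)):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise ValueError(f"duplicate tip labels: {dupes}")
        for nd in tree:
            if not hasattr(nd, "support"):
                nd.support = None
            if nd.support is not None and not (0.0 <= nd.support <= 1.0):
                raise ValueError(f"node support {nd.support} outside [0, 1]")

    # -- construction -------------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str, rooted: bool = True) -> "SupportTree":
        tree = dendropy.Tree.get(data=newick, schema="newick",
                                 suppress_internal_node_taxa=True,
                                 preserve_underscores=True)
        _supports_from_labels(tree)
        return cls(tree, rooted=rooted)

    # -- accessors ----------------------------------------------------------

    def tip_labels(self) -> List[str]:
        # a leaf without a taxon is a childless root (empty tree), not a tip
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()
                if lf.taxon is not None]

    def leaf_count(self) -> int:
        return len(self.tip_labels())

    def internal_nodes(self, exclude_root: bool = False) -> List[dendropy.Node]:
        nodes = [nd for nd in self.tree.preorder_node_iter() if not nd.is_leaf()]
        if exclude_root:
            nodes = [nd for nd in nodes if nd is not self.tree.seed_node]
        return nodes

    @staticmethod
    def leafset(node: dendropy.Node) -> frozenset:
        return frozenset(lf.taxon.label for lf in node.leaf_iter())

    def has_any_support(self) -> bool:
        return any(nd.support is not None
                   for nd in self.internal_nodes(exclude_root=True))

    # -- output -------------------------------------------------------------

    def to_newick(self) -> str:
        for nd in self.tree.preorder_node_iter():
            if not nd.is_leaf():
                nd.label = (None if nd.support is None
                            else format(nd.support, "g"))
        return self.tree.as_string(schema="newick",
                                   suppress_rooting=True,
                                   unquoted_underscores=True).strip()

    def write(self, path) -> None:
        Path(path).write_text(self.to_newick() + "\n")


def _supports_from_labels(tree: dendropy.Tree) -> None:
    """Interpret numeric internal-node labels as supports (in place)."""
    rescaled = False
    for nd in tree.preorder_node_iter():
        nd.support = None
        if nd.is_leaf():
            continue
        if nd.label is None or nd.label == "":
            continue
        try:
            val = float(nd.label)
        except ValueError:
            continue  # non-numeric label is a clade name, not a support
        if 1.0 < val <= 100.0:
            val = val / 100.0
            rescaled = True
        if not (0.0 <= val <= 1.0):
            raise ValueError(f"node support {nd.label!r} outside [0, 1] after rescaling")
        nd.support = val
        nd.label = None
    if rescaled:
        warnings.warn("node supports looked like percentages; rescaled to [0, 1]")
        logger.info("rescaled percentage supports to [0, 1]")


_SUPPORT_ANNOTATION_KEYS = ("prob", "posterior", "posterior_probability", "pp")


def _supports_from_comments(tree: dendropy.Tree) -> None:
    rescaled = False
    for nd in tree.preorder_node_iter():
        nd.support = None
        if nd.is_leaf():
            continue
        val = None
        for key in _SUPPORT_ANNOTATION_KEYS:
            raw = nd.annotations.get_value(key)
            if raw is not None:
                val = float(raw)
                break
        if val is None:
            # fall back on a numeric node label if the writer used one
            if nd.label not in (None, ""):
                try:
                    val = float(nd.label)
                except ValueError:
                    val = None
            if val is None:
                continue
        if 1.0 < val <= 100.0:
            val = val / 100.0
            rescaled = True
        if not (0.0 <= val <= 1.0):
            raise ValueError(f"node support {val} outside [0, 1] after rescaling")
        nd.support = val
    if rescaled:
        warnings.warn("node supports looked like percentages; rescaled to [0, 1]")


TREE_DIALECTS = ("newick_nodelabel", "nexus_comment")


def read_tree(path, dialect: str = "newick_nodelabel") -> SupportTree:
    """Read a support-annotated gene tree.

    ``newick_nodelabel``: numeric internal-node labels are supports.
    ``nexus_comment``: NEXUS with per-node ``[&prob=...]`` comments, the
    convention of MrBayes majority-rule consensus (``.con.tre``) files.
    """
    path = Path(path)
    if dialect not in TREE_DIALECTS:
        raise ValueError(f"unknown tree dialect {dialect!r}; expected one of {TREE_DIALECTS}")
    try:
        if dialect == "newick_nodelabel":
            tree = dendropy.Tree.get(path=str(path), schema="newick",
                                     suppress_internal_node_taxa=True,
                                     preserve_underscores=True)
            _supports_from_labels(tree)
        else:
            tree = dendropy.Tree.get(path=str(path), schema="nexus",
                                     extract_comment_metadata=True,
                                     preserve_underscores=True)
            _supports_from_comments(tree)
    except (dendropy.utility.error.DataParseError, dendropy.dataio.tokenizer.Tokenizer.UnexpectedEndOfStreamError) as exc:
        raise ValueError(f"could not parse tree file {path}: {exc}") from exc
    rooted = len(tree.seed_node.child_nodes()) == 2
    return SupportTree(tree, rooted=rooted)


# ---------------------------------------------------------------------------
# Lineage map
# ---------------------------------------------------------------------------

DEFAULT_FOCAL_PAIR = ("Anthozoa", "Medusozoa")


@dataclass
class LineageMap:
    """species -> (lineage, class), with a focal lineage pair.

    The focal pair names the two deepest lineages whose minimal shared
    clades date genes to the common ancestor (here Anthozoa/Medusozoa).
    """

    entries: Dict[str, Tuple[str, str]]
    focal: Tuple[str, str] = DEFAULT_FOCAL_PAIR

    def lineage_of(self, species: str) -> str:
        return self._lookup(species)[0]

    def class_of(self, species: str) -> str:
        return self._lookup(species)[1]

    def _lookup(self, species: str) -> Tuple[str, str]:
        try:
            return self.entries[species]
        except KeyError:
            raise KeyError(f"species {species!r} missing from lineage map") from None

    def species(self) -> List[str]:
        return list(self.entries)

    def lineages(self) -> List[str]:
        return sorted({lin for lin, _ in self.entries.values()})

    def check_species(self, species: Iterable[str]) -> None:
        """Hard error listing every species not present in the map."""
        missing = sorted({sp for sp in species if sp not in self.entries})
        if missing:
            raise ValueError(f"species missing from lineage map: {missing}")

    def check_focal(self) -> None:
        lineages = set(self.lineages())
        absent = [f for f in self.focal if f not in lineages]
        if absent:
            raise ValueError(f"focal lineage(s) {absent} not present among map lineages {sorted(lineages)}")


def read_lineage_map(path, focal: Tuple[str, str] = DEFAULT_FOCAL_PAIR) -> LineageMap:
    """Read the species->lineage/class TSV.

    Required columns: ``species``, ``lineage``, ``class``. An empty class
    cell defaults to the lineage. Conflicting duplicate rows are an error.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"species", "lineage", "class"}
    missing_cols = required - set(df.columns)
    if missing_cols:
        raise ValueError(f"lineage map {path} missing columns: {sorted(missing_cols)}")
    entries: Dict[str, Tuple[str, str]] = {}
    for _, row in df.iterrows():
        sp = str(row["species"]).strip()
        lin = str(row["lineage"]).strip()
        cls = row["class"]
        cls = lin if (pd.isna(cls) or str(cls).strip() == "") else str(cls).strip()
        if sp in entries and entries[sp] != (lin, cls):
            raise ValueError(f"conflicting duplicate lineage-map rows for species {sp!r}")
        entries[sp] = (lin, cls)
    lmap = LineageMap(entries, focal=focal)
    return lmap


def configure_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(levelname)s %(name)s: %(message)s",
    )
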