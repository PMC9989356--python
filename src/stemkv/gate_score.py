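"""S6 activation-gate degeneration scoring.

Kv alpha-subunits carry a strikingly conserved sequence at the cytoplasmic
end of S6 (the bundle-crossing activation gate). "Silent"/regulatory
R-subunits, which only function in heteromers, tolerate nonconservative
substitutions there; gate degeneration is therefore a sequence-level
marker of the R-subunit phenotype. This module builds the alpha-subunit
gate consensus per subfamily, flags nonconservative positions in candidate
sequences, and makes an ancestral call per ortholog group: degeneration
seen in both focal lineages suggests the phenotype predates their split.

"Nonconservative" is judged against a configurable partition of the amino
acids into chemical classes, with proline and glycine treated as
structurally special: any substitution away from a consensus P or G counts
as nonconservative regardless of class, because both residues set backbone
geometry at the gate bundle crossing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

from .io_core import AA20, DEFAULT_DELIMITER, LineageMap, SequenceSet, species_from_label
from .ortholog_groups import OrthologGroup

logger = logging.getLogger("stemkv")

MISSING_CHARS = ("-", "X")

#: per-position flags
CONSERVATIVE = "conservative"
NONCONSERVATIVE = "nonconservative"
MISSING = "missing"

#: sequence-level classes
ALPHA_LIKE = "alpha_like"
DEGENERATE = "degenerate"
MISSING_DATA = "missing_data"

#: group-level ancestral calls
ANCESTRAL_DEGENERATE = "ancestral_degenerate"
LINEAGE_RESTRICTED = "lineage_restricted"


@dataclass
class ConservationScheme:
    """Partition of the 20 amino acids into chemical classes.

    ``special`` residues (default P and G) are structurally critical: at a
    column whose consensus is special, any different residue is
    nonconservative.
    """

    classes: Dict[str, FrozenSet[str]] = field(default_factory=lambda: {
        "hydrophobic": frozenset("AVLIMFWYC"),
        "polar": frozenset("STNQ"),
        "basic": frozenset("KRH"),
        "acidic": frozenset("DE"),
        "proline": frozenset("P"),
        "glycine": frozenset("G"),
    })
    special: FrozenSet[str] = frozenset("PG")

    def __post_init__(self) -> None:
        covered: Set[str] = set()
        for name, members in self.classes.items():
            overlap = covered & set(members)
            if overlap:
                raise ValueError(f"residues {sorted(overlap)} appear in more than one class")
            covered |= set(members)
        if covered != set(AA20):
            raise ValueError(
                f"classes must partition the 20 amino acids; missing {sorted(set(AA20) - covered)}"
            )
        self._class_of = {res: name for name, members in self.classes.items() for res in members}

    def class_of(self, residue: str) -> Optional[str]:
        """Class name of a residue; None for gap/X."""
        return self._class_of.get(residue)


@dataclass(frozen=True)
class GateConsensus:
    """Per-subfamily alpha-subunit gate consensus over an alignment window."""

    subfamily: str
    columns: Tuple[int, int]  # 1-based inclusive alignment columns
    consensus: str
    admissible: Tuple[FrozenSet[str], ...]  # per column: class names seen in alphas

    def __post_init__(self) -> None:
        lo, hi = self.columns
        if len(self.consensus) != hi - lo + 1:
            raise ValueError("consensus length does not match the column range")
        if len(self.admissible) != len(self.consensus):
            raise ValueError("admissible-class list length does not match consensus")


@dataclass(frozen=True)
class GateCall:
    """Per-sequence gate classification with per-position flags."""

    sequence_id: str
    gate: str
    flags: Tuple[str, ...]
    classification: str

    @property
    def degenerate(self) -> bool:
        return self.classification == DEGENERATE


def extract_gate(aln: SequenceSet, seq_id: str, columns: Tuple[int, int]) -> str:
    """Slice the gate window (1-based inclusive columns) from one row."""
    lo, hi = columns
    ncol = aln.aligned_length()
    if not (1 <= lo <= hi <= ncol):
        raise ValueError(f"column range {lo}-{hi} out of bounds for {ncol}-column alignment")
    return aln.get(seq_id).residues[lo - 1:hi]


def build_consensus(aln: SequenceSet, alpha_ids: Iterable[str],
                    columns: Tuple[int, int],
                    scheme: Optional[ConservationScheme] = None,
                    subfamily: str = "") -> GateConsensus:
    """Plurality consensus of designated alpha-subunit gates.

    Per column, the consensus residue is the plurality among alpha
    subunits (ties broken lexicographically and logged) and the admissible
    classes are exactly the chemical classes observed among them.
    """
    scheme = scheme if scheme is not None else ConservationScheme()
    alpha_ids = sorted(set(alpha_ids))
    if len(alpha_ids) < 2:
        raise ValueError("need at least two alpha-subunit sequences to build a consensus")
    gates = {aid: extract_gate(aln, aid, columns) for aid in alpha_ids}
    width = columns[1] - columns[0] + 1
    consensus = []
    admissible: List[FrozenSet[str]] = []
    for j in range(width):
        residues = [gates[aid][j] for aid in alpha_ids]
        observed = [r for r in residues if r not in MISSING_CHARS]
        if not observed:
            raise ValueError(f"alignment column {columns[0] + j} entirely missing in the alpha set")
        if (len(residues) - len(observed)) * 2 >= len(residues):
            raise ValueError(
                f"alignment column {columns[0] + j} is >=50% missing in the alpha set"
            )
        counts: Dict[str, int] = {}
        for r in observed:
            counts[r] = counts.get(r, 0) + 1
        best = min(counts, key=lambda r: (-counts[r], r))
        top = [r for r, c in counts.items() if c == counts[best]]
        if len(top) > 1:
            logger.info("consensus column %d: tie among %s broken lexicographically -> %s",
                        columns[0] + j, sorted(top), best)
        consensus.append(best)
        admissible.append(frozenset(scheme.class_of(r) for r in observed))
    return GateConsensus(subfamily=subfamily, columns=columns,
                         consensus="".join(consensus), admissible=tuple(admissible))


def classify_gate(gate: str, cons: GateConsensus,
                  scheme: Optional[ConservationScheme] = None,
                  sequence_id: str = "") -> GateCall:
    """Flag each gate position and classify the sequence.

    A position is nonconservative when the observed residue's chemical
    class was never seen among alpha subunits at that column, or when the
    consensus residue is structurally special (P/G) and the observed
    residue differs. Missing positions (gap/X) never count against the
    sequence. ``degenerate`` iff at least one nonconservative position;
    an all-missing gate is ``missing_data``.
    """
    scheme = scheme if scheme is not None else ConservationScheme()
    if len(gate) != len(cons.consensus):
        raise ValueError(
            f"gate length {len(gate)} does not match consensus length {len(cons.consensus)}"
        )
    flags: List[str] = []
    for res, cons_res, admissible in zip(gate, cons.consensus, cons.admissible):
        if res in MISSING_CHARS:
            flags.append(MISSING)
        elif cons_res in scheme.special and res != cons_res:
            flags.append(NONCONSERVATIVE)
        elif scheme.class_of(res) not in admissible:
            flags.append(NONCONSERVATIVE)
        else:
            flags.append(CONSERVATIVE)
    if all(f == MISSING for f in flags):
        classification = MISSING_DATA
    elif any(f == NONCONSERVATIVE for f in flags):
        classification = DEGENERATE
    else:
        classification = ALPHA_LIKE
    return GateCall(sequence_id=sequence_id, gate=gate,
                    flags=tuple(flags), classification=classification)


def group_ancestral_call(group: OrthologGroup, calls: Mapping[str, GateCall],
                         lmap: LineageMap,
                         delimiter: str = DEFAULT_DELIMITER) -> str:
    """Date gate degeneration within one ortholog group.

    ``ancestral_degenerate`` when at least one member from *each* focal
    lineage is degenerate (the alteration plausibly predates the split);
    ``lineage_restricted`` when degenerate members occur in exactly one
    focal lineage; otherwise ``alpha_like``. Members without a usable call
    (absent or missing-data) are excluded.
    """
    focal = set(lmap.focal)
    degenerate_lineages: Set[str] = set()
    for member in group.members:
        call = calls.get(member)
        if call is None or call.classification == MISSING_DATA:
            logger.info("group %s: member %s has no usable gate call", group.label, member)
            continue
        if call.degenerate:
            lin = lmap.lineage_of(species_from_label(member, delimiter))
            if lin in focal:
                degenerate_lineages.add(lin)
    if degenerate_lineages == focal:
        return ANCESTRAL_DEGENERATE
    if len(degenerate_lineages) == 1:
        return LINEAGE_RESTRICTED
    return ALPHA_LIKE
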