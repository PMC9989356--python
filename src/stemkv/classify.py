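"""Family/subfamily assignment of candidate voltage-gated K+ channels.

Candidates are assigned to the Kv, EAG, and KCNQ families (and their
subfamilies) by reciprocal best-hit local alignment against an annotated
reference set, then screened for the family-diagnostic cytoplasmic domains
and for completeness of the transmembrane core:

* Kv        — S1–S6 core plus the N-terminal T1 tetramerization domain;
* KCNQ      — S1–S6 core plus the C-terminal coiled-coil assembly domain;
* EAG       — S1–S6 core plus the C-linker/CNBHD; the N-terminal eag (PAS)
              domain is *not* required because it has been lost repeatedly
              in Erg subfamily channels.

The built-in scorer is exact Smith–Waterman (affine gaps, BLOSUM62,
open 11 / extend 1) with Karlin–Altschul E-values computed from the
published ungapped BLOSUM62 constants. Desk-scale channel sets make the
exact dynamic program affordable; no external search tool is required.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices

from .io_core import AA20, SequenceSet, SeqEntry

logger = logging.getLogger("stemkv")

FAMILIES = ("Kv", "EAG", "KCNQ")
SUBFAMILIES = ("Shaker", "Shab", "Shaw", "Shal", "Eag", "Erg", "Elk", "KCNQ")
FAMILY_OF_SUBFAMILY: Dict[str, str] = {
    "Shaker": "Kv", "Shab": "Kv", "Shaw": "Kv", "Shal": "Kv",
    "Eag": "EAG", "Erg": "EAG", "Elk": "EAG",
    "KCNQ": "KCNQ",
}

DOMAIN_NAMES = ("S1S6_core", "T1", "EAG_PAS", "CNBHD_Clinker", "KCNQ_coiledcoil")

# Ungapped Karlin-Altschul constants for BLOSUM62 (standard published values).
KA_LAMBDA = 0.3176
KA_K = 0.134

_ALIGN_ALPHABET = AA20 | {"X"}


def _validate_ungapped(seq: str, role: str) -> None:
    if not seq:
        raise ValueError(f"{role} sequence is empty")
    bad = set(seq) - _ALIGN_ALPHABET
    if bad:
        raise ValueError(f"{role} sequence contains unknown residue letters: {sorted(bad)}")


def make_aligner(matrix: str = "BLOSUM62", gap_open: float = 11.0,
                 gap_extend: float = 1.0) -> PairwiseAligner:
    """Local aligner where a gap of length k costs open + (k-1)*extend."""
    al = PairwiseAligner()
    al.mode = "local"
    al.substitution_matrix = substitution_matrices.load(matrix)
    al.open_gap_score = -abs(gap_open)
    al.extend_gap_score = -abs(gap_extend)
    return al


@dataclass(frozen=True)
class AlignmentHit:
    """One local-alignment hit with Karlin-Altschul statistics."""

    query_id: str
    target_id: str
    raw_score: int
    bit_score: float
    e_value: float
    query_coverage: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.query_coverage <= 1.0):
            raise ValueError(f"coverage {self.query_coverage} outside [0, 1]")


def karlin_altschul_evalue(score: float, m: int, n: int,
                           lam: float = KA_LAMBDA, k: float = KA_K) -> float:
    """E = K * m * n * exp(-lambda * S) for search space m x n."""
    return k * m * n * math.exp(-lam * score)


def local_align(a: str, b: str, query_id: str = "query", target_id: str = "target",
                matrix: str = "BLOSUM62", gap_open: float = 11.0,
                gap_extend: float = 1.0, db_size: Optional[int] = None,
                aligner: Optional[PairwiseAligner] = None) -> AlignmentHit:
    """Optimal Smith-Waterman local alignment of two ungapped sequences.

    ``db_size`` replaces ``len(b)`` in the E-value search space when the
    target is one member of a larger database (BLAST convention).
    """
    _validate_ungapped(a, "query")
    _validate_ungapped(b, "target")
    al = aligner if aligner is not None else make_aligner(matrix, gap_open, gap_extend)
    try:
        alignment = al.align(a, b)[0]
        score = float(alignment.score)
        q_blocks = alignment.aligned[0]
        span = int(q_blocks[-1][1] - q_blocks[0][0]) if len(q_blocks) else 0
    except IndexError:  # no positive-scoring local alignment at all
        score, span = 0.0, 0
    n = db_size if db_size is not None else len(b)
    return AlignmentHit(
        query_id=query_id,
        target_id=target_id,
        raw_score=int(round(score)),
        bit_score=(KA_LAMBDA * score - math.log(KA_K)) / math.log(2.0),
        e_value=karlin_altschul_evalue(score, len(a), n),
        query_coverage=span / len(a),
    )


# ---------------------------------------------------------------------------
# Reference database and channel records
# ---------------------------------------------------------------------------

@dataclass
class ReferenceDB:
    """Annotated reference channel set used as the reciprocal-search target."""

    sequences: SequenceSet
    annotation: Dict[str, Tuple[str, str]]  # id -> (family, subfamily)

    def __post_init__(self) -> None:
        for rec in self.sequences:
            if rec.id not in self.annotation:
                raise ValueError(f"reference sequence {rec.id!r} lacks an annotation")
        for rid, (fam, sub) in self.annotation.items():
            if sub not in FAMILY_OF_SUBFAMILY:
                raise ValueError(f"unknown subfamily {sub!r} for reference {rid!r}")
            if FAMILY_OF_SUBFAMILY[sub] != fam:
                raise ValueError(
                    f"reference {rid!r}: subfamily {sub!r} inconsistent with family {fam!r}"
                )

    def total_residues(self) -> int:
        return sum(len(rec.residues) for rec in self.sequences)


@dataclass
class ChannelRecord:
    """One candidate protein and the evidence behind its classification."""

    id: str
    species: str
    family: Optional[str] = None
    subfamily: Optional[str] = None
    domain_flags: Dict[str, bool] = field(default_factory=dict)
    complete: bool = False
    reciprocal_valid: bool = False
    best_hit: Optional[AlignmentHit] = None

    @property
    def classified(self) -> bool:
        return self.family is not None


def _best_target(scores: Mapping[str, float]) -> str:
    """Highest score wins; ties broken by lexicographic target id."""
    return min(scores, key=lambda t: (-scores[t], t))


def reciprocal_classify(queries: SequenceSet, ref: ReferenceDB,
                        e_threshold: float = 0.01, mode: str = "cohort",
                        aligner: Optional[PairwiseAligner] = None) -> List[ChannelRecord]:
    """Assign family/subfamily calls by reciprocal best-hit search.

    For each query, the best reference hit proposes a call; the reference
    sequence is then searched back against the query set. In ``strict``
    mode the back-hit must be the query itself; in ``cohort`` mode (the
    default) the back-hit must carry the same proposed call as the query,
    i.e. the reciprocal match must land in the query's family/subfamily
    cohort. A call is assigned only when the reciprocity condition holds
    and the forward E-value is strictly below ``e_threshold``.
    """
    if len(queries) == 0 or len(ref.sequences) == 0:
        raise ValueError("queries and reference must be nonempty")
    if mode not in ("cohort", "strict"):
        raise ValueError(f"unknown reciprocal mode {mode!r}")
    al = aligner if aligner is not None else make_aligner()

    ref_ids = ref.sequences.ids()
    query_ids = queries.ids()
    # full score matrix (desk-scale sets; exact DP is affordable)
    fwd: Dict[str, Dict[str, float]] = {}
    for q in queries:
        _validate_ungapped(q.residues, f"query {q.id!r}")
        fwd[q.id] = {r.id: float(al.score(q.residues, r.residues)) for r in ref.sequences}

    best_ref: Dict[str, str] = {}
    for qid in query_ids:
        scores = fwd[qid]
        top = _best_target(scores)
        tied = [t for t, s in scores.items() if s == scores[top] and t != top]
        if tied:
            logger.info("query %s: best-hit tie between %s and %s broken lexicographically",
                        qid, top, tied)
        best_ref[qid] = top

    # provisional call of every query = annotation of its best reference hit
    provisional = {qid: ref.annotation[best_ref[qid]] for qid in query_ids}

    # back-search: best query hit of each reference that is someone's best hit
    back_best: Dict[str, str] = {}
    for rid in {best_ref[qid] for qid in query_ids}:
        rseq = ref.sequences.get(rid).residues
        scores = {qid: fwd[qid][rid] for qid in query_ids}
        back_best[rid] = _best_target(scores)

    db = ref.total_residues()
    records: List[ChannelRecord] = []
    for q in queries:
        rid = best_ref[q.id]
        hit = local_align(q.residues, ref.sequences.get(rid).residues,
                          query_id=q.id, target_id=rid, db_size=db, aligner=al)
        back = back_best[rid]
        if mode == "strict":
            valid = back == q.id
        else:
            valid = provisional[back] == provisional[q.id]
        rec = ChannelRecord(id=q.id, species=q.species,
                            reciprocal_valid=valid, best_hit=hit)
        if valid and hit.e_value < e_threshold:
            rec.family, rec.subfamily = provisional[q.id]
        else:
            logger.info("query %s left unclassified (reciprocal_valid=%s, E=%.3g)",
                        q.id, valid, hit.e_value)
        records.append(rec)
    return records


# ---------------------------------------------------------------------------
# Domain detection
# ---------------------------------------------------------------------------

@dataclass
class DomainProfile:
    """A diagnostic domain represented by an aligned reference block.

    Presence is scored by local alignment of a candidate against the
    profile's plurality consensus; the score threshold is calibrated from
    an empirical shuffled-sequence null (no published numeric cutoffs
    exist for these domains).
    """

    name: str
    alignment: SequenceSet
    score_threshold: Optional[float] = None

    def __post_init__(self) -> None:
        if self.name not in DOMAIN_NAMES:
            raise ValueError(f"unknown domain profile name {self.name!r}")
        if len(self.alignment) == 0:
            raise ValueError(f"domain profile {self.name!r} has an empty reference alignment")
        self.alignment.aligned_length()  # raises on ragged input

    def consensus(self) -> str:
        """Plurality residue per column, ignoring gaps/X (ties lexicographic)."""
        ncol = self.alignment.aligned_length()
        out = []
        for j in range(ncol):
            counts: Dict[str, int] = {}
            for rec in self.alignment:
                res = rec.residues[j]
                if res in ("-", "X"):
                    continue
                counts[res] = counts.get(res, 0) + 1
            if not counts:
                continue  # all-missing column contributes nothing
            out.append(min(counts, key=lambda r: (-counts[r], r)))
        return "".join(out)


def calibrate_threshold(profile: DomainProfile, n_shuffles: int = 1000,
                        quantile: float = 0.999, seed: int = 0,
                        aligner: Optional[PairwiseAligner] = None) -> float:
    """Set the profile threshold at a quantile of a shuffled-sequence null.

    The null scores are local alignments of residue-shuffled copies of the
    consensus against the consensus itself, so the threshold controls the
    chance that an unrelated sequence of similar composition scores as
    'present'.
    """
    al = aligner if aligner is not None else make_aligner()
    cons = profile.consensus()
    rng = np.random.default_rng(seed)
    letters = list(cons)
    scores = np.empty(n_shuffles)
    for i in range(n_shuffles):
        shuf = "".join(rng.permutation(letters))
        scores[i] = al.score(shuf, cons)
    thr = float(np.quantile(scores, quantile))
    profile.score_threshold = thr
    logger.info("domain %s: threshold %.1f (%.1f%% quantile of %d shuffles)",
                profile.name, thr, 100 * quantile, n_shuffles)
    return thr


def detect_domains(seq: str, profiles: Sequence[DomainProfile],
                   aligner: Optional[PairwiseAligner] = None) -> Dict[str, bool]:
    """Score a sequence against each profile consensus; present iff >= threshold."""
    _validate_ungapped(seq, "candidate")
    al = aligner if aligner is not None else make_aligner()
    flags: Dict[str, bool] = {}
    for prof in profiles:
        if prof.score_threshold is None:
            raise ValueError(
                f"domain profile {prof.name!r} has no score threshold; run calibrate_threshold"
            )
        score = float(al.score(seq, prof.consensus()))
        flags[prof.name] = score >= prof.score_threshold
    return flags


# required diagnostic domains per family (beyond the S1-S6 core)
_REQUIRED_DOMAINS = {
    "Kv": ("S1S6_core", "T1"),
    "KCNQ": ("S1S6_core", "KCNQ_coiledcoil"),
    "EAG": ("S1S6_core", "CNBHD_Clinker"),  # EAG_PAS optional (lost in some Ergs)
}


def completeness_check(rec: ChannelRecord, flags: Optional[Mapping[str, bool]] = None) -> bool:
    """A sequence is complete when its family's diagnostic domains are all present."""
    if rec.family is None:
        raise ValueError(f"record {rec.id!r} has no family call; cannot assess completeness")
    use = flags if flags is not None else rec.domain_flags
    required = _REQUIRED_DOMAINS[rec.family]
    complete = all(use.get(name, False) for name in required)
    rec.domain_flags = dict(use)
    rec.complete = complete
    if not complete:
        missing = [name for name in required if not use.get(name, False)]
        logger.info("record %s incomplete: missing %s", rec.id, missing)
    return complete


def alignment_missing_filter(aln: SequenceSet, max_missing: float = 0.10) -> SequenceSet:
    """Drop aligned sequences whose gap/X fraction exceeds ``max_missing``.

    A sequence missing exactly the threshold fraction survives (removal
    requires strictly more than ``max_missing`` of the aligned region).
    """
    if len(aln) == 0:
        return aln
    ncol = aln.aligned_length()
    kept: List[SeqEntry] = []
    for rec in aln:
        frac = sum(1 for c in rec.residues if c in ("-", "X")) / ncol
        if frac > max_missing:
            logger.info("removed %s: %.1f%% of aligned region missing", rec.id, 100 * frac)
        else:
            kept.append(rec)
    return SequenceSet(kept, source_path=aln.source_path)
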