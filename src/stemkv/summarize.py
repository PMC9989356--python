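"""Per-species channel count tables and ancestral presence/absence matrices.

Covers the two summary products of a lineage-conservation analysis: a
species x subfamily count table with mean/min/max row totals, and a
presence/absence matrix of ancestral ortholog groups across taxonomic
classes (present = the class contributes at least one member to the
group).

The published cnidarian/bilaterian channel count table ships with the
package (``load_published_counts``) so the summary statistics can be
reproduced without rebuilding the underlying proteome searches.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from typing import Dict, Iterable, List, Mapping, Optional, Sequence

import pandas as pd

from .classify import SUBFAMILIES, ChannelRecord
from .ortholog_groups import OrthologGroup

logger = logging.getLogger("stemkv")

PRESENT = "present"
ABSENT = "absent"


def load_published_counts() -> pd.DataFrame:
    """The published per-species channel count table (8 cnidarians + 3 bilaterians).

    Index: species. Columns: lineage, class, the 8 subfamily counts.
    """
    with resources.files("stemkv.data").joinpath("published_channel_counts.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", index_col="species")
    return df


def _validated_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in SUBFAMILIES if c not in table.columns]
    if missing:
        raise ValueError(f"count table missing subfamily columns: {missing}")
    counts = table[list(SUBFAMILIES)]
    if (counts < 0).any().any():
        raise ValueError("count table contains negative cells")
    return counts


def tabulate_counts(records: Iterable[ChannelRecord]) -> pd.DataFrame:
    """Species x subfamily table of complete, classified channel counts.

    Cell = number of complete records with that species and subfamily
    call; records without a call (or incomplete) are excluded and logged.
    A ``Total`` column holds the row sums.
    """
    cells: Dict[str, Dict[str, int]] = {}
    n_excluded = 0
    for rec in records:
        if rec.subfamily is None or not rec.complete:
            n_excluded += 1
            continue
        row = cells.setdefault(rec.species, {sub: 0 for sub in SUBFAMILIES})
        row[rec.subfamily] += 1
    if n_excluded:
        logger.info("tabulate_counts: %d unclassified/incomplete records excluded", n_excluded)
    table = pd.DataFrame.from_dict(cells, orient="index").reindex(columns=list(SUBFAMILIES))
    table = table.fillna(0).astype(int)
    table.index.name = "species"
    table = table.sort_index()
    table["Total"] = table[list(SUBFAMILIES)].sum(axis=1)
    return table


@dataclass(frozen=True)
class TotalsSummary:
    mean: float
    mean_display: int  # rounded half-up for display parity with printed tables
    minimum: int
    argmin: str
    maximum: int
    argmax: str


def row_totals(table: pd.DataFrame) -> pd.Series:
    return _validated_table(table).sum(axis=1)


def summarize_totals(table: pd.DataFrame,
                     species: Optional[Sequence[str]] = None) -> TotalsSummary:
    """Mean/min/max of per-species totals over a species subset.

    The mean is reported unrounded and rounded half-up to an integer for
    display; min and max come with the species attaining them.
    """
    totals = row_totals(table)
    if species is not None:
        if len(species) == 0:
            raise ValueError("species subset must be nonempty")
        missing = [sp for sp in species if sp not in totals.index]
        if missing:
            raise ValueError(f"species not in count table: {missing}")
        totals = totals.loc[list(species)]
    mean = float(totals.mean())
    return TotalsSummary(
        mean=mean,
        mean_display=int(mean + 0.5) if mean >= 0 else -int(-mean + 0.5),
        minimum=int(totals.min()),
        argmin=str(totals.idxmin()),
        maximum=int(totals.max()),
        argmax=str(totals.idxmax()),
    )


def build_presence_matrix(per_class_groups: Mapping[str, Iterable[OrthologGroup]],
                          labels: Sequence[str]) -> pd.DataFrame:
    """Ancestral-group x class presence/absence matrix.

    ``per_class_groups`` maps each taxonomic class to the ortholog groups
    recovered for it, with group labels drawn from ``labels`` (the ordered
    ancestral gene list). A cell is ``present`` iff the class contributes
    at least one member to that ancestral group.
    """
    label_set = set(labels)
    matrix = pd.DataFrame(ABSENT, index=list(labels), columns=list(per_class_groups))
    matrix.index.name = "ancestral_group"
    for cls, groups in per_class_groups.items():
        for group in groups:
            if group.label not in label_set:
                raise ValueError(
                    f"group label {group.label!r} (class {cls!r}) not in the ancestral label list"
                )
            if len(group.members) > 0:
                matrix.loc[group.label, cls] = PRESENT
    counts = (matrix == PRESENT).sum(axis=0)
    for cls, n in counts.items():
        logger.info("class %s: %d of %d ancestral groups present", cls, n, len(labels))
    return matrix


def presence_counts(matrix: pd.DataFrame) -> pd.Series:
    """Ancestral groups present per class."""
    return (matrix == PRESENT).sum(axis=0)
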