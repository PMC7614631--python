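"""LINE-1 insertion rates and 3' transduction source attribution.

Transcriptional read-through occasionally co-mobilises unique genomic
sequence downstream of a LINE-1 source element (a 3' transduction); an
insertion carrying a transduced segment is attributed to the annotated
full-length element whose 3' end lies within a window upstream of the
transduced sequence on the correct strand.  Operates on insertion call
records (not reads); the simulator's truth channel stands in for read-level
detection.
"""

from __future__ import annotations

import pandas as pd

from devilclones.rates import RateFit, burden_regression
from devilclones.trees import CloneTree
from devilclones.phylo_clock import map_event_to_tree

__all__ = ["attribute_sources", "source_activity_by_node", "insertion_rate"]


def attribute_sources(
    insertions: pd.DataFrame,
    l1_annotation: pd.DataFrame,
    window_bp: int = 10_000,
) -> pd.DataFrame:
    """Attribute transduction-bearing insertions to source elements.

    ``insertions`` columns: insertion_id, chrom, pos and (for transduction
    carriers) td_chrom, td_start, td_end (0-based half-open, NaN when
    absent).  ``l1_annotation``: element_id, chrom, start, end, strand.
    Returns the insertion table with ``source`` (element id, "orphan", or
    "" for non-transduction insertions) and a ``tie`` flag when two
    candidate sources fall within the window.
    """
    out = insertions.copy()
    out["source"] = ""
    out["tie"] = False
    elems = list(l1_annotation.itertuples(index=False))
    for i, row in out.iterrows():
        if pd.isna(row.get("td_start")) or row.get("td_chrom", "") in ("", None):
            continue
        candidates = []
        for e in elems:
            if e.chrom != row.td_chrom:
                continue
            if e.strand == "+":
                gap = row.td_start - e.end  # transduction downstream of 3' end
            else:
                gap = e.start - row.td_end
            if 0 <= gap <= window_bp:
                candidates.append((gap, e.element_id))
        if not candidates:
            out.loc[i, "source"] = "orphan"
        else:
            candidates.sort()
            out.loc[i, "source"] = candidates[0][1]
            out.loc[i, "tie"] = len(candidates) > 1
    return out


def source_tally(attributed: pd.DataFrame) -> pd.Series:
    """Per-source transduction counts (orphans reported under 'orphan')."""
    withtd = attributed[attributed["source"] != ""]
    return withtd["source"].value_counts()


def source_activity_by_node(
    attributed: pd.DataFrame,
    carriers: dict,
    tree: CloneTree,
) -> pd.DataFrame:
    """Per-source, per-branch insertion activity via gain parsimony.

    ``carriers`` maps insertion_id -> set of tip labels carrying it.  Each
    insertion is assigned to its parsimony origin branch(es); cumulative
    activity along any root-to-tip path is monotone non-decreasing by
    construction.
    """
    rows = []
    for row in attributed.itertuples(index=False):
        carrier_set = carriers.get(row.insertion_id)
        if not carrier_set:
            continue
        for branch in map_event_to_tree(tree, set(carrier_set), "gain"):
            rows.append((row.source, branch, tree.depth(branch), row.insertion_id))
    df = pd.DataFrame(rows, columns=["source", "branch", "depth", "insertion_id"])
    return (
        df.groupby(["source", "branch", "depth"])
        .size()
        .rename("n_insertions")
        .reset_index()
    )


def insertion_rate(burdens, dates) -> RateFit:
    """LINE-1 insertion accumulation rate (per genome per year); same
    regression model as the other mutation classes."""
    return burden_regression(burdens, dates)
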