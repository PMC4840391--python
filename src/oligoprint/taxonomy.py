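"""Best-hit taxonomy assignment for oligotype representatives.

Each representative sequence is compared to every entry of a lineage-annotated
reference database by optimal global (Needleman-Wunsch) alignment, and the
lineage of the highest-percent-identity reference is adopted.  When several
references tie for the best identity, the assigned lineage is truncated to the
deepest rank at which all tied references agree.  Count matrices can then be
collapsed to any rank of the seven-rank lineage.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from Bio import Align

RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")

MATCH_SCORE = 5
MISMATCH_SCORE = -4
GAP_SCORE = -10  # linear


@dataclass
class ReferenceDB:
    """Reference sequences with 7-rank lineages (domain .. species)."""

    entries: list[tuple[str, str, tuple[str, ...]]]

    def __post_init__(self) -> None:
        ids = [rid for rid, _, _ in self.entries]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate reference ids: {dupes}")
        for rid, seq, lineage in self.entries:
            if not seq:
                raise ValueError(f"reference {rid!r} has an empty sequence")
            if len(lineage) != len(RANKS):
                raise ValueError(f"reference {rid!r} lineage must have {len(RANKS)} ranks")

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class Assignment:
    """Lineage assigned to one oligotype node, with match quality."""

    node_id: str
    lineage: tuple[str, ...]
    percent_identity: float
    n_best_hits: int


def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = MATCH_SCORE
    aligner.mismatch_score = MISMATCH_SCORE
    aligner.open_gap_score = GAP_SCORE
    aligner.extend_gap_score = GAP_SCORE
    return aligner


def global_align(a: str, b: str) -> tuple[str, str, float]:
    """Optimal global alignment of two ungapped DNA sequences.

    Scoring: match +5, mismatch -4, gap -10 per gapped position (linear,
    terminal gaps included).  Returns the two gapped strings and the score;
    among co-optimal alignments the aligner's canonical traceback is taken,
    so the result is deterministic.
    """
    a = a.replace("-", "")
    b = b.replace("-", "")
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    alignment = _aligner().align(a, b)[0]
    return str(alignment[0]), str(alignment[1]), float(alignment.score)


def percent_identity(aligned_a: str, aligned_b: str) -> float:
    """Percent identical columns, excluding terminal-gap columns.

    Internal gap columns count as mismatches; leading/trailing overhangs where
    either sequence has not yet started (or has already ended) are excluded so
    partial-length references are not penalised.  An alignment with no
    comparable columns is an error.
    """
    if len(aligned_a) != len(aligned_b):
        raise ValueError("aligned strings differ in length")

    def _span(s: str) -> tuple[int, int]:
        first = len(s) - len(s.lstrip("-"))
        last = len(s.rstrip("-")) - 1
        return first, last

    a0, a1 = _span(aligned_a)
    b0, b1 = _span(aligned_b)
    start, end = max(a0, b0), min(a1, b1)
    if start > end:
        raise ValueError("no comparable columns (terminal gaps only)")
    n_cols = end - start + 1
    matches = sum(
        1
        for x, y in zip(aligned_a[start : end + 1], aligned_b[start : end + 1])
        if x == y and x != "-"
    )
    return 100.0 * matches / n_cols


def assign_lineage(
    representative: str, refdb: ReferenceDB, node_id: str = ""
) -> Assignment:
    """Best-hit assignment of `representative` against every reference entry.

    Ties at the best percent identity are resolved by truncating the lineage
    to the deepest rank on which all tied references agree (ranks below the
    first disagreement are blanked).  The tie rule depends only on the set of
    tied references, so the result is invariant to reference order.
    """
    if len(refdb) == 0:
        raise ValueError("reference database is empty")
    query = representative.replace("-", "")
    best_pid = -1.0
    best: list[tuple[str, ...]] = []
    for rid, seq, lineage in refdb.entries:
        aa, ab, _ = global_align(query, seq)
        pid = percent_identity(aa, ab)
        if pid > best_pid + 1e-9:
            best_pid = pid
            best = [lineage]
        elif abs(pid - best_pid) <= 1e-9:
            best.append(lineage)
    lineage = _consensus(best)
    return Assignment(node_id, lineage, best_pid, len(best))


def _consensus(lineages: Sequence[tuple[str, ...]]) -> tuple[str, ...]:
    """Deepest-agreeing-rank consensus across tied lineages."""
    out = []
    agreed = True
    for rank_values in zip(*lineages):
        if agreed and len(set(rank_values)) == 1:
            out.append(rank_values[0])
        else:
            agreed = False
            out.append("")
    return tuple(out)


def assign_all(
    representatives: Mapping[str, str], refdb: ReferenceDB
) -> dict[str, Assignment]:
    return {
        nid: assign_lineage(seq, refdb, node_id=nid)
        for nid, seq in representatives.items()
    }


def collapse_counts(
    count_matrix: pd.DataFrame,
    assignments: Mapping[str, Assignment],
    level: str,
) -> pd.DataFrame:
    """Sum node rows of a (nodes x samples) count matrix by lineage rank.

    `level` is 'phylum', 'genus', 'species' or 'oligotype' (identity).  Nodes
    unresolved at the requested rank are pooled under their deepest resolved
    name suffixed '_unclassified'.  Column (per-sample) totals are conserved.
    """
    if level == "oligotype":
        return count_matrix.copy()
    if level == "otu97":
        raise ValueError("otu97 collapse requires an OTU map; see community.bin_otus_97")
    if level not in RANKS:
        raise ValueError(f"unknown level {level!r}")
    rank_idx = RANKS.index(level)
    labels = {}
    for nid in count_matrix.index:
        try:
            lineage = assignments[nid].lineage
        except KeyError:
            raise KeyError(f"node {nid!r} has no assignment") from None
        name = lineage[rank_idx]
        if not name:
            deepest = next((v for v in reversed(lineage) if v), "Unknown")
            name = f"{deepest}_unclassified"
        labels[nid] = name
    grouped = count_matrix.groupby(count_matrix.index.map(labels.get), sort=False).sum()
    grouped.index.name = level
    return grouped


def write_assignments(assignments: Mapping[str, Assignment], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("node_id\tlineage\tpercent_identity\tn_best_hits\n")
        for nid, a in assignments.items():
            lineage = ";".join(a.lineage).rstrip(";")
            fh.write(f"{nid}\t{lineage}\t{a.percent_identity:.2f}\t{a.n_best_hits}\n")
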