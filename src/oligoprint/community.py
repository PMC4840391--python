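"""Community matrices: relative abundance, abundance filters, 97% OTU binning
and cross-study harmonization on shared taxa."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

LEVELS = ("phylum", "genus", "species", "otu97", "oligotype")

OTU_IDENTITY_THRESHOLD = 0.97


@dataclass
class AbundanceTable:
    """Samples x taxa abundance matrix tagged with its taxonomic level.

    `data` rows are samples, columns are taxa; `sample_meta` carries the
    individual and timepoint label of every sample.  When `relative` is True
    each row sums to 1 (before any taxon subsetting).
    """

    data: pd.DataFrame
    sample_meta: pd.DataFrame  # index = sample ids; columns: individual, timepoint
    level: str
    relative: bool = True
    subset: bool = field(default=False)  # True once taxa have been dropped

    def __post_init__(self) -> None:
        if self.level not in LEVELS:
            raise ValueError(f"unknown level {self.level!r}; expected one of {LEVELS}")
        if (self.data.values < 0).any():
            raise ValueError("abundances must be non-negative")
        if self.data.columns.duplicated().any():
            raise ValueError("duplicate taxon names")
        missing = self.data.index.difference(self.sample_meta.index)
        if len(missing):
            raise ValueError(f"samples without metadata: {list(missing)}")
        self.sample_meta = self.sample_meta.loc[self.data.index]
        if self.relative and not self.subset and len(self.data):
            sums = self.data.sum(axis=1).to_numpy()
            if not np.allclose(sums, 1.0, atol=1e-9):
                bad = self.data.index[~np.isclose(sums, 1.0, atol=1e-9)]
                raise ValueError(f"rows do not sum to 1: {list(bad)[:5]}")

    @property
    def samples(self) -> list[str]:
        return list(self.data.index)

    @property
    def taxa(self) -> list[str]:
        return list(self.data.columns)

    def individuals(self) -> pd.Series:
        return self.sample_meta["individual"]

    def with_data(self, data: pd.DataFrame, subset: bool | None = None) -> "AbundanceTable":
        return AbundanceTable(
            data=data,
            sample_meta=self.sample_meta.copy(),
            level=self.level,
            relative=self.relative,
            subset=self.subset if subset is None else subset,
        )

    def write_tsv(self, path: str | Path) -> None:
        """Write samples as rows: sample, individual, timepoint, then taxa.

        Level and normalisation are recorded in a `<path>.meta.json` sidecar.
        """
        path = Path(path)
        out = self.sample_meta.copy()
        out.insert(0, "sample", out.index)
        out = pd.concat([out, self.data], axis=1)
        out.to_csv(path, sep="\t", index=False)
        sidecar = {"level": self.level, "relative": self.relative, "subset": self.subset}
        Path(str(path) + ".meta.json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def read_tsv(cls, path: str | Path) -> "AbundanceTable":
        path = Path(path)
        frame = pd.read_csv(path, sep="\t")
        meta_path = Path(str(path) + ".meta.json")
        sidecar = json.loads(meta_path.read_text()) if meta_path.exists() else {}
        frame = frame.set_index("sample")
        frame.index.name = None
        sample_meta = frame[["individual", "timepoint"]]
        data = frame.drop(columns=["individual", "timepoint"])
        return cls(
            data=data,
            sample_meta=sample_meta,
            level=sidecar.get("level", "genus"),
            relative=bool(sidecar.get("relative", True)),
            subset=bool(sidecar.get("subset", False)),
        )


def counts_to_table(
    count_matrix: pd.DataFrame,
    sample_meta: pd.DataFrame,
    level: str,
) -> AbundanceTable:
    """Wrap a (taxa x samples) count matrix as a count AbundanceTable."""
    return AbundanceTable(
        data=count_matrix.T.astype(float),
        sample_meta=sample_meta,
        level=level,
        relative=False,
    )


def to_relative(table: AbundanceTable) -> AbundanceTable:
    """Divide each sample row by its total.  An all-zero sample is an error."""
    sums = table.data.sum(axis=1)
    zero = sums.index[sums == 0]
    if len(zero):
        raise ValueError(f"all-zero sample(s): {list(zero)}")
    data = table.data.div(sums, axis=0)
    return AbundanceTable(
        data=data, sample_meta=table.sample_meta.copy(), level=table.level, relative=True
    )


def mean_abundance_filter(
    table: AbundanceTable, threshold: float = 0.01
) -> AbundanceTable:
    """Keep taxa with mean relative abundance strictly > threshold over ALL
    samples, ordered by decreasing mean."""
    means = table.data.mean(axis=0)
    kept = means[means > threshold].sort_values(ascending=False)
    return table.with_data(table.data[kept.index.tolist()], subset=True)


def _aligned_identity(a: str, b: str) -> float:
    """Fraction of identical columns over shared non-terminal-gap columns."""
    if len(a) != len(b):
        raise ValueError("representatives are not aligned to equal length")

    def _span(s: str) -> tuple[int, int]:
        first = len(s) - len(s.lstrip("-"))
        last = len(s.rstrip("-")) - 1
        return first, last

    a0, a1 = _span(a)
    b0, b1 = _span(b)
    start, end = max(a0, b0), min(a1, b1)
    if start > end:
        raise ValueError("no shared non-terminal-gap columns")
    cols = end - start + 1
    matches = sum(1 for x, y in zip(a[start : end + 1], b[start : end + 1]) if x == y)
    return matches / cols


def bin_otus_97(
    representatives: Mapping[str, str],
    node_abundances: Mapping[str, float],
    threshold: float = OTU_IDENTITY_THRESHOLD,
) -> dict[str, str]:
    """Greedy abundance-ordered centroid clustering of aligned representatives.

    Nodes are visited in decreasing total abundance (ties by node id); each
    node joins the first existing bin containing ANY member at >= `threshold`
    identity (single-linkage admission, first-bin priority), otherwise it
    founds a new bin.  Returns node_id -> otu_id; every node lands in exactly
    one bin, and re-binning the bin founders reproduces the same partition.
    """
    widths = {len(s) for s in representatives.values()}
    if len(widths) > 1:
        raise ValueError(f"ragged representatives: widths {sorted(widths)}")
    order = sorted(representatives, key=lambda nid: (-node_abundances[nid], nid))
    bins: list[list[str]] = []
    assignment: dict[str, str] = {}
    for nid in order:
        seq = representatives[nid]
        placed = False
        for bi, members in enumerate(bins):
            if any(
                _aligned_identity(seq, representatives[mid]) >= threshold
                for mid in members
            ):
                members.append(nid)
                assignment[nid] = f"otu_{bi + 1:03d}"
                placed = True
                break
        if not placed:
            bins.append([nid])
            assignment[nid] = f"otu_{len(bins):03d}"
    return assignment


def collapse_to_otus(
    count_matrix: pd.DataFrame, otu_map: Mapping[str, str]
) -> pd.DataFrame:
    """Sum node rows of a (nodes x samples) matrix by OTU bin."""
    labels = count_matrix.index.map(lambda nid: otu_map[nid])
    grouped = count_matrix.groupby(labels, sort=False).sum()
    grouped.index.name = "otu97"
    return grouped


def subset_shared_taxa(
    tables: Sequence[AbundanceTable],
) -> tuple[list[AbundanceTable], list[float]]:
    """Restrict tables to the taxa present in all of them.

    Values are NOT renormalized — they stay fractions of the whole community.
    Returns the restricted tables and, per table, the mean summed relative
    abundance (%) of the excluded taxa.
    """
    if len(tables) < 2:
        raise ValueError("need at least two tables to harmonize")
    levels = {t.level for t in tables}
    if len(levels) > 1:
        raise ValueError(f"tables are at different levels: {sorted(levels)}")
    shared = set(tables[0].taxa)
    for t in tables[1:]:
        shared &= set(t.taxa)
    if not shared:
        raise ValueError("no taxa shared between all tables")
    order = [t for t in tables[0].taxa if t in shared]
    restricted = []
    excluded_pct = []
    for t in tables:
        dropped = [x for x in t.taxa if x not in shared]
        excluded_pct.append(float(t.data[dropped].sum(axis=1).mean() * 100.0))
        restricted.append(t.with_data(t.data[order], subset=True))
    return restricted, excluded_pct
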