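"""Minimum-entropy decomposition of an aligned amplicon read set.

The decomposer partitions reads on high-information alignment columns: any
node whose maximum column-wise Shannon entropy exceeds a threshold `m` is
split into child nodes by the residue at its highest-entropy column, and the
recursion stops when every node is internally homogeneous (max entropy <= m).
Two noise filters follow, in order:

* minimum substantive abundance (M): a node is discarded when its most
  frequent unique member sequence has fewer than M copies;
* maximum variation allowed (V): reads differing from their node's
  representative at more than V columns are removed.

Each surviving node is an *oligotype* — a bin of reads separated from every
other bin by at least one nucleotide.  Read accounting is exact:
``n_input == n_retained + n_removed_min_abundance + n_removed_max_variation``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._utils import STATES, decode_row
from .seqio import AlignedReadSet

DEFAULT_MIN_SUBSTANTIVE_ABUNDANCE = 60
DEFAULT_MAX_VARIATION = 3
#: Entropy stopping threshold in bits; nodes at or below it are homogeneous.
DEFAULT_ENTROPY_THRESHOLD = 0.0965

_N_STATES = len(STATES)


@dataclass
class Node:
    """One oligotype: its reads, representative sequence and sample counts."""

    node_id: str
    member_reads: list[str]
    representative: str
    per_sample_counts: dict[str, int]
    max_entropy: float

    @property
    def size(self) -> int:
        return len(self.member_reads)


@dataclass
class DecompositionResult:
    nodes: list[Node]
    n_input: int
    n_retained: int
    n_removed_min_abundance: int
    n_removed_max_variation: int
    parameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        total = self.n_retained + self.n_removed_min_abundance + self.n_removed_max_variation
        if total != self.n_input:
            raise ValueError(
                f"read accounting broken: {self.n_input} != {self.n_retained} + "
                f"{self.n_removed_min_abundance} + {self.n_removed_max_variation}"
            )
        if sum(n.size for n in self.nodes) != self.n_retained:
            raise ValueError("node sizes do not sum to n_retained")

    def count_matrix(self, samples: list[str] | None = None) -> pd.DataFrame:
        """(nodes x samples) integer count matrix."""
        if samples is None:
            seen: dict[str, None] = {}
            for node in self.nodes:
                for s in node.per_sample_counts:
                    seen.setdefault(s, None)
            samples = list(seen)
        data = {
            node.node_id: [node.per_sample_counts.get(s, 0) for s in samples]
            for node in self.nodes
        }
        return pd.DataFrame(data, index=samples).T

    def representatives(self) -> dict[str, str]:
        return {node.node_id: node.representative for node in self.nodes}


def _column_entropies(mat: np.ndarray) -> np.ndarray:
    """Shannon entropy (bits) of every alignment column of a code matrix."""
    n, width = mat.shape
    counts = np.zeros((_N_STATES, width), dtype=np.int64)
    for s in range(_N_STATES):
        counts[s] = (mat == s).sum(axis=0)
    p = counts / n
    logs = np.log2(p, out=np.zeros_like(p), where=p > 0)
    return -(p * logs).sum(axis=0)


def column_entropy(members, column_index: int) -> float:
    """Shannon entropy in bits of one column over a set of member sequences.

    States are {A, C, G, T, -, N}; a single-state column has entropy 0.
    """
    if hasattr(members, "matrix"):
        mat = members.matrix()
    else:
        from ._utils import encode_alignment

        mat = encode_alignment(list(members))
    if mat.shape[0] == 0:
        raise ValueError("empty member set")
    if not 0 <= column_index < mat.shape[1]:
        raise IndexError(f"column {column_index} out of range 0..{mat.shape[1] - 1}")
    return float(_column_entropies(mat[:, [column_index]])[0])


def _unique_with_counts(mat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    return np.unique(mat, axis=0, return_counts=True)


def representative_of(mat: np.ndarray) -> tuple[str, int]:
    """Most frequent unique sequence (ties -> lexicographically smallest string).

    Returns the decoded sequence and its copy number.
    """
    if mat.shape[0] == 0:
        raise ValueError("empty node has no representative")
    uniq, counts = _unique_with_counts(mat)
    top = counts.max()
    candidates = [decode_row(uniq[i]) for i in np.flatnonzero(counts == top)]
    return min(candidates), int(top)


def representative(node_sequences: list[str]) -> str:
    """Representative of a node given as a list of member sequences."""
    from ._utils import encode_alignment

    seq, _ = representative_of(encode_alignment(node_sequences))
    return seq


@dataclass
class _RawNode:
    idx: np.ndarray  # read indices into the original matrix
    max_entropy: float


def _partition(mat: np.ndarray, m: float) -> list[_RawNode]:
    """Split on the single highest-entropy column until all nodes are <= m."""
    final: list[_RawNode] = []
    stack = [np.arange(mat.shape[0], dtype=np.intp)]
    while stack:
        idx = stack.pop()
        sub = mat[idx]
        ent = _column_entropies(sub)
        col = int(np.argmax(ent))  # ties -> lowest column index
        top = float(ent[col])
        if top <= m:
            final.append(_RawNode(idx=idx, max_entropy=top))
            continue
        residues = sub[:, col]
        for state in range(_N_STATES):
            child = idx[residues == state]
            if child.size:
                stack.append(child)
    return final


def filter_min_abundance(
    raw_nodes: list[_RawNode], mat: np.ndarray, M: int
) -> tuple[list[_RawNode], int]:
    """Discard nodes whose most frequent unique sequence has < M copies.

    All reads of a discarded node count as removed; retention at exactly M.
    """
    survivors: list[_RawNode] = []
    removed = 0
    for node in raw_nodes:
        _, top_count = representative_of(mat[node.idx])
        if top_count < M:
            removed += int(node.idx.size)
        else:
            survivors.append(node)
    return survivors, removed


def filter_max_variation(
    node_idx: np.ndarray, mat: np.ndarray, rep_row: np.ndarray, V: int
) -> tuple[np.ndarray, int]:
    """Drop member reads differing from the representative at more than V columns.

    A gap aligned against a base counts as a difference.  The representative's
    own copies differ at 0 columns, so it always survives.
    """
    diffs = (mat[node_idx] != rep_row).sum(axis=1)
    keep = diffs <= V
    return node_idx[keep], int((~keep).sum())


def decompose(
    reads: AlignedReadSet,
    M: int = DEFAULT_MIN_SUBSTANTIVE_ABUNDANCE,
    V: int = DEFAULT_MAX_VARIATION,
    m: float = DEFAULT_ENTROPY_THRESHOLD,
) -> DecompositionResult:
    """Entropy-decompose an aligned read set into oligotypes.

    Parameters
    ----------
    reads:
        Rectangular aligned read set with sample labels.
    M:
        Minimum substantive abundance: required copy number of a node's most
        frequent unique sequence.
    V:
        Maximum variation allowed: tolerated per-read differences from the
        node representative.
    m:
        Entropy stopping threshold in bits.

    Surviving nodes are renamed ``node_0001`` ... in decreasing size order
    (ties by representative string) and per-sample counts are tallied.
    """
    if M < 1:
        raise ValueError("M must be >= 1")
    if V < 0:
        raise ValueError("V must be >= 0")
    params = {"M": M, "V": V, "entropy_threshold": m, "log_base": 2}
    n_input = len(reads)
    if n_input == 0:
        return DecompositionResult([], 0, 0, 0, 0, parameters=params)

    mat = reads.matrix()
    ids = np.array(reads.ids, dtype=object)
    sample_idx, sample_order = reads.sample_indices()

    raw_nodes = _partition(mat, m)
    raw_nodes, removed_m = filter_min_abundance(raw_nodes, mat, M)

    removed_v = 0
    finished: list[tuple[np.ndarray, str, float]] = []
    for node in raw_nodes:
        rep, _ = representative_of(mat[node.idx])
        rep_row = np.array(
            [STATES.index(c) for c in rep], dtype=np.uint8
        )
        kept_idx, dropped = filter_max_variation(node.idx, mat, rep_row, V)
        removed_v += dropped
        finished.append((kept_idx, rep, node.max_entropy))

    finished.sort(key=lambda t: (-t[0].size, t[1]))
    nodes = []
    for rank, (idx, rep, max_ent) in enumerate(finished, start=1):
        counts = np.bincount(sample_idx[idx], minlength=len(sample_order))
        per_sample = {
            s: int(c) for s, c in zip(sample_order, counts) if c > 0
        }
        nodes.append(
            Node(
                node_id=f"node_{rank:04d}",
                member_reads=[str(r) for r in ids[idx]],
                representative=rep,
                per_sample_counts=per_sample,
                max_entropy=max_ent,
            )
        )
    n_retained = sum(n.size for n in nodes)
    return DecompositionResult(
        nodes=nodes,
        n_input=n_input,
        n_retained=n_retained,
        n_removed_min_abundance=removed_m,
        n_removed_max_variation=removed_v,
        parameters=params,
    )


def write_result(
    result: DecompositionResult,
    outdir: str | Path,
    samples: list[str] | None = None,
) -> dict[str, str]:
    """Write count-matrix TSV, representatives FASTA and a run-report JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    matrix_path = outdir / "node_counts.tsv"
    result.count_matrix(samples).to_csv(matrix_path, sep="\t")
    fasta_path = outdir / "representatives.fasta"
    with open(fasta_path, "w") as fh:
        for node in result.nodes:
            fh.write(f">{node.node_id}\n{node.representative}\n")
    report = {
        "n_input": result.n_input,
        "n_retained": result.n_retained,
        "n_removed_min_abundance": result.n_removed_min_abundance,
        "n_removed_max_variation": result.n_removed_max_variation,
        "n_oligotypes": len(result.nodes),
        "parameters": result.parameters,
    }
    report_path = outdir / "decomposition_report.json"
    report_path.write_text(json.dumps(report, indent=2))
    return {
        "count_matrix": str(matrix_path),
        "representatives": str(fasta_path),
        "report": str(report_path),
    }
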