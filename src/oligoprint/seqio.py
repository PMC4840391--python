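"""Aligned-FASTA and sample-map I/O plus pre-decomposition cleanup.

Reads are amplicon sequences that have already been placed in a common
multiple-sequence alignment, so every record has the same width and the
alphabet is {A, C, G, T, N, -}.  Two cleanup rules are applied before
decomposition: reads are truncated to a fixed length (dropping shorter
reads) and alignment columns consisting only of gap characters are removed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._utils import encode_alignment
from .taxonomy import RANKS, ReferenceDB

ALPHABET = set("ACGTN-")

DEFAULT_TRIM_LENGTH = 336


class FormatError(ValueError):
    """Malformed input file (ragged alignment, bad alphabet, bad header)."""


class MappingError(KeyError):
    """A read is not present in the sample map."""


@dataclass
class AlignedReadSet:
    """Equal-length gapped reads with sample / individual / timepoint labels.

    Attributes
    ----------
    ids, seqs:
        Parallel lists: read identifiers and their gapped sequences.
    sample_of:
        read_id -> sample_id.
    individual_of, timepoint_of:
        sample_id -> individual label / ordered timepoint label.
    """

    ids: list[str]
    seqs: list[str]
    sample_of: dict[str, str]
    individual_of: dict[str, str]
    timepoint_of: dict[str, str]
    timepoint_order: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.seqs):
            raise ValueError("ids and seqs must be parallel")
        widths = {len(s) for s in self.seqs}
        if len(widths) > 1:
            raise FormatError(f"ragged alignment: widths {sorted(widths)}")
        for s in self.seqs:
            extra = set(s) - ALPHABET
            if extra:
                raise FormatError(f"invalid characters {sorted(extra)} in read set")
        for rid in self.ids:
            if rid not in self.sample_of:
                raise MappingError(f"read {rid!r} absent from the sample map")
            sid = self.sample_of[rid]
            if sid not in self.individual_of or sid not in self.timepoint_of:
                raise MappingError(f"sample {sid!r} lacks individual/timepoint labels")
        if not self.timepoint_order:
            seen: dict[str, None] = {}
            for sid in self.individual_of:
                seen.setdefault(self.timepoint_of[sid], None)
            self.timepoint_order = list(seen)

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def width(self) -> int:
        return len(self.seqs[0]) if self.seqs else 0

    @property
    def samples(self) -> list[str]:
        return list(self.individual_of)

    def matrix(self) -> np.ndarray:
        """uint8 code matrix (n_reads, width) for numeric column work."""
        return encode_alignment(self.seqs)

    def sample_indices(self) -> tuple[np.ndarray, list[str]]:
        """Per-read integer sample index plus the sample-id order it refers to."""
        order = self.samples
        pos = {s: i for i, s in enumerate(order)}
        idx = np.array([pos[self.sample_of[r]] for r in self.ids], dtype=np.intp)
        return idx, order

    def replaced(self, ids: list[str], seqs: list[str]) -> "AlignedReadSet":
        """Same labelling, new read collection (used by trimming/filtering)."""
        return AlignedReadSet(
            ids=ids,
            seqs=seqs,
            sample_of={r: self.sample_of[r] for r in ids},
            individual_of=dict(self.individual_of),
            timepoint_of=dict(self.timepoint_of),
            timepoint_order=list(self.timepoint_order),
        )


def read_sample_map(path: str | Path) -> tuple[dict, dict, dict, list]:
    """Parse the 4-column TSV: read_id, sample_id, individual, timepoint."""
    sample_of: dict[str, str] = {}
    individual_of: dict[str, str] = {}
    timepoint_of: dict[str, str] = {}
    tp_order: dict[str, None] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise FormatError(f"{path}:{ln}: expected 4 tab-separated fields")
            rid, sid, ind, tp = parts
            sample_of[rid] = sid
            individual_of[sid] = ind
            timepoint_of[sid] = tp
            tp_order.setdefault(tp, None)
    return sample_of, individual_of, timepoint_of, list(tp_order)


def write_sample_map(reads: AlignedReadSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#read_id\tsample_id\tindividual\ttimepoint\n")
        for rid in reads.ids:
            sid = reads.sample_of[rid]
            fh.write(
                f"{rid}\t{sid}\t{reads.individual_of[sid]}\t{reads.timepoint_of[sid]}\n"
            )


def read_aligned_fasta(
    path: str | Path,
    sample_map_path: str | Path,
    trim_to: int | None = None,
) -> AlignedReadSet:
    """Load an aligned FASTA and its sample map into an :class:`AlignedReadSet`.

    With `trim_to` set, records are truncated to that many leading characters
    and shorter records are dropped at load time (the way raw reads of uneven
    quality-trimmed length are equalised).  Without it a ragged file raises
    :class:`FormatError`; a record missing from the map raises
    :class:`MappingError`.
    """
    sample_of, individual_of, timepoint_of, tp_order = read_sample_map(sample_map_path)
    ids, seqs = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if trim_to is not None:
            if len(seq) < trim_to:
                continue
            seq = seq[:trim_to]
        ids.append(rec.id)
        seqs.append(seq)
    return AlignedReadSet(ids, seqs, sample_of, individual_of, timepoint_of, tp_order)


def write_aligned_fasta(reads: AlignedReadSet, path: str | Path) -> None:
    records = (
        SeqRecord(Seq(s), id=r, description="") for r, s in zip(reads.ids, reads.seqs)
    )
    SeqIO.write(records, str(path), "fasta-2line")


def trim_to_length(
    reads: AlignedReadSet, length: int = DEFAULT_TRIM_LENGTH
) -> tuple[AlignedReadSet, int]:
    """Truncate every read to its first `length` characters; drop shorter reads.

    Returns the surviving read set and the number of removed reads.  Keeping
    the 5' end anchors the trim where pyrosequencing quality is highest.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    ids, seqs = [], []
    removed = 0
    for rid, seq in zip(reads.ids, reads.seqs):
        if len(seq) < length:
            removed += 1
        else:
            ids.append(rid)
            seqs.append(seq[:length])
    return reads.replaced(ids, seqs), removed


def drop_gap_only_columns(reads: AlignedReadSet) -> AlignedReadSet:
    """Delete alignment columns in which every read carries '-'."""
    if not reads.seqs:
        return reads
    mat = reads.matrix()
    keep = ~(mat == 4).all(axis=0)  # code 4 == '-'
    if keep.all():
        return reads
    kept = mat[:, keep]
    seqs = ["".join("ACGT-N"[c] for c in row) for row in kept]
    return reads.replaced(list(reads.ids), seqs)


_RANK_PREFIX = re.compile(r"^[a-z]__")


def parse_lineage(text: str) -> tuple[str, ...]:
    """Parse a semicolon-separated lineage into a 7-rank tuple (domain..species).

    Greengenes-style rank prefixes ("k__", "p__", ...) are stripped; missing
    trailing ranks are padded with empty strings.
    """
    parts = [_RANK_PREFIX.sub("", p.strip()) for p in text.split(";")]
    parts = [p for p in parts]
    if len(parts) > len(RANKS):
        raise FormatError(f"lineage has more than {len(RANKS)} ranks: {text!r}")
    if not any(parts):
        raise FormatError(f"empty lineage: {text!r}")
    return tuple(parts + [""] * (len(RANKS) - len(parts)))


def format_lineage(lineage: tuple[str, ...]) -> str:
    return ";".join(lineage).rstrip(";")


def read_reference(path: str | Path) -> ReferenceDB:
    """Load a reference FASTA whose headers carry `id<TAB>lineage`.

    The lineage holds up to 7 semicolon-separated ranks (domain..species).
    A header without a lineage, or a duplicated id, is a format error.
    """
    entries = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        header = rec.description
        if "\t" in header:
            rid, lineage_text = header.split("\t", 1)
        elif " " in header:
            rid, lineage_text = header.split(" ", 1)
        else:
            raise FormatError(f"reference {rec.id!r} has no lineage in its header")
        rid = rid.strip()
        if rid in seen:
            raise FormatError(f"duplicate reference id {rid!r}")
        seen.add(rid)
        lineage = parse_lineage(lineage_text)
        entries.append((rid, str(rec.seq).upper(), lineage))
    return ReferenceDB(entries)


def write_reference(db: ReferenceDB, path: str | Path) -> None:
    with open(path, "w") as fh:
        for rid, seq, lineage in db.entries:
            fh.write(f">{rid}\t{format_lineage(lineage)}\n{seq}\n")
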