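"""Synthetic aligned 16S amplicon time series with known ground truth.

The generator emulates the statistical structure of a plaque-style
longitudinal design: a panel of individuals sampled at fixed timepoints, a
genus framework shared by everyone but mixed in individual-specific
proportions, sparse individual-specific oligotype profiles inside each genus
(the "fingerprint"), Dirichlet-multinomial fluctuation of each sample around
the individual's stable mean profile, and i.i.d. per-base substitution error
on the reads.  Defaults follow the study design it emulates: 8 individuals x
8 timepoints, 336-column alignment, read depth Normal(5618, 923.8) truncated
at 1.

Oligotype sequences are planted as a per-genus root plus single-substitution
variants at dedicated alignment columns, so every pair of distinct oligotypes
differs at >= 1 column and within-genus identity stays above 97%.  Gap
characters appear only as padding columns shared by all sequences (they are
exactly the gap-only columns the preprocessing stage removes), never as
variant sites.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ._utils import decode_row
from .seqio import AlignedReadSet, write_aligned_fasta, write_sample_map
from .taxonomy import ReferenceDB

#: Individual labels of the emulated 8-subject panel.
DEFAULT_INDIVIDUALS = ["A", "B", "D", "E", "H", "J", "K", "R"]
#: Ordered timepoint labels: days, weeks, months.
DEFAULT_TIMEPOINTS = ["D0", "D1", "D3", "W1", "W2", "W3", "M1", "M3"]

#: Plaque-typical genera used to name synthetic taxa, with their phyla.
DEFAULT_GENERA = [
    ("Corynebacterium", "Actinobacteria"),
    ("Neisseria", "Proteobacteria"),
    ("Rothia", "Actinobacteria"),
    ("Capnocytophaga", "Bacteroidetes"),
    ("Actinomyces", "Actinobacteria"),
    ("Streptococcus", "Firmicutes"),
    ("Fusobacterium", "Fusobacteria"),
    ("Veillonella", "Firmicutes"),
    ("Prevotella", "Bacteroidetes"),
    ("Leptotrichia", "Fusobacteria"),
]


class ConfigurationError(ValueError):
    pass


_CHARS = np.frombuffer(b"ACGT-N", dtype=np.uint8)


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic community and sequencing process.

    profile_sparsity is the symmetric Dirichlet concentration of the
    within-genus oligotype profile of each individual; values well below 1
    concentrate mass on a handful of oligotypes per individual.
    fluctuation_alpha is the Dirichlet precision of the per-sample draw
    around the individual mean profile: larger values mean calmer time
    series (temporal CV of a taxon falls as alpha grows).
    genus_concentration controls how similar individuals' genus-level
    proportions are (shared framework, differing proportions).
    """

    n_individuals: int = 8
    n_timepoints: int = 8
    read_length: int = 336
    n_genera: int = 10
    oligos_per_genus: int | Sequence[int] = 8
    reads_per_sample_mean: float = 5618.0
    reads_per_sample_sd: float = 923.8
    profile_sparsity: float = 0.1
    fluctuation_alpha: float = 50.0
    genus_concentration: float = 15.0
    base_error_rate: float = 0.001
    n_gap_columns: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_individuals", "n_timepoints", "read_length", "n_genera"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        if not 0 <= self.base_error_rate < 0.25:
            raise ConfigurationError("base_error_rate must be in [0, 0.25)")
        if self.fluctuation_alpha <= 0:
            raise ConfigurationError("fluctuation_alpha must be > 0")
        if self.profile_sparsity <= 0:
            raise ConfigurationError("profile_sparsity must be > 0")
        if self.genus_concentration <= 0:
            raise ConfigurationError("genus_concentration must be > 0")
        if self.reads_per_sample_mean <= 0:
            raise ConfigurationError("reads_per_sample_mean must be > 0")
        if not 0 <= self.n_gap_columns < self.read_length:
            raise ConfigurationError("n_gap_columns must be in [0, read_length)")
        for k in self.oligo_counts():
            if k < 1:
                raise ConfigurationError("oligos_per_genus entries must be >= 1")
            if k - 1 > self.read_length - self.n_gap_columns:
                raise ConfigurationError(
                    f"cannot plant {k} distinct oligotypes in "
                    f"{self.read_length - self.n_gap_columns} variable columns"
                )

    def oligo_counts(self) -> list[int]:
        if isinstance(self.oligos_per_genus, int):
            return [self.oligos_per_genus] * self.n_genera
        counts = list(self.oligos_per_genus)
        if len(counts) != self.n_genera:
            raise ConfigurationError(
                "oligos_per_genus sequence length must equal n_genera"
            )
        return counts

    def individuals(self) -> list[str]:
        if self.n_individuals <= len(DEFAULT_INDIVIDUALS):
            return DEFAULT_INDIVIDUALS[: self.n_individuals]
        return [f"I{i:02d}" for i in range(1, self.n_individuals + 1)]

    def timepoints(self) -> list[str]:
        if self.n_timepoints <= len(DEFAULT_TIMEPOINTS):
            return DEFAULT_TIMEPOINTS[: self.n_timepoints]
        return [f"T{i:02d}" for i in range(1, self.n_timepoints + 1)]

    def genera(self) -> list[tuple[str, str]]:
        """(genus, phylum) pairs for every synthetic genus."""
        out = list(DEFAULT_GENERA[: self.n_genera])
        phyla = [p for _, p in DEFAULT_GENERA]
        for i in range(len(out), self.n_genera):
            out.append((f"Genus{i + 1:02d}", phyla[i % len(phyla)]))
        return out


@dataclass
class GroundTruth:
    """Everything the generator knows about the planted community."""

    oligo_sequences: dict[str, str]
    oligo_taxonomy: dict[str, tuple[str, ...]]
    gap_columns: list[int]
    individual_mean_profiles: pd.DataFrame | None = None  # individuals x oligos
    sample_proportions: pd.DataFrame | None = None  # samples x oligos
    sample_counts: pd.DataFrame | None = None  # realized multinomial read counts
    sample_sizes: pd.Series | None = None
    sample_meta: pd.DataFrame | None = None  # sample -> individual, timepoint

    @property
    def oligo_ids(self) -> list[str]:
        return list(self.oligo_sequences)

    def genus_of(self) -> dict[str, str]:
        return {oid: lin[5] for oid, lin in self.oligo_taxonomy.items()}

    def reference_db(self) -> ReferenceDB:
        """The planted library as an ungapped lineage-annotated reference."""
        entries = [
            (oid, seq.replace("-", ""), self.oligo_taxonomy[oid])
            for oid, seq in self.oligo_sequences.items()
        ]
        return ReferenceDB(entries)

    def abundance_table(self, level: str = "oligotype"):
        """Ground-truth abundance table from the realized sample proportions."""
        from .community import AbundanceTable

        if self.sample_proportions is None:
            raise ValueError("sample proportions not generated yet")
        data = self.sample_proportions.copy()
        if level != "oligotype":
            rank = {"phylum": 1, "genus": 5, "species": 6}[level]
            labels = {oid: self.oligo_taxonomy[oid][rank] for oid in data.columns}
            data = data.T.groupby(data.columns.map(labels.get), sort=False).sum().T
        return AbundanceTable(
            data=data, sample_meta=self.sample_meta, level=level, relative=True
        )


def _stage_rng(config: SyntheticConfig, stage: int) -> np.random.Generator:
    """Stage rngs are spawned from the config seed, so running the stages
    separately equals running generate_dataset."""
    children = np.random.SeedSequence(config.seed).spawn(3)
    return np.random.default_rng(children[stage])


def generate_oligotype_library(config: SyntheticConfig) -> GroundTruth:
    """Plant oligotype sequences and lineages (stage 1 of 3).

    Each genus gets an independent random root sequence and K_g - 1 variants,
    every variant carrying a substitution at its own dedicated non-gap
    column.  Most oligotypes of a genus share one species; the remainder form
    a second species, mirroring the dominant/minor species split seen within
    real plaque genera.
    """
    rng = _stage_rng(config, 0)
    L = config.read_length
    gap_cols = np.sort(rng.choice(L, size=config.n_gap_columns, replace=False))
    nongap = np.setdiff1d(np.arange(L), gap_cols)

    sequences: dict[str, str] = {}
    taxonomy: dict[str, tuple[str, ...]] = {}
    for (genus, phylum), K in zip(config.genera(), config.oligo_counts()):
        root = np.full(L, 4, dtype=np.uint8)  # '-' everywhere, then fill
        root[nongap] = rng.integers(0, 4, size=nongap.size, dtype=np.uint8)
        variant_cols = rng.choice(nongap, size=K - 1, replace=False)
        n_sp1 = max(1, math.ceil(K * 7 / 8))
        for k in range(K):
            seq = root.copy()
            if k > 0:
                col = variant_cols[k - 1]
                seq[col] = (seq[col] + rng.integers(1, 4)) % 4
            oid = f"{genus}_{k + 1:02d}"
            species = f"{genus}_sp{1 if k < n_sp1 else 2}"
            sequences[oid] = decode_row(seq)
            taxonomy[oid] = (
                "Bacteria",
                phylum,
                f"{phylum}_c",
                f"{phylum}_o",
                f"{genus}aceae",
                genus,
                species,
            )
    return GroundTruth(
        oligo_sequences=sequences,
        oligo_taxonomy=taxonomy,
        gap_columns=[int(c) for c in gap_cols],
    )


def _safe_dirichlet(rng: np.random.Generator, alpha: np.ndarray) -> np.ndarray:
    draw = rng.dirichlet(np.maximum(alpha, 1e-12))
    if not np.isfinite(draw).all() or draw.sum() == 0:
        # pathological underflow at extreme sparsity: put mass on one category
        draw = np.zeros_like(alpha)
        draw[rng.integers(len(alpha))] = 1.0
    return draw / draw.sum()


def generate_individual_profiles(
    config: SyntheticConfig, truth: GroundTruth
) -> GroundTruth:
    """Draw each individual's stable mean oligotype profile (stage 2 of 3).

    A global genus composition is drawn once; each individual's genus-level
    means are a Dirichlet draw around it (precision = genus_concentration),
    and within each genus a sparse symmetric Dirichlet(profile_sparsity)
    assigns the individual's oligotype fingerprint.  Profiles are fixed
    across timepoints.
    """
    rng = _stage_rng(config, 1)
    genera = [g for g, _ in config.genera()]
    base = rng.dirichlet(np.full(len(genera), 3.0))
    genus_of = truth.genus_of()
    oligo_ids = truth.oligo_ids
    by_genus = {g: [o for o in oligo_ids if genus_of[o] == g] for g in genera}

    profiles = {}
    for ind in config.individuals():
        genus_means = _safe_dirichlet(rng, config.genus_concentration * base)
        profile = np.zeros(len(oligo_ids))
        for gi, g in enumerate(genera):
            members = by_genus[g]
            w = _safe_dirichlet(
                rng, np.full(len(members), config.profile_sparsity)
            )
            for oid, wk in zip(members, w):
                profile[oligo_ids.index(oid)] = genus_means[gi] * wk
        profiles[ind] = profile / profile.sum()
    frame = pd.DataFrame.from_dict(profiles, orient="index", columns=oligo_ids)
    return replace(truth, individual_mean_profiles=frame)


def generate_timeseries_reads(
    config: SyntheticConfig, truth: GroundTruth
) -> tuple[AlignedReadSet, GroundTruth]:
    """Draw per-sample proportions, depths and error-bearing reads (stage 3).

    Per sample: proportions ~ Dirichlet(fluctuation_alpha * individual mean),
    depth ~ round(Normal(reads_per_sample_mean, sd)) truncated at 1, read
    counts ~ Multinomial, and every non-gap base of every read is substituted
    independently with probability base_error_rate.
    """
    if truth.individual_mean_profiles is None:
        raise ValueError("profiles must be generated first")
    rng = _stage_rng(config, 2)
    oligo_ids = truth.oligo_ids
    L = config.read_length
    seq_codes = {
        oid: np.frombuffer(seq.encode(), dtype=np.uint8)
        for oid, seq in truth.oligo_sequences.items()
    }
    # map ASCII -> state codes once
    lut = np.zeros(256, dtype=np.uint8)
    for i, c in enumerate("ACGT-N"):
        lut[ord(c)] = i
    seq_codes = {oid: lut[arr] for oid, arr in seq_codes.items()}
    nongap_mask = {oid: arr != 4 for oid, arr in seq_codes.items()}

    ids: list[str] = []
    seqs: list[str] = []
    sample_of: dict[str, str] = {}
    individual_of: dict[str, str] = {}
    timepoint_of: dict[str, str] = {}
    proportions = {}
    realized_counts = {}
    sizes = {}
    meta = {}
    for ind in config.individuals():
        mean_profile = truth.individual_mean_profiles.loc[ind].to_numpy()
        for tp in config.timepoints():
            sid = f"{ind}_{tp}"
            individual_of[sid] = ind
            timepoint_of[sid] = tp
            meta[sid] = {"individual": ind, "timepoint": tp}
            p = _safe_dirichlet(rng, config.fluctuation_alpha * mean_profile)
            n = max(
                1,
                int(round(rng.normal(config.reads_per_sample_mean, config.reads_per_sample_sd))),
            )
            counts = rng.multinomial(n, p)
            proportions[sid] = p
            realized_counts[sid] = counts
            sizes[sid] = n
            serial = 0
            for oid, c in zip(oligo_ids, counts):
                if c == 0:
                    continue
                block = np.tile(seq_codes[oid], (c, 1))
                if config.base_error_rate > 0:
                    mask = rng.random((c, L)) < config.base_error_rate
                    mask &= nongap_mask[oid][None, :]
                    if mask.any():
                        shifts = rng.integers(1, 4, size=int(mask.sum()))
                        block[mask] = (block[mask] + shifts) % 4
                ascii_block = _CHARS[block]
                for row in ascii_block:
                    rid = f"{sid}:{ind}:{tp}:{serial:06d}"
                    serial += 1
                    ids.append(rid)
                    seqs.append(row.tobytes().decode("ascii"))
                    sample_of[rid] = sid
    reads = AlignedReadSet(
        ids=ids,
        seqs=seqs,
        sample_of=sample_of,
        individual_of=individual_of,
        timepoint_of=timepoint_of,
        timepoint_order=config.timepoints(),
    )
    truth = replace(
        truth,
        sample_proportions=pd.DataFrame.from_dict(
            proportions, orient="index", columns=oligo_ids
        ),
        sample_counts=pd.DataFrame.from_dict(
            realized_counts, orient="index", columns=oligo_ids
        ),
        sample_sizes=pd.Series(sizes, name="n_reads"),
        sample_meta=pd.DataFrame.from_dict(meta, orient="index"),
    )
    return reads, truth


def generate_dataset(config: SyntheticConfig) -> tuple[AlignedReadSet, GroundTruth]:
    """Run all three generator stages for one config."""
    truth = generate_oligotype_library(config)
    truth = generate_individual_profiles(config, truth)
    return generate_timeseries_reads(config, truth)


def generate_truth_tables(config: SyntheticConfig) -> GroundTruth:
    """Ground truth including per-sample proportions, skipping read synthesis.

    The library and individual profiles are identical to what
    :func:`generate_dataset` produces for the same config; sample proportions
    are an independent draw at depth 1 so that no read matrices are built.
    Useful when only community structure is needed.
    """
    cfg = replace(config, reads_per_sample_mean=1.0, reads_per_sample_sd=0.0,
                  base_error_rate=0.0)
    truth = generate_oligotype_library(cfg)
    truth = generate_individual_profiles(cfg, truth)
    _, truth = generate_timeseries_reads(cfg, truth)
    return truth


def write_dataset(
    reads: AlignedReadSet, truth: GroundTruth, outdir: str | Path
) -> dict[str, str]:
    """Write aligned FASTA, sample map, lineage-annotated reference FASTA and
    the ground-truth TSV bundle."""
    from .seqio import write_reference

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "reads": str(outdir / "reads.fasta"),
        "sample_map": str(outdir / "sample_map.tsv"),
        "reference": str(outdir / "reference.fasta"),
    }
    write_aligned_fasta(reads, paths["reads"])
    write_sample_map(reads, paths["sample_map"])
    write_reference(truth.reference_db(), paths["reference"])

    truth_dir = outdir / "truth"
    truth_dir.mkdir(exist_ok=True)
    with open(truth_dir / "oligotypes.tsv", "w") as fh:
        fh.write("oligotype\tlineage\tsequence\n")
        for oid, seq in truth.oligo_sequences.items():
            fh.write(f"{oid}\t{';'.join(truth.oligo_taxonomy[oid])}\t{seq}\n")
    if truth.individual_mean_profiles is not None:
        truth.individual_mean_profiles.to_csv(
            truth_dir / "individual_profiles.tsv", sep="\t"
        )
    if truth.sample_proportions is not None:
        truth.sample_proportions.to_csv(truth_dir / "sample_proportions.tsv", sep="\t")
        truth.sample_sizes.to_csv(truth_dir / "sample_sizes.tsv", sep="\t")
    paths["truth"] = str(truth_dir)
    return paths
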