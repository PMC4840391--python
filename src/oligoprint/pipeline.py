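"""End-to-end orchestration: simulate/load -> clean -> decompose -> assign ->
tables -> stability -> ordination, with one seed fanning out to every stage."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import community, decompose, ordination, seqio, stability, synthdata, taxonomy

log = logging.getLogger("oligoprint")


class ConfigError(ValueError):
    pass


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Declarative configuration of a full pipeline run.

    Exactly one input mode must be set: `synthetic` (a SyntheticConfig) or
    the three real-data paths (aligned FASTA, sample map, reference FASTA).
    """

    synthetic: synthdata.SyntheticConfig | None = None
    input_fasta: str | None = None
    sample_map: str | None = None
    reference: str | None = None

    trim_length: int = seqio.DEFAULT_TRIM_LENGTH
    M: int = decompose.DEFAULT_MIN_SUBSTANTIVE_ABUNDANCE
    V: int = decompose.DEFAULT_MAX_VARIATION
    entropy_threshold: float = decompose.DEFAULT_ENTROPY_THRESHOLD
    genus_filter: float = 0.01
    abundant_threshold: float = 0.10
    otu_identity: float = 0.97
    n_starts: int = ordination.DEFAULT_N_STARTS
    n_trials: int = ordination.DEFAULT_N_TRIALS
    consistency_threshold: float = ordination.DEFAULT_CONSISTENCY_THRESHOLD
    outdir: str = "results/run"
    seed: int = 0
    levels: tuple[str, ...] = ("phylum", "genus", "otu97", "oligotype")

    def __post_init__(self) -> None:
        real = [self.input_fasta, self.sample_map, self.reference]
        if self.synthetic is not None and any(real):
            raise ConfigError("set either synthetic config or input paths, not both")
        if self.synthetic is None:
            if not any(real):
                # empty config -> synthetic mode with all documented defaults
                self.synthetic = synthdata.SyntheticConfig()
            elif not all(real):
                raise ConfigError(
                    "real mode needs input_fasta, sample_map and reference paths"
                )
            else:
                for p in real:
                    if not Path(p).exists():
                        raise ConfigError(f"input path does not exist: {p}")
        if self.M < 1:
            raise ConfigError("M must be >= 1")
        if self.V < 0:
            raise ConfigError("V must be >= 0")
        for name in ("genus_filter", "abundant_threshold", "otu_identity",
                     "consistency_threshold"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ConfigError(f"{name} must be in (0, 1), got {v}")


_RUN_KEYS = {f.name for f in RunConfig.__dataclass_fields__.values()}  # type: ignore[attr-defined]
_SYN_KEYS = {f.name for f in synthdata.SyntheticConfig.__dataclass_fields__.values()}  # type: ignore[attr-defined]


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration, filling all defaults."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config file must hold a mapping")
    unknown = set(raw) - _RUN_KEYS
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    syn = raw.pop("synthetic", None)
    if syn is not None:
        bad = set(syn) - _SYN_KEYS
        if bad:
            raise ConfigError(f"unknown synthetic keys: {sorted(bad)}")
        syn = synthdata.SyntheticConfig(**syn)
    try:
        return RunConfig(synthetic=syn, **raw)
    except TypeError as exc:
        raise ConfigError(str(exc)) from exc


def _child_seeds(seed: int, n: int) -> list[int]:
    return [int(s % (2**31)) for s in np.random.SeedSequence(seed).generate_state(n)]


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and write all artifacts plus a JSON run report.

    Identical config + seed gives identical outputs.  Any stage error aborts
    with the stage name; the MANIFEST then marks the run incomplete.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"complete": False, "artifacts": {}}
    report: dict = {"seed": config.seed}
    seeds = _child_seeds(config.seed, 8)

    def _finish_manifest() -> None:
        (outdir / "MANIFEST.json").write_text(json.dumps(manifest, indent=2))

    try:
        # --- acquire -------------------------------------------------------
        stage = "acquire"
        if config.synthetic is not None:
            syn = config.synthetic
            reads, truth = synthdata.generate_dataset(syn)
            paths = synthdata.write_dataset(reads, truth, outdir / "data")
            refdb = truth.reference_db()
            manifest["artifacts"].update(paths)
            report["mode"] = "synthetic"
            report["n_planted_oligotypes"] = len(truth.oligo_ids)
        else:
            for p in (config.input_fasta, config.sample_map, config.reference):
                if not Path(p).exists():
                    raise FileNotFoundError(p)
            reads = seqio.read_aligned_fasta(config.input_fasta, config.sample_map)
            refdb = seqio.read_reference(config.reference)
            truth = None
            report["mode"] = "real"
        log.info("acquire: %d reads, %d reference entries", len(reads), len(refdb))

        # --- preprocess ----------------------------------------------------
        stage = "preprocess"
        n_raw = len(reads)
        reads, removed_short = seqio.trim_to_length(reads, config.trim_length)
        reads = seqio.drop_gap_only_columns(reads)
        report["n_raw_reads"] = n_raw
        report["n_removed_short"] = removed_short
        report["alignment_width"] = reads.width
        log.info("preprocess: %d reads remain, width %d", len(reads), reads.width)

        # --- decompose -----------------------------------------------------
        stage = "decompose"
        result = decompose.decompose(
            reads, M=config.M, V=config.V, m=config.entropy_threshold
        )
        manifest["artifacts"].update(
            decompose.write_result(result, outdir / "decomposition", reads.samples)
        )
        report["decomposition"] = {
            "n_input": result.n_input,
            "n_retained": result.n_retained,
            "n_removed_min_abundance": result.n_removed_min_abundance,
            "n_removed_max_variation": result.n_removed_max_variation,
            "n_oligotypes": len(result.nodes),
        }
        log.info(
            "decompose: %d oligotypes from %d reads", len(result.nodes), result.n_input
        )

        # --- taxonomy ------------------------------------------------------
        stage = "taxonomy"
        assignments = taxonomy.assign_all(result.representatives(), refdb)
        tax_path = outdir / "assignments.tsv"
        taxonomy.write_assignments(assignments, tax_path)
        manifest["artifacts"]["assignments"] = str(tax_path)

        # --- community tables ----------------------------------------------
        stage = "community"
        counts = result.count_matrix(reads.samples)
        meta = pd.DataFrame(
            {
                "individual": [reads.individual_of[s] for s in reads.samples],
                "timepoint": [reads.timepoint_of[s] for s in reads.samples],
            },
            index=reads.samples,
        )
        tables: dict[str, community.AbundanceTable] = {}
        genus_of = {
            nid: a.lineage[5] or f"{next((v for v in reversed(a.lineage) if v), 'Unknown')}_unclassified"
            for nid, a in assignments.items()
        }
        otu_map = community.bin_otus_97(
            result.representatives(),
            {nid: counts.loc[nid].sum() for nid in counts.index},
            threshold=config.otu_identity,
        )
        for level in config.levels + ("species",):
            if level == "otu97":
                collapsed = community.collapse_to_otus(counts, otu_map)
            else:
                collapsed = taxonomy.collapse_counts(counts, assignments, level)
            table = community.to_relative(
                community.counts_to_table(collapsed, meta, level)
            )
            tables[level] = table
            path = outdir / "tables" / f"{level}_relative.tsv"
            path.parent.mkdir(exist_ok=True)
            table.write_tsv(path)
            manifest["artifacts"][f"table_{level}"] = str(path)
        report["n_otus97"] = len(set(otu_map.values()))

        # --- stability ------------------------------------------------------
        stage = "stability"
        genus_table = tables["genus"]
        major = community.mean_abundance_filter(genus_table, config.genus_filter)
        genus_stats = stability.aggregate_stats(
            stability.per_individual_stats(major), major
        )
        stability.write_stability_table(genus_stats, outdir / "genus_stability.tsv")
        anomalies, _ = stability.anomaly_series(major)
        anomalies.to_csv(outdir / "genus_anomalies.tsv", sep="\t")
        report["n_major_genera"] = len(major.taxa)
        report["major_genera_fraction"] = float(
            genus_table.data[major.taxa].sum(axis=1).mean()
        )

        # fingerprint on the most abundant genus
        focal_genus = genus_table.data.mean(axis=0).idxmax()
        profile, excluded = stability.within_genus_profile(
            tables["oligotype"], genus_of, focal_genus
        )
        profile_stats = stability.aggregate_stats(
            stability.per_individual_stats(profile), profile
        )
        abundant, union = stability.abundant_oligotypes(
            profile_stats, threshold=config.abundant_threshold * 100
        )
        fp_abundant_cv, fp_overall_cv = stability.fingerprint_summary(
            profile_stats, abundant
        )
        stability.write_stability_table(
            profile_stats, outdir / f"{focal_genus}_oligotype_stability.tsv"
        )
        report["fingerprint"] = {
            "genus": focal_genus,
            "n_oligotypes": len(profile.taxa),
            "n_abundant_pairs": len(abundant),
            "n_abundant_union": len(union),
            "n_excluded_samples": len(excluded),
            "mean_abundant_cv": fp_abundant_cv,
            "mean_overall_cv": fp_overall_cv,
        }
        report["loo_accuracy"] = {
            level: stability.loo_accuracy(tables[level])
            for level in ("genus", "oligotype")
        }

        # --- ordination -----------------------------------------------------
        stage = "ordination"
        report["ordination"] = {}
        for i, level in enumerate(config.levels):
            res = ordination.ordinate_table(
                tables[level],
                n_starts=config.n_starts,
                n_trials=config.n_trials if level == "oligotype" else 0,
                seed=seeds[4 + (i % 4)],
            )
            manifest["artifacts"].update(
                {
                    f"ordination_{level}_{k}": v
                    for k, v in ordination.write_ordination(
                        res, tables[level], outdir / "ordination", level
                    ).items()
                }
            )
            report["ordination"][level] = {
                "stress": res.stress,
                "n_consistent": res.n_consistent,
                "n_trials": res.n_trials,
            }

        if truth is not None:
            report["ground_truth"] = {"n_planted_oligotypes": len(truth.oligo_ids)}
    except Exception as exc:  # noqa: BLE001 - annotate with the failing stage
        _finish_manifest()
        raise StageError(stage, exc) from exc

    report_path = outdir / "report.json"
    report_path.write_text(json.dumps(report, indent=2))
    manifest["artifacts"]["report"] = str(report_path)
    manifest["complete"] = True
    _finish_manifest()
    return report
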