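"""Generate the synthetic plaque time series and write it to scratch.

Produces the aligned FASTA + sample map + lineage-annotated reference the
rest of the analysis consumes, plus the ground truth for later comparison.
"""

import json

from oligoprint.synthdata import generate_dataset, write_dataset

from study_config import RESULTS, SCRATCH, STUDY


def main() -> None:
    reads, truth = generate_dataset(STUDY)
    paths = write_dataset(reads, truth, SCRATCH / "data")
    depths = truth.sample_sizes
    summary = {
        "n_reads": len(reads),
        "n_samples": len(depths),
        "mean_depth": round(float(depths.mean()), 1),
        "sd_depth": round(float(depths.std(ddof=1)), 1),
        "n_planted_oligotypes": len(truth.oligo_ids),
        "alignment_width": reads.width,
    }
    RESULTS.mkdir(parents=True, exist_ok=True)
    (RESULTS / "01_simulation_summary.json").write_text(json.dumps(summary, indent=2))
    print(
        f"Simulated {summary['n_reads']} aligned reads over "
        f"{summary['n_samples']} samples "
        f"(depth {summary['mean_depth']} +/- {summary['sd_depth']}), "
        f"{summary['n_planted_oligotypes']} planted oligotypes."
    )
    print(f"Data written under {paths['reads']}")


if __name__ == "__main__":
    main()
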