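"""Temporal stability statistics and the oligotype fingerprint contrast.

Builds the genus-level stability table (major genera only), the anomaly
series, the within-genus oligotype profile of the most abundant genus, the
within-mouth vs everywhere CV contrast, and leave-one-out individual
identification accuracy at genus vs oligotype resolution.
"""

import json

from oligoprint import community, stability
from oligoprint.cli import _read_assignments

from study_config import ABUNDANT_THRESHOLD, GENUS_FILTER, RESULTS


def main() -> None:
    genus = community.AbundanceTable.read_tsv(RESULTS / "tables" / "genus_relative.tsv")
    oligo = community.AbundanceTable.read_tsv(
        RESULTS / "tables" / "oligotype_relative.tsv"
    )

    major = community.mean_abundance_filter(genus, GENUS_FILTER)
    covered = float(genus.data[major.taxa].sum(axis=1).mean())
    genus_stats = stability.aggregate_stats(
        stability.per_individual_stats(major), major
    )
    stability.write_stability_table(genus_stats, RESULTS / "genus_stability.tsv")
    anomalies, _ = stability.anomaly_series(major)
    anomalies.to_csv(RESULTS / "genus_anomalies.tsv", sep="\t")
    print(
        f"{len(major.taxa)} genera exceed {GENUS_FILTER:.0%} mean abundance, "
        f"jointly composing {covered:.1%} of the community."
    )

    assignments = _read_assignments(RESULTS / "assignments.tsv")
    genus_of = {
        nid: a.lineage[5] or "unclassified" for nid, a in assignments.items()
    }
    focal = genus.data.mean(axis=0).idxmax()
    profile, excluded = stability.within_genus_profile(oligo, genus_of, focal)
    profile_stats = stability.aggregate_stats(
        stability.per_individual_stats(profile), profile
    )
    stability.write_stability_table(
        profile_stats, RESULTS / f"{focal}_oligotype_stability.tsv"
    )
    abundant, union = stability.abundant_oligotypes(
        profile_stats, threshold=ABUNDANT_THRESHOLD
    )
    abundant_cv, overall_cv = stability.fingerprint_summary(profile_stats, abundant)
    print(
        f"{focal}: {len(profile.taxa)} oligotypes; {len(abundant)} "
        f"(individual, oligotype) pairs exceed {ABUNDANT_THRESHOLD:.0f}% of the genus."
    )
    print(
        f"Mean CV of abundant oligotypes within their own mouths: {abundant_cv:.0f}%"
        f" vs {overall_cv:.0f}% for the same oligotypes across all samples."
    )

    loo = {
        level: stability.loo_accuracy(table)
        for level, table in (("genus", genus), ("oligotype", oligo))
    }
    print(
        "Leave-one-out individual identification: "
        + ", ".join(f"{k} {v:.1%}" for k, v in loo.items())
    )
    summary = {
        "n_major_genera": len(major.taxa),
        "major_coverage": covered,
        "focal_genus": focal,
        "n_focal_oligotypes": len(profile.taxa),
        "n_abundant_pairs": len(abundant),
        "n_abundant_union": len(union),
        "n_zero_genus_samples": len(excluded),
        "mean_abundant_cv": abundant_cv,
        "mean_overall_cv": overall_cv,
        "loo_accuracy": loo,
    }
    (RESULTS / "04_stability_summary.json").write_text(json.dumps(summary, indent=2))


if __name__ == "__main__":
    main()
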