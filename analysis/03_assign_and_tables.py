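"""Assign taxonomy to the oligotypes and build multi-level community tables.

Each representative is matched to the lineage-annotated reference by global
alignment; node counts are then collapsed to phylum, genus, species, 97% OTU
and oligotype relative-abundance tables.
"""

import pandas as pd
from Bio import SeqIO

from oligoprint import community, seqio, taxonomy

from study_config import OTU_IDENTITY, RESULTS, SCRATCH


def main() -> None:
    counts = pd.read_csv(RESULTS / "decomposition" / "node_counts.tsv",
                         sep="\t", index_col=0)
    reps = {
        rec.id: str(rec.seq)
        for rec in SeqIO.parse(RESULTS / "decomposition" / "representatives.fasta",
                               "fasta")
    }
    refdb = seqio.read_reference(SCRATCH / "data" / "reference.fasta")
    assignments = taxonomy.assign_all(reps, refdb)
    taxonomy.write_assignments(assignments, RESULTS / "assignments.tsv")
    exact = sum(1 for a in assignments.values() if a.percent_identity == 100.0)
    print(f"Assigned {len(assignments)} oligotypes; {exact} at 100% identity.")

    _, individual_of, timepoint_of, _ = seqio.read_sample_map(
        SCRATCH / "data" / "sample_map.tsv"
    )
    meta = pd.DataFrame(
        {
            "individual": [individual_of[s] for s in counts.columns],
            "timepoint": [timepoint_of[s] for s in counts.columns],
        },
        index=counts.columns,
    )
    otu_map = community.bin_otus_97(
        reps, {n: counts.loc[n].sum() for n in counts.index}, threshold=OTU_IDENTITY
    )
    outdir = RESULTS / "tables"
    outdir.mkdir(parents=True, exist_ok=True)
    for level in ("phylum", "genus", "species", "otu97", "oligotype"):
        if level == "otu97":
            collapsed = community.collapse_to_otus(counts, otu_map)
        else:
            collapsed = taxonomy.collapse_counts(counts, assignments, level)
        table = community.to_relative(community.counts_to_table(collapsed, meta, level))
        table.write_tsv(outdir / f"{level}_relative.tsv")
        print(f"  {level}: {len(table.taxa)} taxa")
    print(f"97% OTU binning: {len(set(otu_map.values()))} OTUs "
          f"from {len(reps)} oligotypes.")


if __name__ == "__main__":
    main()
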