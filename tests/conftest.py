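import numpy as np
import pandas as pd
import pytest

from oligoprint.community import AbundanceTable
from oligoprint.seqio import AlignedReadSet
from oligoprint.synthdata import SyntheticConfig, generate_dataset


def make_readset(seq_counts, width=None, sample="S1", individual="A", timepoint="T1"):
    """Build a one-sample AlignedReadSet from {sequence: copy_number}."""
    ids, seqs = [], []
    i = 0
    for seq, n in seq_counts.items():
        for _ in range(n):
            ids.append(f"r{i:05d}")
            seqs.append(seq)
            i += 1
    return AlignedReadSet(
        ids=ids,
        seqs=seqs,
        sample_of={r: sample for r in ids},
        individual_of={sample: individual},
        timepoint_of={sample: timepoint},
    )


def make_table(values, individuals, timepoints=None, level="genus", taxa=None):
    """AbundanceTable from a (samples x taxa) array and per-sample individuals."""
    values = np.asarray(values, dtype=float)
    n, t = values.shape
    samples = [f"s{i}" for i in range(n)]
    taxa = taxa or [f"tax{j}" for j in range(t)]
    timepoints = timepoints or [f"T{i}" for i in range(n)]
    meta = pd.DataFrame(
        {"individual": individuals, "timepoint": timepoints}, index=samples
    )
    return AbundanceTable(
        data=pd.DataFrame(values, index=samples, columns=taxa),
        sample_meta=meta,
        level=level,
        relative=True,
    )


@pytest.fixture(scope="session")
def small_config():
    return SyntheticConfig(
        n_individuals=3,
        n_timepoints=4,
        n_genera=3,
        oligos_per_genus=4,
        reads_per_sample_mean=300,
        reads_per_sample_sd=30,
        profile_sparsity=0.3,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate_dataset(small_config)
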