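"""Shared configuration of the synthetic plaque time-series study.

The design mirrors the emulated study: 8 individuals x 8 timepoints,
336-column alignment, depth Normal(5618, 923.8); the first genus
(Corynebacterium) carries 24 planted oligotypes, the rest 8 each.
Intermediate bulky artifacts (reads, alignments) live under scratch/;
small result tables land in results/.
"""

from pathlib import Path

from oligoprint.synthdata import SyntheticConfig

ROOT = Path(__file__).resolve().parent.parent
SCRATCH = ROOT / "scratch" / "analysis"
RESULTS = ROOT / "results"

SEED = 42

STUDY = SyntheticConfig(
    oligos_per_genus=[24, 8, 8, 8, 8, 8, 8, 8, 8, 8],
    seed=SEED,
)

MIN_SUBSTANTIVE_ABUNDANCE = 60
MAX_VARIATION = 3
GENUS_FILTER = 0.01
ABUNDANT_THRESHOLD = 10.0  # percent of the focal genus
OTU_IDENTITY = 0.97
N_TRIALS = 50
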