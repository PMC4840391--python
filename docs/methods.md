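# Methods

This note documents the models, conventions and numerical choices behind
`oligoprint`, in the order the pipeline applies them, and states what the
synthetic data generator does and does not emulate.

## Input model and preprocessing

The decomposition substrate is a rectangular alignment: equal-length gapped
reads over {A, C, G, T, N, –}, each labelled with a sample, and each sample
with an individual and an ordered timepoint. Two cleanup rules run before
decomposition:

* **Trimming** truncates every read to its first `L` characters (default
  336 nt) and drops shorter reads, counting them. The 5′ end is kept because
  per-base quality in long-read amplicon chemistries degrades toward 3′; the
  trim length is a parameter.
* **Gap-only columns** (every read has `–`) are deleted; all other columns
  keep their order. Columns are 0-based internally and 1-based in reports.

`N` bases survive I/O and are treated as a sixth column state downstream.

## Minimum-entropy decomposition

Column entropy is Shannon entropy in bits (base 2; the base only rescales
the stopping threshold). Starting from one root node, any node whose maximum
column entropy exceeds `m` is split by the residue (including `–` and `N`)
at its highest-entropy column, ties going to the lowest column index; the
recursion ends when every node's maximum entropy is ≤ `m`. The default
`m = 0.0965` bits follows the convention of entropy-decomposition tooling
for this read family and is exposed as a parameter. Splitting on a single
column per iteration (rather than several components at once) was chosen
for determinism and testability.

Filters run in a fixed order, which keeps the three-way read accounting
exact and auditable:

1. **Minimum substantive abundance (−M, default 60).** A node is discarded —
   all of its reads counted as removed — when its most frequent unique
   member sequence has fewer than M copies. The criterion tests the top
   unique sequence, not node size, so a diffuse cloud of near-singletons
   cannot pass on bulk alone; the boundary is "discard if < M".
2. **Maximum variation allowed (−V, default 3).** Reads differing from the
   node representative at more than V columns are removed; a gap aligned
   against a base counts as a difference. The representative (the most
   frequent unique sequence, ties broken to the lexicographically smallest)
   differs from itself at 0 columns and always survives.

There is no outlier-relocation step: removed reads stay removed, so
`n_input = n_retained + n_removed_M + n_removed_V` holds identically on
every input (fuzz-tested). Surviving nodes are renamed in decreasing size
order. Fidelity is to the stated criteria and accounting, not to the
internals of any particular decomposition binary.

With error-free reads and every planted oligotype backed by ≥ M reads, the
decomposer provably recovers exactly the planted sequences and the
generator's multinomial per-sample counts; with i.i.d. per-base error ε the
fraction removed by −V matches the closed form P(Binomial(L_nongap, ε) > V).
Both are acceptance-tested.

## Taxonomy assignment

Representatives are compared to every reference by optimal global
(Needleman–Wunsch) alignment under match +5, mismatch −4, linear gap −10.
The scoring scheme is a convention, not a tuned quantity: assignments are
pinned by percent identity, which is robust across reasonable DNA schemes.
Percent identity counts identical columns over the aligned span excluding
terminal-gap columns (so partial-length references are not penalised);
internal gaps count as mismatches; an alignment with no comparable columns
is an error. The best hit's lineage is adopted; when several references tie
at the best identity the lineage is truncated to the deepest rank on which
all tied references agree — a rule that depends only on the tie set, making
assignment invariant to reference order. Count matrices collapse to any rank
by summing node rows; nodes unresolved at the requested rank pool under
their deepest resolved name suffixed `_unclassified`, so per-sample totals
are conserved at every rank.

## Community matrices

Relative abundance divides each sample row by its total (an all-zero sample
is an error naming the sample). The major-taxon filter keeps taxa whose mean
relative abundance over **all** samples is strictly above the threshold
(default 1%). 97%-OTU binning is greedy abundance-ordered centroid
clustering on the aligned representatives: candidates are visited in
decreasing total abundance, each joins the first existing bin containing
*any* member at ≥ 97% identity (identity = identical columns over shared
non-terminal-gap columns), else founds a new bin. First-bin-wins makes the
ambiguous "similar to any member but not already included elsewhere"
admission deterministic; bin founders are pairwise < 97% identical, so
re-binning the founders reproduces the partition (idempotence, tested).
Cross-study harmonization restricts tables to their shared taxa **without
renormalizing** — values stay fractions of the whole community, which
Bray-Curtis tolerates — and reports the abundance mass excluded per table.

## Stability statistics and the fingerprint

All statistics are computed on unrounded values and rounded only in report
writers (means to 1 decimal, CVs to nearest integer, half away from zero).
Per (individual, taxon): mean, sample SD (n−1), CV = 100·sd/mean on the
percent scale. The n−1 convention is pinned by a forensic identity: an
n-sample series with exactly one nonzero value has CV = 100·√n, i.e. 283%
for n = 8, whatever the spike height. CV is undefined (flagged NaN,
excluded from aggregates) only when the mean is exactly 0; series whose
mean *displays* as 0 still get a CV because computation precedes rounding.

Per-taxon aggregates: `overall_mean`/`overall_cv` pool all samples from all
individuals (the pooled convention was chosen over averaging per-individual
variances; with equal per-individual sample counts the overall mean equals
the mean of per-individual means, which the report tables verify), and
`mean_cv` is the **unweighted** mean of per-individual CVs over defined
entries. Anomalies are deviations from the individual's own temporal mean
(they sum to zero per series) with ±1 and ±2 SD band edges.

The fingerprint machinery renormalizes one genus's oligotypes by the genus
total per sample (samples where the genus is absent are excluded with a
flag, not a division error), marks (individual, oligotype) pairs whose
within-individual mean is strictly above 10% of the genus as *abundant*,
and contrasts the unweighted mean CV over abundant pairs against the
unweighted mean pooled-CV over the abundant-in-anyone union. Individual
identification is leave-one-out nearest-centroid: the held-out sample is
assigned to the individual whose mean profile (over that individual's
remaining samples) is closest in Bray-Curtis distance, ties broken by label
order.

## Ordination

NMDS is nonmetric SMACOF: each iteration fits disparities to configuration
distances by Kruskal's **primary** monotone regression (ties in the input
dissimilarities are ordered by the current configuration distances before
pool-adjacent-violators), evaluates Kruskal stress-1
√(Σ(d−d̂)²/Σd²) on the 0–1 scale, and applies a Guttman-transform update.
Iteration stops when the stress decrease falls below `tol` (default 1e-7)
or at `max_iter` (default 500); the per-start stress history is recorded
and is non-increasing in practice (tested on seeded inputs). The returned
fit is the best of `n_starts` (default 8) initializations — the first a
classical-scaling (principal coordinates) configuration, the rest seeded
random — centred at the origin and deterministic given the seed.

Covariance ellipses are per-group (mean, n−1 covariance) with 1-SD
half-widths along the covariance eigenvectors (the SD multiplier is a
display parameter); a near-zero eigenvalue flags a degenerate (collinear)
group; groups need ≥ 3 points. Topology consistency re-runs NMDS
`n_trials` times (default 50), each trial keeping the best of 4 random
starts the way shell NMDS front-ends retry within one run, superimposes
every configuration onto the lowest-stress one by Procrustes (translation,
rotation, reflection, scaling), and counts trials with Procrustes
correlation √(1 − disparity) ≥ 0.99 as consistent. The 0.99 threshold is a
parameter; "consistency" has no standard definition, and this one makes the
check quantitative and seed-reproducible.

## Synthetic data generator

The generator emulates a longitudinal multi-subject amplicon design with a
known answer; its defaults are the emulated study's conditions where those
are known (8 individuals × 8 timepoints; 336-column alignment; per-sample
depth Normal(5618, 923.8) truncated at 1 and rounded; per-base substitution
error 0.001) and field-realistic choices elsewhere:

* **Library.** Each genus gets an independent random root sequence plus
  K−1 variants, each variant substituting one dedicated non-gap column —
  so all oligotypes are pairwise distinct, within-genus identity stays
  above 97%, and between-genus identity is far below it. Defaults: 10
  genera (named after plaque-typical genera, with their real phyla), 8
  oligotypes each; ~7/8 of a genus's oligotypes share a dominant species,
  the rest form a minor species, mirroring the dominant/minor species
  split inside real plaque genera. Gaps appear only as padding columns
  shared by every sequence (default 4) — exactly the gap-only columns
  preprocessing removes — never as variant sites, so identity computations
  are unambiguous.
* **Profiles.** A global genus composition is drawn once
  (Dirichlet, symmetric concentration 3); each individual's genus means are
  Dirichlet around it with precision `genus_concentration` (default 15,
  giving the strong between-individual spread of genus proportions seen in
  real panels); within each genus an individual's oligotype profile is a
  sparse symmetric Dirichlet(`profile_sparsity`, default 0.1), so a handful
  of oligotypes dominate per individual and the dominant subsets differ
  between individuals (Monte-Carlo-checked against the Dirichlet oracle).
  Profiles are fixed across timepoints — the "stable mean".
* **Time series.** Per sample, proportions are
  Dirichlet(`fluctuation_alpha` × individual profile) — the minimal model
  for fluctuation around a stable mean; `fluctuation_alpha` (default 50)
  sets temporal calm, and a taxon's temporal CV decreases monotonically in
  it (tested at three values). Reads are multinomial draws of the planted
  sequences with i.i.d. substitution errors on non-gap bases (no indels,
  because reads are modelled post-alignment).

What the generator does **not** emulate: chimeras, per-cycle quality decay,
PCR/primer bias, indel errors, phylogenetic correlation between genera,
within-individual depth trends (only the global depth mean/SD is modelled),
or true ecological dynamics (trends, successions, regime shifts). Passing
recovery tests therefore shows the machinery is correct under the stated
noise model, not that real communities satisfy that model.

## Problem sizes

The analysis scripts run the full emulated design (~355k reads, 96 planted
oligotypes; minutes on one core). The test suite exercises the same code
paths at reduced size — hundreds to tens of thousands of reads, 10-point
ordinations, 20-seed fingerprint recovery on ground-truth tables — chosen
so the whole suite runs in about a minute while every contract (recovery,
accounting, boundary semantics, determinism) is still checked exactly.

## Known limitations

* The decomposer splits on one column per iteration and never relocates
  removed reads; tools that split on several components or re-home outliers
  will bin borderline reads differently.
* Best-hit taxonomy has no k-mer prefilter and aligns against every
  reference; it is meant for curated references of moderate size, not for
  100k-sequence databases.
* NMDS is a local optimizer; the multi-start + Procrustes machinery
  quantifies, but cannot eliminate, local-minimum risk.
* The greedy 97% binning depends on the abundance order of its seeds, as
  all first-fit centroid methods do; idempotence holds, global optimality
  is not claimed.
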