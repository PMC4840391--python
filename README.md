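# oligoprint

Single-nucleotide-resolution analysis of aligned 16S rRNA amplicon time
series. The package decomposes a multiple-sequence-aligned read collection
into *oligotypes* — read bins separated by as little as one nucleotide at
high-information alignment positions — assigns each oligotype a taxonomic
lineage by best-hit global alignment, builds community matrices at phylum,
genus, species, 97%-OTU and oligotype resolution, and quantifies what makes
a dental-plaque-style microbiome *individual*: within a person, each taxon's
relative abundance fluctuates around a stable mean, while the **set** of
abundant oligotypes differs sharply from person to person ("fingerprints").

It is written for microbial ecologists who want the whole chain — noise
filtering, taxonomy, ordination and stability statistics — as one tested,
scriptable pipeline, together with a synthetic-data generator that emulates
a longitudinal multi-subject design so the entire analysis can be exercised
and validated without downloading anything.

## The method

**Minimum-entropy decomposition.** For a node (bin) of aligned reads, the
Shannon entropy of alignment column *j* over states {A, C, G, T, –, N} is

    H_j = − Σ_s p_{js} log2 p_{js}

Any node whose maximum column entropy exceeds a threshold *m* (default
0.0965 bits) is split into children by the residue at its highest-entropy
column; recursion stops when every node is internally homogeneous. Two noise
filters follow: the **minimum substantive abundance** criterion −M (default
60) discards nodes whose most frequent unique sequence has fewer than M
copies, and the **maximum variation allowed** criterion −V (default 3)
removes reads differing from their node's representative at more than V
columns. Read accounting is exact:
`n_input = n_retained + n_removed_M + n_removed_V`.

**Stability statistics.** For each individual's time series and each taxon:
mean M, sample standard deviation (n−1), and CV = 100·sd/M (percent). An
8-point series with a single nonzero value therefore has CV = 100·2√2 ≈ 283%
— the signature of a taxon present in one sample only. The *fingerprint
contrast* compares the mean CV of oligotypes within the mouths where they
are abundant (mean > 10% of their genus) against the same oligotypes' CV
pooled over all samples from all individuals.

**Ordination.** Bray-Curtis dissimilarity
`BC(x, y) = Σ|x_t − y_t| / Σ(x_t + y_t)` feeds a nonmetric MDS (SMACOF with
Kruskal's primary monotone regression; stress-1 on the 0–1 scale), with
per-individual covariance ellipses and a repeated-random-start Procrustes
check of layout stability. A leave-one-out nearest-centroid classifier under
Bray-Curtis operationalizes "individuals can be told apart at this level of
resolution".

## Worked example

The numbered scripts under `analysis/` run the full study on synthetic data
(8 individuals × 8 timepoints, ~355k aligned 336-nt reads, 96 planted
oligotypes across 10 plaque-typical genera; `analysis/study_config.py`):

```bash
cd analysis
python 01_simulate.py            # writes reads to scratch/, summary to results/
python 02_decompose.py
python 03_assign_and_tables.py
python 04_stability.py
python 05_ordination.py
```

Output from a run at seed 42:

```
355258 reads -> 90 oligotypes; retained 353719, removed 1242 (minimum
  substantive abundance) + 297 (maximum variation); 0 short reads dropped earlier.
Assigned 90 oligotypes; 90 at 100% identity.
97% OTU binning: 10 OTUs from 90 oligotypes.
10 genera exceed 1% mean abundance, jointly composing 100.0% of the community.
Rothia: 8 oligotypes; 15 (individual, oligotype) pairs exceed 10% of the genus.
Mean CV of abundant oligotypes within their own mouths: 43% vs 190% for the
  same oligotypes across all samples.
Leave-one-out individual identification: genus 96.9%, oligotype 100.0%
   phylum: stress 0.131, ellipse spread 0.439
    genus: stress 0.181, ellipse spread 0.365
    otu97: stress 0.181, ellipse spread 0.364
oligotype: stress 0.225, ellipse spread 0.170, topology consistent in 45/50 trials
```

Reading this: 90 of the 96 planted oligotypes carry enough reads to survive
the −M 60 filter, and every survivor matches its planted reference exactly.
At genus resolution individuals already differ in proportions (LOO accuracy
96.9%), but at oligotype resolution identification is perfect and the
covariance ellipses shrink from overlapping clouds to small, separated
patches (ellipse spread 0.44 → 0.17). The abundant-oligotype CV contrast —
stable (43%) inside the mouths where an oligotype is a major community
member, highly variable (190%) across mouths — is the fingerprint: different
people carry different subsets of near-identical organisms at stably
different proportions. The oligotype ordination has the highest stress (64
samples forced into 2-D at 90-taxon resolution), yet independent restarts
reproduce its topology in 45 of 50 trials.

The same pipeline runs end-to-end from a single YAML config (or on real
aligned FASTA + sample map + reference inputs) via the CLI:

```bash
oligoprint run-all --config config.yaml --seed 42
oligoprint simulate --seed 3 --outdir data/
oligoprint decompose --fasta data/reads.fasta --sample-map data/sample_map.tsv -M 60 -V 3
```

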