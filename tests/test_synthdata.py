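import numpy as np
import pytest
from scipy import stats

from oligoprint.synthdata import (
    ConfigurationError,
    SyntheticConfig,
    generate_dataset,
    generate_individual_profiles,
    generate_oligotype_library,
    generate_timeseries_reads,
    generate_truth_tables,
    write_dataset,
)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_individuals": 0},
            {"base_error_rate": 0.3},
            {"base_error_rate": -0.1},
            {"fluctuation_alpha": 0.0},
            {"profile_sparsity": 0.0},
            {"reads_per_sample_mean": 0.0},
            {"oligos_per_genus": 0},
            {"read_length": 10, "oligos_per_genus": 50, "n_gap_columns": 2},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            SyntheticConfig(**kwargs)


class TestLibrary:
    def test_single_oligotype_genus_is_root_only(self):
        cfg = SyntheticConfig(n_genera=1, oligos_per_genus=1, seed=0)
        truth = generate_oligotype_library(cfg)
        assert len(truth.oligo_sequences) == 1

    def test_24_oligotypes_all_distinct(self):
        """A 24-variant genus (the size of the most diverse plaque genus in
        the emulated study) yields 24 pairwise-distinct sequences differing
        at >= 1 column, each >= 97% identical to the root."""
        cfg = SyntheticConfig(n_genera=1, oligos_per_genus=24, seed=1)
        truth = generate_oligotype_library(cfg)
        seqs = list(truth.oligo_sequences.values())
        assert len(seqs) == 24
        assert len(set(seqs)) == 24
        root = seqs[0]
        for s in seqs[1:]:
            diffs = sum(1 for a, b in zip(root, s) if a != b)
            assert 1 <= diffs <= 2
        # within-genus identity stays above the OTU threshold
        assert all(
            sum(a == b for a, b in zip(root, s)) / len(s) >= 0.97 for s in seqs
        )

    def test_same_seed_identical_library(self):
        cfg = SyntheticConfig(seed=7)
        a = generate_oligotype_library(cfg)
        b = generate_oligotype_library(cfg)
        assert a.oligo_sequences == b.oligo_sequences
        assert a.oligo_taxonomy == b.oligo_taxonomy

    def test_lineages_have_phylum_genus_species(self):
        truth = generate_oligotype_library(SyntheticConfig(seed=0))
        for lineage in truth.oligo_taxonomy.values():
            assert lineage[0] == "Bacteria"
            assert lineage[1] and lineage[5] and lineage[6]


class TestProfiles:
    def _montecarlo_abundant_count(self, sparsity, K, n_draws=10_000, seed=123):
        rng = np.random.default_rng(seed)
        draws = rng.dirichlet(np.full(K, sparsity), size=n_draws)
        return (draws > 0.10).sum(axis=1).mean()

    def test_sparse_profiles_concentrate_on_few_oligotypes(self):
        """At sparsity 0.1 and K=20 the Dirichlet oracle says only a handful
        of oligotypes exceed 10% of their genus; the generator's profiles
        agree with the Monte-Carlo expectation."""
        K, sparsity = 20, 0.1
        oracle = self._montecarlo_abundant_count(sparsity, K)
        assert oracle < K / 2
        cfg = SyntheticConfig(
            n_individuals=40, n_genera=1, oligos_per_genus=K,
            profile_sparsity=sparsity, seed=3,
        )
        truth = generate_individual_profiles(cfg, generate_oligotype_library(cfg))
        profiles = truth.individual_mean_profiles.to_numpy()
        within = profiles / profiles.sum(axis=1, keepdims=True)
        observed = (within > 0.10).sum(axis=1).mean()
        # binomial-ish tolerance around the oracle expectation
        assert abs(observed - oracle) < 0.5

    def test_high_concentration_limit_approaches_uniform(self):
        cfg = SyntheticConfig(
            n_individuals=6, n_genera=1, oligos_per_genus=10,
            profile_sparsity=5000.0, seed=4,
        )
        truth = generate_individual_profiles(cfg, generate_oligotype_library(cfg))
        within = truth.individual_mean_profiles.to_numpy()
        within = within / within.sum(axis=1, keepdims=True)
        assert np.abs(within - 0.1).max() < 0.03

    def test_individuals_get_different_dominant_subsets(self):
        cfg = SyntheticConfig(
            n_individuals=8, n_genera=1, oligos_per_genus=20,
            profile_sparsity=0.1, seed=5,
        )
        truth = generate_individual_profiles(cfg, generate_oligotype_library(cfg))
        within = truth.individual_mean_profiles.to_numpy()
        within = within / within.sum(axis=1, keepdims=True)
        dominant = [frozenset(np.flatnonzero(row > 0.10)) for row in within]
        assert len(set(dominant)) > 1

    def test_profiles_sum_to_one(self):
        cfg = SyntheticConfig(n_individuals=4, seed=6)
        truth = generate_individual_profiles(cfg, generate_oligotype_library(cfg))
        assert np.allclose(truth.individual_mean_profiles.sum(axis=1), 1.0)


class TestReads:
    def test_alphabet_and_length(self, small_dataset):
        reads, _ = small_dataset
        width = reads.width
        for s in reads.seqs[:200]:
            assert len(s) == width
            assert set(s) <= set("ACGT-")

    def test_end_to_end_determinism(self, small_config):
        a_reads, a_truth = generate_dataset(small_config)
        b_reads, b_truth = generate_dataset(small_config)
        assert a_reads.ids == b_reads.ids
        assert a_reads.seqs == b_reads.seqs
        assert a_truth.sample_proportions.equals(b_truth.sample_proportions)

    def test_error_free_single_oligotype_reads_identical(self):
        cfg = SyntheticConfig(
            n_individuals=1, n_timepoints=1, n_genera=1, oligos_per_genus=1,
            reads_per_sample_mean=50, reads_per_sample_sd=1,
            base_error_rate=0.0, seed=8,
        )
        reads, truth = generate_dataset(cfg)
        planted = next(iter(truth.oligo_sequences.values()))
        assert set(reads.seqs) == {planted}

    def test_default_depth_matches_declared_normal(self):
        """Realized per-sample depths over the 64-sample default design sit
        within 3 standard errors of the declared 5618-read mean."""
        truth = _default_truth()
        depths = truth.sample_sizes.to_numpy()
        assert len(depths) == 64
        se = 923.8 / np.sqrt(64)
        assert abs(depths.mean() - 5618) < 3 * se

    def test_infinite_precision_limit_recovers_mean_profile(self):
        cfg = SyntheticConfig(
            n_individuals=2, n_timepoints=3, n_genera=2, oligos_per_genus=3,
            fluctuation_alpha=1e9, base_error_rate=0.0,
            reads_per_sample_mean=200, reads_per_sample_sd=10, seed=9,
        )
        truth = generate_individual_profiles(cfg, generate_oligotype_library(cfg))
        _, truth = generate_timeseries_reads(cfg, truth)
        for sid in truth.sample_proportions.index:
            ind = truth.sample_meta.loc[sid, "individual"]
            expected = truth.individual_mean_profiles.loc[ind].to_numpy()
            assert np.allclose(
                truth.sample_proportions.loc[sid].to_numpy(), expected, atol=1e-3
            )

    def test_empirical_proportions_match_drawn_proportions(self):
        """Chi-square goodness of fit of read counts against the drawn
        per-sample proportions is not rejected for most seeds."""
        rejected = 0
        for seed in range(8):
            cfg = SyntheticConfig(
                n_individuals=1, n_timepoints=1, n_genera=2, oligos_per_genus=3,
                reads_per_sample_mean=5000, reads_per_sample_sd=1,
                profile_sparsity=2.0, base_error_rate=0.0, seed=seed,
            )
            _, truth = generate_dataset(cfg)
            sid = truth.sample_counts.index[0]
            counts = truth.sample_counts.loc[sid].to_numpy()
            p = truth.sample_proportions.loc[sid].to_numpy()
            n = counts.sum()
            keep = p * n >= 5
            if keep.sum() < 2:
                continue
            obs = np.append(counts[keep], counts[~keep].sum())
            exp = np.append(p[keep] * n, p[~keep].sum() * n)
            obs, exp = obs[exp > 0], exp[exp > 0]
            exp = exp * obs.sum() / exp.sum()
            if stats.chisquare(obs, exp).pvalue < 0.01:
                rejected += 1
        assert rejected <= 1

    def test_temporal_cv_decreases_with_fluctuation_alpha(self):
        cvs = []
        for alpha in (5.0, 50.0, 500.0):
            cfg = SyntheticConfig(
                n_individuals=4, n_timepoints=8, n_genera=3, oligos_per_genus=2,
                fluctuation_alpha=alpha, reads_per_sample_mean=2.0,
                reads_per_sample_sd=0.1, seed=10,
            )
            truth = generate_truth_tables(cfg)
            table = truth.abundance_table("genus")
            by_ind = table.data.groupby(table.individuals())
            cv = (by_ind.std(ddof=1) / by_ind.mean()).mean().mean()
            cvs.append(cv)
        assert cvs[0] > cvs[1] > cvs[2]


def _default_truth():
    # depths only: use the lightweight truth-table path at default depth
    cfg = SyntheticConfig(seed=12)
    truth = generate_oligotype_library(cfg)
    truth = generate_individual_profiles(cfg, truth)
    # draw depths exactly as the read stage does, without synthesizing reads
    from dataclasses import replace

    cfg_small = replace(cfg, oligos_per_genus=1, n_genera=1)
    truth_small = generate_oligotype_library(cfg_small)
    truth_small = generate_individual_profiles(cfg_small, truth_small)
    _, truth_small = generate_timeseries_reads(cfg_small, truth_small)
    return truth_small


class TestWriters:
    def test_dataset_roundtrip_files(self, tmp_path, small_dataset):
        from oligoprint.seqio import read_aligned_fasta, read_reference

        reads, truth = small_dataset
        paths = write_dataset(reads, truth, tmp_path)
        back = read_aligned_fasta(paths["reads"], paths["sample_map"])
        assert back.ids == reads.ids
        assert back.seqs == reads.seqs
        ref = read_reference(paths["reference"])
        assert len(ref) == len(truth.oligo_ids)
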