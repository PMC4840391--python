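import math
import random

import numpy as np
import pytest
from scipy import stats

from oligoprint.decompose import (
    DecompositionResult,
    column_entropy,
    decompose,
    representative,
)
from oligoprint.seqio import AlignedReadSet
from oligoprint.synthdata import SyntheticConfig, generate_dataset

from conftest import make_readset


def _mutate(seq, positions, base="T"):
    out = list(seq)
    for p in positions:
        out[p] = base if out[p] != base else "G"
    return "".join(out)


X = "ACGTACGTACGTACGTACGT"


class TestColumnEntropy:
    def test_single_state_column_is_zero(self):
        assert column_entropy(["AAAA"], 0) == 0.0
        assert column_entropy(["A", "A", "A", "A"], 0) == 0.0

    def test_even_two_state_split_is_one_bit(self):
        members = ["A"] * 50 + ["C"] * 50
        assert column_entropy(members, 0) == pytest.approx(1.0)

    def test_three_state_split_closed_form(self):
        members = ["A"] * 60 + ["C"] * 20 + ["G"] * 20
        expected = -(0.6 * math.log2(0.6) + 2 * 0.2 * math.log2(0.2))
        assert column_entropy(members, 0) == pytest.approx(expected)
        assert round(column_entropy(members, 0), 3) == 1.371

    def test_gap_and_n_are_states(self):
        members = ["A-", "AN", "A-", "AN"]
        assert column_entropy(members, 1) == pytest.approx(1.0)
        assert column_entropy(members, 0) == 0.0

    def test_out_of_range_column(self):
        with pytest.raises(IndexError):
            column_entropy(["ACGT"], 4)


class TestDecompose:
    def test_identical_reads_single_node(self):
        reads = make_readset({X: 200})
        res = decompose(reads, M=60, V=3)
        assert len(res.nodes) == 1
        assert res.nodes[0].size == 200
        assert res.n_removed_min_abundance == 0
        assert res.n_removed_max_variation == 0

    def test_two_variant_mixture_splits(self):
        y = _mutate(X, [7])
        reads = make_readset({X: 100, y: 80})
        res = decompose(reads, M=60, V=3)
        assert sorted(n.size for n in res.nodes) == [80, 100]
        assert {n.representative for n in res.nodes} == {X, y}
        assert res.n_retained == 180

    def test_minority_variant_below_M_removed(self):
        y = _mutate(X, [7])
        reads = make_readset({X: 100, y: 30})
        res = decompose(reads, M=60, V=3)
        assert len(res.nodes) == 1
        assert res.nodes[0].representative == X
        assert res.nodes[0].size == 100
        assert res.n_removed_min_abundance == 30

    def test_min_abundance_boundary_at_exactly_M(self):
        y = _mutate(X, [7])
        res = decompose(make_readset({X: 100, y: 60}), M=60, V=3)
        assert sorted(n.size for n in res.nodes) == [60, 100]
        res59 = decompose(make_readset({X: 100, y: 59}), M=60, V=3)
        assert [n.size for n in res59.nodes] == [100]
        assert res59.n_removed_min_abundance == 59

    def test_survivors_are_exactly_those_reaching_M(self):
        # five variants with known top-sequence copy numbers
        counts = {_mutate(X, [i]): c for i, c in zip(range(5), [120, 90, 60, 59, 10])}
        res = decompose(make_readset(counts), M=60, V=3)
        assert sorted(n.size for n in res.nodes) == [60, 90, 120]
        assert res.n_removed_min_abundance == 69

    def test_empty_input(self):
        reads = AlignedReadSet([], [], {}, {}, {})
        res = decompose(reads)
        assert res.n_input == 0 and res.nodes == []

    def test_max_variation_boundary(self):
        near = _mutate(X, [3, 8, 11])  # 3 differences: retained
        far = _mutate(X, [3, 8, 11, 15])  # 4 differences: removed
        reads = make_readset({X: 100, near: 2, far: 2})
        # single node: variants too rare to lift entropy over the threshold
        res = decompose(reads, M=60, V=3, m=0.3)
        assert len(res.nodes) == 1
        assert res.nodes[0].size == 102
        assert res.n_removed_max_variation == 2

    def test_gap_counts_as_difference_for_variation(self):
        gapped = X[:4] * 4 + "----"
        res = decompose(make_readset({X: 100, gapped: 2}), M=60, V=3, m=0.5)
        assert res.n_removed_max_variation == 2

    def test_read_accounting_identity_fuzz(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            n_seq = rng.integers(2, 6)
            base = "".join(rng.choice(list("ACGT"), size=30))
            counts = {
                _mutate(base, list(rng.choice(30, size=rng.integers(1, 4), replace=False))):
                int(rng.integers(1, 150))
                for _ in range(n_seq)
            }
            res = decompose(make_readset(counts), M=40, V=2)
            assert (
                res.n_input
                == res.n_retained
                + res.n_removed_min_abundance
                + res.n_removed_max_variation
            )
            assert sum(n.size for n in res.nodes) == res.n_retained

    def test_order_invariance(self):
        y, z = _mutate(X, [2]), _mutate(X, [9])
        reads = make_readset({X: 80, y: 70, z: 65})
        shuffled_ids = list(reads.ids)
        random.Random(3).shuffle(shuffled_ids)
        seq_of = dict(zip(reads.ids, reads.seqs))
        shuffled = AlignedReadSet(
            ids=shuffled_ids,
            seqs=[seq_of[r] for r in shuffled_ids],
            sample_of=reads.sample_of,
            individual_of=reads.individual_of,
            timepoint_of=reads.timepoint_of,
        )
        a, b = decompose(reads, M=60, V=3), decompose(shuffled, M=60, V=3)
        assert [n.representative for n in a.nodes] == [n.representative for n in b.nodes]
        assert [n.per_sample_counts for n in a.nodes] == [
            n.per_sample_counts for n in b.nodes
        ]

    def test_converged_nodes_below_entropy_threshold(self):
        y = _mutate(X, [5])
        res = decompose(make_readset({X: 100, y: 90}), M=60, V=3, m=0.0965)
        assert all(n.max_entropy <= 0.0965 for n in res.nodes)

    def test_broken_accounting_rejected(self):
        with pytest.raises(ValueError, match="accounting"):
            DecompositionResult([], n_input=10, n_retained=5,
                                n_removed_min_abundance=2, n_removed_max_variation=2)


class TestRepresentative:
    def test_identical_reads(self):
        assert representative(["ACGT", "ACGT"]) == "ACGT"

    def test_majority(self):
        assert representative(["ACGT"] * 10 + ["ACGA"] * 3) == "ACGT"

    def test_tie_breaks_lexicographically(self):
        assert representative(["TTTT"] * 5 + ["AAAA"] * 5) == "AAAA"

    def test_empty_node_errors(self):
        with pytest.raises(ValueError):
            representative([])


class TestGroundTruthRecovery:
    def test_error_free_recovery_of_planted_oligotypes(self):
        """With no sequencing error and every planted oligotype backed by at
        least M reads, decomposition returns exactly the planted sequences and
        the multinomial per-sample counts."""
        config = SyntheticConfig(
            n_individuals=2,
            n_timepoints=4,
            n_genera=2,
            oligos_per_genus=3,
            reads_per_sample_mean=2000,
            reads_per_sample_sd=100,
            profile_sparsity=5.0,  # near-even oligotype mix: everyone abundant
            base_error_rate=0.0,
            seed=21,
        )
        reads, truth = generate_dataset(config)
        totals = truth.sample_counts.sum(axis=0)
        assert totals.min() >= 60, "fixture must plant every oligotype above M"
        res = decompose(reads, M=60, V=3)
        assert res.n_removed_min_abundance == 0
        assert res.n_removed_max_variation == 0
        planted = {s.replace("-", "") for s in truth.oligo_sequences.values()}
        recovered = {n.representative.replace("-", "") for n in res.nodes}
        assert recovered == planted
        # per-sample counts match the generator's multinomial draws
        seq_to_oligo = {
            seq: oid for oid, seq in truth.oligo_sequences.items()
        }
        for node in res.nodes:
            gapped = [s for s in truth.oligo_sequences.values()
                      if s == node.representative]
            oid = seq_to_oligo[gapped[0]]
            for sid, count in node.per_sample_counts.items():
                assert count == truth.sample_counts.loc[sid, oid]

    def test_outlier_removal_matches_binomial_rate(self):
        """With per-base error rate eps, the fraction of reads removed by the
        V=3 criterion matches P(Binomial(L_nongap, eps) > 3)."""
        eps = 0.005
        config = SyntheticConfig(
            n_individuals=1,
            n_timepoints=1,
            n_genera=1,
            oligos_per_genus=1,
            reads_per_sample_mean=20000,
            reads_per_sample_sd=1.0,
            base_error_rate=eps,
            seed=5,
        )
        reads, truth = generate_dataset(config)
        res = decompose(reads, M=60, V=3)
        assert len(res.nodes) == 1
        n = res.n_input
        L_nongap = config.read_length - config.n_gap_columns
        expected = stats.binom.sf(3, L_nongap, eps)
        observed = res.n_removed_max_variation / n
        se = math.sqrt(expected * (1 - expected) / n)
        assert abs(observed - expected) < 4 * se
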