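"""Mutual-information footprints, enrichment maps and position ranking."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import sortseq_footprint as sf
from sortseq_footprint.footprint import BIN_ORDER, FootprintOptions
from tests.conftest import make_count_matrix


def entropy_mi_bits(joint: np.ndarray) -> float:
    """Independent oracle: I = H(b) + H(mu) - H(b, mu) via scipy entropies."""
    return float(
        stats.entropy(joint.sum(axis=1), base=2)
        + stats.entropy(joint.sum(axis=0), base=2)
        - stats.entropy(joint.ravel(), base=2)
    )


def single_position_matrices(low: tuple, high: tuple):
    return (
        make_count_matrix({1: low}),
        make_count_matrix({1: high}),
    )


class TestJointFrequencies:
    def test_identical_distributions_factorize(self):
        cl, ch = single_position_matrices((30, 10, 0, 0), (30, 10, 0, 0))
        table = sf.joint_frequencies(cl, ch, 1)
        outer = np.outer(table.f_base, table.f_bin)
        assert np.allclose(table.f_joint.to_numpy(), outer)

    def test_pure_base_splits_evenly_between_bins(self):
        cl, ch = single_position_matrices((40, 0, 0, 0), (40, 0, 0, 0))
        table = sf.joint_frequencies(cl, ch, 1)
        assert table.f_joint.loc["A", "low"] == pytest.approx(0.5)
        assert table.f_joint.loc["A", "high"] == pytest.approx(0.5)

    def test_hand_normalized_example(self):
        cl, ch = single_position_matrices((30, 10, 0, 0), (10, 30, 0, 0))
        table = sf.joint_frequencies(cl, ch, 1)
        assert table.f_joint.loc["A", "low"] == pytest.approx(0.375)
        assert table.f_joint.loc["C", "low"] == pytest.approx(0.125)
        assert table.f_joint.loc["A", "high"] == pytest.approx(0.125)
        assert table.f_joint.loc["C", "high"] == pytest.approx(0.375)

    def test_read_proportional_weighting_uses_library_totals(self):
        cl = make_count_matrix({1: (30, 0, 0, 0)})
        ch = make_count_matrix({1: (10, 0, 0, 0)})
        table = sf.joint_frequencies(cl, ch, 1, bin_weighting="read_proportional")
        assert table.f_bin["low"] == pytest.approx(0.75)

    def test_zero_total_rejected(self):
        cl = make_count_matrix({1: (0, 0, 0, 0)})
        ch = make_count_matrix({1: (10, 0, 0, 0)})
        with pytest.raises(ValueError):
            sf.joint_frequencies(cl, ch, 1)

    def test_missing_position_rejected(self):
        cl, ch = single_position_matrices((5, 0, 0, 0), (5, 0, 0, 0))
        with pytest.raises(ValueError):
            sf.joint_frequencies(cl, ch, 99)


class TestMutualInformation:
    def test_independent_table_has_zero_information(self):
        cl, ch = single_position_matrices((30, 10, 5, 5), (30, 10, 5, 5))
        table = sf.joint_frequencies(cl, ch, 1)
        assert sf.mutual_information(table) == pytest.approx(0.0, abs=1e-14)

    def test_bin_determined_base_reaches_one_bit(self):
        cl, ch = single_position_matrices((40, 0, 0, 0), (0, 40, 0, 0))
        table = sf.joint_frequencies(cl, ch, 1)
        assert sf.mutual_information(table) == pytest.approx(1.0)

    def test_worked_thirty_ten_table(self):
        cl, ch = single_position_matrices((30, 10, 0, 0), (10, 30, 0, 0))
        table = sf.joint_frequencies(cl, ch, 1)
        expected = 0.75 * math.log2(1.5) - 0.25
        assert sf.mutual_information(table) == pytest.approx(expected, abs=1e-12)
        assert sf.mutual_information(table) == pytest.approx(0.18872, abs=1e-5)

    def test_agrees_with_entropy_decomposition_on_random_tables(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            counts = rng.integers(0, 50, size=(2, 4))
            counts[:, 0] += 1  # keep both totals positive
            cl = make_count_matrix({1: tuple(counts[0])})
            ch = make_count_matrix({1: tuple(counts[1])})
            table = sf.joint_frequencies(cl, ch, 1)
            ours = sf.mutual_information(table)
            oracle = entropy_mi_bits(table.f_joint.to_numpy())
            assert abs(ours - oracle) < 1e-12


class TestInformationFootprint:
    def test_single_position_footprint_matches_pointwise_mi(self):
        cl, ch = single_position_matrices((30, 10, 0, 0), (10, 30, 0, 0))
        fp = sf.information_footprint(cl, ch)
        table = sf.joint_frequencies(cl, ch, 1)
        assert fp.mi_bits[1] == pytest.approx(sf.mutual_information(table))

    def test_label_mismatch_rejected(self):
        cl = make_count_matrix({1: (5, 0, 0, 0), 2: (5, 0, 0, 0)})
        ch = make_count_matrix({1: (5, 0, 0, 0), 3: (5, 0, 0, 0)})
        with pytest.raises(ValueError):
            sf.information_footprint(cl, ch)

    def test_no_variation_positions_flagged_with_zero_mi(self):
        cl = make_count_matrix({1: (5, 0, 0, 0), 2: (2, 3, 0, 0)})
        ch = make_count_matrix({1: (7, 0, 0, 0), 2: (3, 4, 0, 0)})
        fp = sf.information_footprint(cl, ch)
        assert fp.no_variation[1] and not fp.no_variation[2]
        assert fp.mi_bits[1] == pytest.approx(0.0, abs=1e-14)

    def test_no_selection_bins_stay_near_the_permutation_null(self, reference):
        """Two bins sampled from one library without sorting should carry
        essentially no information at any position."""
        lib = sf.mutagenize_library(reference, sf.EpPCRModel(), 3000, seed=3)
        reads_a = sf.emit_reads(lib, 0.0, seed=4, n_reads=3000)
        reads_b = sf.emit_reads(lib, 0.0, seed=5, n_reads=3000)
        proc = {
            lbl: sf.preprocess_reads(reads, reference, lbl)
            for lbl, reads in [("low", reads_a), ("high", reads_b)]
        }
        fp = sf.information_footprint(proc["low"]["counts"], proc["high"]["counts"])
        null, positions = sf.permutation_null(
            proc["low"]["readset"], proc["high"]["readset"], reference,
            n_permutations=50, seed=6,
        )
        p99 = np.quantile(null, 0.99, axis=0)
        below = (fp.mi_bits.to_numpy() <= p99).mean()
        assert below >= 0.9


class TestEnrichmentMap:
    def test_identical_frequencies_give_zero_everywhere(self):
        cm = make_count_matrix({1: (30, 10, 5, 5), 2: (10, 10, 10, 20)})
        emap = sf.enrichment_map(cm, cm, pseudocount=1.0)
        assert np.allclose(emap.log2_ratio.to_numpy(), 0.0)

    def test_doubled_frequency_approaches_plus_one_bit(self):
        cb = make_count_matrix({1: (200, 200, 0, 0)})
        cu = make_count_matrix({1: (100, 300, 0, 0)})
        emap = sf.enrichment_map(cb, cu, pseudocount=1e-9)
        assert emap.log2_ratio.loc[1, "A"] == pytest.approx(1.0, abs=1e-6)

    def test_absent_base_with_unit_pseudocount(self):
        cb = make_count_matrix({1: (0, 100, 0, 0)})
        cu = make_count_matrix({1: (10, 90, 0, 0)})
        emap = sf.enrichment_map(cb, cu, pseudocount=1.0)
        expected = math.log2((1 / 104) / (11 / 104))
        assert emap.log2_ratio.loc[1, "A"] == pytest.approx(expected, abs=1e-9)
        assert expected == pytest.approx(-3.459, abs=1e-3)
        assert emap.absent_in_bin.loc[1, "A"]

    def test_swapping_bin_and_unsorted_negates_every_entry(self):
        rng = np.random.default_rng(8)
        rows_b = {p: tuple(v) for p, v in enumerate(rng.integers(0, 30, (5, 4)))}
        # equalize row sums by padding column A
        target = max(sum(v) for v in rows_b.values())
        rows_b = {
            p: (v[0] + target - sum(v), v[1], v[2], v[3]) for p, v in rows_b.items()
        }
        rows_u = {p: (target - 15, 5, 5, 5) for p in rows_b}
        cb, cu = make_count_matrix(rows_b), make_count_matrix(rows_u)
        fwd = sf.enrichment_map(cb, cu, pseudocount=1.0)
        rev = sf.enrichment_map(cu, cb, pseudocount=1.0)
        assert np.allclose(
            fwd.log2_ratio.to_numpy(), -rev.log2_ratio.to_numpy()
        )

    def test_zero_pseudocount_with_zero_counts_rejected(self):
        cb = make_count_matrix({1: (0, 10, 0, 0)})
        cu = make_count_matrix({1: (5, 5, 0, 0)})
        with pytest.raises(ValueError):
            sf.enrichment_map(cb, cu, pseudocount=0.0)


class TestRankingAndRecovery:
    @staticmethod
    def _footprint(values: dict[int, float]) -> sf.FootprintResult:
        return sf.FootprintResult(
            mi_bits=pd.Series(values), options=FootprintOptions()
        )

    def test_full_ordering_descending_and_stable(self):
        fp = self._footprint({1: 0.1, 2: 0.5, 3: 0.3})
        assert sf.rank_positions(fp) == [2, 3, 1]

    def test_ties_broken_by_ascending_position(self):
        fp = self._footprint({7: 0.2, 3: 0.2, 5: 0.9})
        assert sf.rank_positions(fp, 3) == [5, 3, 7]

    def test_k_above_position_count_rejected(self):
        with pytest.raises(ValueError):
            sf.rank_positions(self._footprint({1: 0.1}), 2)

    def test_recovery_score_extremes(self):
        fp = self._footprint({1: 0.9, 2: 0.8, 3: 0.1, 4: 0.0})
        assert sf.recovery_score(fp, {1, 2}, 2) == 1.0
        assert sf.recovery_score(fp, {3, 4}, 2) == 0.0
        assert sf.recovery_score(fp, {1, 3}, 2) == 0.5

    def test_empty_planted_set_rejected(self):
        with pytest.raises(ValueError):
            sf.recovery_score(self._footprint({1: 0.1}), set(), 1)


class TestSignalMonotonicity:
    def test_stronger_planted_effect_does_not_lower_mi(self, reference):
        """Holding all seeds fixed, doubling a planted additive effect must
        not decrease the mutual information at that position."""
        pos, ref_base = 150, reference.base_at(150)
        results = []
        for effect in (-0.5, -2.0):
            model = sf.ExpressionModel(
                reference=reference,
                additive_effects={
                    (pos, b): effect for b in "ACGT" if b != ref_base
                },
                noise_sd=0.3,
            )
            lib = sf.mutagenize_library(reference, sf.EpPCRModel(), 3000, seed=10)
            pools = sf.sort_cells(lib, model, sf.SortGates(), 30_000, seed=11)
            proc = {
                lbl: sf.preprocess_reads(
                    sf.emit_reads(pool, 0.0, seed=12, n_reads=10_000),
                    reference,
                    lbl,
                )
                for lbl, pool in [("low", pools.low), ("high", pools.high)]
            }
            fp = sf.information_footprint(proc["low"]["counts"], proc["high"]["counts"])
            results.append(fp.mi_bits[pos])
        assert results[1] >= results[0]
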