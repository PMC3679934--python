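"""Phred arithmetic, homopolymer scanning, context association and
quality analytics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from amperr.model import VariantEvent
from amperr.quality import (
    annotate_error_context,
    association_test,
    average_quality,
    background_distribution,
    calibration_curve,
    context_class_counts,
    error_neighborhood_quality,
    error_to_phred,
    per_position_quality,
    phred_to_error,
    quality_homopolymer_correlation,
    scan_homopolymers,
)
from _oracles import per_base_run_lengths


def _event(ref_pos=0, kind="sub", length=1, read_pos=5, quals=(20,), read_id="r1",
           ref_bases=None, read_bases=None, strand="+"):
    if ref_bases is None:
        ref_bases = "A" * length if kind != "ins" else ""
    if read_bases is None:
        read_bases = "C" * length if kind != "del" else ""
    return VariantEvent(
        amplicon_id="amp", ref_pos=ref_pos, kind=kind, length=length,
        ref_bases=ref_bases, read_bases=read_bases, read_id=read_id,
        run_id="run1", strand=strand, read_pos=read_pos, quals=tuple(quals),
    )


class TestPhred:
    @pytest.mark.parametrize(
        "q, accuracy_pct",
        [(16.08, 97.53), (17.00, 98.00), (0.0, 0.0), (10.0, 90.0)],
    )
    def test_accuracy_from_quality(self, q, accuracy_pct):
        assert round(100.0 * (1.0 - phred_to_error(q)), 2) == accuracy_pct

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            error_to_phred(0.0)
        with pytest.raises(ValueError):
            phred_to_error(-1.0)

    @given(st.floats(min_value=0.0, max_value=60.0))
    def test_round_trip(self, q):
        assert error_to_phred(phred_to_error(q)) == pytest.approx(q, abs=1e-9)


class TestAverageQuality:
    @pytest.mark.parametrize(
        "quals, expected",
        [([20, 20], 20.0), ([10, 30], 12.97), ([17.0], 17.0)],
    )
    def test_error_rate_space_mean(self, quals, expected):
        assert round(average_quality(quals), 2) == expected

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            average_quality([])

    @given(st.lists(st.floats(min_value=0, max_value=45), min_size=1, max_size=20))
    def test_bounded_and_permutation_invariant(self, quals):
        avg = average_quality(quals)
        assert min(quals) - 1e-9 <= avg <= max(quals) + 1e-9
        assert average_quality(list(reversed(quals))) == pytest.approx(avg)


class TestHomopolymers:
    def test_scan_by_inspection(self):
        runs = scan_homopolymers("AAACCT")
        assert [(r.base, r.start, r.length) for r in runs] == [
            ("A", 0, 3), ("C", 3, 2), ("T", 5, 1)
        ]

    def test_scan_empty(self):
        assert scan_homopolymers("") == []

    def test_scan_rejects_non_acgt(self):
        with pytest.raises(ValueError):
            scan_homopolymers("ACGN")

    def test_runs_tile_sequence_and_match_per_base_oracle(self):
        rng = np.random.default_rng(42)
        seq = "".join(rng.choice(list("ACGT"), size=10_000, p=[0.4, 0.1, 0.4, 0.1]))
        runs = scan_homopolymers(seq)
        assert sum(r.length for r in runs) == len(seq)
        labels = np.zeros(len(seq), dtype=np.int64)
        for r in runs:
            labels[r.start:r.start + r.length] = r.length
        np.testing.assert_array_equal(labels, per_base_run_lengths(seq))

    def test_background_distribution_sums_to_one(self):
        rng = np.random.default_rng(1)
        seq = "".join(rng.choice(list("ACGT"), size=5000, p=[0.4, 0.1, 0.4, 0.1]))
        bg = background_distribution([seq])
        assert bg.sum() == pytest.approx(1.0)
        lengths = per_base_run_lengths(seq)
        assert bg["3"] == pytest.approx((lengths == 3).sum() / len(seq))
        assert bg[">5"] == pytest.approx((lengths > 5).sum() / len(seq))


class TestErrorContext:
    # reference: AACCCC G TTT A  -> runs (A,2)(C,4)(G,1)(T,3)(A,1)
    RUNS = scan_homopolymers("AACCCCGTTTA")

    def test_error_inside_long_run(self):
        assert annotate_error_context(_event(ref_pos=3), self.RUNS) == 4

    def test_error_adjacent_to_run_with_window(self):
        # G at position 6 is one base left of the TTT run
        assert annotate_error_context(_event(ref_pos=6), self.RUNS, adjacency_window=1) == 4
        assert annotate_error_context(_event(ref_pos=6), self.RUNS, adjacency_window=0) == 1

    def test_error_outside_any_run(self):
        assert annotate_error_context(_event(ref_pos=10), self.RUNS, adjacency_window=0) == 1


class TestAssociationTest:
    def test_observed_proportional_to_background(self):
        bg = pd.Series({"1": 0.5, "2": 0.3, "3": 0.2})
        obs = pd.Series({"1": 500, "2": 300, "3": 200})
        stat, p, dof = association_test(obs, bg)
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_hand_computed_chi_square(self):
        stat, p, dof = association_test(
            pd.Series({"a": 30, "b": 70}), pd.Series({"a": 0.5, "b": 0.5})
        )
        assert stat == pytest.approx(16.0)
        assert dof == 1

    def test_low_expectation_classes_pooled(self):
        bg = pd.Series({"1": 0.98, "2": 0.01, "3": 0.01})
        obs = pd.Series({"1": 97, "2": 2, "3": 1})
        stat, p, dof = association_test(obs, bg)
        assert dof == 1  # classes 2 and 3 pooled into one

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            association_test(
                pd.Series({"1": 0, "2": 0}), pd.Series({"1": 0.5, "2": 0.5})
            )


class TestNeighborhoodQuality:
    def test_constant_quality_read(self):
        quals = {"r1": np.full(50, 25)}
        res = error_neighborhood_quality([_event(read_pos=20, quals=(25,))], quals)
        assert res.mean_error_q == pytest.approx(25.0)
        assert res.mean_neighborhood_q == pytest.approx(25.0)
        assert not res.per_event["truncated"].iloc[0]

    def test_quality_valley_detected(self):
        q = np.full(30, 30)
        q[9] = 10  # valley at the error base (read_pos 10)
        res = error_neighborhood_quality([_event(read_pos=10, quals=(10,))], {"r1": q})
        assert res.mean_error_q == pytest.approx(10.0)
        assert res.mean_neighborhood_q == pytest.approx(30.0)

    def test_read_start_neighborhood_truncated_downstream(self):
        quals = {"r1": np.array([20, 21, 22, 23])}
        res = error_neighborhood_quality([_event(read_pos=1, quals=(20,))], quals)
        row = res.per_event.iloc[0]
        assert row["truncated"]
        assert row["neighborhood_q"] == pytest.approx(average_quality([21, 22, 23]))

    def test_ties_broken_upstream(self):
        quals = np.array([10, 10, 30, 10, 99, 99], dtype=float)
        # event at read_pos 3 (index 2): 5 nearest of 5 available; the
        # upstream base at distance 2 beats the downstream one at distance 2
        res = error_neighborhood_quality(
            [_event(read_pos=3, quals=(30,))], {"r1": quals}, n_neighbors=3
        )
        assert res.per_event.iloc[0]["neighborhood_q"] == pytest.approx(
            average_quality([10, 10, 10])
        )


class TestCalibration:
    def test_no_errors_flagged_na(self):
        table = calibration_curve([(np.full(100, 30), np.zeros(100, dtype=bool))])
        assert table["no_errors_observed"].all()
        assert table["empirical_q"].isna().all()

    def test_known_error_fraction(self):
        quals = np.full(1000, 20)
        errs = np.zeros(1000, dtype=bool)
        errs[:10] = True  # 1% observed errors -> empirical Q 20, deviation 0
        table = calibration_curve([(quals, errs)]).set_index("estimated_q")
        assert table.loc[20, "empirical_q"] == pytest.approx(20.0)
        assert table.loc[20, "deviation"] == pytest.approx(0.0)


class TestPerPositionQuality:
    def test_error_rate_space_positional_mean(self):
        reads = [np.array([10, 30]), np.array([10, 30, 40])]
        df = per_position_quality(reads)
        assert df.loc[0, "mean_q"] == pytest.approx(10.0)
        assert df.loc[1, "mean_q"] == pytest.approx(30.0)
        assert df.loc[2, "coverage"] == 1


class TestCorrelation:
    @pytest.mark.parametrize(
        "pairs, r_expected",
        [
            ([(1, 30), (2, 20), (3, 10)], -1.0),
            ([(1, 10), (2, 20), (3, 10)], 0.0),
        ],
    )
    def test_hand_computed_pearson(self, pairs, r_expected):
        r, p = quality_homopolymer_correlation(pairs)
        assert r == pytest.approx(r_expected, abs=1e-12)

    def test_zero_variance_is_na(self):
        with pytest.warns(UserWarning):
            r, p = quality_homopolymer_correlation([(2, 10), (2, 20), (2, 30)])
        assert np.isnan(r)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            quality_homopolymer_correlation([(1, 2), (3, 4)])
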