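"""Burden counting, ratios and the sample-label permutation test."""

import itertools
import math

import numpy as np
import pytest

from cnvdrive.burden_stats import (
    burden_ratio,
    burden_table,
    count_events,
    permutation_test,
)
from cnvdrive.cnv_events import BIN_SMALL, DUPLICATION, segments_to_events
from cnvdrive.errors import DataError

from conftest import make_segment


def exhaustive_permutation_p(counts_by_sample, groups):
    """Independent oracle: enumerate every case/control label assignment."""
    samples = sorted(counts_by_sample)
    counts = np.array([counts_by_sample[s] for s in samples], dtype=float)
    n_case = sum(1 for s in samples if groups[s] == "case")
    n_control = len(samples) - n_case
    total = counts.sum()
    if total == 0:
        return 1.0

    def stat(case_idx):
        case_sum = counts[list(case_idx)].sum()
        control_sum = total - case_sum
        if control_sum == 0:
            return None  # undefined ratio
        ratio = (case_sum / n_case) / (control_sum / n_control)
        return math.inf if case_sum == 0 else abs(math.log(ratio))

    obs = stat([i for i, s in enumerate(samples) if groups[s] == "case"])
    obs = math.inf if obs is None else obs
    exceed = 0
    n_assignments = 0
    for case_idx in itertools.combinations(range(len(samples)), n_case):
        n_assignments += 1
        value = stat(case_idx)
        if value is not None and value >= obs - 1e-12:
            exceed += 1
    return exceed / n_assignments


class TestCountEvents:
    def test_single_cell(self, toy_events):
        table = count_events(toy_events)
        cell = table[
            (table.chromosome == 1)
            & (table.state == DUPLICATION)
            & (table.length_bin == BIN_SMALL)
        ]
        assert int(cell.n_case.iloc[0]) == 2
        assert table.n_case.sum() + table.n_control.sum() == 3

    def test_empty_input_all_zero(self):
        table = count_events([])
        assert table.n_case.sum() == 0 and table.n_control.sum() == 0

    def test_conservation_on_random_events(self):
        rng = np.random.default_rng(7)
        segments = []
        for i in range(500):
            start = int(rng.integers(0, 1_000_000))
            length = int(rng.integers(1_000, 200_000))
            segments.append(
                make_segment(
                    sample=f"s{rng.integers(10)}",
                    group="case" if rng.random() < 0.5 else "control",
                    chromosome=int(rng.integers(1, 23)),
                    start=start,
                    end=start + length,
                    segment_mean=float(rng.choice([-0.6, 0.6])),
                )
            )
        events = segments_to_events(segments)
        table = count_events(events)
        assert table.n_case.sum() + table.n_control.sum() == len(events)


class TestBurdenRatio:
    def test_per_sample_normalized(self):
        assert burden_ratio(12, 4, 10, 10) == pytest.approx(3.0)
        assert burden_ratio(12, 4, 12, 4) == pytest.approx(1.0)

    def test_equal_counts_equal_sizes_is_one(self):
        assert burden_ratio(5, 5, 8, 8) == pytest.approx(1.0)

    def test_zero_control_is_missing_not_infinite(self):
        assert math.isnan(burden_ratio(5, 0, 8, 8))


class TestPermutationTest:
    def test_no_signal_gives_p_one(self):
        counts = {f"s{i}": 3 for i in range(8)}
        groups = {f"s{i}": "case" if i < 4 else "control" for i in range(8)}
        assert permutation_test(counts, groups, n_replicates=200, seed=0) == 1.0

    def test_add_one_lower_bound(self):
        counts = {"a": 50, "b": 40, "c": 0, "d": 1}
        groups = {"a": "case", "b": "case", "c": "control", "d": "control"}
        p = permutation_test(counts, groups, n_replicates=1000, seed=0)
        assert p >= 1 / 1001

    def test_degenerate_labels_error(self):
        with pytest.raises(DataError):
            permutation_test({"a": 1, "b": 2}, {"a": "case", "b": "case"})

    @pytest.mark.parametrize("n_per_group", [2, 3])
    def test_matches_exhaustive_enumeration(self, n_per_group):
        """Monte-Carlo p agrees with full label enumeration within 3 MC SEs."""
        rng = np.random.default_rng(11)
        for trial in range(5):
            samples = [f"s{i}" for i in range(2 * n_per_group)]
            counts = {s: int(rng.poisson(4)) for s in samples}
            groups = {
                s: "case" if i < n_per_group else "control"
                for i, s in enumerate(samples)
            }
            exact = exhaustive_permutation_p(counts, groups)
            n_rep = 10_000
            mc = permutation_test(counts, groups, n_replicates=n_rep, seed=trial)
            se = math.sqrt(max(exact * (1 - exact), 1e-6) / n_rep)
            # add-one estimator shifts by at most 1/(R+1)
            assert abs(mc - exact) <= 3 * se + 2 / (n_rep + 1)

    def test_deterministic_given_seed(self):
        counts = {f"s{i}": i % 4 for i in range(10)}
        groups = {f"s{i}": "case" if i < 5 else "control" for i in range(10)}
        p1 = permutation_test(counts, groups, n_replicates=500, seed=42)
        p2 = permutation_test(counts, groups, n_replicates=500, seed=42)
        assert p1 == p2

    def test_invariant_to_sample_relabeling(self):
        counts = {"a": 5, "b": 1, "c": 0, "d": 2}
        groups = {"a": "case", "b": "case", "c": "control", "d": "control"}
        renamed_counts = {"w": 5, "x": 1, "y": 0, "z": 2}
        renamed_groups = {"w": "case", "x": "case", "y": "control", "z": "control"}
        p1 = permutation_test(counts, groups, n_replicates=2000, seed=3)
        p2 = permutation_test(renamed_counts, renamed_groups, n_replicates=2000, seed=3)
        assert p1 == p2


class TestBurdenTable:
    def test_reproducible_and_complete(self, toy_events):
        kwargs = dict(
            case_samples=["case_a", "case_b"],
            control_samples=["ctrl_a", "ctrl_b"],
            n_replicates=200,
            seed=5,
        )
        t1 = burden_table(toy_events, **kwargs)
        t2 = burden_table(toy_events, **kwargs)
        assert t1.equals(t2)
        assert set(t1.columns) >= {
            "chromosome", "state", "length_bin", "n_case", "n_control",
            "ratio", "p_value", "q_value_bh",
        }
        assert ((t1.p_value > 0) & (t1.p_value <= 1)).all()

    def test_table_p_matches_single_cell_null(self):
        # a cell with no events must report p = 1 and a missing ratio
        table = burden_table(
            [], ["c1", "c2"], ["n1", "n2"], n_replicates=100, seed=0,
            chromosomes=[1],
        )
        assert (table.p_value == 1.0).all()
        assert table.ratio.isna().all()
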