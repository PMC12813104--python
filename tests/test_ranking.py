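"""Ranking rules, QC derivations and rank aggregation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import kitbench as kb
from kitbench.tables import ValidationError

# ---------------------------------------------------------------------------
# independent brute-force oracles: rank = 1 + number of strictly better kits
# ---------------------------------------------------------------------------

def oracle_rank_by_mean(values, higher_is_better):
    means = {k: float(np.mean(np.atleast_1d(v))) for k, v in values.items()}
    out = {}
    for kit, mean in means.items():
        if higher_is_better:
            better = sum(1 for other in means.values() if other > mean)
        else:
            better = sum(1 for other in means.values() if other < mean)
        out[kit] = 1 + better
    return out


def oracle_rank_contamination(values, threshold=0.01):
    qualifying = {k for k, v in values.items() if all(x < threshold for x in v)}
    means = {k: float(np.mean(v)) for k, v in values.items()}
    out = {}
    for kit in values:
        if kit in qualifying:
            out[kit] = 1
        else:
            better = sum(
                1 for other in values
                if other not in qualifying and means[other] < means[kit]
            )
            out[kit] = len(qualifying) + 1 + better
    return out


def oracle_rank_reproducibility(values, n_bins=6):
    vmin, vmax = min(values.values()), max(values.values())
    if vmax == vmin:
        return {k: 1 for k in values}
    edges = np.linspace(vmin, vmax, n_bins + 1)
    out = {}
    for kit, v in values.items():
        bin_index = n_bins - 1  # top bin is closed
        for j in range(n_bins):
            if edges[j] <= v < edges[j + 1]:
                bin_index = j
                break
        out[kit] = n_bins - bin_index
    return out


def oracle_rank_dilution(values):
    keys = {
        k: math.inf if v == "failed" else float(v) for k, v in values.items()
    }
    return {
        kit: 1 + sum(1 for other in keys.values() if other < key)
        for kit, key in keys.items()
    }


# ---------------------------------------------------------------------------
# QC derivations
# ---------------------------------------------------------------------------

class TestYieldPerGram:
    def test_direct_product(self):
        assert kb.yield_per_gram(10.0, 1.0) == pytest.approx(600.0)

    def test_floored_concentration(self):
        assert kb.yield_per_gram(0.02, 2.0) == pytest.approx(0.1 * 60 / 2.0)

    def test_zero_mass_rejected(self):
        with pytest.raises(ValidationError):
            kb.yield_per_gram(10.0, 0.0)


class TestPurityFlags:
    @pytest.mark.parametrize(
        "a280,a230,pure",
        [
            (1.8, 2.1, True),
            (1.8, 1.0, False),
            (2.0, 2.0, True),   # inclusive bounds
            (1.7, 2.2, True),
            (1.65, 2.1, False),
        ],
    )
    def test_windows(self, a280, a230, pure):
        assert kb.purity_flags(a280, a230).pure is pure

    def test_non_positive_ratio_rejected(self):
        with pytest.raises(ValidationError):
            kb.purity_flags(0.0, 2.1)


# ---------------------------------------------------------------------------
# ranking rules: worked examples
# ---------------------------------------------------------------------------

class TestRankByMean:
    def test_descending_means(self):
        ranks = kb.rank_by_mean({"a": 10.0, "b": 5.0, "c": 1.0}, True)
        assert ranks == {"a": 1, "b": 2, "c": 3}

    def test_all_tied(self):
        assert kb.rank_by_mean({"a": 2.0, "b": 2.0}, True) == {"a": 1, "b": 1}

    def test_tie_with_skip(self):
        ranks = kb.rank_by_mean({"a": 5.0, "b": 5.0, "c": 3.0}, True)
        assert ranks == {"a": 1, "b": 1, "c": 3}

    def test_replicate_lists_use_means(self):
        ranks = kb.rank_by_mean({"a": [1, 3], "b": [2, 2.5]}, False)
        assert ranks == {"a": 1, "b": 2}  # means 2.0 < 2.25, lower better

    def test_empty_values_rejected(self):
        with pytest.raises(ValidationError):
            kb.rank_by_mean({"a": []}, True)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(
        means=st.lists(st.floats(0.1, 100.0), min_size=2, max_size=8),
        exponent=st.floats(0.5, 2.0),
    )
    def test_invariant_under_monotone_transform(self, means, exponent):
        values = {f"k{i}": m for i, m in enumerate(means)}
        transformed = {k: v**exponent for k, v in values.items()}
        assert kb.rank_by_mean(values, True) == kb.rank_by_mean(transformed, True)


class TestRankContamination:
    def test_sub_threshold_kit_top_ranked(self):
        ranks = kb.rank_contamination(
            {"a": [0.005, 0.008, 0.009], "b": [0.05, 0.06, 0.07]}
        )
        assert ranks["a"] == 1 and ranks["b"] == 2

    def test_two_qualifying_block(self):
        ranks = kb.rank_contamination(
            {
                "q1": [0.001, 0.002, 0.003],
                "q2": [0.004, 0.005, 0.006],
                "x": [0.02, 0.02, 0.02],
                "y": [0.05, 0.05, 0.05],
            }
        )
        assert ranks == {"q1": 1, "q2": 1, "x": 3, "y": 4}

    def test_no_qualifier_degenerates_to_mean_rank(self):
        ranks = kb.rank_contamination({"a": [0.05], "b": [0.02], "c": [0.08]})
        assert ranks == {"a": 2, "b": 1, "c": 3}

    def test_qualifier_never_outranked(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            values = {
                f"k{i}": list(rng.uniform(0, 0.05, size=3)) for i in range(5)
            }
            ranks = kb.rank_contamination(values)
            qualifying = {
                k for k, v in values.items() if all(x < 0.01 for x in v)
            }
            for q in qualifying:
                assert all(ranks[q] <= ranks[k] for k in values)


class TestRankReproducibility:
    def test_degenerate_range_all_rank_one(self):
        assert kb.rank_reproducibility({"a": 0.4, "b": 0.4}) == {"a": 1, "b": 1}

    def test_worked_bin_example(self):
        values = {"a": 0.0, "b": 10.0, "c": 20.0, "d": 30.0, "e": 40.0, "f": 100.0}
        ranks = kb.rank_reproducibility(values)
        assert ranks == {"a": 6, "b": 6, "c": 5, "d": 5, "e": 4, "f": 1}

    def test_max_value_always_rank_one(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            values = {f"k{i}": float(v) for i, v in enumerate(rng.random(6))}
            ranks = kb.rank_reproducibility(values)
            best = max(values, key=values.get)
            assert ranks[best] == 1

    def test_rank_non_increasing_in_value(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            values = {f"k{i}": float(v) for i, v in enumerate(rng.random(7))}
            ranks = kb.rank_reproducibility(values)
            ordered = sorted(values, key=values.get)
            for worse, better in zip(ordered, ordered[1:]):
                assert ranks[better] <= ranks[worse]


class TestRankDilution:
    def test_ascending_factors(self):
        assert kb.rank_dilution({"a": 1, "b": 10, "c": 100}) == {"a": 1, "b": 2, "c": 3}

    def test_all_tied(self):
        assert kb.rank_dilution({"a": 1, "b": 1}) == {"a": 1, "b": 1}

    def test_failed_ordered_last_with_skip(self):
        assert kb.rank_dilution({"a": 1, "b": 1, "c": "failed"}) == {
            "a": 1, "b": 1, "c": 3,
        }

    def test_unknown_token_rejected(self):
        with pytest.raises(ValidationError):
            kb.rank_dilution({"a": 7})


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------

class TestAggregateRanks:
    def test_single_criterion_preserves_order(self):
        table = kb.aggregate_ranks({"shannon": {"a": 1, "b": 2, "c": 3}})
        assert table.total_rank_order == ["a", "b", "c"]
        assert table.quality_rank_order == ["a", "b", "c"]

    def test_opposite_orders_tie_at_position_one(self):
        table = kb.aggregate_ranks(
            {"x": {"a": 1, "b": 2}, "y": {"a": 2, "b": 1}}
        )
        assert table.total_positions.tolist() == [1, 1]

    def test_worked_summation(self):
        table = kb.aggregate_ranks(
            {"x": {"a": 1, "b": 2, "c": 3}, "y": {"a": 2, "b": 1, "c": 3}}
        )
        assert table.totals.tolist() == [3, 3, 6]
        assert table.total_positions.tolist() == [1, 1, 3]

    def test_quality_excludes_cost_and_simplicity(self):
        table = kb.aggregate_ranks(
            {
                "shannon": {"a": 2, "b": 1},
                "cost": {"a": 1, "b": 2},
                "simplicity": {"a": 1, "b": 2},
            }
        )
        assert table.totals.tolist() == [4, 5]
        assert table.quality.tolist() == [2, 1]
        assert table.best_quality() == ["b"]

    def test_missing_kit_rejected(self):
        with pytest.raises(ValidationError, match="cover"):
            kb.aggregate_ranks({"x": {"a": 1, "b": 2}, "y": {"a": 1}})

    def test_din_measurement_failure_imputed_worst(self):
        criterion = kb.CriterionValues(
            "din", {"a": [6.0], "b": [5.0], "c": None}, higher_is_better=True
        )
        assert criterion.ranks() == {"a": 1, "b": 2, "c": 3}


# ---------------------------------------------------------------------------
# oracle spot equivalence (the 1000-input sweeps live in the acceptance suite)
# ---------------------------------------------------------------------------

def test_rules_match_oracles_spot_check():
    rng = np.random.default_rng(3)
    for _ in range(50):
        n = int(rng.integers(2, 7))
        by_mean = {f"k{i}": list(rng.uniform(0, 10, 3)) for i in range(n)}
        assert kb.rank_by_mean(by_mean, True) == oracle_rank_by_mean(by_mean, True)
        contamination = {f"k{i}": list(rng.uniform(0, 0.03, 3)) for i in range(n)}
        assert kb.rank_contamination(contamination) == oracle_rank_contamination(
            contamination
        )
        reproducibility = {f"k{i}": float(rng.random()) for i in range(n)}
        assert kb.rank_reproducibility(reproducibility) == oracle_rank_reproducibility(
            reproducibility
        )
        dilution = {
            f"k{i}": rng.choice([1, 10, 100, "failed"]) for i in range(n)
        }
        dilution = {
            k: (v if v == "failed" else int(v)) for k, v in dilution.items()
        }
        assert kb.rank_dilution(dilution) == oracle_rank_dilution(dilution)
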