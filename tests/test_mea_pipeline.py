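"""Activity/inclusion filters, unit classification, normalization, and the
Friedman/Conover/BH concentration-response chain."""

import numpy as np
import pandas as pd
import pytest

from larvastat import (
    InclusionBounds,
    MeaSimConfig,
    analyze_mea,
    apply_inclusion,
    classify_unit,
    compute_inclusion_bounds,
    concentration_response,
    filter_active_units,
    normalize_unit,
    normalize_units,
    simulate_paradigm,
)

SEGS = [f"seg{i}" for i in range(1, 12)]


def make_table(rows):
    out = []
    for i, counts in enumerate(rows):
        out.append({"unit": f"u{i}", "well": "w0", "antagonist": "bicuculline",
                    **{s: c for s, c in zip(SEGS, counts)}})
    return pd.DataFrame(out)


class TestFilters:
    def test_zero_baseline_dropped_low_but_positive_retained(self):
        t = make_table([[0] + [5] * 10, [5, 5, 5, 1] + [5] * 7])
        kept = filter_active_units(t)
        assert kept["unit"].tolist() == ["u1"]

    def test_random_table_matches_predicate(self, rng):
        rows = rng.integers(0, 3, size=(50, 11)).tolist()
        t = make_table(rows)
        kept = filter_active_units(t)
        expected = [f"u{i}" for i, r in enumerate(rows) if r[0] > 0 and r[3] > 0]
        assert kept["unit"].tolist() == expected

    def test_bounds_constant_counts(self):
        t = make_table([[7] * 11] * 5)
        b = compute_inclusion_bounds(t)
        assert b.baseline1 == (7.0, 7.0) and b.baseline2 == (7.0, 7.0)

    def test_bounds_interpolation_1_to_40(self):
        rows = [[i] + [1] * 10 for i in range(1, 41)]
        t = make_table(rows)
        b = compute_inclusion_bounds(t)
        assert b.baseline1 == (pytest.approx(1.975), pytest.approx(39.025))

    def test_bounds_need_two_units(self):
        with pytest.raises(ValueError, match="at least 2"):
            compute_inclusion_bounds(make_table([[1] * 11]))

    def test_inclusion_is_inclusive_at_bounds(self):
        bounds = InclusionBounds(baseline1=(3.0, 10.0), baseline2=(2.0, 10.0))
        t = make_table([[3, 1, 1, 2] + [0] * 7, [11, 1, 1, 2] + [0] * 7,
                        [5, 1, 1, 1] + [0] * 7])
        kept = apply_inclusion(t, bounds)
        assert kept["unit"].tolist() == ["u0"]

    def test_inclusion_matches_brute_force(self, rng):
        rows = rng.integers(0, 30, size=(60, 11)).tolist()
        t = make_table(rows)
        bounds = InclusionBounds(baseline1=(3.0, 20.0), baseline2=(2.0, 25.0))
        kept = set(apply_inclusion(t, bounds)["unit"])
        expected = {
            f"u{i}" for i, r in enumerate(rows)
            if 3 <= r[0] <= 20 and 2 <= r[3] <= 25
        }
        assert kept == expected

    def test_filters_are_idempotent(self, rng):
        counts, _ = simulate_paradigm(MeaSimConfig(seed=5))
        active = filter_active_units(counts)
        assert active.equals(filter_active_units(active))
        bounds = compute_inclusion_bounds(active)
        once = apply_inclusion(active, bounds)
        assert once.equals(apply_inclusion(once, bounds))


class TestClassification:
    @pytest.mark.parametrize(
        "counts,antagonist,expected",
        [
            ((100, 40, 90), "bicuculline", "GABA_A"),
            ((80, 30, 60), "saclofen", "GABA_B"),
            ((100, 120, 200), "bicuculline", "unclassified"),
            ((100, 120, 200), "saclofen", "unclassified"),
            ((100, 100, 200), "bicuculline", "unclassified"),  # tie: no decrease
            ((100, 40, 40), "saclofen", "unclassified"),  # tie: no rebound
        ],
    )
    def test_rule_instantiations(self, counts, antagonist, expected):
        assert classify_unit(counts, antagonist) == expected

    def test_unknown_antagonist_rejected(self):
        with pytest.raises(ValueError, match="antagonist"):
            classify_unit((3, 2, 4), "picrotoxin")


class TestNormalization:
    def test_simple_fractions(self):
        frac = normalize_unit([0] * 3 + [10, 30, 60] + [0] * 5, analyzed_segments=(4, 5, 6))
        assert np.allclose(frac, [0.1, 0.3, 0.6])

    def test_all_mass_one_segment(self):
        frac = normalize_unit([0, 0, 0, 0, 50, 0, 0, 0, 0, 0, 0], analyzed_segments=(4, 5, 6))
        assert np.allclose(frac, [0.0, 1.0, 0.0])

    def test_random_counts_sum_to_one(self, rng):
        counts, _ = simulate_paradigm(MeaSimConfig(seed=6))
        normalized, dropped = normalize_units(counts)
        assert np.allclose(normalized.sum(axis=1), 1.0, atol=1e-9)
        zero_total = counts[
            counts[[f"seg{i}" for i in range(4, 12)]].sum(axis=1) == 0
        ]["unit"].tolist()
        assert dropped == zero_total

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError, match="zero total"):
            normalize_unit([5] * 3 + [0] * 8)


class TestConcentrationResponse:
    def test_identical_profiles_give_unit_p(self):
        frame = pd.DataFrame(
            np.tile(np.full(8, 1 / 8.0), (6, 1)),
            columns=[f"seg{i}" for i in range(4, 12)],
            index=[f"u{i}" for i in range(6)],
        )
        res = concentration_response(frame)
        assert res.friedman.p_value == 1.0
        assert np.allclose(res.adjusted_p, 1.0)
        assert len(res.adjusted_p) == 7

    def test_monotone_increase_detected_in_top_concentrations(self):
        cfg = MeaSimConfig(
            n_units={"gabaA": 50},
            pfos_effects=(1.0, 1.0, 1.0, 1.0, 1.0, 1.8, 2.2),
            antagonist_assignment="matched",
            seed=7,
        )
        counts, _ = simulate_paradigm(cfg)
        normalized, _ = normalize_units(filter_active_units(counts))
        res = concentration_response(normalized)
        assert res.friedman.p_value < 0.05
        # the two elevated concentrations are detected
        assert res.adjusted_p[5] < 0.05 and res.adjusted_p[6] < 0.05

    def test_adjusted_dominates_raw(self, rng):
        counts, _ = simulate_paradigm(MeaSimConfig(seed=8))
        normalized, _ = normalize_units(filter_active_units(counts))
        res = concentration_response(normalized)
        assert np.all(res.adjusted_p >= res.raw_p - 1e-12)

    def test_too_few_units_rejected(self):
        frame = pd.DataFrame(
            [np.full(8, 1 / 8.0)], columns=[f"seg{i}" for i in range(4, 12)]
        )
        with pytest.raises(ValueError, match="at least 2"):
            concentration_response(frame)


class TestEndToEnd:
    def test_classification_recovery_at_stated_effects(self):
        cfg = MeaSimConfig(
            n_units={"gabaA": 150, "gabaB": 150, "nonresponsive": 100, "inactive": 20},
            gaba_effect=0.3,
            antagonist_effect=2.5,
            baseline_median=200.0,
            nb_dispersion=5.0,
            antagonist_assignment="matched",
            seed=9,
        )
        counts, truth = simulate_paradigm(cfg)
        res = analyze_mea(counts)
        called = pd.Series(res["classes"])
        merged = truth.set_index("unit").join(called.rename("called"), how="inner")
        resp = merged[merged["true_type"].isin(["gabaA", "gabaB"])]
        correct = (
            ((resp["true_type"] == "gabaA") & (resp["called"] == "GABA_A"))
            | ((resp["true_type"] == "gabaB") & (resp["called"] == "GABA_B"))
        )
        assert correct.mean() >= 0.95  # sensitivity at the stated effect sizes

    def test_inactive_units_removed_by_activity_filter(self):
        cfg = MeaSimConfig(n_units={"gabaA": 20, "inactive": 15}, seed=10)
        counts, truth = simulate_paradigm(cfg)
        res = analyze_mea(counts)
        inactive = set(truth.loc[truth["true_type"] == "inactive", "unit"])
        assert not inactive & set(res["classes"])
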