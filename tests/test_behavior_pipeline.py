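"""Binning, scaling, VSR extraction, exclusions, and the analysis chains."""

import numpy as np
import pandas as pd
import pytest

from larvastat import (
    BehaviorSimConfig,
    DEFAULT_PROTOCOL,
    analyze_phases,
    analyze_vsr,
    bin_distances,
    compute_scale,
    compute_vsr,
    exclude_invalid,
    scale_bins,
    simulate_bins,
    simulate_trace,
)


def make_trace(distances_fn, animal="a1", treatment="T"):
    t = np.arange(3720)
    return pd.DataFrame(
        {
            "experiment": "e1",
            "animal": animal,
            "treatment": treatment,
            "time_s": t,
            "distance_cm": distances_fn(t),
            "dead": False,
            "malformed": False,
            "uninflated": False,
        }
    )


class TestExclusions:
    def test_all_clean_all_retained(self):
        tr = make_trace(lambda t: np.ones_like(t, dtype=float))
        kept, report = exclude_invalid(tr)
        assert report.n_retained == report.n_input == 1
        assert len(kept) == len(tr)

    def test_one_dead_larva_reported(self):
        a = make_trace(lambda t: np.ones_like(t, dtype=float), animal="a1")
        b = make_trace(lambda t: np.ones_like(t, dtype=float), animal="a2")
        b["dead"] = True
        kept, report = exclude_invalid(pd.concat([a, b], ignore_index=True))
        assert report.n_retained == 1
        assert report.counts_by_reason == {"dead": 1}
        assert set(kept["animal"]) == {"a1"}

    def test_randomized_flags_match_brute_force(self, rng):
        frames = []
        expected_keep = set()
        for i in range(12):
            tr = make_trace(lambda t: np.ones_like(t, dtype=float), animal=f"a{i}")
            flags = rng.random(3) < 0.4
            tr["dead"], tr["malformed"], tr["uninflated"] = flags
            if not flags.any():
                expected_keep.add(f"a{i}")
            frames.append(tr)
        kept, _ = exclude_invalid(pd.concat(frames, ignore_index=True))
        assert set(kept["animal"]) == expected_keep


class TestBinning:
    def test_constant_rate_gives_sixty_cm_bins(self):
        bins = bin_distances(make_trace(lambda t: np.full_like(t, 0.5, dtype=float)))
        assert len(bins) == 20  # 4 phases x 5 bins
        assert np.allclose(bins["distance_cm"], 60.0)

    def test_zero_trace_gives_zero_bins(self):
        bins = bin_distances(make_trace(lambda t: np.zeros_like(t, dtype=float)))
        assert np.allclose(bins["distance_cm"], 0.0)

    def test_random_trace_matches_direct_summation(self, rng):
        vals = rng.random(3720)
        tr = make_trace(lambda t: vals[t])
        bins = bin_distances(tr)
        for _, row in bins.iterrows():
            start, _ = DEFAULT_PROTOCOL.phase_windows[row["phase"]]
            lo = start + 120 * (int(row["bin"]) - 1)
            assert row["distance_cm"] == pytest.approx(vals[lo : lo + 120].sum(), abs=1e-9)
        # per-phase totals conserved
        for phase, (a, b) in DEFAULT_PROTOCOL.phase_windows.items():
            assert bins.loc[bins["phase"] == phase, "distance_cm"].sum() == pytest.approx(
                vals[a:b].sum(), abs=1e-9
            )

    def test_missing_second_names_the_gap(self):
        tr = make_trace(lambda t: np.ones_like(t, dtype=float))
        tr = tr[tr["time_s"] != 2500]
        with pytest.raises(ValueError, match="t=2500"):
            bin_distances(tr)


class TestScaling:
    def test_scale_constant(self):
        bins = pd.DataFrame({"distance_cm": [10.0, 200.0, 50.0]})
        assert compute_scale(bins) == pytest.approx(200.2)

    def test_single_bin(self):
        assert compute_scale(pd.DataFrame({"distance_cm": [7.0]})) == pytest.approx(7.007)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="scale undefined"):
            compute_scale(pd.DataFrame({"distance_cm": [0.0, 0.0]}))

    def test_max_maps_to_inverse_factor_and_zero_nudged(self):
        bins = pd.DataFrame({"distance_cm": [0.0, 100.0, 40.0]})
        m = compute_scale(bins)
        scaled = scale_bins(bins, m, epsilon=1e-6)
        assert scaled["value"].max() == pytest.approx(1 / 1.001)
        assert scaled["value"].min() == 1e-6
        assert scaled["value"].between(0, 1, inclusive="neither").all()

    def test_scaling_preserves_order(self, rng):
        vals = np.sort(rng.random(10) * 100 + 1)
        bins = pd.DataFrame({"distance_cm": vals})
        scaled = scale_bins(bins, compute_scale(bins))
        assert (np.diff(scaled["value"]) > 0).all()

    def test_value_above_scale_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            scale_bins(pd.DataFrame({"distance_cm": [10.0]}), 5.0)


class TestVsr:
    def test_constant_two_cm_gives_six(self):
        tr = make_trace(lambda t: np.full_like(t, 2.0, dtype=float))
        vsr = compute_vsr(tr)
        assert np.allclose(vsr["vsr_cm"], 6.0)
        assert set(vsr["startle_phase"]) == {"VSR1", "VSR2"}

    def test_zero_trace(self):
        vsr = compute_vsr(make_trace(lambda t: np.zeros_like(t, dtype=float)))
        assert np.allclose(vsr["vsr_cm"], 0.0)

    def test_random_trace_matches_three_term_sum(self, rng):
        vals = rng.random(3720)
        vsr = compute_vsr(make_trace(lambda t: vals[t])).set_index("startle_phase")
        assert vsr.loc["VSR1", "vsr_cm"] == pytest.approx(vals[1200:1203].sum())
        assert vsr.loc["VSR2", "vsr_cm"] == pytest.approx(vals[2400:2403].sum())


class TestAnalysisChains:
    def test_phase_analysis_label_symmetry(self, small_bins):
        """Relabeling identical treatment groups permutes letters but keeps
        the partition structure."""
        table, _ = small_bins
        res = analyze_phases(table)
        swapped = table.copy()
        swapped["treatment"] = swapped["treatment"].map(
            {"control": "PFOS", "PFOS": "control"}
        )
        res2 = analyze_phases(swapped)
        # the letter partition is identical up to the treatment relabeling
        def partition(letters):
            groups = {}
            for cell, ls in letters.items():
                for l in ls:
                    groups.setdefault(l, set()).add(cell)
            return {frozenset(v) for v in groups.values()}

        def rename(cells):
            return frozenset(
                c.replace("control", "@").replace("PFOS", "control").replace("@", "PFOS")
                for c in cells
            )

        assert {rename(g) for g in partition(res.letters)} == partition(res2.letters)

    def test_injected_dark_effect_detected(self, small_bins):
        table, _ = small_bins
        res = analyze_phases(table)
        # exposed dark cells must not share letters with the control dark cells
        for cell in ("PFOS D1", "PFOS D2"):
            assert not set(res.letters[cell]) & set(res.letters[cell.replace("PFOS", "control")])

    def test_vsr_single_treatment_all_a(self):
        cfg = BehaviorSimConfig(
            n_per_group=10, treatment_labels=("control",), seed=8, exclusion_rate=0.0
        )
        tr, _ = simulate_trace(cfg)
        res = analyze_vsr(compute_vsr(tr))
        assert res.letters == {"control": "a"}
        assert res.contrasts == []

    def test_vsr_shift_detected(self):
        rng = np.random.default_rng(12)
        rows = []
        for trt, shift in [("control", 0.0), ("PFOS", 3.0)]:
            for i in range(45):
                b = rng.normal(0, 1.0)
                for ph in ("VSR1", "VSR2"):
                    rows.append(
                        (f"{trt}{i}", trt, ph, 6.0 + shift + b + rng.normal(0, 2.0))
                    )
        vsr = pd.DataFrame(rows, columns=["animal", "treatment", "startle_phase", "vsr_cm"])
        res = analyze_vsr(vsr)
        assert res.letters["control"] != res.letters["PFOS"]

    def test_missing_startle_phase_rejected(self):
        vsr = pd.DataFrame(
            {"animal": ["a", "b"], "treatment": "T", "startle_phase": "VSR1",
             "vsr_cm": [1.0, 2.0]}
        )
        with pytest.raises(ValueError, match="startle phases"):
            analyze_vsr(vsr)
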