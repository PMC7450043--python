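"""Replicate statistics: aggregation, t tests, scans, windows, thermal."""

import dataclasses
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from nascentfret import (
    ConditionKey,
    aggregate_profile,
    compare_conditions,
    compute_experiment_fret,
    delta_fret,
    detect_folding_window,
    length_scan,
    release_comparison,
    simulate_experiment_series,
    simulate_thermal_series,
    thermal_curve,
)
from nascentfret.errors import PairingError
from nascentfret.types import ConditionProfile, FretResult

from conftest import measure_series


def make_result(e, condition=None, qc_pass=True, eid="x"):
    if condition is None:
        condition = ConditionKey("WT", 487, 654)
    return FretResult(
        experiment_id=eid, condition=condition, e_fret=e, f_d=1.0,
        f_da=1.0 - e, conc_d=100.0, conc_da=100.0, readthrough_ratio=1.0,
        qc_pass=qc_pass,
    )


def make_profile(values, condition=None):
    return aggregate_profile([make_result(v, condition, eid=f"r{i}")
                              for i, v in enumerate(values)])


class TestAggregateProfile:
    def test_mean_and_sem(self):
        prof = make_profile([10.0, 12.0, 14.0])
        assert prof.mean == pytest.approx(12.0)
        assert prof.sem == pytest.approx(2.0 / math.sqrt(3), abs=1e-4)  # 1.1547

    def test_single_replicate_flagged(self):
        prof = make_profile([10.0])
        assert prof.sem == 0.0
        assert prof.low_n

    def test_qc_failed_excluded_and_counted(self):
        results = [make_result(v, eid=f"r{v}") for v in (10.0, 12.0, 14.0)]
        results.append(make_result(99.0, qc_pass=False, eid="bad"))
        prof = aggregate_profile(results)
        assert prof.n == 3
        assert prof.n_excluded == 1
        assert prof.mean == pytest.approx(12.0)
        kept = aggregate_profile(results, include_qc_failed=True)
        assert kept.n == 4

    def test_no_usable_replicates(self):
        with pytest.raises(ValueError):
            aggregate_profile([make_result(1.0, qc_pass=False)])


class TestCompareConditions:
    def test_identical_groups(self):
        a = make_profile([5.0, 5.0, 5.0])
        assert compare_conditions(a, a).t_statistic == 0.0
        assert compare_conditions(a, a).p_value == pytest.approx(1.0)

    def test_matches_reference_implementation(self):
        xa, xb = [4.1, 4.2, 4.0], [6.0, 6.1, 6.2]
        cmp_ = compare_conditions(make_profile(xa), make_profile(xb))
        ref = stats.ttest_ind(xa, xb, equal_var=True)
        assert cmp_.t_statistic == pytest.approx(ref.statistic, abs=1e-10)
        assert cmp_.p_value == pytest.approx(ref.pvalue, abs=1e-10)
        assert cmp_.degrees_of_freedom == 4

    def test_welch_matches_reference(self):
        xa, xb = [4.1, 4.9, 4.0, 5.5], [6.0, 6.05, 6.1]
        cmp_ = compare_conditions(make_profile(xa), make_profile(xb), welch=True)
        ref = stats.ttest_ind(xa, xb, equal_var=False)
        assert cmp_.t_statistic == pytest.approx(ref.statistic, abs=1e-10)
        assert cmp_.p_value == pytest.approx(ref.pvalue, abs=1e-10)

    def test_one_tailed_is_half_two_tailed_in_stated_direction(self):
        a, b = make_profile([6.0, 6.1, 6.2]), make_profile([4.0, 4.1, 4.2])
        two = compare_conditions(a, b, tail="two")
        one = compare_conditions(a, b, tail="one")
        assert one.p_value == pytest.approx(two.p_value / 2, rel=1e-12)

    def test_paired_matches_reference(self):
        xa, xb = [4.1, 4.2, 4.0, 4.4], [6.0, 6.1, 6.2, 5.9]
        cmp_ = compare_conditions(make_profile(xa), make_profile(xb), paired=True)
        ref = stats.ttest_rel(xa, xb)
        assert cmp_.t_statistic == pytest.approx(ref.statistic, abs=1e-10)
        assert cmp_.p_value == pytest.approx(ref.pvalue, abs=1e-10)

    def test_insufficient_replicates(self):
        with pytest.raises(ValueError):
            compare_conditions(make_profile([1.0]), make_profile([1.0, 2.0]))


class TestLengthScan:
    def profiles_for(self, construct, truncs, truth, params, n=4, seed=3):
        return {
            t: measure_series(ConditionKey(construct, 487, t), truth, n, seed,
                              params)
            for t in truncs
        }

    def test_identical_series_zero_difference(self, truth, quiet_params):
        truncs = (604, 614, 654)
        wt = self.profiles_for("WT", truncs, truth, quiet_params)
        scan = length_scan(wt, wt)
        assert np.allclose(scan["difference"], 0.0)

    def test_most_profound_decrease_at_654(self, truth, noisy_params):
        truncs = (500, 550, 568, 584, 604, 614, 624, 654, 674)
        wt = self.profiles_for("WT", truncs, truth, noisy_params)
        mut = self.profiles_for("A455E", truncs, truth, noisy_params)
        scan = length_scan(wt, mut)
        best = scan.loc[scan["difference"].idxmax(), "truncation"]
        assert best == 654

    def test_neutral_variant_no_significant_truncation(self, truth, noisy_params):
        truncs = (604, 614, 654)
        wt = self.profiles_for("WT", truncs, truth, noisy_params, seed=5)
        g551d = self.profiles_for("G551D", truncs, truth, noisy_params, seed=5)
        scan = length_scan(wt, g551d)
        window = detect_folding_window(scan, alpha=0.05)
        assert window.empty

    def test_mismatched_grids_rejected(self, truth, quiet_params):
        wt = self.profiles_for("WT", (604, 614), truth, quiet_params)
        mut = self.profiles_for("A455E", (604, 654), truth, quiet_params)
        with pytest.raises(ValueError):
            length_scan(wt, mut)


class TestFoldingWindow:
    def make_scan(self, sig_truncs, truncs=(500, 568, 584, 604, 614, 654, 674)):
        rows = []
        for t in truncs:
            sig = t in sig_truncs
            rows.append(
                {"truncation": t, "difference": 5.0 if sig else 0.1,
                 "p_value": 0.001 if sig else 0.8}
            )
        return pd.DataFrame(rows)

    def test_no_significant_points(self):
        assert detect_folding_window(self.make_scan(set())).empty

    def test_contiguous_run(self):
        w = detect_folding_window(self.make_scan({604, 614, 654}))
        assert (w.start_truncation, w.end_truncation) == (604, 654)

    def test_negative_differences_never_count(self):
        scan = self.make_scan({604})
        scan.loc[scan["truncation"] == 604, "difference"] = -5.0
        assert detect_folding_window(scan).empty

    def test_invariant_to_nonsignificant_flanks(self):
        base = detect_folding_window(self.make_scan({584, 604}))
        padded = detect_folding_window(
            self.make_scan({584, 604},
                           truncs=(450, 500, 568, 584, 604, 614, 654, 674, 704))
        )
        assert base.truncations == padded.truncations

    def test_a455e_window_starts_at_584(self, truth, noisy_params):
        # stochastic, checked over several master seeds
        truncs = (500, 550, 568, 584, 604, 614, 624, 654)
        starts = []
        for seed in (1, 2, 3):
            wt = {t: measure_series(ConditionKey("WT", 487, t), truth, 4, seed,
                                    noisy_params) for t in truncs}
            mut = {t: measure_series(ConditionKey("A455E", 487, t), truth, 4,
                                     seed, noisy_params) for t in truncs}
            w = detect_folding_window(length_scan(wt, mut), alpha=0.05)
            starts.append(w.start_truncation)
        assert starts.count(584) >= 2


class TestReleaseComparison:
    def bound(self, trunc, truth, params):
        return measure_series(ConditionKey("WT", 487, trunc), truth, 3, 1, params)

    def released(self, trunc, truth, params):
        key = ConditionKey("WT", 487, trunc, ribosome_state="released")
        return measure_series(key, truth, 3, 1, params)

    @pytest.mark.parametrize("bound_t, released_t", [(604, 568), (704, 664)])
    def test_equivalent_exposure_pairings(self, bound_t, released_t, truth,
                                          noisy_params):
        cmp_, annotation = release_comparison(
            self.bound(bound_t, truth, noisy_params),
            self.released(released_t, truth, noisy_params),
        )
        assert annotation.tunnel_offset == bound_t - released_t
        assert 30 <= annotation.tunnel_offset <= 40
        assert annotation.exposed_up_to == released_t

    def test_nonequivalent_pairing_rejected(self, truth, noisy_params):
        # released chain at 500 exposes a shorter span than bound at 604
        key = ConditionKey("WT", 487, 500, ribosome_state="released")
        released = make_profile([0.30, 0.31, 0.32], condition=key)
        with pytest.raises(PairingError) as exc:
            release_comparison(self.bound(604, truth, noisy_params), released)
        assert "604" in str(exc.value) and "500" in str(exc.value)

    def test_state_order_enforced(self, truth, noisy_params):
        with pytest.raises(PairingError):
            release_comparison(
                self.released(568, truth, noisy_params),
                self.released(568, truth, noisy_params),
            )


class TestThermalAnalysis:
    def series(self, construct, truth, params, temps=(4, 25, 35, 50), n=3,
               trunc=654):
        key = ConditionKey(construct, 487, trunc)
        by_t = {}
        for t in temps:
            sets = [
                simulate_thermal_series(key, truth, [t], seed=s, params=params)[0]
                for s in range(n)
            ]
            by_t[float(t)] = [compute_experiment_fret(b) for b in sets]
        return thermal_curve(by_t)

    def test_tether_control_curve_is_flat(self, truth, quiet_params):
        # the Thr389 tether control (no denaturation curve, zero quench)
        key = ConditionKey("WT", 389, 654)
        by_t = {}
        for t in (4, 25, 50):
            sets = simulate_thermal_series(key, truth, [t], params=quiet_params)
            by_t[float(t)] = [compute_experiment_fret(b) for b in sets]
        control = thermal_curve(by_t)
        means = [p.mean for p in control]
        assert max(means) - min(means) < 1e-10

    def test_monotone_denaturation_noise_off(self, truth, quiet_params):
        profs = self.series("WT", truth, quiet_params, temps=(4, 15, 25, 35, 45, 50),
                            n=1)
        means = [p.mean for p in profs]
        assert all(a >= b - 1e-12 for a, b in zip(means, means[1:]))

    def test_unequal_replicate_counts_per_temperature(self, truth, noisy_params):
        key = ConditionKey("WT", 487, 654)
        by_t = {}
        for t, n in ((4.0, 3), (25.0, 7)):
            sets = [
                simulate_thermal_series(key, truth, [t], seed=s,
                                        params=noisy_params)[0]
                for s in range(n)
            ]
            by_t[t] = [compute_experiment_fret(b) for b in sets]
        profs = thermal_curve(by_t)
        assert [p.n for p in profs] == [3, 7]


class TestDeltaCurve:
    def test_identical_series_zero_delta(self, truth, quiet_params):
        helper = TestThermalAnalysis()
        wt = helper.series("WT", truth, quiet_params)
        delta = delta_fret(wt, wt)
        assert all(d == 0 for d in delta.delta_mean)

    def test_sem_propagation(self):
        key_wt = ConditionKey("WT", 487, 654, temperature=25.0)
        key_mut = ConditionKey("A455E", 487, 654, temperature=25.0)
        wt = ConditionProfile(key_wt, (1.0, 2.0), 1.5, 0.8, 2)
        mut = ConditionProfile(key_mut, (1.0, 2.0), 1.5, 0.9, 2)
        delta = delta_fret([wt], [mut])
        assert delta.delta_sem[0] == pytest.approx(math.sqrt(0.64 + 0.81))  # 1.204

    def test_mutant_deficit_shrinks_at_high_temperature(self, truth, quiet_params):
        helper = TestThermalAnalysis()
        wt = helper.series("WT", truth, quiet_params, temps=(4, 25, 50), n=1)
        mut = helper.series("A455E", truth, quiet_params, temps=(4, 25, 50), n=1)
        delta = delta_fret(wt, mut)
        assert delta.delta_mean[0] > delta.delta_mean[-1]

    def test_grid_mismatch_rejected(self, truth, quiet_params):
        helper = TestThermalAnalysis()
        wt = helper.series("WT", truth, quiet_params, temps=(4, 25))
        mut = helper.series("A455E", truth, quiet_params, temps=(4, 50))
        with pytest.raises(ValueError):
            delta_fret(wt, mut)


class TestPowerMonotonicity:
    """Rejection power grows with effect size and with replicate count."""

    @staticmethod
    def power(effect, n, n_repeats=400, sd=1.0, alpha=0.05, seed=0):
        rng = np.random.default_rng(seed)
        hits = 0
        for _ in range(n_repeats):
            a = make_profile(rng.normal(effect, sd, n).tolist())
            b = make_profile(rng.normal(0.0, sd, n).tolist())
            if compare_conditions(a, b).p_value < alpha:
                hits += 1
        return hits / n_repeats

    def test_monotone_in_effect_and_n(self):
        effects = (0.5, 1.0, 2.0)
        ns = (3, 4, 6)
        grid = {(e, n): self.power(e, n, seed=hash((e, n)) % 2**31)
                for e in effects for n in ns}
        margin = 0.05  # Monte-Carlo slack
        for n in ns:
            assert grid[(0.5, n)] <= grid[(1.0, n)] + margin
            assert grid[(1.0, n)] <= grid[(2.0, n)] + margin
        for e in effects:
            assert grid[(e, 3)] <= grid[(e, 4)] + margin
            assert grid[(e, 4)] <= grid[(e, 6)] + margin
        assert grid[(2.0, 6)] > grid[(0.5, 3)]
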