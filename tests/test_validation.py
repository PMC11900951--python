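"""Validation tests: Spearman gate, MAE reports, subcategory analysis, power."""

import math

import numpy as np
import pytest
from scipy import optimize, stats

from promwalk import (
    HOOS,
    MHHS,
    PowerSpec,
    correlation_power,
    equipercentile_crosswalk,
    linear_regression_crosswalk,
    mae_report,
    required_sample_size,
    spearman_gate,
    subcategory_mae,
)
from promwalk.equating import line_crosswalk
from promwalk.errors import ConfigError, DegenerateDistributionError, SpearmanGateError
from promwalk.instruments import load_instrument
from promwalk.validation import spearman_rho, subcategory_pairs

from conftest import graded_responses, make_pairs, responses_frame
from oracles import brute_equipercentile, brute_spearman


class TestSpearmanGate:
    def test_perfect_concordance_and_discordance(self):
        xs = [1, 2, 3, 4, 5]
        assert spearman_gate(make_pairs(xs, xs)) == pytest.approx(1.0)
        with pytest.raises(SpearmanGateError) as err:
            spearman_gate(make_pairs(xs, xs[::-1]))
        assert err.value.rho == pytest.approx(-1.0)

    def test_weak_correlation_fails_the_gate_with_rho_attached(self):
        rng = np.random.default_rng(3)
        xs = rng.uniform(0, 90, size=10)
        ys = rng.uniform(0, 100, size=10)
        rho = brute_spearman(xs, ys)
        assert rho < 0.3  # fixture premise, via the independent oracle
        with pytest.raises(SpearmanGateError) as err:
            spearman_gate(make_pairs(xs, ys, (0, 90), (0, 100)))
        assert err.value.rho == pytest.approx(rho)

    def test_matches_brute_force_with_ties(self):
        xs = [1, 2, 2, 3, 5, 5, 5, 8]
        ys = [2, 1, 4, 4, 6, 5, 9, 9]
        assert spearman_rho(xs, ys) == pytest.approx(brute_spearman(xs, ys))

    def test_invariant_under_strictly_monotone_transforms(self):
        rng = np.random.default_rng(9)
        xs = rng.uniform(1, 89, size=30)
        ys = np.clip(xs + rng.normal(0, 10, size=30), 1, 99)
        base = spearman_rho(xs, ys)
        for fx in (np.exp, np.cbrt, lambda v: v**3):
            assert spearman_rho(fx(xs / 30), ys) == pytest.approx(base)
            assert spearman_rho(xs, fx(ys / 30)) == pytest.approx(base)

    def test_constant_series_rejected(self):
        with pytest.raises(DegenerateDistributionError):
            spearman_rho([1, 1, 1, 1], [1, 2, 3, 4])


class TestMaeReport:
    def identity_table(self):
        return line_crosswalk("X", "Y", 1.0, 0.0, (0, 100), (0, 100))

    def test_perfect_agreement_gives_zero(self):
        pairs = make_pairs([10, 40, 80], [10, 40, 80])
        rep = mae_report(pairs, self.identity_table())
        assert rep.mae_overall == 0.0
        assert rep.max_abs_difference == 0.0

    def test_hand_mean_of_two_errors(self):
        pairs = make_pairs([10, 20], [20, 25], timepoints=["preop", "3m"])
        rep = mae_report(pairs, self.identity_table())
        assert rep.mae_overall == pytest.approx(7.5)
        assert rep.mae_by_timepoint == {"preop": 10.0, "3m": 5.0}
        assert rep.max_abs_difference == 10.0
        assert rep.max_abs_at_source == 10.0

    def test_overall_equals_count_weighted_stratum_mean(self, pairs_121):
        table = equipercentile_crosswalk(pairs_121)
        rep = mae_report(pairs_121, table)
        weighted = sum(
            rep.mae_by_timepoint[tp] * rep.n_by_timepoint[tp]
            for tp in rep.mae_by_timepoint
        ) / sum(rep.n_by_timepoint.values())
        assert rep.mae_overall == pytest.approx(weighted, abs=1e-9)
        assert all(v >= 0 for v in rep.mae_by_timepoint.values())

    def test_empty_stratum_flagged_absent_not_zero(self):
        pairs = make_pairs(
            [10, 20, 30, 42], [12, 18, 33, 40],
            timepoints=["preop", "preop", "3m", "3m"],
        )
        rep = mae_report(pairs, self.identity_table())
        assert set(rep.mae_by_timepoint) == {"preop", "3m"}
        assert "12m" not in rep.mae_by_timepoint

    def test_direction_mismatch_rejected(self, pairs_121):
        table = equipercentile_crosswalk(pairs_121, "y_to_x")
        with pytest.raises(ConfigError):
            mae_report(pairs_121, table)

    def test_eq_beats_constant_mean_predictor_on_training_pairs(self, pairs_121):
        table = equipercentile_crosswalk(pairs_121)
        rep = mae_report(pairs_121, table)
        const_mae = float(np.mean(np.abs(pairs_121.y - pairs_121.y.mean())))
        assert rep.mae_overall <= const_mae

    def test_eq_and_lr_err_similarly_on_the_synthetic_cohort(self, pairs_121):
        """Both methods should show comparable overall error (loose band)."""
        eq = mae_report(pairs_121, equipercentile_crosswalk(pairs_121)).mae_overall
        lr = mae_report(pairs_121, linear_regression_crosswalk(pairs_121)).mae_overall
        assert abs(eq - lr) / max(eq, lr) <= 0.25


class TestSubcategoryAnalysis:
    def build_fixture(self):
        visits = []
        mhhs_levels = [0, 1, 2, 3, 4, 5]
        hoos_levels = [0, 1, 1, 2, 3, 4]
        for i, (ml, hl) in enumerate(zip(mhhs_levels, hoos_levels)):
            pid = f"p{i}"
            visits.append((pid, "preop", MHHS, graded_responses(MHHS, ml)))
            visits.append((pid, "preop", HOOS, graded_responses(HOOS, hl)))
        return responses_frame(visits)

    def test_identical_series_give_zero_mae(self):
        visits = []
        for i, level in enumerate([0, 1, 2, 3]):
            visits.append((f"p{i}", "preop", HOOS, graded_responses(HOOS, level)))
            visits.append((f"p{i}", "3m", HOOS, graded_responses(HOOS, level)))
        df = responses_frame(visits)
        out = subcategory_mae(df, HOOS, HOOS)
        assert out == {"pain": 0.0, "activity": 0.0}

    def test_six_pair_worked_set_matches_end_to_end_oracle(self):
        df = self.build_fixture()
        result = subcategory_mae(df, MHHS, HOOS)

        # independent recomputation: hand-score, brute-force equate, apply, average
        mhhs = load_instrument(MHHS)
        pain_pts = dict(mhhs.item_map["pain"].options)
        act_items = ["stairs", "shoes_socks", "sitting"]
        for sub in ("pain", "activity"):
            xs, ys = [], []
            for ml, hl in zip([0, 1, 2, 3, 4, 5], [0, 1, 1, 2, 3, 4]):
                if sub == "pain":
                    xs.append(pain_pts[min(ml, 5)])
                else:
                    xs.append(
                        sum(
                            dict(mhhs.item_map[i].options)[
                                min(ml, len(mhhs.item_map[i].options) - 1)
                            ]
                            for i in act_items
                        )
                    )
                ys.append(100.0 - min(hl, 4) / 4.0 * 100.0)
            hi = 44 if sub == "pain" else 13
            table = brute_equipercentile(xs, ys, (0, hi), (0, 100))
            mae = sum(abs(table[int(x)] - y) for x, y in zip(xs, ys)) / len(xs)
            assert result[sub] == pytest.approx(mae, abs=1e-9)

    def test_subcategory_pair_ranges(self):
        df = self.build_fixture()
        pairs = subcategory_pairs(df, MHHS, HOOS, "activity")
        assert pairs.range_x == (0.0, 13.0)
        assert pairs.range_y == (0.0, 100.0)
        assert len(pairs) == 6


class TestPowerAnalysis:
    def test_reproduces_the_one_sided_sample_size_67(self):
        assert required_sample_size(PowerSpec(0.3, 0.05, 0.8, sided=1)) == 67

    def test_two_sided_sample_size_verified_by_root_finding(self):
        spec = PowerSpec(0.3, 0.05, 0.8, sided=2)
        n = required_sample_size(spec)

        def power_minus_target(n_float):
            # independent continuous re-derivation of the power curve
            df = n_float - 2
            tcrit = stats.t.ppf(1 - 0.05 / 2, df)
            rc = math.sqrt(tcrit**2 / (tcrit**2 + df))
            z = (math.atanh(0.3) + 0.3 / (2 * (n_float - 1)) - math.atanh(rc))
            return (
                stats.norm.cdf(z * math.sqrt(n_float - 3))
                + stats.norm.cdf(
                    (-math.atanh(0.3) - 0.3 / (2 * (n_float - 1)) - math.atanh(rc))
                    * math.sqrt(n_float - 3)
                )
                - 0.8
            )

        root = optimize.brentq(power_minus_target, 10, 500)
        assert n == math.ceil(root) == 85

    def test_power_collapses_to_minimum_n_at_the_alpha_limit(self):
        assert required_sample_size(PowerSpec(0.3, 0.05, 0.05, sided=1)) == 4

    def test_monotone_in_spec_parameters(self):
        base = PowerSpec(0.3, 0.05, 0.8)
        n_base = required_sample_size(base)
        for r in (0.35, 0.5, 0.8):
            assert required_sample_size(PowerSpec(r, 0.05, 0.8)) <= n_base
        for alpha in (0.1, 0.2):
            assert required_sample_size(PowerSpec(0.3, alpha, 0.8)) <= n_base
        for power in (0.9, 0.95):
            assert required_sample_size(PowerSpec(0.3, 0.05, power)) >= n_base

    def test_power_increases_with_n(self):
        spec = PowerSpec(0.3, 0.05, 0.8)
        powers = [correlation_power(n, spec) for n in range(10, 200, 10)]
        assert np.all(np.diff(powers) > 0)

    @pytest.mark.parametrize("bad", [dict(r_min=1.0), dict(r_min=0.0),
                                     dict(alpha=0.0), dict(power=1.0)])
    def test_invalid_specs_rejected(self, bad):
        with pytest.raises(ConfigError):
            PowerSpec(**{**dict(r_min=0.3, alpha=0.05, power=0.8), **bad})
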