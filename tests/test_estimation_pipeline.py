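"""Propensity-to-punish recovery: realizations, median CI, KS, curve."""

import numpy as np
import pandas as pd
import pytest

from pggpunish import (
    PunishmentRecord,
    SyntheticSpec,
    alpha_realizations,
    attach_contributions,
    generate_experiment,
    ks_first_period_vs_all,
    median_se_ci,
    punishment_curve,
)


def rec(c_p, c_t, s, period=1, punisher="a", target="b"):
    return PunishmentRecord(
        session="x", period=period, group="g", punisher=punisher, target=target,
        c_punisher=c_p, c_target=c_t, expenditure=s,
    )


class TestAlphaRealizations:
    def test_basic_ratio(self):
        values, excluded = alpha_realizations([rec(20, 0, 5)])
        assert values.tolist() == [0.25]
        assert excluded.empty

    def test_zero_deviation_excluded(self):
        values, excluded = alpha_realizations([rec(10, 10, 2)])
        assert len(values) == 0
        assert excluded["reason"].tolist() == ["non-positive deviation"]

    def test_zero_expenditure_included_as_zero(self):
        values, _ = alpha_realizations([rec(15, 5, 0)])
        assert values.tolist() == [0.0]

    def test_zero_expenditure_sensitivity_switch(self):
        values, excluded = alpha_realizations(
            [rec(15, 5, 0), rec(15, 5, 2)], include_zero_expenditure=False
        )
        assert values.tolist() == [0.2]
        assert len(excluded) == 1

    def test_exclusion_accounting(self, rng):
        records = []
        for i in range(300):
            c_p, c_t = rng.integers(0, 21, 2)
            records.append(
                rec(float(c_p), float(c_t), float(rng.uniform(0, 3)),
                    punisher=f"p{i}", target=f"t{i}")
            )
        values, excluded = alpha_realizations(records)
        assert len(values) + len(excluded) == 300

    def test_malformed_record_raises_with_identity(self):
        with pytest.raises(ValueError, match="punisher and target"):
            rec(10, 5, 1, punisher="a", target="a")
        with pytest.raises(ValueError, match="negative"):
            rec(10, 5, -1)


class TestMedianSeCi:
    def test_even_sample_median(self):
        est = median_se_ci([0.1, 0.2, 0.3, 0.4], b_outer=200, b_inner=20, seed=0)
        assert est.median == pytest.approx(0.25)

    def test_constant_sample_degenerates(self):
        est = median_se_ci([0.25] * 30, b_outer=200, b_inner=20, seed=0)
        assert est.median == 0.25
        assert est.se_median == 0.0
        assert est.ci_low == est.ci_high == 0.25

    def test_interval_brackets_median(self, rng):
        vals = rng.normal(0.25, 0.08, 150)
        est = median_se_ci(vals, b_outer=400, b_inner=40, seed=5)
        assert est.ci_low <= est.median <= est.ci_high
        assert est.se_median > 0

    def test_deterministic_under_seed(self, rng):
        vals = rng.uniform(0, 0.5, 120)
        a = median_se_ci(vals, b_outer=300, b_inner=30, seed=9)
        b = median_se_ci(vals, b_outer=300, b_inner=30, seed=9)
        assert (a.median, a.se_median, a.ci_low, a.ci_high) == (
            b.median, b.se_median, b.ci_low, b.ci_high
        )

    def test_jackknife_studentization_variant_runs(self, rng):
        # the delete-one jackknife is offered as an alternative pivot; it
        # is known to be unstable for medians, so only its contract is
        # checked (interval brackets the median, deterministic under seed)
        vals = rng.normal(0.3, 0.1, 200)
        b = median_se_ci(vals, b_outer=600, seed=2, studentization="jackknife")
        b2 = median_se_ci(vals, b_outer=600, seed=2, studentization="jackknife")
        assert b.ci_low <= b.median <= b.ci_high
        assert (b.ci_low, b.ci_high) == (b2.ci_low, b2.ci_high)

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            median_se_ci([0.25])

    @pytest.mark.parametrize("alpha_true", [0.1, 0.25, 0.5])
    def test_parameter_recovery(self, alpha_true):
        """Generator slope recovered by the sample median within +-0.02 at
        roughly a thousand pairwise observations and mild noise."""
        spec = SyntheticSpec(
            n_subjects=40, periods=20, alpha_true=alpha_true, noise_sigma=0.5,
            seed=int(alpha_true * 1000),
        )
        contributions, punishments = generate_experiment(spec)
        values, _ = alpha_realizations(attach_contributions(contributions, punishments))
        assert len(values) >= 1000
        assert np.median(values) == pytest.approx(alpha_true, abs=0.02)


class TestKsStationarity:
    def _records(self, seed=0, periods=8):
        spec = SyntheticSpec(n_subjects=24, periods=periods, seed=seed)
        c, p = generate_experiment(spec)
        return attach_contributions(c, p)

    def test_identical_subsets_do_not_reject(self):
        df = self._records()
        single = df[df["period"] == 1]
        stat, p = ks_first_period_vs_all(single)  # "all" is period 1 itself
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_disjoint_supports_give_statistic_one(self):
        rows = [vars(rec(20, 10, 1.0, period=1, punisher=f"p{i}", target=f"t{i}"))
                for i in range(20)]
        rows += [vars(rec(20, 10, 8.0, period=2, punisher=f"q{i}", target=f"u{i}"))
                 for i in range(20)]
        df = pd.DataFrame(rows)
        first, _ = alpha_realizations(df[df["period"] == 1])
        rest, _ = alpha_realizations(df[df["period"] == 2])
        from scipy.stats import ks_2samp

        assert ks_2samp(first, rest).statistic == pytest.approx(1.0)

    def test_stationary_generator_rarely_rejects(self):
        rejections = sum(
            ks_first_period_vs_all(self._records(seed=100 + i))[1] < 0.05
            for i in range(25)
        )
        assert rejections <= 4  # ~5% nominal, conservative under overlap

    def test_empty_subset_rejected(self):
        df = self._records()
        with pytest.raises(ValueError):
            ks_first_period_vs_all(df[df["period"] > 1].assign(period=2))


class TestPunishmentCurve:
    def test_noiseless_linear_data_recovers_slope(self):
        records = [
            rec(c_p, c_t, 0.25 * (c_p - c_t), punisher=f"p{c_p}", target=f"t{c_t}")
            for c_p in range(1, 21)
            for c_t in range(0, c_p)
        ]
        curve, slope, hist = punishment_curve(records, bin_width=1.0)
        assert slope == pytest.approx(0.25)
        occupied = curve[curve["count"] > 0]
        centers = (occupied["bin_low"] + occupied["bin_high"]) / 2
        # all bin means sit on the line through the origin (bin centers up
        # to half-width discretization)
        np.testing.assert_allclose(
            occupied["mean_expenditure"], 0.25 * centers, atol=0.13
        )
        assert hist["relative_frequency"].sum() == pytest.approx(1.0)

    def test_single_record_has_undefined_se(self):
        curve, slope, _ = punishment_curve([rec(12, 4, 2.0)], bin_width=1.0)
        occupied = curve[curve["count"] > 0]
        assert len(occupied) == 1
        assert np.isnan(occupied["se_expenditure"].iloc[0])
        assert slope == pytest.approx(0.25)

    def test_empty_bins_reported_not_dropped(self):
        curve, _, _ = punishment_curve([rec(10, 0, 2.5), rec(3, 0, 0.75,
                                        punisher="c", target="d")])
        assert (curve["count"] == 0).any()
        assert len(curve) == 10

    def test_unbiased_under_symmetric_noise(self, rng):
        d = rng.uniform(1, 15, 4000)
        s = np.maximum(0.25 * d + rng.normal(0, 0.3, 4000), 0)
        df = pd.DataFrame({
            "session": "x", "period": 1, "group": "g",
            "punisher": [f"p{i}" for i in range(4000)],
            "target": [f"t{i}" for i in range(4000)],
            "c_punisher": 15.0, "c_target": 15.0 - d, "expenditure": s,
        })
        _, slope, _ = punishment_curve(df)
        assert slope == pytest.approx(0.25, abs=0.02)
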