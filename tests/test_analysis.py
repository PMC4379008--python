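"""Detection, rate summaries, latency, ANOVA and threshold estimators."""

import numpy as np
import pandas as pd
import pytest

from melstep.analysis import (
    RateEstimate,
    classify_responsive,
    delta_firing_rate,
    irradiance_tracking,
    isoluminance_scan,
    normalise_tbc,
    psth,
    response_latencies,
    rm_anova,
    threshold_irradiance,
    trial_bin_count,
    window_rates,
)


class TestPsth:
    def test_empty_trains_all_zero(self):
        est = psth([np.empty(0)] * 3, np.array([10.0]), (-5, 5), 0.5)
        assert np.all(est.rate == 0.0)

    def test_one_spike_per_trial_in_one_bin(self):
        # 10 trials, one spike 0.05 s after the event, 0.1-s bins -> 10 Hz
        trains = [np.array([100.05]) for _ in range(10)]
        est = psth(trains, np.array([100.0]), (-1.0, 1.0), 0.1)
        idx = int(np.argmin(np.abs(est.bin_centres - 0.05)))
        assert est.rate[idx] == pytest.approx(10.0)
        assert est.rate.sum() == pytest.approx(10.0)

    def test_regular_train_flat_at_rate(self):
        train = np.arange(0.005, 100.0, 0.1)  # exact 10 Hz
        est = psth([train], np.array([50.0]), (-10.0, 10.0), 1.0)
        np.testing.assert_allclose(est.rate, 10.0)


class TestTrialBinCount:
    def test_constant_rate_counts(self):
        trains = [np.arange(0.125, 100.0, 0.25)]  # 4 Hz, off bin edges
        mat, centres = trial_bin_count(trains, np.array([50.0]), (-20.0, 20.0), 5.0)
        np.testing.assert_allclose(mat, 4.0)
        assert centres.size == 8

    def test_normalisation_peak_one_and_zero_flag(self):
        mat = np.array([[1.0, 2.0], [0.5, 4.0]])
        norm, zero = normalise_tbc(mat)
        assert norm.max() == 1.0 and not zero
        norm0, zero0 = normalise_tbc(np.zeros((2, 2)))
        assert zero0 and np.all(norm0 == 0.0)

    def test_stepper_bins_exceed_baseline_bins(self):
        rng = np.random.default_rng(4)
        base = rng.uniform(0.0, 30.0, 60)  # ~2 Hz over 30 s baseline
        step = 30.0 + rng.uniform(0.0, 30.0, 300)  # ~10 Hz during step
        mat, centres = trial_bin_count([np.sort(np.r_[base, step])], np.array([30.0]), (-30.0, 30.0), 5.0)
        assert mat[0, centres > 0].mean() > mat[0, centres < 0].mean()


class TestClassifyResponsive:
    def test_identical_rates_not_responsive(self):
        r = np.array([5.0, 4.0, 6.0, 5.0])
        p, responsive = classify_responsive(r, r)
        assert p == 1.0 and not responsive

    def test_consistent_shift_detected(self):
        base = np.array([5.0, 4.8, 5.2, 5.1, 4.9, 5.0])
        p, responsive = classify_responsive(base, base + 2.0)
        assert responsive and p < 0.001

    def test_zero_variance_nonzero_shift_convention(self):
        base = np.full(5, 5.0)
        p, responsive = classify_responsive(base, base + 1.0)
        assert p == 0.0 and responsive

    def test_planted_effect_detected_at_reported_scale(self):
        # delta 2 Hz on a 5-Hz baseline, 14 trials of 30-s windows
        rng = np.random.default_rng(0)
        base = rng.poisson(5.0 * 30, 14) / 30.0
        step = rng.poisson(7.0 * 30, 14) / 30.0
        p, responsive = classify_responsive(base, step)
        assert responsive


class TestDeltaFiringRate:
    def test_zero_for_equal_windows(self):
        r = np.array([3.0, 4.0])
        assert delta_firing_rate(r, r) == 0.0

    def test_sign_flips_when_windows_swapped(self):
        a, b = np.array([3.0, 4.0]), np.array([5.0, 7.0])
        assert delta_firing_rate(a, b) == -delta_firing_rate(b, a) == 2.5

    def test_recovers_planted_delta_within_se(self):
        rng = np.random.default_rng(1)
        base = rng.poisson(5.0 * 30, 200) / 30.0
        step = rng.poisson(6.5 * 30, 200) / 30.0
        se = np.sqrt(5.0 / 30 / 200 + 6.5 / 30 / 200)
        assert delta_firing_rate(base, step) == pytest.approx(1.5, abs=3 * se)


def alternating_baseline(n, mean, amp):
    return mean + amp * np.where(np.arange(n) % 2 == 0, 1.0, -1.0)


class TestResponseLatencies:
    def make_estimate(self, rate, bin_s=0.1, t0=-30.0):
        centres = t0 + bin_s / 2 + bin_s * np.arange(rate.size)
        return RateEstimate(centres, rate, np.zeros_like(rate), bin_s)

    def test_constructed_crossing_at_two_seconds(self):
        base = alternating_baseline(300, 5.0, 1.0)
        post = np.full(600, 5.0)
        post[int(2.0 / 0.1) :] = 12.0  # jumps above threshold at onset + 2 s
        est = self.make_estimate(np.r_[base, post])
        res = response_latencies(est, (-30.0, 0.0), 0.0, 30.0)
        assert res.onset_s == pytest.approx(2.0, abs=0.1)

    def test_no_onset_crossing_reported_as_none(self):
        base = alternating_baseline(300, 5.0, 1.0)
        est = self.make_estimate(np.r_[base, np.full(600, 5.0)])
        res = response_latencies(est, (-30.0, 0.0), 0.0, 30.0)
        assert res.onset_s is None

    def test_no_offset_return_reported_as_none(self):
        # rate rises and never comes back below the threshold line
        base = alternating_baseline(300, 5.0, 1.0)
        est = self.make_estimate(np.r_[base, np.full(600, 12.0)])
        res = response_latencies(est, (-30.0, 0.0), 0.0, 30.0)
        assert res.onset_s is not None and res.offset_s is None

    def test_degenerate_zero_sd_flagged(self):
        base = np.full(300, 5.0)
        post = np.full(600, 5.0)
        post[50:] = 9.0
        est = self.make_estimate(np.r_[base, post])
        res = response_latencies(est, (-30.0, 0.0), 0.0, 30.0)
        assert res.degenerate_threshold
        assert res.onset_s == pytest.approx(5.0, abs=0.1)

    def test_first_order_filter_crossing_matches_closed_form(self):
        # rising exponential of known gain/tau against a known threshold line
        bin_s, tau_on, tau_off, gain, base_hz, amp = 0.1, 6.0, 20.0, 2.0, 5.0, 0.8
        n_base, n_step, n_post = 300, 300, 1200
        t_step = bin_s * np.arange(n_step) + bin_s / 2
        t_post = bin_s * np.arange(n_post) + bin_s / 2
        rise = gain * (1 - np.exp(-t_step / tau_on))
        peak = gain * (1 - np.exp(-n_step * bin_s / tau_on))
        rate = np.r_[
            alternating_baseline(n_base, base_hz, amp),
            base_hz + rise,
            base_hz + peak * np.exp(-t_post / tau_off),
        ]
        est = self.make_estimate(rate)
        res = response_latencies(est, (-30.0, 0.0), 0.0, 30.0)
        sd = np.std(alternating_baseline(n_base, base_hz, amp), ddof=1)
        t_on_true = -tau_on * np.log(1 - sd / gain)
        t_off_true = tau_off * np.log(peak / sd)
        assert res.onset_s == pytest.approx(t_on_true, abs=bin_s)
        assert res.offset_s == pytest.approx(t_off_true, abs=bin_s)

    def test_baseline_must_precede_onset(self):
        est = self.make_estimate(np.zeros(900))
        with pytest.raises(ValueError):
            response_latencies(est, (0.0, 10.0), 5.0, 30.0)


def anova_oracle(df):
    """Independent two-way repeated-measures sums-of-squares computation."""
    subs = sorted(df["unit"].unique())
    phases = sorted(df["phase"].unique())
    conds = sorted(df["condition"].unique())
    y = {
        (r.unit, r.phase, r.condition): r.rate for r in df.itertuples()
    }
    ns, na, nb = len(subs), len(phases), len(conds)
    grand = np.mean(list(y.values()))
    m_a = {a: np.mean([y[s, a, b] for s in subs for b in conds]) for a in phases}
    m_b = {b: np.mean([y[s, a, b] for s in subs for a in phases]) for b in conds}
    m_s = {s: np.mean([y[s, a, b] for a in phases for b in conds]) for s in subs}
    m_ab = {(a, b): np.mean([y[s, a, b] for s in subs]) for a in phases for b in conds}
    m_as = {(a, s): np.mean([y[s, a, b] for b in conds]) for a in phases for s in subs}
    m_bs = {(b, s): np.mean([y[s, a, b] for a in phases]) for b in conds for s in subs}

    ss_a = ns * nb * sum((m_a[a] - grand) ** 2 for a in phases)
    ss_b = ns * na * sum((m_b[b] - grand) ** 2 for b in conds)
    ss_ab = ns * sum(
        (m_ab[a, b] - m_a[a] - m_b[b] + grand) ** 2 for a in phases for b in conds
    )
    ss_as = nb * sum(
        (m_as[a, s] - m_a[a] - m_s[s] + grand) ** 2 for a in phases for s in subs
    )
    ss_bs = na * sum(
        (m_bs[b, s] - m_b[b] - m_s[s] + grand) ** 2 for b in conds for s in subs
    )
    ss_abs = sum(
        (
            y[s, a, b]
            - m_ab[a, b]
            - m_as[a, s]
            - m_bs[b, s]
            + m_a[a]
            + m_b[b]
            + m_s[s]
            - grand
        )
        ** 2
        for s in subs
        for a in phases
        for b in conds
    )
    f_a = (ss_a / (na - 1)) / (ss_as / ((na - 1) * (ns - 1)))
    f_b = (ss_b / (nb - 1)) / (ss_bs / ((nb - 1) * (ns - 1)))
    f_ab = (ss_ab / ((na - 1) * (nb - 1))) / (ss_abs / ((na - 1) * (nb - 1) * (ns - 1)))
    return f_a, f_b, f_ab


TOY_TABLE = pd.DataFrame(
    [
        # unit, phase, condition, rate
        (1, "base", "c1", 4.0),
        (1, "step", "c1", 6.5),
        (1, "base", "c2", 4.2),
        (1, "step", "c2", 5.4),
        (2, "base", "c1", 5.1),
        (2, "step", "c1", 7.9),
        (2, "base", "c2", 5.0),
        (2, "step", "c2", 6.1),
        (3, "base", "c1", 3.6),
        (3, "step", "c1", 6.0),
        (3, "base", "c2", 3.9),
        (3, "step", "c2", 5.2),
    ],
    columns=["unit", "phase", "condition", "rate"],
)


class TestRmAnova:
    def test_matches_hand_computed_sums_of_squares(self):
        res = rm_anova(TOY_TABLE)
        f_a, f_b, f_ab = anova_oracle(TOY_TABLE)
        assert res.f("phase") == pytest.approx(f_a, abs=1e-10)
        assert res.f("condition") == pytest.approx(f_b, abs=1e-10)
        assert res.f("phase:condition") == pytest.approx(f_ab, abs=1e-10)

    def test_invariant_to_additive_constant(self):
        shifted = TOY_TABLE.assign(rate=TOY_TABLE["rate"] + 100.0)
        a, b = rm_anova(TOY_TABLE), rm_anova(shifted)
        for effect in ("phase", "condition", "phase:condition"):
            assert a.f(effect) == pytest.approx(b.f(effect), rel=1e-9)

    def test_bonferroni_multiplies_by_comparison_count_capped(self):
        res = rm_anova(TOY_TABLE)
        for cond in ("c1", "c2"):
            row = res.posthoc.loc[cond]
            assert row["p_bonferroni"] == pytest.approx(min(1.0, 2.0 * row["p_raw"]))

    def test_incomplete_table_rejected(self):
        with pytest.raises(ValueError, match="balanced|cell"):
            rm_anova(TOY_TABLE.iloc[:-1])


class TestIsoluminanceScan:
    def test_v_shaped_profile_returns_middle(self):
        rng = np.random.default_rng(2)
        resp = {}
        for label, amp in [("g0.8", 4.0), ("g0.9", 2.0), ("g1.0", 0.0), ("g1.1", 2.0), ("g1.2", 4.0)]:
            bg = rng.normal(5.0, 1.0, 100)
            resp[label] = (bg, bg + amp + rng.normal(0.0, 0.5, 100))
        res = isoluminance_scan(resp)
        assert res.null_setting == "g1.0" and not res.excluded

    def test_significant_everywhere_is_excluded(self):
        rng = np.random.default_rng(3)
        resp = {}
        for label in ("a", "b", "c"):
            bg = rng.normal(5.0, 0.5, 100)
            resp[label] = (bg, bg + 3.0)
        res = isoluminance_scan(resp)
        assert res.excluded and res.null_setting is None


class TestIrradianceTracking:
    def test_monotone_rate_is_tracker(self):
        flux = np.linspace(10.5, 14.5, 9)
        tracker, rho, p, slope = irradiance_tracking(1.0 + 0.8 * flux, flux)
        assert tracker and slope > 0 and p < 0.05

    def test_flat_rate_is_not(self):
        flux = np.linspace(10.5, 14.5, 9)
        tracker, *_ = irradiance_tracking(np.full(9, 5.0), flux)
        assert not tracker

    def test_decreasing_rate_is_not_tracker(self):
        flux = np.linspace(10.5, 14.5, 9)
        tracker, rho, _, slope = irradiance_tracking(20.0 - flux, flux)
        assert not tracker and slope < 0


class TestThresholdIrradiance:
    def test_planted_threshold_recovered(self):
        rng = np.random.default_rng(5)
        levels = {}
        for log_f in (11.1, 11.6, 12.1, 12.6, 13.1):
            base = rng.normal(5.0, 0.3, 60)
            delta = 1.5 if log_f >= 12.1 else 0.0
            levels[log_f] = (base, base + delta + rng.normal(0, 0.3, 60))
        thr, table = threshold_irradiance(levels)
        assert thr == pytest.approx(12.1)
        assert not table.loc[11.6, "significant"]

    def test_no_response_anywhere_undefined(self):
        rng = np.random.default_rng(6)
        levels = {
            f: (rng.normal(5, 0.3, 40), rng.normal(5, 0.3, 40)) for f in (11.0, 12.0, 13.0)
        }
        thr, _ = threshold_irradiance(levels)
        assert thr is None


class TestWindowRates:
    def test_counts_in_windows(self):
        train = np.array([9.5, 10.2, 10.4, 11.9, 25.0])
        rates = window_rates([train], np.array([10.0]), (0.0, 2.0))
        assert rates[0] == pytest.approx(3 / 2.0)
        rates_pre = window_rates([train], np.array([10.0]), (-2.0, 0.0))
        assert rates_pre[0] == pytest.approx(1 / 2.0)
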