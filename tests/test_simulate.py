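"""Synthetic unit rate models, preparations and Poisson spiking."""

import numpy as np
import pytest
from scipy import stats

from melstep.protocols import StimulusTrace, build_flicker, build_protocol1, build_protocol2, render_trace
from melstep.simulate import (
    PopulationSpec,
    allocate_classes,
    apply_prep,
    make_population,
    make_unit_params,
    mel_drive,
    rod_drive,
    sample_spikes,
    simulate_dataset,
    unit_rate,
)


def flat_trace(mel_log, dt=0.1, rod_flux=1.0e14):
    """Hand-built trace with piecewise-constant melanopsin flux, constant rod."""
    mel = 10.0 ** np.asarray(mel_log, dtype=float)
    n = mel.size
    return StimulusTrace(
        times=dt * np.arange(n),
        dt=dt,
        fluxes={"melanopsin": mel, "rod": np.full(n, rod_flux)},
        nd=np.zeros(n),
        epoch_index=np.zeros(n, dtype=int),
        labels=("flat",),
        kinds=("background",),
    )


class TestMelDrive:
    def test_subthreshold_flux_gives_zero_drive(self):
        p = make_unit_params("mel_stepper", "cnga3_retina")
        trace = flat_trace(np.full(2000, 11.5))  # below the 12.0 log threshold
        assert np.all(mel_drive(trace, p) == 0.0)

    def test_step_asymptote_matches_first_order_closed_form(self):
        # 14.04 -> 14.30 step with adaptation frozen: asymptotic increment
        # above the pre-step drive is mel_gain * 0.26
        p = make_unit_params("mel_stepper", "cnga3_retina")  # adapt_gain 0
        x = np.concatenate([np.full(1000, 14.04), np.full(6000, 14.30)])
        d = mel_drive(flat_trace(x), p)
        pre = d[999]
        assert pre == pytest.approx(p.mel_gain * (14.04 - p.mel_threshold_log), rel=1e-6)
        assert d[-1] - pre == pytest.approx(p.mel_gain * 0.26, rel=1e-3)

    def test_rise_time_constant_is_tau_on(self):
        p = make_unit_params("mel_stepper", "cnga3_retina")
        x = np.concatenate([np.full(1000, 14.04), np.full(6000, 14.30)])
        trace = flat_trace(x)
        d = mel_drive(trace, p)
        pre = d[999]
        target = pre + (1 - np.exp(-1)) * p.mel_gain * 0.26
        t_cross = trace.times[999 + np.argmax(d[999:] >= target)] - trace.times[1000]
        assert t_cross == pytest.approx(p.mel_tau_on_s, abs=2 * trace.dt)

    def test_offset_decay_slower_than_onset(self):
        p = make_unit_params("mel_stepper", "cnga3_retina")
        x = np.concatenate([np.full(1000, 12.0), np.full(300, 14.3), np.full(3000, 12.0)])
        d = mel_drive(flat_trace(x), p)
        peak = d[1299]
        rise_t = np.argmax(d[1000:1300] >= 0.5 * peak)
        fall_t = np.argmax(d[1300:] <= 0.5 * peak)
        assert fall_t > rise_t


class TestRodDrive:
    def test_rod_silent_step_gives_exactly_zero(self, device, pair71):
        proto = build_protocol1([pair71], repeats=2, adaptation_s=30.0, isi_s=30.0)
        trace = render_trace(proto, 0.1, device)
        p = make_unit_params("rod_only")
        assert np.all(rod_drive(trace, p) == 0.0)

    @pytest.mark.parametrize("protocol_kind", ["flicker", "step"])
    def test_contrast_threshold_separates_4_from_15_percent(
        self, device, rod_bg, protocol_kind
    ):
        p = make_unit_params("rod_only")  # rod_contrast_threshold 0.10
        peaks = {}
        for target in (0.04, 0.15, 0.30):
            [pair] = device.rod_contrast_control(rod_bg, [target])
            if protocol_kind == "flicker":
                proto = build_flicker(50.0, 200.0, 40, pair)
                dt = 0.01
            else:
                proto = build_protocol1([pair], repeats=1, adaptation_s=30.0, isi_s=30.0)
                dt = 0.1
            drive = rod_drive(render_trace(proto, dt, device), p)
            peaks[target] = drive.max()
        assert peaks[0.04] == 0.0
        assert peaks[0.15] > 0.0
        assert peaks[0.30] > peaks[0.15]

    def test_peak_linear_in_rod_gain(self, device, rod_bg):
        [pair] = device.rod_contrast_control(rod_bg, [0.30])
        proto = build_protocol1([pair], repeats=1, adaptation_s=30.0, isi_s=30.0)
        trace = render_trace(proto, 0.1, device)
        p1 = make_unit_params("rod_only")
        p2 = make_unit_params("rod_only", rod_gain=2 * p1.rod_gain)
        assert rod_drive(trace, p2).max() == pytest.approx(2 * rod_drive(trace, p1).max(), rel=1e-9)


class TestApplyPrep:
    def test_blockade_silences_rod_only_unit(self, device, rod_bg):
        [pair] = device.rod_contrast_control(rod_bg, [0.30])
        proto = build_protocol1([pair], repeats=1, adaptation_s=30.0, isi_s=30.0)
        trace = render_trace(proto, 0.1, device)
        p = apply_prep(make_unit_params("rod_only"), "blockade")
        rate = unit_rate(trace, p)
        assert np.all(rate == rate[0])  # baseline only

    def test_blockade_slows_kinetics_and_lowers_baseline(self):
        pre = make_unit_params("mel_stepper", "cnga3_retina")
        post = apply_prep(pre, "blockade")
        assert post.mel_tau_on_s > pre.mel_tau_on_s
        assert post.mel_tau_off_s > pre.mel_tau_off_s
        assert post.baseline_hz < pre.baseline_hz

    def test_rdcl_is_slow_and_unreliable(self):
        p = apply_prep(make_unit_params("mel_stepper", "cnga3_retina"), "rdcl_retina")
        assert p.rod_gain == 0.0
        assert p.mel_tau_off_s == 50.0
        assert p.reliability_p == 0.6

    def test_idempotent(self):
        p = make_unit_params("mel_stepper", "cnga3_retina")
        once = apply_prep(p, "blockade")
        assert apply_prep(once, "blockade") == once


class TestSampleSpikes:
    def test_zero_rate_empty_train(self):
        assert sample_spikes(np.zeros(100), 0.1, 0).size == 0

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            sample_spikes(np.array([1.0, -1.0]), 0.1, 0)

    def test_same_seed_identical_train(self):
        rate = np.full(1000, 8.0)
        np.testing.assert_array_equal(sample_spikes(rate, 0.1, 11), sample_spikes(rate, 0.1, 11))
        assert sample_spikes(rate, 0.1, 12).size != 0

    def test_poisson_mean_over_seeds(self):
        # 10 Hz for 100 s: mean count over 200 seeds within 3 SE of 1000
        rate = np.full(1000, 10.0)
        counts = [sample_spikes(rate, 0.1, s).size for s in range(200)]
        se = np.sqrt(1000.0 / 200)
        assert abs(np.mean(counts) - 1000.0) < 3 * se

    def test_time_rescaled_isis_are_exponential(self):
        # inhomogeneous rate; rescaled intervals must be Exp(1) (KS, fixed seed)
        rate = np.concatenate([np.full(5000, 7.0), np.full(5000, 12.0), np.full(5000, 4.0)])
        tt = sample_spikes(rate, 0.1, 5)
        cum = np.concatenate([[0.0], np.cumsum(rate) * 0.1])
        rescaled = np.interp(tt, 0.1 * np.arange(rate.size + 1), cum)
        p = stats.kstest(np.diff(rescaled), "expon").pvalue
        assert p > 0.01


class TestSimulateDataset:
    def test_largest_remainder_class_allocation(self):
        spec = PopulationSpec(n_units=100, seed=0)
        labels = allocate_classes(spec)
        assert labels.count("mel_stepper") == 28
        assert labels.count("irradiance_tracker") == 17
        assert labels.count("rod_only") == 35
        assert labels.count("null") == 20

    def test_null_units_fire_at_baseline_everywhere(self, device, pair71):
        proto = build_protocol1([pair71], repeats=1, adaptation_s=30.0, isi_s=30.0)
        trace = render_trace(proto, 0.1, device)
        p = make_unit_params("null")
        rate = unit_rate(trace, p)
        assert np.all(rate == p.baseline_hz)

    def test_stepper_delta_matches_analytic_rate(self, device, pair71):
        # noiseless drive during a 30-s step vs the first-order filter's
        # window-averaged closed form, adaptation quasi-frozen
        proto = build_protocol1([pair71], repeats=1, adaptation_s=300.0, isi_s=60.0)
        trace = render_trace(proto, 0.1, device)
        p = make_unit_params("mel_stepper", "cnga3_retina")
        d = mel_drive(trace, p)
        ep = proto.epochs_of_kind("step")[0]
        sel = (trace.times >= ep.t_start) & (trace.times < ep.t_end)
        before = (trace.times >= ep.t_start - 30) & (trace.times < ep.t_start)
        delta = d[sel].mean() - d[before].mean()
        dlog = np.log10((1 + 0.71) / (1 - 0.71))
        tau = p.mel_tau_on_s
        expected = p.mel_gain * dlog * (1 - tau / 30.0 * (1 - np.exp(-30.0 / tau)))
        assert delta == pytest.approx(expected, rel=0.02)

    def test_ground_truth_stored_and_reproducible(self, device, pair71):
        proto = build_protocol1([pair71], repeats=2, adaptation_s=30.0, isi_s=30.0)
        spec = PopulationSpec(n_units=10, seed=5)
        a = simulate_dataset(proto, spec, device)
        b = simulate_dataset(proto, spec, device)
        assert set(a.params) == set(range(10))
        for uid in a.unit_ids:
            np.testing.assert_array_equal(a.spikes[uid][0], b.spikes[uid][0])
            assert a.params[uid] == b.params[uid]

    def test_unreliable_units_skip_some_trials(self, device, pair71):
        proto = build_protocol1([pair71], repeats=8, adaptation_s=30.0, isi_s=30.0)
        spec = PopulationSpec(
            n_units=4,
            class_fractions={"mel_stepper": 1.0, "irradiance_tracker": 0.0, "rod_only": 0.0, "null": 0.0},
            prep="rdcl_retina",
            seed=3,
        )
        ds = simulate_dataset(proto, spec, device)
        assert all(p.reliability_p == 0.6 for p in ds.params.values())


class TestAdaptationShift:
    def test_threshold_shift_increases_with_adapt_gain(self, device, pair_at, level_log):
        # noiseless drives; effective threshold = interpolated log flux where
        # the per-level step delta crosses a fixed 0.3-Hz criterion
        proto = build_protocol2(pair_at)
        trace = render_trace(proto, 0.2, device)

        def arm_threshold_of(drive, arm):
            levels = []
            for ep in proto.epochs_of_kind("step"):
                if f"arm={arm}" not in ep.label:
                    continue
                nd = float(ep.label.split("|")[0].split("=")[1])
                sel = (trace.times >= ep.t_start) & (trace.times < ep.t_end)
                before = (trace.times >= ep.t_start - 10) & (trace.times < ep.t_start)
                levels.append((level_log(nd), drive[sel].mean() - drive[before].mean()))
            levels.sort()
            crit = 0.3
            for (x0, d0), (x1, d1) in zip(levels, levels[1:]):
                if d0 < crit <= d1:
                    return x0 + (crit - d0) / (d1 - d0) * (x1 - x0)
            raise AssertionError("criterion never crossed")

        shifts = []
        for gain in (0.2, 0.4, 0.6):
            p = make_unit_params("mel_stepper", "cnga3_dlgn", adapt_gain=gain)
            d = mel_drive(trace, p)
            shifts.append(arm_threshold_of(d, "down") - arm_threshold_of(d, "up"))
        assert shifts[0] > 0.0
        assert shifts[0] < shifts[1] < shifts[2]
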