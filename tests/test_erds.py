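import numpy as np
import pytest

from vqent.core_io import TrialSet
from vqent.embedding_entropy import EntropyParams
from vqent.erds import entropy_erds, plan_windows, power_erds

RATE = 250.0


def noise_trials(rng, n=4, c=2, dur=4.0, scale=1.0):
    data = scale * rng.standard_normal((n, c, int(dur * RATE)))
    if dur > 3.5:
        mi, ref = (2.0, 3.5), (0.5, 1.5)
    else:
        mi, ref = (0.55 * dur, 0.9 * dur), (0.1 * dur, 0.4 * dur)
    return TrialSet(
        trials=data,
        labels=(("left", "right") * ((n + 1) // 2))[:n],
        sample_interval=1.0 / RATE,
        channel_names=tuple(f"ch{i}" for i in range(c)),
        mi_window=mi,
        reference_window=ref,
    )


class TestPlanWindows:
    def test_one_second_windows_90_percent_overlap(self):
        plan = plan_windows(2.0, 1.0, 0.9, RATE)
        assert plan.n_tau == 250
        assert plan.n_windows == 11
        np.testing.assert_array_equal(plan.starts, np.arange(0, 251, 25))
        assert (np.diff(plan.centers) > 0).all()

    def test_zero_overlap_tiles(self):
        plan = plan_windows(2.0, 1.0, 0.0, RATE)
        assert plan.n_windows == 2

    def test_window_equals_segment(self):
        plan = plan_windows(2.0, 2.0, 0.9, RATE)
        assert plan.n_windows == 1

    def test_window_longer_than_segment_rejected(self):
        with pytest.raises(ValueError):
            plan_windows(1.0, 2.0, 0.9, RATE)


class TestPowerErds:
    def test_stationary_signal_flat_zero(self, rng):
        ts = noise_trials(rng, n=40)
        course = power_erds(ts)
        t = course.time_axis
        mi = (t >= 2.0) & (t < 3.5)
        assert abs(course.values[:, mi].mean()) < 0.1

    def test_half_power_gives_minus_half(self, rng):
        ts = noise_trials(rng, n=60)
        data = ts.trials.copy()
        t = np.arange(data.shape[2]) / RATE
        mi = (t >= 2.0) & (t < 3.5)
        data[:, :, mi] *= np.sqrt(0.5)
        from dataclasses import replace

        ts = replace(ts, trials=data)
        course = power_erds(ts)
        assert course.values[:, mi].mean() == pytest.approx(-0.5, abs=0.05)

    def test_scale_invariance(self, rng):
        ts = noise_trials(rng)
        from dataclasses import replace

        scaled = replace(ts, trials=42.0 * ts.trials)
        np.testing.assert_allclose(
            power_erds(scaled).values, power_erds(ts).values, rtol=1e-9
        )

    def test_zero_reference_rejected(self):
        ts = TrialSet(
            trials=np.zeros((2, 1, 1000)),
            labels=("left", "right"),
            sample_interval=1.0 / RATE,
            channel_names=("a",),
            mi_window=(2.0, 3.5),
            reference_window=(0.5, 1.5),
        )
        with pytest.raises(ValueError, match="reference"):
            power_erds(ts)

    def test_programmed_erd_depth_recovered(self):
        """Generator with 60% amplitude suppression: the mu-band power
        ratio on the contralateral channel recovers (1-0.6)^2 - 1."""
        from vqent.preprocess import FilterSpec, bandpass
        from vqent.synthdata import SynthSpec, generate, ground_truth

        spec = SynthSpec(
            n_trials_per_class=25, n_channels=4, erd_depth=0.6, snr=15.0,
            mixing_strength=0.0, seed=7,
        )
        ts = bandpass(generate(spec), FilterSpec(band=(8.0, 13.0)))
        labels = ts.label_array()
        for effect in ground_truth(spec):
            sel = labels == effect["class"]
            from dataclasses import replace

            sub = replace(
                ts, trials=ts.trials[sel], labels=tuple(labels[sel])
            )
            course = power_erds(sub)
            p0, p1 = effect["plateau"]
            m = (course.time_axis >= p0) & (course.time_axis < p1)
            zeta = course.channel(effect["channel"])[m].mean()
            assert zeta == pytest.approx(effect["power_ratio"], abs=0.05)


class TestEntropyErds:
    def test_constant_trials_zero_course(self):
        ts = TrialSet(
            trials=np.full((3, 2, 1000), 5.0),
            labels=("left", "right", "left"),
            sample_interval=1.0 / RATE,
            channel_names=("a", "b"),
            mi_window=(2.0, 3.5),
            reference_window=(0.5, 1.5),
        )
        plan = plan_windows(ts.duration, 1.0, 0.9, RATE)
        course = entropy_erds(ts, plan, EntropyParams(M=2, rho=0.3, estimator="sampen"))
        np.testing.assert_array_equal(course.values, 0.0)

    def test_white_noise_flat_at_analytic_level(self, rng):
        from scipy.special import erf

        ts = noise_trials(rng, n=8, c=1, dur=3.0)
        plan = plan_windows(3.0, 2.0, 0.5, RATE)
        course = entropy_erds(
            ts, plan, EntropyParams(M=2, rho=0.2, estimator="sampen"),
            tolerance_scope="window",
        )
        assert course.values.mean() == pytest.approx(-np.log(erf(0.1)), abs=0.15)

    def test_average_equals_mean_of_per_trial(self, rng):
        ts = noise_trials(rng, n=6, c=2, dur=2.0)
        plan = plan_windows(2.0, 1.0, 0.5, RATE)
        course = entropy_erds(ts, plan, EntropyParams(M=2, rho=0.3, estimator="fuzzyen"))
        np.testing.assert_allclose(
            course.values, np.nanmean(course.per_trial, axis=0), atol=1e-12
        )

    def test_channel_subset(self, rng):
        ts = noise_trials(rng, n=4, c=3, dur=2.0)
        plan = plan_windows(2.0, 1.0, 0.5, RATE)
        params = EntropyParams(M=2, rho=0.3, estimator="sampen")
        sub = entropy_erds(ts, plan, params, channels=["ch2"])
        full = entropy_erds(ts, plan, params)
        np.testing.assert_allclose(sub.values[0], full.values[2])

    def test_contralateral_dip_all_estimators(self):
        """The entropy course on the contralateral channel dips inside
        the MI interval while the ipsilateral course stays high."""
        from vqent.preprocess import FilterSpec, bandpass
        from vqent.synthdata import SynthSpec, generate

        spec = SynthSpec(n_trials_per_class=12, n_channels=2, seed=5)
        ts = bandpass(generate(spec), FilterSpec())
        labels = ts.label_array()
        plan = plan_windows(ts.duration, 1.0, 0.9, ts.rate)
        for estimator in ("sampen", "fuzzyen", "vqent"):
            course = entropy_erds(
                ts, plan, EntropyParams(M=2, rho=0.3, estimator=estimator)
            )
            t = course.time_axis
            mi = (t >= 2.5) & (t < 4.5)
            base = (t >= 0.5) & (t < 1.5)
            per = course.per_trial
            c3, c4 = ts.channel_index("C3"), ts.channel_index("C4")
            contra = np.where(labels == "right", c3, c4)
            ipsi = np.where(labels == "right", c4, c3)
            idx = np.arange(ts.n_trials)
            contra_mi = np.nanmean(per[idx, contra][:, mi])
            contra_base = np.nanmean(per[idx, contra][:, base])
            ipsi_mi = np.nanmean(per[idx, ipsi][:, mi])
            assert contra_mi < contra_base, estimator
            assert contra_mi < ipsi_mi, estimator
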