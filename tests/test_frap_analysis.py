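"""Recovery-fit correctness: phase handling, averaging, combined and
two-step fits, independent grid-search oracle."""

import math

import numpy as np
import pytest

from ssb_recycling.traces import IntensityTrace
from ssb_recycling import frap_analysis as fa


def make_eq1_trace(a=0.3, tau_b=9.5, I0=1.0, tau=10.0, t_end=60.0, dt=0.5,
                   noise_sd=0.0, seed=0):
    t = np.arange(0.0, t_end, dt)
    I = a * np.exp(-t / tau_b) + I0 * (1.0 - np.exp(-t / tau))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        I = I + rng.normal(0.0, noise_sd, size=len(t))
    return IntensityTrace(t=t, I=I, spot_id="synthetic")


class TestExtractRecoveryPhases:
    def test_three_pulses_give_three_zeroed_phases(self):
        t = np.arange(0.0, 90.0, 0.5)
        I = np.ones_like(t)
        for tp in (10.0, 40.0, 70.0):
            mask = t >= tp
            I[mask] = 1.0 - np.exp(-(t[mask] - tp) / 8.0)
        trace = IntensityTrace(t=t, I=I, pulse_times=[10.0, 40.0, 70.0])
        phases = fa.extract_recovery_phases(trace)
        assert len(phases) == 3
        for p in phases:
            assert p.t[0] == pytest.approx(0.0)
            assert p.I[0] == pytest.approx(0.0, abs=1e-9)

    def test_pulse_at_last_frame_dropped_with_warning(self):
        t = np.arange(0.0, 20.0, 0.5)
        trace = IntensityTrace(t=t, I=np.ones_like(t), pulse_times=[5.0, t[-1]])
        with pytest.warns(UserWarning, match="empty recovery phase"):
            phases = fa.extract_recovery_phases(trace)
        assert len(phases) == 1

    def test_detection_agrees_with_metadata(self):
        """Detected pulse frames equal the known ground-truth pulse frames
        on synthetic traces with >80% drops."""
        rng = np.random.default_rng(42)
        for trial in range(20):
            pulses = [10.0, 40.0]
            t = np.arange(0.0, 70.0, 0.5)
            I = np.ones_like(t)
            for tp in pulses:
                mask = t >= tp
                I[mask] = 1.0 - np.exp(-(t[mask] - tp) / 6.0)
            I = np.clip(I + rng.normal(0, 0.02, len(t)), 0.0, None)
            trace = IntensityTrace(t=t, I=I)  # no metadata
            detected = fa.extract_recovery_phases(trace)
            with_meta = fa.extract_recovery_phases(
                IntensityTrace(t=t, I=I, pulse_times=pulses)
            )
            assert len(detected) == len(with_meta)
            for d, m in zip(detected, with_meta):
                assert abs(len(d) - len(m)) <= 1

    def test_no_pulse_raises_with_candidates(self):
        t = np.arange(0.0, 20.0, 0.5)
        trace = IntensityTrace(t=t, I=np.ones_like(t))
        with pytest.raises(ValueError, match="candidate"):
            fa.extract_recovery_phases(trace)


class TestAverageTraces:
    def test_identical_phases_average_to_themselves(self):
        p = make_eq1_trace()
        mean, sem = fa.average_traces([p, p, p])
        assert np.allclose(mean.I, p.I)
        assert np.allclose(sem, 0.0)

    def test_two_constant_traces_average_to_midpoint(self):
        t = np.arange(0.0, 10.0, 0.5)
        a = IntensityTrace(t=t, I=np.zeros_like(t))
        b = IntensityTrace(t=t, I=np.full_like(t, 2.0))
        mean, _ = fa.average_traces([a, b])
        assert np.allclose(mean.I, 1.0)

    def test_mean_of_many_noisy_phases_matches_expectation(self):
        """Law of large numbers: the pointwise mean of many noisy phases
        stays within 3 SEM of the noise-free expectation everywhere."""
        rng = np.random.default_rng(7)
        t = np.arange(0.0, 30.0, 0.5)
        expectation = 1.0 - np.exp(-t / 5.0)
        phases = [
            IntensityTrace(t=t, I=expectation + rng.normal(0, 0.2, len(t)))
            for _ in range(2000)
        ]
        mean, sem = fa.average_traces(phases)
        assert np.all(np.abs(mean.I - expectation) <= 3.0 * np.maximum(sem, 1e-12))

    def test_misaligned_time_bases_rejected(self):
        a = IntensityTrace(t=np.arange(0, 10, 0.5), I=np.zeros(20))
        b = IntensityTrace(t=np.arange(0, 10, 0.25), I=np.zeros(40))
        with pytest.raises(ValueError, match="misaligned"):
            fa.average_traces([a, b])


def grid_search_tau(trace, n_grid=50):
    """Independent oracle: exhaustive log-grid over (tau, tau_b) with the two
    linear amplitudes solved by least squares at each node."""
    t, I = trace.t, trace.I
    taus = np.geomspace(0.2, 200.0, n_grid)
    tau_bs = np.geomspace(0.2, 2000.0, n_grid)
    best = (np.inf, None, None)
    for tau in taus:
        rec = 1.0 - np.exp(-t / tau)
        for tau_b in tau_bs:
            X = np.column_stack([np.exp(-t / tau_b), rec])
            coef, *_ = np.linalg.lstsq(X, I, rcond=None)
            if (coef < 0).any():
                continue
            rss = float(np.sum((I - X @ coef) ** 2))
            if rss < best[0]:
                best = (rss, tau, tau_b)
    return best[1]


class TestFitRecoveryEq1:
    def test_noise_free_round_trip_to_six_significant_figures(self):
        trace = make_eq1_trace(a=0.3, tau_b=9.5, I0=1.0, tau=10.0)
        fit = fa.fit_recovery_eq1(trace)
        assert fit.a == pytest.approx(0.3, rel=1e-6)
        assert fit.tau_b == pytest.approx(9.5, rel=1e-6)
        assert fit.I0 == pytest.approx(1.0, rel=1e-6)
        assert fit.tau == pytest.approx(10.0, rel=1e-6)

    def test_degenerate_no_bleach_component_flagged(self):
        trace = make_eq1_trace(a=0.0, tau_b=33.0, I0=1.0, tau=8.0)
        fit = fa.fit_recovery_eq1(trace)
        assert fit.tau == pytest.approx(8.0, rel=1e-4)
        assert "tau_b_unidentifiable" in fit.flags

    def test_near_degenerate_exponentials_flagged(self):
        trace = make_eq1_trace(a=0.4, tau_b=10.5, I0=1.0, tau=10.0)
        fit = fa.fit_recovery_eq1(trace)
        assert "near_degenerate_exponentials" in fit.flags

    def test_noisy_fit_agrees_with_grid_search_oracle(self):
        trace = make_eq1_trace(a=0.3, tau_b=9.5, I0=1.0, tau=10.0,
                               noise_sd=0.05, seed=42)
        fit = fa.fit_recovery_eq1(trace)
        tau_grid = grid_search_tau(trace)
        # within one multiplicative grid step of the exhaustive minimum
        step = (200.0 / 0.2) ** (1.0 / 49)
        assert tau_grid / step <= fit.tau <= tau_grid * step


class TestBleachControl:
    def test_noise_free_single_exponential_recovered(self):
        t = np.arange(0.0, 40.0, 0.5)
        traces = [IntensityTrace(t=t, I=np.exp(-t / 9.5)) for _ in range(3)]
        fit = fa.fit_bleach_control(traces)
        assert fit.tau_b == pytest.approx(9.5, rel=1e-6)

    def test_constant_control_flagged_no_bleaching(self):
        t = np.arange(0.0, 40.0, 0.5)
        traces = [IntensityTrace(t=t, I=np.ones_like(t)) for _ in range(2)]
        fit = fa.fit_bleach_control(traces)
        assert math.isinf(fit.tau_b)
        assert "no_bleaching" in fit.flags

    def test_increasing_control_rejected(self):
        t = np.arange(0.0, 40.0, 0.5)
        traces = [IntensityTrace(t=t, I=1.0 + 0.1 * t) for _ in range(2)]
        with pytest.raises(ValueError, match="increase"):
            fa.fit_bleach_control(traces)

    def test_forty_noisy_controls_recover_lifetime(self):
        """Generate-then-fit round trip at N=40 control cells: tau_b within
        5% in at least 95/100 seeds."""
        t = np.arange(0.0, 40.0, 0.5)
        hits = 0
        n_seeds = 100
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            traces = [
                IntensityTrace(
                    t=t,
                    I=np.clip(
                        np.exp(-t / 9.5) + rng.normal(0, 0.08, len(t)), 1e-6, None
                    ),
                )
                for _ in range(40)
            ]
            fit = fa.fit_bleach_control(traces)
            hits += abs(fit.tau_b - 9.5) / 9.5 < 0.05
        assert hits >= 95


class TestBleachCorrectAndFit:
    def test_exact_round_trip_when_control_known(self):
        t = np.arange(0.0, 20.0, 0.25)
        tau, tau_b = 2.5, 5.0
        I = (1.0 - np.exp(-t / tau)) * np.exp(-t / tau_b)
        ctrl = fa.BleachControlFit(tau_b=tau_b, amplitude=1.0, n_cells=2)
        fit = fa.bleach_correct_and_fit(IntensityTrace(t=t, I=I), ctrl)
        assert fit.tau == pytest.approx(2.5, rel=1e-6)
        assert fit.I0 == pytest.approx(1.0, rel=1e-6)

    def test_constant_control_is_identity_correction(self):
        t = np.arange(0.0, 20.0, 0.25)
        I = 1.0 - np.exp(-t / 4.0)
        ctrl = fa.BleachControlFit(tau_b=math.inf, amplitude=1.0, n_cells=2)
        fit = fa.bleach_correct_and_fit(IntensityTrace(t=t, I=I), ctrl)
        assert fit.tau == pytest.approx(4.0, rel=1e-6)

    def test_two_step_consistent_with_combined_fit_when_bleaching_is_weak(self):
        """Cross-method oracle: with weak imaging bleaching the additive and
        multiplicative bleach models coincide, so the two-step tau and the
        combined-fit tau must agree on the same synthetic data.  (With strong
        bleaching the two models genuinely differ — the reason the in-vivo
        analysis uses the two-step procedure in the first place.)"""
        t = np.arange(0.0, 40.0, 0.5)
        tau, tau_b = 6.0, 1000.0
        rng = np.random.default_rng(3)
        diffs = []
        for _ in range(20):
            I = (1.0 - np.exp(-t / tau)) * np.exp(-t / tau_b)
            noisy = I + rng.normal(0, 0.01, len(t))
            ctrl = fa.BleachControlFit(tau_b=tau_b, amplitude=1.0, n_cells=2)
            two_step = fa.bleach_correct_and_fit(IntensityTrace(t=t, I=noisy), ctrl)
            combined = fa.fit_recovery_eq1(IntensityTrace(t=t, I=noisy))
            diffs.append(two_step.tau - combined.tau)
        assert abs(np.mean(diffs)) < 0.5  # both estimate the same tau ~ 6 s
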