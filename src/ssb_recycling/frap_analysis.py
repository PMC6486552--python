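"""FRAP inference: recovery-phase handling, ensemble averaging and fitting.

Two distinct procedures are implemented, mirroring how the in-vitro and
in-vivo experiments are analysed:

* the *combined* fit, for in-vitro recovery with an always-bright solution
  pool::

      I(t) = a * exp(-t / tau_b) + I0 * (1 - exp(-t / tau))

  where ``a`` and ``tau_b`` absorb the imaging-photobleach component and
  ``tau`` is the exchange time of fork-bound SSB;

* the *two-step* fit for in-vivo data, where the finite cytosolic pool itself
  bleaches during imaging: unpulsed control cells are fit with a single
  exponential to obtain the imaging bleach lifetime, the averaged FRAP trace
  is divided pointwise by that decay, and the corrected trace is fit with
  ``I0 * (1 - exp(-t / tau))``.

All fits are nonlinear least squares (lmfit) with positivity bounds; parameter
standard errors come from the Jacobian, and an optional bootstrap over traces
gives resampling errors on tau.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from lmfit import Model

from .traces import IntensityTrace

__all__ = [
    "RecoveryFit",
    "BleachControlFit",
    "extract_recovery_phases",
    "average_traces",
    "fit_recovery_eq1",
    "fit_bleach_control",
    "bleach_correct_and_fit",
    "bootstrap_tau",
]


@dataclass
class RecoveryFit:
    """Fitted recovery parameters (combined model unless noted)."""

    a: float
    tau_b: float
    I0: float
    tau: float
    a_err: float | None = None
    tau_b_err: float | None = None
    I0_err: float | None = None
    tau_err: float | None = None
    rss: float = np.nan
    n_traces: int = 0
    flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "a": self.a,
            "tau_b": self.tau_b,
            "I0": self.I0,
            "tau": self.tau,
            "a_err": self.a_err,
            "tau_b_err": self.tau_b_err,
            "I0_err": self.I0_err,
            "tau_err": self.tau_err,
            "rss": self.rss,
            "n_traces": self.n_traces,
            "flags": list(self.flags),
        }


@dataclass
class BleachControlFit:
    """Single-exponential imaging-bleach fit from unpulsed control cells."""

    tau_b: float
    amplitude: float
    tau_b_err: float | None = None
    n_cells: int = 0
    flags: list[str] = field(default_factory=list)

    def decay(self, t: np.ndarray) -> np.ndarray:
        if math.isinf(self.tau_b):
            return np.ones_like(np.asarray(t, dtype=float))
        return np.exp(-np.asarray(t, dtype=float) / self.tau_b)


def _detect_pulses(
    trace: IntensityTrace, drop_fraction: float = 0.8, lookback: int = 5
) -> list[float]:
    """Candidate pulse times: frames losing > ``drop_fraction`` of the median
    intensity of the preceding ``lookback`` frames."""
    I, t = trace.I, trace.t
    out = []
    i = 1
    while i < len(I):
        ref = float(np.median(I[max(0, i - lookback): i]))
        if ref > 0 and (ref - I[i]) / ref > drop_fraction:
            out.append(float(t[i]))
            i += lookback  # skip the recovery onset
        else:
            i += 1
    return out


def extract_recovery_phases(trace: IntensityTrace) -> list[IntensityTrace]:
    """Split a pulsed trace into post-pulse sub-traces re-zeroed to pulse time.

    Pulse times are taken from the trace metadata; if absent, they are
    detected as >80% single-frame intensity drops.  Each phase is truncated at
    the next pulse; empty phases (pulse at the final frame) are dropped with a
    warning.
    """
    pulses = sorted(trace.pulse_times) if trace.pulse_times else _detect_pulses(trace)
    if not pulses:
        raise ValueError(
            "no pulse times in metadata and none detected; candidate drop frames: "
            f"{_detect_pulses(trace, drop_fraction=0.5)}"
        )
    bounds = list(pulses) + [trace.t[-1] + 1e-9]
    phases = []
    for tp, tnext in zip(pulses, bounds[1:]):
        mask = (trace.t >= tp) & (trace.t < tnext)
        if mask.sum() < 2:
            warnings.warn(f"pulse at t={tp:g}s leaves an empty recovery phase; skipped")
            continue
        phases.append(
            IntensityTrace(
                t=trace.t[mask] - tp,
                I=trace.I[mask],
                spot_id=f"{trace.spot_id}@{tp:g}s",
                pulse_times=[],
            )
        )
    return phases


def average_traces(
    phases: list[IntensityTrace], align_tolerance: float = 1e-6
) -> tuple[IntensityTrace, np.ndarray]:
    """Pointwise mean of recovery phases on a common time base.

    Phases are linearly interpolated onto the time base of the shortest one;
    returns the mean trace and the per-point SEM.  Time bases whose frame
    spacing disagrees by more than ``align_tolerance`` (relative) raise.
    """
    if len(phases) < 2:
        raise ValueError("need at least 2 phases to average")
    dts = [float(np.median(np.diff(p.t))) for p in phases if len(p) > 1]
    if max(dts) - min(dts) > align_tolerance * max(dts):
        raise ValueError("phase time bases are misaligned beyond tolerance")
    t_end = min(p.t[-1] for p in phases)
    base = min(phases, key=lambda p: p.t[-1])
    tt = base.t[base.t <= t_end + 1e-12]
    stack = np.vstack([np.interp(tt, p.t, p.I) for p in phases])
    mean = stack.mean(axis=0)
    sem = stack.std(axis=0, ddof=1) / math.sqrt(len(phases))
    return IntensityTrace(t=tt, I=mean, spot_id=f"mean_of_{len(phases)}"), sem


def _eq1(t, a, tau_b, I0, tau):
    return a * np.exp(-t / tau_b) + I0 * (1.0 - np.exp(-t / tau))


def _recovery_only(t, I0, tau):
    return I0 * (1.0 - np.exp(-t / tau))


def _init_tau(t: np.ndarray, I: np.ndarray) -> float:
    """Time to half-recovery divided by ln 2."""
    plateau = float(np.mean(I[-max(3, len(I) // 10):]))
    if plateau <= 0:
        return max(float(t[-1]) / 3.0, float(t[1] - t[0]))
    idx = np.argmax(I >= 0.5 * plateau)
    t_half = float(t[idx]) if I[idx] >= 0.5 * plateau else float(t[-1]) / 2.0
    return max(t_half / math.log(2.0), float(t[1] - t[0]) / 10.0)


def fit_recovery_eq1(
    mean_trace: IntensityTrace,
    weights: np.ndarray | None = None,
    n_traces: int = 0,
) -> RecoveryFit:
    """Combined photobleach + exchange fit of an averaged recovery trace.

    The trace should be normalized so the pre-pulse steady state is 1 and
    re-zeroed to the pulse.  Initialization: tau from time-to-half-recovery /
    ln 2, tau_b from the tail slope, a from I(0), I0 from the plateau.  All
    parameters are bounded positive; fits with tau at its bounds or with
    tau and tau_b within 20% of each other (near-degenerate exponentials)
    are flagged.
    """
    t, I = mean_trace.t, mean_trace.I
    if len(t) < 5:
        raise ValueError("trace too short to fit")
    tau0 = _init_tau(t, I)
    plateau = float(np.mean(I[-max(3, len(I) // 10):]))
    a0 = max(float(I[0]), 1e-3)
    # tail log-slope for tau_b init (fall back to 3x tau0)
    tail = slice(len(t) // 2, None)
    with np.errstate(all="ignore"):
        pos = I[tail] > 0
        if pos.sum() > 3:
            slope = np.polyfit(t[tail][pos], np.log(I[tail][pos]), 1)[0]
            tau_b0 = -1.0 / slope if slope < -1e-9 else 3.0 * tau0
        else:
            tau_b0 = 3.0 * tau0
    tau_b0 = float(np.clip(tau_b0, tau0 * 0.1, t[-1] * 50))

    model = Model(_eq1)
    res = None
    # a boundary-pinned bleach amplitude can stall the optimizer; retry from
    # a few spread-out starting points before giving up
    inits = [
        (a0, tau_b0, tau0),
        (max(a0, 0.05), tau_b0 * 3.0, tau0 * 0.5),
        (1e-3, tau_b0, tau0 * 2.0),
        (0.2, t[-1], tau0),
    ]
    for a_i, tau_b_i, tau_i in inits:
        params = model.make_params(
            a=dict(value=a_i, min=0.0),
            tau_b=dict(value=tau_b_i, min=1e-3),
            I0=dict(value=max(plateau, 1e-3), min=0.0),
            tau=dict(value=min(max(tau_i, 1e-3), t[-1] * 50), min=1e-4, max=t[-1] * 100),
        )
        trial = model.fit(I, params, t=t, weights=weights, nan_policy="raise")
        if trial.success and (res is None or np.sum(trial.residual**2) < np.sum(res.residual**2)):
            res = trial
        if res is not None and trial is res:
            break
    if res is None:
        raise RuntimeError(
            f"combined recovery fit did not converge (init a={a0:.3g}, "
            f"tau_b={tau_b0:.3g}, I0={plateau:.3g}, tau={tau0:.3g})"
        )
    p = res.params
    flags: list[str] = []
    if p["tau"].value >= 0.99 * p["tau"].max or p["tau"].value <= 1.01 * p["tau"].min:
        flags.append("tau_at_bounds")
    if p["a"].value < 1e-6 * max(p["I0"].value, 1.0):
        flags.append("tau_b_unidentifiable")  # no bleach component in the data
    elif abs(p["tau"].value - p["tau_b"].value) < 0.2 * p["tau_b"].value:
        flags.append("near_degenerate_exponentials")
    return RecoveryFit(
        a=p["a"].value,
        tau_b=p["tau_b"].value,
        I0=p["I0"].value,
        tau=p["tau"].value,
        a_err=p["a"].stderr,
        tau_b_err=p["tau_b"].stderr,
        I0_err=p["I0"].stderr,
        tau_err=p["tau"].stderr,
        rss=float(np.sum(res.residual**2)),
        n_traces=n_traces,
        flags=flags,
    )


def fit_bleach_control(controls: list[IntensityTrace]) -> BleachControlFit:
    """Single-exponential decay fit of averaged unpulsed-cell intensity.

    Traces are normalized to their initial level before averaging.  A control
    whose averaged signal increases is rejected; a flat control is returned
    as ``tau_b = inf`` with a ``no_bleaching`` flag.
    """
    if len(controls) < 2:
        raise ValueError("need at least 2 control cells")
    t_end = min(tr.t[-1] for tr in controls)
    tt = controls[0].t[controls[0].t <= t_end + 1e-12]
    stack = []
    for tr in controls:
        I = np.interp(tt, tr.t, tr.I)
        ref = np.mean(I[: max(1, len(I) // 20)])
        if ref <= 0:
            raise ValueError(f"control {tr.spot_id} has nonpositive initial intensity")
        stack.append(I / ref)
    mean = np.vstack(stack).mean(axis=0)
    late = float(np.mean(mean[-max(3, len(mean) // 10):]))
    early = float(np.mean(mean[: max(3, len(mean) // 10)]))
    if late > early * 1.05:
        raise ValueError("control intensity increases over time; invalid bleach control")
    if late > 0.99 * early:
        return BleachControlFit(
            tau_b=math.inf, amplitude=early, n_cells=len(controls), flags=["no_bleaching"]
        )

    def _single_exp(t, amp, tau_b):
        return amp * np.exp(-t / tau_b)

    model = Model(_single_exp)
    with np.errstate(all="ignore"):
        pos = mean > 0
        slope = np.polyfit(tt[pos], np.log(mean[pos]), 1)[0] if pos.sum() > 3 else -0.1
    tau0 = -1.0 / slope if slope < -1e-9 else tt[-1]
    params = model.make_params(amp=dict(value=early, min=0.0), tau_b=dict(value=tau0, min=1e-3))
    res = model.fit(mean, params, t=tt)
    return BleachControlFit(
        tau_b=res.params["tau_b"].value,
        amplitude=res.params["amp"].value,
        tau_b_err=res.params["tau_b"].stderr,
        n_cells=len(controls),
    )


def bleach_correct_and_fit(
    mean_trace: IntensityTrace,
    control: BleachControlFit,
    max_amplification: float = 10.0,
) -> RecoveryFit:
    """Two-step in-vivo procedure: divide by the control decay, fit recovery.

    The corrected trace ``I(t) / exp(-t / tau_b)`` is fit with
    ``I0 * (1 - exp(-t / tau))``.  Late-time points where the correction
    amplifies by more than ``max_amplification`` are truncated with a warning.
    A constant (no-bleaching) control makes the correction the identity.
    """
    t, I = mean_trace.t, mean_trace.I
    gain = 1.0 / control.decay(t)
    keep = gain <= max_amplification
    if not keep.all():
        warnings.warn(
            f"bleach correction exceeds {max_amplification:.0f}x amplification; "
            f"truncating at t={t[keep][-1]:g}s"
        )
    t, I = t[keep], (I * gain)[keep]
    if len(t) < 4:
        raise ValueError("corrected trace too short to fit")
    tau0 = _init_tau(t, I)
    plateau = float(np.mean(I[-max(3, len(I) // 10):]))
    model = Model(_recovery_only)
    params = model.make_params(
        I0=dict(value=max(plateau, 1e-3), min=0.0),
        tau=dict(value=tau0, min=1e-4, max=t[-1] * 100),
    )
    res = model.fit(I, params, t=t)
    p = res.params
    flags = []
    if p["tau"].value >= 0.99 * p["tau"].max:
        flags.append("tau_at_bounds")
    return RecoveryFit(
        a=0.0,
        tau_b=control.tau_b,
        I0=p["I0"].value,
        tau=p["tau"].value,
        I0_err=p["I0"].stderr,
        tau_err=p["tau"].stderr,
        rss=float(np.sum(res.residual**2)),
        n_traces=0,
        flags=flags,
    )


def bootstrap_tau(
    phases: list[IntensityTrace],
    n_boot: int = 200,
    seed: int = 0,
    control: BleachControlFit | None = None,
) -> tuple[float, float]:
    """Bootstrap (over traces) median and sd of the fitted exchange time.

    Resamples the recovery phases with replacement, re-averages and refits
    (combined fit, or two-step if a control fit is given).
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xB00]))
    taus = []
    for _ in range(n_boot):
        idx = rng.integers(0, len(phases), size=len(phases))
        sample = [phases[i] for i in idx]
        try:
            mean, _ = average_traces(sample)
            if control is None:
                taus.append(fit_recovery_eq1(mean, n_traces=len(sample)).tau)
            else:
                taus.append(bleach_correct_and_fit(mean, control).tau)
        except (ValueError, RuntimeError):
            continue
    if not taus:
        raise RuntimeError("all bootstrap refits failed")
    return float(np.median(taus)), float(np.std(taus, ddof=1))
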