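"""End-to-end experiment templates, run manifests and test fixtures.

Each template wires the simulator and the analysis chain together under the
study conditions of the corresponding experiment:

``frap_invitro``
    Rolling-circle replisomes at a given SSB concentration, periodic FRAP
    pulses, first three recovery phases averaged over replisomes, combined
    recovery fit.  Recovery-phase imaging is attenuated (long per-dye bleach
    lifetime) so the recovery kinetics report on exchange; see
    docs/methods.md.
``chase_no_ssb``
    Pre-assembled labelled SSB, no solution SSB, continuous imaging at full
    power; the ensemble decay fits a single exponential with the imaging
    photobleach lifetime.
``frap_invivo``
    Pulsed foci plus unpulsed control cells; two-step control-corrected fit.
``okazaki_preassembly``
    SSB spot positions along stretched products; inter-spot spacings with
    truncated-exponential estimation, plus the matching gel-lane emulation.
``rate_only``
    Kymographs rendered and re-tracked; per-segment slopes pooled into a
    Gaussian rate distribution.

Every file write is atomic (temp + rename) and every stage output is
checksummed into a run manifest, so re-running a manifest reproduces
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

from . import __version__
from .config import SimulationConfig, EXCHANGE_TIME_TABLE, DEFAULT_L_TABLE
from . import frap_analysis as fa
from . import microscopy_render as mr
from . import okazaki_analysis as oa
from . import sim_core as sc
from . import trajectory_analysis as ta
from .traces import IntensityTrace, write_traces_csv

__all__ = [
    "RunManifest",
    "frap_invitro_config",
    "run_frap_invitro",
    "frap_invitro_tau_seeds",
    "run_chase_bleach",
    "run_frap_invivo",
    "frap_invivo_tau_seeds",
    "run_rate_only",
    "run_okazaki_preassembly",
    "run_experiment",
    "make_fixtures",
    "atomic_write_text",
    "EXPERIMENT_TEMPLATES",
    "FIXTURE_SUITES",
]

#: per-dye bleach lifetime (s) under attenuated recovery-phase imaging
FRAP_IMAGING_TAU_B = 400.0
#: per-dye bleach lifetime (s) under continuous full-power imaging
CONTINUOUS_TAU_B = 9.5
#: imaging bleach lifetime (s) of the in-vivo fluorescent-protein label
IN_VIVO_TAU_B = 10.0
#: pre-pulse acquisition (s) establishing the steady-state baseline
FRAP_PRE_TIME = 15.0


def atomic_write_text(path: Path, text: str) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


@dataclass
class RunManifest:
    template: str
    seed: int
    config: dict
    version: str = __version__
    outputs: dict[str, str] = field(default_factory=dict)  # path -> sha256
    stages: dict[str, str] = field(default_factory=dict)  # stage -> ok/failed
    results: dict = field(default_factory=dict)

    def record(self, path: Path) -> None:
        self.outputs[str(path)] = _sha256(path)

    def write(self, path: Path) -> None:
        atomic_write_text(path, json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True))


# --------------------------------------------------------------------------
# in-vitro FRAP
# --------------------------------------------------------------------------


def frap_invitro_config(
    c_nM: float,
    seed: int,
    tau_true: float | None = None,
    n_phases: int = 3,
) -> SimulationConfig:
    """Study-condition config for one in-vitro FRAP replisome.

    If ``tau_true`` is given, the exchange constants are set so the effective
    exchange rate equals ``1/tau_true`` at this concentration (parameter
    injection for recovery experiments); otherwise the calibrated defaults
    apply.  The recovery window per phase spans >= 3.5 expected exchange
    times (minimum 30 s)."""
    kw = {}
    if tau_true is not None:
        if c_nM <= 0:
            raise ValueError("tau injection needs c > 0")
        kw = {"k_intr": 0.0, "k_fac": 1.0 / (tau_true * c_nM)}
    probe = SimulationConfig(c_ssb=c_nM, seed=seed, **kw)
    tau_exp = 1.0 / sc.effective_exchange_rate(probe)
    window = max(30.0, 3.5 * tau_exp)
    pulses = [FRAP_PRE_TIME + i * window for i in range(n_phases)]
    return probe.replace(
        tau_b=FRAP_IMAGING_TAU_B,
        pulse_times=pulses,
        duration=FRAP_PRE_TIME + n_phases * window,
        noise_sd=1.0,
    )


def run_frap_invitro(
    c_nM: float,
    n_replisomes: int,
    seed: int,
    tau_true: float | None = None,
    n_phases: int = 3,
) -> tuple[fa.RecoveryFit, list[IntensityTrace], list[sc.GroundTruth]]:
    """Simulate N replisomes, average the first ``n_phases`` recovery phases
    of each, and fit the combined recovery model."""
    raw_traces: list[IntensityTrace] = []
    gts = []
    for i in range(n_replisomes):
        cfg = frap_invitro_config(c_nM, seed=seed * 10007 + i, tau_true=tau_true, n_phases=n_phases)
        _, ledger, gt = sc.simulate_replisome(cfg)
        gts.append(gt)
        raw_traces.append(sc.emit_intensity_trace(ledger, cfg))
    # one shared normalizer (ensemble pre-pulse mean): dividing each trace by
    # its own short pre-pulse window would inject a time-correlated 1/X ratio
    # bias from fork-to-fork intensity fluctuations
    t_pulse1 = min(raw_traces[0].pulse_times)
    pre_means = [
        float(np.mean(tr.I[(tr.t >= FRAP_PRE_TIME / 2.0) & (tr.t < t_pulse1)]))
        for tr in raw_traces
    ]
    grand_pre = float(np.mean(pre_means))
    phases: list[IntensityTrace] = []
    for tr in raw_traces:
        scaled = IntensityTrace(tr.t, tr.I / grand_pre, tr.spot_id, list(tr.pulse_times))
        phases.extend(fa.extract_recovery_phases(scaled)[:n_phases])
    mean, sem = fa.average_traces(phases)
    fit = fa.fit_recovery_eq1(mean, n_traces=len(phases))
    return fit, phases, gts


def frap_invitro_tau_seeds(
    c_nM: float,
    tau_true: float,
    n_replisomes: int,
    n_seeds: int,
    seed: int = 1,
) -> np.ndarray:
    """Fitted exchange time across ``n_seeds`` independent repetitions."""
    taus = []
    for s in range(n_seeds):
        fit, _, _ = run_frap_invitro(
            c_nM, n_replisomes, seed=seed + 1000 * s, tau_true=tau_true
        )
        taus.append(fit.tau)
    return np.array(taus)


# --------------------------------------------------------------------------
# chase (photobleach lifetime)
# --------------------------------------------------------------------------


def chase_config(seed: int, duration: float = 40.0) -> SimulationConfig:
    return SimulationConfig(
        c_ssb=0.0,
        k_intr=0.0,
        L_mean_knt=DEFAULT_L_TABLE[2.0],
        initial_tetramers=40,
        duration=duration,
        tau_b=CONTINUOUS_TAU_B,
        noise_sd=1.0,
        seed=seed,
    )


def run_chase_bleach(
    n_replisomes: int = 24, seed: int = 1, duration: float = 40.0
) -> tuple[fa.BleachControlFit, list[IntensityTrace]]:
    """Chase-mode decay: pre-assembled SSB, no solution pool, full-power
    imaging; ensemble decay fit with a single exponential."""
    traces = []
    for i in range(n_replisomes):
        cfg = chase_config(seed=seed * 10007 + i, duration=duration)
        _, ledger, _ = sc.simulate_replisome(cfg)
        traces.append(sc.emit_intensity_trace(ledger, cfg))
    fit = fa.fit_bleach_control(traces)
    return fit, traces


# --------------------------------------------------------------------------
# in-vivo FRAP
# --------------------------------------------------------------------------


def frap_invivo_config(seed: int, tau_true: float = 2.5, c_equiv_nM: float = 450.0) -> SimulationConfig:
    """In-vivo study conditions: exchange time ``tau_true`` at the in-vivo
    equivalent concentration, fluorescent-protein bleach lifetime, 0.5-s
    frames, pulse after a 5-s baseline."""
    return SimulationConfig(
        c_ssb=c_equiv_nM,
        k_intr=0.0,
        k_fac=1.0 / (tau_true * c_equiv_nM),
        L_mean_knt=1.5,
        tau_b=IN_VIVO_TAU_B,
        pulse_times=[5.0],
        duration=30.0,
        noise_sd=0.5,
        seed=seed,
    )


def run_frap_invivo(
    n_foci: int = 29,
    n_controls: int = 40,
    seed: int = 1,
    tau_true: float = 2.5,
) -> tuple[fa.RecoveryFit, fa.BleachControlFit, sc.InVivoScene]:
    """Two-step in-vivo procedure on one simulated field of view."""
    cfg = frap_invivo_config(seed=seed, tau_true=tau_true)
    scene = sc.simulate_in_vivo_scene(cfg, n_cells=n_foci + n_controls, n_pulsed=n_foci)
    control_fit = fa.fit_bleach_control(scene.control_traces)
    phases = []
    for tr in scene.focus_traces:
        phases.extend(fa.extract_recovery_phases(tr))
    mean, _ = fa.average_traces(phases)
    fit = fa.bleach_correct_and_fit(mean, control_fit)
    fit.n_traces = len(phases)
    return fit, control_fit, scene


def frap_invivo_tau_seeds(
    tau_true: float = 2.5,
    n_foci: int = 29,
    n_controls: int = 40,
    n_seeds: int = 100,
    seed: int = 1,
) -> np.ndarray:
    taus = []
    for s in range(n_seeds):
        fit, _, _ = run_frap_invivo(n_foci, n_controls, seed=seed + 1000 * s, tau_true=tau_true)
        taus.append(fit.tau)
    return np.array(taus)


# --------------------------------------------------------------------------
# replication rates from kymographs
# --------------------------------------------------------------------------


def run_rate_only(
    n_molecules: int = 71,
    v_mean: float = 626.0,
    v_sd: float = 73.0,
    seed: int = 1,
    duration: float = 60.0,
) -> tuple[ta.RateDistribution, list[float], list[float]]:
    """Render kymographs and recover the replication-rate distribution.

    Returns the Gaussian-fit distribution, the measured segment rates and the
    true per-replisome rates."""
    rates, truths = [], []
    for i in range(n_molecules):
        cfg = SimulationConfig(
            v_mean=v_mean,
            v_sd=v_sd,
            c_ssb=20.0,
            duration=duration,
            tau_b=CONTINUOUS_TAU_B * 10,  # SSB channel stays trackable
            noise_sd=0.5,
            seed=seed * 10007 + i,
        )
        traj, ledger, gt = sc.simulate_replisome(cfg)
        kymo = mr.render_kymograph(traj, ledger, cfg)
        series = ta.track_kymograph(kymo)
        segs = ta.segment_rates(series, bp_per_px=kymo.bp_per_px)
        # the fork moves at one constant rate here; use the longest segment
        seg = max(segs.segments, key=lambda s: s.duration)
        rates.append(seg.slope_bp_s)
        truths.append(gt.v_bp_s)
    dist = ta.rate_distribution(rates)
    return dist, rates, truths


# --------------------------------------------------------------------------
# Okazaki lengths
# --------------------------------------------------------------------------


def sample_spot_positions(
    L_mean_knt: float,
    n_fragments: int,
    seed: int,
    fragments_per_molecule: int = 10,
    bp_per_px: float = mr.BP_PER_NM * mr.PIXEL_SIZE_NM,
) -> list[np.ndarray]:
    """Synthetic SSB spot positions (px) along pre-assembly products: spots
    sit in the gaps between fragments, so positions are cumulative sums of
    exponential fragment lengths."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x0A]))
    molecules = []
    n_done = 0
    while n_done < n_fragments:
        k = min(fragments_per_molecule, n_fragments - n_done)
        lengths = rng.exponential(L_mean_knt, size=k)
        pos_knt = np.concatenate([[0.0], np.cumsum(lengths)])
        molecules.append(pos_knt * 1000.0 / bp_per_px)  # knt -> nt -> px
        n_done += k
    return molecules


def run_okazaki_preassembly(
    concentrations: dict[float, float] | None = None,
    n_fragments: int = 500,
    seed: int = 1,
    censor_limit_knt: float = 0.5,
) -> tuple[dict[float, oa.OkazakiSample], dict[float, oa.GelLane], pd.DataFrame]:
    """Single-molecule spacing estimates and gel-lane estimates per
    concentration, plus the concordance table."""
    if concentrations is None:
        concentrations = dict(DEFAULT_L_TABLE)
    bp_per_px = mr.BP_PER_NM * mr.PIXEL_SIZE_NM
    sm: dict[float, oa.OkazakiSample] = {}
    gel: dict[float, oa.GelLane] = {}
    for j, (c, L_mean) in enumerate(sorted(concentrations.items())):
        molecules = sample_spot_positions(L_mean, n_fragments, seed=seed * 7919 + j, bp_per_px=bp_per_px)
        sample = oa.spot_spacing_lengths(
            molecules, bp_per_px, concentration_nM=c, censor_limit_knt=censor_limit_knt
        )
        sm[c] = oa.fit_exponential_lengths(sample, seed=seed * 7919 + j)
        rng = np.random.default_rng(np.random.SeedSequence([seed * 7919 + j, 0x6E1]))
        gel[c] = oa.emulate_gel_lane(rng.exponential(L_mean, size=n_fragments))
    table = oa.compare_estimates(sm, gel)
    return sm, gel, table


# --------------------------------------------------------------------------
# orchestration
# --------------------------------------------------------------------------


def _stage_frap_invitro(outdir: Path, manifest: RunManifest, pars: dict) -> None:
    c = pars.get("c_nM", 10.0)
    fit, phases, gts = run_frap_invitro(
        c, pars.get("n_replisomes", 24), seed=pars["seed"], tau_true=pars.get("tau_true")
    )
    write_traces_csv(phases, outdir / "phases.csv")
    manifest.record(outdir / "phases.csv")
    atomic_write_text(
        outdir / "ground_truth.json", json.dumps([g.to_dict() for g in gts], indent=1)
    )
    manifest.record(outdir / "ground_truth.json")
    atomic_write_text(outdir / "fit.json", json.dumps(fit.to_dict(), indent=1))
    manifest.record(outdir / "fit.json")
    manifest.results["tau"] = fit.tau


def _stage_chase(outdir: Path, manifest: RunManifest, pars: dict) -> None:
    fit, traces = run_chase_bleach(pars.get("n_replisomes", 24), seed=pars["seed"])
    write_traces_csv(traces, outdir / "traces.csv")
    manifest.record(outdir / "traces.csv")
    cfg = chase_config(pars["seed"])
    _, ledger, _ = sc.simulate_replisome(cfg)
    ledger.to_csv(outdir / "ledger.csv")
    manifest.record(outdir / "ledger.csv")
    atomic_write_text(
        outdir / "fit.json",
        json.dumps({"tau_b": fit.tau_b, "n_traces": fit.n_cells}, indent=1),
    )
    manifest.record(outdir / "fit.json")
    manifest.results["tau_b"] = fit.tau_b


def _stage_frap_invivo(outdir: Path, manifest: RunManifest, pars: dict) -> None:
    fit, ctrl, scene = run_frap_invivo(
        pars.get("n_foci", 29), pars.get("n_controls", 40), seed=pars["seed"],
        tau_true=pars.get("tau_true", 2.5),
    )
    write_traces_csv(scene.focus_traces, outdir / "foci.csv")
    write_traces_csv(scene.control_traces, outdir / "controls.csv")
    manifest.record(outdir / "foci.csv")
    manifest.record(outdir / "controls.csv")
    atomic_write_text(
        outdir / "fit.json",
        json.dumps({"tau": fit.tau, "tau_b_control": ctrl.tau_b}, indent=1),
    )
    manifest.record(outdir / "fit.json")
    manifest.results.update({"tau": fit.tau, "tau_b_control": ctrl.tau_b})


def _stage_rate_only(outdir: Path, manifest: RunManifest, pars: dict) -> None:
    dist, rates, truths = run_rate_only(
        pars.get("n_molecules", 71), seed=pars["seed"],
        v_mean=pars.get("v_mean", 626.0), v_sd=pars.get("v_sd", 73.0),
    )
    pd.DataFrame({"rate_bp_s": rates, "true_rate_bp_s": truths}).to_csv(
        outdir / "rates.csv", index=False
    )
    manifest.record(outdir / "rates.csv")
    atomic_write_text(outdir / "distribution.json", json.dumps(dist.to_dict(), indent=1))
    manifest.record(outdir / "distribution.json")
    manifest.results.update(dist.to_dict())


def _stage_okazaki(outdir: Path, manifest: RunManifest, pars: dict) -> None:
    sm, gel, table = run_okazaki_preassembly(
        n_fragments=pars.get("n_fragments", 500), seed=pars["seed"]
    )
    table.to_csv(outdir / "estimates.csv", index=False)
    manifest.record(outdir / "estimates.csv")
    manifest.results["estimates"] = table.to_dict(orient="records")


EXPERIMENT_TEMPLATES: dict[str, Callable[[Path, RunManifest, dict], None]] = {
    "frap_invitro": _stage_frap_invitro,
    "frap_invivo": _stage_frap_invivo,
    "chase_no_ssb": _stage_chase,
    "okazaki_preassembly": _stage_okazaki,
    "rate_only": _stage_rate_only,
}


def run_experiment(template: str, outdir, seed: int = 1, **pars) -> RunManifest:
    """Execute one canned experiment template end to end.

    Writes stage outputs and a checksummed manifest under ``outdir``; on
    stage failure partial outputs are preserved and the manifest marks the
    failed stage before the exception propagates."""
    if template not in EXPERIMENT_TEMPLATES:
        raise ValueError(
            f"unknown template {template!r}; available: {sorted(EXPERIMENT_TEMPLATES)}"
        )
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pars = dict(pars, seed=seed)
    manifest = RunManifest(template=template, seed=seed, config=dict(pars))
    try:
        EXPERIMENT_TEMPLATES[template](outdir, manifest, pars)
        manifest.stages[template] = "ok"
    except BaseException:
        manifest.stages[template] = "failed"
        manifest.write(outdir / "manifest.json")
        raise
    manifest.write(outdir / "manifest.json")
    return manifest


# --------------------------------------------------------------------------
# fixtures
# --------------------------------------------------------------------------


def _fixture_eq1_clean(outdir: Path, seed: int) -> None:
    t = np.arange(0.0, 60.0, 0.5)
    a, tau_b, I0, tau = 0.3, 9.5, 1.0, 10.0
    I = a * np.exp(-t / tau_b) + I0 * (1.0 - np.exp(-t / tau))
    write_traces_csv([IntensityTrace(t=t, I=I, spot_id="eq1_clean")], outdir / "trace.csv")
    atomic_write_text(
        outdir / "truth.json", json.dumps({"a": a, "tau_b": tau_b, "I0": I0, "tau": tau})
    )


def _fixture_fig3_series(outdir: Path, seed: int) -> None:
    for c, tau in EXCHANGE_TIME_TABLE.items():
        fit, phases, gts = run_frap_invitro(c, n_replisomes=6, seed=seed, tau_true=tau)
        write_traces_csv(phases, outdir / f"phases_{c:g}nM.csv")
    atomic_write_text(outdir / "truth.json", json.dumps(EXCHANGE_TIME_TABLE))


def _fixture_two_segment_kymo(outdir: Path, seed: int) -> None:
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x2E6]))
    t = np.arange(0.0, 60.0, 0.5)
    bp_per_px = mr.BP_PER_NM * mr.PIXEL_SIZE_NM
    pos_bp = np.where(t < 30.0, 500.0 * t, 500.0 * 30.0 + 800.0 * (t - 30.0))
    pos_px = pos_bp / bp_per_px + rng.normal(0.0, 1.0, size=len(t))
    pd.DataFrame({"t": t, "position_px": pos_px}).to_csv(outdir / "track.csv", index=False)
    atomic_write_text(
        outdir / "truth.json",
        json.dumps({"rates_bp_s": [500.0, 800.0], "changepoint_s": 30.0}),
    )


def _fixture_okazaki_4conc(outdir: Path, seed: int) -> None:
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x0C4]))
    rows = []
    for c, L in DEFAULT_L_TABLE.items():
        lengths = rng.exponential(L, size=500)
        for x in lengths:
            rows.append({"concentration_nM": c, "length_knt": x})
    pd.DataFrame(rows).to_csv(outdir / "lengths.csv", index=False)
    atomic_write_text(outdir / "truth.json", json.dumps(DEFAULT_L_TABLE))


def _fixture_invivo_6cell(outdir: Path, seed: int) -> None:
    cfg = frap_invivo_config(seed=seed)
    scene = sc.simulate_in_vivo_scene(cfg, n_cells=6, n_pulsed=2)
    write_traces_csv(scene.focus_traces, outdir / "foci.csv")
    write_traces_csv(scene.control_traces, outdir / "controls.csv")
    atomic_write_text(
        outdir / "truth.json",
        json.dumps({"tau": 2.5, "tau_b": IN_VIVO_TAU_B, "pulse_time": scene.pulse_time}),
    )


FIXTURE_SUITES = {
    "eq1_clean": _fixture_eq1_clean,
    "fig3_series": _fixture_fig3_series,
    "two_segment_kymo": _fixture_two_segment_kymo,
    "okazaki_4conc": _fixture_okazaki_4conc,
    "invivo_6cell": _fixture_invivo_6cell,
}


def make_fixtures(suite: str, seed: int, outdir) -> Path:
    """Write one deterministic fixture suite under ``outdir/<suite>``."""
    if suite not in FIXTURE_SUITES:
        raise ValueError(f"unknown suite {suite!r}; available: {sorted(FIXTURE_SUITES)}")
    outdir = Path(outdir) / suite
    outdir.mkdir(parents=True, exist_ok=True)
    FIXTURE_SUITES[suite](outdir, seed)
    return outdir
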