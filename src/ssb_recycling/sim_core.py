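"""Event-driven stochastic simulation of SSB dynamics at a replication fork.

The model
---------
A single replisome synthesizes DNA at a per-replisome rate ``v`` drawn from a
Gaussian.  Lagging-strand synthesis is discontinuous: Okazaki-fragment lengths
are i.i.d. exponential with a concentration-dependent mean; the helicase
exposes lagging-strand ssDNA linearly within each cycle and the polymerase
consumes it at the cycle boundary (the sawtooth is tracked in the
:class:`ForkTrajectory`).  The tetramer ledger models the fork's steady-state
complement — the SSB the diffraction-limited spot integrates over the whole
loop region, ``L_mean / footprint_nt`` tetramers on time average.  At each
cycle boundary every displaced tetramer either transfers internally to ssDNA
newly exposed behind the helicase (probability ``p_int``) or is competed out
by a solution tetramer that takes its place.

While bound, each tetramer is additionally replaced directly by solution SSB
(facilitated exchange).  The *total* per-tetramer solution-replacement rate
is the effective exchange rate ``k_ex = k_intr + k_fac * c_ssb``; the
while-bound Poisson intensity is ``k_ex`` minus the boundary-channel rate
``(1 - p_int) * v / L_mean`` so the two channels together realize ``k_ex``
(see docs/methods.md).  Because Okazaki durations are exponential, boundary
replacements are themselves Poisson, so the combined replacement process is
Poisson with rate ``k_ex`` and the expected bright-dye fraction after a FRAP
pulse recovers as ``1 - exp(-k_ex * t)`` in vitro, where the solution pool
stays bright.

Photophysics: a labelled tetramer carries 1 or 2 dyes; each dye bleaches
independently under imaging illumination with lifetime ``tau_b`` (clock runs
while the tetramer is at the fork), and is bleached instantly by a FRAP pulse
if the tetramer is at the fork at pulse time.
"""

from __future__ import annotations

import heapq
import math
import warnings
from dataclasses import dataclass, field
import numpy as np
import pandas as pd

from .config import SimulationConfig
from .traces import IntensityTrace

__all__ = [
    "TetramerRecord",
    "TetramerLedger",
    "ForkTrajectory",
    "GroundTruth",
    "InVivoCell",
    "InVivoScene",
    "effective_exchange_rate",
    "simulate_replisome",
    "steady_state_tetramers",
    "apply_frap_pulse",
    "emit_intensity_trace",
    "simulate_in_vivo_scene",
]

FATES = ("internal_transfer", "solution_exchange", "retained_at_end", "bleached_in_place")


def effective_exchange_rate(cfg: SimulationConfig) -> float:
    """Total per-tetramer solution-exchange rate ``k_intr + k_fac * c_ssb`` (s^-1).

    Strictly increasing in concentration when ``k_fac > 0``; zero only when
    both the intrinsic rate and the concentration term vanish (pure retention).
    """
    if cfg.c_ssb < 0:
        raise ValueError("negative concentration")
    return cfg.k_intr + cfg.k_fac * cfg.c_ssb


@dataclass
class TetramerRecord:
    """Event history of one SSB tetramer at the fork."""

    tid: int
    origin: str  # 'initial' | 'solution'
    bind_time: float
    release_time: float | None = None
    release_reason: str | None = None  # 'exchange' | 'boundary' | None (open)
    n_dyes: int = 0
    dye_bleach_times: list[float] = field(default_factory=list)
    n_internal_transfers: int = 0
    fate: str | None = None

    def at_fork(self, t: float) -> bool:
        return self.bind_time <= t and (self.release_time is None or t < self.release_time)

    def bright_dyes(self, t: float) -> int:
        if not self.at_fork(t):
            return 0
        return sum(1 for tb in self.dye_bleach_times if tb > t)


@dataclass
class TetramerLedger:
    """Per-tetramer event history of one simulated replisome."""

    records: list[TetramerRecord]
    duration: float
    seed: int

    def __len__(self) -> int:
        return len(self.records)

    def fates(self) -> dict[str, int]:
        out = {f: 0 for f in FATES}
        for r in self.records:
            if r.fate is not None:
                out[r.fate] += 1
        return out

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            rows.append(
                {
                    "tetramer_id": r.tid,
                    "origin": r.origin,
                    "bind_time": r.bind_time,
                    "release_time": np.nan if r.release_time is None else r.release_time,
                    "fate": r.fate,
                    "n_dyes": r.n_dyes,
                    "n_internal_transfers": r.n_internal_transfers,
                    "dye_bleach_times": ";".join(f"{t:.6g}" for t in r.dye_bleach_times),
                }
            )
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


@dataclass
class ForkTrajectory:
    """Sampled fork state: position and exposed lagging-strand ssDNA."""

    t: np.ndarray  # s
    position_bp: np.ndarray  # total DNA synthesized
    ssdna_exposed_nt: np.ndarray
    cycle_boundaries: np.ndarray  # s, end time of each completed cycle
    fragment_lengths_nt: np.ndarray  # one per initiated cycle

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"t": self.t, "position_bp": self.position_bp, "ssdna_exposed_nt": self.ssdna_exposed_nt}
        )


@dataclass
class GroundTruth:
    """Realized per-run quantities, recorded for parameter-recovery tests."""

    v_bp_s: float
    okazaki_mean_knt: float
    k_ex: float
    seed: int

    @property
    def tau_true(self) -> float:
        return math.inf if self.k_ex == 0 else 1.0 / self.k_ex

    def to_dict(self) -> dict:
        return {
            "v_bp_s": self.v_bp_s,
            "okazaki_mean_knt": self.okazaki_mean_knt,
            "k_ex": self.k_ex,
            "tau_true": None if self.k_ex == 0 else self.tau_true,
            "seed": self.seed,
        }


def _draw_dyes(rng: np.random.Generator, cfg: SimulationConfig) -> int:
    """Dye count of one solution tetramer: 0 if unlabelled, else 1 or 2."""
    if rng.random() >= cfg.labeled_fraction:
        return 0
    return 1 + (rng.random() < (cfg.dyes_mean - 1.0))


def simulate_replisome(
    cfg: SimulationConfig,
) -> tuple[ForkTrajectory, TetramerLedger, GroundTruth]:
    """Run one replisome for ``cfg.duration`` seconds.

    Returns the sampled fork trajectory, the per-tetramer ledger (with FRAP
    pulses from ``cfg.pulse_times`` already applied) and the realized ground
    truth.  Identical configs (including seed) give identical outputs.
    """
    cfg.validate()
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x51B]))

    # per-replisome rate, truncated positive
    v = float(rng.normal(cfg.v_mean, cfg.v_sd)) if cfg.v_sd > 0 else cfg.v_mean
    tries = 0
    while v <= 0 and cfg.v_mean > 0:
        v = float(rng.normal(cfg.v_mean, cfg.v_sd))
        tries += 1
        if tries > 1000:
            raise RuntimeError("could not draw a positive replication rate")
    v = max(v, 0.0)

    L_mean_nt = cfg.okazaki_mean_knt * 1000.0
    k_ex = effective_exchange_rate(cfg)
    p_int = cfg.p_internal
    r_boundary = (1.0 - p_int) * v / L_mean_nt if v > 0 else 0.0
    k_pois = k_ex - r_boundary
    if k_pois < -1e-12:
        warnings.warn(
            "cycle-boundary solution departures alone exceed the configured "
            f"effective exchange rate ({r_boundary:.4g} > {k_ex:.4g} s^-1); "
            "realized exchange will be faster than 1/tau_true",
            stacklevel=2,
        )
    k_pois = max(k_pois, 0.0)

    records: list[TetramerRecord] = []
    next_exchange: dict[int, float] = {}  # tid -> absolute next replacement time
    exchange_heap: list[tuple[float, int]] = []  # lazily invalidated
    at_fork: dict[int, TetramerRecord] = {}

    def new_record(origin: str, t: float, labeled: bool | None = None) -> TetramerRecord:
        tid = len(records)
        if labeled is None:
            n_dyes = _draw_dyes(rng, cfg)
        else:
            n_dyes = (1 + (rng.random() < (cfg.dyes_mean - 1.0))) if labeled else 0
        rec = TetramerRecord(
            tid=tid,
            origin=origin,
            bind_time=t,
            n_dyes=n_dyes,
            dye_bleach_times=[t + rng.exponential(cfg.tau_b) for _ in range(n_dyes)],
        )
        records.append(rec)
        at_fork[tid] = rec
        if k_pois > 0:
            te = t + rng.exponential(1.0 / k_pois)
            next_exchange[tid] = te
            heapq.heappush(exchange_heap, (te, tid))
        return rec

    # Steady-state fork complement (mean-field occupancy): the diffraction-
    # limited fork spot integrates SSB over the whole lagging-strand loop
    # region, whose time-averaged coverage for exponential fragment lengths
    # is L_mean/footprint tetramers (see docs/methods.md).  The instantaneous
    # sawtooth tiling of exposed ssDNA is tracked in the ForkTrajectory.
    if cfg.initial_tetramers is not None:
        n0 = cfg.initial_tetramers
    else:
        n0 = max(1, round(L_mean_nt / cfg.footprint_nt)) if cfg.c_ssb > 0 else 0
    for _ in range(n0):
        new_record("initial", 0.0, labeled=rng.random() < cfg.labeled_fraction)

    cycle_starts: list[float] = []
    boundaries: list[float] = []
    frag_lengths: list[float] = []

    def do_exchange_events(t_to: float) -> None:
        """Fire facilitated-exchange replacements (swap in place) up to t_to."""
        while exchange_heap and exchange_heap[0][0] <= t_to:
            te, tid = heapq.heappop(exchange_heap)
            if next_exchange.get(tid) != te or tid not in at_fork:
                continue  # stale entry (tetramer already released)
            old = at_fork.pop(tid)
            next_exchange.pop(tid, None)
            old.release_time = te
            old.release_reason = "exchange"
            if cfg.c_ssb > 0:
                new_record("solution", te)

    # internal clock runs over [0, warmup + duration); the first warmup_s
    # seconds are unilluminated replication before acquisition starts
    total = cfg.warmup_s + cfg.duration
    t = 0.0
    while t < total and v > 0:
        L_i = float(rng.exponential(L_mean_nt))
        T_i = L_i / v
        t_end = t + T_i
        cycle_starts.append(t)
        frag_lengths.append(L_i)
        do_exchange_events(min(t_end, total))
        if t_end >= total:
            t = total
            break
        # cycle boundary: the lagging-strand polymerase consumes the
        # fragment's ssDNA, displacing the fork-bound tetramers; each either
        # transfers internally to ssDNA newly exposed behind the helicase or
        # is competed out by a solution tetramer that takes its place
        boundaries.append(t_end)
        for tid in list(at_fork):
            rec = at_fork[tid]
            if rng.random() < p_int:
                rec.n_internal_transfers += 1
            else:
                rec.release_time = t_end
                rec.release_reason = "boundary"
                at_fork.pop(tid)
                next_exchange.pop(tid, None)
                if cfg.c_ssb > 0:
                    new_record("solution", t_end)
        t = t_end

    # shift the observation window to t = 0: drop tetramers released during
    # the warm-up, clip bind times, and restart dye clocks at the moment
    # illumination begins (no bleaching without light; exponential offsets
    # drawn at binding remain valid draws for the illuminated period)
    W = cfg.warmup_s
    if W > 0:
        kept = []
        for rec in records:
            if rec.release_time is not None and rec.release_time <= W:
                continue
            offs = [tb - rec.bind_time for tb in rec.dye_bleach_times]
            rec.bind_time = max(rec.bind_time - W, 0.0)
            if rec.release_time is not None:
                rec.release_time -= W
            rec.dye_bleach_times = [rec.bind_time + o for o in offs]
            kept.append(rec)
        records = kept
        keep_cycle = [s + l / v > W for s, l in zip(cycle_starts, frag_lengths)] if v > 0 else []
        cycle_starts = [s - W for s, k in zip(cycle_starts, keep_cycle) if k]
        frag_lengths = [l for l, k in zip(frag_lengths, keep_cycle) if k]
        boundaries = [b - W for b in boundaries if b > W]

    # finalize fates
    for rec in records:
        if rec.release_reason in ("exchange", "boundary"):
            rec.fate = "solution_exchange"
        elif rec.n_internal_transfers > 0:
            rec.fate = "internal_transfer"
        elif rec.n_dyes > 0 and all(tb <= cfg.duration for tb in rec.dye_bleach_times):
            rec.fate = "bleached_in_place"
        else:
            rec.fate = "retained_at_end"

    ledger = TetramerLedger(records=records, duration=cfg.duration, seed=cfg.seed)
    for tp in sorted(cfg.pulse_times):
        apply_frap_pulse(ledger, tp)

    # sampled trajectory
    tt = np.arange(0.0, cfg.duration + 1e-9, cfg.frame_interval)
    position = np.minimum(v * tt, v * cfg.duration)
    starts = np.array(cycle_starts) if cycle_starts else np.array([0.0])
    lens = np.array(frag_lengths) if frag_lengths else np.array([0.0])
    idx = np.clip(np.searchsorted(starts, tt, side="right") - 1, 0, len(starts) - 1)
    exposed = np.minimum(v * (tt - starts[idx]), lens[idx]) if v > 0 else np.zeros_like(tt)
    traj = ForkTrajectory(
        t=tt,
        position_bp=position,
        ssdna_exposed_nt=exposed,
        cycle_boundaries=np.array(boundaries),
        fragment_lengths_nt=np.array(frag_lengths),
    )
    gt = GroundTruth(
        v_bp_s=v,
        okazaki_mean_knt=(float(np.mean(frag_lengths)) / 1000.0 if frag_lengths else 0.0),
        k_ex=k_ex,
        seed=cfg.seed,
    )
    return traj, ledger, gt


def steady_state_tetramers(cfg: SimulationConfig, traj: ForkTrajectory | None = None) -> float:
    """Time-averaged exposed ssDNA divided by the tetramer footprint.

    This is the expected steady-state tetramer coverage of the lagging strand
    (Okazaki-fragment-scale occupancy).  If no trajectory is supplied one is
    simulated from ``cfg``.
    """
    if traj is None:
        traj, _, _ = simulate_replisome(cfg)
    if len(traj.t) == 0:
        return 0.0
    return float(np.mean(traj.ssdna_exposed_nt)) / cfg.footprint_nt


def apply_frap_pulse(ledger: TetramerLedger, t_pulse: float) -> TetramerLedger:
    """Bleach every dye on every fork-associated tetramer at ``t_pulse``.

    The solution pool is unaffected (in vitro, flow replenishes bright SSB).
    Mutates and returns the ledger.
    """
    if not 0.0 <= t_pulse <= ledger.duration:
        raise ValueError(f"pulse time {t_pulse} outside simulation window [0, {ledger.duration}]")
    for rec in ledger.records:
        if rec.at_fork(t_pulse):
            rec.dye_bleach_times = [min(tb, t_pulse) for tb in rec.dye_bleach_times]
    return ledger


def emit_intensity_trace(
    ledger: TetramerLedger,
    cfg: SimulationConfig,
    spot_id: str = "fork",
) -> IntensityTrace:
    """Per-frame fork-spot intensity from the ledger's dye bookkeeping.

    intensity = (bright dyes on fork-associated tetramers) * unit_brightness
    + baseline + Gaussian read noise.  Noise is reproducible from cfg.seed.
    """
    t = np.arange(0.0, ledger.duration + 1e-9, cfg.frame_interval)
    counts = np.zeros(len(t) + 1)
    for rec in ledger.records:
        t_off = rec.release_time if rec.release_time is not None else np.inf
        for tb in rec.dye_bleach_times:
            hi = min(tb, t_off)
            i0 = np.searchsorted(t, rec.bind_time, side="left")
            i1 = np.searchsorted(t, hi, side="left")
            if i1 > i0:
                counts[i0] += 1
                counts[i1] -= 1
    bright = np.cumsum(counts[:-1])
    rng = np.random.default_rng(np.random.SeedSequence([ledger.seed, 0x7A0]))
    noise = rng.normal(0.0, cfg.noise_sd, size=len(t)) if cfg.noise_sd > 0 else 0.0
    intensity = bright * cfg.unit_brightness + cfg.baseline + noise
    return IntensityTrace(t=t, I=intensity, spot_id=spot_id, pulse_times=list(cfg.pulse_times))


# --------------------------------------------------------------------------
# in-vivo mode
# --------------------------------------------------------------------------


@dataclass
class InVivoCell:
    """One rod-shaped cell: capsule geometry, cytosolic pool and foci."""

    cell_id: int
    center_um: tuple[float, float]
    length_um: float
    width_um: float
    foci_um: list[tuple[float, float]]
    focus_tetramers: int
    pool_tetramers: int
    is_control: bool
    cytosol_bleach_fraction: float = 0.0  # fraction of pool dyes killed by the pulse
    pulse_center_um: tuple[float, float] | None = None  # this cell's pulsed focus

    def contains(self, p: tuple[float, float]) -> bool:
        """Point-in-capsule test (axis along x)."""
        dx = abs(p[0] - self.center_um[0])
        dy = abs(p[1] - self.center_um[1])
        r = self.width_um / 2.0
        half_rect = self.length_um / 2.0 - r
        if dx <= half_rect:
            return dy <= r
        return (dx - half_rect) ** 2 + dy**2 <= r**2


@dataclass
class InVivoScene:
    """Ground truth of a simulated in-vivo FRAP field of view."""

    cells: list[InVivoCell]
    focus_traces: list[IntensityTrace]  # one per pulsed-cell focus (FRAP targets)
    control_traces: list[IntensityTrace]  # whole-cell intensity of control cells
    pulse_time: float
    pulse_center_um: tuple[float, float]
    pulse_fwhm_um: float
    pulse_dose: float
    frame_interval: float
    duration: float
    tau_b: float
    k_ex: float
    seed: int


def _capsule_area(length_um: float, width_um: float) -> float:
    r = width_um / 2.0
    return (length_um - width_um) * width_um + math.pi * r * r


def _cytosol_bleach_fraction(
    cell: InVivoCell, center: tuple[float, float], sigma_um: float, dose: float
) -> float:
    """Grid integral of the pulse bleach probability over the cell footprint."""
    n = 60
    xs = np.linspace(cell.center_um[0] - cell.length_um / 2, cell.center_um[0] + cell.length_um / 2, n)
    ys = np.linspace(cell.center_um[1] - cell.width_um / 2, cell.center_um[1] + cell.width_um / 2, n)
    X, Y = np.meshgrid(xs, ys)
    dx = abs(X - cell.center_um[0])
    dy = abs(Y - cell.center_um[1])
    r = cell.width_um / 2.0
    half_rect = cell.length_um / 2.0 - r
    inside = np.where(dx <= half_rect, dy <= r, (dx - half_rect) ** 2 + dy**2 <= r**2)
    g = np.exp(-((X - center[0]) ** 2 + (Y - center[1]) ** 2) / (2 * sigma_um**2))
    p = 1.0 - np.exp(-dose * g)
    return float(p[inside].mean()) if inside.any() else 0.0


def simulate_in_vivo_scene(
    cfg: SimulationConfig,
    n_cells: int,
    frap_target: tuple[float, float] | None = None,
    n_pulsed: int = 1,
    focus_tetramers: int = 12,
    pool_tetramers: int = 600,
    pulse_fwhm_um: float = 0.5,
    pulse_dose: float = 3.0,
    pulse_time: float | None = None,
) -> InVivoScene:
    """Simulate an in-vivo FRAP field: pulsed cells plus unpulsed controls.

    Each cell carries a finite cytosolic pool whose bright fraction decays
    under imaging with lifetime ``cfg.tau_b`` and 1-4 replisome foci of
    ``focus_tetramers`` tetramers.  A diffraction-limited Gaussian pulse
    (FWHM ``pulse_fwhm_um``) bleaches dyes according to the local dose; focus
    exchange draws tetramers from that cell's pool at the effective exchange
    rate.  The first ``n_pulsed`` cells are pulsed on their first focus
    (or on ``frap_target`` if given); the remaining cells are never pulsed
    and serve as the photobleaching control.
    """
    cfg.validate()
    if n_cells < 2:
        raise ValueError("need at least 2 cells (one control)")
    if not 1 <= n_pulsed <= n_cells - 1:
        raise ValueError("n_pulsed must leave at least one control cell")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x1F]))
    k_ex = effective_exchange_rate(cfg)
    t_pulse = cfg.pulse_times[0] if cfg.pulse_times else (pulse_time if pulse_time is not None else 5.0)
    if not 0 <= t_pulse <= cfg.duration:
        raise ValueError("pulse time outside the acquisition window")
    sigma = pulse_fwhm_um / (2.0 * math.sqrt(2.0 * math.log(2.0)))

    # lay cells on a grid (field of view ~ 40 x 40 um)
    cells: list[InVivoCell] = []
    per_row = max(1, int(math.ceil(math.sqrt(n_cells))))
    for i in range(n_cells):
        row, col = divmod(i, per_row)
        length = float(rng.uniform(4.5, 6.0))
        width = float(rng.uniform(1.0, 1.2))
        cx = 4.0 + col * 7.0
        cy = 3.0 + row * 3.0
        n_foci = int(rng.integers(1, 5))
        r = width / 2.0
        margin = r + 0.3
        lo, hi = cx - length / 2 + margin, cx + length / 2 - margin
        # replisome foci are diffraction-resolvable: keep them >= 0.8 um apart
        for _ in range(200):
            fx = np.sort(rng.uniform(lo, hi, n_foci))
            if n_foci == 1 or np.diff(fx).min() >= 0.8:
                break
        else:
            fx = np.linspace(lo, hi, n_foci)
        foci = [(float(x), cy) for x in fx]
        cells.append(
            InVivoCell(
                cell_id=i,
                center_um=(cx, cy),
                length_um=length,
                width_um=width,
                foci_um=foci,
                focus_tetramers=focus_tetramers,
                pool_tetramers=int(rng.poisson(pool_tetramers)),
                is_control=i >= n_pulsed,
            )
        )

    if frap_target is not None:
        hits = [c for c in cells if not c.is_control and c.contains(frap_target)]
        if not hits:
            raise ValueError(f"frap_target {frap_target} lies outside every pulsed cell")

    tt = np.arange(0.0, cfg.duration + 1e-9, cfg.frame_interval)
    p2 = cfg.dyes_mean - 1.0  # P(2 dyes | labelled)

    def draw_dye_bleach_times(n_tet: int, bleach_extra_p: float) -> list[list[float]]:
        """Absolute imaging-bleach times for each tetramer's dyes (clock from t=0,
        whole cell illuminated); the pulse kills cytosolic dyes with prob
        ``bleach_extra_p`` at t_pulse."""
        out = []
        for _ in range(n_tet):
            if rng.random() >= cfg.labeled_fraction:
                out.append([])
                continue
            nd = 1 + (rng.random() < p2)
            times = []
            for _ in range(nd):
                tb = rng.exponential(cfg.tau_b)
                # draw unconditionally so the random stream is identical
                # whatever the pulse energy (a zero-dose pulse is a no-op)
                if rng.random() < bleach_extra_p and tb > t_pulse:
                    tb = t_pulse
                times.append(tb)
            out.append(times)
        return out

    focus_traces: list[IntensityTrace] = []
    control_traces: list[IntensityTrace] = []

    for cell in cells:
        if not cell.is_control:
            center = frap_target if (frap_target is not None and cell.contains(frap_target)) else cell.foci_um[0]
            cell.pulse_center_um = center
            cell.cytosol_bleach_fraction = _cytosol_bleach_fraction(cell, center, sigma, pulse_dose)
        beta = cell.cytosol_bleach_fraction

        if cell.is_control:
            # whole-cell intensity: every labelled tetramer carries 1 or 2
            # dyes, all bleaching at tau_b under the imaging illumination
            n_lab = rng.binomial(cell.pool_tetramers, cfg.labeled_fraction)
            n_dyes_total = int(n_lab + rng.binomial(n_lab, p2))
            bleach = rng.exponential(cfg.tau_b, size=n_dyes_total)
            bright = (bleach[None, :] > tt[:, None]).sum(axis=1).astype(float)
            noise = rng.normal(0.0, cfg.noise_sd * 5.0, size=len(tt))
            trace = IntensityTrace(
                t=tt,
                I=bright * cfg.unit_brightness + cfg.baseline + noise,
                spot_id=f"cell{cell.cell_id}",
                pulse_times=[],
            )
            control_traces.append(trace)
            continue

        # pulsed cell: simulate the targeted focus at tetramer resolution
        center = frap_target if (frap_target is not None and cell.contains(frap_target)) else cell.foci_um[0]
        # pulse is centered on the target focus -> full dose there
        focus_kill_p = 1.0 - math.exp(-pulse_dose)

        # occupant tetramers: exchange renewal per site
        bright_count = np.zeros(len(tt))
        for _ in range(cell.focus_tetramers):
            # renewal process of occupants over [0, duration]
            occ_start = 0.0
            dyes = draw_dye_bleach_times(1, 0.0)[0]
            while True:
                dwell = rng.exponential(1.0 / k_ex) if k_ex > 0 else np.inf
                occ_end = occ_start + dwell
                # this occupant's bright-dye contribution
                for tb in dyes:
                    tb_eff = tb
                    hit = rng.random() < focus_kill_p  # unconditional draw
                    if hit and occ_start <= t_pulse < occ_end:
                        tb_eff = min(tb_eff, t_pulse)
                    lo, hi = occ_start, min(occ_end, tb_eff, cfg.duration)
                    if hi > lo:
                        i0 = np.searchsorted(tt, lo, side="left")
                        i1 = np.searchsorted(tt, hi, side="left")
                        bright_count[i0:i1] += 1
                if occ_end >= cfg.duration:
                    break
                occ_start = occ_end
                # replacement drawn from this cell's pool; its dyes have been
                # bleaching in the cytosol since t=0 and may have been hit by
                # the pulse tail
                dyes = draw_dye_bleach_times(1, beta)[0]
        noise = rng.normal(0.0, cfg.noise_sd, size=len(tt))
        trace = IntensityTrace(
            t=tt,
            I=bright_count * cfg.unit_brightness + cfg.baseline + noise,
            spot_id=f"cell{cell.cell_id}:focus0",
            pulse_times=[t_pulse],
        )
        focus_traces.append(trace)

    return InVivoScene(
        cells=cells,
        focus_traces=focus_traces,
        control_traces=control_traces,
        pulse_time=t_pulse,
        pulse_center_um=cells[0].foci_um[0] if frap_target is None else frap_target,
        pulse_fwhm_um=pulse_fwhm_um,
        pulse_dose=pulse_dose,
        frame_interval=cfg.frame_interval,
        duration=cfg.duration,
        tau_b=cfg.tau_b,
        k_ex=k_ex,
        seed=cfg.seed,
    )
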