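"""Simulation configuration for the fork/SSB-exchange model.

All kinetic, photophysical and imaging parameters of the stochastic replisome
simulator live in :class:`SimulationConfig`.  Configurations round-trip through
flat YAML files so that every pipeline stage can be re-run from disk.

Units
-----
Rates are per second, concentrations in nM (tetramer), lengths in nucleotides
or kilo-nucleotides (knt) as noted, times in seconds.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import yaml

__all__ = [
    "SimulationConfig",
    "DEFAULT_L_TABLE",
    "EXCHANGE_TIME_TABLE",
    "calibrate_exchange_constants",
    "interp_okazaki_mean",
    "internal_transfer_probability",
]

#: Mean Okazaki-fragment length (knt) versus solution SSB concentration (nM),
#: from alkaline-gel densitometry of rolling-circle products.  The highest
#: concentration is tabulated as 100 nM; the source reports it inconsistently
#: as 100 or 200 nM in different places, and we follow the figure caption
#: (100 nM).  See docs/methods.md.
DEFAULT_L_TABLE: dict[float, float] = {2.0: 1.4, 10.0: 1.5, 20.0: 2.0, 100.0: 2.8}

#: Measured FRAP exchange time (s) versus SSB concentration (nM) used to
#: calibrate the default exchange-rate constants.  The 20 nM exchange time was
#: never reported and is deliberately absent.
EXCHANGE_TIME_TABLE: dict[float, float] = {2.0: 20.0, 10.0: 10.0, 100.0: 2.9}


def calibrate_exchange_constants(
    pairs: Mapping[float, float] | None = None,
) -> tuple[float, float]:
    """Least-squares calibration of the pseudo-first-order exchange law.

    The effective per-tetramer exchange rate is modelled as
    ``k_ex(c) = k_intr + k_fac * c``.  Given measured ``{c: tau}`` pairs the
    rates ``1/tau`` are regressed linearly on ``c``.

    Returns
    -------
    (k_intr, k_fac) : tuple of float
        Intercept (s^-1) and slope (nM^-1 s^-1).
    """
    if pairs is None:
        pairs = EXCHANGE_TIME_TABLE
    if len(pairs) < 2:
        raise ValueError("need at least two (concentration, tau) pairs")
    c = np.array(sorted(pairs), dtype=float)
    k = 1.0 / np.array([pairs[ci] for ci in c], dtype=float)
    slope, intercept = np.polyfit(c, k, 1)
    return float(intercept), float(slope)


# Frozen defaults from calibrate_exchange_constants(EXCHANGE_TIME_TABLE):
# k_intr ~ 0.0571 s^-1, k_fac ~ 0.00289 nM^-1 s^-1, which reproduce the
# measured exchange times at 2/10/100 nM to within their quoted errors.
DEFAULT_K_INTR, DEFAULT_K_FAC = calibrate_exchange_constants()


def interp_okazaki_mean(c_ssb: float, table: Mapping[float, float]) -> float:
    """Mean Okazaki-fragment length (knt) at concentration ``c_ssb`` (nM).

    Log-linear interpolation in concentration between tabulated entries;
    clamped to the end values outside the tabulated range.  ``c_ssb == 0``
    (chase conditions) returns the lowest tabulated length.
    """
    if not table:
        raise ValueError("empty Okazaki-length table")
    if any(ci <= 0 for ci in table):
        raise ValueError("L_table keys (concentrations) must be > 0")
    cs = np.array(sorted(table), dtype=float)
    ls = np.array([table[ci] for ci in cs], dtype=float)
    if c_ssb <= cs[0]:
        return float(ls[0])
    if c_ssb >= cs[-1]:
        return float(ls[-1])
    return float(np.interp(math.log(c_ssb), np.log(cs), ls))


def internal_transfer_probability(c_ssb: float, p_int_scale: float) -> float:
    """Probability that a displaced tetramer transfers internally.

    Saturable competition between rebinding behind the helicase and loss to
    solution: ``p_int = s / (s + c)``.  Equals 1 at zero solution
    concentration (pure internal recycling, the chase regime).
    """
    if c_ssb < 0:
        raise ValueError("negative concentration")
    if p_int_scale <= 0:
        raise ValueError("p_int_scale must be > 0")
    return p_int_scale / (p_int_scale + c_ssb)


@dataclass
class SimulationConfig:
    """Parameters of one simulated replisome experiment.

    Attributes
    ----------
    v_mean, v_sd:
        Mean replication rate and between-replisome spread (bp/s).
    c_ssb:
        Solution SSB tetramer concentration (nM).  Zero means chase
        conditions (no external exchange from solution).
    k_intr, k_fac:
        Intrinsic (s^-1) and facilitated (nM^-1 s^-1) components of the
        effective per-tetramer exchange rate ``k_intr + k_fac * c_ssb``.
    p_int_scale:
        Competition constant (nM) of the internal-transfer probability
        ``p_int = p_int_scale / (p_int_scale + c_ssb)``.
    L_table:
        Map concentration (nM) -> mean Okazaki length (knt).
    L_mean_knt:
        Optional explicit mean Okazaki length overriding the table lookup
        (used e.g. for chase runs at ``c_ssb == 0``).
    footprint_nt:
        Nucleotides of ssDNA occluded per tetramer (35-nt binding mode).
    labeled_fraction:
        Fraction of solution tetramers carrying dye.
    dyes_mean:
        Mean dyes per labelled tetramer; dye count is 1 or 2 so the mean
        must lie in [1, 2].
    tau_b:
        Imaging photobleach lifetime per dye under the run's illumination (s).
    frame_interval, duration, pulse_times:
        Acquisition timing (s); FRAP pulse times within [0, duration].
    initial_tetramers:
        Labelled tetramers pre-assembled at the fork at t = 0 (chase mode);
        None tiles the fork from solution.
    warmup_s:
        Unilluminated replication time before acquisition starts at t = 0.
        The fork population equilibrates during the warm-up; dyes only start
        bleaching once imaging begins.
    unit_brightness, baseline, noise_sd:
        Intensity model of the emitted traces (AU per bright dye, offset,
        Gaussian read-noise sd).
    seed:
        Base seed of the run's random generator; recorded in all outputs.
    """

    v_mean: float = 750.0
    v_sd: float = 73.0
    c_ssb: float = 10.0
    k_intr: float = DEFAULT_K_INTR
    k_fac: float = DEFAULT_K_FAC
    p_int_scale: float = 200.0
    L_table: dict[float, float] = field(default_factory=lambda: dict(DEFAULT_L_TABLE))
    L_mean_knt: float | None = None
    footprint_nt: int = 35
    labeled_fraction: float = 1.0
    dyes_mean: float = 1.5
    tau_b: float = 9.5
    frame_interval: float = 0.5
    pulse_times: list[float] = field(default_factory=list)
    duration: float = 60.0
    initial_tetramers: int | None = None
    warmup_s: float = 0.0
    unit_brightness: float = 1.0
    baseline: float = 0.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.v_mean < 0 or self.v_sd < 0:
            raise ValueError("replication rate parameters must be >= 0")
        if self.c_ssb < 0:
            raise ValueError("negative concentration")
        if self.k_intr < 0 or self.k_fac < 0:
            raise ValueError("exchange-rate constants must be >= 0")
        if self.p_int_scale <= 0:
            raise ValueError("p_int_scale must be > 0")
        if not self.L_table:
            raise ValueError("empty L_table")
        if any(c <= 0 or l <= 0 for c, l in self.L_table.items()):
            raise ValueError("L_table concentrations and lengths must be > 0")
        if self.L_mean_knt is not None and self.L_mean_knt <= 0:
            raise ValueError("L_mean_knt must be > 0")
        if self.footprint_nt < 1:
            raise ValueError("footprint_nt must be >= 1")
        if not 0.0 <= self.labeled_fraction <= 1.0:
            raise ValueError("labeled_fraction must lie in [0, 1]")
        if not 1.0 <= self.dyes_mean <= 2.0:
            raise ValueError("dyes_mean must lie in [1, 2]")
        if self.tau_b <= 0:
            raise ValueError("tau_b must be > 0")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        for tp in self.pulse_times:
            if not 0.0 <= tp <= self.duration:
                raise ValueError(f"pulse time {tp} outside [0, duration]")
        if self.initial_tetramers is not None and self.initial_tetramers < 0:
            raise ValueError("initial_tetramers must be >= 0")
        if self.warmup_s < 0:
            raise ValueError("warmup_s must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    # -- derived quantities -------------------------------------------------

    @property
    def okazaki_mean_knt(self) -> float:
        if self.L_mean_knt is not None:
            return self.L_mean_knt
        return interp_okazaki_mean(self.c_ssb, self.L_table)

    @property
    def p_internal(self) -> float:
        return internal_transfer_probability(self.c_ssb, self.p_int_scale)

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["L_table"] = {float(k): float(v) for k, v in self.L_table.items()}
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        d = dict(d)
        if "L_table" in d and d["L_table"] is not None:
            d["L_table"] = {float(k): float(v) for k, v in d["L_table"].items()}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def replace(self, **kw) -> "SimulationConfig":
        return dataclasses.replace(self, **kw)
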