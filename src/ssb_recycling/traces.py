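"""Time-stamped fluorescence intensity traces and their CSV/JSON layout.

A trace is the intensity of one spot or focus versus time, together with the
FRAP pulse times that apply to it.  Traces are exchanged between pipeline
stages as CSV (columns ``t``, ``intensity``, ``spot_id``) with pulse times in
a JSON sidecar, so real measured traces can be dropped in.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["IntensityTrace", "read_traces_csv", "write_traces_csv"]


@dataclass
class IntensityTrace:
    t: np.ndarray  # s, strictly increasing
    I: np.ndarray  # AU
    spot_id: str = "spot0"
    pulse_times: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.I = np.asarray(self.I, dtype=float)
        if self.t.shape != self.I.shape:
            raise ValueError("t and I must have the same shape")
        if len(self.t) > 1 and not np.all(np.diff(self.t) > 0):
            raise ValueError("t must be strictly increasing")
        if not np.all(np.isfinite(self.I)):
            raise ValueError("intensities must be finite")

    def __len__(self) -> int:
        return len(self.t)

    def normalized(self, t_max: float | None = None, t_min: float = 0.0) -> "IntensityTrace":
        """Scale so the mean intensity in [t_min, t_max) equals 1.

        ``t_max`` defaults to the first pulse (else the whole trace); ``t_min``
        lets callers skip the fork-assembly burn-in at the start of a run.
        """
        if t_max is None:
            t_max = min(self.pulse_times) if self.pulse_times else self.t[-1] + 1.0
        mask = (self.t < t_max) & (self.t >= t_min)
        ref = float(np.mean(self.I[mask])) if mask.any() else float(np.mean(self.I))
        if ref == 0:
            raise ValueError("cannot normalize: zero pre-pulse intensity")
        return IntensityTrace(self.t, self.I / ref, self.spot_id, list(self.pulse_times))


def write_traces_csv(traces: list[IntensityTrace], path) -> None:
    path = Path(path)
    frames = [
        pd.DataFrame({"t": tr.t, "intensity": tr.I, "spot_id": tr.spot_id}) for tr in traces
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    sidecar = {tr.spot_id: list(map(float, tr.pulse_times)) for tr in traces}
    path.with_suffix(".pulses.json").write_text(json.dumps(sidecar, indent=1))


def read_traces_csv(path) -> list[IntensityTrace]:
    path = Path(path)
    df = pd.read_csv(path)
    sidecar_path = path.with_suffix(".pulses.json")
    pulses = json.loads(sidecar_path.read_text()) if sidecar_path.exists() else {}
    out = []
    for sid, grp in df.groupby("spot_id", sort=False):
        out.append(
            IntensityTrace(
                t=grp["t"].to_numpy(),
                I=grp["intensity"].to_numpy(),
                spot_id=str(sid),
                pulse_times=list(pulses.get(str(sid), [])),
            )
        )
    return out
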