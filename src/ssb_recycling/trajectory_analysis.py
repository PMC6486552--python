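"""Spots, trajectories, replication rates and focus co-localization.

The fork in a kymograph is tracked as the brightest persistent spot per time
row (nearest-neighbour linking, maximum step 3 px/frame); replication rates
come from piecewise-linear segmentation of the tracked position with a
BIC-penalized changepoint search, each constant-slope segment contributing
one rate.  Rates pooled over many replisomes are summarized by a Gaussian
fit to their histogram, reported as mean +/- SEM.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from lmfit.models import GaussianModel
from scipy.spatial import cKDTree
from skimage.feature import peak_local_max

from .microscopy_render import KymographStack

__all__ = [
    "Spot",
    "SpotSeries",
    "SegmentedTrajectory",
    "RateDistribution",
    "detect_spots",
    "detect_spots_1d",
    "track_kymograph",
    "segment_rates",
    "rate_distribution",
    "colocalize_foci",
]

log = logging.getLogger(__name__)


@dataclass
class Spot:
    y: float  # px (row)
    x: float  # px (col)
    intensity: float


@dataclass
class SpotSeries:
    """Per-frame position/intensity of one tracked spot."""

    spot_id: str
    t: np.ndarray  # s, strictly increasing
    position_px: np.ndarray
    intensity: np.ndarray
    channel: str = "ssb"

    def __post_init__(self) -> None:
        if len(self.t) > 1 and not np.all(np.diff(self.t) > 0):
            raise ValueError("frames must be strictly increasing in t")


@dataclass
class Segment:
    t_start: float
    t_end: float
    slope_bp_s: float
    intercept_bp: float

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


@dataclass
class SegmentedTrajectory:
    segments: list[Segment]
    residual_variance: float

    @property
    def breakpoints(self) -> list[float]:
        return [s.t_start for s in self.segments[1:]]

    @property
    def rates(self) -> list[float]:
        return [s.slope_bp_s for s in self.segments]


@dataclass
class RateDistribution:
    rates: np.ndarray
    mean: float
    sd: float
    sem: float
    n: int
    n_rejected: int = 0

    def to_dict(self) -> dict:
        return {
            "mean_bp_s": self.mean,
            "sd_bp_s": self.sd,
            "sem_bp_s": self.sem,
            "N": self.n,
            "n_rejected": self.n_rejected,
        }


# --------------------------------------------------------------------------
# detection
# --------------------------------------------------------------------------


def _centroid_refine(frame: np.ndarray, peak: tuple[int, int], half: int = 3) -> tuple[float, float]:
    """Subpixel refinement by background-subtracted intensity centroid."""
    y0, x0 = peak
    ys = slice(max(0, y0 - half), min(frame.shape[0], y0 + half + 1))
    xs = slice(max(0, x0 - half), min(frame.shape[1], x0 + half + 1))
    win = frame[ys, xs].astype(float)
    win = np.maximum(win - np.median(win), 0.0)
    tot = win.sum()
    if tot <= 0:
        return float(y0), float(x0)
    yy, xx = np.mgrid[ys, xs]
    return float((win * yy).sum() / tot), float((win * xx).sum() / tot)


def detect_spots(
    frame: np.ndarray,
    k_mad: float = 5.0,
    min_distance: int = 3,
    saturation: float = 65535.0,
) -> list[Spot]:
    """Local maxima above median + k*MAD, refined to subpixel centroids."""
    frame = np.asarray(frame, dtype=float)
    if (frame >= saturation).any():
        log.warning("saturated pixels in frame; positions may be biased")
    med = np.median(frame)
    mad = np.median(np.abs(frame - med)) * 1.4826
    thr = med + k_mad * max(mad, 1e-12)
    peaks = peak_local_max(frame, min_distance=min_distance, threshold_abs=thr)
    out = []
    for y0, x0 in peaks:
        y, x = _centroid_refine(frame, (int(y0), int(x0)))
        out.append(Spot(y=y, x=x, intensity=float(frame[int(y0), int(x0)] - med)))
    return out


def detect_spots_1d(row: np.ndarray, k_mad: float = 5.0, half: int = 3) -> list[Spot]:
    """1-D variant for kymograph time rows."""
    row = np.asarray(row, dtype=float)
    med = np.median(row)
    mad = np.median(np.abs(row - med)) * 1.4826
    thr = med + k_mad * max(mad, 1e-12)
    out = []
    for i in range(1, len(row) - 1):
        if row[i] >= thr and row[i] >= row[i - 1] and row[i] > row[i + 1]:
            lo, hi = max(0, i - half), min(len(row), i + half + 1)
            win = np.maximum(row[lo:hi] - med, 0.0)
            x = float((win * np.arange(lo, hi)).sum() / win.sum()) if win.sum() > 0 else float(i)
            out.append(Spot(y=0.0, x=x, intensity=float(row[i] - med)))
    return out


def track_kymograph(
    kymo: KymographStack,
    channel: str = "ssb",
    max_step_px: float = 3.0,
    k_mad: float = 5.0,
) -> SpotSeries:
    """Track the fork as the brightest persistent spot across time rows.

    Nearest-neighbour linking with a maximum step of ``max_step_px`` per
    frame; frames with no admissible detection are skipped.
    """
    img = getattr(kymo, channel)
    t = np.arange(img.shape[0]) * kymo.frame_interval_s
    per_frame = [detect_spots_1d(img[i], k_mad=k_mad) for i in range(img.shape[0])]
    if not any(per_frame):
        raise ValueError("could not track a spot in this kymograph")
    # seed at the globally brightest detection, then link outward in both
    # directions; the dim assembly phase at the start cannot hijack the track
    seed_frame = max(
        (i for i, s in enumerate(per_frame) if s),
        key=lambda i: max(sp.intensity for sp in per_frame[i]),
    )
    picks: dict[int, Spot] = {
        seed_frame: max(per_frame[seed_frame], key=lambda s: s.intensity)
    }
    for direction in (1, -1):
        last_x = picks[seed_frame].x
        i = seed_frame + direction
        while 0 <= i < img.shape[0]:
            near = [s for s in per_frame[i] if abs(s.x - last_x) <= max_step_px]
            if near:
                best = max(near, key=lambda s: s.intensity)
                picks[i] = best
                last_x = best.x
            i += direction
    frames = sorted(picks)
    ts = [t[i] for i in frames]
    xs = [picks[i].x for i in frames]
    Is = [picks[i].intensity for i in frames]
    if len(ts) < 2:
        raise ValueError("could not track a spot in this kymograph")
    return SpotSeries(
        spot_id="fork",
        t=np.array(ts),
        position_px=np.array(xs),
        intensity=np.array(Is),
        channel=channel,
    )


# --------------------------------------------------------------------------
# segmentation
# --------------------------------------------------------------------------


def _seg_rss(t: np.ndarray, y: np.ndarray, i: int, j: int, suff) -> float:
    """RSS of the LS line on points [i, j) from cumulative sufficient stats."""
    S1, St, Sy, Stt, Sty, Syy = (s[j] - s[i] for s in suff)
    n = S1
    det = n * Stt - St * St
    if det <= 0:
        return 0.0
    b = (n * Sty - St * Sy) / det
    a = (Sy - b * St) / n
    rss = Syy - 2 * a * Sy - 2 * b * Sty + n * a * a + 2 * a * b * St + b * b * Stt
    return max(rss, 0.0)


def segment_rates(
    series: SpotSeries,
    bp_per_px: float,
    min_segment_s: float = 5.0,
    penalty: float | None = None,
) -> SegmentedTrajectory:
    """Piecewise-linear fit of position vs time by penalized least squares.

    Dynamic-programming changepoint search minimizing total RSS plus a
    BIC-style penalty (default ``3 * sigma^2 * log n`` per extra segment,
    sigma estimated from first differences).  Series shorter than twice the
    minimum segment fall back to a single segment.
    """
    t, y = series.t, series.position_px * bp_per_px
    n = len(t)
    if n < 10:
        log.warning("series has %d < 10 frames; single-segment fallback", n)
        return _single_segment(t, y)
    dt = float(np.median(np.diff(t)))
    min_pts = max(3, int(round(min_segment_s / dt)))
    if n < 2 * min_pts:
        return _single_segment(t, y)
    # noise scale from detrended first differences
    d = np.diff(y)
    sigma2 = float(np.median(np.abs(d - np.median(d))) * 1.4826) ** 2 / 2.0
    sigma2 = max(sigma2, 1e-12)
    if penalty is None:
        penalty = 3.0 * sigma2 * math.log(n)
    ones = np.ones(n)
    suff = tuple(
        np.concatenate([[0.0], np.cumsum(v)])
        for v in (ones, t, y, t * t, t * y, y * y)
    )
    # DP over segment ends
    INF = float("inf")
    cost = np.full(n + 1, INF)
    prev = np.zeros(n + 1, dtype=int)
    cost[0] = -penalty  # first segment carries no penalty
    for j in range(min_pts, n + 1):
        best, barg = INF, 0
        for i in range(0, j - min_pts + 1):
            if cost[i] == INF:
                continue
            c = cost[i] + penalty + _seg_rss(t, y, i, j, suff)
            if c < best:
                best, barg = c, i
        cost[j] = best
        prev[j] = barg
    # backtrack
    cuts = [n]
    while cuts[-1] > 0:
        cuts.append(int(prev[cuts[-1]]))
    cuts = cuts[::-1]
    segments = []
    rss_total = 0.0
    for i, j in zip(cuts[:-1], cuts[1:]):
        b, a = np.polyfit(t[i:j], y[i:j], 1)
        res = y[i:j] - (a + b * t[i:j])
        rss_total += float(res @ res)
        segments.append(
            Segment(t_start=float(t[i]), t_end=float(t[j - 1]), slope_bp_s=float(b), intercept_bp=float(a))
        )
    return SegmentedTrajectory(segments=segments, residual_variance=rss_total / n)


def _single_segment(t: np.ndarray, y: np.ndarray) -> SegmentedTrajectory:
    if len(t) < 2:
        raise ValueError("need at least 2 points")
    b, a = np.polyfit(t, y, 1)
    res = y - (a + b * t)
    return SegmentedTrajectory(
        segments=[Segment(float(t[0]), float(t[-1]), float(b), float(a))],
        residual_variance=float(res @ res) / len(t),
    )


# --------------------------------------------------------------------------
# rate pooling and co-localization
# --------------------------------------------------------------------------


def rate_distribution(rates: list[float] | np.ndarray, bins: str | int = "auto") -> RateDistribution:
    """Histogram + Gaussian fit of per-replisome rates; mean +/- SEM.

    Non-finite rates are rejected (count logged).  The Gaussian is fit by
    least squares to the histogram, as is conventional for these rate
    distributions; with few rates or degenerate histograms the moment
    estimates are used directly."""
    rates = np.asarray(rates, dtype=float)
    finite = np.isfinite(rates)
    n_rej = int((~finite).sum())
    if n_rej:
        log.warning("rejected %d non-finite rates", n_rej)
    rates = rates[finite]
    if len(rates) < 5:
        raise ValueError("need at least 5 rates")
    mu, sd = float(np.mean(rates)), float(np.std(rates, ddof=1))
    if sd > 0 and len(rates) >= 10:
        counts, edges = np.histogram(rates, bins=bins)
        centers = 0.5 * (edges[:-1] + edges[1:])
        if (counts > 0).sum() >= 4:
            model = GaussianModel()
            params = model.make_params(amplitude=counts.max() * sd, center=mu, sigma=sd)
            try:
                res = model.fit(counts, params, x=centers)
                if res.success and sd * 0.2 < res.params["sigma"].value < sd * 5:
                    mu = float(res.params["center"].value)
                    sd = float(res.params["sigma"].value)
            except Exception:  # pragma: no cover - fall back to moments
                pass
    n = len(rates)
    return RateDistribution(
        rates=rates, mean=mu, sd=sd, sem=sd / math.sqrt(n), n=n, n_rejected=n_rej
    )


def colocalize_foci(
    foci_a: list[tuple[float, float]],
    foci_b: list[tuple[float, float]],
    radius_nm: float = 250.0,
) -> float | None:
    """Fraction of A-foci with a B-focus within ``radius_nm``.

    Positions are in nm (same frame).  Returns None when A is empty
    (explicit no-data marker)."""
    if radius_nm <= 0:
        raise ValueError("radius must be > 0")
    if not foci_a:
        return None
    if not foci_b:
        return 0.0
    tree = cKDTree(np.asarray(foci_b, dtype=float))
    d, _ = tree.query(np.asarray(foci_a, dtype=float), k=1)
    return float(np.mean(d <= radius_nm))
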