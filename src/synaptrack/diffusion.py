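"""Per-trajectory diffusion analysis: MSD curves, D estimation, mobility stats.

The instantaneous diffusion coefficient of each trajectory is obtained from an
ordinary least-squares line through the first few points of its time-averaged
mean-square-displacement curve, D = slope / 4 for 2-D Brownian motion.  The
fit keeps a free intercept so that static localization noise (which offsets
the MSD by 4*sigma_loc^2) does not bias D.  Confined trajectories can yield a
non-positive slope; their D is clamped to a fixed floor of 1e-5 µm²/s and
flagged.  Trajectories with D below 0.01 µm²/s — molecules exploring less
than the pointing accuracy of the instrument — are classified immobile.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd

from .track import Track

__all__ = [
    "AnalysisParams", "MSDCurve", "DiffusionEstimate", "MobilitySummary",
    "compute_msd", "estimate_diffusion", "classify_mobility",
    "summarize_mobility", "diffusion_distribution", "analyze_tracks",
]


@dataclass(frozen=True)
class AnalysisParams:
    """MSD-fit and classification parameters.

    ``n_fit`` MSD points enter the linear fit (4 by convention), tracks need
    at least ``L_min`` points (10), non-positive slopes floor D at ``D_floor``
    (1e-5 µm²/s), and ``D_immobile`` (0.01 µm²/s) splits immobile from mobile
    with a strict ``<`` comparison.
    """

    n_fit: int = 4
    L_min: int = 10
    D_floor: float = 1e-5
    D_immobile: float = 0.01
    frame_interval: float = 0.02

    def __post_init__(self) -> None:
        if self.n_fit < 2:
            raise ValueError("n_fit must be >= 2")
        if self.L_min <= self.n_fit:
            raise ValueError("L_min must exceed n_fit")
        if not self.D_floor < self.D_immobile:
            raise ValueError("D_floor must be < D_immobile")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")


@dataclass
class MSDCurve:
    track_id: int
    lag_times: np.ndarray   # s
    msd: np.ndarray         # µm²
    n_pairs: np.ndarray     # pairs averaged per lag


@dataclass
class DiffusionEstimate:
    track_id: int
    D: float                # µm²/s
    intercept: float        # µm²
    floored: bool
    n_points_used: int


@dataclass
class MobilitySummary:
    n_tracks: int
    immobile_fraction: float
    mobile_fraction: float
    median_D: float


def compute_msd(track: Track, max_lag: int | None = None,
                frame_interval: float = 0.02) -> MSDCurve:
    """Time-averaged MSD over all overlapping ordered pairs.

    ``MSD(n*dt) = mean_i |r(i+n) - r(i)|^2`` with ``n_pairs(n) = L - n``.
    Assumes uniform frame spacing (gap-containing tracks are excluded
    upstream).  ``max_lag`` past ``L - 1`` is truncated with a warning.
    """
    L = len(track)
    if L < 2:
        raise ValueError("track must have at least 2 points")
    if max_lag is None:
        max_lag = L - 1
    if max_lag >= L:
        warnings.warn(f"max_lag {max_lag} >= track length {L}; truncating to {L - 1}")
        max_lag = L - 1
    pos = track.positions
    lags = np.arange(1, max_lag + 1)
    msd = np.array([np.mean(np.sum((pos[n:] - pos[:-n]) ** 2, axis=1)) for n in lags])
    return MSDCurve(track.track_id, lags * frame_interval, msd, L - lags)


def estimate_diffusion(msd: MSDCurve, params: AnalysisParams = AnalysisParams()) -> DiffusionEstimate:
    """OLS line through the first ``n_fit`` MSD points; D = slope / 4.

    A non-positive slope (a very confined trajectory) floors D at
    ``params.D_floor`` exactly, with ``floored=True``.
    """
    if len(msd.msd) < params.n_fit:
        raise ValueError(f"MSD curve has {len(msd.msd)} lags; need n_fit={params.n_fit}")
    t = msd.lag_times[: params.n_fit]
    y = msd.msd[: params.n_fit]
    slope, intercept = np.polyfit(t, y, 1)
    if slope <= 0:
        return DiffusionEstimate(msd.track_id, params.D_floor, float(intercept), True, params.n_fit)
    return DiffusionEstimate(msd.track_id, float(slope) / 4.0, float(intercept), False, params.n_fit)


def classify_mobility(est: DiffusionEstimate, params: AnalysisParams = AnalysisParams()) -> str:
    """'immobile' iff D < D_immobile (strict); 'mobile' otherwise."""
    return "immobile" if est.D < params.D_immobile else "mobile"


def summarize_mobility(estimates: list[DiffusionEstimate],
                       params: AnalysisParams = AnalysisParams()) -> MobilitySummary:
    """Mobile/immobile fractions and median D over one cell's estimates.

    Floored estimates count toward the immobile pool and enter the median.
    """
    if not estimates:
        raise ValueError("summarize_mobility requires at least one estimate")
    Ds = np.array([e.D for e in estimates])
    immobile = np.array([classify_mobility(e, params) == "immobile" for e in estimates])
    frac = float(immobile.mean())
    return MobilitySummary(len(estimates), frac, 1.0 - frac, float(np.median(Ds)))


def diffusion_distribution(
    estimates: list[DiffusionEstimate],
    bin_width: float = 0.15,
    lo: float | None = None,
    hi: float = 1.0,
    D_floor: float = 1e-5,
) -> tuple[np.ndarray, np.ndarray]:
    """Normalized histogram of log10 D (semi-log mobility distribution).

    Bins span ``[log10(D_floor), hi]`` in ``bin_width``-decade steps; the
    returned ``(edges, mass)`` satisfies ``mass.sum() == 1`` for non-empty
    input.  Floored estimates land in the lowest bin.
    """
    if lo is None:
        lo = np.log10(D_floor)
    n_bins = int(np.ceil((hi - lo) / bin_width - 1e-9))
    edges = lo + bin_width * np.arange(n_bins + 1)
    logD = np.log10(np.array([max(e.D, D_floor) for e in estimates]))
    counts, _ = np.histogram(np.clip(logD, lo, edges[-1] - 1e-12), bins=edges)
    total = counts.sum()
    mass = counts / total if total else counts.astype(float)
    return edges, mass


def analyze_tracks(tracks: list[Track],
                   params: AnalysisParams = AnalysisParams()) -> list[DiffusionEstimate]:
    """MSD-fit every track of length >= L_min; shorter tracks are excluded."""
    out = []
    for t in tracks:
        if len(t) < params.L_min:
            continue
        msd = compute_msd(t, max_lag=params.n_fit, frame_interval=params.frame_interval)
        out.append(estimate_diffusion(msd, params))
    return out


def estimates_to_table(estimates: list[DiffusionEstimate]) -> pd.DataFrame:
    return pd.DataFrame({
        "track_id": [e.track_id for e in estimates],
        "D_um2_s": [e.D for e in estimates],
        "intercept_um2": [e.intercept for e in estimates],
        "floored": [e.floored for e in estimates],
        "n_points": [e.n_points_used for e in estimates],
    })
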