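"""Accuracy metrics: componentwise and Euclidean RMSE in pixels and degrees.

For every valid frame ``n`` the signed errors ``e_x[n] = X_est - X_true``
and ``e_y[n]`` are accumulated.  The per-phase figures are

    MSE_x = sum_n e_x^2[n] / N          RMSE_x = sqrt(MSE_x)
    MSE_rho = MSE_x + MSE_y             RMSE_rho = sqrt(MSE_rho)

i.e. the Euclidean (radial) error combines the two components in
quadrature; it is the single most representative accuracy number.
Errors are computed in pixels and the aggregated RMSE values are then
converted to degrees of visual angle.  Across users, reports give the
mean, the population standard deviation (divisor N) and the relative
standard deviation RSD% = 100 * SD / mean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .geometry import ScreenGeometry

__all__ = [
    "SessionResult",
    "ErrorStats",
    "AggregateStats",
    "rmse_components",
    "euclidean_rmse",
    "pixels_to_degrees",
    "aggregate_users",
    "session_report",
]


@dataclass
class SessionResult:
    """Per-frame true/estimated POG pairs for one phase of one session."""

    frame_index: np.ndarray  # (N,)
    true_pog: np.ndarray  # (N, 2) screen px
    est_pog: np.ndarray  # (N, 2) screen px
    phase: str  # "calibration" | "test"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frame_index = np.asarray(self.frame_index, dtype=int)
        self.true_pog = np.asarray(self.true_pog, dtype=float)
        self.est_pog = np.asarray(self.est_pog, dtype=float)
        n = self.frame_index.shape[0]
        if self.true_pog.shape != (n, 2) or self.est_pog.shape != (n, 2):
            raise ValueError("true/estimated POG arrays must be (N, 2)")

    @classmethod
    def from_pairs(cls, true_pog, est_pog, frame_index=None, phase="test",
                   metadata=None) -> "SessionResult":
        true_pog = np.asarray(true_pog, dtype=float)
        if frame_index is None:
            frame_index = np.arange(len(true_pog))
        return cls(frame_index=np.asarray(frame_index),
                   true_pog=true_pog,
                   est_pog=np.asarray(est_pog, dtype=float),
                   phase=phase, metadata=metadata or {})

    @property
    def n_valid(self) -> int:
        return self.true_pog.shape[0]

    @property
    def errors(self) -> np.ndarray:
        """Signed (e_x, e_y) per frame, estimated minus true, in pixels."""
        return self.est_pog - self.true_pog

    def to_frame(self) -> pd.DataFrame:
        e = self.errors
        return pd.DataFrame({
            "frame_idx": self.frame_index,
            "true_x": self.true_pog[:, 0], "true_y": self.true_pog[:, 1],
            "est_x": self.est_pog[:, 0], "est_y": self.est_pog[:, 1],
            "e_x": e[:, 0], "e_y": e[:, 1],
        })


@dataclass(frozen=True)
class ErrorStats:
    """MSE/RMSE per component and Euclidean, in pixels and (optionally) degrees."""

    N: int
    MSE_x: float
    MSE_y: float
    RMSE_x: float
    RMSE_y: float
    MSE_rho: float
    RMSE_rho: float
    deg_RMSE_x: Optional[float] = None
    deg_RMSE_y: Optional[float] = None
    deg_RMSE_rho: Optional[float] = None


def rmse_components(
    result: SessionResult, screen: Optional[ScreenGeometry] = None
) -> ErrorStats:
    """Componentwise and Euclidean MSE/RMSE over the valid frames.

    With a screen geometry the pixel RMSE values are additionally
    converted to degrees of visual angle (conversion applied to the
    aggregated pixel RMSE, not per frame).
    """
    if result.n_valid < 1:
        raise ValueError("cannot evaluate a session with no valid records")
    e = result.errors
    mse_x = float(np.mean(e[:, 0] ** 2))
    mse_y = float(np.mean(e[:, 1] ** 2))
    mse_rho = mse_x + mse_y
    deg = {}
    if screen is not None:
        dx = screen.pixels_to_degrees(math.sqrt(mse_x))
        dy = screen.pixels_to_degrees(math.sqrt(mse_y))
        deg = {
            "deg_RMSE_x": dx,
            "deg_RMSE_y": dy,
            "deg_RMSE_rho": euclidean_rmse(dx, dy),
        }
    return ErrorStats(
        N=result.n_valid,
        MSE_x=mse_x, MSE_y=mse_y,
        RMSE_x=math.sqrt(mse_x), RMSE_y=math.sqrt(mse_y),
        MSE_rho=mse_rho, RMSE_rho=math.sqrt(mse_rho),
        **deg,
    )


def euclidean_rmse(rmse_x: float, rmse_y: float) -> float:
    """Radial RMSE from the two components: sqrt(RMSE_x^2 + RMSE_y^2)."""
    return math.hypot(rmse_x, rmse_y)


def pixels_to_degrees(e_px: float, screen: ScreenGeometry) -> float:
    """Visual angle in degrees for an on-screen pixel distance."""
    return screen.pixels_to_degrees(e_px)


@dataclass(frozen=True)
class AggregateStats:
    """Across-user summary: mean, population SD, relative SD in percent."""

    n: int
    mean: float
    sd: float
    rsd_pct: float


def aggregate_users(values: Sequence[float]) -> AggregateStats:
    """Mean, population standard deviation (divisor N) and RSD% of values."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot aggregate an empty list")
    mean = float(v.mean())
    sd = float(v.std(ddof=0))
    if mean == 0.0:
        if sd > 0.0:
            raise ValueError("RSD undefined: zero mean with nonzero spread")
        rsd = 0.0
    else:
        rsd = 100.0 * sd / mean
    return AggregateStats(n=int(v.size), mean=mean, sd=sd, rsd_pct=rsd)


def session_report(
    results: Sequence[SessionResult], screen: ScreenGeometry
) -> pd.DataFrame:
    """Long-format accuracy table with per-session aggregate footer rows.

    One row per (user, session, phase) with RMSE_x/RMSE_y/RMSE_rho in
    degrees, followed by mean/SD/RSD% rows per (session, phase) block
    and combined across sessions.
    """
    if not results:
        raise ValueError("no session results to report")
    rows = []
    for res in results:
        stats = rmse_components(res, screen)
        rows.append({
            "user": res.metadata.get("user", ""),
            "session": res.metadata.get("session", ""),
            "setting": res.metadata.get("setting", ""),
            "phase": res.phase,
            "row": "user",
            "rmse_x_deg": stats.deg_RMSE_x,
            "rmse_y_deg": stats.deg_RMSE_y,
            "rmse_rho_deg": stats.deg_RMSE_rho,
        })
    df = pd.DataFrame(rows)
    footers = []
    groupings = [["session", "phase"], ["phase"]]
    for keys in groupings:
        for gvals, grp in df.groupby(keys, sort=False):
            if keys == ["session", "phase"] or df["session"].nunique() > 1:
                base = dict(zip(keys, gvals if isinstance(gvals, tuple) else (gvals,)))
                for metric in ("rmse_x_deg", "rmse_y_deg", "rmse_rho_deg"):
                    agg = aggregate_users(grp[metric].to_numpy())
                    base[metric] = agg.mean
                    base[f"{metric}_sd"] = agg.sd
                    base[f"{metric}_rsd_pct"] = agg.rsd_pct
                base["row"] = "aggregate" if keys == ["session", "phase"] else "combined"
                footers.append(base)
    return pd.concat([df, pd.DataFrame(footers)], ignore_index=True)
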