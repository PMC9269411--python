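"""Horizontal-propagation measurements: latency basin, phase, bilinear fit.

The onset latency of Surround-Only responses grows linearly with the
stimulus eccentricity from the RF center (the "latency basin"); the slope of
an ordinary least-squares regression of latency on eccentricity, combined
with a retino-cortical magnification factor (mm of cortex per degree),
yields the **apparent speed of horizontal propagation**

    ASHP (mm/ms) = magnification (mm/deg) / slope (ms/deg).

The **input phase** is the onset-latency difference between the laterally
driven (Surround-Only) and feedforward (Center-Only) responses after
realignment on a common reference (the time the center stimulus was, or
would have been, shown); positive phase means the horizontal input leads.
The dependence of the spiking latency advance on input phase is summarized
by a **bilinear fit**: two connex linear segments whose breakpoint is chosen
by exhaustive search to maximize explained variance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy.stats import gaussian_kde

__all__ = [
    "AshpFit",
    "PhasePoint",
    "BilinearFit",
    "fit_latency_basin",
    "input_phase",
    "fit_bilinear",
    "kde_density",
    "deg_per_s_to_mm_per_ms",
    "mm_per_ms_to_deg_per_s",
    "human_to_cat_speed",
    "DEFAULT_MAGNIFICATION_MM_PER_DEG",
    "HUMAN_TO_CAT_MAGNIFICATION_RATIO",
]

#: cat retino-cortical conversion consistent with 150-250 deg/s ~ 0.15-0.25 mm/ms
DEFAULT_MAGNIFICATION_MM_PER_DEG = 1.0
#: parafoveal magnification-factor ratio between human and cat
HUMAN_TO_CAT_MAGNIFICATION_RATIO = 3.0


# ---------------------------------------------------------------------------
# unit conversions
# ---------------------------------------------------------------------------

def deg_per_s_to_mm_per_ms(
    speed_deg_per_s: float, magnification: float = DEFAULT_MAGNIFICATION_MM_PER_DEG
) -> float:
    """Visual-flow speed (deg/s) to cortical propagation speed (mm/ms)."""
    return speed_deg_per_s * magnification / 1000.0


def mm_per_ms_to_deg_per_s(
    speed_mm_per_ms: float, magnification: float = DEFAULT_MAGNIFICATION_MM_PER_DEG
) -> float:
    return speed_mm_per_ms * 1000.0 / magnification


def human_to_cat_speed(
    speed_deg_per_s: float, ratio: float = HUMAN_TO_CAT_MAGNIFICATION_RATIO
) -> float:
    """Human retinal speed to its cat equivalent via the magnification ratio."""
    return speed_deg_per_s * ratio


# ---------------------------------------------------------------------------
# latency basin -> ASHP
# ---------------------------------------------------------------------------

@dataclass
class AshpFit:
    """OLS latency-vs-eccentricity fit and the inferred propagation speed."""

    slope: float  # ms/deg
    intercept: float  # ms
    ashp: float  # mm/ms; NaN when slope <= 0 (no propagation signature)
    r2: float
    magnification_used: float
    points: np.ndarray  # (n, 2) eccentricity, latency
    slope_stderr: float = float("nan")

    @property
    def valid(self) -> bool:
        return np.isfinite(self.ashp)

    def summary(self) -> str:
        lines = [
            "Latency-basin regression (latency ~ eccentricity)",
            f"  n points          : {len(self.points)}",
            f"  slope             : {self.slope:.4g} ms/deg (SE {self.slope_stderr:.3g})",
            f"  intercept         : {self.intercept:.4g} ms",
            f"  R^2               : {self.r2:.4f}",
            f"  magnification     : {self.magnification_used:.3g} mm/deg",
            f"  ASHP              : {self.ashp:.4g} mm/ms"
            + ("" if self.valid else "  (undefined: non-positive slope)"),
        ]
        return "\n".join(lines)


def fit_latency_basin(
    points, magnification: float = DEFAULT_MAGNIFICATION_MM_PER_DEG
) -> AshpFit:
    """Fit the 1D latency basin and infer the ASHP.

    ``points`` is an iterable of (eccentricity_deg, latency_ms) pairs; pairs
    with undefined (NaN) latency are dropped. Requires >= 3 points at
    distinct eccentricities.
    """
    pts = np.asarray([(e, l) for e, l in points], dtype=float)
    pts = pts[np.isfinite(pts).all(axis=1)]
    if len(pts) < 3 or len(np.unique(pts[:, 0])) < 3:
        raise ValueError("need >= 3 latency points at distinct eccentricities")
    X = sm.add_constant(pts[:, 0])
    res = sm.OLS(pts[:, 1], X).fit()
    intercept, slope = res.params
    ashp = magnification / slope if slope > 0 else float("nan")
    return AshpFit(
        slope=float(slope),
        intercept=float(intercept),
        ashp=float(ashp),
        r2=float(res.rsquared),
        magnification_used=magnification,
        points=pts,
        slope_stderr=float(res.bse[1]),
    )


# ---------------------------------------------------------------------------
# input phase
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhasePoint:
    """(input phase, spiking latency change) for one cell x condition."""

    phase: float  # ms; positive = horizontal input leads the feedforward drive
    delta_spike_latency: float  # ms; positive = spiking advance
    condition: str = ""

    def __post_init__(self) -> None:
        allowed = {"CP-ISO", "CP-CROSS", "CF-ISO", "CF-CROSS", ""}
        if self.condition not in allowed:
            raise ValueError(f"condition must be one of {sorted(allowed)}")


def input_phase(surround_only_onset: float, center_only_onset: float) -> float:
    """Phase between horizontal and feedforward inputs (ms).

    Both onsets must already be expressed on the common reference (time at
    which the center stimulus was / would have been shown). Positive when
    the lateral (Surround-Only) input leads the feedforward one.
    """
    if not (np.isfinite(surround_only_onset) and np.isfinite(center_only_onset)):
        return float("nan")
    return float(center_only_onset - surround_only_onset)


# ---------------------------------------------------------------------------
# bilinear (two connex segments) fit
# ---------------------------------------------------------------------------

@dataclass
class BilinearFit:
    breakpoint: float  # ms
    left_slope: float
    right_slope: float
    left_intercept: float
    right_intercept: float
    r2_left: float
    r2_right: float
    n_left: int
    n_right: int
    sse: float
    continuous: bool = True
    single_segment_fallback: bool = False

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, float)
        left = self.left_intercept + self.left_slope * x
        right = self.right_intercept + self.right_slope * x
        return np.where(x <= self.breakpoint, left, right)

    def summary(self) -> str:
        return "\n".join(
            [
                "Bilinear (two connex segments) regression",
                f"  breakpoint : {self.breakpoint:.3g} ms",
                f"  left  : slope {self.left_slope:.4g}, r2 {self.r2_left:.3f}, n {self.n_left}",
                f"  right : slope {self.right_slope:.4g}, r2 {self.r2_right:.3f}, n {self.n_right}",
                f"  SSE   : {self.sse:.4g}",
            ]
        )


def _segment_r2(x: np.ndarray, y: np.ndarray, yhat: np.ndarray) -> float:
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0:
        return 1.0
    return 1.0 - float(np.sum((y - yhat) ** 2)) / sst


def fit_bilinear(
    phases,
    delta_latencies=None,
    continuous: bool = True,
) -> BilinearFit:
    """Two-segment regression of latency change on input phase.

    Accepts either a list of :class:`PhasePoint` or two arrays. The
    breakpoint is found by exhaustive search over candidate abscissae (the
    observed phases plus their midpoints); with ``continuous=True`` the two
    segments are constrained to meet at the breakpoint (hinge model), with
    ``continuous=False`` two independent half-regressions are fitted. When
    all points fall on one side of every candidate, a single-line fallback
    is returned and flagged.
    """
    if delta_latencies is None:
        pts = list(phases)
        x = np.array([p.phase for p in pts], float)
        y = np.array([p.delta_spike_latency for p in pts], float)
    else:
        x = np.asarray(phases, float)
        y = np.asarray(delta_latencies, float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if len(x) < 6:
        raise ValueError("need >= 6 points for a bilinear fit")

    xs = np.unique(x)
    candidates = np.unique(np.concatenate([xs, (xs[:-1] + xs[1:]) / 2.0]))
    # interior candidates only: >= 2 points strictly on each side
    candidates = [c for c in candidates if np.sum(x < c) >= 2 and np.sum(x > c) >= 2]
    if not candidates:
        X = sm.add_constant(x)
        res = sm.OLS(y, X).fit()
        b0, b1 = res.params
        return BilinearFit(
            breakpoint=float(np.median(x)), left_slope=float(b1), right_slope=float(b1),
            left_intercept=float(b0), right_intercept=float(b0),
            r2_left=float(res.rsquared), r2_right=float(res.rsquared),
            n_left=int(np.sum(x <= np.median(x))), n_right=int(np.sum(x >= np.median(x))),
            sse=float(np.sum(res.resid**2)), continuous=continuous,
            single_segment_fallback=True,
        )

    best: BilinearFit | None = None
    for c in candidates:
        if continuous:
            # hinge model: y = b0 + bl*min(x-c,0) + br*max(x-c,0)
            D = np.column_stack(
                [np.ones_like(x), np.minimum(x - c, 0.0), np.maximum(x - c, 0.0)]
            )
            beta, *_ = np.linalg.lstsq(D, y, rcond=None)
            yhat = D @ beta
            b0, bl, br = beta
            li = b0 - bl * c
            ri = b0 - br * c
        else:
            ml, mr = x <= c, x >= c
            resl = sm.OLS(y[ml], sm.add_constant(x[ml])).fit()
            resr = sm.OLS(y[mr], sm.add_constant(x[mr])).fit()
            li, bl = resl.params
            ri, br = resr.params
            yhat = np.where(x <= c, li + bl * x, ri + br * x)
        sse = float(np.sum((y - yhat) ** 2))
        if best is None or sse < best.sse - 1e-12:
            ml, mr = x <= c, x >= c
            best = BilinearFit(
                breakpoint=float(c),
                left_slope=float(bl),
                right_slope=float(br),
                left_intercept=float(li),
                right_intercept=float(ri),
                r2_left=_segment_r2(x[ml], y[ml], (li + bl * x[ml])),
                r2_right=_segment_r2(x[mr], y[mr], (ri + br * x[mr])),
                n_left=int(np.sum(ml)),
                n_right=int(np.sum(mr)),
                sse=sse,
                continuous=continuous,
            )
    return best


# ---------------------------------------------------------------------------
# KDE summaries
# ---------------------------------------------------------------------------

def kde_density(
    values,
    bandwidth: float | str | None = None,
    grid: np.ndarray | None = None,
    n_grid: int = 512,
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian kernel density estimate (integrates to 1 over the grid).

    ``bandwidth`` follows :func:`scipy.stats.gaussian_kde` (default
    Silverman's rule). Returns ``(grid, density)``.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("KDE needs at least 2 values")
    if np.allclose(v, v[0]):
        # degenerate sample: a narrow Gaussian centred on the repeated value
        s = max(abs(v[0]) * 1e-3, 1e-3)
        if grid is None:
            grid = np.linspace(v[0] - 6 * s, v[0] + 6 * s, n_grid)
        dens = np.exp(-0.5 * ((grid - v[0]) / s) ** 2) / (s * np.sqrt(2 * np.pi))
        return grid, dens
    kde = gaussian_kde(v, bw_method=bandwidth if bandwidth is not None else "silverman")
    if grid is None:
        lo, hi = v.min(), v.max()
        span = hi - lo
        grid = np.linspace(lo - 0.5 * span - 1e-9, hi + 0.5 * span + 1e-9, n_grid)
    return grid, kde(grid)
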