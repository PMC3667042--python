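"""Non-metapopulation fragmentation metrics.

Two comparison metrics accompany the capacity calculation:

* total remaining range area, screened against two area thresholds — the
  habitat-trimmed-range threshold of 11,000 km² below which a species is at
  particular risk, and the IUCN extent-of-occurrence threshold of 20,000 km²
  below which a species is likely to be threatened;
* the cumulative size-ranked fragment-area curve — cumulative total area in
  patches up to a given size, against that size — with its log-log ordinary
  least-squares slope.  The shallower the slope, the more of the range sits
  in small fragments; the right-most point reads off the largest fragment
  (x) and the total area (y).  Note this metric can mislead: many tiny
  patches around large ones lower the slope without changing persistence.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .landscape import PatchSet

__all__ = [
    "HARRIS_PIMM_THRESHOLD_KM2",
    "IUCN_EOO_THRESHOLD_KM2",
    "DEFAULT_THRESHOLDS",
    "CumAreaCurve",
    "total_range_area",
    "area_risk_flags",
    "cumulative_area_curve",
    "curve_to_frame",
    "plot_curve",
]

HARRIS_PIMM_THRESHOLD_KM2 = 11_000.0
IUCN_EOO_THRESHOLD_KM2 = 20_000.0
DEFAULT_THRESHOLDS = {
    "harris_pimm": HARRIS_PIMM_THRESHOLD_KM2,
    "iucn_eoo": IUCN_EOO_THRESHOLD_KM2,
}


@dataclass(frozen=True)
class CumAreaCurve:
    """Cumulative size-ranked fragment-area curve with its log-log fit.

    ``sorted_areas_km2`` holds the distinct patch sizes ascending (ties merged
    into one point at the cumulative total through that size);
    ``cum_area_km2`` the running totals.  The fit fields are NaN when fewer
    than two distinct sizes exist.
    """

    sorted_areas_km2: np.ndarray
    cum_area_km2: np.ndarray
    loglog_slope: float
    loglog_intercept: float
    r_squared: float
    largest_patch_km2: float
    total_area_km2: float


def total_range_area(patches: PatchSet) -> float:
    """Total remaining range area in km² (0 for an empty landscape).

    The simplest metric: it ignores fragmentation completely.
    """
    return patches.total_area_km2


def area_risk_flags(area_km2: float, thresholds: dict[str, float] | None = None) -> dict[str, bool]:
    """Screen a range area against risk thresholds (strict ``<``).

    A flag is set iff ``area_km2`` is strictly below the threshold, so a
    species exactly at a threshold is not flagged.  Thresholds are
    configurable; the defaults are 11,000 km² (habitat-trimmed range) and
    20,000 km² (IUCN EOO).
    """
    if area_km2 < 0:
        raise ValueError("area must be nonnegative")
    thresholds = thresholds if thresholds is not None else DEFAULT_THRESHOLDS
    return {name: bool(area_km2 < t) for name, t in thresholds.items()}


def cumulative_area_curve(areas) -> CumAreaCurve:
    """Cumulative fragment-area curve over a set of patch areas.

    Areas are sorted ascending and accumulated; patches of identical size are
    merged into a single point whose ordinate is the cumulative total through
    that size (keeps the x-axis a function).  The slope is the OLS fit of
    log10(cumulative area) on log10(patch area) over the merged points, NaN
    when fewer than two distinct sizes exist.
    """
    A = np.sort(np.asarray(areas, dtype=float))
    if A.size == 0:
        raise ValueError("need at least one patch area")
    if (A <= 0).any():
        raise ValueError("patch areas must be positive")
    cum = np.cumsum(A)
    # keep the last occurrence of each distinct size: cumulative through ties
    last = np.r_[A[1:] != A[:-1], True]
    x, y = A[last], cum[last]
    if x.size >= 2:
        fit = stats.linregress(np.log10(x), np.log10(y))
        slope, intercept, r2 = fit.slope, fit.intercept, fit.rvalue**2
    else:
        slope = intercept = r2 = float("nan")
    return CumAreaCurve(
        sorted_areas_km2=x,
        cum_area_km2=y,
        loglog_slope=float(slope),
        loglog_intercept=float(intercept),
        r_squared=float(r2),
        largest_patch_km2=float(x[-1]),
        total_area_km2=float(cum[-1]),
    )


def curve_to_frame(curve: CumAreaCurve) -> pd.DataFrame:
    """Curve points as a two-column table (area_km2, cum_area_km2)."""
    return pd.DataFrame(
        {"area_km2": curve.sorted_areas_km2, "cum_area_km2": curve.cum_area_km2}
    )


def plot_curve(curve: CumAreaCurve, path: str | Path, title: str = "") -> None:
    """Log-log plot of the cumulative-area curve with its fitted line (PNG)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.loglog(curve.sorted_areas_km2, curve.cum_area_km2, "o", ms=4)
    if np.isfinite(curve.loglog_slope):
        xs = np.log10(curve.sorted_areas_km2)
        ax.loglog(
            curve.sorted_areas_km2,
            10 ** (curve.loglog_intercept + curve.loglog_slope * xs),
            "-",
            lw=1,
        )
    ax.set_xlabel("patch area (km²)")
    ax.set_ylabel("cumulative area in patches up to this size (km²)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
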