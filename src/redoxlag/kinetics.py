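"""Sediment age models and exponential decay/growth kinetics of guilds.

Depth below the sediment surface is converted to age with a constant,
lead-210-derived sedimentation rate omega (mm/yr)::

    age(z) = 10 * z_cm / omega_mm_yr      [years]

Guild relative abundance a(t) is modelled as a single exponential within a
depth window, ``a(t) = a0 * exp(-lambda * t)`` for decay (or ``+lambda`` for
growth), fitted by ordinary least squares on ``ln a`` versus age; the
half-life (or doubling time) is ``ln 2 / lambda``.  Relative abundance is
treated as proportional to cell density, which assumes a constant total cell
abundance across depth.  A nonlinear least-squares alternative on the linear
scale is available via ``method="nls"``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .redox_zones import annotate_zones
from .tables_io import ValidationError

__all__ = [
    "InsufficientDataError",
    "KineticFit",
    "depth_to_age",
    "doubling_from_distance",
    "fit_exponential",
    "fit_guild_kinetics",
]

logger = logging.getLogger(__name__)

LN2 = math.log(2.0)


class InsufficientDataError(ValueError):
    """Too few usable points inside the fit window."""


def depth_to_age(depth_cm: float, omega_mm_yr: float) -> float:
    """Years since deposition for a depth (cm) at sedimentation rate (mm/yr)."""
    if omega_mm_yr <= 0:
        raise ValidationError(f"sedimentation rate must be > 0, got {omega_mm_yr}")
    if np.any(np.asarray(depth_cm) < 0):
        raise ValidationError("depth must be >= 0")
    return 10.0 * np.asarray(depth_cm, dtype=float) / omega_mm_yr


def doubling_from_distance(distance_cm: float, omega_mm_yr: float) -> float:
    """Convert a doubling distance (cm) to a doubling time (years).

    Identical arithmetic to :func:`depth_to_age`; exposed separately because
    a growth rate per unit depth times a sedimentation rate is how doubling
    times of downcore-growing guilds are reported.
    """
    if distance_cm <= 0:
        raise ValidationError(f"doubling distance must be > 0, got {distance_cm}")
    return float(depth_to_age(distance_cm, omega_mm_yr))


@dataclass
class KineticFit:
    """One exponential fit of a group within one site's depth window."""

    site_id: str
    group: str
    direction: str  # "decay" or "growth"
    rate_per_yr: float  # lambda, > 0 when converged
    half_life_yr: float  # ln2/lambda; doubling time for growth fits
    depth_window_cm: tuple[float, float]
    n_points: int
    r_squared: float
    log_intercept: float  # ln(abundance) extrapolated to age 0
    converged: bool = True
    n_zeros_dropped: int = 0

    def __post_init__(self) -> None:
        if self.direction not in ("decay", "growth"):
            raise ValidationError(f"direction must be decay|growth, got {self.direction}")


def fit_exponential(
    ages_yr: Sequence[float],
    abundances: Sequence[float],
    direction: str = "decay",
    site_id: str = "",
    group: str = "",
    depth_window_cm: tuple[float, float] = (math.nan, math.nan),
    method: str = "ols",
) -> KineticFit:
    """Fit ``a(t) = a0 * exp(sign * lambda * t)`` to (age, abundance) points.

    Zero abundances are dropped before fitting (exponentials never reach
    zero; zeros are detection failures) and counted in ``n_zeros_dropped``;
    if more than half of the points are zero the fit is refused.  A fitted
    slope whose sign contradicts ``direction`` yields a flagged
    (``converged=False``) result rather than an exception.
    """
    t = np.asarray(ages_yr, dtype=float)
    y = np.asarray(abundances, dtype=float)
    if t.shape != y.shape or t.ndim != 1:
        raise ValidationError("ages and abundances must be equal-length 1-D arrays")
    if np.any(np.diff(t) <= 0):
        raise ValidationError("ages must be strictly increasing")
    if np.any(y < 0):
        raise ValidationError("abundances must be >= 0")
    keep = y > 0
    n_zeros = int((~keep).sum())
    if n_zeros > 0.5 * len(y):
        raise InsufficientDataError(
            f"{n_zeros}/{len(y)} window points are zero; refusing to fit"
        )
    t, y = t[keep], y[keep]
    if len(t) < 3:
        raise InsufficientDataError(
            f"need >= 3 positive points inside the window, got {len(t)}"
        )
    logy = np.log(y)
    slope, intercept = np.polyfit(t, logy, 1)
    if method == "nls":
        # refine on the linear scale; log-OLS is the starting point
        def model(tt, a0, s):
            return a0 * np.exp(s * tt)

        try:
            popt, _ = optimize.curve_fit(
                model, t, y, p0=(math.exp(intercept), slope), maxfev=10000
            )
            intercept, slope = math.log(abs(popt[0])), popt[1]
        except RuntimeError:  # pragma: no cover - fall back to the log fit
            pass
    elif method != "ols":
        raise ValidationError(f"unknown fit method {method!r}")
    sign = -1.0 if direction == "decay" else 1.0
    rate = sign * slope
    fitted = intercept + slope * t
    ss_res = float(np.sum((logy - fitted) ** 2))
    ss_tot = float(np.sum((logy - logy.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else max(0.0, 1.0 - ss_res / ss_tot)
    converged = rate > 0
    return KineticFit(
        site_id=site_id,
        group=group,
        direction=direction,
        rate_per_yr=float(rate),
        half_life_yr=LN2 / rate if converged else math.nan,
        depth_window_cm=depth_window_cm,
        n_points=int(len(t)),
        r_squared=r2,
        log_intercept=float(intercept),
        converged=converged,
        n_zeros_dropped=n_zeros,
    )


@dataclass
class GuildKineticsResult:
    fits: list[KineticFit] = field(default_factory=list)
    skipped_sites: list[str] = field(default_factory=list)

    @property
    def half_life_range_yr(self) -> tuple[float, float]:
        """(min, max) half-life over converged per-site fits; no pooling."""
        vals = [f.half_life_yr for f in self.fits if f.converged]
        if not vals:
            return (math.nan, math.nan)
        return (min(vals), max(vals))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "site_id": f.site_id,
                    "group": f.group,
                    "direction": f.direction,
                    "rate_per_yr": f.rate_per_yr,
                    "half_life_yr": f.half_life_yr,
                    "window_top_cm": f.depth_window_cm[0],
                    "window_bottom_cm": f.depth_window_cm[1],
                    "n_points": f.n_points,
                    "r_squared": f.r_squared,
                    "log_intercept": f.log_intercept,
                    "converged": f.converged,
                    "n_zeros_dropped": f.n_zeros_dropped,
                }
                for f in self.fits
            ]
        )


def fit_guild_kinetics(
    group_abund: pd.DataFrame,
    metadata: pd.DataFrame,
    group: str,
    direction: str = "decay",
    window_cm: tuple[float, float] | None = None,
    method: str = "ols",
) -> GuildKineticsResult:
    """Per-site exponential fits of one group's depth profile.

    ``group_abund`` is a group x sample table (e.g. from
    :func:`redoxlag.abundance_profiles.aggregate_groups`).  For decay fits
    the default window runs from the top of the site's ferruginous zone to
    its deepest horizon; growth fits require an explicit window (midpoints
    are compared inclusively at both ends).  Sites lacking usable points are
    skipped with a warning.
    """
    if group not in group_abund.index:
        raise ValidationError(f"group {group!r} not present in the abundance table")
    meta = metadata
    if "zone" not in meta.columns or meta["zone"].isna().any():
        meta = annotate_zones(meta)
    if direction == "growth" and window_cm is None:
        raise ValidationError("growth fits need an explicit depth window")
    result = GuildKineticsResult()
    for site, sub in meta.groupby("site_id", sort=True):
        sub = sub.copy()
        sub["mid"] = 0.5 * (sub["depth_top_cm"] + sub["depth_bottom_cm"])
        sub = sub.sort_values("mid")
        if window_cm is None:
            ferr = sub[sub["zone"] == "ferruginous"]
            if ferr.empty:
                logger.warning("site %s lacks a ferruginous zone; skipped", site)
                result.skipped_sites.append(str(site))
                continue
            lo, hi = float(ferr["mid"].min()), float(ferr["mid"].max())
        else:
            lo, hi = float(window_cm[0]), float(window_cm[1])
        win = sub[(sub["mid"] >= lo) & (sub["mid"] <= hi)]
        omega = float(win["sedimentation_rate_mm_yr"].iloc[0]) if len(win) else math.nan
        samples = [s for s in win["sample_id"] if s in group_abund.columns]
        if len(samples) < 3:
            logger.warning(
                "site %s: only %d horizon(s) in window [%g, %g] cm; skipped",
                site,
                len(samples),
                lo,
                hi,
            )
            result.skipped_sites.append(str(site))
            continue
        ages = depth_to_age(win.set_index("sample_id").loc[samples, "mid"].values, omega)
        values = group_abund.loc[group, samples].values.astype(float)
        try:
            fit = fit_exponential(
                ages,
                values,
                direction=direction,
                site_id=str(site),
                group=group,
                depth_window_cm=(lo, hi),
                method=method,
            )
        except InsufficientDataError as err:
            logger.warning("site %s: %s; skipped", site, err)
            result.skipped_sites.append(str(site))
            continue
        result.fits.append(fit)
    return result
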