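"""Angular mean-squared displacement and rotational diffusion constants.

For a single angular coordinate undergoing simple rotational diffusion with
coefficient ``D``, the mean squared displacement grows linearly with lag time,

    MSD(dt) = <(alpha(t + dt) - alpha(t))^2> = 2 D dt,

so ``D`` is half the slope of a linear fit of MSD against lag.  Curves are
estimated by pooling squared displacements over all tracks and all overlapping
start times; the fit is weighted least squares ("chi-square linear fitting")
with the per-lag pair counts as weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from tubudyn.io import AngularTrack

__all__ = [
    "DiffusionFit",
    "EnsembleComparison",
    "MSDCurve",
    "combined_msd",
    "compare_ensembles",
    "fit_diffusion",
    "msd_curve",
]

#: largest angle step (degrees) between consecutive frames before a track is
#: suspected of containing wrap-around jumps rather than continuous angles
WRAP_WARN_THRESHOLD = 90.0


@dataclass
class MSDCurve:
    """Mean squared displacement against lag time.

    ``lags`` are in the tracks' time unit (strictly increasing, lag 0 is not
    stored: it is identically zero), ``msd`` in the square of the angle unit,
    and ``n_pairs`` counts the pooled displacement pairs entering each lag.
    """

    lags: np.ndarray
    msd: np.ndarray
    n_pairs: np.ndarray
    component: str
    units: str = "deg^2"
    #: optional per-track sums of squared displacements and pair counts
    #: (n_tracks x n_lags); kept so fits can jackknife over tracks
    per_track_sums: np.ndarray | None = None
    per_track_counts: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.msd = np.asarray(self.msd, dtype=float)
        self.n_pairs = np.asarray(self.n_pairs, dtype=int)
        if not (len(self.lags) == len(self.msd) == len(self.n_pairs)):
            raise ValueError("lags, msd and n_pairs must have equal length")
        if (np.diff(self.lags) <= 0).any():
            raise ValueError("lags must be strictly increasing")
        if (self.msd < 0).any():
            raise ValueError("msd values must be non-negative")
        if (self.n_pairs <= 0).any():
            raise ValueError("every reported lag needs a positive pair count")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "lag": self.lags,
                "msd": self.msd,
                "n_pairs": self.n_pairs,
                "component": self.component,
            }
        )

    @property
    def standard_errors(self) -> np.ndarray:
        """Approximate per-lag standard error of the MSD estimate.

        For Gaussian displacements the squared displacement has variance
        ``2 MSD^2``; averaging ``n`` (correlated, overlapping) pairs gives the
        working estimate ``MSD * sqrt(2 / n)``, which is what the goodness of
        fit is measured against.
        """
        return self.msd * np.sqrt(2.0 / self.n_pairs)


def _check_tracks(tracks: Sequence[AngularTrack]) -> list[AngularTrack]:
    tracks = list(tracks)
    if not tracks:
        raise ValueError("empty track set")
    intervals = {t.frame_interval for t in tracks}
    if len(intervals) != 1:
        raise ValueError("tracks must share one frame interval")
    return tracks


def _warn_on_wraps(values: np.ndarray, track_id: str) -> None:
    import warnings

    steps = np.abs(np.diff(values))
    if (steps > WRAP_WARN_THRESHOLD).any():
        warnings.warn(
            f"track {track_id!r} contains frame-to-frame angle jumps "
            f"> {WRAP_WARN_THRESHOLD} deg; angles should be unwrapped",
            stacklevel=3,
        )


def msd_curve(
    tracks: Sequence[AngularTrack],
    component: Literal["theta", "chi"],
    max_lag: int,
    averaging: Literal["pooled", "per_track"] = "pooled",
) -> MSDCurve:
    """MSD over lags 1..``max_lag`` (frames) for one angular component.

    All overlapping start times contribute: for lag ``k`` every displacement
    ``alpha(t+k) - alpha(t)`` with both samples inside a track is used.  With
    ``averaging="pooled"`` (default) squared displacements are pooled over
    tracks with equal weight per displacement pair; ``"per_track"`` averages
    within each track first, then across tracks with equal weight per track.
    """
    tracks = _check_tracks(tracks)
    shortest = min(len(t) for t in tracks)
    if not 1 <= max_lag < shortest:
        raise ValueError(
            f"max_lag must be in [1, {shortest - 1}] for the shortest track, got {max_lag}"
        )
    dt = tracks[0].frame_interval
    lags = np.arange(1, max_lag + 1)
    track_sums = np.zeros((len(tracks), max_lag))
    track_counts = np.zeros((len(tracks), max_lag), dtype=int)
    for j, t in enumerate(tracks):
        values = t.component(component)
        _warn_on_wraps(values, t.track_id)
        for i, k in enumerate(lags):
            sq = (values[k:] - values[:-k]) ** 2
            track_sums[j, i] = sq.sum()
            track_counts[j, i] = len(sq)
    counts = track_counts.sum(axis=0)
    if averaging == "per_track":
        msd = (track_sums / track_counts).mean(axis=0)
    else:
        msd = track_sums.sum(axis=0) / counts
    return MSDCurve(
        lags=lags * dt,
        msd=msd,
        n_pairs=counts,
        component=component,
        per_track_sums=track_sums,
        per_track_counts=track_counts,
    )


def combined_msd(tracks: Sequence[AngularTrack], max_lag: int) -> MSDCurve:
    """Combined tilting+twisting metric: MSD_theta(dt) + MSD_chi(dt).

    Used to compare ensembles whose anchoring orientation is indeterminate,
    where tilting and twisting cannot be told apart individually.
    """
    theta = msd_curve(tracks, "theta", max_lag)
    chi = msd_curve(tracks, "chi", max_lag)
    return MSDCurve(
        lags=theta.lags,
        msd=theta.msd + chi.msd,
        n_pairs=theta.n_pairs + chi.n_pairs,
        component="combined",
        per_track_sums=(
            None
            if theta.per_track_sums is None
            else 2.0 * (theta.per_track_sums + chi.per_track_sums)
        ),
        per_track_counts=(
            None
            if theta.per_track_counts is None
            else theta.per_track_counts + chi.per_track_counts
        ),
    )


@dataclass
class DiffusionFit:
    """Weighted linear fit ``MSD = slope * dt + intercept`` with
    ``D = slope / 2`` for a single angular coordinate.

    ``reduced_chi2`` measures the fit against the per-lag standard errors of
    the curve; values much larger than 1 flag a non-linear MSD.
    """

    slope: float
    intercept: float
    slope_se: float
    intercept_se: float
    diffusion_constant: float
    diffusion_constant_se: float
    lag_range: tuple[float, float]
    n_points: int
    reduced_chi2: float
    component: str
    units: str = "deg^2/time"

    def summary(self) -> str:
        lines = [
            f"Diffusion fit ({self.component})",
            "-" * 32,
            f"points used        : {self.n_points} (lags {self.lag_range[0]:g}..{self.lag_range[1]:g})",
            f"slope              : {self.slope:.6g} +/- {self.slope_se:.3g}",
            f"intercept          : {self.intercept:.6g} +/- {self.intercept_se:.3g}",
            f"D = slope/2        : {self.diffusion_constant:.6g} +/- {self.diffusion_constant_se:.3g} ({self.units})",
            f"reduced chi-square : {self.reduced_chi2:.3g}",
        ]
        return "\n".join(lines)


def _wls_line(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    sw = w.sum()
    sx = (w * x).sum()
    sy = (w * y).sum()
    sxx = (w * x * x).sum()
    sxy = (w * x * y).sum()
    delta = sw * sxx - sx * sx
    slope = (sw * sxy - sx * sy) / delta
    intercept = (sxx * sy - sx * sxy) / delta
    return float(slope), float(intercept)


def _jackknife_variance(
    curve: MSDCurve, mask: np.ndarray, w_mode: str
) -> tuple[float, float]:
    sums = curve.per_track_sums[:, mask]
    counts = curve.per_track_counts[:, mask]
    x = curve.lags[mask]
    m = sums.shape[0]
    total_sums = sums.sum(axis=0)
    total_counts = counts.sum(axis=0)
    slopes = np.empty(m)
    intercepts = np.empty(m)
    for i in range(m):
        c = total_counts - counts[i]
        y = (total_sums - sums[i]) / c
        if w_mode == "errors":
            se = y * np.sqrt(2.0 / c)
            w = 1.0 / se**2
        elif w_mode == "none":
            w = np.ones(len(x))
        else:
            w = c.astype(float)
        slopes[i], intercepts[i] = _wls_line(x, y, w)
    factor = (m - 1.0) / m
    slope_var = factor * ((slopes - slopes.mean()) ** 2).sum()
    intercept_var = factor * ((intercepts - intercepts.mean()) ** 2).sum()
    return float(slope_var), float(intercept_var)


def fit_diffusion(
    curve: MSDCurve,
    lag_range: tuple[float, float] | None = None,
    weights: Literal["n_pairs", "errors", "none"] = "n_pairs",
) -> DiffusionFit:
    """Chi-square (weighted least squares) linear fit of an MSD curve.

    ``lag_range`` selects the lags entering the fit (inclusive, in the curve's
    time unit); the default is the first 8 lags, the short-lag regime where the
    linear diffusion law holds before confinement flattens the curve.  Weights
    default to the per-lag pair counts; ``"errors"`` weights by the inverse
    squared per-lag standard errors instead.
    """
    if lag_range is None:
        hi = curve.lags[min(7, len(curve.lags) - 1)]
        lag_range = (float(curve.lags[0]), float(hi))
    lo, hi = lag_range
    mask = (curve.lags >= lo) & (curve.lags <= hi)
    x = curve.lags[mask]
    y = curve.msd[mask]
    n_pairs = curve.n_pairs[mask]
    n = len(x)
    if n < 3:
        raise ValueError("fit needs at least 3 lag points in lag_range")
    if np.ptp(x) == 0:
        raise ValueError("degenerate fit: all lags equal")
    if not y.any():
        raise ValueError(
            "MSD is identically zero over the fit range; no diffusive signal to fit"
        )
    if weights == "n_pairs":
        w = n_pairs.astype(float)
    elif weights == "errors":
        se = curve.standard_errors[mask]
        if (se == 0).any():
            raise ValueError("zero standard errors; cannot weight by errors")
        w = 1.0 / se**2
    elif weights == "none":
        w = np.ones(n)
    else:
        raise ValueError(f"unknown weights mode {weights!r}")

    slope, intercept = _wls_line(x, y, w)
    resid = y - (slope * x + intercept)
    dof = n - 2
    if curve.per_track_sums is not None and curve.per_track_sums.shape[0] >= 2:
        # Delete-one-track jackknife.  MSD values at different lags share
        # displacement pairs and are strongly correlated, so the naive WLS
        # covariance badly understates the slope uncertainty; resampling whole
        # tracks (the independent unit) accounts for both the correlation and
        # the weighting.
        slope_var, intercept_var = _jackknife_variance(curve, mask, w_mode=weights)
    else:
        # residual-based fallback (weights treated as relative)
        sw = w.sum()
        sx = (w * x).sum()
        sxx = (w * x * x).sum()
        delta = sw * sxx - sx * sx
        scale = (w * resid**2).sum() / dof if dof > 0 else np.nan
        slope_var = scale * sw / delta
        intercept_var = scale * sxx / delta
    # goodness against the curve's own error estimates (absolute scale)
    se_curve = curve.standard_errors[mask]
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = float(np.nansum((resid / se_curve) ** 2))
    reduced_chi2 = chi2 / dof if dof > 0 else np.nan
    return DiffusionFit(
        slope=float(slope),
        intercept=float(intercept),
        slope_se=float(np.sqrt(slope_var)),
        intercept_se=float(np.sqrt(intercept_var)),
        diffusion_constant=float(slope / 2.0),
        diffusion_constant_se=float(np.sqrt(slope_var) / 2.0),
        lag_range=(float(lo), float(hi)),
        n_points=n,
        reduced_chi2=float(reduced_chi2),
        component=curve.component,
        units=curve.units + "/time",
    )


@dataclass
class EnsembleComparison:
    """Lag-by-lag and fitted-D comparison of two track ensembles (A vs B)."""

    per_lag: pd.DataFrame = field(repr=False)
    fit_a: DiffusionFit = field(repr=False)
    fit_b: DiffusionFit = field(repr=False)
    d_ratio: float = 0.0
    d_ratio_se: float = 0.0
    component: str = ""

    @property
    def a_lower_at_every_lag(self) -> bool:
        return bool((self.per_lag["msd_a"] < self.per_lag["msd_b"]).all())

    def summary(self) -> str:
        return (
            f"Ensemble comparison ({self.component})\n"
            f"D_A = {self.fit_a.diffusion_constant:.6g} +/- {self.fit_a.diffusion_constant_se:.3g}\n"
            f"D_B = {self.fit_b.diffusion_constant:.6g} +/- {self.fit_b.diffusion_constant_se:.3g}\n"
            f"D_A / D_B = {self.d_ratio:.4g} +/- {self.d_ratio_se:.3g}\n"
            f"MSD_A < MSD_B at every lag: {self.a_lower_at_every_lag}"
        )


def compare_ensembles(
    curve_a: MSDCurve,
    curve_b: MSDCurve,
    lag_range: tuple[float, float] | None = None,
) -> EnsembleComparison:
    """Compare two MSD curves sharing a lag grid: per-lag differences plus the
    ratio of fitted diffusion constants with propagated uncertainty.

    Swapping the arguments yields the reciprocal ratio.
    """
    if curve_a.component != curve_b.component:
        raise ValueError("curves must describe the same component")
    if len(curve_a.lags) != len(curve_b.lags) or not np.allclose(
        curve_a.lags, curve_b.lags
    ):
        raise ValueError("incompatible lag grids")
    fit_a = fit_diffusion(curve_a, lag_range)
    fit_b = fit_diffusion(curve_b, lag_range)
    da, db = fit_a.diffusion_constant, fit_b.diffusion_constant
    if db == 0:
        raise ValueError("ensemble B has zero fitted diffusion constant")
    ratio = da / db
    rel = np.sqrt(
        (fit_a.diffusion_constant_se / da) ** 2 + (fit_b.diffusion_constant_se / db) ** 2
    )
    per_lag = pd.DataFrame(
        {
            "lag": curve_a.lags,
            "msd_a": curve_a.msd,
            "msd_b": curve_b.msd,
            "difference": curve_a.msd - curve_b.msd,
        }
    )
    return EnsembleComparison(
        per_lag=per_lag,
        fit_a=fit_a,
        fit_b=fit_b,
        d_ratio=float(ratio),
        d_ratio_se=float(abs(ratio) * rel),
        component=curve_a.component,
    )
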