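"""Derived quantities from tracked single-cell fluorescence traces.

Implements the standard read-outs of calcein-AM metabolic activity
sensing:

* colony series — summed cell area, unweighted mean of single-cell mean
  fluorescence, cell count and extracellular signals per frame;
* apparent growth rate ``mu_app`` — log-slope of the summed colony area
  over a sliding window (10 frames / 80 min in CGXII minimal medium,
  6 frames / 48 min in BHI complex medium), and its maximum ``mu_max``;
* conversion rate constant — first-order constant of the fluorescence
  rise directly after the shift to carbon-free medium, fitted as
  ``F(t) = Finf - (Finf - F0) exp(-k t)``.  Because a 50-min window of
  a slow rise is nearly linear, the saturation level ``Finf`` is
  estimated once from the whole famine segment (or supplied) and held
  fixed in the sliding per-window fits; the reported constant is the
  maximum over windows;
* efflux rate constant — first-order decay constant over exactly the
  first 50 min after carbon re-supply, ``F(t) = Fres + (F0 - Fres)
  exp(-k t)`` with a free residual level;
* loading half-time ``t50`` — time for a freshly exposed cell's
  fluorescence to reach half of its fitted plateau, interpolated
  linearly between samples;
* photobleaching per frame — geometric per-frame loss fitted on the log
  traces of growth-arrested, efflux-inhibited cells;
* SNR — mean intracellular over mean extracellular (cell proximity)
  fluorescence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "ColonySeries",
    "GrowthEstimate",
    "RateFit",
    "LoadingEstimate",
    "colony_series",
    "apparent_growth_rate",
    "bleach_correct",
    "fit_conversion_rate",
    "fit_efflux_rate",
    "half_time",
    "bleaching_per_frame",
    "snr",
]

#: Default growth-rate window lengths (frame intervals) per medium.
GROWTH_WINDOW_FRAMES = {"cgxii": 10, "bhi": 6}


@dataclass
class ColonySeries:
    t: np.ndarray                  # minutes, strictly increasing
    sum_area: np.ndarray           # um^2
    mean_fluor: np.ndarray         # AU, unweighted mean of single-cell means
    cell_count: np.ndarray
    extracellular: "dict[str, np.ndarray]" = field(default_factory=dict)

    def __post_init__(self):
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("t must be strictly increasing")


def colony_series(cell_table: pd.DataFrame,
                  background_table: Optional[pd.DataFrame] = None,
                  fluor_floor: float = 0.0) -> ColonySeries:
    """Aggregate a per-cell measurement table into a colony series.

    Cells below the fluorescence detection floor (e.g. lysed or
    esterase-free dark cells) are excluded from the colony mean
    fluorescence but still counted in the summed area.
    """
    if len(cell_table) == 0:
        raise ValueError("empty measurement table")
    g = cell_table.groupby("frame", sort=True)
    t = g["t_min"].first().to_numpy(dtype=float)
    sum_area = g["area_um2"].sum().to_numpy(dtype=float)
    count = g["label"].count().to_numpy(dtype=float)
    bright = cell_table[cell_table["mean_fluor_au"] >= fluor_floor]
    mean_f = bright.groupby("frame")["mean_fluor_au"].mean()
    mean_fluor = mean_f.reindex(g.size().index).to_numpy(dtype=float)

    extracellular = {}
    if background_table is not None and len(background_table):
        for site, sub in background_table.groupby("site"):
            sub = sub.sort_values("frame")
            extracellular[site] = sub["mean_fluor_au"].to_numpy(dtype=float)
    return ColonySeries(t=t, sum_area=sum_area, mean_fluor=mean_fluor,
                        cell_count=count, extracellular=extracellular)


@dataclass
class GrowthEstimate:
    mu_app: np.ndarray             # 1/h, one value per window position
    t_center: np.ndarray           # minutes
    window_frames: int

    @property
    def mu_max(self) -> float:
        return float(np.nanmax(self.mu_app))


def apparent_growth_rate(series: ColonySeries,
                         window_frames: int = 10) -> GrowthEstimate:
    """Sliding-window apparent growth rate.

    For each window of ``window_frames`` frame intervals
    (``window_frames + 1`` samples), ``mu_app`` is the least-squares
    slope of ln(summed area) against time in hours.  Exact on noiseless
    exponentials.
    """
    if window_frames < 1:
        raise ValueError("window must span at least one frame interval")
    n = len(series.t)
    if n <= window_frames:
        raise ValueError("series shorter than the growth window")
    if np.any(series.sum_area <= 0):
        raise ValueError("non-positive colony area")
    th = series.t / 60.0
    la = np.log(series.sum_area)
    mu, tc = [], []
    for i in range(n - window_frames):
        sl = slice(i, i + window_frames + 1)
        res = stats.linregress(th[sl], la[sl])
        mu.append(res.slope)
        tc.append(0.5 * (series.t[sl][0] + series.t[sl][-1]))
    return GrowthEstimate(mu_app=np.asarray(mu), t_center=np.asarray(tc),
                          window_frames=window_frames)


def bleach_correct(mean_fluor: np.ndarray, frac_per_exposure: float,
                   exposure_every: int = 1,
                   background: float = 0.0) -> np.ndarray:
    """Undo exposure-coupled photobleaching on a per-frame trace.

    Divides the background-subtracted signal of frame ``k`` by the
    cumulative attenuation ``(1 - b)^(number of exposures up to k)``,
    using the separately calibrated per-exposure loss ``b`` (see
    :func:`bleaching_per_frame`).  Slow famine-phase rises accumulate a
    >10 % attenuation over hundreds of frames, which would otherwise
    bias fitted rate constants.
    """
    y = np.asarray(mean_fluor, dtype=float)
    if not (0.0 <= frac_per_exposure < 1.0):
        raise ValueError("frac_per_exposure must lie in [0, 1)")
    k = np.arange(len(y))
    n_exposures = k // exposure_every + 1
    atten = (1.0 - frac_per_exposure) ** n_exposures
    return (y - background) / atten + background


@dataclass
class RateFit:
    k: float                       # 1/min, first-order constant
    fit_window: tuple              # (t_start, t_end) minutes
    r_squared: float
    model: str                     # "rise" | "decay"
    f_inf: float = np.nan          # fixed/estimated saturation (rise)
    f_res: float = np.nan          # fitted residual level (decay)

    def __post_init__(self):
        if self.k < 0:
            raise ValueError("k must be >= 0")


def _r2(y, yhat):
    ss = np.sum((y - np.mean(y)) ** 2)
    if ss == 0:
        return 1.0
    return float(np.clip(1.0 - np.sum((y - yhat) ** 2) / ss, 0.0, 1.0))


def _multistart_fit(model, t, y, p0_list, bounds):
    best = None
    for p0 in p0_list:
        try:
            popt, _ = optimize.curve_fit(model, t, y, p0=p0, bounds=bounds,
                                         maxfev=20000, xtol=1e-11, ftol=1e-11)
        except (RuntimeError, ValueError):
            continue
        sse = float(np.sum((y - model(t, *popt)) ** 2))
        if best is None or sse < best[1]:
            best = (popt, sse)
    return best


def _fit_global_rise(t, y):
    """3-parameter rise fit used to pin the saturation level Finf."""
    y0, y1 = float(y[0]), float(np.max(y))
    span = max(y1 - y0, 1e-12)

    def model(tt, k, finf, f0):
        return finf - (finf - f0) * np.exp(-k * tt)

    bounds = ([1e-7, y1, -np.inf], [1.0, y0 + 1e4 * span, y1])
    starts = [[k0, y1 + span, y0] for k0 in (1e-4, 1e-3, 3e-3, 1e-2, 1e-1)]
    best = _multistart_fit(model, t - t[0], y, starts, bounds)
    if best is None:
        raise RuntimeError("saturation fit failed")
    k, finf, f0 = best[0]
    return float(finf)


def fit_conversion_rate(t: np.ndarray, mean_fluor: np.ndarray,
                        shift_time: float, fit_span: Optional[float] = None,
                        window_min: float = 50.0,
                        f_inf: Optional[float] = None) -> RateFit:
    """Apparent CAM-conversion constant from the famine-phase rise.

    Fits ``F(t) = Finf - (Finf - F0) exp(-k (t - tw))`` in sliding
    windows of ``window_min`` minutes over the famine segment (from
    ``shift_time``, optionally limited to ``fit_span`` minutes), with
    ``Finf`` held fixed — estimated once from the whole segment when not
    supplied — and reports the maximal fitted ``k``.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(mean_fluor, dtype=float)
    sel = t >= shift_time - 1e-9
    if fit_span is not None:
        sel &= t <= shift_time + fit_span + 1e-9
    ts, ys = t[sel], y[sel]
    if len(ts) < 4:
        raise ValueError("famine trace does not cover the fit span")
    if ys[-1] < ys[0] - 1e-9 * max(abs(ys[0]), 1.0):
        warnings.warn("famine trace decreases: efflux may not be shut off")
    span = np.max(ys) - np.min(ys)
    if span <= 1e-12 * max(abs(float(np.max(ys))), 1.0):
        return RateFit(k=0.0, fit_window=(float(ts[0]), float(ts[-1])),
                       r_squared=1.0, model="rise", f_inf=float(ys[0]))
    if f_inf is None:
        f_inf = _fit_global_rise(ts, ys)

    def model(tt, k, f0):
        return f_inf - (f_inf - f0) * np.exp(-k * tt)

    best_fit = None
    i = 0
    while ts[i] + window_min <= ts[-1] + 1e-9:
        wsel = (ts >= ts[i] - 1e-9) & (ts <= ts[i] + window_min + 1e-9)
        tw, yw = ts[wsel], ys[wsel]
        if len(tw) >= 4:
            starts = [[k0, yw[0]] for k0 in (1e-4, 1e-3, 3e-3, 1e-2)]
            res = _multistart_fit(model, tw - tw[0], yw, starts,
                                  ([0.0, -np.inf], [1.0, f_inf]))
            if res is not None:
                k, f0 = res[0]
                r2 = _r2(yw, model(tw - tw[0], k, f0))
                if best_fit is None or k > best_fit.k:
                    best_fit = RateFit(k=float(k),
                                       fit_window=(float(tw[0]), float(tw[-1])),
                                       r_squared=r2, model="rise",
                                       f_inf=float(f_inf))
        i += 1
        if i >= len(ts):
            break
    if best_fit is None:
        raise RuntimeError("no valid conversion-fit window")
    return best_fit


def fit_efflux_rate(t: np.ndarray, mean_fluor: np.ndarray,
                    backshift_time: float,
                    span_min: float = 50.0) -> RateFit:
    """Calcein efflux constant over exactly the first ``span_min``
    minutes of re-established feast conditions.

    Fits ``F(t) = Fres + (F0 - Fres) exp(-k (t - t_back))`` with a free
    residual ``Fres >= 0`` (cells retain some calcein).  The frame at
    the backshift timestamp itself is excluded: it is acquired at the
    moment of the medium switch and still reflects the famine state.
    A rising post-backshift trace triggers a delayed-efflux warning.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(mean_fluor, dtype=float)
    sel = (t > backshift_time + 1e-9) & (t <= backshift_time + span_min + 1e-9)
    ts, ys = t[sel], y[sel]
    if len(ts) < 4:
        raise ValueError("trace does not cover the post-backshift window")
    if ys[-1] > ys[0] + 1e-9 * max(abs(ys[0]), 1.0):
        warnings.warn("post-backshift trace rises: delayed-efflux phenotype")
    span = np.max(ys) - np.min(ys)
    if span <= 1e-12 * max(abs(float(np.max(ys))), 1.0):
        return RateFit(k=0.0, fit_window=(float(ts[0]), float(ts[-1])),
                       r_squared=1.0, model="decay", f_res=float(ys[-1]))

    def model(tt, k, f0, fres):
        return fres + (f0 - fres) * np.exp(-k * tt)

    hi = float(np.max(ys))
    starts = [[k0, ys[0], max(float(ys[-1]), 0.0)]
              for k0 in (1e-4, 1e-3, 3e-3, 1e-2, 3e-2)]
    res = _multistart_fit(model, ts - ts[0], ys, starts,
                          ([0.0, -np.inf, 0.0], [1.0, 2 * hi + 1.0, hi + 1.0]))
    if res is None:
        raise RuntimeError("efflux fit failed")
    k, f0, fres = res[0]
    return RateFit(k=float(k), fit_window=(float(ts[0]), float(ts[-1])),
                   r_squared=_r2(ys, model(ts - ts[0], k, f0, fres)),
                   model="decay", f_res=float(fres))


def per_cell_efflux_constant(tracks: "list[tuple[np.ndarray, np.ndarray, np.ndarray]]",
                             backshift_time: float, span_min: float = 50.0,
                             exclude_delayed_factor: float = 0.5,
                             bleach_frac: float = 0.0,
                             exposure_every: int = 1,
                             background: float = 0.0):
    """Colony efflux constant from single-cell fits.

    ``tracks`` is a list of ``(frames, t_min, mean_fluor)`` arrays, one
    per tracked cell covering the backshift.  Each cell's trace is
    photobleach-corrected (per global frame index) and fitted over the
    first ``span_min`` minutes of re-established feast conditions.
    Cells whose constant falls below ``exclude_delayed_factor`` times
    the colony median belong to the delayed-efflux phenotype, which is
    reported as its own class rather than folded into the colony's
    typical secretion constant; they are excluded from the mean, as are
    cells above the mirrored upper bound (unstable fits on segmentation
    flicker or lysing tracks).  Returns ``(mean_k, per_cell_ks)``.
    """
    ks = []
    for frames, t, y in tracks:
        t = np.asarray(t, dtype=float)
        y = np.asarray(y, dtype=float)
        if bleach_frac > 0:
            n_exp = np.asarray(frames, dtype=int) // exposure_every + 1
            y = (y - background) / (1.0 - bleach_frac) ** n_exp + background
        sel = (t >= backshift_time - 1e-9) & (t <= backshift_time + span_min + 1e-9)
        if sel.sum() < 4:
            continue
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ks.append(fit_efflux_rate(t[sel], y[sel], backshift_time,
                                          span_min).k)
        except (ValueError, RuntimeError):
            continue
    if not ks:
        raise ValueError("no usable post-backshift tracks")
    ks = np.asarray(ks)
    med = float(np.median(ks))
    lo = exclude_delayed_factor * med
    hi = med / exclude_delayed_factor
    typical = ks[(ks >= lo) & (ks <= hi)]
    return float(np.mean(typical)), ks


@dataclass
class LoadingEstimate:
    t50: float                     # minutes
    plateau: float                 # AU

    def __post_init__(self):
        if self.t50 <= 0:
            raise ValueError("t50 must be > 0")


def half_time(t: np.ndarray, mean_fluor: np.ndarray) -> LoadingEstimate:
    """Half-time of fluorescence signal formation after CAM exposure.

    The plateau is the asymptote of a saturating fit
    ``F = P (1 - exp(-k (t - t0)))`` with a short free onset lag ``t0``
    (uptake and conversion form a chain, so the rise starts with a
    brief delay); ``t50`` is the earliest time the raw trace reaches
    ``P/2``, interpolated linearly between samples.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(mean_fluor, dtype=float)
    if len(t) < 4 or np.max(y) <= 0:
        raise ValueError("trace too short or empty for a loading fit")
    tt = t - t[0]
    ymax = float(np.max(y))
    lag_max = max(tt[-1] / 3.0, 1e-6)

    def model(x, p, k, t0):
        return p * (1.0 - np.exp(-k * np.maximum(x - t0, 0.0)))

    starts = [[ymax, k0, 1.0] for k0 in (1e-3, 1e-2, 0.05, 0.1, 1.0)]
    res = _multistart_fit(model, tt, y, starts,
                          ([1e-12, 1e-6, 0.0], [4.0 * ymax, 1e3, lag_max]))
    if res is None:
        raise RuntimeError("saturating fit failed")
    plateau = float(res[0][0])
    half = plateau / 2.0
    above = np.nonzero(y >= half)[0]
    if above.size == 0:
        raise ValueError("trace never reaches half of the fitted plateau "
                         "(non-saturating)")
    i = int(above[0])
    if i == 0:
        t50 = tt[0] if tt[0] > 0 else tt[1] / 2.0
    else:
        frac = (half - y[i - 1]) / (y[i] - y[i - 1])
        t50 = tt[i - 1] + frac * (tt[i] - tt[i - 1])
    return LoadingEstimate(t50=float(max(t50, 1e-12)), plateau=plateau)


def bleaching_per_frame(traces: "list[np.ndarray]",
                        areas: Optional["list[np.ndarray]"] = None,
                        growth_tol: float = 0.05) -> float:
    """Mean percentage fluorescence loss per imaging frame.

    Each trace must come from a growth-arrested, efflux-inhibited cell
    under a constant exposure schedule; the per-frame geometric loss is
    the slope of the log trace.  Growing cells (area increase beyond
    ``growth_tol``) are rejected because dilution confounds bleaching.
    Returns the mean loss in percent per frame (0 for no exposure).
    """
    if not traces:
        raise ValueError("no traces supplied")
    if areas is not None:
        for a in areas:
            a = np.asarray(a, dtype=float)
            if a[-1] > a[0] * (1.0 + growth_tol):
                raise ValueError("growing cells confound bleaching estimates")
    losses = []
    for tr in traces:
        y = np.asarray(tr, dtype=float)
        if len(y) < 2 or np.any(y <= 0):
            continue
        frames = np.arange(len(y))
        slope = stats.linregress(frames, np.log(y)).slope
        losses.append((1.0 - np.exp(slope)) * 100.0)
    if not losses:
        raise ValueError("no usable traces")
    return float(np.mean(losses))


def snr(cell_mean_fluor, background_mean_fluor) -> float:
    """Intracellular-to-extracellular signal ratio.

    ``mean(intracellular single-cell means) / mean(cell-proximity
    background)``; raises on empty inputs or zero background.
    """
    cells = np.asarray(cell_mean_fluor, dtype=float)
    bg = np.asarray(background_mean_fluor, dtype=float)
    if cells.size == 0 or bg.size == 0:
        raise ValueError("need both cell and background observations")
    denom = float(np.mean(bg))
    if denom == 0:
        raise ValueError("zero background")
    return float(np.mean(cells)) / denom
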