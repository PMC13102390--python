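"""Fitting and time-series procedures for excavation analyses.

Covers the quantities the model analysis hinges on: the age-dependent target
line and basal rate fitted from fixed-demographics cohorts, the through-origin
area-vs-population scaling, the stabilized area per ant, the lagged
cross-correlation between digging and population growth (irregularly sampled
series interpolated to a daily grid), the digging-onset delay after population
increases, the post-collapse recovery fraction, and the logistic population
fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .demography import PopulationParams
from .excavation import (CollapseEvent, ModelParams, NoPlateauError,
                         TargetAreaLine, closed_form_single_cohort)


@dataclass(frozen=True)
class TargetLineFit:
    line: TargetAreaLine
    r_squared: float
    stderr_slope: float
    stderr_intercept: float
    n: int


@dataclass(frozen=True)
class RateFit:
    r: float
    a_age: float
    stderr_r: float
    residual_rms: float
    n: int


@dataclass(frozen=True)
class OriginFit:
    slope: float
    r_squared: float
    n: int


def fit_target_line(cohort_ages, per_ant_saturation) -> TargetLineFit:
    """OLS of per-ant saturation area (cm^2) against cohort age (days)."""
    x = np.asarray(cohort_ages, float)
    y = np.asarray(per_ant_saturation, float)
    if x.shape != y.shape or x.size < 3 or np.unique(x).size < 3:
        raise ValueError("need >= 3 points at >= 3 distinct ages")
    (slope, intercept), cov = np.polyfit(x, y, 1, cov=True)
    resid = y - (slope * x + intercept)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float((resid ** 2).sum()) / ss_tot if ss_tot > 0 else 1.0
    return TargetLineFit(TargetAreaLine(slope=float(slope), intercept=float(intercept)),
                         r_squared=r2,
                         stderr_slope=float(np.sqrt(cov[0, 0])),
                         stderr_intercept=float(np.sqrt(cov[1, 1])),
                         n=int(x.size))


def estimate_r(days, area, N: int, a0: float = 0.0) -> RateFit:
    """Nonlinear LS fit of the single-cohort saturation curve.

    Fits r and the cohort target a_age jointly to a trajectory of N same-age
    ants starting from per-ant area ``a0``; returns the basal rate in
    cm^2/(ant day).
    """
    t = np.asarray(days, float)
    y = np.asarray(area, float)
    if t.size < 4:
        raise ValueError("need >= 4 samples to fit the saturation curve")

    if np.ptp(y) < 1e-9:  # never grew: no digging, r -> 0
        return RateFit(r=0.0, a_age=max(a0, float(y.mean()) / N),
                       stderr_r=0.0, residual_rms=0.0, n=int(t.size))

    def f(t, r, a_age):
        p = ModelParams(r=max(r, 1e-9), target=TargetAreaLine(0.0, a_age),
                        maturation_delay=0.0)
        return closed_form_single_cohort(t, N, 0.0, a0, p)

    a_guess = max(y.max() / N, a0 + 1e-3, 0.1)
    try:
        popt, pcov = curve_fit(f, t, y, p0=(1.0, a_guess),
                               bounds=([0.0, 1e-6], [50.0, 1e3]), maxfev=10000)
    except RuntimeError as err:
        rms = float(np.sqrt(np.mean((y - y.mean()) ** 2)))
        raise RuntimeError(f"saturation-curve fit did not converge "
                           f"(residual rms about data mean: {rms:.3g})") from err
    resid = y - f(t, *popt)
    return RateFit(r=float(popt[0]), a_age=float(popt[1]),
                   stderr_r=float(np.sqrt(pcov[0, 0])),
                   residual_rms=float(np.sqrt(np.mean(resid ** 2))), n=int(t.size))


def rate_series(days, values, smooth_window: float = 3.0):
    """Daily rate d(value)/dt from an irregularly sampled series.

    Linear interpolation onto an integer-day grid, central differences, then
    a centered moving average of ``smooth_window`` days (the photography gap
    is 1-3 days, so 3 is the default). Returns (grid_days, rate).
    """
    t = np.asarray(days, float)
    y = np.asarray(values, float)
    if t.size < 3:
        raise ValueError("need >= 3 samples")
    if np.any(np.diff(t) <= 0):
        raise ValueError("days must be strictly increasing")
    grid = np.arange(np.ceil(t[0]), np.floor(t[-1]) + 1.0)
    yi = np.interp(grid, t, y)
    rate = np.gradient(yi, grid)
    w = max(1, int(round(smooth_window)))
    if w > 1:
        kernel = np.ones(w) / w
        # centered smoothing with edge-shrunk windows
        num = np.convolve(rate, kernel, mode="same")
        den = np.convolve(np.ones_like(rate), kernel, mode="same")
        rate = num / den
    return grid, rate


def xcorr_lagged(x, y, max_lag: int):
    """Per-lag Pearson correlation of two daily series.

    ``coeff[lag]`` correlates x(t) with y(t + lag): a *negative* peak lag
    means y (population change) precedes x (digging). Each lag re-normalizes
    on the overlapping segments, so coefficients are true correlations in
    [-1, 1]; zero-variance overlaps give NaN (masked).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size:
        raise ValueError("series must share one daily grid")
    L = x.size
    if L < 2 * max_lag:
        raise ValueError("series shorter than twice max_lag")
    lags = np.arange(-max_lag, max_lag + 1)
    out = np.full(lags.shape, np.nan)
    for j, lag in enumerate(lags):
        if lag >= 0:
            xs, ys = x[:L - lag or L], y[lag:]
        else:
            xs, ys = x[-lag:], y[:L + lag]
        if xs.size < 3:
            continue
        sx, sy = xs.std(), ys.std()
        if sx == 0 or sy == 0:
            continue
        out[j] = float(np.mean((xs - xs.mean()) * (ys - ys.mean())) / (sx * sy))
    return lags, out


def peak_lag(lags, coeffs) -> int:
    """Lag of the maximum coefficient; ties break toward the smallest |lag|."""
    lags = np.asarray(lags)
    coeffs = np.asarray(coeffs, float)
    valid = np.isfinite(coeffs)
    if not valid.any():
        raise ValueError("all coefficients are masked")
    cmax = coeffs[valid].max()
    cand = lags[valid & (coeffs >= cmax - 1e-12)]
    return int(cand[np.argmin(np.abs(cand))])


def fit_area_vs_population(mean_area, mean_N) -> OriginFit:
    """Least-squares line through the origin: area = slope * N.

    slope = sum(x y)/sum(x^2); R^2 is computed against the origin line
    (uncentered total sum of squares, as appropriate for a no-intercept fit).
    """
    x = np.asarray(mean_N, float)
    y = np.asarray(mean_area, float)
    sxx = float((x ** 2).sum())
    if sxx == 0:
        raise ValueError("population series is identically zero")
    slope = float((x * y).sum() / sxx)
    ss_res = float(((y - slope * x) ** 2).sum())
    ss_tot = float((y ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return OriginFit(slope=slope, r_squared=r2, n=int(x.size))


def area_per_ant_stabilization(days, area, n_ants,
                               day1_mode: str = "first_worker",
                               first_worker_day: float = 0.0,
                               n_last: int = 5,
                               plateau_tol: float = 0.25) -> float:
    """Stabilized area per ant: mean of A/N over the final sampling points.

    ``day1_mode`` chooses the time origin: "experiment_start" keeps all
    samples, "first_worker" drops samples before the first worker emerged.
    Signals NoPlateauError when the area still trends by more than
    ``plateau_tol`` (relative) across the averaging window.
    """
    t = np.asarray(days, float)
    A = np.asarray(area, float)
    N = np.asarray(n_ants, float)
    if day1_mode not in ("experiment_start", "first_worker"):
        raise ValueError(f"unknown day1_mode {day1_mode!r}")
    if day1_mode == "first_worker":
        keep = t >= first_worker_day
        t, A, N = t[keep], A[keep], N[keep]
    if t.size < n_last:
        raise NoPlateauError("too few samples in the averaging window")
    tw, Aw = t[-n_last:], A[-n_last:]
    if Aw.mean() > 0:
        slope = np.polyfit(tw, Aw, 1)[0]
        if abs(slope) * (tw[-1] - tw[0]) > plateau_tol * Aw.mean():
            raise NoPlateauError("area still trending over the final window")
    series = Aw / N[-n_last:]
    return float(series.mean())


def recovery_fraction(days, area, event: CollapseEvent,
                      eps: float = 0.1, k: float = 5.0) -> float:
    """Fraction of collapse-lost area re-excavated by digging cessation.

    (A_cease - A_post) / (A_pre - A_post) with A_pre the area just before the
    collapse, A_post just after, and A_cease the plateau where the digging
    rate stays below ``eps`` cm^2/day for ``k`` consecutive days.
    """
    t = np.asarray(days, float)
    A = np.asarray(area, float)
    pre = t < event.day
    post = t >= event.day
    if not pre.any() or not post.any():
        raise ValueError("collapse day outside the trajectory")
    a_pre = float(A[pre][-1])
    # the drop is applied within one step/sample of the event day; take the
    # lowest level seen in the first day after it
    near = post & (t <= event.day + 1.0)
    a_post = float(A[near].min()) if near.any() else float(A[post][0])
    if a_pre <= a_post:
        raise ValueError("no area drop found at the collapse day")
    tp, Ap = t[post], A[post]
    grid = np.arange(np.ceil(tp[0]), np.floor(tp[-1]) + 1.0)
    Ai = np.interp(grid, tp, Ap)
    rate = np.diff(Ai)
    win = max(1, int(round(k)))
    run = 0
    for i, ok in enumerate(np.abs(rate) < eps):
        run = run + 1 if ok else 0
        if run >= win:
            # once the rate has stayed below eps for k days digging has
            # ceased; the ceased level is the plateau from there on
            a_cease = float(Ai[i + 1:].mean())
            return (a_cease - a_post) / (a_pre - a_post)
    raise NoPlateauError("digging never ceased after the collapse")


def onset_delay(pop_days, pop, rate_days, digging_rate,
                rate_threshold: float = 0.5) -> float:
    """Mean delay (days) from a population increase to the next digging bout.

    An event is any daily increase of the population count; its delay is the
    time to the first day (the event day included) with digging rate above
    ``rate_threshold``. Events never followed by digging are skipped; if no
    event qualifies, raises ValueError.
    """
    pop_days = np.asarray(pop_days, float)
    pop = np.asarray(pop, float)
    rate_days = np.asarray(rate_days, float)
    digging_rate = np.asarray(digging_rate, float)
    events = pop_days[1:][np.diff(pop) > 0]
    if events.size == 0:
        raise ValueError("no population-increase events")
    delays = []
    hot = rate_days[digging_rate > rate_threshold]
    for d in events:
        later = hot[hot >= d]
        if later.size:
            delays.append(later[0] - d)
    if not delays:
        raise ValueError("no digging bout followed any population increase")
    return float(np.mean(delays))


def fit_logistic_population(days, counts) -> PopulationParams:
    """Least-squares logistic fit of worker counts over time.

    Fits K, rho and the midpoint day, then reports the equivalent
    PopulationParams with N0 = 1 (t_first back-solved from the midpoint).
    Constant counts are returned as a degenerate saturated population.
    """
    t = np.asarray(days, float)
    y = np.asarray(counts, float)
    if t.size < 4:
        raise ValueError("need >= 4 points")
    if np.ptp(y) == 0:
        return PopulationParams(K=max(float(y[0]), 1.0), rho=1e-6,
                                t_first=float(t[0]), N0=max(float(y[0]), 1.0))

    def f(t, K, rho, t_mid):
        return K / (1.0 + np.exp(-rho * (t - t_mid)))

    p0 = (float(y.max()), 0.1, float(np.median(t)))
    try:
        popt, _ = curve_fit(f, t, y, p0=p0,
                            bounds=([1.0, 1e-4, t[0] - 500], [5.0 * y.max(), 2.0, t[-1] + 500]),
                            maxfev=20000)
    except RuntimeError as err:
        raise RuntimeError("logistic population fit did not converge") from err
    K, rho, t_mid = map(float, popt)
    n0 = 1.0 if K > 1 else K
    t_first = t_mid - np.log(max(K - n0, 1e-9) / n0) / rho
    return PopulationParams(K=K, rho=rho, t_first=float(t_first), N0=n0)
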