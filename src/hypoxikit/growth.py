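"""Tumour growth kinetics: Gompertz smoothing and daily growth-rate readout.

Calliper measurements (width, length in mm) convert to volume via the
ellipsoid formula pi/6 * width * length^2. Each tumour's trajectory is
smoothed with a Gompertz curve in the W0-parameterisation

    W(t) = A * exp( ln(W0/A) * exp(-(e*Ku/A) * t) )

where W0 is the volume at treatment start (day 0, fixed from a linear
regression over days -7..+5), A is the asymptote and Ku the maximum absolute
growth rate (mm^3/day) — the slope of the curve at its inflection. The fit
is a data-smoothing device: fitted parameters are not interpreted directly;
the mean daily growth rate over the treatment period is the mean of the
curve's slope at days 1..21 by central finite difference. Where a tumour
shrinks, days on which the fitted volume is below 10 mm^3 are excluded.
Treated animals are compared to controls per model by unpaired t-test with
Holm-Sidak adjustment across models.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

SMALL_TUMOUR_MM3 = 10.0  # fitted volumes below this are excluded for shrinking tumours


def volume(width: float, length: float) -> float:
    """Tumour volume (mm^3) from calliper width and length (mm):
    pi/6 * width * length^2. Width should be the shorter axis; swapped with a
    warning if not."""
    if width <= 0 or length <= 0:
        raise ValueError("calliper dimensions must be positive")
    if width > length:
        logger.warning("width %.3g > length %.3g; swapping axes", width, length)
        width, length = length, width
    return math.pi / 6.0 * width * length**2


@dataclass(frozen=True)
class GrowthSeries:
    """Per-animal tumour volume time series; day 0 is treatment start."""

    animal_id: str
    model_id: str
    group: str  # "control" or "treated"
    days: tuple[float, ...]
    volumes: tuple[float, ...]  # mm^3

    def __post_init__(self) -> None:
        if len(self.days) != len(self.volumes):
            raise ValueError("days and volumes must have equal length")
        d = np.asarray(self.days, dtype=float)
        if len(d) and (np.diff(d) <= 0).any():
            raise ValueError(f"days must be strictly increasing for {self.animal_id}")
        if any(v <= 0 for v in self.volumes):
            raise ValueError(f"volumes must be positive for {self.animal_id}")


def read_growth_table(path) -> list[GrowthSeries]:
    """Read longitudinal measurements from TSV.

    Required columns: animal_id, model_id, group, day, and either volume_mm3
    or the pair width_mm/length_mm (converted on load).
    """
    df = pd.read_csv(path, sep="\t")
    required = {"animal_id", "model_id", "group", "day"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"growth table missing columns: {sorted(missing)}")
    if "volume_mm3" in df.columns:
        vols = df["volume_mm3"].astype(float)
    elif {"width_mm", "length_mm"} <= set(df.columns):
        vols = [volume(w, l) for w, l in zip(df["width_mm"], df["length_mm"])]
        vols = pd.Series(vols, index=df.index)
    else:
        raise ValueError(
            "growth table missing columns: ['volume_mm3'] or ['width_mm', 'length_mm']"
        )
    df = df.assign(_vol=vols)
    series = []
    for (animal, model, group), grp in df.groupby(
        ["animal_id", "model_id", "group"], sort=False
    ):
        grp = grp.sort_values("day")
        series.append(
            GrowthSeries(
                animal_id=str(animal),
                model_id=str(model),
                group=str(group),
                days=tuple(grp["day"].astype(float)),
                volumes=tuple(grp["_vol"].astype(float)),
            )
        )
    return series


def estimate_w0(series: GrowthSeries, window: tuple[float, float] = (-7.0, 5.0)) -> float:
    """Initial volume at day 0 by OLS of volume on day over the closed window.

    Falls back to the observation nearest day 0 (with a warning) if the
    regression intercept is non-positive.
    """
    days = np.asarray(series.days)
    vols = np.asarray(series.volumes)
    mask = (days >= window[0]) & (days <= window[1])
    if mask.sum() < 2:
        raise ValueError(
            f"need >= 2 observations in window {window} for {series.animal_id}"
        )
    slope, intercept = np.polyfit(days[mask], vols[mask], 1)
    w0 = float(intercept)
    if w0 <= 0:
        nearest = int(np.abs(days).argmin())
        w0 = float(vols[nearest])
        logger.warning(
            "%s: regression W0 <= 0; using observation at day %g (%.1f mm^3)",
            series.animal_id, days[nearest], w0,
        )
    return w0


def gompertz_volume(t, w0: float, ku: float, a: float):
    """Gompertz curve in the W0-form: W(t) = A*exp(ln(W0/A)*exp(-(e*Ku/A)*t))."""
    k = math.e * ku / a
    return a * np.exp(np.log(w0 / a) * np.exp(-k * np.asarray(t, dtype=float)))


def gompertz_rate(t, w0: float, ku: float, a: float):
    """Closed-form derivative dW/dt of :func:`gompertz_volume`."""
    k = math.e * ku / a
    t = np.asarray(t, dtype=float)
    return -k * np.log(w0 / a) * np.exp(-k * t) * gompertz_volume(t, w0, ku, a)


@dataclass(frozen=True)
class GompertzFit:
    """Converged (Ku, A) for a fixed-W0 Gompertz least-squares fit."""

    animal_id: str
    model_id: str
    group: str
    w0: float
    ku: float
    a: float
    rss: float
    converged: bool
    n_points: int

    def predict(self, t):
        return gompertz_volume(t, self.w0, self.ku, self.a)

    def rate(self, t):
        return gompertz_rate(t, self.w0, self.ku, self.a)


def _fit_window_mask(days: np.ndarray, t_min: float = -7.0, t_max: float = 21.0):
    """Observations entering the fit: all points in [t_min, t_max] plus the
    first one beyond t_max, to anchor the curve at the window's end."""
    mask = (days >= t_min) & (days <= t_max)
    beyond = np.flatnonzero(days > t_max)
    if len(beyond):
        mask[beyond[0]] = True
    return mask


def fit_gompertz(series: GrowthSeries, w0: float | None = None) -> GompertzFit:
    """Nonlinear least-squares fit of (Ku, A) with W0 fixed.

    Multi-start Levenberg-Marquardt-style optimisation: A started at 2x, 5x
    and 10x the maximum observed volume, Ku at the steepest observed
    two-point slope; A is bounded below at 0.9 * max(W0, max volume) while Ku
    is unconstrained in sign so shrinking tumours are representable.
    Non-convergence is flagged, never silently accepted.
    """
    if w0 is None:
        w0 = estimate_w0(series)
    if w0 <= 0:
        raise ValueError("W0 must be positive")
    days = np.asarray(series.days)
    vols = np.asarray(series.volumes)
    mask = _fit_window_mask(days)
    t, w = days[mask], vols[mask]
    if len(t) < 3:
        raise ValueError(
            f"need >= 3 observations in the fit window for {series.animal_id}"
        )
    slopes = np.diff(w) / np.diff(t)
    ku0 = float(slopes[np.abs(slopes).argmax()]) if len(slopes) else 1.0
    if ku0 == 0:
        ku0 = 1.0
    vmax = float(w.max())
    a_lo = 0.9 * max(w0, vmax)
    # upper bound stabilises the exponential-growth ridge (A, Ku -> inf at
    # fixed A/Ku); at 1000x the data range the curve is exponential to
    # within measurement precision, so the bound does not constrain the fit
    a_hi = 1000.0 * max(w0, vmax)

    def residuals(params):
        ku, a = params
        return gompertz_volume(t, w0, ku, a) - w

    best = None
    for a0_mult in (2.0, 5.0, 10.0):
        a0 = max(a0_mult * vmax, a_lo * 1.01)
        try:
            res = optimize.least_squares(
                residuals,
                x0=[ku0, a0],
                bounds=([-np.inf, a_lo], [np.inf, a_hi]),
                method="trf",
                xtol=1e-12, ftol=1e-12, gtol=1e-12,
                max_nfev=2000,
            )
        except Exception:  # singular model at pathological starts
            continue
        if res.success:
            rss = float(2 * res.cost)
            if best is None or rss < best[1]:
                best = (res, rss)
    if best is None:
        logger.warning("Gompertz fit failed for %s", series.animal_id)
        return GompertzFit(
            series.animal_id, series.model_id, series.group,
            w0, float("nan"), float("nan"), float("inf"), False, len(t),
        )
    res, rss = best
    ku, a = (float(x) for x in res.x)
    return GompertzFit(
        series.animal_id, series.model_id, series.group,
        w0, ku, a, rss, True, len(t),
    )


@dataclass(frozen=True)
class GrowthRateResult:
    """Daily finite-difference growth rates and their treatment-period mean."""

    animal_id: str
    model_id: str
    group: str
    days: tuple[int, ...]
    daily_rates: tuple[float, ...]  # mm^3/day at each day
    excluded_days: tuple[int, ...]
    mean_daily_rate: float
    degenerate: bool = False
    normalized_rate: float | None = None


def daily_growth_rates(
    fit: GompertzFit,
    days=range(1, 22),
    fd_step: float = 0.5,
    min_volume: float = SMALL_TUMOUR_MM3,
) -> GrowthRateResult:
    """Daily growth rates from the fitted curve by central finite difference.

    rate(t) = [W(t+h) - W(t-h)] / 2h at each listed day. If the fitted curve
    decreases anywhere over the day window, days with fitted volume below
    ``min_volume`` are excluded; the mean daily rate averages the retained
    days. A result with no retained days is flagged degenerate.
    """
    if not fit.converged:
        raise ValueError(f"refusing rate estimation on failed fit for {fit.animal_id}")
    days = np.asarray(list(days), dtype=float)
    rates = (fit.predict(days + fd_step) - fit.predict(days - fd_step)) / (2 * fd_step)
    fitted = fit.predict(days)
    dense = fit.predict(np.linspace(days.min(), days.max(), 201))
    shrinking = bool((np.diff(dense) < 0).any())
    excluded = (
        np.flatnonzero(fitted < min_volume) if shrinking else np.array([], dtype=int)
    )
    keep = np.ones(len(days), dtype=bool)
    keep[excluded] = False
    degenerate = not keep.any()
    mean_rate = float(rates[keep].mean()) if not degenerate else float("nan")
    if degenerate:
        logger.warning("all days excluded for %s; degenerate result", fit.animal_id)
    return GrowthRateResult(
        animal_id=fit.animal_id,
        model_id=fit.model_id,
        group=fit.group,
        days=tuple(int(d) for d in days),
        daily_rates=tuple(float(r) for r in rates),
        excluded_days=tuple(int(days[i]) for i in excluded),
        mean_daily_rate=mean_rate,
        degenerate=degenerate,
    )


def estimate_growth_rates(series_list) -> list[GrowthRateResult]:
    """Full per-animal pipeline: W0 regression, Gompertz fit, daily rates."""
    results = []
    for series in series_list:
        fit = fit_gompertz(series)
        if not fit.converged:
            continue
        results.append(daily_growth_rates(fit))
    return results


def normalize_to_control(results) -> list[GrowthRateResult]:
    """Within each model, divide mean daily rates by the median control rate.

    The control median maps to 1.0. Models whose control median is
    non-positive (or that lack controls) are skipped with a warning; their
    normalized_rate stays None.
    """
    by_model: dict[str, list[GrowthRateResult]] = {}
    for r in results:
        by_model.setdefault(r.model_id, []).append(r)
    out = []
    for model, rs in by_model.items():
        controls = [
            r.mean_daily_rate for r in rs if r.group == "control" and not r.degenerate
        ]
        if not controls:
            logger.warning("model %s has no control animals; normalisation skipped", model)
            out.extend(rs)
            continue
        med = float(np.median(controls))
        if med <= 0:
            logger.warning(
                "model %s: control median %.3g <= 0; normalisation skipped", model, med
            )
            out.extend(rs)
            continue
        for r in rs:
            norm = r.mean_daily_rate / med if not r.degenerate else None
            out.append(
                GrowthRateResult(
                    **{**r.__dict__, "normalized_rate": norm}
                )
            )
    return out


def compare_groups_table(rates: pd.DataFrame, alpha: float = 0.005) -> pd.DataFrame:
    """:func:`compare_groups` on an animal-level table with columns
    model_id, group, animal_id, mean_daily_rate."""
    results = [
        GrowthRateResult(
            animal_id=str(row.animal_id),
            model_id=str(row.model_id),
            group=str(row.group),
            days=(),
            daily_rates=(),
            excluded_days=(),
            mean_daily_rate=float(row.mean_daily_rate),
        )
        for row in rates.itertuples()
    ]
    return compare_groups(results, alpha=alpha)


def compare_groups(results, alpha: float = 0.005) -> pd.DataFrame:
    """Treated-vs-control comparison of mean daily growth rates per model.

    Two-sided unpaired (Student) t-test per model, Holm-Sidak adjustment
    across the family of models tested; a model is flagged significant when
    its adjusted p-value is below ``alpha``. Models with fewer than two
    animals in either arm are skipped with a warning.
    """
    rows = []
    by_model: dict[str, list[GrowthRateResult]] = {}
    for r in results:
        if not r.degenerate:
            by_model.setdefault(r.model_id, []).append(r)
    for model in by_model:
        rs = by_model[model]
        ctrl = np.array([r.mean_daily_rate for r in rs if r.group == "control"])
        trt = np.array([r.mean_daily_rate for r in rs if r.group == "treated"])
        if len(ctrl) < 2 or len(trt) < 2:
            logger.warning("model %s skipped: < 2 animals in an arm", model)
            continue
        pooled_var = (
            ((len(ctrl) - 1) * ctrl.var(ddof=1) + (len(trt) - 1) * trt.var(ddof=1))
            / (len(ctrl) + len(trt) - 2)
        )
        if pooled_var == 0:
            # degenerate zero-variance arms: identical means -> p = 1, else 0
            p = 1.0 if ctrl.mean() == trt.mean() else 0.0
            tstat = 0.0 if p == 1.0 else math.copysign(math.inf, trt.mean() - ctrl.mean())
        else:
            tstat, p = stats.ttest_ind(trt, ctrl, equal_var=True)
        rows.append(
            {
                "model_id": model,
                "n_control": len(ctrl),
                "n_treated": len(trt),
                "mean_control": float(ctrl.mean()),
                "mean_treated": float(trt.mean()),
                "t_statistic": float(tstat),
                "p_value": float(p),
            }
        )
    df = pd.DataFrame(rows)
    if df.empty:
        return df.assign(p_adjusted=[], significant=[])
    # clip p = 1 just below 1 for the Sidak transform (log1p(-p) at p = 1)
    p_in = np.clip(df["p_value"], 0.0, 1.0 - 1e-15)
    reject, p_adj, _, _ = multipletests(p_in, alpha=alpha, method="holm-sidak")
    df["p_adjusted"] = p_adj
    df["significant"] = reject
    return df
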