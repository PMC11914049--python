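"""Net ecosystem calcification (NEC) from tide-pool alkalinity drawdown.

When the rim of an artificial tide pool is exposed at low tide the water
inside is stagnant, and the total-alkalinity (TA) anomaly method applies:
precipitating one mole of CaCO3 consumes two moles of TA, so

    NEC = -1/2 * (dTA/dt) * Zbar * rho_water     [mmol m^-2 h^-1]

with TA in mmol kg^-1, dTA/dt the least-squares slope over a short window of
consecutive samplings (> 30 min), Zbar the mean water depth (m) over the
window, and rho_water the seawater density (kg m^-3).  A TA *decrease*
(calcification) therefore gives positive NEC.  Windowed NEC values are
regressed against photon flux with a hyperbolic tangent (photosynthesis-
irradiance analogue) or a linear function, the form chosen by small-sample
AIC; daily NEC is the integral of the fitted response over a 24-h light
curve, with its SD propagated from the parameter covariance by the delta
method.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import curve_fit

logger = logging.getLogger(__name__)

__all__ = [
    "TidePoolSeries",
    "NecEstimate",
    "LightResponseFit",
    "DailyNec",
    "seawater_density",
    "window_nec",
    "series_windows",
    "fit_light_response",
    "integrate_daily_nec",
    "compare_station_slopes",
]

SAMPLE_COLUMNS = ("time_h", "ta_mmol_kg", "depth_m", "temp_c", "salinity", "photon_flux")


def seawater_density(
    temp_c: float, salinity: float, *, constant: float | None = None
) -> float:
    """Surface seawater density (kg m^-3) from the EOS-80 equation of state.

    ``constant`` overrides the equation of state (e.g. a fixed 1023 kg m^-3).
    Valid for temperature in [-2, 40] degC and salinity in [0, 42].
    """
    if constant is not None:
        return float(constant)
    t = float(temp_c)
    s = float(salinity)
    if not (-2.0 <= t <= 40.0):
        raise ValueError(f"temperature {t} degC outside [-2, 40]")
    if not (0.0 <= s <= 42.0):
        raise ValueError(f"salinity {s} outside [0, 42]")
    rho_w = (
        999.842594
        + 6.793952e-2 * t
        - 9.095290e-3 * t**2
        + 1.001685e-4 * t**3
        - 1.120083e-6 * t**4
        + 6.536332e-9 * t**5
    )
    a = (
        0.824493
        - 4.0899e-3 * t
        + 7.6438e-5 * t**2
        - 8.2467e-7 * t**3
        + 5.3875e-9 * t**4
    )
    b = -5.72466e-3 + 1.0227e-4 * t - 1.6546e-6 * t**2
    c = 4.8314e-4
    return rho_w + a * s + b * s**1.5 + c * s**2


@dataclass
class TidePoolSeries:
    """A chemistry time series for one tide pool on one date.

    ``samples`` holds columns ``time_h, ta_mmol_kg, depth_m, temp_c,
    salinity, photon_flux`` plus a boolean ``stagnant`` flag marking spans
    when the pool rim is exposed (the advection-free assumption of the TA
    anomaly method holds only there).
    """

    station_id: str
    date: str
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in SAMPLE_COLUMNS + ("stagnant",) if c not in self.samples.columns]
        if missing:
            raise ValueError(f"series missing columns {missing}")
        t = self.samples["time_h"].to_numpy(dtype=float)
        if np.any(np.diff(t) <= 0):
            raise ValueError("sample times must be strictly increasing")
        ta = self.samples["ta_mmol_kg"].to_numpy(dtype=float)
        if np.any(ta <= 0):
            raise ValueError("TA must be positive")
        if np.nanmax(ta) > 10.0:
            logger.warning(
                "TA above 10 mmol kg^-1: check units (umol kg^-1 needs /1000)"
            )
        stag = self.samples["stagnant"].to_numpy(dtype=bool)
        if np.any(self.samples["depth_m"].to_numpy(dtype=float)[stag] <= 0):
            raise ValueError("depth must be positive during stagnant spans")

    @property
    def stagnant_samples(self) -> pd.DataFrame:
        return self.samples[self.samples["stagnant"].astype(bool)]


@dataclass(frozen=True)
class NecEstimate:
    """NEC over one sampling window, with the slope-propagated SE."""

    station_id: str
    window: tuple[float, float]       # (start, end) time in h
    nec: float                        # mmol m^-2 h^-1
    se: float
    mean_light: float
    ta_slope: float                   # mmol kg^-1 h^-1
    ta_slope_se: float
    n_samples: int


def window_nec(
    series: TidePoolSeries,
    start: int = 0,
    size: int = 3,
    *,
    density_constant: float | None = None,
) -> NecEstimate:
    """NEC from ``size`` consecutive stagnant samples starting at ``start``.

    The TA trend is the least-squares slope of TA against time over the
    window (using every sample rather than the endpoints); the window must
    lie entirely within a stagnant span and cover more than 30 min.
    """
    if size < 3:
        raise ValueError("a window needs at least 3 samples")
    stag = series.stagnant_samples.reset_index(drop=True)
    if start < 0 or start + size > len(stag):
        raise ValueError("window exceeds the stagnant span")
    win = stag.iloc[start : start + size]
    # consecutive within the original series: no non-stagnant rows in between
    full_t = series.samples["time_h"].to_numpy(dtype=float)
    in_window = (full_t >= win["time_h"].iloc[0]) & (full_t <= win["time_h"].iloc[-1])
    if not series.samples.loc[in_window, "stagnant"].astype(bool).all():
        raise ValueError("window crosses a non-stagnant span (advection not negligible)")
    t = win["time_h"].to_numpy(dtype=float)
    span = t[-1] - t[0]
    if span <= 0.5:
        raise ValueError(f"window spans {span * 60:.0f} min; need > 30 min")
    ta = win["ta_mmol_kg"].to_numpy(dtype=float)
    fit = stats.linregress(t, ta)
    zbar = float(win["depth_m"].mean())
    rho = seawater_density(
        float(win["temp_c"].mean()),
        float(win["salinity"].mean()),
        constant=density_constant,
    )
    nec = -0.5 * fit.slope * zbar * rho
    se = 0.5 * fit.stderr * zbar * rho
    return NecEstimate(
        station_id=series.station_id,
        window=(float(t[0]), float(t[-1])),
        nec=float(nec),
        se=float(se),
        mean_light=float(win["photon_flux"].mean()),
        ta_slope=float(fit.slope),
        ta_slope_se=float(fit.stderr),
        n_samples=size,
    )


def series_windows(
    series: TidePoolSeries, size: int = 3, *, density_constant: float | None = None
) -> list[NecEstimate]:
    """All rolling ``size``-sample NEC windows over the stagnant span."""
    n = len(series.stagnant_samples)
    out = []
    for start in range(n - size + 1):
        try:
            out.append(
                window_nec(series, start, size, density_constant=density_constant)
            )
        except ValueError:
            continue
    return out


# ---------------------------------------------------------------------------
# light response

def _tanh_model(light, a, i_k, c):
    return a * np.tanh(light / i_k) + c


@dataclass
class LightResponseFit:
    """NEC-vs-light regression: tanh saturating form or a straight line."""

    form: str                       # "tanh" | "linear"
    params: dict[str, float]
    covariance: np.ndarray
    aicc: float
    n_points: int

    def predict(self, light: np.ndarray) -> np.ndarray:
        light = np.asarray(light, dtype=float)
        if self.form == "tanh":
            return _tanh_model(light, self.params["a"], self.params["i_k"], self.params["c"])
        return self.params["b"] * light + self.params["c"]

    def gradient(self, light: np.ndarray) -> np.ndarray:
        """d NEC / d params, shape (n, p), parameter order as in ``params``."""
        light = np.asarray(light, dtype=float)
        if self.form == "tanh":
            a, i_k = self.params["a"], self.params["i_k"]
            u = light / i_k
            return np.column_stack(
                [np.tanh(u), -a * light / i_k**2 / np.cosh(u) ** 2, np.ones_like(light)]
            )
        return np.column_stack([light, np.ones_like(light)])


def _aicc(rss: float, n: int, k: int) -> float:
    if n - k - 1 <= 0:
        return np.inf
    return n * np.log(max(rss, 1e-300) / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def fit_light_response(
    nec: np.ndarray, light: np.ndarray, *, force_form: str | None = None
) -> LightResponseFit:
    """Regress windowed NEC against photon flux.

    Fits both NEC(I) = a*tanh(I/i_k) + c (nonlinear least squares) and
    NEC(I) = b*I + c (ordinary least squares) and keeps the form with the
    lower small-sample AIC, unless ``force_form`` picks one.  A tanh fit
    that fails to converge falls back to linear with a warning.
    """
    nec = np.asarray(nec, dtype=float)
    light = np.asarray(light, dtype=float)
    if np.ptp(light) == 0.0:
        raise ValueError("all light values equal: light dependence not identifiable")
    n = nec.size
    if n < 3:
        raise ValueError("need at least 3 (NEC, light) points")

    # linear candidate
    x = np.column_stack([light, np.ones(n)])
    coef, *_ = np.linalg.lstsq(x, nec, rcond=None)
    resid = nec - x @ coef
    rss_lin = float(resid @ resid)
    dof = n - 2
    sigma2 = rss_lin / dof if dof > 0 else np.nan
    cov_lin = sigma2 * np.linalg.inv(x.T @ x)
    linear = LightResponseFit(
        form="linear",
        params={"b": float(coef[0]), "c": float(coef[1])},
        covariance=cov_lin,
        aicc=_aicc(rss_lin, n, 3),     # slope, intercept, residual variance
        n_points=n,
    )
    if force_form == "linear":
        return linear

    tanh_fit = None
    if n >= 4:
        span = float(np.ptp(nec)) or 1.0
        positive = light[light > 0]
        i_k0 = float(np.median(positive)) if positive.size else 1.0
        try:
            popt, pcov = curve_fit(
                _tanh_model,
                light,
                nec,
                p0=[span, max(i_k0, 1.0), float(np.min(nec))],
                maxfev=20000,
            )
            if np.all(np.isfinite(pcov)):
                rss = float(np.sum((nec - _tanh_model(light, *popt)) ** 2))
                tanh_fit = LightResponseFit(
                    form="tanh",
                    params={"a": float(popt[0]), "i_k": float(popt[1]), "c": float(popt[2])},
                    covariance=pcov,
                    aicc=_aicc(rss, n, 4),
                    n_points=n,
                )
        except (RuntimeError, ValueError):
            pass
    if force_form == "tanh":
        if tanh_fit is None:
            raise RuntimeError("tanh light-response fit did not converge")
        return tanh_fit
    if tanh_fit is None:
        if force_form is None and n >= 4:
            logger.warning("tanh light-response fit did not converge; using linear")
        return linear
    return tanh_fit if tanh_fit.aicc < linear.aicc else linear


@dataclass(frozen=True)
class DailyNec:
    """Daily integrated calcification with its delta-method SD."""

    value: float      # mmol CaCO3 m^-2 day^-1
    sd: float
    form: str


def integrate_daily_nec(
    fit: LightResponseFit,
    light_day: pd.DataFrame,
    *,
    max_gap_h: float = 2.0,
) -> DailyNec:
    """Integrate the fitted light response over a 24-h photon-flux series.

    ``light_day`` has columns ``time_h`` (covering 0-24, night values 0) and
    ``photon_flux``.  The integral is trapezoidal on the sampled light curve;
    the SD propagates the parameter covariance through the integral's
    gradient (first-order delta method).
    """
    t = light_day["time_h"].to_numpy(dtype=float)
    light = light_day["photon_flux"].to_numpy(dtype=float)
    if t[0] > 0.0 + 1e-9 or t[-1] < 24.0 - 1e-9:
        raise ValueError("light series must cover the full 24 h")
    gaps = np.diff(t)
    if np.any(gaps > max_gap_h):
        raise ValueError(f"gap of {gaps.max():.2f} h exceeds {max_gap_h} h")
    value = float(np.trapezoid(fit.predict(light), t))
    grad = np.trapezoid(fit.gradient(light), t, axis=0)
    var = float(grad @ fit.covariance @ grad)
    return DailyNec(value=value, sd=float(np.sqrt(max(var, 0.0))), form=fit.form)


# ---------------------------------------------------------------------------
# station comparison

def compare_station_slopes(
    series_by_station: dict[str, TidePoolSeries],
) -> dict[str, pd.DataFrame | dict]:
    """Compare TA-drawdown slopes between stations (ANCOVA-style).

    Returns per-station slopes with SEs, the common-slope F-test on the
    time x station interaction, and Tukey-style pairwise slope comparisons
    using the studentized range distribution.  Stations with fewer than 3
    stagnant samples are skipped with a warning.
    """
    usable: dict[str, pd.DataFrame] = {}
    for station, series in series_by_station.items():
        stag = series.stagnant_samples
        if len(stag) < 3:
            logger.warning("station %s skipped (<3 stagnant samples)", station)
            continue
        usable[station] = stag
    if len(usable) < 2:
        raise ValueError("need at least 2 stations with >= 3 stagnant samples")

    rows = []
    rss_full = 0.0
    n_total = 0
    slopes = {}
    for station, stag in usable.items():
        t = stag["time_h"].to_numpy(dtype=float)
        ta = stag["ta_mmol_kg"].to_numpy(dtype=float)
        fit = stats.linregress(t, ta)
        resid = ta - (fit.intercept + fit.slope * t)
        rss_full += float(resid @ resid)
        n_total += t.size
        slopes[station] = fit
        rows.append(
            {
                "station": station,
                "ta_slope": fit.slope,
                "se": fit.stderr,
                "n": t.size,
            }
        )
    slope_table = pd.DataFrame(rows).set_index("station")

    # common-slope model: separate intercepts, one shared slope
    k = len(usable)
    df_full = n_total - 2 * k
    design = []
    y_all = []
    for j, (station, stag) in enumerate(usable.items()):
        t = stag["time_h"].to_numpy(dtype=float)
        block = np.zeros((t.size, k + 1))
        block[:, j] = 1.0
        block[:, k] = t
        design.append(block)
        y_all.append(stag["ta_mmol_kg"].to_numpy(dtype=float))
    x = np.vstack(design)
    y = np.concatenate(y_all)
    coef, *_ = np.linalg.lstsq(x, y, rcond=None)
    rss_common = float(np.sum((y - x @ coef) ** 2))
    f_stat = ((rss_common - rss_full) / (k - 1)) / (rss_full / df_full)
    p_inter = float(stats.f.sf(f_stat, k - 1, df_full))

    sigma2 = rss_full / df_full
    pairs = []
    names = list(usable)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            # SEs recomputed under the pooled residual variance
            ta_a = usable[a]["time_h"].to_numpy(dtype=float)
            ta_b = usable[b]["time_h"].to_numpy(dtype=float)
            var = sigma2 * (
                1.0 / np.sum((ta_a - ta_a.mean()) ** 2)
                + 1.0 / np.sum((ta_b - ta_b.mean()) ** 2)
            )
            diff = slopes[a].slope - slopes[b].slope
            q = abs(diff) / np.sqrt(var / 2.0)
            p = float(stats.studentized_range.sf(q, k, df_full))
            pairs.append(
                {"station_a": a, "station_b": b, "slope_diff": diff, "p_tukey": p}
            )
    return {
        "slopes": slope_table,
        "interaction": {"F": float(f_stat), "df": (k - 1, df_full), "p": p_inter},
        "pairwise": pd.DataFrame(pairs),
    }
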