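"""Seeded generators with known ground truth for every pipeline stage.

Three observation designs are emulated:

* **harbor survey** (:func:`simulate_survey`) — 11 sites (artificial
  breakwaters and natural reefs) visited over 1989-2018 by 5 survey methods,
  recording percent cover of 7 hard-coral taxa.  Per-taxon alr cover follows
  the substrate/depth/year fixed-effect structure with site and method random
  intercepts; a mass-bleaching drop in 1998 is followed by substrate-specific
  linear recovery.  A configurable fraction of sub-5% cells is degraded to
  the semi-quantitative "R"/"+"/range symbols of historical records.
* **wave-dissipating block survey** (:func:`simulate_block_survey`) —
  processed (grooved) vs unprocessed block faces at three depths, three
  replicate quadrats each (18 quadrats per year) over years 1-18 since
  installation; alr cover is normal, colony density is gamma with a log link
  and is strictly positive.
* **tide-pool chemistry** (:func:`simulate_tidepool_day`) — a sinusoidal
  daytime light curve, instantaneous NEC from a saturating tanh light
  response, and total alkalinity evolved backward through the TA-anomaly
  relation during the stagnant (rim-exposed) window, sampled every 10-12 min
  with measurement noise.

When the simulated year span starts at or after the bleaching year, the
survey mean structure is *exactly* the linear fixed-effects model on
standardized covariates, so the truth sidecar coefficients are directly
comparable to fitted standardized effect sizes.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .composition import AlrVector, inverse_alr
from .nec import TidePoolSeries, seawater_density
from .survey_records import TAXA

__all__ = [
    "SurveySimConfig",
    "BlockSimConfig",
    "TidePoolSimConfig",
    "simulate_survey",
    "simulate_block_survey",
    "simulate_tidepool_day",
    "simulate_tidepool_campaign",
    "save_simulation",
]


# ---------------------------------------------------------------------------
# harbor survey

#: Default standardized effect sizes (intercept, substrate, depth, year,
#: substrate:depth, substrate:year) on the alr scale, shared across taxa with
#: per-taxon intercept offsets.
_DEFAULT_BETA = (-1.5, -1.0, -0.5, 0.8, 0.2, -0.4)

#: Per-taxon alr intercept offsets: fast-growing branching taxa dominate.
_TAXON_OFFSET = {
    "acropora": 0.6,
    "pocillopora": 0.0,
    "montipora": -0.3,
    "porites": -0.5,
    "faviidae": -0.9,
    "millepora": -1.3,
    "other_hard": -0.7,
}


@dataclass
class SurveySimConfig:
    """Conditions for the harbor-survey generator."""

    seed: int = 0
    n_sites: int = 11
    n_methods: int = 5
    years: tuple[int, int] = (1989, 2018)
    surveys_per_site_year: int = 2
    elevation_grid: tuple[float, ...] = (-2.0, -5.0, -8.0)
    beta: tuple[float, ...] = _DEFAULT_BETA
    s_site: float = 0.5
    s_method: float = 0.3
    eps: float = 0.6
    bleach_year: int = 1998
    bleach_drop: float = 2.0           # alr-scale drop at the bleaching event
    recovery_artificial: float = 0.15  # alr units per year
    recovery_natural: float = 0.05
    rate_r: float = 0.3                # fraction of <1% cells emitted as "R"
    rate_plus: float = 0.3             # fraction of 1-5% cells emitted as "+"
    rate_range: float = 0.1            # fraction of >=5% cells emitted as a range

    def __post_init__(self) -> None:
        for rate in (self.rate_r, self.rate_plus, self.rate_range):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("symbol-injection rates must lie in [0, 1]")
        if min(self.s_site, self.s_method, self.eps) <= 0:
            raise ValueError("all SDs must be positive")


def _standardize(x: np.ndarray) -> np.ndarray:
    return (x - x.mean()) / (2.0 * x.std(ddof=1))


def simulate_survey(cfg: SurveySimConfig) -> tuple[pd.DataFrame, dict]:
    """Generate a survey table in the documented CSV schema, plus the truth.

    Returns the table (string cells, symbols injected) and a truth record
    holding every parameter, the per-record true percents, and whether the
    mean structure is exactly linear (year span at/after the bleaching year)
    or includes the bleaching trajectory.
    """
    rng = np.random.default_rng(cfg.seed)
    years = np.arange(cfg.years[0], cfg.years[1] + 1)
    linear_mode = cfg.years[0] >= cfg.bleach_year

    sites = [f"site{i + 1:02d}" for i in range(cfg.n_sites)]
    substrate_of = {
        s: ("artificial" if i % 2 == 0 else "natural") for i, s in enumerate(sites)
    }
    methods = ["quadrat", "belt_transect", "spot_check", "manta", "snorkel"][
        : cfg.n_methods
    ]
    r_site = rng.normal(0.0, cfg.s_site, cfg.n_sites)
    r_method = rng.normal(0.0, cfg.s_method, cfg.n_methods)

    rows = []
    for site_i, site in enumerate(sites):
        for year in years:
            for _ in range(cfg.surveys_per_site_year):
                rows.append(
                    {
                        "site_id": site,
                        "site_i": site_i,
                        "substrate": substrate_of[site],
                        "year": int(year),
                        "elevation_lwl_m": float(rng.choice(cfg.elevation_grid)),
                        "method_i": int(rng.integers(cfg.n_methods)),
                    }
                )
    design = pd.DataFrame(rows)
    n = len(design)
    f_sub = (design["substrate"] == "natural").to_numpy(dtype=float)
    depth = -design["elevation_lwl_m"].to_numpy()
    year_v = design["year"].to_numpy(dtype=float)
    f_s, d_s, y_s = _standardize(f_sub), _standardize(depth), _standardize(year_v)

    b1, b2, b3, b4, b5, b6 = cfg.beta
    base = b2 * f_s + b3 * d_s + b5 * f_s * d_s
    if linear_mode:
        base = base + b4 * y_s + b6 * f_s * y_s
    else:
        dt = year_v - cfg.bleach_year
        rate = np.where(f_sub == 0.0, cfg.recovery_artificial, cfg.recovery_natural)
        traj = np.where(dt < 0, 0.0, np.minimum(-cfg.bleach_drop + rate * dt, 0.0))
        base = base + traj
    random_part = r_site[design["site_i"]] + r_method[design["method_i"]]

    # per-taxon alr coordinates (vs other benthic), then a joint inverse alr:
    # log(percent_taxon / percent_other) recovers each coordinate exactly
    true_alr = np.empty((n, len(TAXA)))
    for j, taxon in enumerate(TAXA):
        mu = b1 + _TAXON_OFFSET[taxon] + base + random_part
        true_alr[:, j] = mu + rng.normal(0.0, cfg.eps, n)
    expd = np.exp(true_alr)
    true_percent = 100.0 * expd / (1.0 + expd.sum(axis=1, keepdims=True))

    table_rows = []
    for i in range(n):
        rec: dict[str, str] = {
            "record_id": f"r{i + 1:05d}",
            "site_id": design["site_id"].iloc[i],
            "substrate": design["substrate"].iloc[i],
            "year": str(design["year"].iloc[i]),
            "elevation_lwl_m": f"{design['elevation_lwl_m'].iloc[i]:.1f}",
            "slope_deg": "",
            "method": methods[design["method_i"].iloc[i]],
            "total": f"{true_percent[i].sum():.4f}",
        }
        for j, taxon in enumerate(TAXA):
            rec[taxon] = _emit_cell(true_percent[i, j], cfg, rng)
        table_rows.append(rec)
    frame = pd.DataFrame(table_rows)

    truth = {
        "config": asdict(cfg),
        "mode": "linear" if linear_mode else "bleaching_trajectory",
        "beta": list(cfg.beta),
        "taxon_offsets": dict(_TAXON_OFFSET),
        "r_site": dict(zip(sites, r_site.tolist())),
        "r_method": dict(zip(methods, r_method.tolist())),
        "true_percent": {
            t: true_percent[:, j].tolist() for j, t in enumerate(TAXA)
        },
        "true_alr": {t: true_alr[:, j].tolist() for j, t in enumerate(TAXA)},
        "n_records": n,
    }
    return frame, truth


def _emit_cell(value: float, cfg: SurveySimConfig, rng: np.random.Generator) -> str:
    """Degrade a true percent to the recorded token (symbols only below 5%)."""
    if value < 1.0 and rng.random() < cfg.rate_r:
        return "R"
    if 1.0 <= value < 5.0 and rng.random() < cfg.rate_plus:
        return "+"
    if value >= 5.0 and rng.random() < cfg.rate_range:
        lo = max(value - 2.5, 0.0)
        return f"{lo:.1f}-{value + 2.5:.1f}" if lo > 0 else f"{value:.4f}"
    return f"{value:.4f}"


# ---------------------------------------------------------------------------
# wave-dissipating block survey

@dataclass
class BlockSimConfig:
    """Conditions for the block-survey generator (years since installation)."""

    seed: int = 0
    n_years: int = 18
    depths: tuple[float, ...] = (2.0, 5.0, 8.0)   # m below LWL
    replicates: int = 3
    beta_cover: tuple[float, ...] = (-1.0, 0.6, -0.5, 0.9, 0.0, 0.3)
    eps_cover: float = 0.5
    beta_colony: tuple[float, ...] = (1.5, 0.5, -0.4, 0.7, 0.0, 0.2)
    eps_colony: float = 1.0

    def __post_init__(self) -> None:
        if self.eps_cover <= 0 or self.eps_colony <= 0:
            raise ValueError("residual SDs must be positive")


def simulate_block_survey(cfg: BlockSimConfig) -> tuple[pd.DataFrame, dict]:
    """Generate the processed/unprocessed block design with cover and colonies.

    Two processing levels x 3 depths x ``replicates`` quadrats observed each
    year (18 quadrats per year under the defaults).  ``alr_cover`` is normal
    with the eq-2 style mean; ``colony`` is gamma (mean exp(linear predictor),
    constant variance), strictly positive.
    """
    rng = np.random.default_rng(cfg.seed)
    grid = [
        (proc, depth, rep)
        for proc in (0.0, 1.0)
        for depth in cfg.depths
        for rep in range(cfg.replicates)
    ]
    rows = []
    for year in range(1, cfg.n_years + 1):
        for proc, depth, rep in grid:
            rows.append(
                {
                    "quadrat_id": f"q{int(proc)}_{depth:g}_{rep}",
                    "surface_processing": proc,
                    "depth": depth,
                    "years": float(year),
                    "replicate": rep,
                }
            )
    frame = pd.DataFrame(rows)
    p_s = _standardize(frame["surface_processing"].to_numpy())
    d_s = _standardize(frame["depth"].to_numpy())
    y_s = _standardize(frame["years"].to_numpy())
    n = len(frame)

    b = cfg.beta_cover
    mu_cover = b[0] + b[1] * p_s + b[2] * d_s + b[3] * y_s + b[4] * p_s * d_s + b[5] * p_s * y_s
    frame["alr_cover"] = mu_cover + rng.normal(0.0, cfg.eps_cover, n)

    g = cfg.beta_colony
    eta = g[0] + g[1] * p_s + g[2] * d_s + g[3] * y_s + g[4] * p_s * d_s + g[5] * p_s * y_s
    mu_col = np.exp(eta)
    v = cfg.eps_colony**2
    frame["colony"] = rng.gamma(shape=mu_col**2 / v, scale=v / mu_col)

    truth = {
        "config": asdict(cfg),
        "beta_cover": list(cfg.beta_cover),
        "eps_cover": cfg.eps_cover,
        "beta_colony": list(cfg.beta_colony),
        "eps_colony": cfg.eps_colony,
        "quadrats_per_year": len(grid),
        "n_records": n,
    }
    return frame, truth


# ---------------------------------------------------------------------------
# tide-pool chemistry

@dataclass
class StationTruth:
    """True light response and geometry of one artificial tide pool."""

    rim_elevation_lwl_m: float = 0.7
    depth_m: float = 0.5
    a: float = 6.0        # tanh amplitude, mmol m^-2 h^-1
    i_k: float = 500.0    # saturation photon flux
    c: float = -1.0       # dark NEC (dissolution when negative)


@dataclass
class TidePoolSimConfig:
    """Conditions for the tide-pool chemistry generator."""

    seed: int = 0
    stations: dict[str, StationTruth] = field(
        default_factory=lambda: {"st1": StationTruth()}
    )
    ta0_mmol_kg: float = 2.2
    ta_noise_sd: float = 0.003        # ~3 umol kg^-1 measurement accuracy
    interval_min: tuple[float, float] = (10.0, 12.0)
    peak_flux: float = 2000.0
    sunrise_h: float = 6.0
    sunset_h: float = 18.0
    temp_c: float = 28.0
    salinity: float = 34.5

    def __post_init__(self) -> None:
        if self.interval_min[0] <= 0:
            raise ValueError("sampling interval must be positive")
        for st in self.stations.values():
            if st.depth_m <= 0:
                raise ValueError("pool depth must be positive during stagnant spans")


def _light_curve(cfg: TidePoolSimConfig, t: np.ndarray) -> np.ndarray:
    day = (t >= cfg.sunrise_h) & (t <= cfg.sunset_h)
    phase = (t - cfg.sunrise_h) / (cfg.sunset_h - cfg.sunrise_h)
    return np.where(day, cfg.peak_flux * np.sin(np.pi * np.clip(phase, 0, 1)) ** 2, 0.0)


def _true_nec(st: StationTruth, light: np.ndarray) -> np.ndarray:
    return st.a * np.tanh(light / st.i_k) + st.c


def simulate_tidepool_day(
    cfg: TidePoolSimConfig,
    station: str = "st1",
    *,
    stagnant_start_h: float = 10.0,
    stagnant_hours: float = 3.5,
    date: str = "2019-07-02",
) -> tuple[TidePoolSeries, dict]:
    """One day of chemistry sampling at one station, plus the truth record.

    During the stagnant window the TA decrement over each fine time step is
    ``2 * NEC * dt / (Zbar * rho)`` (the TA-anomaly relation run forward);
    outside it TA sits at the open-water baseline.  Samples fall every 10-12
    min through the stagnant window, with independent measurement noise.
    """
    if station not in cfg.stations:
        raise ValueError(f"unknown station {station!r}")
    st = cfg.stations[station]
    station_key = zlib.crc32(station.encode()) % 2**31
    rng = np.random.default_rng(
        np.random.SeedSequence([cfg.seed, station_key, int(stagnant_start_h * 60)])
    )
    rho = seawater_density(cfg.temp_c, cfg.salinity)

    # true TA trajectory on a fine grid through the stagnant window
    fine = np.linspace(
        stagnant_start_h, stagnant_start_h + stagnant_hours, 1000
    )
    nec_fine = _true_nec(st, _light_curve(cfg, fine))
    dt = np.diff(fine)
    ta_fine = cfg.ta0_mmol_kg + np.concatenate(
        [[0.0], np.cumsum(-2.0 * nec_fine[:-1] * dt / (st.depth_m * rho))]
    )

    # sample times: pre-stagnant lead-in, stagnant window, post
    times = [stagnant_start_h - 0.3]
    t = stagnant_start_h
    while t <= stagnant_start_h + stagnant_hours:
        times.append(t)
        t += rng.uniform(*cfg.interval_min) / 60.0
    times.append(times[-1] + 0.3)
    times_arr = np.array(times)
    stagnant = (times_arr >= stagnant_start_h) & (
        times_arr <= stagnant_start_h + stagnant_hours
    )
    ta = np.where(
        stagnant, np.interp(times_arr, fine, ta_fine), cfg.ta0_mmol_kg
    ) + rng.normal(0.0, cfg.ta_noise_sd, times_arr.size)
    samples = pd.DataFrame(
        {
            "time_h": times_arr,
            "ta_mmol_kg": ta,
            "depth_m": st.depth_m,
            "temp_c": cfg.temp_c,
            "salinity": cfg.salinity,
            "photon_flux": _light_curve(cfg, times_arr),
            "stagnant": stagnant,
        }
    )
    series = TidePoolSeries(station_id=station, date=date, samples=samples)

    full_day = np.linspace(0.0, 24.0, 24 * 60 + 1)
    light_day = _light_curve(cfg, full_day)
    truth = {
        "station": station,
        "params": asdict(st),
        "rho": rho,
        "stagnant_window": [stagnant_start_h, stagnant_start_h + stagnant_hours],
        "daily_nec_true": float(np.trapezoid(_true_nec(st, light_day), full_day)),
        "light_day": {"time_h": full_day.tolist(), "photon_flux": light_day.tolist()},
    }
    return series, truth


def simulate_tidepool_campaign(
    cfg: TidePoolSimConfig, station: str = "st1"
) -> tuple[list[TidePoolSeries], dict]:
    """A sampling campaign: stagnant windows across the day plus one night.

    Morning, midday and afternoon windows span the light range; the night
    series pins the dark end of the light response.
    """
    windows = [(7.0, 3.5), (10.25, 3.5), (14.5, 3.5), (0.5, 3.5)]
    series = []
    truth = None
    for i, (start, dur) in enumerate(windows):
        s, t = simulate_tidepool_day(
            cfg, station, stagnant_start_h=start, stagnant_hours=dur,
            date=f"2019-07-{i + 2:02d}",
        )
        series.append(s)
        truth = t
    assert truth is not None
    truth = {k: v for k, v in truth.items() if k != "stagnant_window"}
    truth["n_days"] = len(windows)
    return series, truth


# ---------------------------------------------------------------------------
# sidecars

def save_simulation(frame: pd.DataFrame, truth: dict, csv_path: str | Path) -> Path:
    """Write a simulated table plus its machine-readable truth sidecar.

    The sidecar lands next to the CSV as ``<stem>.truth.json`` and contains
    everything needed to score recovery without re-deriving parameters.
    """
    csv_path = Path(csv_path)
    frame.to_csv(csv_path, index=False)
    sidecar = csv_path.with_suffix(".truth.json")
    sidecar.write_text(json.dumps(truth, indent=1))
    return sidecar
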