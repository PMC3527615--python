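"""Synthetic Arctic environmental/abundance tables.

The study design being emulated is a Beaufort Sea sampling programme with
two parts:

* a **seasonal** time series at a single Franklin Bay station (70°03′ N,
  126°30′ W): 21 sampling dates from 2003-11-04 to 2004-08-06 at eight
  fixed depths (3, 10, 20, 30, 50, 100, 150, 220 m), with 12 of the 168
  date-by-depth cells lost to sampling problems, leaving 156 samples;
* a **spatial** summer survey of 7 stations between the Mackenzie River
  and Amundsen Gulf (69.5–71.5° N, 122.3–138.6° W), 2004-07-04 to
  2004-08-10, 37 samples above 80 m.

Each sample carries temperature, salinity, depth, day length, Chl-a, and
flow-cytometric abundances of high/low nucleic-acid prokaryotes (HNA/LNA,
10^5 mL^-1) and high/low-fluorescence viruses (V1/V2, 10^6 mL^-1), with
totals as exact row-wise sums.

Generation proceeds in four steps: (1) smooth covariate fields (winter
mixed layer near -1.7 °C, summer surface warming and freshening, a summer
chlorophyll bloom); (2) affine/power moment calibration of the covariates
to the published summary moments; (3) abundances from deterministic
response surfaces times multiplicative lognormal noise; (4) moment
calibration of the abundances and recomputation of the sum columns.

The response surfaces (:func:`true_response`) are the latent truth that
model-recovery tests measure against: HNA is unimodal in temperature with
its optimum between -1.3 and -0.3 °C, LNA increases with temperature and
Chl-a, V1 increases with Chl-a and day length and declines with depth,
and V2 declines strictly with depth and increases with Chl-a.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .astro import GeoDate, day_length

__all__ = [
    "COLUMNS",
    "COVARIATE_COLUMNS",
    "ABUNDANCE_COLUMNS",
    "GeneratorConfig",
    "generate_seasonal",
    "generate_spatial",
    "true_response",
    "calibrate_moments",
    "SEASONAL_DEPTHS",
    "SEASONAL_LAT",
    "SEASONAL_LON",
]

COLUMNS = [
    "station",
    "date",
    "depth_m",
    "temperature_c",
    "salinity_psu",
    "day_length_h",
    "chl_a_ug_l",
    "hna_1e5_ml",
    "lna_1e5_ml",
    "prokaryotes_1e5_ml",
    "v1_1e6_ml",
    "v2_1e6_ml",
    "viruses_1e6_ml",
]

#: The five candidate model inputs.
COVARIATE_COLUMNS = [
    "chl_a_ug_l",
    "day_length_h",
    "depth_m",
    "salinity_psu",
    "temperature_c",
]

#: Population abundance columns (the four model outputs).
ABUNDANCE_COLUMNS = {
    "hna": "hna_1e5_ml",
    "lna": "lna_1e5_ml",
    "v1": "v1_1e6_ml",
    "v2": "v2_1e6_ml",
}

SEASONAL_DEPTHS = (3.0, 10.0, 20.0, 30.0, 50.0, 100.0, 150.0, 220.0)
SEASONAL_LAT = 70.05  # 70°03' N
SEASONAL_LON = -126.5  # 126°30' W
SEASONAL_START = _dt.date(2003, 11, 4)
SEASONAL_END = _dt.date(2004, 8, 6)
SPATIAL_START = _dt.date(2004, 7, 4)
SPATIAL_END = _dt.date(2004, 8, 10)

# Published summary moments (mean, SD) used as calibration targets.
SEASONAL_TARGETS = {
    "temperature_c": (-1.20, 0.69),
    "salinity_psu": (31.90, 1.63),
    "chl_a_ug_l": (0.08, 0.10),
    "hna_1e5_ml": (2.22, 1.62),
    "lna_1e5_ml": (2.05, 1.08),
    "v1_1e6_ml": (0.93, 0.81),
    "v2_1e6_ml": (5.26, 3.17),
}
SPATIAL_TARGETS = {
    "temperature_c": (1.04, 2.93),
    "salinity_psu": (28.78, 4.33),
    "chl_a_ug_l": (0.49, 0.60),
    "hna_1e5_ml": (6.84, 3.31),
    "lna_1e5_ml": (4.93, 2.44),
    "v1_1e6_ml": (1.86, 1.44),
    "v2_1e6_ml": (12.80, 5.75),
}

# Columns calibrated on the raw scale (may be negative) vs the log scale.
_AFFINE_COLS = ("temperature_c", "salinity_psu")


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic-data generator.

    Defaults are the published study conditions: moment targets equal the
    printed seasonal/spatial summary tables, the multiplicative abundance
    noise is lognormal with sigma 0.35 on the log scale, and the HNA
    temperature optimum sits at -0.8 °C.
    """

    seed: int = 0
    seasonal_targets: dict = field(default_factory=lambda: dict(SEASONAL_TARGETS))
    spatial_targets: dict = field(default_factory=lambda: dict(SPATIAL_TARGETS))
    noise_sd_log: float = 0.35
    #: Temperature (°C) of the HNA abundance maximum.
    hna_temp_optimum: float = -0.8
    #: Width (°C) of the HNA temperature response.
    hna_temp_width: float = 1.4
    #: e-folding depth (m) of the viral decline.
    v1_depth_scale: float = 70.0
    v2_depth_scale: float = 90.0
    #: Productivity-coupling strength per population: the response scales
    #: as exp(g * tanh(log(chl/0.15)/1.5)), i.e. a bounded multiplicative
    #: factor in [e^-g, e^g] increasing with Chl-a.
    chl_coupling: dict = field(
        default_factory=lambda: {"hna": 1.7, "lna": 0.7, "v1": 0.8, "v2": 0.8}
    )


# ---------------------------------------------------------------------------
# Response surfaces


def true_response(
    covariates: pd.DataFrame | dict, population: str, cfg: GeneratorConfig | None = None
) -> np.ndarray:
    """Noise-free expected abundance of a population (arbitrary units).

    ``covariates`` must provide ``temperature_c``, ``depth_m``,
    ``chl_a_ug_l`` and ``day_length_h``.  The returned surface is smooth,
    strictly positive and deterministic; absolute units are irrelevant
    because generated abundances are moment-calibrated afterwards.
    """
    cfg = cfg or GeneratorConfig()
    if population not in ABUNDANCE_COLUMNS:
        raise ValueError(f"unknown population {population!r}")
    t = np.asarray(covariates["temperature_c"], dtype=float)
    z = np.asarray(covariates["depth_m"], dtype=float)
    chl = np.asarray(covariates["chl_a_ug_l"], dtype=float)
    dl = np.asarray(covariates["day_length_h"], dtype=float)
    # Productivity factor: increasing and saturating in Chl-a (the
    # chlorophyll-to-DOM supply link levels off at bloom concentrations).
    prod = np.exp(cfg.chl_coupling[population] * np.tanh(np.log(chl / 0.15) / 1.5))
    if population == "hna":
        peak = np.exp(-(((t - cfg.hna_temp_optimum) / cfg.hna_temp_width) ** 2))
        return (0.35 + peak) * prod
    if population == "lna":
        # strictly increasing, saturating temperature response
        return np.exp(0.9 * np.tanh(t / 2.0)) * prod
    if population == "v1":
        return np.exp(-z / cfg.v1_depth_scale) * prod * (0.45 + 0.55 * dl / 24.0)
    # v2: strict depth decline, productivity coupling, mild day-length effect
    return np.exp(-z / cfg.v2_depth_scale) * prod * (0.75 + 0.25 * dl / 24.0)


# ---------------------------------------------------------------------------
# Moment calibration


def _affine_calibrate(x: np.ndarray, mean: float, sd: float) -> np.ndarray:
    s = x.std(ddof=1)
    if s == 0:
        if sd != 0:
            raise ValueError("constant column cannot be calibrated to nonzero SD")
        return np.full_like(x, mean)
    return mean + (x - x.mean()) * (sd / s)


def _power_link(x: np.ndarray, mean: float, sd: float) -> tuple[float, float]:
    """Parameters (b, C) of the rank-preserving map x -> C * x**b that
    hits the raw-scale mean and SD on this sample.

    An affine map log C + b*log(x) on the log scale; the exponent b sets
    the coefficient of variation (monotone in b) and the scale C sets
    the mean.
    """
    if np.any(x <= 0):
        raise ValueError("power calibration requires strictly positive values")
    if x.std(ddof=1) == 0:
        raise ValueError("constant column cannot be calibrated to nonzero SD")
    target_cv = sd / mean
    logx = np.log(x)
    m = logx.mean()
    logc = logx - m  # centring only changes C, improves conditioning

    def cv_gap(b: float) -> float:
        y = np.exp(b * logc)
        return y.std(ddof=1) / y.mean() - target_cv

    b = brentq(cv_gap, 1e-6, 60.0, xtol=1e-14, rtol=1e-15)
    y = np.exp(b * logc)
    scale = mean / y.mean()
    return b, scale * np.exp(-b * m)


def _power_calibrate(x: np.ndarray, mean: float, sd: float) -> np.ndarray:
    """Rank-preserving power-law map of ``x`` to target mean and SD."""
    if x.std(ddof=1) == 0:
        if sd != 0:
            raise ValueError("constant column cannot be calibrated to nonzero SD")
        return np.full_like(x, mean)
    b, c = _power_link(x, mean, sd)
    return c * x**b


def calibrate_moments(table: pd.DataFrame, targets: dict) -> pd.DataFrame:
    """Calibrate columns to target (mean, SD), preserving ranks.

    Positive-scale columns are mapped through a power law (an affine map
    of their logarithms); temperature and salinity through a raw-scale
    affine map.  Sum columns (total prokaryotes, total viruses) are
    recomputed afterwards so additivity holds exactly.
    """
    out = table.copy()
    for col, (mean, sd) in targets.items():
        x = out[col].to_numpy(dtype=float)
        if col in _AFFINE_COLS:
            out[col] = _affine_calibrate(x, mean, sd)
        else:
            out[col] = _power_calibrate(x, mean, sd)
    _recompute_sums(out)
    return out


def _recompute_sums(table: pd.DataFrame) -> None:
    table["prokaryotes_1e5_ml"] = table["hna_1e5_ml"] + table["lna_1e5_ml"]
    table["viruses_1e6_ml"] = table["v1_1e6_ml"] + table["v2_1e6_ml"]


# ---------------------------------------------------------------------------
# Table generation


def _seasonal_dates() -> list[_dt.date]:
    start, end = SEASONAL_START.toordinal(), SEASONAL_END.toordinal()
    ords = np.linspace(start, end, 21).round().astype(int)
    return [_dt.date.fromordinal(int(o)) for o in ords]


def _season_index(dl_hours: np.ndarray) -> np.ndarray:
    """Dimensionless 0..1 summer index from day length."""
    return (np.asarray(dl_hours) / 24.0) ** 2


def _calibrate_covariates(table: pd.DataFrame, targets: dict) -> None:
    for col, (mean, sd) in targets.items():
        if col not in COVARIATE_COLUMNS:
            continue
        x = table[col].to_numpy(dtype=float)
        if col in _AFFINE_COLS:
            table[col] = _affine_calibrate(x, mean, sd)
        else:
            table[col] = _power_calibrate(x, mean, sd)


def generate_seasonal(cfg: GeneratorConfig | None = None) -> pd.DataFrame:
    """Generate the 156-row seasonal table (21 dates x 8 depths - 12 lost)."""
    table, _ = _generate_seasonal_with_links(cfg)
    return table


def _generate_seasonal_with_links(
    cfg: GeneratorConfig | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Seasonal table plus the per-population power-law link (b, C)
    that maps raw response-surface units to calibrated abundance units.

    The link defines the abundance scale of the synthetic world: the
    spatial survey reuses it, so both tables sample one response
    surface in consistent units.
    """
    cfg = cfg or GeneratorConfig()
    rng = np.random.default_rng(cfg.seed)
    dates = _seasonal_dates()
    dl_by_date = {
        d: day_length(GeoDate(d, SEASONAL_LAT, SEASONAL_LON)) for d in dates
    }
    rows = [(d, z) for d in dates for z in SEASONAL_DEPTHS]
    dropped = set(rng.choice(len(rows), size=12, replace=False).tolist())
    rows = [r for i, r in enumerate(rows) if i not in dropped]

    date_col = np.array([r[0] for r in rows])
    z = np.array([r[1] for r in rows])
    dl = np.array([dl_by_date[d] for d in date_col])
    s = _season_index(dl)
    # Winter mixed layer near -1.7 C; summer warming confined to the surface.
    temp = -1.7 + 4.5 * s * np.exp(-z / 15.0) + rng.normal(0, 0.08, z.size)
    # Fresh surface layer in summer (river influence), saltier at depth.
    sal = 33.0 + 0.004 * z - 3.5 * s * np.exp(-z / 10.0) + rng.normal(0, 0.25, z.size)
    # Summer near-surface bloom on a lognormal background.
    chl = np.exp(
        -2.8 + 1.8 * s * np.exp(-z / 30.0) + rng.normal(0, 0.5, z.size)
    )
    table = pd.DataFrame(
        {
            "station": "FB",
            "date": date_col,
            "depth_m": z,
            "temperature_c": temp,
            "salinity_psu": sal,
            "day_length_h": dl,
            "chl_a_ug_l": chl,
        }
    )
    _calibrate_covariates(table, cfg.seasonal_targets)
    links = {}
    for pop, col in ABUNDANCE_COLUMNS.items():
        mu = true_response(table, pop, cfg)
        noisy = mu * np.exp(rng.normal(0.0, cfg.noise_sd_log, size=len(table)))
        mean, sd = cfg.seasonal_targets[col]
        b, c = _power_link(noisy, mean, sd)
        links[pop] = (b, c)
        table[col] = c * noisy**b
    _recompute_sums(table)
    table.attrs["kind"] = "seasonal"
    return table.reset_index(drop=True), links


def generate_spatial(cfg: GeneratorConfig | None = None) -> pd.DataFrame:
    """Generate the 37-row summer spatial survey table (depths <= 80 m)."""
    cfg = cfg or GeneratorConfig()
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    n_stations = 7
    lats = rng.uniform(69.5, 71.5, n_stations)
    lons = rng.uniform(-138.6, -122.3, n_stations)
    start, end = SPATIAL_START.toordinal(), SPATIAL_END.toordinal()
    date_ords = np.sort(rng.integers(start, end + 1, n_stations))
    # 37 samples over 7 casts: 5 or 6 depths per station.
    per_station = np.array([6, 5, 5, 6, 5, 5, 5])
    depth_pool = np.array([1.0, 5.0, 10.0, 15.0, 20.0, 30.0, 40.0, 55.0, 78.0])
    records = []
    for i in range(n_stations):
        zs = np.sort(rng.choice(depth_pool, size=per_station[i], replace=False))
        d = _dt.date.fromordinal(int(date_ords[i]))
        dl = day_length(GeoDate(d, float(lats[i]), float(lons[i])))
        for z in zs:
            records.append((f"S{i + 1}", d, float(z), dl))
    z = np.array([r[2] for r in records])
    dl = np.array([r[3] for r in records])
    # Strong summer stratification: warm fresh productive surface layer.
    temp = -1.0 + 9.5 * np.exp(-z / 12.0) + rng.normal(0, 0.4, z.size)
    sal = 31.5 - 14.0 * np.exp(-z / 8.0) + rng.normal(0, 0.6, z.size)
    chl = np.exp(-1.2 + 1.3 * np.exp(-z / 25.0) + rng.normal(0, 0.55, z.size))
    table = pd.DataFrame(
        {
            "station": [r[0] for r in records],
            "date": [r[1] for r in records],
            "depth_m": z,
            "temperature_c": temp,
            "salinity_psu": sal,
            "day_length_h": dl,
            "chl_a_ug_l": chl,
        }
    )
    _calibrate_covariates(table, cfg.spatial_targets)
    # Abundances reuse the seasonal power-law link so that both tables
    # sample the same response surface in consistent units; only a
    # per-population scale is applied to hit the published spatial means.
    _, links = _generate_seasonal_with_links(cfg)
    for pop, col in ABUNDANCE_COLUMNS.items():
        mu = true_response(table, pop, cfg)
        noisy = mu * np.exp(rng.normal(0.0, cfg.noise_sd_log, size=len(table)))
        b, c = links[pop]
        ab = c * noisy**b
        table[col] = ab * (cfg.spatial_targets[col][0] / ab.mean())
    _recompute_sums(table)
    table.attrs["kind"] = "spatial"
    return table.reset_index(drop=True)
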