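"""Synthetic field data with controlled ground truth.

Everything the analysis pipeline would read from the field — tag temperature
records, survey weight-at-age, lipid/energy-density samples and the lake's
"warmest available" surface temperatures — can be generated here as a pure
function of (parameters, seed), so every pipeline stage is testable offline.

The two shipped profiles emulate the qualitative occupancy contrast of a
large dimictic temperate lake: a lake-trout-like fish sits below its 10 degC optimum most of
the year with a warm excursion to the shallows around fall spawning, while a
Chinook-like fish tracks temperatures near its 14.3 degC optimum with warmer
summer/fall excursions and a cooler spring.  Profile constants are
illustrative, not fitted to any archived dataset.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .compare import WeightAtAge
from .energy_density import BRODY_KJ_PER_G_LIPID, EnergyDensityModel, default_models
from .errors import DomainError
from .scenarios import TagTemperatureSet, day_of_year

__all__ = [
    "SynthProfile",
    "lake_trout_profile",
    "chinook_profile",
    "seasonal_temperature",
    "offset_at",
    "synth_tags",
    "synth_surface_daily",
    "synth_weight_at_age",
    "synth_lipid_weight",
    "LAKE_TROUT_GROWTH",
    "CHINOOK_GROWTH",
    "DEFAULT_SURFACE_POINTS",
]

#: von-Bertalanffy cube constants (asymptote g, rate 1/yr, t0 yr) solved so
#: the curve passes exactly through the survey anchors: lake trout 142 g at
#: age 1, 6573 g at 13, 6980 g at 14; Chinook 200 g at age 0, 9742 g at 3,
#: 10387 g at 4.
LAKE_TROUT_GROWTH = (9919.35337, 0.14801469, -0.879153786)
CHINOOK_GROWTH = (10750.4323, 1.0416132, -0.29554908)

#: Annual cycle of the warmest available (surface) habitat temperature, as
#: (day-of-year, degC) control points.  Deep temperate lakes warm late and
#: cool late, so the cycle is asymmetric: a long cold spring, an August peak
#: and a slow autumn decline — a sinusoid would overstate spring warmth.
DEFAULT_SURFACE_POINTS = (
    (15, 2.0),
    (46, 1.5),
    (74, 2.0),
    (105, 4.0),
    (135, 8.0),
    (166, 13.0),
    (196, 19.0),
    (227, 23.0),
    (258, 20.0),
    (288, 15.0),
    (319, 10.0),
    (349, 5.5),
)


def seasonal_temperature(doy, mean: float, amplitude: float, phase_day: float):
    """Sinusoidal annual cycle peaking at ``phase_day``."""
    doy = np.asarray(doy, dtype=float)
    return mean + amplitude * np.cos(2.0 * math.pi * (doy - phase_day) / 365.0)


def offset_at(points: tuple[tuple[float, float], ...], doy) -> np.ndarray:
    """Piecewise-linear seasonal offset through (day-of-year, degC) control
    points, wrapped circularly over the 365-day year."""
    pts = sorted(points)
    xs = np.array([p[0] for p in pts], dtype=float)
    ys = np.array([p[1] for p in pts], dtype=float)
    # wrap: repeat first point at +365 and last at -365 for circular interp
    xs_ext = np.concatenate([[xs[-1] - 365.0], xs, [xs[0] + 365.0]])
    ys_ext = np.concatenate([[ys[-1]], ys, [ys[0]]])
    return np.interp(np.asarray(doy, dtype=float), xs_ext, ys_ext)


@dataclass(frozen=True)
class SynthProfile:
    """Generator settings for one species' synthetic tag temperatures."""

    species: str
    mean_temp: float          # degC, annual mean of the occupied base cycle
    amplitude: float          # degC
    phase_day: float          # day-of-year of the seasonal peak
    offset_points: tuple[tuple[float, float], ...]  # behavioural occupancy offsets
    noise_sd: float = 1.0     # stationary sd of the AR(1) noise, degC
    individual_sd: float = 0.5  # sd of the per-fish random intercept, degC
    ar1: float = 0.8          # day-to-day autocorrelation of the noise
    n_individuals: int = 15
    date_start: dt.date = dt.date(2014, 1, 1)
    date_end: dt.date = dt.date(2019, 12, 31)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise DomainError("amplitude must be non-negative")
        if self.noise_sd < 0 or self.individual_sd < 0:
            raise DomainError("noise standard deviations must be non-negative")
        if not -1.0 < self.ar1 < 1.0:
            raise DomainError("ar1 coefficient must lie in (-1, 1)")
        if self.date_end < self.date_start:
            raise DomainError("date_end precedes date_start")


def lake_trout_profile(seed: int = 0, **overrides) -> SynthProfile:
    """Cold-biased occupancy with a fall spawning excursion to the shallows."""
    prof = SynthProfile(
        species="lake trout",
        mean_temp=4.6,
        amplitude=2.4,
        phase_day=235,
        offset_points=(
            (1, 0.0),
            (244, 0.0),
            (274, 3.0),
            (300, 4.2),
            (325, 1.5),
            (345, 0.0),
        ),
        seed=seed,
    )
    return replace(prof, **overrides) if overrides else prof


def chinook_profile(seed: int = 0, **overrides) -> SynthProfile:
    """Near-optimum occupancy with warm summer/fall excursions, cooler spring."""
    prof = SynthProfile(
        species="chinook salmon",
        mean_temp=9.5,
        amplitude=6.0,
        phase_day=220,
        offset_points=(
            # warmer-than-surface winter (fish hold deep water while the
            # satellite surface reads ~2 degC), slightly cooler spring, a
            # brief summer peak just above the optimum, and a fall that stays
            # near the optimum while the available surface water cools
            (1, 1.8),
            (60, 1.8),
            (100, -0.5),
            (140, -0.5),
            (170, 0.3),
            (210, 1.0),
            (250, 1.0),
            (280, 2.0),
            (320, 3.0),
            (345, 2.5),
        ),
        seed=seed,
    )
    return replace(prof, **overrides) if overrides else prof


def synth_tags(profile: SynthProfile) -> TagTemperatureSet:
    """Simulate daily tag temperatures for every individual in the profile.

    Per individual: seasonal sinusoid + behavioural occupancy offset +
    individual random intercept + AR(1) noise, truncated to [0, 30] degC.
    Reproducible: the record set is a pure function of the profile.
    """
    if profile.n_individuals < 1:
        raise DomainError("profile must include at least one individual")
    rng = np.random.default_rng(profile.seed)
    dates = pd.date_range(profile.date_start, profile.date_end, freq="D")
    doys = np.array(
        [day_of_year(d.date()) or 0 for d in dates], dtype=float
    )
    keep = doys > 0  # drop Feb 29
    dates = dates[keep]
    doys = doys[keep]
    n_days = doys.size

    base = seasonal_temperature(
        doys, profile.mean_temp, profile.amplitude, profile.phase_day
    ) + offset_at(profile.offset_points, doys)

    frames = []
    # innovation sd chosen so the AR(1) process has stationary sd = noise_sd
    innov_sd = profile.noise_sd * math.sqrt(1.0 - profile.ar1 ** 2)
    for i in range(profile.n_individuals):
        b_i = rng.normal(0.0, profile.individual_sd)
        eps = np.empty(n_days)
        eps[0] = rng.normal(0.0, profile.noise_sd)
        shocks = rng.normal(0.0, innov_sd, size=n_days)
        for t in range(1, n_days):
            eps[t] = profile.ar1 * eps[t - 1] + shocks[t]
        temps = np.clip(base + b_i + eps, 0.0, 30.0)
        frames.append(
            pd.DataFrame(
                {
                    "individual_id": f"{profile.species.replace(' ', '_')}_{i:03d}",
                    "date": dates,
                    "temp_C": temps,
                }
            )
        )
    records = pd.concat(frames, ignore_index=True)
    return TagTemperatureSet(records=records, species=profile.species)


def synth_surface_daily(
    points: tuple[tuple[float, float], ...] = DEFAULT_SURFACE_POINTS,
) -> pd.Series:
    """Deterministic 365-day cycle of the warmest available (surface)
    temperature, indexed by day-of-year: circular piecewise-linear
    interpolation of the climatology control points."""
    doys = np.arange(1, 366)
    return pd.Series(offset_at(points, doys), index=doys, name="temp_C")


def synth_weight_at_age(
    growth: tuple[float, float, float],
    ages,
    noise_sd: float = 0.0,
    seed: int | None = None,
    anchor_first: float | None = None,
) -> WeightAtAge:
    """Survey-like weight-at-age from a von-Bertalanffy cube curve.

    W(a) = Winf * (1 - exp(-k (a - t0)))^3, plus optional Gaussian noise;
    monotonicity is restored by an isotonic (running-max) pass.
    ``anchor_first`` pins the first age's weight exactly (e.g. the known
    stocking weight).
    """
    winf, k, t0 = growth
    if winf <= 0:
        raise DomainError("asymptotic weight must be positive")
    ages = tuple(int(a) for a in ages)
    a = np.asarray(ages, dtype=float)
    w = winf * (1.0 - np.exp(-k * (a - t0))) ** 3
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        w = w + rng.normal(0.0, noise_sd, size=w.size)
    if anchor_first is not None:
        w[0] = anchor_first
    w = np.maximum.accumulate(np.maximum(w, 1.0))
    return WeightAtAge(ages=ages, weights=tuple(float(x) for x in w))


def synth_lipid_weight(
    model: EnergyDensityModel | None = None,
    n: int = 1000,
    noise_sd: float = 1.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Synthetic lipid/energy-density samples from a known ED model.

    Weights are log-uniform over the model's declared valid range; the ED
    value is the model prediction plus Gaussian noise, and the matching
    whole-body lipid concentration (mg/g) back-computes through the 39.5
    kJ/g lipid-energy constant.  Columns: weight_g, lipid_mg_g, source,
    ed_kJ_g.
    """
    if n < 10:
        raise DomainError("need n >= 10 samples")
    if model is None:
        model = default_models()["lake_trout"]
    lo, hi = model.valid_range if model.valid_range else (100.0, 10000.0)
    lo = max(lo, 1.0)
    rng = np.random.default_rng(seed)
    w = np.exp(rng.uniform(math.log(lo), math.log(hi), size=n))
    ed = np.array([model.energy_density(x) for x in w])
    if noise_sd > 0:
        ed = ed + rng.normal(0.0, noise_sd, size=n)
    ed = np.maximum(ed, 0.05)
    lipid_mg_g = ed / BRODY_KJ_PER_G_LIPID * 1000.0
    return pd.DataFrame(
        {
            "weight_g": w,
            "lipid_mg_g": lipid_mg_g,
            "source": "whole-body",
            "ed_kJ_g": ed,
        }
    )
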