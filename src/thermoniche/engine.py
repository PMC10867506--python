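"""Daily mass-balance Wisconsin bioenergetics engine.

Growth each day is the energy left after subtracting egestion, excretion,
respiration and the cost of digestion (SDA) from the energy consumed:

    dE = EC - EF - EU - ER - ES          (J per g predator per day)

Consumption is a fraction ``p`` (the feeding rate) of the allometric maximum
Cmax = CA * W^CB, modulated by a temperature-dependence factor f(T).  Net
energy is converted to weight through the predator's energy-density model:
tomorrow's weight satisfies E(W_{t+1}) = E(W_t) + dE * W_t.

All specific rates are per gram of predator per day; energies are J, weights
g, temperatures deg C.  The functional forms follow the Fish Bioenergetics
4.0 conventions; every constant comes in through :class:`SpeciesParams` and
is treated strictly as data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .energy_density import EnergyDensityModel
from .errors import ConfigurationError, DomainError, NumericalRangeError, SimulationError
from .params import DietSchedule, SpeciesParams

__all__ = [
    "consumption_ft",
    "thornton_lessem_factors",
    "max_consumption",
    "realized_consumption",
    "respiration",
    "waste",
    "step_day",
    "simulate",
    "DailyBudget",
    "AgeSummary",
    "SimulationTrajectory",
]


# ---------------------------------------------------------------------------
# Temperature dependence of consumption

def _dome_factor(T: float, Q: float, TO: float, TM: float) -> float:
    """Kitchell dome: 1 at TO, 0 at TM, clamped to 0 above TM."""
    if T >= TM:
        return 0.0
    V = (TM - T) / (TM - TO)
    Z = math.log(Q) * (TM - TO)
    Y = math.log(Q) * (TM - TO + 2.0)
    X = (Z * Z * (1.0 + math.sqrt(1.0 + 40.0 / Y)) ** 2) / 400.0
    return (V ** X) * math.exp(X * (1.0 - V))


def thornton_lessem_factors(T: float, c) -> tuple[float, float]:
    """Ascending (KA) and descending (KB) sigmoids of the CEQ=3 form.

    By construction KA(CTO) = 0.98 and KB(CTM) = 0.98 for any valid CK1,
    CK4.  Exposed separately so the fixed points are testable.
    """
    G1 = (1.0 / (c.CTO - c.CQ)) * math.log(0.98 * (1.0 - c.CK1) / (0.02 * c.CK1))
    L1 = math.exp(G1 * (T - c.CQ))
    KA = c.CK1 * L1 / (1.0 + c.CK1 * (L1 - 1.0))
    G2 = (1.0 / (c.CTL - c.CTM)) * math.log(0.98 * (1.0 - c.CK4) / (0.02 * c.CK4))
    L2 = math.exp(G2 * (c.CTL - T))
    KB = c.CK4 * L2 / (1.0 + c.CK4 * (L2 - 1.0))
    return KA, KB


def consumption_ft(T: float, params: SpeciesParams) -> float:
    """Temperature-dependence factor f(T) of maximum consumption."""
    c = params.consumption
    if c.CEQ == 1:
        return math.exp(c.CQ * T)
    if c.CEQ == 2:
        return _dome_factor(T, c.CQ, c.CTO, c.CTM)
    if c.CEQ == 3:
        KA, KB = thornton_lessem_factors(T, c)
        return KA * KB
    raise ConfigurationError(f"invalid consumption form selector CEQ={c.CEQ}")


def max_consumption(W: float, params: SpeciesParams) -> float:
    """Maximum specific consumption Cmax = CA * W^CB (g prey / g / d)."""
    if W <= 0:
        raise DomainError(f"weight must be positive, got {W}")
    c = params.consumption
    return c.CA * W ** c.CB


def realized_consumption(W: float, T: float, p: float, params: SpeciesParams) -> float:
    """Realized consumption C = Cmax(W) * p * f(T) (g prey / g / d)."""
    if p < 0:
        raise DomainError(f"feeding rate p must be non-negative, got {p}")
    return max_consumption(W, params) * p * consumption_ft(T, params)


# ---------------------------------------------------------------------------
# Waste and respiration

def waste(
    C: float, T: float, p: float, diet: DietSchedule, params: SpeciesParams
) -> tuple[float, float]:
    """Egestion and excretion energy losses (EF, EU), J / g / d.

    FEQ=1: F = FA*C.  FEQ=2: F = FA * T^FB * e^(FG*p) * C.  FEQ=3 corrects
    the Elliott proportion for the indigestible fraction of the ration.
    Excretion acts on assimilated ration C - F.
    """
    if C < 0:
        raise DomainError(f"consumption must be non-negative, got {C}")
    w = params.waste
    ed_prey = diet.mean_energy_density
    if C == 0.0:
        return 0.0, 0.0
    if w.FEQ == 1:
        F = w.FA * C
    elif w.FEQ == 2:
        F = w.FA * T ** w.FB * math.exp(w.FG * p) * C
    elif w.FEQ == 3:
        PE = w.FA * T ** w.FB * math.exp(w.FG * p)
        PFF = diet.mean_indigestible
        PEstar = ((PE - 0.1) / 0.9) * (1.0 - PFF) + PFF
        if not 0.0 <= PEstar <= 1.0:
            raise NumericalRangeError(
                f"egestion proportion PE*={PEstar:.4f} outside [0, 1] "
                f"(T={T:.3g} degC, p={p:.3g}, PE={PE:.4f}, PFF={PFF:.4f})"
            )
        F = PEstar * C
    else:
        raise ConfigurationError(f"invalid egestion form selector FEQ={w.FEQ}")

    if w.UEQ == 1:
        U = w.UA * (C - F)
    elif w.UEQ in (2, 3):
        U = w.UA * T ** w.UB * math.exp(w.UG * p) * (C - F)
    else:
        raise ConfigurationError(f"invalid excretion form selector UEQ={w.UEQ}")
    return F * ed_prey, U * ed_prey


def respiration(
    W: float,
    T: float,
    p: float,
    C: float,
    diet: DietSchedule,
    params: SpeciesParams,
) -> tuple[float, float]:
    """Respiration and SDA energy costs (ER, ES), J / g / d.

    REQ=1: exponential temperature dependence with a swimming-speed activity
    multiplier (speed follows ACT * W^RK4 * e^(BACT*T) up to the cutoff RTL,
    RK1 * W^RK4 above it).  REQ=2: Kitchell dome with constant activity.
    SDA is a fixed fraction of assimilated energy, SDA * (EC - EF).
    """
    if W <= 0:
        raise DomainError(f"weight must be positive, got {W}")
    if C < 0:
        raise DomainError(f"consumption must be non-negative, got {C}")
    r = params.respiration
    if r.REQ == 1:
        fR = math.exp(r.RQ * T)
        if T > r.RTL:
            VEL = r.RK1 * W ** r.RK4
        else:
            VEL = r.ACT * W ** r.RK4 * math.exp(r.BACT * T)
        activity = math.exp(r.RTO * VEL)
    elif r.REQ == 2:
        fR = _dome_factor(T, r.RQ, r.RTO, r.RTM)
        activity = r.ACT
    else:
        raise ConfigurationError(f"invalid respiration form selector REQ={r.REQ}")
    ER = r.RA * W ** r.RB * fR * activity * params.oxycal

    EC = C * diet.mean_energy_density
    EF, _ = waste(C, T, p, diet, params)
    ES = r.SDA * (EC - EF)
    return ER, ES


# ---------------------------------------------------------------------------
# Daily step and multi-year simulation

@dataclass(frozen=True)
class DailyBudget:
    """One day's energy budget, all energy terms in J / g predator / d."""

    day: int
    temperature: float
    weight: float
    p: float
    C: float   # g prey / g predator / d
    EC: float
    EF: float
    EU: float
    ER: float
    ES: float
    dE: float


def step_day(
    weight: float,
    T: float,
    p: float,
    diet: DietSchedule,
    ed_model: EnergyDensityModel,
    params: SpeciesParams,
    day: int = 1,
) -> tuple[DailyBudget, float]:
    """Advance one day; returns the budget and the next weight (g)."""
    C = realized_consumption(weight, T, p, params)
    EC = C * diet.mean_energy_density
    EF, EU = waste(C, T, p, diet, params)
    ER, ES = respiration(weight, T, p, C, diet, params)
    dE = EC - EF - EU - ER - ES
    E_t = ed_model.body_energy(weight)
    E_next = E_t + dE * weight
    if E_next <= 0:
        raise SimulationError(
            f"body energy collapsed to {E_next:.4g} J on day {day} "
            f"(W={weight:.4g} g, T={T:.3g} degC, p={p:.3g})"
        )
    next_weight = ed_model.weight_from_energy(E_next)
    budget = DailyBudget(day, T, weight, p, C, EC, EF, EU, ER, ES, dE)
    return budget, next_weight


@dataclass(frozen=True)
class AgeSummary:
    age: int
    start_weight: float
    end_weight: float
    mean_p: float
    annual_consumption_g: float


@dataclass
class SimulationTrajectory:
    """Daily records of a multi-year run; the unit of scenario comparison.

    ``weights`` holds the start-of-day weight for each simulated day plus the
    final weight as a trailing element (length n_days + 1).
    """

    days: np.ndarray
    ages: np.ndarray
    temps: np.ndarray
    p: np.ndarray
    weights: np.ndarray          # length n_days + 1
    energy: np.ndarray           # body energy J, carried state; length n_days + 1
    C: np.ndarray                # g/g/d
    EC: np.ndarray
    EF: np.ndarray
    EU: np.ndarray
    ER: np.ndarray
    ES: np.ndarray
    dE: np.ndarray
    prey_consumption_g: dict[str, float] = field(default_factory=dict)
    age_summaries: list[AgeSummary] = field(default_factory=list)

    @property
    def n_days(self) -> int:
        return int(self.days.size)

    @property
    def final_weight(self) -> float:
        return float(self.weights[-1])

    @property
    def daily_consumption_g(self) -> np.ndarray:
        """Grams of prey eaten per day, C * W."""
        return self.C * self.weights[:-1]

    @property
    def total_consumption_g(self) -> float:
        return float(self.daily_consumption_g.sum())

    @property
    def total_consumption_kg(self) -> float:
        return self.total_consumption_g / 1000.0

    def annual_consumption_g(self) -> np.ndarray:
        """Total grams of prey per simulated year."""
        n_years = self.n_days // 365
        return self.daily_consumption_g.reshape(n_years, 365).sum(axis=1)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "day": self.days,
                "age": self.ages,
                "temp_C": self.temps,
                "weight_g": self.weights[:-1],
                "p": self.p,
                "C_ggd": self.C,
                "EC": self.EC,
                "EF": self.EF,
                "EU": self.EU,
                "ER": self.ER,
                "ES": self.ES,
                "dE": self.dE,
            }
        )


def simulate(
    start_weight: float,
    daily_temps: np.ndarray,
    p_schedule,
    diet: DietSchedule,
    ed_model: EnergyDensityModel,
    params: SpeciesParams,
    start_age: int | None = None,
) -> SimulationTrajectory:
    """Simulate ``len(p_schedule)`` years of daily growth.

    ``daily_temps`` is the 365-value annual cycle, repeated every simulated
    year (the scenario is presumed steady across the lifetime).
    ``p_schedule`` gives one constant feeding rate per age-year.

    Body energy is the carried state: E_{t+1} = E_t + dE * W_t, with weight
    derived from energy each day.  Carrying energy (rather than recomputing
    it from weight) keeps the daily energy balance exact even where the
    piecewise ED model is slightly discontinuous at its breakpoint.
    """
    temps = np.asarray(daily_temps, dtype=float)
    if temps.shape != (365,):
        raise DomainError(f"daily_temps must have length 365, got {temps.shape}")
    p_schedule = np.asarray(p_schedule, dtype=float)
    n_years = p_schedule.size
    if n_years == 0:
        raise DomainError("p_schedule must contain at least one year")
    if start_age is None:
        start_age = params.age_span[0]

    n = 365 * n_years
    out = {
        k: np.empty(n)
        for k in ("temps", "p", "C", "EC", "EF", "EU", "ER", "ES", "dE")
    }
    weights = np.empty(n + 1)
    energy = np.empty(n + 1)
    days = np.arange(1, n + 1)
    ages = np.repeat(np.arange(start_age, start_age + n_years), 365)

    w = float(start_weight)
    E = ed_model.body_energy(w)
    summaries: list[AgeSummary] = []
    i = 0
    for yr in range(n_years):
        p = float(p_schedule[yr])
        w_year_start = w
        for d in range(365):
            T = float(temps[d])
            C = realized_consumption(w, T, p, params)
            EC = C * diet.mean_energy_density
            EF, EU = waste(C, T, p, diet, params)
            ER, ES = respiration(w, T, p, C, diet, params)
            dE = EC - EF - EU - ER - ES
            E_next = E + dE * w
            if E_next <= 0:
                raise SimulationError(
                    f"body energy collapsed to {E_next:.4g} J on day {i + 1} "
                    f"(W={w:.4g} g, T={T:.3g} degC, p={p:.3g})"
                )
            weights[i] = w
            energy[i] = E
            out["temps"][i] = T
            out["p"][i] = p
            out["C"][i] = C
            out["EC"][i] = EC
            out["EF"][i] = EF
            out["EU"][i] = EU
            out["ER"][i] = ER
            out["ES"][i] = ES
            out["dE"][i] = dE
            w = ed_model.weight_from_energy(E_next)
            E = E_next
            i += 1
        annual_g = float(
            (out["C"][i - 365 : i] * weights[i - 365 : i]).sum()
        )
        summaries.append(
            AgeSummary(start_age + yr, w_year_start, w, p, annual_g)
        )
    weights[n] = w
    energy[n] = E

    traj = SimulationTrajectory(
        days=days,
        ages=ages,
        temps=out["temps"],
        p=out["p"],
        weights=weights,
        energy=energy,
        C=out["C"],
        EC=out["EC"],
        EF=out["EF"],
        EU=out["EU"],
        ER=out["ER"],
        ES=out["ES"],
        dE=out["dE"],
        age_summaries=summaries,
    )
    total = traj.total_consumption_g
    traj.prey_consumption_g = {
        item.prey: total * item.proportion for item in diet.items
    }
    return traj
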