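"""Scenario drivers: stiff integration of the pool ODEs, laboratory
incubation with a substrate pulse, steady-state spin-up, and multi-decade
warming projections.

Time is measured in hours throughout; schedules quoted in days are converted
at 24 h per day.  Incubations are closed systems (no external carbon input);
spin-up and projection use a constant input equal to a fixed fraction of the
soil's carbon content per year.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .mend_core import (
    Environment,
    FixedParams,
    MicrobialParams,
    N_STATE,
    POOL_NAMES,
    PoolState,
    ScaledParams,
    _rhs_array,
    scale_params,
)

HOURS_PER_DAY = 24.0
HOURS_PER_YEAR = 365.0 * 24.0

#: initial enzyme pools, mg C cm^-3 soil
EP1_INIT = 1.1e-3
EP2_INIT = 1.1e-3
EM_INIT = 1.4e-3

#: incubation temperature, degC
INCUBATION_T = 22.0

#: substrate pulse as a fraction of total soil carbon
PULSE_FRACTION = 0.01


@dataclass(frozen=True)
class Schedule:
    """Collection times (hours) for CO2 and MBC measurements."""

    name: str
    co2_hours: tuple
    mbc_hours: tuple
    substrate: str = "none"

    @property
    def duration_hours(self) -> float:
        return max(max(self.co2_hours), max(self.mbc_hours))


#: short-term glucose incubation: 7 CO2 and 3 MBC collections over 6 days
ST_G = Schedule(
    name="ST_G",
    co2_hours=(2.0, 4.0, 8.0, 24.0, 48.0, 72.0, 144.0),
    mbc_hours=(24.0, 72.0, 144.0),
    substrate="glucose",
)

_LT_C_CO2_DAYS = (1, 2, 4, 6, 11, 20, 39, 64, 90, 120, 151, 229, 323, 390,
                  480, 571, 665, 729)
_LT_C_MBC_DAYS = (1, 4, 20, 64, 151, 323, 480, 729)

#: long-term cellulose incubation: 18 CO2 and 8 MBC collections over 729 days
LT_C = Schedule(
    name="LT_C",
    co2_hours=tuple(d * HOURS_PER_DAY for d in _LT_C_CO2_DAYS),
    mbc_hours=tuple(d * HOURS_PER_DAY for d in _LT_C_MBC_DAYS),
    substrate="cellulose",
)

SCHEDULES = {"ST_G": ST_G, "LT_C": LT_C}


class IntegrationError(RuntimeError):
    """Raised when the stiff solver fails; carries the last good time."""

    def __init__(self, message: str, last_time: float):
        super().__init__(f"{message} (last good time: {last_time} h)")
        self.last_time = last_time


@dataclass
class Trajectory:
    """Solution of the pool ODEs on a time grid (hours)."""

    times: np.ndarray            # (n,)
    states: np.ndarray           # (n, 11) in POOL_NAMES order

    def pool(self, name: str) -> np.ndarray:
        return self.states[:, POOL_NAMES.index(name)]

    def soc(self) -> np.ndarray:
        return self.states[:, :10].sum(axis=1)

    def mbc(self) -> np.ndarray:
        return self.pool("BA") + self.pool("BD")

    def co2_rates(self) -> np.ndarray:
        """Mean CO2 efflux over each inter-collection interval (aligned with
        ``times[1:]``), matching headspace-accumulation measurements."""
        co2 = self.pool("CO2cum")
        return np.diff(co2) / np.diff(self.times)

    def final_state(self) -> PoolState:
        return PoolState.from_array(self.states[-1])


@dataclass(frozen=True)
class SoilInit:
    """Measured initial condition of one soil case.

    Pool masses in mg C cm^-3 soil; ``poc`` is split between the oxidative
    (P1) and hydrolytic (P2) particulate pools by ``p1_fraction``.
    """

    site: str
    ecosystem: str
    poc: float
    moc: float
    doc: float
    mbc: float
    bulk_density: float = 1.3   # g cm^-3, used only by unit-converting I/O
    p1_fraction: float = 1.0 / 3.0
    substrate: str = "none"

    def __post_init__(self) -> None:
        for name in ("poc", "moc", "doc", "mbc"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.p1_fraction <= 1.0:
            raise ValueError("p1_fraction must be in [0, 1]")

    @property
    def total_c(self) -> float:
        """Total measured soil carbon (POC + MOC + DOC + MBC)."""
        return self.poc + self.moc + self.doc + self.mbc

    @property
    def case_id(self) -> str:
        return f"{self.site}_{self.ecosystem}_{self.substrate}"

    def initial_state(self, r0: float) -> PoolState:
        """Initial pool vector: POC split P1/P2, the sorbed layer Q taken as
        the active 1% of MOC, biomass partitioned by the active fraction r0,
        reference enzyme levels."""
        return PoolState(
            P1=self.p1_fraction * self.poc,
            P2=(1.0 - self.p1_fraction) * self.poc,
            M=0.99 * self.moc,
            D=self.doc,
            Q=0.01 * self.moc,
            BA=r0 * self.mbc,
            BD=(1.0 - r0) * self.mbc,
            EP1=EP1_INIT, EP2=EP2_INIT, EM=EM_INIT,
            CO2cum=0.0,
        )


@dataclass
class ProjectionResult:
    """Outcome of a warming projection relative to its unwarmed baseline."""

    baseline_soc: float          # end-simulation SOC at Tref
    warmed_soc: float            # end-simulation SOC at Tref + dT
    relative_change: float       # percent
    times: np.ndarray            # hours
    relative_change_series: np.ndarray   # percent, per time point


# ---------------------------------------------------------------------------
# integration
# ---------------------------------------------------------------------------

def integrate(state0: PoolState, mp: MicrobialParams, fp: FixedParams,
              env: Environment, t_grid: np.ndarray,
              rtol: float = 1e-8, atol: float = 1e-11) -> Trajectory:
    """Integrate the pool ODEs on an increasing time grid (hours).

    Uses LSODA (adaptive, switches to BDF when stiff).  The global carbon
    balance |dSOC + dCO2 - integral of inputs| stays below 1e-6 relative at
    the default tolerances.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or len(t_grid) < 2 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be strictly increasing with >= 2 points")
    state0.validate()
    sp = scale_params(mp, fp, env.T)
    args = (sp, env.IP1, env.IP2, env.ID)

    def f(t, y, *a):
        return _rhs_array(y, *a)

    y0 = state0.as_array()
    sol = solve_ivp(f, (t_grid[0], t_grid[-1]), y0, method="LSODA",
                    t_eval=t_grid, args=args, rtol=rtol, atol=atol)
    if not sol.success:
        last = sol.t[-1] if len(sol.t) else t_grid[0]
        raise IntegrationError(f"ODE solver failed: {sol.message}", last)
    return Trajectory(times=sol.t, states=sol.y.T)


# ---------------------------------------------------------------------------
# laboratory incubation
# ---------------------------------------------------------------------------

@dataclass
class SimulatedIncubation:
    """Model observables on an incubation collection schedule."""

    co2_times: np.ndarray    # hours, collection times
    co2_rates: np.ndarray    # mean efflux over interval ending at each time
    mbc_times: np.ndarray    # hours
    mbc_values: np.ndarray   # BA + BD
    trajectory: Trajectory


def apply_substrate_pulse(state: PoolState, substrate: str,
                          total_c: float) -> PoolState:
    """Instantaneous substrate addition at t = 0: glucose enters the DOC
    pool, cellulose the hydrolysable particulate pool; 1% of total soil C."""
    pulse = PULSE_FRACTION * total_c
    if substrate == "none":
        return state
    if substrate == "glucose":
        return replace(state, D=state.D + pulse)
    if substrate == "cellulose":
        return replace(state, P2=state.P2 + pulse)
    raise ValueError(f"unknown substrate {substrate!r}; "
                     "expected none, glucose or cellulose")


def run_incubation(soil: SoilInit, mp: MicrobialParams, fp: FixedParams,
                   substrate: str, schedule: Schedule,
                   rtol: float = 1e-8, atol: float = 1e-11) -> SimulatedIncubation:
    """Simulate a closed dark incubation at 22 degC.

    The CO2 observable is the mean respiration rate over the interval ending
    at each collection (first interval starts at t = 0); MBC is instantaneous
    total biomass at its own collection times.
    """
    state0 = apply_substrate_pulse(soil.initial_state(mp.r0), substrate,
                                   soil.total_c)
    env = Environment(T=INCUBATION_T, IP1=0.0, IP2=0.0, ID=0.0)
    co2_t = np.asarray(schedule.co2_hours, dtype=float)
    mbc_t = np.asarray(schedule.mbc_hours, dtype=float)
    grid = np.unique(np.concatenate([[0.0], co2_t, mbc_t]))
    traj = integrate(state0, mp, fp, env, grid, rtol=rtol, atol=atol)

    co2_cum = traj.pool("CO2cum")
    cum_at = np.interp(co2_t, traj.times, co2_cum)
    prev = np.concatenate([[0.0], co2_t[:-1]])
    cum_prev = np.interp(prev, traj.times, co2_cum)
    rates = (cum_at - cum_prev) / (co2_t - prev)

    mbc_series = np.interp(mbc_t, traj.times, traj.mbc())
    return SimulatedIncubation(co2_times=co2_t, co2_rates=rates,
                               mbc_times=mbc_t, mbc_values=mbc_series,
                               trajectory=traj)


# ---------------------------------------------------------------------------
# spin-up and projection
# ---------------------------------------------------------------------------

class SpinUpError(RuntimeError):
    pass


@dataclass
class SpinUpResult:
    state: PoolState          # steady pools (CO2cum reset to zero)
    env: Environment          # forcing used (temperature and inputs)
    residual: float           # max relative |d pool/dt|, h^-1
    simulated_years: float


def make_input_env(T: float, soc: float, annual_input_frac: float = 0.05,
                   split: tuple = (0.4, 0.4, 0.2)) -> Environment:
    """Constant forcing with annual carbon input = ``annual_input_frac`` of
    ``soc``, partitioned into particulate (P1, P2) and dissolved inputs."""
    if not np.isclose(sum(split), 1.0):
        raise ValueError("input split fractions must sum to 1")
    total = annual_input_frac * soc / HOURS_PER_YEAR
    return Environment(T=T, IP1=split[0] * total, IP2=split[1] * total,
                       ID=split[2] * total)


def _relative_residual(y: np.ndarray, sp: ScaledParams,
                       env: Environment) -> float:
    dy = _rhs_array(y, sp, env.IP1, env.IP2, env.ID)[:10]
    scale = np.maximum(y[:10], 1e-12)
    return float(np.max(np.abs(dy) / scale))


def spin_up(soil: SoilInit, mp: MicrobialParams, fp: FixedParams,
            T: float = 20.0, annual_input_frac: float = 0.05,
            split: tuple = (0.4, 0.4, 0.2), tol: float = 1e-9,
            max_years: float = 2000.0) -> SpinUpResult:
    """Run the model to steady state under constant forcing.

    Integrates in multi-decade chunks; once transients have decayed the
    steady pools are polished with a damped Newton solve of rhs = 0, which
    is accepted only if non-negative and below the residual tolerance.
    Raises :class:`SpinUpError` with a residual report if ``max_years`` of
    simulated time do not reach ``tol``.
    """
    if annual_input_frac <= 0:
        raise ValueError("annual_input_frac must be > 0")
    env = make_input_env(T, soil.total_c, annual_input_frac, split)
    sp = scale_params(mp, fp, T)
    y = soil.initial_state(mp.r0).as_array()
    y[10] = 0.0

    chunk_years = 100.0
    years = 0.0
    while years < max_years:
        t_end = chunk_years * HOURS_PER_YEAR
        traj = integrate(PoolState.from_array(y), mp, fp, env,
                         np.array([0.0, t_end]), rtol=1e-8, atol=1e-12)
        # the solver may leave O(atol) negatives on pools that decay to zero
        y = np.clip(traj.states[-1], 0.0, None)
        y[10] = 0.0
        years += chunk_years
        res = _relative_residual(y, sp, env)
        if res < 1e-4:
            polished = _polish_steady_state(y, sp, env)
            if polished is not None:
                y = polished
                res = _relative_residual(y, sp, env)
                if res < tol:
                    y[10] = 0.0
                    return SpinUpResult(PoolState.from_array(y), env, res, years)
        if res < tol:
            return SpinUpResult(PoolState.from_array(y), env, res, years)
    raise SpinUpError(
        f"no steady state within {max_years} simulated years; "
        f"residual {res:.3e} h^-1 against tolerance {tol:.1e}")


def _polish_steady_state(y: np.ndarray, sp: ScaledParams,
                         env: Environment):
    """Newton polish of the 10 living pools; returns None on failure."""
    def g(p):
        full = np.concatenate([p, [0.0]])
        return _rhs_array(full, sp, env.IP1, env.IP2, env.ID)[:10]

    sol = root(g, y[:10], method="hybr", tol=1e-14)
    if not sol.success or np.any(sol.x < 0):
        return None
    return np.concatenate([sol.x, [0.0]])


def project_warming(spinup: SpinUpResult, mp: MicrobialParams,
                    fp: FixedParams, dT: float = 5.0, years: int = 50,
                    n_points: int = 101) -> ProjectionResult:
    """Project SOC for ``years`` at the baseline temperature and at
    baseline + ``dT`` with identical constant inputs, starting from the
    spun-up state.

    The headline number is the percent difference of end-simulation SOC
    between the warmed and baseline runs.
    """
    t_grid = np.linspace(0.0, years * HOURS_PER_YEAR, n_points)
    base_env = spinup.env
    warm_env = replace(base_env, T=base_env.T + dT)
    base = integrate(spinup.state, mp, fp, base_env, t_grid)
    warm = integrate(spinup.state, mp, fp, warm_env, t_grid)
    soc_b = base.soc()
    soc_w = warm.soc()
    series = (soc_w - soc_b) / soc_b * 100.0
    return ProjectionResult(
        baseline_soc=float(soc_b[-1]), warmed_soc=float(soc_w[-1]),
        relative_change=float(series[-1]), times=t_grid,
        relative_change_series=series)


def steady_state_warming_response(soil: SoilInit, mp: MicrobialParams,
                                  fp: FixedParams, dT: float = 5.0,
                                  T_base: float = 20.0,
                                  annual_input_frac: float = 0.05) -> float:
    """Percent change of *steady-state* SOC under a temperature step.

    Spins the model up at the baseline and the warmed temperature with the
    same constant inputs and compares steady SOC pools; this is the response
    surface on which the carbon-use-efficiency sign change lives.
    """
    base = spin_up(soil, mp, fp, T=T_base, annual_input_frac=annual_input_frac)
    warm = spin_up(soil, mp, fp, T=T_base + dT,
                   annual_input_frac=annual_input_frac)
    soc_b = base.state.soc()
    soc_w = warm.state.soc()
    return (soc_w - soc_b) / soc_b * 100.0


def yg_response_curve(yg_values, soil: SoilInit, mp: MicrobialParams,
                      fp: FixedParams, dT: float = 5.0) -> np.ndarray:
    """Steady-state SOC warming response as a function of intrinsic carbon
    use efficiency, all other parameters held at ``mp``."""
    out = []
    for yg in yg_values:
        mp_y = replace(mp, Yg=float(yg))
        out.append(steady_state_warming_response(soil, mp_y, fp, dT=dT))
    return np.asarray(out)


def find_yg_sign_change(soil: SoilInit, mp: MicrobialParams, fp: FixedParams,
                        lo: float = 0.2, hi: float = 0.6, dT: float = 5.0,
                        xtol: float = 1e-3) -> float:
    """Bisect for the carbon-use-efficiency value at which the steady-state
    SOC warming response changes sign on [lo, hi]."""
    def f(yg):
        return steady_state_warming_response(soil, replace(mp, Yg=yg), fp,
                                             dT=dT)
    flo, fhi = f(lo), f(hi)
    if flo * fhi > 0:
        raise ValueError("warming response does not change sign on the "
                         f"interval [{lo}, {hi}] ({flo:.3g}, {fhi:.3g})")
    while hi - lo > xtol:
        mid = 0.5 * (lo + hi)
        fm = f(mid)
        if flo * fm <= 0:
            hi, fhi = mid, fm
        else:
            lo, flo = mid, fm
    return 0.5 * (lo + hi)


__all__ = [
    "HOURS_PER_DAY", "HOURS_PER_YEAR", "INCUBATION_T", "PULSE_FRACTION",
    "EP1_INIT", "EP2_INIT", "EM_INIT",
    "Schedule", "ST_G", "LT_C", "SCHEDULES",
    "Trajectory", "SoilInit", "ProjectionResult", "SimulatedIncubation",
    "IntegrationError", "SpinUpError", "SpinUpResult",
    "integrate", "apply_substrate_pulse", "run_incubation",
    "make_input_env", "spin_up", "project_warming",
    "steady_state_warming_response", "yg_response_curve",
    "find_yg_sign_change",
]
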