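"""Core state, parameters and right-hand side of the microbial-enzyme
soil-carbon (MEND) model with dormancy.

The model tracks ten carbon pools (mg C cm^-3 soil) plus cumulative respired
CO2: two particulate pools degraded by oxidative (P1) and hydrolytic (P2)
enzymes, mineral-associated carbon (M), dissolved organic carbon (D), DOC
adsorbed to minerals (Q), active and dormant microbial biomass (BA, BD) and
three extracellular enzyme pools (EP1, EP2, EM).  Decomposition and microbial
DOC uptake follow Michaelis-Menten kinetics; maximum rates and half-saturation
constants carry Arrhenius temperature dependence; adsorption/desorption of DOC
is Langmuir-type with its own activation energy; intrinsic carbon use
efficiency declines linearly with temperature.

All fluxes are assembled in :func:`compute_fluxes` so that alternative flux
formulations can be swapped without touching the integrator or calibration
layers.  The derivative assembly in :func:`rhs` conserves carbon exactly:
the sum of all pool derivatives plus the CO2 rate equals the external input.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, fields

import numpy as np
import yaml

R_GAS = 8.314  # J mol^-1 K^-1
T_ZERO = 273.15  # K at 0 degC

#: order of state-vector components used throughout the package
POOL_NAMES = ("P1", "P2", "M", "D", "Q", "BA", "BD", "EP1", "EP2", "EM", "CO2cum")
N_STATE = len(POOL_NAMES)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class PoolState:
    """Carbon pools in mg C cm^-3 soil plus cumulative respired carbon."""

    P1: float = 0.0
    P2: float = 0.0
    M: float = 0.0
    D: float = 0.0
    Q: float = 0.0
    BA: float = 0.0
    BD: float = 0.0
    EP1: float = 0.0
    EP2: float = 0.0
    EM: float = 0.0
    CO2cum: float = 0.0

    def soc(self) -> float:
        """Total soil organic carbon: every pool except respired CO2."""
        return (self.P1 + self.P2 + self.M + self.D + self.Q
                + self.BA + self.BD + self.EP1 + self.EP2 + self.EM)

    def mbc(self) -> float:
        """Microbial biomass carbon (active + dormant)."""
        return self.BA + self.BD

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in POOL_NAMES], dtype=float)

    @classmethod
    def from_array(cls, y: np.ndarray) -> "PoolState":
        return cls(**{n: float(v) for n, v in zip(POOL_NAMES, y)})

    def validate(self) -> None:
        for n in POOL_NAMES:
            v = getattr(self, n)
            if not np.isfinite(v):
                raise ValueError(f"pool {n} is not finite: {v}")
            if v < 0:
                raise ValueError(f"pool {n} is negative: {v}")


@dataclass(frozen=True)
class MicrobialParams:
    """The five calibrated microbial parameters.

    r0     initial active fraction of microbial biomass, (0, 1]
    Vg     maximum specific growth rate at Tref, h^-1
    alpha  Vmt / (Vg + Vmt), relating maintenance to growth, [0, 1)
    KD     half-saturation constant for DOC uptake, mg C cm^-3
    Yg     intrinsic carbon use efficiency at Tref, (0, 1)
    """

    r0: float = 0.59
    Vg: float = 0.038
    alpha: float = 0.27
    KD: float = 0.02
    Yg: float = 0.30

    def __post_init__(self) -> None:
        if not 0.0 < self.r0 <= 1.0:
            raise ValueError(f"r0 must be in (0, 1], got {self.r0}")
        if self.Vg < 0:
            raise ValueError(f"Vg must be >= 0, got {self.Vg}")
        if not 0.0 <= self.alpha < 1.0:
            raise ValueError(f"alpha must be in [0, 1), got {self.alpha}")
        if self.KD <= 0:
            raise ValueError(f"KD must be > 0, got {self.KD}")
        if not 0.0 < self.Yg < 1.0:
            raise ValueError(f"Yg must be in (0, 1), got {self.Yg}")

    @property
    def Vmt(self) -> float:
        return derived_maintenance_rate(self.Vg, self.alpha)

    def as_array(self) -> np.ndarray:
        return np.array([self.r0, self.Vg, self.alpha, self.KD, self.Yg])

    @classmethod
    def from_array(cls, x: np.ndarray) -> "MicrobialParams":
        return cls(*(float(v) for v in x))


PARAM_NAMES = ("r0", "Vg", "alpha", "KD", "Yg")

#: prior bounds for calibration; bracket the best-fit means reported for both
#: short- and long-term incubation datasets
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "r0": (0.01, 1.0),
    "Vg": (0.001, 0.2),
    "alpha": (0.01, 0.6),
    "KD": (1e-4, 0.5),
    "Yg": (0.1, 0.7),
}

#: the ranges best-fit estimates of real incubated soils actually occupy,
#: across substrates, ecosystems and durations; used where a sweep or truth
#: draw should stay on soils-like parameter combinations (the search-box
#: extremes include non-viable ones, e.g. growth too slow to offset
#: mortality, where no steady state exists)
OBSERVED_PARAM_RANGES: dict[str, tuple[float, float]] = {
    "r0": (0.4, 0.9),
    "Vg": (0.02, 0.06),
    "alpha": (0.2, 0.35),
    "KD": (0.01, 0.15),
    "Yg": (0.25, 0.45),
}


@dataclass(frozen=True)
class FixedParams:
    """Non-calibrated kinetic, partition and temperature constants.

    Rates are per hour, concentrations in mg C cm^-3 soil, activation
    energies in kJ mol^-1.  Defaults ship in ``data/mend_defaults.yaml``.
    """

    VP1: float = 2.5     # max specific decomposition of P1 per unit EP1
    VP2: float = 5.0     # max specific decomposition of P2 per unit EP2
    VM: float = 1.0      # max specific decomposition of M per unit EM
    KP1: float = 50.0
    KP2: float = 25.0
    KM: float = 25.0
    Kads: float = 0.006  # DOC adsorption rate constant
    Kdes: float = 0.001  # DOC desorption rate constant
    Qmax: float = 1.7    # adsorption capacity
    fD: float = 0.5      # fraction of decomposed P1/P2 routed to DOC
    rM: float = 2e-3     # microbial mortality rate
    gD: float = 0.5      # fraction of dead biomass routed to DOC (rest to P2)
    pEP1: float = 1e-5   # specific production rate of EP1 from BA
    pEP2: float = 1e-5
    pEM: float = 1.3e-5
    rE: float = 1e-3     # enzyme turnover rate (to DOC)
    beta: float = 0.001  # dormant maintenance reduction factor
    Ea_V: float = 47.0   # activation energy of V-type rates
    Ea_K: float = 10.0   # activation energy of half-saturation constants
    Ea_ads: float = 5.0  # activation energy of adsorption/desorption
    kYg: float = -0.01   # temperature slope of Yg, per degC
    Tref: float = 20.0   # reference temperature, degC

    def __post_init__(self) -> None:
        for name in ("VP1", "VP2", "VM", "KP1", "KP2", "KM", "Kads", "Kdes",
                     "rM", "pEP1", "pEP2", "pEM", "rE"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("fD", "gD", "beta"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.Qmax <= 0:
            raise ValueError("Qmax must be > 0")

    @classmethod
    def from_config(cls, path=None) -> "FixedParams":
        """Load constants from a key/value YAML config.

        Without ``path`` the packaged ``mend_defaults.yaml`` fixture is used.
        The file may group keys by process; groups are flattened.
        """
        if path is None:
            ref = importlib.resources.files("soilmend") / "data" / "mend_defaults.yaml"
            raw = yaml.safe_load(ref.read_text())
        else:
            with open(path) as fh:
                raw = yaml.safe_load(fh)
        flat: dict[str, float] = {}
        for key, val in raw.items():
            if isinstance(val, dict):
                flat.update(val)
            else:
                flat[key] = val
        known = {f.name for f in fields(cls)}
        unknown = set(flat) - known
        if unknown:
            raise ValueError(f"unknown parameter keys in config: {sorted(unknown)}")
        return cls(**flat)


@dataclass(frozen=True)
class Environment:
    """External forcing: soil temperature and carbon input rates.

    Inputs feed the P1, P2 and D pools, in mg C cm^-3 h^-1.
    """

    T: float = 20.0
    IP1: float = 0.0
    IP2: float = 0.0
    ID: float = 0.0

    def __post_init__(self) -> None:
        if min(self.IP1, self.IP2, self.ID) < 0:
            raise ValueError("external inputs must be >= 0")

    @property
    def total_input(self) -> float:
        return self.IP1 + self.IP2 + self.ID


@dataclass(frozen=True)
class FluxSet:
    """All instantaneous carbon fluxes, mg C cm^-3 h^-1."""

    uptake: float              # F1: DOC uptake by active biomass
    decomp_P1: float           # F2
    decomp_P2: float           # F3
    decomp_M: float            # F4
    adsorption: float          # F5: D -> Q
    desorption: float          # F6: Q -> D
    dormancy: float            # F7: BA -> BD
    reactivation: float        # F8: BD -> BA
    growth: float              # net growth of BA
    maintenance_active: float
    maintenance_dormant: float
    growth_respiration: float
    mortality: float
    enzyme_production: tuple   # (EP1, EP2, EM) production fluxes
    enzyme_turnover: tuple     # (EP1, EP2, EM) turnover fluxes


# ---------------------------------------------------------------------------
# elementary relations
# ---------------------------------------------------------------------------

def derived_maintenance_rate(Vg: float, alpha: float) -> float:
    """Specific maintenance rate Vmt from alpha = Vmt / (Vg + Vmt)."""
    if not 0.0 <= alpha < 1.0:
        raise ValueError(f"alpha must be in [0, 1), got {alpha}")
    if Vg < 0:
        raise ValueError(f"Vg must be >= 0, got {Vg}")
    return alpha * Vg / (1.0 - alpha)


def arrhenius_factor(Ea: float, T: float, Tref: float = 20.0) -> float:
    """Arrhenius rate multiplier relative to the reference temperature.

    ``exp[(Ea/R) (1/Tref_K - 1/T_K)]`` with Ea in kJ mol^-1 and
    temperatures in degC.
    """
    if T <= -T_ZERO or Tref <= -T_ZERO:
        raise ValueError("temperatures must exceed absolute zero")
    return float(np.exp(Ea * 1000.0 / R_GAS
                        * (1.0 / (Tref + T_ZERO) - 1.0 / (T + T_ZERO))))


def yg_at_temperature(Yg_ref: float, kYg: float, T: float,
                      Tref: float = 20.0) -> float:
    """Carbon use efficiency at temperature T, clipped to (0.001, 0.999).

    The clip is numerical safety for the 1/Yg uptake prefactor; it is never
    active in the temperature range of the experiments modelled here.
    """
    if not 0.0 < Yg_ref < 1.0:
        raise ValueError(f"Yg_ref must be in (0, 1), got {Yg_ref}")
    return float(np.clip(Yg_ref + kYg * (T - Tref), 0.001, 0.999))


# ---------------------------------------------------------------------------
# temperature-scaled parameter bundle (internal fast path)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScaledParams:
    """Parameters pre-scaled to one temperature; used by the integrator."""

    VP1: float
    VP2: float
    VM: float
    KP1: float
    KP2: float
    KM: float
    Kads: float
    Kdes: float
    Qmax: float
    fD: float
    rM: float
    gD: float
    pEP1: float
    pEP2: float
    pEM: float
    pE_total: float
    rE: float
    beta: float
    Vg: float
    Vmt: float
    KD: float
    Yg: float


def scale_params(mp: MicrobialParams, fp: FixedParams, T: float) -> ScaledParams:
    """Apply Arrhenius scaling and the Yg-temperature relation at T."""
    fV = arrhenius_factor(fp.Ea_V, T, fp.Tref)
    fK = arrhenius_factor(fp.Ea_K, T, fp.Tref)
    fA = arrhenius_factor(fp.Ea_ads, T, fp.Tref)
    return ScaledParams(
        VP1=fp.VP1 * fV, VP2=fp.VP2 * fV, VM=fp.VM * fV,
        KP1=fp.KP1 * fK, KP2=fp.KP2 * fK, KM=fp.KM * fK,
        Kads=fp.Kads * fA, Kdes=fp.Kdes * fA, Qmax=fp.Qmax,
        fD=fp.fD, rM=fp.rM, gD=fp.gD,
        pEP1=fp.pEP1, pEP2=fp.pEP2, pEM=fp.pEM,
        pE_total=fp.pEP1 + fp.pEP2 + fp.pEM,
        rE=fp.rE, beta=fp.beta,
        Vg=mp.Vg * fV, Vmt=mp.Vmt * fV,
        KD=mp.KD * fK,
        Yg=yg_at_temperature(mp.Yg, fp.kYg, T, fp.Tref),
    )


def _rhs_array(y: np.ndarray, sp: ScaledParams,
               IP1: float, IP2: float, ID: float) -> np.ndarray:
    """Derivatives for the raw state vector; pools clipped at zero so the
    adaptive solver may probe slightly negative values without spurious
    carbon creation."""
    P1 = y[0] if y[0] > 0.0 else 0.0
    P2 = y[1] if y[1] > 0.0 else 0.0
    M = y[2] if y[2] > 0.0 else 0.0
    D = y[3] if y[3] > 0.0 else 0.0
    Q = y[4] if y[4] > 0.0 else 0.0
    BA = y[5] if y[5] > 0.0 else 0.0
    BD = y[6] if y[6] > 0.0 else 0.0
    EP1 = y[7] if y[7] > 0.0 else 0.0
    EP2 = y[8] if y[8] > 0.0 else 0.0
    EM = y[9] if y[9] > 0.0 else 0.0

    S = D / (sp.KD + D)                       # substrate saturation
    F1 = (sp.Vg + sp.Vmt) * S * BA / sp.Yg    # DOC uptake
    F2 = sp.VP1 * EP1 * P1 / (sp.KP1 + P1)
    F3 = sp.VP2 * EP2 * P2 / (sp.KP2 + P2)
    F4 = sp.VM * EM * M / (sp.KM + M)
    F5 = sp.Kads * D * (1.0 - Q / sp.Qmax)
    F6 = sp.Kdes * Q / sp.Qmax
    F7 = (1.0 - S) * sp.Vmt * BA              # dormancy
    F8 = S * sp.Vmt * BD                      # reactivation
    mort = sp.rM * BA
    maint_a = sp.Vmt * S * BA
    maint_d = sp.beta * sp.Vmt * BD
    enz_turn = sp.rE * (EP1 + EP2 + EM)

    out = np.empty(N_STATE)
    out[0] = IP1 - F2
    out[1] = IP2 + (1.0 - sp.gD) * mort - F3
    out[2] = (1.0 - sp.fD) * (F2 + F3) - F4
    out[3] = (ID + sp.fD * (F2 + F3) + F4 + sp.gD * mort + enz_turn
              - F1 - F5 + F6)
    out[4] = F5 - F6
    out[5] = sp.Vg * S * BA - mort - sp.pE_total * BA - F7 + F8
    out[6] = F7 - F8 - maint_d
    out[7] = sp.pEP1 * BA - sp.rE * EP1
    out[8] = sp.pEP2 * BA - sp.rE * EP2
    out[9] = sp.pEM * BA - sp.rE * EM
    out[10] = (1.0 - sp.Yg) * F1 + maint_a + maint_d
    return out


# ---------------------------------------------------------------------------
# public flux / derivative API
# ---------------------------------------------------------------------------

def compute_fluxes(state: PoolState, mp: MicrobialParams, fp: FixedParams,
                   env: Environment) -> FluxSet:
    """Evaluate every carbon flux at the given state and temperature."""
    state.validate()
    sp = scale_params(mp, fp, env.T)
    S = state.D / (sp.KD + state.D)
    F1 = (sp.Vg + sp.Vmt) * S * state.BA / sp.Yg
    return FluxSet(
        uptake=F1,
        decomp_P1=sp.VP1 * state.EP1 * state.P1 / (sp.KP1 + state.P1),
        decomp_P2=sp.VP2 * state.EP2 * state.P2 / (sp.KP2 + state.P2),
        decomp_M=sp.VM * state.EM * state.M / (sp.KM + state.M),
        adsorption=sp.Kads * state.D * (1.0 - state.Q / sp.Qmax),
        desorption=sp.Kdes * state.Q / sp.Qmax,
        dormancy=(1.0 - S) * sp.Vmt * state.BA,
        reactivation=S * sp.Vmt * state.BD,
        growth=sp.Vg * S * state.BA,
        maintenance_active=sp.Vmt * S * state.BA,
        maintenance_dormant=sp.beta * sp.Vmt * state.BD,
        growth_respiration=(1.0 - sp.Yg) * F1,
        mortality=sp.rM * state.BA,
        enzyme_production=(sp.pEP1 * state.BA, sp.pEP2 * state.BA,
                           sp.pEM * state.BA),
        enzyme_turnover=(sp.rE * state.EP1, sp.rE * state.EP2,
                         sp.rE * state.EM),
    )


def rhs(state: PoolState, mp: MicrobialParams, fp: FixedParams,
        env: Environment) -> PoolState:
    """Time derivative of every pool plus the CO2 rate, as a PoolState.

    Carbon is conserved by construction: the sum of all returned components
    equals ``env.total_input`` to machine precision.
    """
    state.validate()
    sp = scale_params(mp, fp, env.T)
    dy = _rhs_array(state.as_array(), sp, env.IP1, env.IP2, env.ID)
    return PoolState.from_array(dy)


__all__ = [
    "POOL_NAMES", "N_STATE", "PARAM_NAMES", "DEFAULT_BOUNDS",
    "PoolState", "MicrobialParams", "FixedParams", "Environment", "FluxSet",
    "ScaledParams", "derived_maintenance_rate", "arrhenius_factor",
    "yg_at_temperature", "scale_params", "compute_fluxes", "rhs",
]
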