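"""Synthetic inputs for every pipeline stage.

Generates (i) soil initial-condition tables with realistic pool partitions,
(ii) noisy incubation time series by forward-simulating the model on the
laboratory collection schedules and applying multiplicative lognormal noise,
(iii) duration-truncated variants of long incubations, and (iv) field-warming
observation tables with prescribed group effects for the meta-analysis.  All
generators are deterministic under a fixed seed.

The default study design mirrors the incubation campaign the package
models: 4 soil locations x 2 ecosystems x 2 substrates = 16 cases, three
replicates, CO2 on 7 (short) or 18 (long) collections and MBC on 3 or 8.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .mend_core import FixedParams, MicrobialParams
from .meta_analysis import DEFAULT_BINS, MetaObservation
from .simulate import (
    HOURS_PER_DAY,
    LT_C,
    ST_G,
    Schedule,
    SoilInit,
    run_incubation,
)

#: default multiplicative noise (coefficient of variation)
CO2_NOISE_CV = 0.10
MBC_NOISE_CV = 0.15

#: the incubation campaign design emulated by default
SITES = ("IA", "MO", "OH", "TN")
ECOSYSTEMS = ("forest", "grassland")
SUBSTRATES = ("glucose", "cellulose")

#: field-warming meta-table group effects: label -> (mean %, sd %, n).
#: Means and sds are the duration-group statistics the model projections are
#: validated against; group sizes total 149 observations and are chosen so
#: the count-weighted mean of the group means reproduces the overall +1.6%
#: effect (10*(-4.8) + 73*1.4 + 66*2.8 = 239 over 149 rows)
DEFAULT_META_GROUPS = {
    "<1": (-4.8, 8.4, 10),
    "1-10": (1.4, 4.1, 73),
    ">10": (2.8, 9.1, 66),
}


@dataclass(frozen=True)
class SoilRanges:
    """Sampling ranges for synthetic soil initial conditions.

    Total SOC is drawn uniformly (mg C cm^-3); MBC, DOC and MOC are drawn
    as uniform fractions of it, the remainder is POC split 1:2 between the
    oxidative and hydrolytic pools.
    """

    soc: tuple = (10.0, 60.0)
    mbc_frac: tuple = (0.005, 0.02)
    doc_frac: tuple = (0.002, 0.006)
    moc_frac: tuple = (0.40, 0.70)
    p1_fraction: float = 1.0 / 3.0
    bulk_density: tuple = (1.0, 1.6)

    def validate(self) -> None:
        for name in ("soc", "mbc_frac", "doc_frac", "moc_frac", "bulk_density"):
            lo, hi = getattr(self, name)
            if not 0 <= lo <= hi:
                raise ValueError(f"invalid range for {name}: ({lo}, {hi})")
        if self.mbc_frac[1] + self.doc_frac[1] + self.moc_frac[1] >= 1.0:
            raise ValueError("fraction ranges may exhaust total SOC")


def generate_soil(seed=None, ranges: SoilRanges = SoilRanges(),
                  site: str = "SYN", ecosystem: str = "forest",
                  substrate: str = "none") -> SoilInit:
    """Draw one consistent soil initial condition; pools sum to total SOC."""
    ranges.validate()
    rng = np.random.default_rng(seed)
    soc = rng.uniform(*ranges.soc)
    mbc = rng.uniform(*ranges.mbc_frac) * soc
    doc = rng.uniform(*ranges.doc_frac) * soc
    moc = rng.uniform(*ranges.moc_frac) * soc
    poc = soc - mbc - doc - moc
    return SoilInit(site=site, ecosystem=ecosystem, poc=poc, moc=moc,
                    doc=doc, mbc=mbc,
                    bulk_density=rng.uniform(*ranges.bulk_density),
                    p1_fraction=ranges.p1_fraction, substrate=substrate)


@dataclass
class IncubationDataset:
    """Observed or synthetic incubation series for one soil case.

    ``co2`` and ``mbc`` are tidy frames with columns time_h, replicate,
    value; CO2 values are interval-mean efflux rates (mg C cm^-3 h^-1), MBC
    values total biomass (mg C cm^-3).  Replicates are averaged by
    ``co2_mean``/``mbc_mean`` before entering the calibration objective.
    """

    site: str
    ecosystem: str
    substrate: str
    soil: SoilInit
    co2: pd.DataFrame
    mbc: pd.DataFrame
    schedule_name: str = "custom"
    true_params: MicrobialParams | None = None
    truncated_days: float | None = None

    @property
    def case_id(self) -> str:
        return f"{self.site}_{self.ecosystem}_{self.substrate}"

    def co2_mean(self):
        g = self.co2.groupby("time_h")["value"].mean()
        return g.index.to_numpy(), g.to_numpy()

    def mbc_mean(self):
        g = self.mbc.groupby("time_h")["value"].mean()
        return g.index.to_numpy(), g.to_numpy()

    @property
    def n_co2(self) -> int:
        return self.co2["time_h"].nunique()

    @property
    def n_mbc(self) -> int:
        return self.mbc["time_h"].nunique()

    @property
    def n_obs(self) -> int:
        return self.n_co2 + self.n_mbc


def _noisy_frame(times: np.ndarray, values: np.ndarray, cv: float,
                 replicates: int, rng: np.random.Generator) -> pd.DataFrame:
    """Tidy frame of replicate series with mean-one lognormal noise."""
    if cv < 0:
        raise ValueError("noise_cv must be >= 0")
    rows = []
    sigma = np.sqrt(np.log1p(cv ** 2))
    for rep in range(1, replicates + 1):
        if cv == 0:
            noise = np.ones_like(values)
        else:
            noise = rng.lognormal(mean=-0.5 * sigma ** 2, sigma=sigma,
                                  size=len(values))
        rows.append(pd.DataFrame({"time_h": times, "replicate": rep,
                                  "value": values * noise}))
    return pd.concat(rows, ignore_index=True)


def generate_incubation_dataset(soil: SoilInit, true_params: MicrobialParams,
                                schedule, fp: FixedParams | None = None,
                                co2_noise_cv: float = CO2_NOISE_CV,
                                mbc_noise_cv: float = MBC_NOISE_CV,
                                replicates: int = 3,
                                seed=None) -> IncubationDataset:
    """Forward-simulate an incubation and dress it with measurement noise.

    ``schedule`` is a Schedule or one of the named schedules "ST_G"/"LT_C".
    Noise is multiplicative lognormal with mean one (respiration and biomass
    are positive with roughly proportional errors), independent per
    replicate and collection.
    """
    if isinstance(schedule, str):
        from .simulate import SCHEDULES
        schedule = SCHEDULES[schedule]
    if fp is None:
        fp = FixedParams()
    rng = np.random.default_rng(seed)
    sim = run_incubation(soil, true_params, fp, schedule.substrate, schedule)
    co2 = _noisy_frame(sim.co2_times, sim.co2_rates, co2_noise_cv,
                       replicates, rng)
    mbc = _noisy_frame(sim.mbc_times, sim.mbc_values, mbc_noise_cv,
                       replicates, rng)
    return IncubationDataset(site=soil.site, ecosystem=soil.ecosystem,
                             substrate=schedule.substrate, soil=soil,
                             co2=co2, mbc=mbc,
                             schedule_name=schedule.name,
                             true_params=true_params)


def truncate_dataset(dataset: IncubationDataset,
                     duration_days: float) -> IncubationDataset:
    """Keep only collections at or before ``duration_days``.

    Calibration needs both observables, so a truncation that removes every
    MBC (or CO2) point is an error.
    """
    max_h = duration_days * HOURS_PER_DAY
    if max_h > dataset.co2["time_h"].max() + 1e-9:
        raise ValueError("truncation exceeds the dataset duration")
    co2 = dataset.co2[dataset.co2["time_h"] <= max_h].reset_index(drop=True)
    mbc = dataset.mbc[dataset.mbc["time_h"] <= max_h].reset_index(drop=True)
    if len(mbc) == 0 or len(co2) == 0:
        raise ValueError(f"truncation to {duration_days} days leaves no "
                         "MBC (or CO2) observations")
    return replace(dataset, co2=co2, mbc=mbc, truncated_days=duration_days)


def generate_case_suite(seed=None, schedule=LT_C,
                        fp: FixedParams | None = None,
                        true_params: MicrobialParams | None = None,
                        ranges: SoilRanges = SoilRanges(),
                        replicates: int = 3,
                        co2_noise_cv: float = CO2_NOISE_CV,
                        mbc_noise_cv: float = MBC_NOISE_CV) -> list:
    """The full 16-case design (4 sites x 2 ecosystems x 2 substrate
    treatments) on one collection schedule.

    When ``true_params`` is None each case draws its own truth uniformly
    from the calibration prior box, emulating between-soil variation.
    """
    from .mend_core import DEFAULT_BOUNDS, PARAM_NAMES
    rng = np.random.default_rng(seed)
    datasets = []
    for site in SITES:
        for eco in ECOSYSTEMS:
            for sub in SUBSTRATES:
                soil = generate_soil(rng, ranges, site=site, ecosystem=eco,
                                     substrate=sub)
                if true_params is None:
                    draw = [rng.uniform(*DEFAULT_BOUNDS[n])
                            for n in PARAM_NAMES]
                    tp = MicrobialParams.from_array(np.array(draw))
                else:
                    tp = true_params
                sched = replace(schedule, substrate=sub)
                datasets.append(generate_incubation_dataset(
                    soil, tp, sched, fp=fp, co2_noise_cv=co2_noise_cv,
                    mbc_noise_cv=mbc_noise_cv, replicates=replicates,
                    seed=rng))
    return datasets


def generate_meta_table(group_specs=None, seed=None,
                        control_range: tuple = (20.0, 150.0),
                        warming_range: tuple = (1.0, 5.0)) -> list:
    """Synthetic field-warming observation table.

    ``group_specs`` maps a duration-bin label to (true mean %, sd %, n);
    percent effects are drawn normally per group, converted to
    control/warmed SOC pairs with controls uniform in ``control_range``,
    and durations drawn inside the bin.
    """
    if group_specs is None:
        group_specs = DEFAULT_META_GROUPS
    rng = np.random.default_rng(seed)
    bin_ranges = {label: (lo, hi) for label, lo, hi in DEFAULT_BINS}
    obs = []
    i = 0
    for label, (mean, sd, n) in group_specs.items():
        if sd < 0:
            raise ValueError("group sd must be >= 0")
        if n < 1:
            raise ValueError("group n must be >= 1")
        lo, hi = bin_ranges[label]
        hi = min(hi, 25.0)          # longest field experiments run ~decades
        lo = max(lo, 0.1)
        for _ in range(n):
            # floor keeps warmed SOC positive; ~11 sd below the default means
            eff = max(rng.normal(mean, sd), -95.0)
            control = rng.uniform(*control_range)
            duration = rng.uniform(lo, hi)
            if label == "<1":
                duration = min(duration, hi - 1e-6)
            obs.append(MetaObservation(
                study_id=f"S{i:03d}",
                control_soc=control,
                warmed_soc=control * (1.0 + eff / 100.0),
                warming_degC=rng.uniform(*warming_range),
                duration_years=duration))
            i += 1
    return obs


__all__ = [
    "CO2_NOISE_CV", "MBC_NOISE_CV", "SITES", "ECOSYSTEMS", "SUBSTRATES",
    "DEFAULT_META_GROUPS", "SoilRanges", "generate_soil",
    "IncubationDataset", "generate_incubation_dataset", "truncate_dataset",
    "generate_case_suite", "generate_meta_table",
]
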