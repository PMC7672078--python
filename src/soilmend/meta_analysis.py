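"""Effect sizes and duration-grouped summaries of field-warming SOC
observations.

Each observation is a control/warmed pair of soil organic carbon stocks from
one field warming manipulation (1-5 degC) of known duration.  The primary
effect metric is the unweighted percent change, summarized as mean +/- sd
within duration groups (< 1 year, 1-10 years, > 10 years) and overall; the
log response ratio ln(warmed/control) is available as an alternative mode.
"""

from __future__ import annotations

import math

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: duration bins in years: [0, 1), [1, 10], (10, inf) as printed on figure
#: axes "<1", "1-10", ">10"
DEFAULT_BINS = (
    ("<1", 0.0, 1.0),
    ("1-10", 1.0, 10.0),
    (">10", 10.0, math.inf),
)


@dataclass(frozen=True)
class MetaObservation:
    """One field-warming record."""

    study_id: str
    control_soc: float
    warmed_soc: float
    warming_degC: float
    duration_years: float

    def __post_init__(self) -> None:
        if self.control_soc <= 0 or self.warmed_soc <= 0:
            raise ValueError("SOC stocks must be > 0")
        if self.duration_years <= 0:
            raise ValueError("duration must be > 0")


def effect_size(obs: MetaObservation, mode: str = "percent") -> float:
    """Warming effect on SOC for one observation.

    percent: 100 * (warmed - control) / control
    lnRR:    ln(warmed / control)
    """
    if mode == "percent":
        return 100.0 * (obs.warmed_soc - obs.control_soc) / obs.control_soc
    if mode == "lnRR":
        return float(np.log(obs.warmed_soc / obs.control_soc))
    raise ValueError(f"unknown mode {mode!r}; expected 'percent' or 'lnRR'")


def assign_bin(duration_years: float, bins=DEFAULT_BINS) -> str:
    """Duration-group label.

    As printed on the figure axes, the first group is right-open ("<1"),
    middle groups are closed at both ends ("1-10"), and the last group is
    left-open (">10").
    """
    for i, (label, lo, hi) in enumerate(bins):
        if i == 0 and lo <= duration_years < hi:
            return label
        if i == len(bins) - 1 and duration_years > lo:
            return label
        if 0 < i < len(bins) - 1 and lo <= duration_years <= hi:
            return label
    raise ValueError(f"duration {duration_years} not covered by bins")


def summarize_effects(observations, bins=DEFAULT_BINS,
                      mode: str = "percent") -> pd.DataFrame:
    """Per-duration-group and overall mean +/- sd of effect sizes.

    Returns a frame indexed by group label plus an ``all`` row, with columns
    mean, sd (sample sd, NaN for n < 2) and n; empty groups appear with
    n = 0.  The overall mean equals the count-weighted mean of group means
    exactly, since groups partition the observations.
    """
    effects = np.array([effect_size(o, mode=mode) for o in observations])
    labels = [assign_bin(o.duration_years, bins) for o in observations]
    rows = {}
    for label, lo, hi in bins:
        vals = effects[[l == label for l in labels]]
        rows[label] = _mean_sd_n(vals)
    rows["all"] = _mean_sd_n(effects)
    return pd.DataFrame.from_dict(rows, orient="index")


def _mean_sd_n(vals: np.ndarray) -> dict:
    n = len(vals)
    return {
        "mean": float(np.mean(vals)) if n else float("nan"),
        "sd": float(np.std(vals, ddof=1)) if n > 1 else float("nan"),
        "n": n,
    }


__all__ = ["DEFAULT_BINS", "MetaObservation", "effect_size", "assign_bin",
           "summarize_effects"]
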