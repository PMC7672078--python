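"""Parameter uncertainty and sensitivity machinery.

Uncertainty is quantified by the critical objective function index (COFI):
all parameter vectors whose objective value lies between the calibration
optimum J_opt and the threshold

    J_cr = J_opt * (1 + p / (n - p) * F(alpha; p, n - p))

form the feasible parameter region, where n is the number of fitted
observations, p the number of calibrated parameters and F the upper-tail
F-quantile.  Feasible ensembles from different calibrations are compared per
parameter with the Kruskal-Wallis rank test; paired best-fit estimates with
the paired t-test.  Parametric sensitivity of steady-state pools uses a
log-log high-versus-low index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .mend_core import (DEFAULT_BOUNDS, FixedParams, MicrobialParams,
                        OBSERVED_PARAM_RANGES, PARAM_NAMES)
from .simulate import SoilInit, spin_up


# ---------------------------------------------------------------------------
# COFI feasible region
# ---------------------------------------------------------------------------

def cofi_threshold(j_opt: float, n: int, p: int, alpha: float = 0.05) -> float:
    """Critical objective function value J_cr bounding the feasible region."""
    if j_opt < 0:
        raise ValueError("j_opt must be >= 0")
    if not n > p > 0:
        raise ValueError(f"need n > p > 0, got n={n}, p={p}")
    fq = stats.f.isf(alpha, p, n - p)
    return float(j_opt * (1.0 + p / (n - p) * fq))


@dataclass
class ParameterEnsemble:
    """Feasible parameter vectors (J <= J_cr) from an evaluation archive."""

    params: np.ndarray       # (m, k)
    j_values: np.ndarray     # (m,)
    j_cr: float
    j_opt: float
    n_obs: int
    n_params: int
    alpha: float = 0.05
    names: tuple = PARAM_NAMES

    def __len__(self) -> int:
        return len(self.j_values)

    def column(self, name: str) -> np.ndarray:
        return self.params[:, self.names.index(name)]

    def intervals(self) -> pd.DataFrame:
        """Per-parameter feasible range (min, max, width)."""
        lo = self.params.min(axis=0)
        hi = self.params.max(axis=0)
        return pd.DataFrame({"low": lo, "high": hi, "width": hi - lo},
                            index=list(self.names))

    def contains(self, x) -> np.ndarray:
        """Component-wise membership of a vector in the feasible intervals."""
        x = np.asarray(x, dtype=float)
        iv = self.intervals()
        return (x >= iv["low"].to_numpy()) & (x <= iv["high"].to_numpy())

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.params, columns=list(self.names))
        df["J"] = self.j_values
        return df


def feasible_ensemble(archive_x: np.ndarray, archive_j: np.ndarray,
                      j_cr: float, n_obs: int = 0,
                      alpha: float = 0.05) -> ParameterEnsemble:
    """Members of an evaluation archive with J <= J_cr.

    An empty result is returned (with a warning) rather than raised, so
    sparse archives degrade gracefully.
    """
    archive_x = np.asarray(archive_x, dtype=float)
    archive_j = np.asarray(archive_j, dtype=float)
    if len(archive_j) == 0:
        raise ValueError("archive is empty")
    mask = archive_j <= j_cr
    if not np.any(mask):
        warnings.warn("no archive member satisfies J <= J_cr; "
                      "returning an empty ensemble", stacklevel=2)
    return ParameterEnsemble(
        params=archive_x[mask], j_values=archive_j[mask], j_cr=float(j_cr),
        j_opt=float(archive_j.min()), n_obs=n_obs,
        n_params=archive_x.shape[1] if archive_x.ndim == 2 else 0,
        alpha=alpha)


def ensemble_from_calibration(result, alpha: float = 0.05,
                              refill: int = 0,
                              seed: int | None = None,
                              objective_fn=None) -> ParameterEnsemble:
    """COFI ensemble from a calibration result's archive.

    ``refill`` optionally adds Latin-hypercube samples inside the current
    feasible box (evaluated with ``objective_fn``) when the archive is
    sparse near the optimum.
    """
    j_cr = cofi_threshold(result.j_opt, result.n_obs, len(PARAM_NAMES),
                          alpha=alpha)
    ens = feasible_ensemble(result.archive_x, result.archive_j, j_cr,
                            n_obs=result.n_obs, alpha=alpha)
    if refill > 0:
        if objective_fn is None:
            raise ValueError("refill requires objective_fn")
        if len(ens) == 0:
            raise ValueError("cannot refill an empty ensemble")
        iv = ens.intervals()
        lo = iv["low"].to_numpy()
        span = np.maximum(iv["width"].to_numpy(), 1e-12)
        rng = np.random.default_rng(seed)
        pts = lo + rng.random((refill, len(lo))) * span
        vals = np.array([objective_fn(x) for x in pts])
        keep = vals <= j_cr
        ens = ParameterEnsemble(
            params=np.vstack([ens.params, pts[keep]]),
            j_values=np.concatenate([ens.j_values, vals[keep]]),
            j_cr=j_cr, j_opt=ens.j_opt, n_obs=result.n_obs,
            n_params=ens.n_params, alpha=alpha)
    return ens


# ---------------------------------------------------------------------------
# ensemble and best-fit comparisons
# ---------------------------------------------------------------------------

def cofi_ensemble_with_refill(result, objective_fn, bounds,
                              n_samples: int = 400,
                              seed: int | None = None,
                              alpha: float = 0.05) -> ParameterEnsemble:
    """COFI ensemble from an archive augmented with a Latin-hypercube scan
    of the prior box.

    SCE archives concentrate near the optimum, so the archive alone can
    under-map the outer reaches of the feasible region; the refill samples
    the full prior box and keeps every point with J <= J_cr.
    """
    from scipy.stats import qmc

    from .calibrate import _as_bounds_array
    b = _as_bounds_array(bounds)
    j_cr = cofi_threshold(result.j_opt, result.n_obs, b.shape[0], alpha=alpha)
    sampler = qmc.LatinHypercube(d=b.shape[0],
                                 seed=np.random.default_rng(seed))
    pts = b[:, 0] + sampler.random(n_samples) * (b[:, 1] - b[:, 0])
    vals = np.array([objective_fn(x) for x in pts])
    all_x = np.vstack([result.archive_x, pts])
    all_j = np.concatenate([result.archive_j, vals])
    return feasible_ensemble(all_x, all_j, j_cr, n_obs=result.n_obs,
                             alpha=alpha)


def map_feasible_region(result, objective_fn, bounds,
                        rounds: int = 3, per_round: int = 150,
                        inflate: float = 2.0, seed: int | None = None,
                        alpha: float = 0.05) -> ParameterEnsemble:
    """COFI ensemble with covariance-adapted exploration of the feasible
    region.

    The feasible set is typically a thin correlated ridge (carbon use
    efficiency trades off against maintenance and growth), which axis-
    aligned box sampling maps poorly.  Starting from the archive's feasible
    members, each round fits their mean and covariance and samples
    candidates from the inflated Gaussian (clipped to the prior box), so
    the search elongates along the ridge; feasible candidates join the
    pool.  Returns the ensemble of every feasible evaluation seen.
    """
    from .calibrate import _as_bounds_array
    b = _as_bounds_array(bounds)
    j_cr = cofi_threshold(result.j_opt, result.n_obs, b.shape[0], alpha=alpha)
    rng = np.random.default_rng(seed)
    xs = result.archive_x.copy()
    js = result.archive_j.copy()
    jitter = np.diag((1e-6 * (b[:, 1] - b[:, 0])) ** 2)
    for _ in range(rounds):
        feas = xs[js <= j_cr]
        if len(feas) < 2:
            break
        mean = feas.mean(axis=0)
        cov = np.cov(feas.T) + jitter
        cand = rng.multivariate_normal(mean, inflate ** 2 * cov,
                                       size=per_round)
        cand = np.clip(cand, b[:, 0], b[:, 1])
        vals = np.array([objective_fn(x) for x in cand])
        xs = np.vstack([xs, cand])
        js = np.concatenate([js, vals])
    return feasible_ensemble(xs, js, j_cr, n_obs=result.n_obs, alpha=alpha)


def kruskal_wallis_compare(ens_a, ens_b) -> pd.DataFrame:
    """Per-parameter Kruskal-Wallis test between two feasible ensembles.

    Accepts ParameterEnsemble objects or plain (m, k) arrays.  Identical
    samples (all values tied) have no rank information; they are reported
    with H = 0 and p = 1.
    """
    a = ens_a.params if hasattr(ens_a, "params") else np.asarray(ens_a)
    b = ens_b.params if hasattr(ens_b, "params") else np.asarray(ens_b)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each ensemble needs at least 2 members")
    rows = []
    for i, name in enumerate(PARAM_NAMES[:a.shape[1]]):
        va, vb = a[:, i], b[:, i]
        if np.all(va == va[0]) and np.all(vb == va[0]):
            h, p = 0.0, 1.0
        else:
            h, p = stats.kruskal(va, vb)
        rows.append({"parameter": name, "H": float(h), "p": float(p),
                     "significant": bool(p < 0.05)})
    return pd.DataFrame(rows).set_index("parameter")


@dataclass(frozen=True)
class PairedTResult:
    t: float
    p: float
    mean_difference: float       # mean(short - long)
    n_short_greater: int
    n_pairs: int
    degenerate: bool             # zero variance of the differences


def paired_t_compare(short_best, long_best) -> PairedTResult:
    """Paired t-test of best-fit estimates from two calibration variants.

    Reports the mean difference (short minus long) and how many pairs had
    the short-term estimate above the long-term one.  Zero-variance
    differences are flagged degenerate (t undefined).
    """
    a = np.asarray(short_best, dtype=float)
    b = np.asarray(long_best, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("need equal-length 1-D paired samples, n >= 2")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        # no variance in the differences: identical pairs carry no evidence
        # (t = 0, p = 1); a constant nonzero shift is infinitely significant
        if np.allclose(d.mean(), 0.0):
            t, p = 0.0, 1.0
        else:
            t, p = float(np.sign(d.mean()) * np.inf), 0.0
        return PairedTResult(t=t, p=p, mean_difference=float(d.mean()),
                             n_short_greater=int(np.sum(d > 0)),
                             n_pairs=len(d), degenerate=True)
    t, p = stats.ttest_rel(a, b)
    return PairedTResult(t=float(t), p=float(p),
                         mean_difference=float(d.mean()),
                         n_short_greater=int(np.sum(d > 0)),
                         n_pairs=len(d), degenerate=False)


# ---------------------------------------------------------------------------
# parametric sensitivity
# ---------------------------------------------------------------------------

def sensitivity_index(y_high: float, y_low: float,
                      x_high: float, x_low: float) -> float:
    """Log-log sensitivity of an output to a parameter swept across its
    prior range: decades of output change per decade of parameter change."""
    for v, name in ((y_high, "y_high"), (y_low, "y_low"),
                    (x_high, "x_high"), (x_low, "x_low")):
        if v == 0 or not np.isfinite(v):
            raise ValueError(f"{name} must be nonzero and finite")
    if x_high == x_low:
        raise ValueError("x_high and x_low must differ")
    num = abs(np.log10(abs(y_high)) - np.log10(abs(y_low)))
    den = abs(np.log10(abs(x_high)) - np.log10(abs(x_low)))
    return float(num / den)


def parameter_sensitivity(soil: SoilInit, mp: MicrobialParams,
                          fp: FixedParams, bounds=None,
                          T: float = 20.0) -> pd.DataFrame:
    """Sensitivity of steady-state pools and CO2 efflux to each microbial
    parameter.

    Each parameter in turn is set to the low and high end of its sweep
    range (others at ``mp``); the model is spun up at both settings and the
    log-log index is applied to steady SOC, MBC, DOC and the CO2 efflux.
    The default sweep uses the empirically observed parameter ranges: the
    full search-box extremes include combinations with no steady state
    (growth too slow to offset mortality drives biomass extinct while
    carbon accumulates without bound).
    """
    if bounds is None:
        bounds = OBSERVED_PARAM_RANGES
    rows = []
    for name in PARAM_NAMES:
        lo, hi = bounds[name]
        outputs = {}
        for label, val in (("low", lo), ("high", hi)):
            su = spin_up(soil, replace(mp, **{name: val}), fp, T=T)
            st = su.state
            sp_env = su.env
            outputs[label] = {
                "SOC": st.soc(), "MBC": st.mbc(), "DOC": st.D,
                # at steady state respiration balances the input exactly,
                # so efflux is computed from the pools' respiration terms
                "CO2": sp_env.total_input,
            }
        row = {"parameter": name}
        for var in ("SOC", "MBC", "DOC", "CO2"):
            row[f"SI_{var}"] = sensitivity_index(
                outputs["high"][var], outputs["low"][var], hi, lo)
        rows.append(row)
    return pd.DataFrame(rows).set_index("parameter")


__all__ = [
    "cofi_threshold", "ParameterEnsemble", "feasible_ensemble",
    "ensemble_from_calibration", "kruskal_wallis_compare",
    "PairedTResult", "paired_t_compare", "sensitivity_index",
    "parameter_sensitivity",
]
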