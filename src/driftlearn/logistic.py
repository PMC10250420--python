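"""Accuracy-only baseline: logistic psychometric functions with time-varying
thresholds.

The probability of a rightward response given signed coherence ``x`` (negative
= leftward motion) is

    p(x) = lapse/2 + (1 - lapse) * logistic(x / threshold)

with a fixed 1% lapse.  The threshold (the inverse slope, in coherence units)
evolves on the log scale under one of four candidate dynamics: ``continuous``
(cumulative trial number), ``day_resetting``, ``flexible``, or
``continuous_plus_day_resetting`` — a continuous curve plus a day-resetting
*offset* that decays to zero within each day, identical across days.
Z-scored response times enter as per-subject slopes on the starting and
asymptotic log-threshold of the continuous component, so the baseline sees
the same information as the joint RT+accuracy models, if only crudely.

Fits are Bernoulli maximum likelihood per subject; pointwise log-likelihoods
are retained so the same comparison machinery applies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit

from .dynamics import curve_value, rate_for_t50

__all__ = ["LOGISTIC_DYNAMICS", "LogisticSpec", "psychometric_p",
           "logistic_param_names", "log_threshold_series",
           "fit_logistic_dynamics", "LogisticLearningModel", "LogisticResults",
           "simulate_logistic_choices"]

LOGISTIC_DYNAMICS = ("continuous", "day_resetting", "flexible",
                     "continuous_plus_day_resetting")


@dataclass
class LogisticSpec:
    """Configuration of the logistic threshold-learning model."""

    dynamics: str = "continuous_plus_day_resetting"
    lapse: float = 0.01
    n_days: int = 4
    trials_per_day: int = 700
    rt_slopes: bool = True

    def __post_init__(self):
        if self.dynamics not in LOGISTIC_DYNAMICS:
            raise ValueError(f"dynamics must be one of {LOGISTIC_DYNAMICS}")
        if not 0.0 <= self.lapse <= 0.05:
            raise ValueError("lapse must be in [0, 0.05]")


def psychometric_p(signed_coherence, threshold, lapse: float = 0.01):
    """P(respond 'right') under the lapse-bounded logistic psychometric function."""
    threshold = np.asarray(threshold, dtype=float)
    if np.any(threshold <= 0):
        raise ValueError("threshold must be positive")
    x = np.asarray(signed_coherence, dtype=float)
    out = lapse / 2.0 + (1.0 - lapse) * expit(x / threshold)
    return out if out.ndim else float(out)


def logistic_param_names(spec: LogisticSpec) -> list:
    nd = spec.n_days
    if spec.dynamics in ("continuous", "day_resetting"):
        names = ["log_th_start", "log_th_asym", "rate"]
    elif spec.dynamics == "flexible":
        names = [f"log_th_start_d{d}" for d in range(1, nd + 1)]
        names += [f"log_th_asym_d{d}" for d in range(1, nd + 1)]
        names += ["rate"]
    else:
        names = ["log_th_start", "log_th_asym", "rate",
                 "reset_offset", "reset_rate"]
    if spec.rt_slopes:
        names += ["rt_slope_start", "rt_slope_asym"]
    return names


def log_threshold_series(spec: LogisticSpec, params: dict, day, wtrial, ctrial,
                         z_rt=None):
    """Per-trial log threshold under the given dynamics.

    The learning curve is linear in (start, asymptote), so the z-scored-RT
    adjustment is itself the same curve evaluated at the two slopes.
    """
    day = np.asarray(day, dtype=int)
    wtrial = np.asarray(wtrial, dtype=float)
    ctrial = np.asarray(ctrial, dtype=float)
    g = params.get
    if spec.dynamics == "continuous":
        base = curve_value(ctrial, g("log_th_start"), g("log_th_asym"), g("rate"))
    elif spec.dynamics == "day_resetting":
        base = curve_value(wtrial, g("log_th_start"), g("log_th_asym"), g("rate"))
    elif spec.dynamics == "flexible":
        s = np.asarray([g(f"log_th_start_d{d}") for d in range(1, spec.n_days + 1)])
        a = np.asarray([g(f"log_th_asym_d{d}") for d in range(1, spec.n_days + 1)])
        base = curve_value(wtrial, s[day - 1], a[day - 1], g("rate"))
    else:  # continuous + day-resetting offset decaying to 0 within each day
        base = curve_value(ctrial, g("log_th_start"), g("log_th_asym"), g("rate"))
        base = base + curve_value(wtrial, g("reset_offset"), 0.0, g("reset_rate"))
    if spec.rt_slopes and z_rt is not None:
        n_for_slope = wtrial if spec.dynamics in ("day_resetting", "flexible") else ctrial
        base = base + np.asarray(z_rt, dtype=float) * curve_value(
            n_for_slope, g("rt_slope_start", 0.0), g("rt_slope_asym", 0.0),
            g("rate"))
    return base


def _trial_vectors(table: pd.DataFrame):
    signed = np.where(table["stim_dir"].to_numpy() == "R", 1.0, -1.0) \
        * table["coherence_pct"].to_numpy(dtype=float)
    y = (table["resp_dir"].to_numpy() == "R").astype(float)
    return signed, y


@dataclass
class LogisticResults:
    """Per-subject threshold-dynamics estimates and pointwise log-likelihoods."""

    spec: LogisticSpec
    subject_params: dict
    llf: float
    pointwise: np.ndarray          # (1, n_trials)
    diagnostics: dict
    table: pd.DataFrame = field(repr=False, default=None)
    backend: str = "mle"

    @property
    def model_id(self) -> str:
        return self.spec.dynamics

    @property
    def k_params(self) -> int:
        return len(logistic_param_names(self.spec)) * len(self.subject_params)

    @property
    def nobs(self) -> int:
        return self.pointwise.shape[1]

    @property
    def aic(self) -> float:
        return -2.0 * self.llf + 2.0 * self.k_params

    @property
    def bic(self) -> float:
        return -2.0 * self.llf + self.k_params * np.log(self.nobs)

    def threshold_trajectory(self, subject) -> np.ndarray:
        """Fitted per-trial threshold (coherence units) at zero RT adjustment."""
        spec = self.spec
        ct = np.arange(1, spec.n_days * spec.trials_per_day + 1.0)
        day = ((ct - 1) // spec.trials_per_day + 1).astype(int)
        wt = ct - (day - 1) * spec.trials_per_day
        return np.exp(log_threshold_series(spec, self.subject_params[subject],
                                           day, wt, ct))

    def summary(self) -> str:
        est = pd.DataFrame.from_dict(self.subject_params, orient="index")
        lines = [f"Logistic threshold model ({self.spec.dynamics}); "
                 f"lapse {self.spec.lapse:.2%}",
                 f"subjects: {len(self.subject_params)}   trials: {self.nobs}   "
                 f"free parameters: {self.k_params}",
                 f"log-likelihood: {self.llf:.2f}   BIC: {self.bic:.1f}", "",
                 "Per-subject estimates (mean ± SD):"]
        for col in est.columns:
            lines.append(f"  {col:>16s}: {est[col].mean():8.3f} ± {est[col].std():.3f}")
        return "\n".join(lines)


def fit_logistic_dynamics(table: pd.DataFrame, spec: LogisticSpec,
                          n_restarts: int = 3, seed: int = 0,
                          regularize: bool = True) -> LogisticResults:
    """Bernoulli MLE of the time-varying-threshold psychometric model.

    As with the diffusion fits, the rate parameters carry a unit-SD Gaussian
    ridge centered on the binary log of 25% of the relevant maximum trial
    number (without it, a collapsing time-to-half leaves the starting level
    and its RT slope unidentified), and the z-scored-RT slopes a weak
    normal(0, 0.5) ridge.  The reported log-likelihood is unpenalized.
    """
    names = logistic_param_names(spec)
    rate_centers = {}
    if regularize:
        tmax_main = spec.n_days * spec.trials_per_day \
            if spec.dynamics in ("continuous", "continuous_plus_day_resetting") \
            else spec.trials_per_day
        if "rate" in names:
            rate_centers["rate"] = rate_for_t50(max(0.25 * tmax_main, 3.0))
        if "reset_rate" in names:
            rate_centers["reset_rate"] = rate_for_t50(max(0.25 * spec.trials_per_day, 3.0))
    table = table.reset_index(drop=True)
    params, diags = {}, {}
    pointwise = np.empty(len(table))
    # z-score RTs within subject (covariate only)
    for sid, sdf in table.groupby("subject", sort=True):
        from .fitting import _sid_key
        rng = np.random.default_rng([seed % (2 ** 31), _sid_key(sid)])
        signed, y = _trial_vectors(sdf)
        if y.min() == y.max():
            warnings.warn(f"subject {sid}: all responses identical; fit degenerate")
        rt = sdf["rt_s"].to_numpy(dtype=float)
        z_rt = (rt - rt.mean()) / max(rt.std(), 1e-9)
        day = sdf["day"].to_numpy(dtype=int)
        wt = sdf["trial_in_day"].to_numpy(dtype=float)
        ct = sdf["trial_overall"].to_numpy(dtype=float)

        def raw_nll(vec):
            p = dict(zip(names, vec))
            th = np.exp(np.clip(log_threshold_series(spec, p, day, wt, ct, z_rt),
                                -10, 10))
            prob = psychometric_p(signed, th, spec.lapse)
            ll = np.where(y > 0.5, np.log(prob), np.log1p(-prob))
            return -float(np.sum(ll))

        def nll(vec):
            out = raw_nll(vec)
            p = dict(zip(names, vec))
            for nm, c in rate_centers.items():
                out += 0.5 * (p[nm] - c) ** 2
            if regularize and spec.rt_slopes:
                out += 0.5 * (p["rt_slope_start"] / 0.5) ** 2
                out += 0.5 * (p["rt_slope_asym"] / 0.5) ** 2
            return out

        x0_base = []
        for nm in names:
            if nm.startswith("log_th_start"):
                x0_base.append(np.log(10.0))
            elif nm.startswith("log_th_asym"):
                x0_base.append(np.log(5.0))
            elif nm == "rate":
                tmax = spec.trials_per_day if spec.dynamics != "continuous" \
                    else spec.n_days * spec.trials_per_day
                x0_base.append(rate_for_t50(max(0.25 * tmax, 3.0)))
            elif nm == "reset_offset":
                x0_base.append(0.1)
            elif nm == "reset_rate":
                x0_base.append(rate_for_t50(max(0.15 * spec.trials_per_day, 3.0)))
            else:
                x0_base.append(0.0)
        x0_base = np.asarray(x0_base)
        best = None
        for r in range(max(n_restarts, 1)):
            x0 = x0_base if r == 0 else x0_base + 0.5 * rng.standard_normal(len(names))
            res = minimize(nll, x0, method="L-BFGS-B",
                           options={"maxiter": 500, "ftol": 1e-10})
            if best is None or res.fun < best.fun:
                best = res
        params[sid] = dict(zip(names, best.x))
        diags[sid] = {"converged": bool(best.success or best.fun < 1e9),
                      "nll": float(best.fun)}
        p = params[sid]
        th = np.exp(np.clip(log_threshold_series(spec, p, day, wt, ct, z_rt), -10, 10))
        prob = psychometric_p(signed, th, spec.lapse)
        pointwise[sdf.index.to_numpy()] = np.where(y > 0.5, np.log(prob),
                                                   np.log1p(-prob))
    return LogisticResults(spec=spec, subject_params=params,
                           llf=float(np.sum(pointwise)), pointwise=pointwise[None, :],
                           diagnostics=diags, table=table)


def simulate_logistic_choices(design: pd.DataFrame, truth: dict, spec: LogisticSpec,
                              seed=0, rt_sigma: float = 0.35) -> pd.DataFrame:
    """Generate choices from the psychometric model (lognormal stand-in RTs).

    ``truth`` maps subject id to a parameter dict in the spec's
    parameterization.  RTs carry no choice information here; they exist so the
    z-scored-RT covariate path is exercised.
    """
    rng = np.random.default_rng(seed)
    out = []
    for sid, sdf in design.groupby("subject", sort=True):
        sdf = sdf.sort_values("trial_overall").reset_index(drop=True)
        rt = np.exp(rng.normal(np.log(0.7), rt_sigma, size=len(sdf)))
        z_rt = (rt - rt.mean()) / rt.std()
        day = sdf["day"].to_numpy(dtype=int)
        wt = sdf["trial_in_day"].to_numpy(dtype=float)
        ct = sdf["trial_overall"].to_numpy(dtype=float)
        th = np.exp(log_threshold_series(spec, truth[sid], day, wt, ct, z_rt))
        signed = np.where(sdf["stim_dir"] == "R", 1.0, -1.0) \
            * sdf["coherence_pct"].to_numpy(dtype=float)
        p_right = psychometric_p(signed, th, spec.lapse)
        right = rng.uniform(size=len(sdf)) < p_right
        resp = np.where(right, "R", "L")
        tdf = sdf.copy()
        tdf["group"] = "AVGP"
        tdf["resp_dir"] = resp
        tdf["correct"] = resp == sdf["stim_dir"].to_numpy()
        tdf["rt_s"] = rt
        out.append(tdf)
    from .simulate import TRIAL_COLUMNS
    return pd.concat(out, ignore_index=True)[TRIAL_COLUMNS]


class LogisticLearningModel:
    """statsmodels-style front end for the logistic threshold baseline."""

    def __init__(self, data: pd.DataFrame, dynamics: str = "continuous_plus_day_resetting",
                 *, lapse: float = 0.01, rt_slopes: bool = True):
        days = int(data["day"].max())
        tpd = int(data.groupby(["subject", "day"]).size().max())
        self.spec = LogisticSpec(dynamics=dynamics, lapse=lapse, n_days=days,
                                 trials_per_day=tpd, rt_slopes=rt_slopes)
        self.data = data.reset_index(drop=True)

    @classmethod
    def from_dataframe(cls, data, dynamics="continuous_plus_day_resetting", **kw):
        return cls(data, dynamics, **kw)

    def fit(self, **kwargs) -> LogisticResults:
        return fit_logistic_dynamics(self.data, self.spec, **kwargs)
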