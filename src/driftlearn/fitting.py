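"""Fitting the learning-DDM to trial tables.

The default backend is per-participant maximum likelihood over an
unconstrained transform of the subject parameters (boundary and non-decision
time bounded by construction), with seeded multistart initialization from
shrunk prior draws plus a moment-matching heuristic.  A Bayesian backend
(affine-invariant ensemble MCMC via emcee) samples the same transformed
space under the stated priors and retains per-draw pointwise log-likelihoods
for cross-validated model comparison and bridge sampling.

The user-facing surface follows the statsmodels convention:
``WienerLearningModel(data, "D").fit()`` returns a
:class:`WienerLearningResults` carrying estimates, diagnostics, information
criteria and a ``summary()`` table.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logit

from . import wiener
from .dynamics import TrajectorySpec
from .models import (NDT_FLOOR, ModelSpec, PriorSpec, SubjectParams,
                     parameter_count, per_trial_params)

__all__ = [
    "exclude_trials", "negative_log_likelihood", "fit_mle", "fit_bayes",
    "WienerLearningModel", "WienerLearningResults", "ParamLayout",
]

RT_LOW = 0.16
RT_HIGH = 2.5
_NDT_MARGIN = 1e-4
_MAX_NDT_OFFSET = 1.0


def exclude_trials(table: pd.DataFrame, low: float = RT_LOW, high: float = RT_HIGH):
    """Apply the RT exclusion rule: drop trials strictly below/above the cuts.

    Boundary values are retained.  Returns ``(filtered_table, report)`` where
    the report lists per-subject retained/excluded counts.  Subjects left with
    no trials are flagged with a warning.
    """
    rt = table["rt_s"].to_numpy(dtype=float)
    keep = (rt >= low) & (rt <= high)
    filtered = table.loc[keep].reset_index(drop=True)
    rep = (table.assign(_keep=keep)
           .groupby("subject")["_keep"]
           .agg(n_total="size", n_retained="sum"))
    rep["n_excluded"] = rep["n_total"] - rep["n_retained"]
    empty = rep.index[rep["n_retained"] == 0].tolist()
    if empty:
        warnings.warn(f"subjects with no retained trials after RT exclusion: {empty}")
    return filtered, rep.reset_index()


def _sid_key(sid) -> int:
    """Stable non-negative integer key for any subject-id type."""
    try:
        return int(sid) % (2 ** 31)
    except (TypeError, ValueError):
        return zlib.crc32(str(sid).encode()) % (2 ** 31)


def _table_arrays(table: pd.DataFrame):
    return {
        "day": table["day"].to_numpy(dtype=int),
        "trial_in_day": table["trial_in_day"].to_numpy(dtype=float),
        "trial_overall": table["trial_overall"].to_numpy(dtype=float),
        "coherence_pct": table["coherence_pct"].to_numpy(dtype=float),
    }


def _pointwise_loglik(spec: ModelSpec, subj: SubjectParams, table: pd.DataFrame):
    v, a, z, t0 = per_trial_params(spec, subj, _table_arrays(table))
    rt = table["rt_s"].to_numpy(dtype=float)
    correct = table["correct"].to_numpy(dtype=bool)
    # accuracy coding: upper boundary = correct response
    ll = np.empty(len(table))
    if np.any(correct):
        ll[correct] = wiener.fpt_logdensity(
            rt[correct], "upper", (v[correct], a[correct], z[correct], t0[correct]))
    if np.any(~correct):
        e = ~correct
        ll[e] = wiener.fpt_logdensity(rt[e], "lower", (v[e], a[e], z[e], t0[e]))
    return ll


def negative_log_likelihood(model: ModelSpec, params: dict, table: pd.DataFrame):
    """Joint negative log-likelihood over all subjects in the table.

    ``params`` maps subject id to :class:`SubjectParams`.  Returns
    ``(total_nll, pointwise_loglik)`` with the pointwise vector aligned to the
    table rows; any impossible trial (rt <= t0) makes the total ``+inf``.
    """
    pointwise = np.empty(len(table))
    for sid, sdf in table.groupby("subject", sort=False):
        pointwise[sdf.index.to_numpy()] = _pointwise_loglik(model, params[sid], sdf)
    total = np.inf if np.any(~np.isfinite(pointwise)) else -float(np.sum(pointwise))
    return total, pointwise


# ---------------------------------------------------------------------------
# parameter layout: named unconstrained vector <-> SubjectParams
# ---------------------------------------------------------------------------

class ParamLayout:
    """Per-subject parameter vector for one ModelSpec.

    All entries are unconstrained: drift-scale and log-boundary coefficients
    raw, rates raw, bias on the logit scale, and the NDT offset mapped through
    a scaled sigmoid so that ``0.001 < t0 < min_rt - 1e-4`` by construction
    (the likelihood is -inf beyond the subject's smallest retained RT).
    """

    def __init__(self, spec: ModelSpec):
        self.spec = spec
        nd = spec.n_days
        names: list[str] = []
        if spec.dr_form == "constant":
            names += ["dr_int", "dr_slope"]
        elif spec.dr_form in ("continuous", "day_resetting"):
            names += ["dr_int_start", "dr_int_asym", "dr_slope_start", "dr_slope_asym",
                      "dr_rate"]
        else:
            names += [f"dr_int_start_d{d}" for d in range(1, nd + 1)]
            names += [f"dr_int_asym_d{d}" for d in range(1, nd + 1)]
            names += [f"dr_slope_start_d{d}" for d in range(1, nd + 1)]
            names += [f"dr_slope_asym_d{d}" for d in range(1, nd + 1)]
            names += ["dr_rate"]
        if spec.rb_form == "constant":
            names += ["log_rb"]
        elif spec.rb_form in ("continuous", "day_resetting"):
            names += ["log_rb_start", "log_rb_asym", "rb_rate"]
        else:
            names += [f"log_rb_start_d{d}" for d in range(1, nd + 1)]
            names += [f"log_rb_asym_d{d}" for d in range(1, nd + 1)]
            names += ["rb_rate"]
        names += ["bias_logit", "ndt_u"]
        self.names = names
        self.size = len(names)
        self._idx = {n: i for i, n in enumerate(names)}

    def offset_cap(self, min_rt: float) -> float:
        cap = min(min_rt - NDT_FLOOR - _NDT_MARGIN, _MAX_NDT_OFFSET)
        return max(cap, 0.02)

    def _traj(self, vec, prefix, form, rate_name):
        nd = self.spec.n_days
        g = lambda n: vec[self._idx[n]]
        if form == "constant":
            return TrajectorySpec("constant", g(prefix), n_days=nd)
        if form in ("continuous", "day_resetting"):
            return TrajectorySpec(form, g(f"{prefix}_start"), g(f"{prefix}_asym"),
                                  g(rate_name), n_days=nd)
        starts = [g(f"{prefix}_start_d{d}") for d in range(1, nd + 1)]
        asyms = [g(f"{prefix}_asym_d{d}") for d in range(1, nd + 1)]
        return TrajectorySpec("flexible", starts, asyms, g(rate_name), n_days=nd)

    def unpack(self, vec, min_rt: float) -> SubjectParams:
        vec = np.asarray(vec, dtype=float)
        cap = self.offset_cap(min_rt)
        return SubjectParams(
            dr_intercept=self._traj(vec, "dr_int", self.spec.dr_form, "dr_rate"),
            dr_slope=self._traj(vec, "dr_slope", self.spec.dr_form, "dr_rate"),
            log_rb=self._traj(vec, "log_rb", self.spec.rb_form, "rb_rate"),
            bias_logit=float(vec[self._idx["bias_logit"]]),
            ndt_offset=float(cap * expit(vec[self._idx["ndt_u"]])),
        )

    def pack(self, subj: SubjectParams, min_rt: float) -> np.ndarray:
        cap = self.offset_cap(min_rt)
        vec = np.zeros(self.size)
        nd = self.spec.n_days

        def put(name, val):
            vec[self._idx[name]] = val

        for prefix, traj in (("dr_int", subj.dr_intercept), ("dr_slope", subj.dr_slope),
                             ("log_rb", subj.log_rb)):
            form = self.spec.dr_form if prefix.startswith("dr") else self.spec.rb_form
            rate_name = "dr_rate" if prefix.startswith("dr") else "rb_rate"
            if form == "constant":
                put(prefix, np.mean(traj.starts))
            elif form in ("continuous", "day_resetting"):
                s = np.mean(traj.starts)
                a = np.mean(traj.asymptotes)
                put(f"{prefix}_start", s)
                put(f"{prefix}_asym", a)
                put(rate_name, traj.rate)
            else:
                s = np.broadcast_to(np.atleast_1d(traj.starts), (nd,))
                a = np.broadcast_to(np.atleast_1d(traj.asymptotes), (nd,))
                for d in range(1, nd + 1):
                    put(f"{prefix}_start_d{d}", s[d - 1])
                    put(f"{prefix}_asym_d{d}", a[d - 1])
                put(rate_name, traj.rate)
        put("bias_logit", subj.bias_logit)
        frac = np.clip(subj.ndt_offset / cap, 1e-6, 1 - 1e-6)
        put("ndt_u", logit(frac))
        return vec

    # -- priors over the unconstrained vector (with the NDT Jacobian) -------

    def _natural_name(self, name: str) -> str:
        return "ndt_offset" if name == "ndt_u" else name.split("_d")[0] \
            if name.split("_d")[-1].isdigit() else name

    def prior_logpdf(self, vec, prior: PriorSpec, min_rt: float) -> float:
        vec = np.asarray(vec, dtype=float)
        cap = self.offset_cap(min_rt)
        lp = 0.0
        for i, name in enumerate(self.names):
            if name == "ndt_u":
                s = expit(vec[i])
                offset = cap * s
                lp += prior.dist_for("ndt_offset", self.spec).logpdf(offset)
                lp += np.log(cap) + np.log(s) + np.log1p(-s)  # Jacobian
            else:
                lp += prior.dist_for(self._natural_name(name), self.spec).logpdf(vec[i])
        return float(lp)

    def draw_init(self, rng, prior: PriorSpec, min_rt: float, shrink: float = 0.25):
        """Seeded initialization draw from scale-shrunk priors."""
        vec = np.zeros(self.size)
        for i, name in enumerate(self.names):
            if name == "ndt_u":
                offset = min(rng.exponential(prior.ndt_mean), 0.9 * self.offset_cap(min_rt))
                frac = np.clip(offset / self.offset_cap(min_rt), 1e-5, 1 - 1e-5)
                vec[i] = logit(frac)
                continue
            dist = prior.dist_for(self._natural_name(name), self.spec)
            loc = dist.mean() if np.isfinite(dist.mean()) else dist.median()
            scale = dist.std() if np.isfinite(dist.std()) else 1.0
            vec[i] = loc + shrink * scale * rng.standard_normal()
        return vec


# ---------------------------------------------------------------------------
# batched objective: vectorized NLL over a batch of parameter vectors
# ---------------------------------------------------------------------------

class _SubjectObjective:
    """Per-subject negative log-likelihood with batched evaluation.

    Evaluates the NLL for a (B, d) batch of unconstrained vectors in one
    vectorized pass, which makes finite-difference gradients cost a couple of
    likelihood evaluations instead of d+1.  Rate parameters optionally carry
    a Gaussian ridge centered on the rate priors: without it the likelihood
    has a flat ridge (time-to-half pushed beyond the design length leaves the
    asymptote unconstrained), the classic identifiability failure of
    exponential learning curves on finite designs.
    """

    def __init__(self, spec: ModelSpec, layout: ParamLayout, sdf: pd.DataFrame,
                 prior: PriorSpec, regularize_rates: bool = True):
        self.spec = spec
        self.layout = layout
        self.min_rt = float(sdf["rt_s"].min())
        self.cap = layout.offset_cap(self.min_rt)
        self.rt = sdf["rt_s"].to_numpy(dtype=float)
        self.correct = sdf["correct"].to_numpy(dtype=bool)
        self.day = sdf["day"].to_numpy(dtype=int)
        self.wtrial = sdf["trial_in_day"].to_numpy(dtype=float)
        self.ctrial = sdf["trial_overall"].to_numpy(dtype=float)
        self.x = spec.coherence_covariate(sdf["coherence_pct"].to_numpy(dtype=float))
        idx = layout._idx
        self._i = idx
        self.rate_penalty = []
        if regularize_rates:
            for name in ("dr_rate", "rb_rate"):
                if name in idx:
                    d = prior.dist_for(name, spec)
                    self.rate_penalty.append((idx[name], float(d.mean()), float(d.std())))

    def _traj_batch(self, vecs, prefix, form, rate_name, n):
        """(B, n) per-trial trajectory values for one coefficient family."""
        i = self._i
        if form == "constant":
            return np.broadcast_to(vecs[:, i[prefix]][:, None], (len(vecs), n)).copy()
        if form in ("continuous", "day_resetting"):
            s = vecs[:, i[f"{prefix}_start"]][:, None]
            a = vecs[:, i[f"{prefix}_asym"]][:, None]
            r = vecs[:, i[rate_name]][:, None]
            trial = self.ctrial if form == "continuous" else self.wtrial
            return a + (s - a) * np.exp2((1.0 - trial[None, :]) / (2.0 + np.exp2(r)))
        nd = self.spec.n_days
        s_mat = vecs[:, [i[f"{prefix}_start_d{d}"] for d in range(1, nd + 1)]]
        a_mat = vecs[:, [i[f"{prefix}_asym_d{d}"] for d in range(1, nd + 1)]]
        s = s_mat[:, self.day - 1]
        a = a_mat[:, self.day - 1]
        r = vecs[:, i[rate_name]][:, None]
        return a + (s - a) * np.exp2((1.0 - self.wtrial[None, :]) / (2.0 + np.exp2(r)))

    def pointwise_batch(self, vecs):
        """(B, n) pointwise log-likelihoods."""
        vecs = np.atleast_2d(np.asarray(vecs, dtype=float))
        n = len(self.rt)
        spec = self.spec
        dr0 = self._traj_batch(vecs, "dr_int", spec.dr_form, "dr_rate", n)
        dr1 = self._traj_batch(vecs, "dr_slope", spec.dr_form, "dr_rate", n)
        v = dr0 + dr1 * self.x[None, :]
        a = np.exp(np.clip(self._traj_batch(vecs, "log_rb", spec.rb_form, "rb_rate", n),
                           -5.0, 5.0))
        z = expit(vecs[:, self._i["bias_logit"]])[:, None]
        t0 = NDT_FLOOR + self.cap * expit(vecs[:, self._i["ndt_u"]])[:, None]
        z = np.broadcast_to(z, v.shape)
        t0 = np.broadcast_to(t0, v.shape)
        ll = np.empty_like(v)
        c = self.correct
        with np.errstate(over="ignore", invalid="ignore"):
            if np.any(c):
                ll[:, c] = wiener.fpt_logdensity(
                    self.rt[None, c], "upper", (v[:, c], a[:, c], z[:, c], t0[:, c]))
            if np.any(~c):
                e = ~c
                ll[:, e] = wiener.fpt_logdensity(
                    self.rt[None, e], "lower", (v[:, e], a[:, e], z[:, e], t0[:, e]))
        return ll

    def _penalty(self, vecs):
        pen = np.zeros(len(vecs))
        for j, mu, sd in self.rate_penalty:
            pen += 0.5 * ((vecs[:, j] - mu) / sd) ** 2
        return pen

    def nll_batch(self, vecs, penalized: bool = True):
        vecs = np.atleast_2d(np.asarray(vecs, dtype=float))
        ll = self.pointwise_batch(vecs)
        total = np.sum(ll, axis=1)
        out = np.where(np.isfinite(total), -total, 1e10)
        if penalized:
            out = out + self._penalty(vecs)
        return out

    def nll(self, vec, penalized: bool = True) -> float:
        return float(self.nll_batch(vec[None, :], penalized)[0])

    def grad(self, vec):
        vec = np.asarray(vec, dtype=float)
        h = 1e-6 * np.maximum(1.0, np.abs(vec))
        batch = np.vstack([vec[None, :], vec[None, :] + np.diag(h)])
        f = self.nll_batch(batch)
        return (f[1:] - f[0]) / h


# ---------------------------------------------------------------------------
# heuristic initialization (closed-form moment matching per subject)
# ---------------------------------------------------------------------------

def _ez_moments(acc, rt_mean, rt_var):
    """Rough (v, a, mean-decision-time) from accuracy and RT moments.

    Closed-form moment inversion of the constant-parameter unbiased DDM
    (the classic "EZ" equations); used only to seed the optimizer.
    """
    p = float(np.clip(acc, 0.55, 0.98))
    L = np.log(p / (1 - p))
    x = L * (L * p ** 2 - L * p + p - 0.5) / max(rt_var, 1e-4)
    v = np.sign(p - 0.5) * x ** 0.25
    a = L / v
    mdt = (a / (2 * v)) * (1 - np.exp(-v * a)) / (1 + np.exp(-v * a))
    return v, a, mdt


def _heuristic_start(layout: ParamLayout, prior: PriorSpec, sdf: pd.DataFrame,
                     min_rt: float) -> np.ndarray:
    spec = layout.spec
    cov = spec.coherence_covariate(sdf["coherence_pct"].to_numpy(dtype=float))
    hi = cov >= np.median(cov)
    vs, covs = [], []
    for m in (hi, ~hi):
        if m.sum() < 10:
            continue
        v, a, mdt = _ez_moments(sdf.loc[m, "correct"].mean(),
                                sdf.loc[m, "rt_s"].mean(),
                                sdf.loc[m, "rt_s"].var())
        vs.append(v)
        covs.append(cov[m].mean())
    _, a_all, mdt_all = _ez_moments(sdf["correct"].mean(), sdf["rt_s"].mean(),
                                    sdf["rt_s"].var())
    if len(vs) == 2 and covs[0] != covs[1]:
        slope = (vs[0] - vs[1]) / (covs[0] - covs[1])
        slope = float(np.clip(slope, 1e-3, 1.0))
        inter = vs[0] - slope * covs[0]
    else:
        inter, slope = 0.7, 0.05
    a_all = float(np.clip(a_all, 0.5, 4.0))
    t0 = float(np.clip(sdf["rt_s"].mean() - mdt_all, NDT_FLOOR + 0.01, min_rt - 0.02))

    vec = layout.draw_init(np.random.default_rng(0), prior, min_rt, shrink=0.0)
    for i, name in enumerate(layout.names):
        if name.startswith("dr_int"):
            vec[i] = inter
        elif name.startswith("dr_slope"):
            vec[i] = slope
        elif name.startswith("log_rb"):
            vec[i] = np.log(a_all)
        elif name == "bias_logit":
            vec[i] = 0.0
        elif name == "ndt_u":
            cap = layout.offset_cap(min_rt)
            frac = np.clip((t0 - NDT_FLOOR) / cap, 1e-5, 1 - 1e-5)
            vec[i] = logit(frac)
    return vec


# ---------------------------------------------------------------------------
# results container
# ---------------------------------------------------------------------------

@dataclass
class WienerLearningResults:
    """Estimates, pointwise log-likelihoods and diagnostics for one model fit."""

    spec: ModelSpec
    backend: str                      # "mle" | "bayes"
    subject_params: dict              # subject id -> SubjectParams (point estimates)
    llf: float                        # total log-likelihood at the point estimates
    pointwise: np.ndarray             # (draws, n_trials); single row for MLE
    diagnostics: dict
    seed: object
    table: pd.DataFrame = field(repr=False, default=None)
    draws: dict = field(repr=False, default=None)          # subject -> (n, d) draws
    log_post_fns: dict = field(repr=False, default=None)   # subject -> callable
    param_names: list = field(default=None)
    standard_errors: dict = field(default=None)            # subject -> dict name -> se

    @property
    def model_id(self) -> str:
        return self.spec.model_id

    @property
    def nobs(self) -> int:
        return self.pointwise.shape[1]

    @property
    def k_params(self) -> int:
        return parameter_count(self.spec, n_subjects=len(self.subject_params))

    @property
    def aic(self) -> float:
        return -2.0 * self.llf + 2.0 * self.k_params

    @property
    def bic(self) -> float:
        return -2.0 * self.llf + self.k_params * np.log(self.nobs)

    @property
    def converged(self) -> bool:
        return all(d.get("converged", True) for d in self.diagnostics.values()
                   if isinstance(d, dict))

    def natural_estimates(self) -> pd.DataFrame:
        """Per-subject point estimates on their link scales, one row a subject."""
        layout = ParamLayout(self.spec)
        rows = {}
        for sid, subj in self.subject_params.items():
            vec = layout.pack(subj, min_rt=np.inf)
            row = dict(zip(layout.names, vec))
            row["ndt_offset"] = subj.ndt_offset
            row.pop("ndt_u", None)
            rows[sid] = row
        return pd.DataFrame.from_dict(rows, orient="index").rename_axis("subject")

    def predict(self, table: pd.DataFrame | None = None) -> pd.DataFrame:
        """Per-trial predicted accuracy and mean RT at the point estimates."""
        table = self.table if table is None else table
        out = []
        for sid, sdf in table.groupby("subject", sort=False):
            v, a, z, t0 = per_trial_params(self.spec, self.subject_params[sid],
                                           _table_arrays(sdf))
            p_corr = np.asarray(wiener.choice_probability((v, a, z, t0)))
            mrt = np.asarray(wiener.mean_decision_time((v, a, z, t0))) + t0
            out.append(pd.DataFrame({"pred_accuracy": p_corr, "pred_rt_s": mrt},
                                    index=sdf.index))
        return pd.concat(out).sort_index()

    def simulate(self, seed=0, design: pd.DataFrame | None = None) -> pd.DataFrame:
        """Forward-simulate a dataset at the fitted point estimates."""
        from .simulate import GroundTruth, simulate_trials
        design = self.table if design is None else design
        truth = GroundTruth(self.subject_params,
                            {s: "AVGP" for s in self.subject_params}, 0.0, (0.05, 3.0))
        return simulate_trials(design, truth, self.spec, seed=seed)

    def plot_trajectories(self, ax=None, parameter: str = "dr"):
        """Fitted per-trial trajectories (drift at median coherence, or boundary)."""
        import matplotlib.pyplot as plt
        from .dynamics import trajectory
        if ax is None:
            _, ax = plt.subplots()
        nd, tpd = self.spec.n_days, self.spec.trials_per_day
        ctrial = np.arange(1, nd * tpd + 1.0)
        day = ((ctrial - 1) // tpd + 1).astype(int)
        wtrial = ctrial - (day - 1) * tpd
        for sid, subj in self.subject_params.items():
            traj = subj.dr_intercept if parameter == "dr" else subj.log_rb
            y = trajectory(traj, day, wtrial, ctrial)
            if parameter != "dr":
                y = np.exp(y)
            ax.plot(ctrial, y, lw=0.8, alpha=0.7, label=f"s{sid}")
        ax.set_xlabel("cumulative trial")
        ax.set_ylabel("drift rate (median coherence)" if parameter == "dr"
                      else "boundary separation")
        return ax

    def summary(self) -> str:
        est = self.natural_estimates()
        lines = [
            f"Wiener learning model {self.model_id} "
            f"(DR {self.spec.dr_form}, RB {self.spec.rb_form}) — backend: {self.backend}",
            f"subjects: {len(self.subject_params)}   trials: {self.nobs}   "
            f"free parameters: {self.k_params}",
            f"log-likelihood: {self.llf:.2f}   AIC: {self.aic:.1f}   BIC: {self.bic:.1f}",
            f"converged: {self.converged}",
            "",
            "Per-subject estimates (link scales; mean ± between-subject SD):",
        ]
        for col in est.columns:
            lines.append(f"  {col:>18s}: {est[col].mean():8.3f} ± {est[col].std():.3f}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# MLE backend
# ---------------------------------------------------------------------------

def _fit_subject_mle(spec, layout, prior, sdf, n_restarts, rng, tolerance,
                     init_vec=None, maxiter=600, regularize_rates=True):
    obj = _SubjectObjective(spec, layout, sdf, prior, regularize_rates)
    min_rt = obj.min_rt

    candidates = [_heuristic_start(layout, prior, sdf, min_rt)]
    if init_vec is not None:
        candidates.append(np.asarray(init_vec, dtype=float))
    while len(candidates) < max(n_restarts, 2) + 4:
        candidates.append(layout.draw_init(rng, prior, min_rt))
    scores = obj.nll_batch(np.vstack(candidates))
    order = np.argsort(scores, kind="stable")[:max(n_restarts, 1)]

    best = None
    for oi in order:
        res = minimize(obj.nll, candidates[oi], jac=obj.grad, method="L-BFGS-B",
                       options={"maxiter": maxiter, "ftol": tolerance, "gtol": 1e-7})
        if best is None or res.fun < best.fun:
            best = res
    converged = bool(best is not None and best.fun < 1e9)
    if not converged:
        warnings.warn(f"no restart converged for subject {sdf['subject'].iloc[0]}")
    subj = layout.unpack(best.x, min_rt)
    diag = {"converged": converged, "nll": float(obj.nll(best.x, penalized=False)),
            "n_restarts": len(order), "n_iter": int(best.nit), "min_rt": min_rt,
            "vec": best.x.copy()}
    return subj, diag


def fit_mle(model: ModelSpec, table: pd.DataFrame, n_restarts: int = 10, seed=0,
            tolerance: float = 1e-8, init: dict | None = None,
            maxiter: int = 600, regularize_rates: bool = True,
            shrinkage: float | None = None) -> WienerLearningResults:
    """Per-participant maximum likelihood fit of one candidate model.

    ``init`` optionally maps subject ids to :class:`SubjectParams` used as a
    warm start (for example a constant-model fit seeding a dynamic model).
    ``shrinkage`` (a penalty SD in unconstrained-parameter units) enables a
    second pass that re-fits each subject with a Gaussian pull toward the
    first-pass group means — a light-weight stand-in for a hierarchical
    model.  Deterministic under ``seed``.
    """
    layout = ParamLayout(model)
    prior = PriorSpec()
    params, diags = {}, {}
    table = table.reset_index(drop=True)
    for sid, sdf in table.groupby("subject", sort=True):
        if len(sdf) < 50:
            warnings.warn(f"subject {sid}: only {len(sdf)} trials; estimates unstable")
        rng = np.random.default_rng([int(seed) % (2 ** 31), _sid_key(sid)])
        init_vec = None
        if init is not None and sid in init:
            init_vec = layout.pack(init[sid], float(sdf["rt_s"].min()))
        params[sid], diags[sid] = _fit_subject_mle(
            model, layout, prior, sdf, n_restarts, rng, tolerance, init_vec, maxiter,
            regularize_rates)
    if shrinkage is not None:
        center = np.mean([diags[s]["vec"] for s in diags], axis=0)
        for sid, sdf in table.groupby("subject", sort=True):
            obj = _SubjectObjective(model, layout, sdf, prior, regularize_rates)

            def pen_nll(vec, _o=obj):
                return _o.nll(vec) + 0.5 * float(np.sum(((vec - center) / shrinkage) ** 2))

            res = minimize(pen_nll, diags[sid]["vec"], method="L-BFGS-B",
                           options={"maxiter": maxiter, "ftol": tolerance})
            params[sid] = layout.unpack(res.x, obj.min_rt)
            diags[sid]["vec"] = res.x.copy()
            diags[sid]["shrunk"] = True
    total, pointwise = negative_log_likelihood(model, params, table)
    return WienerLearningResults(
        spec=model, backend="mle", subject_params=params, llf=-total,
        pointwise=pointwise[None, :], diagnostics=diags, seed=seed, table=table,
        param_names=layout.names)


# ---------------------------------------------------------------------------
# Bayesian backend (emcee ensemble sampler)
# ---------------------------------------------------------------------------

def fit_bayes(model: ModelSpec, table: pd.DataFrame, prior: PriorSpec | None = None,
              draws: int = 500, warmup: int = 500, chains: int | None = None,
              seed=0, thin: int = 2, progress: bool = False) -> WienerLearningResults:
    """Posterior sampling of the per-subject parameters under the stated priors.

    Uses an affine-invariant ensemble sampler (emcee) over the unconstrained
    transform; walkers double as chains for R-hat / ESS diagnostics (the
    convergence bar is R-hat < 1.03 and tail ESS of a few hundred).  An empty
    table yields a prior-only run.  Pointwise log-likelihoods are retained per
    kept draw.
    """
    import arviz as az
    import emcee

    prior = prior or PriorSpec()
    layout = ParamLayout(model)
    table = table.reset_index(drop=True)
    groups = list(table.groupby("subject", sort=True)) if len(table) else [(0, table)]

    params, diags, all_draws, log_posts = {}, {}, {}, {}
    pointwise_blocks = {}
    n_keep = None
    for gi, (sid, sdf) in enumerate(groups):
        min_rt = float(sdf["rt_s"].min()) if len(sdf) else np.inf
        arrays = _table_arrays(sdf) if len(sdf) else None
        rt = sdf["rt_s"].to_numpy(dtype=float)
        correct = sdf["correct"].to_numpy(dtype=bool)

        def loglik_vec(vec):
            if arrays is None:
                return np.zeros(0)
            subj = layout.unpack(vec, min_rt)
            v, a, z, t0 = per_trial_params(model, subj, arrays)
            ll = np.empty(len(rt))
            with np.errstate(over="ignore"):
                ll[correct] = wiener.fpt_logdensity(
                    rt[correct], "upper", (v[correct], a[correct], z[correct], t0[correct]))
                ll[~correct] = wiener.fpt_logdensity(
                    rt[~correct], "lower", (v[~correct], a[~correct], z[~correct], t0[~correct]))
            return ll

        def log_post(vec, _ll=loglik_vec, _mr=min_rt):
            lp = layout.prior_logpdf(vec, prior, _mr)
            if not np.isfinite(lp):
                return -np.inf
            ll = np.sum(_ll(vec))
            return lp + ll if np.isfinite(ll) else -np.inf

        ndim = layout.size
        nwalk = chains or max(2 * ndim + 2, 12)
        rng = np.random.default_rng([int(seed) % (2 ** 31), gi])
        if len(sdf):
            center, _ = _fit_subject_mle(model, layout, prior, sdf, 2, rng, 1e-8,
                                         maxiter=300)
            c_vec = layout.pack(center, min_rt)
        else:
            c_vec = layout.draw_init(rng, prior, min_rt, shrink=0.0)
        p0 = c_vec + 0.05 * rng.standard_normal((nwalk, ndim))
        sampler = emcee.EnsembleSampler(nwalk, ndim, log_post)
        rs = np.random.RandomState((int(seed) % (2 ** 31)) * 1000 + gi)
        state0 = emcee.State(p0, random_state=rs.get_state())
        state = sampler.run_mcmc(state0, warmup, progress=progress)
        sampler.reset()
        sampler.run_mcmc(state, draws, progress=progress)
        chain = sampler.get_chain()              # (draws, walkers, ndim)
        kept = chain[::thin]                     # (kept, walkers, ndim)
        flat = kept.reshape(-1, ndim)
        idata = az.from_dict(posterior={
            n: np.moveaxis(kept[:, :, i], 0, 1) for i, n in enumerate(layout.names)})
        rhat = az.rhat(idata).to_array().to_numpy()
        ess_tail = az.ess(idata, method="tail").to_array().to_numpy()
        med_vec = np.median(flat, axis=0)
        params[sid] = layout.unpack(med_vec, min_rt)
        diags[sid] = {
            "rhat_max": float(np.nanmax(rhat)),
            "ess_tail_min": float(np.nanmin(ess_tail)),
            "acceptance": float(np.mean(sampler.acceptance_fraction)),
            "converged": bool(np.nanmax(rhat) < 1.03),
            "min_rt": min_rt,
        }
        if not diags[sid]["converged"]:
            warnings.warn(f"subject {sid}: R-hat {diags[sid]['rhat_max']:.3f} >= 1.03")
        all_draws[sid] = flat
        log_posts[sid] = log_post
        if len(sdf):
            block = np.stack([loglik_vec(vec) for vec in flat])
            pointwise_blocks[sid] = (sdf.index.to_numpy(), block)
            n_keep = block.shape[0]

    if pointwise_blocks:
        pointwise = np.empty((n_keep, len(table)))
        for idx, block in pointwise_blocks.values():
            pointwise[:, idx] = block
    else:  # prior-only run
        pointwise = np.zeros((next(iter(all_draws.values())).shape[0], 0))
    total, _ = (negative_log_likelihood(model, params, table)
                if len(table) else (0.0, np.zeros(0)))
    return WienerLearningResults(
        spec=model, backend="bayes", subject_params=params, llf=-total,
        pointwise=pointwise, diagnostics=diags, seed=seed, table=table,
        draws=all_draws, log_post_fns=log_posts, param_names=layout.names)


# ---------------------------------------------------------------------------
# statsmodels-style front end
# ---------------------------------------------------------------------------

class WienerLearningModel:
    """Learning-DDM for a trial-level table.

    Parameters
    ----------
    data : DataFrame
        Trial table with the canonical columns (``subject``, ``day``,
        ``trial_in_day``, ``trial_overall``, ``coherence_pct``, ``correct``,
        ``rt_s``; ``group`` optional).
    model : str or ModelSpec
        Candidate model id ``"A"``–``"F"`` or a full :class:`ModelSpec`.
    exclude : bool
        Apply the RT exclusion rule (retain 0.16 s <= rt <= 2.5 s) on input.
    """

    def __init__(self, data: pd.DataFrame, model="D", *, exclude: bool = True,
                 rt_low: float = RT_LOW, rt_high: float = RT_HIGH, **spec_kwargs):
        if isinstance(model, ModelSpec):
            self.spec = model
        else:
            days = int(data["day"].max()) if len(data) else 4
            tpd = int(data.groupby(["subject", "day"]).size().max()) if len(data) else 700
            self.spec = ModelSpec(model, n_days=days,
                                  trials_per_day=spec_kwargs.pop("trials_per_day", tpd),
                                  **spec_kwargs)
        if exclude and len(data):
            self.data, self.exclusion_report = exclude_trials(data, rt_low, rt_high)
        else:
            self.data, self.exclusion_report = data.reset_index(drop=True), None

    @classmethod
    def from_dataframe(cls, data, model="D", **kwargs):
        return cls(data, model, **kwargs)

    @classmethod
    def from_csv(cls, path, model="D", **kwargs):
        from .simulate import read_trials_csv
        return cls(read_trials_csv(path), model, **kwargs)

    def loglike(self, params: dict) -> float:
        total, _ = negative_log_likelihood(self.spec, params, self.data)
        return -total

    def fit(self, method: str = "mle", **kwargs) -> WienerLearningResults:
        if method == "mle":
            return fit_mle(self.spec, self.data, **kwargs)
        if method == "bayes":
            return fit_bayes(self.spec, self.data, **kwargs)
        raise ValueError("method must be 'mle' or 'bayes'")
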