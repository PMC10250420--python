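"""Seeded validation experiments: parameter recovery, model recovery, and
closed-form conjugate benchmarks for the comparison machinery.

These are the package's own calibration studies — scaled-down analogues of
the multi-day training design that check, from known ground truth, that the
estimation and model-comparison machinery does what it claims.  Problem
sizes are chosen to run on one desktop CPU in minutes: the recovery study
uses 12 subjects x 4 days x 196 trials (7 coherence levels x 28) and the
model-recovery study 8 subjects x 4 days x 98 trials, with learning
time-constants rescaled proportionally to design length.  Ground truth for
parameter recovery sits at the reference fixed-effect estimates (drift start
0.44, asymptote mean ~0.96, time-to-half 1261 trials on the 2800-trial
scale, between-subject change N(0.516, 0.175)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .compare import bridge_sample_logml, compare, psis_loo
from .fitting import exclude_trials, fit_mle
from .models import ModelSpec, embed_subject_params
from .simulate import PopulationConfig, generate_design, sample_ground_truth, simulate_trials

__all__ = [
    "recovery_experiment", "model_selection_experiment",
    "conjugate_loo_benchmark", "conjugate_bridge_benchmark",
    "logistic_recovery_experiment",
]

_CLEAN = PopulationConfig(contaminant_rate=0.0)


def _fit_pair(filtered, model_ids, n_days, trials_per_day, seed, n_restarts=2):
    """Fit several models, warm-starting dynamic models from the constant fit."""
    spec_a = ModelSpec("A", n_days=n_days, trials_per_day=trials_per_day)
    base = fit_mle(spec_a, filtered, n_restarts=n_restarts, seed=seed)
    fits = []
    for mid in model_ids:
        if mid == "A":
            fits.append(base)
            continue
        spec = ModelSpec(mid, n_days=n_days, trials_per_day=trials_per_day)
        init = {sid: embed_subject_params(p, spec)
                for sid, p in base.subject_params.items()}
        fits.append(fit_mle(spec, filtered, n_restarts=n_restarts, seed=seed,
                            init=init))
    return fits


@dataclass
class RecoveryResult:
    r_dr_asymptote: float
    dr_start_mean_true: float
    dr_start_mean_est: float
    dr_asym_mean_true: float
    dr_asym_mean_est: float
    n_trials: int
    n_subjects: int

    @property
    def start_rel_err(self) -> float:
        return abs(self.dr_start_mean_est - self.dr_start_mean_true) \
            / abs(self.dr_start_mean_true)

    @property
    def asym_rel_err(self) -> float:
        return abs(self.dr_asym_mean_est - self.dr_asym_mean_true) \
            / abs(self.dr_asym_mean_true)


def recovery_experiment(seed=0, n_subjects=12, n_days=4, per_level=28,
                        n_restarts=2) -> RecoveryResult:
    """Simulate under the winning model (continuous DR, flexible RB) and refit.

    Measures how well per-subject drift asymptotes (at the median coherence)
    and the group-mean start/asymptote are recovered by per-subject fits.
    """
    tpd = per_level * 7
    spec = ModelSpec("D", n_days=n_days, trials_per_day=tpd)
    design = generate_design(n_subjects, n_days, tpd, per_level=per_level, seed=seed)
    truth = sample_ground_truth(spec, n_subjects, seed=seed + 1, config=_CLEAN)
    table = simulate_trials(design, truth, spec, seed=seed + 2)
    filtered, _ = exclude_trials(table)
    fits = _fit_pair(filtered, ["D"], n_days, tpd, seed, n_restarts)
    est = fits[0].natural_estimates()
    true_start = np.array([truth.subjects[s].dr_intercept.starts for s in est.index])
    true_asym = np.array([truth.subjects[s].dr_intercept.asymptotes for s in est.index])
    est_start = est["dr_int_start"].to_numpy()
    est_asym = est["dr_int_asym"].to_numpy()
    r = float(stats.pearsonr(true_asym, est_asym).statistic)
    return RecoveryResult(
        r_dr_asymptote=r,
        dr_start_mean_true=float(true_start.mean()),
        dr_start_mean_est=float(est_start.mean()),
        dr_asym_mean_true=float(true_asym.mean()),
        dr_asym_mean_est=float(est_asym.mean()),
        n_trials=len(filtered), n_subjects=n_subjects)


def model_selection_experiment(seed=0, n_replicates=10, n_subjects=8, per_level=14,
                               n_days=4, candidates=("A", "D"), n_restarts=2):
    """Generate under each candidate in turn; count correct criterion picks.

    Returns ``{generating_id: n_correct}`` over ``n_replicates`` seeded
    replicates per condition.
    """
    tpd = per_level * 7
    wins = {}
    for gen_id in candidates:
        spec_gen = ModelSpec(gen_id, n_days=n_days, trials_per_day=tpd)
        n_correct = 0
        for rep in range(n_replicates):
            s = (seed + 1) * 10_000 + rep * 97 + ord(gen_id)
            design = generate_design(n_subjects, n_days, tpd, per_level=per_level,
                                     seed=s)
            truth = sample_ground_truth(spec_gen, n_subjects, seed=s + 1,
                                        config=_CLEAN)
            table = simulate_trials(design, truth, spec_gen, seed=s + 2)
            filtered, _ = exclude_trials(table)
            fits = _fit_pair(filtered, list(candidates), n_days, tpd, s, n_restarts)
            comp = compare(fits)
            if comp.table.iloc[0]["model"] == gen_id:
                n_correct += 1
        wins[gen_id] = n_correct
    return wins


# ---------------------------------------------------------------------------
# conjugate-normal benchmarks (analytic oracles for LOO and bridge sampling)
# ---------------------------------------------------------------------------

def _conjugate_posterior(y, sigma, mu0, tau0):
    n = len(y)
    prec = 1.0 / tau0 ** 2 + n / sigma ** 2
    var = 1.0 / prec
    mean = var * (mu0 / tau0 ** 2 + np.sum(y) / sigma ** 2)
    return mean, np.sqrt(var)


def conjugate_loo_benchmark(seed=0, n=20, n_draws=4000, sigma=1.0, mu0=0.0, tau0=2.0):
    """PSIS-LOO vs brute-force exact LOO on a normal-mean conjugate model.

    Exact LOO refits the posterior n times (closed form) and evaluates the
    posterior-predictive density of each held-out point.  Returns a dict with
    both elpds and their absolute difference.
    """
    rng = np.random.default_rng(seed)
    y = rng.normal(0.7, sigma, size=n)
    mean, sd = _conjugate_posterior(y, sigma, mu0, tau0)
    draws = rng.normal(mean, sd, size=n_draws)
    pointwise = stats.norm.logpdf(y[None, :], loc=draws[:, None], scale=sigma)
    loo = psis_loo(pointwise)
    exact = 0.0
    for i in range(n):
        m_i, s_i = _conjugate_posterior(np.delete(y, i), sigma, mu0, tau0)
        exact += stats.norm.logpdf(y[i], loc=m_i, scale=np.sqrt(s_i ** 2 + sigma ** 2))
    return {"elpd_psis": loo.elpd, "elpd_exact": float(exact),
            "abs_diff": abs(loo.elpd - float(exact)), "looic": loo.looic,
            "pareto_k_max": float(np.max(loo.pareto_k)), "n": n}


def _log_marginal_normal(y, sigma, mu0, tau0):
    """Analytic log marginal likelihood of the normal-mean conjugate model."""
    n = len(y)
    cov = sigma ** 2 * np.eye(n) + tau0 ** 2 * np.ones((n, n))
    return float(stats.multivariate_normal.logpdf(y, mean=np.full(n, mu0), cov=cov))


def conjugate_bridge_benchmark(seed=0, n=25, n_draws=4000, n_runs=15,
                               sigma=1.0, tau0_a=2.0, tau0_b=0.5):
    """Bridge-sampled log3 Bayes factor vs the analytic value on a conjugate pair.

    Two models for the same data differing only in prior width; both marginal
    likelihoods are available in closed form.  Also runs a self-comparison
    (identical models), whose log3 BF should sit at 0 within run spread.
    """
    rng = np.random.default_rng(seed)
    y = rng.normal(0.4, sigma, size=n)
    sy, ssy = float(np.sum(y)), float(np.sum(y ** 2))
    results = {}
    per_model = {}
    for tag, tau0 in (("a", tau0_a), ("b", tau0_b)):
        mean, sd = _conjugate_posterior(y, sigma, 0.0, tau0)
        draws = rng.normal(mean, sd, size=(n_draws, 1))

        def log_post(theta, _tau0=tau0):
            th = float(np.asarray(theta).ravel()[0])
            loglik = -0.5 * n * np.log(2 * np.pi * sigma ** 2) \
                - (ssy - 2 * th * sy + n * th ** 2) / (2 * sigma ** 2)
            logprior = -0.5 * np.log(2 * np.pi * _tau0 ** 2) \
                - th ** 2 / (2 * _tau0 ** 2)
            return loglik + logprior

        per_model[tag] = (draws, log_post)
        results[f"logml_exact_{tag}"] = _log_marginal_normal(y, sigma, 0.0, tau0)
    runs = []
    for r in range(n_runs):
        la = bridge_sample_logml(*per_model["a"], seed=seed + 31 * r + 1)
        lb = bridge_sample_logml(*per_model["b"], seed=seed + 31 * r + 2)
        if np.isfinite(la) and np.isfinite(lb):
            runs.append((la - lb) / np.log(3.0))
    runs = np.asarray(runs)
    exact = (results["logml_exact_a"] - results["logml_exact_b"]) / np.log(3.0)
    most_equivocal = runs[np.argmin(np.abs(runs))] if len(runs) else np.nan
    # self-comparison: same model against itself
    self_runs = []
    for r in range(min(n_runs, 5)):
        l1 = bridge_sample_logml(*per_model["a"], seed=seed + 101 * r + 3)
        l2 = bridge_sample_logml(*per_model["a"], seed=seed + 101 * r + 7)
        if np.isfinite(l1) and np.isfinite(l2):
            self_runs.append((l1 - l2) / np.log(3.0))
    self_runs = np.asarray(self_runs)
    return {"log3_bf_exact": float(exact),
            "log3_bf_runs": runs,
            "log3_bf_most_equivocal": float(most_equivocal),
            "abs_err": float(abs(most_equivocal - exact)),
            "self_log3_bf": float(self_runs[np.argmin(np.abs(self_runs))])
            if len(self_runs) else np.nan,
            "n_runs_ok": int(len(runs))}


def logistic_recovery_experiment(seed=0, n_subjects=8, per_level=100, n_days=4,
                                 n_replicates=8):
    """Threshold-trajectory and dynamics recovery for the accuracy-only baseline.

    Simulates choice data under each of the four threshold dynamics in
    rotation, refits all four, and reports (i) the correlation between true
    and fitted per-trial threshold trajectories under the combined dynamics
    and (ii) the fraction of replicates in which the information criterion
    picks the generating dynamics.
    """
    from .dynamics import rate_for_t50
    from .logistic import (LOGISTIC_DYNAMICS, LogisticSpec, fit_logistic_dynamics,
                           simulate_logistic_choices)

    tpd = per_level * 7
    rng = np.random.default_rng(seed)

    # day-level offsets for the flexible truth are deliberately non-monotone:
    # heterogeneous between-day variation is the defining feature of that form
    flex_start_off = np.array([0.0, -0.35, -0.10, -0.45])
    flex_asym_off = np.array([0.0, -0.30, 0.05, -0.40])

    def make_truth(spec, n_subjects, rng):
        truth = {}
        for sid in range(1, n_subjects + 1):
            base = {
                "log_th_start": np.log(12.0) + rng.normal(0, 0.15),
                "log_th_asym": np.log(5.0) + rng.normal(0, 0.15),
                "rt_slope_start": rng.normal(0.05, 0.02),
                "rt_slope_asym": rng.normal(0.02, 0.01),
            }
            if spec.dynamics == "flexible":
                p = {f"log_th_start_d{d}": base["log_th_start"] + flex_start_off[d - 1]
                     for d in range(1, n_days + 1)}
                p.update({f"log_th_asym_d{d}": base["log_th_asym"] + flex_asym_off[d - 1]
                          for d in range(1, n_days + 1)})
                p["rate"] = rate_for_t50(max(0.15 * tpd, 3.0)) + rng.normal(0, 0.2)
            elif spec.dynamics == "continuous_plus_day_resetting":
                p = dict(base)
                p["rate"] = rate_for_t50(max(0.2 * n_days * tpd, 3.0)) + rng.normal(0, 0.2)
                p["reset_offset"] = 0.6 + rng.normal(0, 0.05)
                p["reset_rate"] = rate_for_t50(max(0.12 * tpd, 3.0))
            else:
                p = dict(base)
                tmax = tpd if spec.dynamics == "day_resetting" else n_days * tpd
                p["rate"] = rate_for_t50(max(0.25 * tmax, 3.0)) + rng.normal(0, 0.2)
            p["rt_slope_start"] = base["rt_slope_start"]
            p["rt_slope_asym"] = base["rt_slope_asym"]
            truth[sid] = p
        return truth

    # (i) trajectory recovery under the combined dynamics
    spec_c = LogisticSpec("continuous_plus_day_resetting", n_days=n_days,
                          trials_per_day=tpd)
    design = generate_design(n_subjects, n_days, tpd, per_level=per_level, seed=seed)
    truth = make_truth(spec_c, n_subjects, rng)
    table = simulate_logistic_choices(design, truth, spec_c, seed=seed + 1)
    fit = fit_logistic_dynamics(table, spec_c, seed=seed)
    rs = []
    from .logistic import log_threshold_series
    ct = np.arange(1, n_days * tpd + 1.0)
    day = ((ct - 1) // tpd + 1).astype(int)
    wt = ct - (day - 1) * tpd
    for sid in truth:
        true_traj = log_threshold_series(spec_c, truth[sid], day, wt, ct)
        est_traj = np.log(fit.threshold_trajectory(sid))
        rs.append(stats.pearsonr(true_traj, est_traj).statistic)
    r_traj = float(np.mean(rs))

    # (ii) dynamics recovery, rotating the generator across replicates
    n_correct = 0
    for rep in range(n_replicates):
        gen = LOGISTIC_DYNAMICS[rep % len(LOGISTIC_DYNAMICS)]
        spec_gen = LogisticSpec(gen, n_days=n_days, trials_per_day=tpd)
        s = (seed + 7) * 1000 + rep
        rng_rep = np.random.default_rng(s)
        design = generate_design(n_subjects, n_days, tpd, per_level=per_level, seed=s)
        truth = make_truth(spec_gen, n_subjects, rng_rep)
        table = simulate_logistic_choices(design, truth, spec_gen, seed=s + 1)
        aics = {}
        for cand in LOGISTIC_DYNAMICS:
            spec_cand = LogisticSpec(cand, n_days=n_days, trials_per_day=tpd)
            f = fit_logistic_dynamics(table, spec_cand, seed=s)
            aics[cand] = f.aic
        if min(aics, key=aics.get) == gen:
            n_correct += 1
    return {"r_threshold_trajectory": r_traj,
            "dynamics_recovery_rate": n_correct / n_replicates,
            "n_replicates": n_replicates,
            "n_trials_per_subject": n_days * tpd}
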