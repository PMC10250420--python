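"""The six candidate learning models (A–F) and their parameterizations.

Each model names a pair of dynamic forms, one for drift rate (DR) and one for
the log response boundary (RB):

====  ===========  =============
id    DR form      RB form
====  ===========  =============
A     constant     constant
B     continuous   continuous
C     continuous   day_resetting
D     continuous   flexible
E     flexible     continuous
F     flexible     flexible
====  ===========  =============

Drift rate is modeled on the identity scale as a per-subject linear function
of median-centered stimulus coherence: both the intercept and the coherence
slope follow the DR trajectory form and share the DR rate.  The response
boundary evolves on the log scale (positivity by construction).  Bias (logit
scale) and non-decision time (``t0 = 0.001 + offset``) are constant over time
within subject.  Responses use accuracy coding: the upper boundary is the
correct response, so positive drift favors a correct choice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit
from scipy import stats

from .dynamics import TrajectorySpec, trajectory

__all__ = [
    "MODEL_FORMS", "ModelSpec", "SubjectParams", "PriorSpec",
    "per_trial_params", "parameter_count",
]

MODEL_FORMS = {
    "A": ("constant", "constant"),
    "B": ("continuous", "continuous"),
    "C": ("continuous", "day_resetting"),
    "D": ("continuous", "flexible"),
    "E": ("flexible", "continuous"),
    "F": ("flexible", "flexible"),
}

NDT_FLOOR = 0.001  # seconds; small additive offset below any plausible NDT
DESIGN_COHERENCES = (0.8, 1.6, 3.2, 6.4, 12.8, 25.6, 51.2)
DESIGN_MEDIAN_COHERENCE = 6.4


@dataclass(frozen=True)
class ModelSpec:
    """One of the candidate models A–F plus design constants."""

    model_id: str
    coherence_link: str = "linear"  # or "log"
    group_covariate: bool = False
    n_days: int = 4
    trials_per_day: int = 700
    coherence_median: float = DESIGN_MEDIAN_COHERENCE

    def __post_init__(self):
        if self.model_id not in MODEL_FORMS:
            raise ValueError(f"model_id must be one of {sorted(MODEL_FORMS)}")
        if self.coherence_link not in ("linear", "log"):
            raise ValueError("coherence_link must be 'linear' or 'log'")

    @property
    def dr_form(self) -> str:
        return MODEL_FORMS[self.model_id][0]

    @property
    def rb_form(self) -> str:
        return MODEL_FORMS[self.model_id][1]

    @property
    def n_trials(self) -> int:
        return self.n_days * self.trials_per_day

    def coherence_covariate(self, coherence_pct):
        """Median-centered coherence covariate (linear or log link)."""
        c = np.asarray(coherence_pct, dtype=float)
        if self.coherence_link == "log":
            return np.log(c) - np.log(self.coherence_median)
        return c - self.coherence_median


@dataclass
class SubjectParams:
    """One subject's generative parameters for a given ModelSpec.

    ``dr_intercept`` and ``dr_slope`` are trajectories on the drift (identity)
    scale; ``log_rb`` is the boundary trajectory on the log scale.
    ``group_effects`` holds optional additive fixed shifts (keys among
    ``dr``, ``log_rb``, ``bias``, ``ndt``), zero when absent.
    """

    dr_intercept: TrajectorySpec
    dr_slope: TrajectorySpec
    log_rb: TrajectorySpec
    bias_logit: float
    ndt_offset: float
    group_effects: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.ndt_offset <= 0:
            raise ValueError("ndt_offset must be positive (t0 = 0.001 + offset)")

    @property
    def z(self) -> float:
        return float(expit(self.bias_logit + self.group_effects.get("bias", 0.0)))

    @property
    def t0(self) -> float:
        return NDT_FLOOR + self.ndt_offset + self.group_effects.get("ndt", 0.0)


def per_trial_params(spec: ModelSpec, subj: SubjectParams, trials):
    """Map a trial table to per-trial Wiener parameters ``(v, a, z, t0)``.

    ``trials`` is a DataFrame (or mapping of arrays) with columns ``day``,
    ``trial_in_day``, ``trial_overall`` and ``coherence_pct``.  Returns arrays
    broadcast to the number of trials.  Coherences outside the configured
    design levels are evaluated by linear extrapolation of the same formula
    (with a warning).
    """
    coh = np.asarray(trials["coherence_pct"], dtype=float)
    known = np.isin(np.round(coh, 6), np.round(np.asarray(DESIGN_COHERENCES), 6))
    if not np.all(known):
        import warnings
        warnings.warn("coherence values outside the design levels; extrapolating linearly")
    day = np.asarray(trials["day"], dtype=int)
    wtrial = np.asarray(trials["trial_in_day"], dtype=float)
    ctrial = np.asarray(trials["trial_overall"], dtype=float)

    x = spec.coherence_covariate(coh)
    dr0 = trajectory(subj.dr_intercept, day, wtrial, ctrial)
    dr1 = trajectory(subj.dr_slope, day, wtrial, ctrial)
    v = dr0 + dr1 * x + subj.group_effects.get("dr", 0.0)
    log_a = trajectory(subj.log_rb, day, wtrial, ctrial) + subj.group_effects.get("log_rb", 0.0)
    a = np.exp(log_a)
    z = np.full_like(v, subj.z)
    t0 = np.full_like(v, subj.t0)
    return v, a, z, t0


def _form_count(form: str, n_days: int) -> int:
    """Free parameters of one trajectory (start/asymptote structure, no rate)."""
    if form == "constant":
        return 1
    if form in ("continuous", "day_resetting"):
        return 2  # start + asymptote
    return 2 * n_days  # flexible: per-day starts + asymptotes


def parameter_count(spec: ModelSpec, n_subjects: int = 1, n_days: int | None = None) -> int:
    """Number of free parameters of the per-subject parameterization.

    Per subject: DR intercept and DR coherence slope each follow the DR form
    (sharing one DR rate when time-varying), the log-RB trajectory has its own
    rate when time-varying, plus constant bias and NDT.  Model A therefore has
    5 per subject.  An enabled group covariate adds one fixed shift per
    parameter family (dr, log_rb, bias, ndt).
    """
    n_days = spec.n_days if n_days is None else n_days
    k = _form_count(spec.dr_form, n_days) * 2  # intercept + coherence slope
    if spec.dr_form != "constant":
        k += 1  # shared DR rate
    k += _form_count(spec.rb_form, n_days)
    if spec.rb_form != "constant":
        k += 1  # RB rate
    k += 2  # bias, ndt
    total = k * n_subjects
    if spec.group_covariate:
        total += 4
    return total


def embed_subject_params(subj: SubjectParams, to_spec: ModelSpec,
                         rate_defaults: dict | None = None) -> SubjectParams:
    """Re-express subject parameters in another model's trajectory forms.

    Constant trajectories embed exactly into any form (start = asymptote);
    continuous trajectories embed into flexible form by evaluating the curve
    at day boundaries.  Used to warm-start a richer model's fit from a
    simpler model's estimates (the nesting structure guarantees the embedded
    point attains the same likelihood).
    """
    from .dynamics import curve_value, rate_for_t50
    nd, tpd = to_spec.n_days, to_spec.trials_per_day
    defaults = rate_defaults or {}

    def convert(traj: TrajectorySpec, to_form: str, default_rate: float):
        if traj.form == to_form and traj.n_days == nd:
            return traj
        rate = traj.rate if traj.form != "constant" else default_rate
        if to_form == "constant":
            return TrajectorySpec("constant", float(np.mean(traj.asymptotes)), n_days=nd)
        if to_form in ("continuous", "day_resetting"):
            s = float(np.mean(traj.starts))
            a = float(np.mean(traj.asymptotes))
            return TrajectorySpec(to_form, s, a, rate, n_days=nd)
        # flexible target
        if traj.form == "continuous":
            edges = np.arange(nd + 1) * tpd + 1.0
            vals = curve_value(edges, traj.starts, traj.asymptotes, traj.rate)
            wrate = defaults.get("within_day", rate_for_t50(max(0.25 * tpd, 3.0)))
            return TrajectorySpec("flexible", vals[:-1], vals[1:], wrate, n_days=nd)
        s = np.full(nd, np.mean(traj.starts))
        a = np.full(nd, np.mean(traj.asymptotes))
        return TrajectorySpec("flexible", s, a, rate, n_days=nd)

    dr_default = defaults.get(
        "dr", float(np.log2(max(0.25 * (to_spec.n_trials if to_spec.dr_form == "continuous"
                                        else tpd), 3.0))))
    rb_default = defaults.get(
        "rb", float(np.log2(max(0.25 * (to_spec.n_trials if to_spec.rb_form == "continuous"
                                        else tpd), 3.0))))
    return SubjectParams(
        dr_intercept=convert(subj.dr_intercept, to_spec.dr_form, dr_default),
        dr_slope=convert(subj.dr_slope, to_spec.dr_form, dr_default),
        log_rb=convert(subj.log_rb, to_spec.rb_form, rb_default),
        bias_logit=subj.bias_logit,
        ndt_offset=subj.ndt_offset,
        group_effects=dict(subj.group_effects),
    )


@dataclass(frozen=True)
class PriorSpec:
    """Priors for the per-subject parameters (link scales).

    Drift-scale parameters get student_t(3, 1, 10); log-boundary parameters
    normal(-0.6, 1.3); logit bias normal(0, 1); NDT offset exponential with
    mean 0.15 s.  Rate parameters get normal priors centered on the binary log
    of 25% of the relevant maximum trial number (within-day vs cumulative)
    with SD 1.  The drift~coherence slope gets a weakly-informative
    student_t(3, 0, 2.5).
    """

    drift_df: float = 3.0
    drift_loc: float = 1.0
    drift_scale: float = 10.0
    slope_df: float = 3.0
    slope_loc: float = 0.0
    slope_scale: float = 2.5
    log_boundary_loc: float = -0.6
    log_boundary_scale: float = 1.3
    bias_loc: float = 0.0
    bias_scale: float = 1.0
    rate_sd: float = 1.0
    ndt_mean: float = 0.15

    def rate_center(self, spec: ModelSpec, timescale: str) -> float:
        max_trial = spec.trials_per_day if timescale == "within_day_trial" else spec.n_trials
        return float(np.log2(0.25 * max_trial))

    def dist_for(self, name: str, spec: ModelSpec):
        """scipy frozen distribution for a named per-subject parameter."""
        if name.startswith("dr_slope"):
            return stats.t(df=self.slope_df, loc=self.slope_loc, scale=self.slope_scale)
        if name.startswith("dr_") and name.endswith("rate"):
            ts = "cumulative_trial" if spec.dr_form == "continuous" else "within_day_trial"
            return stats.norm(self.rate_center(spec, ts), self.rate_sd)
        if name.startswith("rb_rate"):
            ts = "cumulative_trial" if spec.rb_form == "continuous" else "within_day_trial"
            return stats.norm(self.rate_center(spec, ts), self.rate_sd)
        if name.startswith("dr_"):
            return stats.t(df=self.drift_df, loc=self.drift_loc, scale=self.drift_scale)
        if name.startswith("log_rb"):
            return stats.norm(self.log_boundary_loc, self.log_boundary_scale)
        if name == "bias_logit":
            return stats.norm(self.bias_loc, self.bias_scale)
        if name == "ndt_offset":
            return stats.expon(scale=self.ndt_mean)
        raise KeyError(name)
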