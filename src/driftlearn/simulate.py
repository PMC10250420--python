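"""Synthetic trial-level data with the multi-day training-study design.

Emulates the reference design — 21 participants x 4 days x 700 trials of a
random-dot motion direction discrimination, 100 trials at each of 7 coherence
levels (0.8–51.2%) in randomized order — with response times and choices
drawn from the Wiener first-passage distribution at per-trial parameters
implied by a chosen learning model and a known ground truth.  A small
fraction of contaminant trials (uniform RTs, random choices) is mixed in to
exercise the RT exclusion filter.

Default population values follow the fitted fixed effects of the reference
analysis: drift rate rising from 0.44 toward 0.96 (at the median coherence)
with a time-to-half of 1261 trials on the 2800-trial design (rescaled
proportionally for shorter designs), between-subject drift change
N(0.516, 0.175).  Quantities the study does not report (coherence slope,
boundary levels, NDT spread) are set to values typical of dot-motion DDM
fits and documented in the methods note.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import wiener
from .dynamics import TrajectorySpec, curve_value, rate_for_t50
from .models import ModelSpec, SubjectParams, per_trial_params

__all__ = [
    "generate_design", "PopulationConfig", "GroundTruth",
    "sample_ground_truth", "simulate_trials", "write_trials_csv", "read_trials_csv",
]

DESIGN_COHERENCES = (0.8, 1.6, 3.2, 6.4, 12.8, 25.6, 51.2)

TRIAL_COLUMNS = [
    "subject", "group", "day", "trial_in_day", "trial_overall",
    "coherence_pct", "stim_dir", "resp_dir", "correct", "rt_s",
]


def generate_design(n_subjects, n_days=4, trials_per_day=700,
                    coherences=DESIGN_COHERENCES, per_level=100, seed=0):
    """Balanced randomized design table (no responses yet).

    Each subject-day holds exactly ``per_level`` trials of each coherence in
    seeded-random order, with left/right stimulus direction assigned 50/50 at
    random.  Requires ``per_level * len(coherences) == trials_per_day``.
    """
    coherences = tuple(float(c) for c in coherences)
    if per_level * len(coherences) != trials_per_day:
        raise ValueError(
            f"per_level * n_levels ({per_level}*{len(coherences)}) must equal "
            f"trials_per_day ({trials_per_day})")
    rng = np.random.default_rng(seed)
    rows = []
    base = np.repeat(coherences, per_level)
    for s in range(1, n_subjects + 1):
        for d in range(1, n_days + 1):
            coh = rng.permutation(base)
            stim = rng.choice(["L", "R"], size=trials_per_day)
            wtrial = np.arange(1, trials_per_day + 1)
            rows.append(pd.DataFrame({
                "subject": s,
                "day": d,
                "trial_in_day": wtrial,
                "trial_overall": (d - 1) * trials_per_day + wtrial,
                "coherence_pct": coh,
                "stim_dir": stim,
            }))
    return pd.concat(rows, ignore_index=True)


@dataclass(frozen=True)
class PopulationConfig:
    """Population laws the per-subject ground truth is drawn from.

    Scalars are means; ``*_sd`` the between-subject SDs (set an SD to 0 for a
    homogeneous population).  Time-to-half values are expressed on the
    2800-trial reference design and rescaled proportionally to the actual
    design length (cumulative timescale) or day length (within-day).
    """

    dr_start: float = 0.44
    dr_start_sd: float = 0.15
    dr_change: float = 0.516
    dr_change_sd: float = 0.175
    dr_t50_ref: float = 1261.0      # cumulative trials on the 2800-trial design
    dr_rate_sd: float = 0.4
    slope_start: float = 0.05
    slope_change: float = 0.03
    slope_sd: float = 0.01
    # log response boundary; flexible day-specific levels with overall decline
    log_rb_day_starts: tuple = (0.70, 0.52, 0.58, 0.50)
    log_rb_day_asymptotes: tuple = (0.50, 0.42, 0.48, 0.40)
    log_rb_sd: float = 0.10
    rb_t50_ref: float = 150.0       # within-day trials on the 700-trial day
    rb_rate_sd: float = 0.4
    bias_logit: float = 0.0
    bias_logit_sd: float = 0.2
    ndt_offset: float = 0.25
    ndt_offset_sd: float = 0.03
    contaminant_rate: float = 0.005
    contaminant_range: tuple = (0.05, 3.0)
    prop_avgp: float = 0.5
    group_shift: dict = field(default_factory=dict)  # additive NVGP shifts


@dataclass
class GroundTruth:
    """Per-subject generative parameters plus the contamination law."""

    subjects: dict            # subject id -> SubjectParams
    groups: dict              # subject id -> "AVGP" | "NVGP"
    contaminant_rate: float
    contaminant_range: tuple

    def __post_init__(self):
        if not 0.0 <= self.contaminant_rate <= 0.05:
            raise ValueError("contaminant_rate must be in [0, 0.05]")


def _trunc_normal(rng, mean, sd, low, size=None):
    """Normal draw redrawn (vector-wise clipped) to stay above ``low``."""
    x = rng.normal(mean, sd, size=size)
    return np.maximum(x, low)


def sample_ground_truth(spec: ModelSpec, n_subjects: int, seed=0,
                        config: PopulationConfig | None = None) -> GroundTruth:
    """Draw per-subject parameters consistent with the model's dynamic forms."""
    cfg = config or PopulationConfig()
    rng = np.random.default_rng(seed)
    scale_c = spec.n_trials / 2800.0
    scale_w = spec.trials_per_day / 700.0
    dr_t50 = max(cfg.dr_t50_ref * scale_c, 3.0)
    rb_t50 = max(cfg.rb_t50_ref * scale_w, 3.0)
    nd = spec.n_days

    subjects, groups = {}, {}
    for s in range(1, n_subjects + 1):
        start = rng.normal(cfg.dr_start, cfg.dr_start_sd)
        change = _trunc_normal(rng, cfg.dr_change, cfg.dr_change_sd, 0.05)
        asym = start + change
        dr_rate = rng.normal(rate_for_t50(dr_t50), cfg.dr_rate_sd)
        sl_start = _trunc_normal(rng, cfg.slope_start, cfg.slope_sd, 0.005)
        sl_asym = _trunc_normal(rng, cfg.slope_start + cfg.slope_change, cfg.slope_sd, 0.005)

        if spec.dr_form == "constant":
            mid = 0.5 * (start + asym)
            dr_int = TrajectorySpec("constant", mid, n_days=nd)
            dr_slope = TrajectorySpec("constant", 0.5 * (sl_start + sl_asym), n_days=nd)
        elif spec.dr_form in ("continuous", "day_resetting"):
            dr_int = TrajectorySpec(spec.dr_form, start, asym, dr_rate, n_days=nd)
            dr_slope = TrajectorySpec(spec.dr_form, sl_start, sl_asym, dr_rate, n_days=nd)
        else:  # flexible: day segments tracking the continuous curve
            edges = np.arange(nd + 1) * spec.trials_per_day + 1.0
            vals_i = curve_value(edges, start, asym, dr_rate)
            vals_s = curve_value(edges, sl_start, sl_asym, dr_rate)
            wrate = rng.normal(rate_for_t50(rb_t50), cfg.dr_rate_sd)
            dr_int = TrajectorySpec("flexible", vals_i[:-1], vals_i[1:], wrate, n_days=nd)
            dr_slope = TrajectorySpec("flexible", vals_s[:-1], vals_s[1:], wrate, n_days=nd)

        rb_rate = rng.normal(rate_for_t50(rb_t50), cfg.rb_rate_sd)
        d_starts = np.asarray(cfg.log_rb_day_starts[:nd]) + rng.normal(0, cfg.log_rb_sd)
        d_asyms = np.asarray(cfg.log_rb_day_asymptotes[:nd]) + rng.normal(0, cfg.log_rb_sd)
        if spec.rb_form == "constant":
            log_rb = TrajectorySpec("constant", float(np.mean(d_asyms)), n_days=nd)
        elif spec.rb_form == "continuous":
            t50c = max(cfg.rb_t50_ref * 4 * scale_c, 3.0)
            log_rb = TrajectorySpec("continuous", float(d_starts[0]), float(np.mean(d_asyms)),
                                    rng.normal(rate_for_t50(t50c), cfg.rb_rate_sd), n_days=nd)
        elif spec.rb_form == "day_resetting":
            log_rb = TrajectorySpec("day_resetting", float(np.mean(d_starts)),
                                    float(np.mean(d_asyms)), rb_rate, n_days=nd)
        else:
            log_rb = TrajectorySpec("flexible", d_starts, d_asyms, rb_rate, n_days=nd)

        group = "AVGP" if rng.uniform() < cfg.prop_avgp else "NVGP"
        effects = dict(cfg.group_shift) if (group == "NVGP" and cfg.group_shift) else {}
        subjects[s] = SubjectParams(
            dr_intercept=dr_int, dr_slope=dr_slope, log_rb=log_rb,
            bias_logit=rng.normal(cfg.bias_logit, cfg.bias_logit_sd),
            ndt_offset=_trunc_normal(rng, cfg.ndt_offset, cfg.ndt_offset_sd, 0.05),
            group_effects=effects)
        groups[s] = group
    return GroundTruth(subjects, groups, cfg.contaminant_rate, cfg.contaminant_range)


def _sample_heterogeneous(v, a, z, t0, rng, n_grid=48, chunk=512):
    """Exact (rt, upper) draws for per-trial parameter vectors.

    Per trial: pick the absorbing boundary from the closed-form choice
    probability, then invert that boundary's defective CDF — coarse per-trial
    quantile grid, linear interpolation, then Newton polish with the analytic
    density.
    """
    n = v.size
    rt = np.empty(n)
    upper = np.zeros(n, dtype=bool)
    pu = np.asarray(wiener.choice_probability((v, a, z, t0)))
    u = rng.uniform(size=n)
    upper = u < pu
    targ = rng.uniform(size=n)
    lam1 = (v ** 2 + (np.pi / a) ** 2) / 2.0
    mdt = np.asarray(wiener.mean_decision_time((v, a, z, t0)))
    t_max = mdt + np.maximum(40.0 / lam1, 1.0)
    q = np.linspace(0.0, 1.0, n_grid) ** 2
    for lo in range(0, n, chunk):
        sl = slice(lo, min(lo + chunk, n))
        for is_up in (True, False):
            m = np.flatnonzero(upper[sl] == is_up)
            if m.size == 0:
                continue
            idx = np.arange(n)[sl][m]
            bound = "upper" if is_up else "lower"
            grid = np.maximum(t_max[idx, None] * q[None, :], 1e-9)
            F = wiener.fpt_cdf(grid + t0[idx, None], bound,
                               (v[idx, None], a[idx, None], z[idx, None], t0[idx, None]))
            F = np.maximum.accumulate(F, axis=1)
            mass = np.where(is_up, pu[idx], 1.0 - pu[idx])
            tgt = targ[idx] * mass
            # row-wise inverse interpolation
            j = np.clip(np.sum(F < tgt[:, None], axis=1), 1, n_grid - 1)
            F0 = F[np.arange(m.size), j - 1]
            F1 = F[np.arange(m.size), j]
            g0 = grid[np.arange(m.size), j - 1]
            g1 = grid[np.arange(m.size), j]
            w = np.where(F1 > F0, (tgt - F0) / np.maximum(F1 - F0, 1e-300), 0.5)
            tt = g0 + np.clip(w, 0.0, 1.0) * (g1 - g0)
            for _ in range(3):
                f = np.maximum(np.exp(wiener.fpt_logdensity(
                    tt + t0[idx], bound, (v[idx], a[idx], z[idx], t0[idx]))), 1e-12)
                Ft = wiener.fpt_cdf(tt + t0[idx], bound, (v[idx], a[idx], z[idx], t0[idx]))
                tt = np.clip(tt - (Ft - tgt) / f, 1e-9, t_max[idx])
            rt[idx] = tt + t0[idx]
    return rt, upper


def simulate_trials(design: pd.DataFrame, truth: GroundTruth, model: ModelSpec,
                    seed=0, method: str = "inverse_cdf", dt: float = 1e-3) -> pd.DataFrame:
    """Simulate choices and RTs for every design row.

    Non-contaminant trials draw from the Wiener first-passage distribution at
    that trial's parameters (exact inverse-CDF sampling by default; an
    Euler–Maruyama fallback with step ``dt`` is available as an independent
    cross-check).  Contaminant trials draw a uniform RT and a random response.
    Accuracy coding: absorption at the upper boundary is a correct response.
    """
    rng = np.random.default_rng(seed)
    out = []
    for sid, sdf in design.groupby("subject", sort=True):
        sdf = sdf.sort_values("trial_overall").reset_index(drop=True)
        subj = truth.subjects[sid]
        v, a, z, t0 = per_trial_params(model, subj, sdf)
        if method == "inverse_cdf":
            rt, upper = _sample_heterogeneous(v, a, z, t0, rng)
        elif method == "euler":
            rt = np.empty(len(sdf))
            upper = np.zeros(len(sdf), dtype=bool)
            for i in range(len(sdf)):
                r, up = wiener.simulate_euler(1, (v[i], a[i], z[i], t0[i]), rng, dt=dt)
                rt[i], upper[i] = r[0], up[0]
        else:
            raise ValueError("method must be 'inverse_cdf' or 'euler'")
        correct = upper.copy()
        contam = rng.uniform(size=len(sdf)) < truth.contaminant_rate
        if np.any(contam):
            lo, hi = truth.contaminant_range
            rt[contam] = rng.uniform(lo, hi, size=int(contam.sum()))
            correct[contam] = rng.uniform(size=int(contam.sum())) < 0.5
        stim = sdf["stim_dir"].to_numpy()
        resp = np.where(correct, stim, np.where(stim == "L", "R", "L"))
        tdf = sdf.copy()
        tdf["group"] = truth.groups[sid]
        tdf["resp_dir"] = resp
        tdf["correct"] = correct
        tdf["rt_s"] = rt
        out.append(tdf)
    table = pd.concat(out, ignore_index=True)
    return table[TRIAL_COLUMNS]


def write_trials_csv(table: pd.DataFrame, path) -> None:
    """Write the trial table in the canonical CSV dialect (UTF-8, '.' decimal)."""
    table[TRIAL_COLUMNS].to_csv(path, index=False, encoding="utf-8")


def read_trials_csv(path) -> pd.DataFrame:
    table = pd.read_csv(path, encoding="utf-8")
    missing = [c for c in TRIAL_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"trial table missing columns: {missing}")
    table["correct"] = table["correct"].astype(bool)
    return table[TRIAL_COLUMNS]
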