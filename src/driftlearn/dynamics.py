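"""Exponential learning trajectories for DDM parameters.

A time-varying parameter follows the three-parameter exponential learning
curve

    param(n) = asymptote + (start - asymptote) * 2 ** ((1 - n) / (2 + 2**rate))

where ``n`` is a 1-based trial number and ``rate`` is the binary log of the
time-to-50%-of-change constant minus 2 (``T50 = 2 + 2**rate``); the additive 2
keeps the half-change time above 2 trials, which aids identifiability.  At
``n = 1`` the curve returns ``start`` exactly and it approaches ``asymptote``
monotonically.

Four dynamic forms are supported:

``constant``       the parameter never changes;
``continuous``     one curve in *cumulative* trial number across all days;
``day_resetting``  one curve in *within-day* trial number, identical every day
                   (a transient excursion that resets to baseline overnight);
``flexible``       a within-day curve with day-specific starts and asymptotes
                   but a single shared rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["TrajectorySpec", "curve_value", "time_to_half", "rate_for_t50", "trajectory"]

FORMS = ("constant", "continuous", "day_resetting", "flexible")


def curve_value(trial_number, start, asymptote, rate):
    """Evaluate the exponential learning curve at a 1-based trial number."""
    n = np.asarray(trial_number, dtype=float)
    if np.any(n < 1):
        raise ValueError("trial_number must be >= 1")
    start = np.asarray(start, dtype=float)
    asymptote = np.asarray(asymptote, dtype=float)
    t50 = 2.0 + np.exp2(np.asarray(rate, dtype=float))
    out = asymptote + (start - asymptote) * np.exp2((1.0 - n) / t50)
    return out if out.ndim else float(out)


def time_to_half(rate):
    """Trials to traverse half the start-to-asymptote distance: 2 + 2**rate."""
    out = 2.0 + np.exp2(np.asarray(rate, dtype=float))
    return out if out.ndim else float(out)


def rate_for_t50(t50):
    """Inverse of :func:`time_to_half`; requires t50 > 2."""
    t50 = np.asarray(t50, dtype=float)
    if np.any(t50 <= 2):
        raise ValueError("time-to-half must exceed 2 trials")
    out = np.log2(t50 - 2.0)
    return out if out.ndim else float(out)


@dataclass
class TrajectorySpec:
    """One learning trajectory on its link scale.

    ``starts``/``asymptotes`` are scalars for constant/continuous/day_resetting
    forms and per-day sequences (length ``n_days``) for the flexible form.
    ``timescale`` is implied by the form: cumulative trial number for
    ``continuous``, within-day trial number for ``day_resetting``/``flexible``.
    """

    form: str
    starts: object = 0.0
    asymptotes: object = None
    rate: float = 0.0
    n_days: int = field(default=4)

    def __post_init__(self):
        if self.form not in FORMS:
            raise ValueError(f"unknown trajectory form {self.form!r}")
        if self.asymptotes is None:
            self.asymptotes = self.starts
        if self.form == "flexible":
            s = np.atleast_1d(np.asarray(self.starts, dtype=float))
            a = np.atleast_1d(np.asarray(self.asymptotes, dtype=float))
            if len(s) != self.n_days or len(a) != self.n_days:
                raise ValueError(
                    f"flexible form needs per-day starts/asymptotes of length {self.n_days}")
            self.starts, self.asymptotes = s, a
        else:
            self.starts = float(np.asarray(self.starts, dtype=float))
            self.asymptotes = float(np.asarray(self.asymptotes, dtype=float))
            if self.form == "constant":
                self.asymptotes = self.starts

    @property
    def timescale(self) -> str:
        return "cumulative_trial" if self.form == "continuous" else "within_day_trial"


def trajectory(spec: TrajectorySpec, day_index, within_day_trial, cumulative_trial):
    """Expand a trajectory spec into per-trial parameter values.

    ``day_index`` is 1-based; the two trial indices are 1-based and must be
    consistent with the design (``cumulative = (day-1)*trials_per_day +
    within_day`` under the reference design — not re-checked here so that
    irregular retained-trial subsets remain usable).
    """
    day = np.atleast_1d(np.asarray(day_index, dtype=int))
    wtrial = np.atleast_1d(np.asarray(within_day_trial, dtype=float))
    ctrial = np.atleast_1d(np.asarray(cumulative_trial, dtype=float))
    if spec.form == "constant":
        return np.full(ctrial.shape, spec.starts, dtype=float)
    if spec.form == "continuous":
        return np.asarray(curve_value(ctrial, spec.starts, spec.asymptotes, spec.rate))
    if spec.form == "day_resetting":
        return np.asarray(curve_value(wtrial, spec.starts, spec.asymptotes, spec.rate))
    # flexible: day-specific start/asymptote, shared rate
    if np.any(day < 1) or np.any(day > spec.n_days):
        raise ValueError("day index outside the configured number of days")
    s = np.asarray(spec.starts)[day - 1]
    a = np.asarray(spec.asymptotes)[day - 1]
    return np.asarray(curve_value(wtrial, s, a, spec.rate))
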