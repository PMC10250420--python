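"""Absolute model fit and descriptive learning checks.

Absolute fit follows the block-correlation recipe: retained trials are cut
into consecutive 25-trial blocks per subject (112 blocks per subject under
the full reference design), observed and model-predicted accuracy and mean RT
are averaged within block x coherence-level cells, and the two Pearson
correlations (accuracy, RT) between data and prediction are reported, pooled
across subjects.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["absolute_fit", "coherence_level_change", "block_summaries"]


def block_summaries(table: pd.DataFrame, fit, block: int = 25) -> pd.DataFrame:
    """Block x coherence cell means of observed and predicted accuracy/RT.

    Blocks partition each subject's retained trials in order: every trial
    belongs to exactly one block; the final partial block (if any) is kept.
    """
    if block < 1:
        raise ValueError("block size must be positive")
    pred = fit.predict(table)
    df = table.copy()
    df["pred_accuracy"] = pred["pred_accuracy"].to_numpy()
    df["pred_rt_s"] = pred["pred_rt_s"].to_numpy()
    parts = []
    for sid, sdf in df.groupby("subject", sort=True):
        sdf = sdf.sort_values("trial_overall").reset_index(drop=True)
        sdf["block"] = sdf.index // block
        parts.append(sdf)
    df = pd.concat(parts, ignore_index=True)
    cells = (df.groupby(["subject", "block", "coherence_pct"])
             .agg(obs_accuracy=("correct", "mean"), obs_rt_s=("rt_s", "mean"),
                  pred_accuracy=("pred_accuracy", "mean"),
                  pred_rt_s=("pred_rt_s", "mean"), n=("rt_s", "size"))
             .reset_index())
    return cells


def absolute_fit(table: pd.DataFrame, fit, block: int = 25):
    """Zero-order correlations between binned data and model predictions.

    Returns ``(r_accuracy, r_rt, cells)``.  Degenerate (constant) columns
    yield NaN with a warning.
    """
    cells = block_summaries(table, fit, block)
    if cells["block"].nunique() < 2 and cells["coherence_pct"].nunique() < 2:
        raise ValueError("need at least 2 blocks or coherence levels for correlations")

    def _r(x, y):
        if np.std(x) < 1e-12 or np.std(y) < 1e-12:
            warnings.warn("constant observed or predicted values; correlation undefined")
            return np.nan
        return float(stats.pearsonr(x, y).statistic)

    r_acc = _r(cells["obs_accuracy"].to_numpy(), cells["pred_accuracy"].to_numpy())
    r_rt = _r(cells["obs_rt_s"].to_numpy(), cells["pred_rt_s"].to_numpy())
    return r_acc, r_rt, cells


def coherence_level_change(table: pd.DataFrame, first_day: int | None = None,
                           last_day: int | None = None) -> pd.DataFrame:
    """Per-coherence paired first-vs-last-day comparisons of RT and accuracy.

    For each coherence level, subject means on the first and last day are
    compared across subjects with both a paired two-sided t test and a
    Wilcoxon signed-rank test.  Change is last-day minus first-day, so
    learning shows as negative ``rt_change`` (faster) and positive
    ``accuracy_change``.
    """
    days = np.sort(table["day"].unique())
    if len(days) < 2:
        raise ValueError("need at least two days for a learning comparison")
    d1 = first_day if first_day is not None else int(days[0])
    d4 = last_day if last_day is not None else int(days[-1])
    rows = []
    for coh, cdf in table.groupby("coherence_pct", sort=True):
        piv_rt = (cdf[cdf["day"].isin([d1, d4])]
                  .pivot_table(index="subject", columns="day", values="rt_s"))
        piv_ac = (cdf[cdf["day"].isin([d1, d4])]
                  .pivot_table(index="subject", columns="day",
                               values="correct", aggfunc="mean"))
        if d1 not in piv_rt.columns or d4 not in piv_rt.columns or len(piv_rt) < 2:
            warnings.warn(f"coherence {coh}: insufficient data, skipped")
            continue
        piv_rt = piv_rt.dropna()
        piv_ac = piv_ac.dropna()
        drt = piv_rt[d4] - piv_rt[d1]
        dac = piv_ac[d4] - piv_ac[d1]
        def _paired_t(diff):
            if np.allclose(np.std(diff), 0):  # degenerate: constant change
                if np.allclose(np.mean(diff), 0):
                    return 0.0, 1.0
                return float(np.sign(np.mean(diff)) * np.inf), 0.0
            t = stats.ttest_rel(diff, np.zeros_like(diff))
            return float(t.statistic), float(t.pvalue)

        t_rt = _paired_t(drt.to_numpy())
        t_ac = _paired_t(dac.to_numpy())

        def _wilcoxon(diff):
            if np.allclose(diff, 0):
                return np.nan, 1.0
            w = stats.wilcoxon(diff)
            return float(w.statistic), float(w.pvalue)

        w_rt_s, w_rt_p = _wilcoxon(drt.to_numpy())
        w_ac_s, w_ac_p = _wilcoxon(dac.to_numpy())
        rows.append({
            "coherence_pct": coh, "n_subjects": len(piv_rt),
            "rt_change": float(drt.mean()), "rt_t": t_rt[0],
            "rt_p": t_rt[1], "rt_wilcoxon_p": w_rt_p,
            "accuracy_change": float(dac.mean()), "accuracy_t": t_ac[0],
            "accuracy_p": t_ac[1], "accuracy_wilcoxon_p": w_ac_p,
        })
    return pd.DataFrame(rows)
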