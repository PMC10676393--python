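"""Item- and scale-level descriptive statistics for dichotomous symptom panels.

Moments use population-style central moments (divisor n, no small-sample
correction), which for a Bernoulli item coincide exactly with the closed
forms skew = (1-2p)/sqrt(p(1-p)) and excess kurtosis = (1-6p(1-p))/(p(1-p))
evaluated at the sample proportion.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .types import (
    DEPRESSED_AFFECT,
    REVERSE_CODED,
    SOMATIC_COMPLAINTS,
    PanelDataset,
)

__all__ = [
    "UndefinedStatisticError",
    "moment_stats",
    "endorsement_table",
    "cronbach_alpha",
    "sum_scores",
    "describe_panel",
]


class UndefinedStatisticError(ValueError):
    """A statistic is undefined for the given data (e.g. zero variance)."""


def moment_stats(values) -> tuple[float, float]:
    """Sample skewness and excess kurtosis of a vector, missing allowed.

    skew = m3 / m2^(3/2), excess kurtosis = m4 / m2^2 - 3, with central
    moments computed with divisor n over the observed values.
    """
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size < 3:
        raise UndefinedStatisticError("need at least 3 observed values")
    d = v - v.mean()
    m2 = np.mean(d**2)
    if m2 <= 0:
        raise UndefinedStatisticError("zero variance")
    skew = np.mean(d**3) / m2**1.5
    exkurt = np.mean(d**4) / m2**2 - 3.0
    return float(skew), float(exkurt)


def endorsement_table(panel: PanelDataset) -> pd.DataFrame:
    """Per item x wave: endorsement proportion among observed, with n."""
    rows = []
    vals = panel.values_float()
    for w, wave in enumerate(panel.wave_labels):
        for j, item in enumerate(panel.item_labels):
            col = vals[:, w, j]
            obs = ~np.isnan(col)
            n = int(obs.sum())
            rows.append({
                "wave": wave,
                "item": item,
                "endorsement": float(np.nanmean(col)) if n else np.nan,
                "n_observed": n,
            })
    return pd.DataFrame(rows)


def cronbach_alpha(item_matrix) -> float:
    """Cronbach's alpha of a subjects x items matrix, complete cases only.

    alpha = k/(k-1) * (1 - sum of item variances / variance of the sum).
    """
    m = np.asarray(item_matrix, dtype=float)
    m = m[~np.isnan(m).any(axis=1)]
    n, k = m.shape
    if k < 2:
        raise ValueError("need at least 2 items")
    if n < 3:
        raise UndefinedStatisticError("need at least 3 complete cases")
    total_var = m.sum(axis=1).var(ddof=1)
    if total_var <= 0:
        raise UndefinedStatisticError("zero total-score variance")
    item_var = m.var(axis=0, ddof=1).sum()
    return float(k / (k - 1) * (1.0 - item_var / total_var))


def sum_scores(panel: PanelDataset, reverse_items=REVERSE_CODED) -> np.ndarray:
    """(n, W) depression sum scores; reversed items flipped; complete-case.

    Any missing item at a wave makes that wave's sum missing (NaN).
    """
    vals = panel.values_float()
    reverse = np.array([lab in tuple(reverse_items) for lab in panel.item_labels])
    flipped = np.where(reverse, 1.0 - vals, vals)
    return flipped.sum(axis=2)  # NaN propagates under complete-case rule


def describe_panel(panel: PanelDataset) -> pd.DataFrame:
    """Full descriptive table: endorsement, moments, alphas, sum scores.

    One row per item x wave plus per-wave scale rows (``item`` set to the
    scale name) mirroring the study's descriptive table layout.
    """
    vals = panel.values_float()
    table = endorsement_table(panel)
    skews, kurts = [], []
    for _, row in table.iterrows():
        w = panel.wave_labels.index(row["wave"])
        j = panel.item_index(row["item"])
        try:
            s, kkurt = moment_stats(vals[:, w, j])
        except UndefinedStatisticError:
            s, kkurt = np.nan, np.nan
        skews.append(s)
        kurts.append(kkurt)
    table["skewness"] = skews
    table["excess_kurtosis"] = kurts

    scores = sum_scores(panel)
    # internal consistency runs on the scored direction: positively worded
    # items are reversed before computing alpha
    reverse = np.array([lab in REVERSE_CODED for lab in panel.item_labels])
    scored = np.where(reverse, 1.0 - vals, vals)
    scale_rows = []
    for w, wave in enumerate(panel.wave_labels):
        wave_vals = scored[:, w, :]
        subsets = {
            "alpha_full": panel.item_labels,
            "alpha_depressed_affect": DEPRESSED_AFFECT,
            "alpha_somatic": SOMATIC_COMPLAINTS,
        }
        rec = {"wave": wave, "item": "(scale)"}
        for name, items in subsets.items():
            idx = [panel.item_index(i) for i in items if i in panel.item_labels]
            try:
                rec[name] = cronbach_alpha(wave_vals[:, idx])
            except (UndefinedStatisticError, ValueError):
                rec[name] = np.nan
        sw = scores[:, w]
        rec["sum_mean"] = float(np.nanmean(sw))
        rec["sum_sd"] = float(np.nanstd(sw, ddof=1))
        scale_rows.append(rec)
    return pd.concat([table, pd.DataFrame(scale_rows)], ignore_index=True)
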