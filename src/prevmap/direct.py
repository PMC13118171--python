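"""Design-based direct estimation: weighted prevalence, Taylor variance, logit CIs.

The direct (Hájek ratio) estimator for area i uses only that area's sample:

    p̂_i = Σ_{j∈S_i} w_j y_j / Σ_{j∈S_i} w_j

Its design variance is estimated by stratified, with-replacement-PSU Taylor
linearisation of the ratio, treating clusters as primary sampling units.
Estimates are mapped to the logit scale, θ̂_i = logit(p̂_i), with delta-method
variance V̂_i = var(p̂_i)/[p̂_i(1-p̂_i)]², which is the input to area-level
(Fay-Herriot) smoothing. Sparse areas where the point estimate hits 0 or 1, or
the variance formula collapses to (near) zero, are flagged degenerate rather
than propagated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import norm

from prevmap.survey_data import SurveyDataset

logger = logging.getLogger(__name__)

#: variances below this are treated as zero -> degenerate
VARIANCE_FLOOR = 1e-12


@dataclass
class DirectEstimates:
    """Per-area direct estimates with degeneracy flags.

    ``table`` columns: area, p_hat, var, theta, V, ci_lower, ci_upper, cv,
    width, n_clusters, degenerate. Degenerate rows (no data, p̂ ∈ {0,1},
    single cluster, or variance at/below the floor) keep NaN in the derived
    columns.
    """

    table: pd.DataFrame
    level: str

    def non_degenerate(self) -> pd.DataFrame:
        return self.table[~self.table["degenerate"]]


def weighted_prevalence(dataset: SurveyDataset, level: str = "admin1") -> pd.Series:
    """Hájek weighted prevalence per area; areas without data are NaN."""
    labels = (
        dataset.hierarchy.admin1_labels if level == "admin1" else dataset.hierarchy.admin2_labels
    )
    rows = dataset.rows
    num = rows.groupby(level).apply(
        lambda g: np.sum(g["weight"] * g["y"]), include_groups=False
    )
    den = rows.groupby(level)["weight"].sum()
    p = (num / den).reindex(list(labels))
    p.name = "p_hat"
    return p


def design_variance(dataset: SurveyDataset, level: str = "admin1") -> pd.DataFrame:
    """Stratified with-replacement-PSU Taylor variance of the ratio estimator.

    For area i with estimate p̂ and weight total N̂ = Σ w, each cluster
    contributes the linearised total z_c = Σ_{j∈c} w_j (y_j − p̂) / N̂ and

        var(p̂) = Σ_h n_h/(n_h−1) Σ_{c∈h} (z_c − z̄_h)²

    over the strata h represented in the area. A stratum contributing a single
    cluster to the area (a "lonely PSU") cannot estimate a within-stratum
    spread; its cluster contributes its squared deviation from the area-wide
    mean of the z_c instead, with a logged warning. Returns per-area columns
    ``var, n_clusters, degenerate``.
    """
    labels = (
        dataset.hierarchy.admin1_labels if level == "admin1" else dataset.hierarchy.admin2_labels
    )
    rows = dataset.rows
    records = []
    for area in labels:
        sub = rows[rows[level] == area]
        if len(sub) == 0:
            records.append((area, np.nan, 0, True))
            continue
        w, y = sub["weight"].to_numpy(), sub["y"].to_numpy()
        nhat = w.sum()
        p = float(np.sum(w * y) / nhat)
        z = (
            sub.assign(zz=w * (y - p) / nhat)
            .groupby(["stratum", "cluster"])["zz"]
            .sum()
            .reset_index()
        )
        n_clusters = len(z)
        if p in (0.0, 1.0) or n_clusters == 1:
            records.append((area, np.nan, n_clusters, True))
            continue
        zbar_area = z["zz"].mean()
        var = 0.0
        for _, zh in z.groupby("stratum"):
            n_h = len(zh)
            if n_h == 1:
                var += float((zh["zz"].iloc[0] - zbar_area) ** 2)
                logger.warning(
                    "area %s: lonely PSU in stratum %s, using deviation from area mean",
                    area,
                    zh["stratum"].iloc[0],
                )
            else:
                var += n_h / (n_h - 1) * float(((zh["zz"] - zh["zz"].mean()) ** 2).sum())
        degenerate = var < VARIANCE_FLOOR
        records.append((area, var, n_clusters, degenerate))
    return pd.DataFrame(records, columns=["area", "var", "n_clusters", "degenerate"])


def logit_delta(estimates: DirectEstimates) -> DirectEstimates:
    """Fill logit-scale estimates θ̂ = logit(p̂) and V̂ = var/[p̂(1−p̂)]²."""
    tab = estimates.table
    ok = ~tab["degenerate"]
    n_skipped = int((~ok).sum())
    if n_skipped:
        logger.warning("logit transform skipped for %d degenerate area(s)", n_skipped)
    p = tab.loc[ok, "p_hat"]
    tab.loc[ok, "theta"] = logit(p)
    tab.loc[ok, "V"] = tab.loc[ok, "var"] / (p * (1.0 - p)) ** 2
    return estimates


def intervals_and_cv(estimates: DirectEstimates, level_prob: float = 0.95) -> DirectEstimates:
    """Fill CVs and uncertainty intervals.

    Intervals are built on the logit scale, θ̂ ± z·√V̂, and back-transformed,
    which respects the [0,1] range; cv = √var / p̂.
    """
    tab = estimates.table
    ok = ~tab["degenerate"]
    zq = norm.ppf(0.5 + level_prob / 2.0)
    half = zq * np.sqrt(tab.loc[ok, "V"])
    tab.loc[ok, "ci_lower"] = expit(tab.loc[ok, "theta"] - half)
    tab.loc[ok, "ci_upper"] = expit(tab.loc[ok, "theta"] + half)
    tab.loc[ok, "cv"] = np.sqrt(tab.loc[ok, "var"]) / tab.loc[ok, "p_hat"]
    tab.loc[ok, "width"] = tab.loc[ok, "ci_upper"] - tab.loc[ok, "ci_lower"]
    return estimates


def direct_estimates(
    dataset: SurveyDataset, level: str = "admin1", level_prob: float = 0.95
) -> DirectEstimates:
    """Full direct-estimation pass: prevalence, variance, logit transform, CIs."""
    p = weighted_prevalence(dataset, level)
    v = design_variance(dataset, level).set_index("area")
    tab = pd.DataFrame(
        {
            "area": p.index,
            "p_hat": p.to_numpy(),
            "var": v["var"].reindex(p.index).to_numpy(),
            "n_clusters": v["n_clusters"].reindex(p.index).fillna(0).astype(int).to_numpy(),
            "degenerate": v["degenerate"].reindex(p.index).fillna(True).astype(bool).to_numpy(),
        }
    )
    for col in ("theta", "V", "ci_lower", "ci_upper", "cv", "width"):
        tab[col] = np.nan
    est = DirectEstimates(tab, level)
    logit_delta(est)
    intervals_and_cv(est, level_prob)
    return est
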