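"""Model evaluation and posterior summaries.

Implements the screening diagnostics used to compare candidate prevalence
models: the posterior between-area variation statistic

    v = 1/(M−1) Σ_i (θ_i − θ̄)²,

computed per draw, which flags over-smoothing when a fine-resolution model
shows *less* between-area variation than a coarse model whose estimates are
copied down to the fine level; CV/interval-width screens against reporting
guidelines; exceedance probabilities P(θ_i > t); and aligned comparison
tables across models (correlation, shrinkage slope, interval exclusions).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from prevmap.direct import DirectEstimates
from prevmap.posterior import PosteriorField
from prevmap.survey_data import AreaHierarchy

#: CV threshold below which estimates are conventionally usable without restriction
DEFAULT_CV_THRESHOLD = 0.167


@dataclass
class BetweenAreaVariation:
    draws: np.ndarray  # v per posterior draw
    mean: float
    ci_lower: float
    ci_upper: float


def between_area_variation(field: PosteriorField, level_prob: float = 0.95) -> BetweenAreaVariation:
    """Posterior distribution of the between-area variance v of the prevalence field."""
    if len(field.areas) < 2:
        raise ValueError("need at least 2 areas")
    v = field.draws.var(axis=1, ddof=1)
    lo, hi = np.quantile(v, [0.5 - level_prob / 2, 0.5 + level_prob / 2])
    return BetweenAreaVariation(v, float(v.mean()), float(lo), float(hi))


def populate_finer_level(coarse: PosteriorField, hierarchy: AreaHierarchy) -> PosteriorField:
    """Copy Admin-1 draws down to every nested Admin-2 area (constant within parent)."""
    idx = {lab: k for k, lab in enumerate(coarse.areas)}
    cols = []
    for i, a2 in enumerate(hierarchy.admin2_labels):
        a1 = hierarchy.admin1_labels[hierarchy.a_of[i]]
        if a1 not in idx:
            raise ValueError(f"admin2 {a2!r} maps to admin1 {a1!r} absent from the coarse field")
        cols.append(coarse.draws[:, idx[a1]])
    return PosteriorField(np.column_stack(cols), hierarchy.admin2_labels, "admin2")


def exceedance_probability(field: PosteriorField, threshold: float) -> pd.Series:
    """Per-area posterior probability that the prevalence exceeds ``threshold``."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    prob = (field.draws > threshold).mean(axis=0)
    return pd.Series(prob, index=list(field.areas), name=f"P(theta>{threshold})")


def cv_screen(summary: pd.DataFrame, threshold: float = DEFAULT_CV_THRESHOLD) -> pd.DataFrame:
    """Flag areas whose coefficient of variation exceeds the reporting threshold."""
    out = summary.copy()
    out["cv_usable"] = out["cv"] < threshold
    return out


def _points(est) -> pd.DataFrame:
    if isinstance(est, DirectEstimates):
        tab = est.table
        return pd.DataFrame(
            {
                "area": tab["area"],
                "mean": tab["p_hat"],
                "median": tab["p_hat"],
                "q05": tab["ci_lower"],
                "q95": tab["ci_upper"],
                "cv": tab["cv"],
                "width": tab["width"],
                "degenerate": tab["degenerate"],
            }
        )
    s = est.summary()
    s["degenerate"] = False
    return s


def comparison_table(estimates: dict) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Align named estimate sets and summarise pairwise agreement.

    ``estimates`` maps model names to DirectEstimates or PosteriorFields.
    Returns a long table (one row per area x model; degenerate direct areas
    are flagged, not dropped) and a pairwise summary with the correlation of
    point estimates, the shrinkage slope of model B on model A around the
    cross-area grand mean (slope < 1 means B is shrunk relative to A), and
    counts of areas where one model's 90% interval excludes the other's point
    estimate.
    """
    tables = {}
    for name, est in estimates.items():
        t = _points(est)
        t.insert(1, "model", name)
        tables[name] = t
    shared = set.intersection(*[set(t["area"]) for t in tables.values()])
    if not shared:
        raise ValueError("estimate sets share no areas")
    long = pd.concat(tables.values(), ignore_index=True)

    rows = []
    names = list(tables)
    for a_name in names:
        for b_name in names:
            ta = tables[a_name].set_index("area").loc[sorted(shared, key=str)]
            tb = tables[b_name].set_index("area").loc[sorted(shared, key=str)]
            ok = (~ta["degenerate"]) & (~tb["degenerate"]) & ta["mean"].notna() & tb["mean"].notna()
            x, y = ta.loc[ok, "mean"].to_numpy(), tb.loc[ok, "mean"].to_numpy()
            if len(x) >= 2 and np.var(x) > 0:
                corr = float(np.corrcoef(x, y)[0, 1])
                slope = float(np.sum((x - x.mean()) * (y - y.mean())) / np.sum((x - x.mean()) ** 2))
            else:
                corr, slope = np.nan, np.nan
            excl = int(
                ((tb.loc[ok, "mean"] < ta.loc[ok, "q05"]) | (tb.loc[ok, "mean"] > ta.loc[ok, "q95"])).sum()
            )
            rows.append(
                {
                    "model_a": a_name,
                    "model_b": b_name,
                    "n_areas": int(ok.sum()),
                    "correlation": corr,
                    "shrinkage_slope": slope,
                    "b_outside_a_interval": excl,
                }
            )
    return long, pd.DataFrame(rows)
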