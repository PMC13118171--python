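"""Posterior containers shared by the area-level and cluster-level models."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd


@dataclass
class PosteriorField:
    """Posterior draws of area prevalences on the probability scale.

    ``draws`` is an S x M matrix; column order matches ``areas``. Summaries
    (means, quantiles, CVs) are always derived from the draws.
    """

    draws: np.ndarray
    areas: tuple
    level: str

    def __post_init__(self):
        self.draws = np.asarray(self.draws, dtype=float)
        self.areas = tuple(self.areas)
        if self.draws.ndim != 2 or self.draws.shape[1] != len(self.areas):
            raise ValueError("draws must be S x M with M = len(areas)")

    @property
    def n_draws(self) -> int:
        return self.draws.shape[0]

    def subset_draws(self, n: int) -> "PosteriorField":
        return PosteriorField(self.draws[:n], self.areas, self.level)

    def summary(self) -> pd.DataFrame:
        d = self.draws
        q05, q50, q95 = np.quantile(d, [0.05, 0.5, 0.95], axis=0)
        mean = d.mean(axis=0)
        sd = d.std(axis=0, ddof=1)
        return pd.DataFrame(
            {
                "area": list(self.areas),
                "mean": mean,
                "median": q50,
                "q05": q05,
                "q95": q95,
                "cv": sd / mean,
                "width": q95 - q05,
            }
        )


@dataclass
class PosteriorFit:
    """Posterior draws of model parameters.

    ``alpha`` is (S,) for a common intercept or (S, A) for per-Admin-1
    intercepts; ``gamma`` (rural log-odds shift) is None, (S,) or (S, A);
    ``u`` holds the area random effects at the model's resolution. For
    beta-binomial fits, ``d`` is the within-cluster overdispersion,
    ``p_draws`` the per-draw cluster prevalences and ``loglik`` the per-draw,
    per-cluster log-likelihood matrix used for WAIC.
    """

    variant: str
    level: str
    areas: tuple
    admin1_labels: tuple
    a_of: np.ndarray  # area -> admin1 index at the model resolution
    alpha: np.ndarray
    u: np.ndarray
    sigma: np.ndarray
    gamma: Optional[np.ndarray] = None
    beta: Optional[np.ndarray] = None
    phi: Optional[np.ndarray] = None
    d: Optional[np.ndarray] = None
    p_draws: Optional[np.ndarray] = None
    loglik: Optional[np.ndarray] = None
    diagnostics: dict = field(default_factory=dict)

    @property
    def n_draws(self) -> int:
        return self.u.shape[0]

    def alpha_by_area(self) -> np.ndarray:
        """Intercept draws expanded to one column per area, (S, M)."""
        if self.alpha.ndim == 1:
            return np.repeat(self.alpha[:, None], len(self.areas), axis=1)
        return self.alpha[:, self.a_of]

    def gamma_by_area(self) -> Optional[np.ndarray]:
        if self.gamma is None:
            return None
        if self.gamma.ndim == 1:
            return np.repeat(self.gamma[:, None], len(self.areas), axis=1)
        return self.gamma[:, self.a_of]

    def hyper_summary(self) -> pd.DataFrame:
        rows = []
        for name in ("sigma", "phi", "d", "gamma"):
            x = getattr(self, name)
            if x is None or x.ndim != 1:
                continue
            rows.append(
                {
                    "parameter": name,
                    "mean": float(x.mean()),
                    "q025": float(np.quantile(x, 0.025)),
                    "q975": float(np.quantile(x, 0.975)),
                }
            )
        return pd.DataFrame(rows)


def effective_sample_size(x: np.ndarray) -> float:
    """ESS via the initial positive sequence of autocorrelations (single chain)."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 10 or np.var(x) == 0:
        return float(n)
    xc = x - x.mean()
    acf = np.correlate(xc, xc, mode="full")[n - 1 :] / (np.arange(n, 0, -1) * np.var(x))
    tau = 1.0
    for k in range(1, min(n // 2, 1000)):
        if acf[k] < 0.0:
            break
        tau += 2.0 * acf[k]
    return float(n / tau)
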