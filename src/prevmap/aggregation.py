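"""Urban-fraction reconstruction and aggregation of cluster-level fits to areas.

Stratified cluster-level models estimate urban- and rural-specific
prevalences; turning them into an area prevalence requires the urban share of
the *target population*, q_i, which surveys do not provide at fine
resolution. It is reconstructed from gridded population counts by
thresholding: within each Admin-1 area, pixels are ranked by population
density and the densest prefix whose population share first reaches the
reported urban fraction (at the sampling-frame epoch T0) is designated urban.
The urban partition is frozen at T0 and combined with a target-population
grid at the survey year T to give

    q_i  = share of area i's target population in urban pixels,
    q'_p = share of area i's target population in pixel p (aggregation weights).

Area-level aggregation for the nested stratified model is then, per posterior
draw,

    θ_i = (1 − q_i)·expit(α_a[i] + γ + x_iᵀβ + u_i) + q_i·expit(α_a[i] + x_iᵀβ + u_i),

and pixel-level aggregation replaces the population clusters by pixels,
θ_i = Σ_p q'_p · expit(α_a + γ·1{p rural} + x_pᵀβ + u_i).

Rasters are plain gridded arrays with an ESRI-ASCII-style text header; pixel
arrays carry internal area ids (−1 outside the study region).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from prevmap.posterior import PosteriorField, PosteriorFit
from prevmap.survey_data import AreaHierarchy

logger = logging.getLogger(__name__)


@dataclass
class PopulationRaster:
    """Rectangular grid of non-negative population values with area labels.

    ``admin1`` / ``admin2`` hold internal area ids per pixel (−1 = outside
    the study region); ``values`` are population counts per pixel; ``epoch``
    tags the reference year ("T0" frame epoch or "T" survey epoch).
    """

    values: np.ndarray
    admin1: np.ndarray
    admin2: np.ndarray
    epoch: str = "T0"
    origin: tuple = (0.0, 0.0)
    step: float = 1.0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.admin1 = np.asarray(self.admin1, dtype=int)
        self.admin2 = np.asarray(self.admin2, dtype=int)
        if not (self.values.shape == self.admin1.shape == self.admin2.shape):
            raise ValueError("raster layers must share one shape")
        if np.any(self.values[self.admin1 >= 0] < 0):
            raise ValueError("population values must be non-negative")

    @property
    def inside(self) -> np.ndarray:
        return self.admin1 >= 0


def write_grid(path: str, values: np.ndarray, origin=(0.0, 0.0), step=1.0, nodata=-9999.0) -> None:
    """Write a 2D grid as a headered text file (ESRI ASCII grid layout)."""
    values = np.asarray(values, dtype=float)
    body = np.where(np.isfinite(values), values, nodata)
    with open(path, "w") as fh:
        fh.write(f"ncols {values.shape[1]}\n")
        fh.write(f"nrows {values.shape[0]}\n")
        fh.write(f"xllcorner {origin[0]}\n")
        fh.write(f"yllcorner {origin[1]}\n")
        fh.write(f"cellsize {step}\n")
        fh.write(f"NODATA_value {nodata}\n")
        np.savetxt(fh, body, fmt="%.10g")


def read_grid(path: str) -> tuple[np.ndarray, dict]:
    """Read a headered text grid; nodata cells become NaN."""
    header = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        body = np.loadtxt(fh)
    body = body.reshape(int(header["nrows"]), int(header["ncols"]))
    body[body == header["nodata_value"]] = np.nan
    return body, header


@dataclass
class UrbanPartition:
    """Per-pixel urban labels with per-Admin-1 density thresholds."""

    urban: np.ndarray  # 2D bool
    thresholds: pd.Series  # per admin1 internal id
    achieved_fraction: pd.Series
    target_fraction: pd.Series


@dataclass
class UrbanFractions:
    """Urban population shares q_i per area and within-area pixel weights q'."""

    q: pd.Series  # per area internal id, NaN where no target population
    qprime: np.ndarray  # 2D, sums to 1 over each area with population
    level: str = "admin2"


def urban_threshold_partition(
    raster_T0: PopulationRaster, admin1_urban_fracs: Sequence[float]
) -> UrbanPartition:
    """Partition pixels into urban/rural matching reported Admin-1 urban fractions.

    Within each Admin-1, pixels are sorted by population descending (ties
    broken by flat pixel index) and the smallest prefix whose cumulative
    population share first reaches the target fraction is urban; the achieved
    fraction (>= target except when clamped) and the gap are logged.
    """
    fracs = np.asarray(admin1_urban_fracs, dtype=float)
    if np.any((fracs < 0) | (fracs > 1)):
        raise ValueError("urban fractions must lie in [0, 1]")
    urban = np.zeros(raster_T0.values.shape, dtype=bool)
    thresholds, achieved = {}, {}
    flat_pop = raster_T0.values.ravel()
    flat_a1 = raster_T0.admin1.ravel()
    for a1, target in enumerate(fracs):
        idx = np.flatnonzero(flat_a1 == a1)
        total = flat_pop[idx].sum()
        if total <= 0:
            raise ValueError(f"admin1 {a1} has zero total population")
        order = idx[np.lexsort((idx, -flat_pop[idx]))]
        cum = np.cumsum(flat_pop[order]) / total
        reach = np.flatnonzero(cum >= target - 1e-12)
        if target <= 0:
            n_urban = 0
        elif len(reach) == 0:
            n_urban = len(order)  # unattainable: clamp to all-urban
            logger.warning("admin1 %d: urban target %.3f unattainable, clamped", a1, target)
        else:
            n_urban = int(reach[0]) + 1
        chosen = order[:n_urban]
        urban.ravel()[chosen] = True
        thresholds[a1] = float(flat_pop[chosen].min()) if n_urban else float("inf")
        achieved[a1] = float(flat_pop[chosen].sum() / total)
        if abs(achieved[a1] - target) > 1e-9:
            logger.info(
                "admin1 %d: achieved urban fraction %.4f vs target %.4f", a1, achieved[a1], target
            )
    return UrbanPartition(
        urban,
        pd.Series(thresholds, name="threshold"),
        pd.Series(achieved, name="achieved"),
        pd.Series(fracs, name="target"),
    )


def target_population_fractions(
    partition: UrbanPartition,
    target_raster_T: PopulationRaster,
    hierarchy: AreaHierarchy,
    level: str = "admin2",
) -> UrbanFractions:
    """Urban shares q_i of the target population, and within-area pixel weights q'."""
    pop = target_raster_T.values
    labels = target_raster_T.admin2 if level == "admin2" else target_raster_T.admin1
    n_areas = hierarchy.n_admin2 if level == "admin2" else hierarchy.n_admin1
    if partition.urban.shape != pop.shape:
        raise ValueError("partition and target raster are not co-registered")
    q = np.full(n_areas, np.nan)
    qprime = np.zeros(pop.shape)
    for i in range(n_areas):
        mask = labels == i
        total = pop[mask].sum()
        if total <= 0:
            logger.warning("area %d has zero target population; q missing", i)
            continue
        q[i] = pop[mask & partition.urban].sum() / total
        qprime[mask] = pop[mask] / total
    return UrbanFractions(pd.Series(q, name="q"), qprime, level)


def _eta_components(fit: PosteriorFit, area_covariates: Optional[np.ndarray]):
    eta = fit.alpha_by_area() + fit.u
    if area_covariates is not None:
        if fit.beta is None:
            raise ValueError("fit has no covariate coefficients")
        X = np.atleast_2d(np.asarray(area_covariates, dtype=float))
        eta = eta + fit.beta @ X.T
    return eta


def aggregate_stratified_area(
    fit: PosteriorFit,
    fractions: UrbanFractions | pd.Series,
    area_covariates: Optional[np.ndarray] = None,
) -> PosteriorField:
    """Aggregate a cluster-level fit to area prevalences with area-level inputs.

    Per draw, θ_i = (1−q_i)·expit(η_i + γ_i) + q_i·expit(η_i) with
    η_i = α_a[i] + x_iᵀβ + u_i; an unstratified fit returns expit(η_i)
    regardless of q. Areas with missing q are dropped with a warning.
    """
    q = fractions.q if isinstance(fractions, UrbanFractions) else pd.Series(fractions)
    q = q.reindex(range(len(fit.areas))).to_numpy(dtype=float)
    eta = _eta_components(fit, area_covariates)
    gamma = fit.gamma_by_area()
    if gamma is None:
        theta = expit(eta)
        keep = np.ones(len(fit.areas), dtype=bool)
    else:
        keep = np.isfinite(q)
        if not keep.all():
            logger.warning(
                "skipping %d area(s) with missing urban fraction", int((~keep).sum())
            )
        theta = (1.0 - q) * expit(eta + gamma) + q * expit(eta)
    areas = tuple(a for a, k in zip(fit.areas, keep) if k)
    return PosteriorField(theta[:, keep], areas, fit.level)


def aggregate_pixel_level(
    fit: PosteriorFit,
    partition: UrbanPartition,
    covariate_rasters: Optional[Sequence[np.ndarray]],
    target_raster_T: PopulationRaster,
    batch: int = 256,
) -> PosteriorField:
    """Aggregate a cluster-level fit over pixels standing in for population clusters.

    Per draw, θ_i = Σ_{pixels p in i} q'_p · expit(α_a(p) + γ·1{p rural} +
    x_pᵀβ + u_i(p)). Pixel urban/rural labels come from the T0 partition;
    weights q' from the target population at T. Raises if a covariate is
    missing (NaN) on a populated pixel.
    """
    pop = target_raster_T.values
    a2 = target_raster_T.admin2
    a1 = target_raster_T.admin1
    level_labels = a2 if fit.level == "admin2" else a1
    populated = (level_labels >= 0) & (pop > 0)
    flat = np.flatnonzero(populated.ravel())
    if covariate_rasters:
        Xpix = np.column_stack([np.asarray(r, dtype=float).ravel()[flat] for r in covariate_rasters])
        bad = flat[~np.isfinite(Xpix).all(axis=1)]
        if len(bad):
            raise ValueError(f"covariate nodata on populated pixel(s) {bad.tolist()}")
    else:
        Xpix = None
    area_pix = level_labels.ravel()[flat]
    a1_pix = a1.ravel()[flat]
    rural_pix = ~partition.urban.ravel()[flat]
    pop_pix = pop.ravel()[flat]

    M = len(fit.areas)
    area_tot = np.bincount(area_pix, weights=pop_pix, minlength=M)
    has_pop = area_tot > 0
    if not has_pop.all():
        logger.warning("%d area(s) have zero target population; dropped", int((~has_pop).sum()))
    w_pix = pop_pix / area_tot[area_pix]

    S = fit.n_draws
    gamma = fit.gamma
    theta = np.zeros((S, M))
    from scipy import sparse

    sum_by_area = sparse.csr_matrix(
        (np.ones(len(flat)), (np.arange(len(flat)), area_pix)), shape=(len(flat), M)
    )
    for s0 in range(0, S, batch):
        sl = slice(s0, min(s0 + batch, S))
        if fit.alpha.ndim == 2:
            eta = fit.alpha[sl][:, a1_pix]
        else:
            eta = np.repeat(fit.alpha[sl][:, None], len(flat), axis=1)
        if gamma is not None:
            if gamma.ndim == 2:
                g = gamma[sl][:, a1_pix]
            else:
                g = gamma[sl][:, None]
            eta = eta + g * rural_pix[None, :]
        if Xpix is not None:
            if fit.beta is None:
                raise ValueError("fit has no covariate coefficients")
            eta = eta + fit.beta[sl] @ Xpix.T
        eta = eta + fit.u[sl][:, area_pix]
        contrib = expit(eta) * w_pix[None, :]
        theta[sl] = contrib @ sum_by_area
    areas = tuple(a for a, k in zip(fit.areas, has_pop) if k)
    return PosteriorField(theta[:, has_pop], areas, fit.level)
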