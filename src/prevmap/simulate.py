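"""Synthetic population frames and stratified two-stage PPS surveys.

The generator emulates the design of a national household survey built on a
census frame: enumeration areas (EAs) nested in Admin-2 areas nested in
Admin-1 areas, urban/rural strata within each Admin-1, clusters drawn by
systematic probability-proportional-to-size (PPS) sampling with households as
the size measure, a fixed take of individuals per cluster, and design weights
equal to inverse inclusion probabilities (with optional non-response
inflation). Defaults follow the scale of a recent national survey: 47 Admin-1
areas, 300 Admin-2 areas on a lattice, ~129,000 EAs, 92 urban/rural strata,
~1,700 sampled clusters, 25 individuals per cluster, and urban over-sampling.

EA-level truth is drawn from the nested stratified cluster model
(logit p_c = α_a + γ·1{rural} + x_cᵀβ + u_i with BYM2 Admin-2 effects), so
every stage of the estimation pipeline can be validated against known truth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from prevmap.aggregation import PopulationRaster
from prevmap.spatial import AdjacencyGraph, bym2_effect, lattice_adjacency, scaled_icar
from prevmap.survey_data import AreaHierarchy, SurveyDataset

logger = logging.getLogger(__name__)


@dataclass
class SimConfig:
    """True-model and frame configuration.

    The linear predictor of EA prevalence is
    logit(p_c) = α_a + γ·1{rural} + x_cᵀβ + u_i with u BYM2(σ, ϕ) on the
    Admin-2 lattice. ``alpha0`` is the national-level intercept (its default
    is logit of a two-thirds national prevalence) and ``alpha_sd`` the spread
    of the per-Admin-1 intercepts around it.
    """

    n_admin1: int = 47
    n_admin2: int = 300
    mean_eas_per_admin2: float = 430.0  # ~129,000 EAs nationally
    urban_ea_frac: float = 0.35
    alpha0: float = 0.663
    alpha_sd: float = 0.3
    gamma: float = -0.45
    beta: tuple = ()
    sigma: float = 0.3
    phi: float = 0.5
    d: float = 0.15
    household_mu: float = np.log(100.0)
    household_sigma: float = 0.5
    eligible_mean: float = 60.0

    def __post_init__(self):
        if self.n_admin2 < self.n_admin1 or self.n_admin1 < 1:
            raise ValueError("need n_admin2 >= n_admin1 >= 1")
        if not (0 <= self.phi <= 1) or self.sigma < 0 or not (0 <= self.d < 1):
            raise ValueError("invalid variance parameters")
        if not 0 < self.urban_ea_frac < 1:
            raise ValueError("urban_ea_frac must lie in (0, 1)")


@dataclass
class DesignConfig:
    """Two-stage sampling design.

    ``clusters_per_admin1`` are allocated to the urban/rural strata in
    proportion to stratum households, with the urban share multiplied by
    ``urban_oversample`` before normalisation (2 = urban clusters twice as
    likely per household as proportional allocation would give).
    """

    clusters_per_admin1: int = 36
    take_per_cluster: int = 25
    urban_oversample: float = 2.0
    nonresponse_rate: float = 0.0

    def __post_init__(self):
        if self.clusters_per_admin1 < 1 or self.take_per_cluster < 1:
            raise ValueError("sample sizes must be positive")
        if self.urban_oversample <= 0:
            raise ValueError("over-sampling factor must be > 0")
        if not 0 <= self.nonresponse_rate < 1:
            raise ValueError("nonresponse rate must lie in [0, 1)")


@dataclass
class PopulationFrame:
    """EA-level frame with known truth.

    ``eas`` columns: ea, admin1, admin2, urban, households, eligible, p_c and
    covariates x0.. ; ``graph`` is the Admin-2 lattice adjacency used for the
    true spatial effect; truth tables are eligible-weighted means of p_c.
    """

    eas: pd.DataFrame
    hierarchy: AreaHierarchy
    graph: AdjacencyGraph
    config: SimConfig
    lattice_shape: tuple
    u_true: np.ndarray
    alpha_true: np.ndarray

    def covariate_columns(self) -> list:
        return [c for c in self.eas.columns if c.startswith("x")]


def _lattice_shape(n_admin2: int) -> tuple[int, int]:
    nrows = int(np.floor(np.sqrt(n_admin2)))
    while n_admin2 % nrows:
        nrows -= 1
    return nrows, n_admin2 // nrows


def generate_frame(config: SimConfig, seed: int = 0) -> PopulationFrame:
    """Draw a population frame with EA prevalences from the nested stratified model."""
    rng = np.random.default_rng(seed)
    M1, M2 = config.n_admin1, config.n_admin2
    nrows, ncols = _lattice_shape(M2)
    graph = lattice_adjacency(nrows, ncols)
    a_of = (np.arange(M2) * M1) // M2  # contiguous admin1 blocks in lattice order
    hierarchy = AreaHierarchy.from_table(
        pd.DataFrame({"admin2": np.arange(M2), "admin1": a_of})
    )

    alpha_a = config.alpha0 + config.alpha_sd * rng.standard_normal(M1)
    if config.sigma > 0:
        icar = scaled_icar(graph)
        e_st = icar.sample(rng, 1)[0]
        e_st[icar.singletons] = rng.standard_normal(int(icar.singletons.sum()))
        u = bym2_effect(config.sigma, config.phi, rng.standard_normal(M2), e_st)
    else:
        u = np.zeros(M2)

    n_ea = rng.poisson(config.mean_eas_per_admin2, size=M2).clip(min=1)
    admin2 = np.repeat(np.arange(M2), n_ea)
    admin1 = a_of[admin2]
    n_total = len(admin2)
    # per-admin1 urban EA shares vary around the national mean
    f = config.urban_ea_frac
    kappa = 30.0
    urban_share = rng.beta(f * kappa, (1 - f) * kappa, size=M1)
    urban = rng.uniform(size=n_total) < urban_share[admin1]
    households = np.maximum(
        1, np.round(rng.lognormal(config.household_mu, config.household_sigma, n_total))
    ).astype(int)
    eligible = np.maximum(1, rng.poisson(config.eligible_mean, n_total))

    eta = alpha_a[admin1] + config.gamma * (~urban) + u[admin2]
    eas = pd.DataFrame(
        {
            "ea": np.arange(n_total),
            "admin1": admin1,
            "admin2": admin2,
            "urban": urban,
            "households": households,
            "eligible": eligible,
        }
    )
    beta = np.asarray(config.beta, dtype=float)
    if beta.size:
        # smooth low-order spatial surfaces plus noise, standardised
        r = (admin2 // ncols) / max(nrows - 1, 1)
        c = (admin2 % ncols) / max(ncols - 1, 1)
        for j in range(beta.size):
            raw = (
                np.cos((j + 1) * np.pi * r)
                + np.sin((j + 2) * np.pi * c)
                + 0.3 * rng.standard_normal(n_total)
            )
            x = (raw - raw.mean()) / raw.std()
            eas[f"x{j}"] = x
            eta = eta + beta[j] * x
    eas["p_c"] = expit(eta)
    logger.info("generated frame: %d EAs, %d strata", n_total, 2 * M1)
    return PopulationFrame(eas, hierarchy, graph, config, (nrows, ncols), u, alpha_a)


def true_area_prevalence(frame: PopulationFrame, level: str = "admin2") -> pd.Series:
    """Eligible-population-weighted mean of EA prevalences per area."""
    eas = frame.eas
    num = (eas["p_c"] * eas["eligible"]).groupby(eas[level]).sum()
    den = eas["eligible"].groupby(eas[level]).sum()
    truth = num / den
    truth.name = "truth"
    return truth


def _systematic_pps(sizes: np.ndarray, m: int, rng: np.random.Generator):
    """Systematic PPS without replacement; returns (indices, inclusion probs).

    Units whose size share exceeds 1/m are selected with certainty and the
    remainder re-allocated, the standard recursive treatment.
    """
    sizes = np.asarray(sizes, dtype=float)
    n = len(sizes)
    if m >= n:
        return np.arange(n), np.ones(n)[np.arange(n)]
    pi = m * sizes / sizes.sum()
    certain = pi >= 1.0
    if certain.any():
        rest_idx = np.flatnonzero(~certain)
        sub_sel, sub_pi = _systematic_pps(sizes[rest_idx], m - int(certain.sum()), rng)
        sel = np.concatenate([np.flatnonzero(certain), rest_idx[sub_sel]])
        probs = np.concatenate([np.ones(int(certain.sum())), sub_pi])
        return sel, probs
    order = rng.permutation(n)  # random ordering before the systematic pass
    cum = np.cumsum(sizes[order])
    interval = cum[-1] / m
    start = rng.uniform(0, interval)
    points = start + interval * np.arange(m)
    pos = np.searchsorted(cum, points)
    sel = order[pos]
    return sel, pi[sel]


def draw_survey(frame: PopulationFrame, design: DesignConfig, seed: int = 0) -> SurveyDataset:
    """Draw one stratified two-stage PPS survey from the frame.

    Strata are Admin-1 x urban/rural. Cluster inclusion probabilities are
    PPS on households; individuals are an SRS of the fixed take within each
    selected cluster (capped at availability); outcomes are beta-binomial
    (a cluster-level Beta draw around p_c with correlation d, then Bernoulli);
    weights are inverse inclusion probabilities with non-response inflation.
    """
    rng = np.random.default_rng(seed)
    eas = frame.eas
    cfg = frame.config
    cols = {k: [] for k in ("cluster", "stratum", "admin1", "admin2", "urban", "y", "weight")}
    for a1, grp in eas.groupby("admin1"):
        h_u = grp.loc[grp["urban"], "households"].sum()
        h_r = grp.loc[~grp["urban"], "households"].sum()
        m = design.clusters_per_admin1
        if h_u == 0 or h_r == 0:
            alloc = {True: m if h_u else 0, False: m if h_r else 0}
        else:
            w_u = design.urban_oversample * h_u / (design.urban_oversample * h_u + h_r)
            m_u = int(np.clip(round(m * w_u), 1, m - 1))
            alloc = {True: m_u, False: m - m_u}
        for is_urban, m_h in alloc.items():
            if m_h == 0:
                continue
            stratum = grp[grp["urban"] == is_urban]
            if len(stratum) < m_h:
                raise ValueError(
                    f"stratum admin1={a1} {'urban' if is_urban else 'rural'} has "
                    f"{len(stratum)} EAs < {m_h} requested clusters"
                )
            sel, pi = _systematic_pps(stratum["households"].to_numpy(), m_h, rng)
            chosen = stratum.iloc[sel]
            label = f"{a1}:{'U' if is_urban else 'R'}"
            N_c = chosen["eligible"].to_numpy()
            t = np.minimum(design.take_per_cluster, N_c)
            p_c = chosen["p_c"].to_numpy()
            if cfg.d > 0:
                a = p_c * (1 - cfg.d) / cfg.d
                b = (1 - p_c) * (1 - cfg.d) / cfg.d
                q_c = rng.beta(a, b)
            else:
                q_c = p_c
            tot = int(t.sum())
            y = (rng.uniform(size=tot) < np.repeat(q_c, t)).astype(int)
            keep = np.ones(tot, dtype=bool)
            if design.nonresponse_rate > 0:
                keep = rng.uniform(size=tot) >= design.nonresponse_rate
            n_resp = np.bincount(
                np.repeat(np.arange(m_h), t), weights=keep.astype(float), minlength=m_h
            )
            ok = n_resp > 0
            keep &= np.repeat(ok, t)
            # inverse inclusion probability with non-response inflation:
            # w = (N_c / t) / pi_c * (t / n_responding)
            w_cluster = np.divide(
                N_c / pi, n_resp, out=np.zeros(m_h), where=n_resp > 0
            )
            cols["cluster"].append(np.repeat(chosen["ea"].to_numpy(), t)[keep])
            cols["admin1"].append(np.repeat(chosen["admin1"].to_numpy(), t)[keep])
            cols["admin2"].append(np.repeat(chosen["admin2"].to_numpy(), t)[keep])
            cols["urban"].append(np.full(tot, is_urban)[keep])
            cols["stratum"].append(np.full(tot, label, dtype=object)[keep])
            cols["y"].append(y[keep])
            cols["weight"].append(np.repeat(w_cluster, t)[keep])
    table = pd.DataFrame({k: np.concatenate(v) for k, v in cols.items()})
    return SurveyDataset(table, frame.hierarchy)


def generate_rasters(
    frame: PopulationFrame, pixels_per_area: int = 2, seed: int = 0
) -> tuple[PopulationRaster, PopulationRaster, np.ndarray]:
    """Co-registered population grids at T0 and T plus one covariate surface.

    Each Admin-2 lattice cell becomes a ``pixels_per_area`` x
    ``pixels_per_area`` block of pixels; T0 pixel populations are lognormal,
    the T target population perturbs them, and the covariate is a smooth
    surface with noise. Intended as a desk-scale stand-in for gridded
    population products.
    """
    rng = np.random.default_rng(seed)
    nrows, ncols = frame.lattice_shape
    g = pixels_per_area
    shape = (nrows * g, ncols * g)
    rr, cc = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    admin2 = (rr // g) * ncols + (cc // g)
    a_of = frame.hierarchy.a_of
    admin1 = a_of[admin2]
    pop0 = rng.lognormal(np.log(500.0), 1.0, shape)
    popT = pop0 * rng.lognormal(0.0, 0.2, shape) * 0.3  # target sub-population at T
    cov = (
        np.cos(np.pi * rr / shape[0])
        + np.sin(2 * np.pi * cc / shape[1])
        + 0.2 * rng.standard_normal(shape)
    )
    cov = (cov - cov.mean()) / cov.std()
    r0 = PopulationRaster(pop0, admin1, admin2, epoch="T0")
    rT = PopulationRaster(popT, admin1, admin2, epoch="T")
    return r0, rT, cov
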