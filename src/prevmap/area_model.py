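"""Area-level (Fay-Herriot) smoothing of logit-scale direct estimates.

Sampling model:   θ̂_i | θ_i ~ N(θ_i, V̂_i)   (V̂_i known, from the design)
Linking model:    θ_i = α + x_iᵀβ + u_i

with u either IID normal or a BYM2 spatial effect, and PC hyperpriors.
Latent prevalences are expit(θ_i). Inference is by MCMC: the Gaussian latent
field (α, β, u) is integrated out analytically, an adaptive random-walk
Metropolis chain explores (σ, ϕ), and exact Gaussian conditional draws of the
latent field are generated for each retained hyperparameter draw, so latent
draws carry no Metropolis error of their own.

Areas whose direct estimate is degenerate contribute no likelihood term and
are predicted from the linking model alone (through the spatial correlation
and the fixed effects). Before fitting at a fine level, areas whose design
variance is missing or collapses to zero can be rescued by *phantom clusters*
carrying the parent Admin-1 prevalence (:func:`add_phantom_clusters`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.special import expit

from prevmap.direct import VARIANCE_FLOOR, DirectEstimates, direct_estimates
from prevmap.posterior import PosteriorField, PosteriorFit, effective_sample_size
from prevmap.spatial import AdjacencyGraph, PCPriorSpec, pc_prior_phi, pc_prior_sd, scaled_icar
from prevmap.survey_data import SurveyDataset

logger = logging.getLogger(__name__)


@dataclass
class FHModelSpec:
    """Configuration of a Fay-Herriot fit.

    ``effect`` selects the random-effect structure ("iid" or "bym2").
    ``covariates`` is an optional (M, k) array aligned with the areas of the
    direct estimates. Hyperparameters can be pinned with ``fixed_sigma`` /
    ``fixed_phi`` (and the intercept with ``fixed_intercept``), which turns
    the sampler into exact Gaussian conditional simulation.
    """

    effect: str = "bym2"
    covariates: Optional[np.ndarray] = None
    priors: PCPriorSpec = field(default_factory=PCPriorSpec)
    draws: int = 4000
    burn: int = 2000
    seed: int = 0
    fixed_sigma: Optional[float] = None
    fixed_phi: Optional[float] = None
    fixed_intercept: Optional[float] = None
    intercept_sd: float = 31.6
    beta_sd: float = 31.6

    def __post_init__(self):
        if self.effect not in ("iid", "bym2"):
            raise ValueError("effect must be 'iid' or 'bym2'")
        if self.draws < 1:
            raise ValueError("draws must be >= 1")


def find_failing_areas(direct: DirectEstimates) -> list:
    """Areas whose design variance is missing or at/below the floor."""
    tab = direct.table
    bad = tab["degenerate"] | ~np.isfinite(tab["var"]) | (tab["var"] < VARIANCE_FLOOR)
    return tab.loc[bad, "area"].tolist()


def add_phantom_clusters(
    dataset: SurveyDataset,
    direct_admin1: DirectEstimates,
    failing_areas: Sequence,
) -> SurveyDataset:
    """Rescue Admin-2 areas with unusable design variances by phantom clusters.

    Each failing Admin-2 area receives a synthetic cluster whose prevalence
    equals the direct estimate of its parent Admin-1 area and whose summed
    weight equals the mean cluster weight-sum among the Admin-1's observed
    clusters. Counts are realised as n = round(mean cluster size) and
    Y = round(n·p̂). An area with no observed cluster receives a *pair* of
    phantom clusters with counts split one above/one below round(n·p̂): a
    single cluster (or two identical ones) always yields a zero linearised
    variance, so the pair is the minimal augmentation that makes the
    within-area Taylor variance computable. Phantom rows are flagged via a
    ``phantom`` column; the phantom cluster joins the modal stratum of its
    Admin-1's observed clusters.
    """
    if len(failing_areas) == 0:
        return dataset
    hierarchy = dataset.hierarchy
    clusters = dataset.to_clusters().table
    a1_tab = direct_admin1.table.set_index("area")
    rows = dataset.rows.copy()
    if "phantom" not in rows.columns:
        rows["phantom"] = False
    new_rows = []
    for area in failing_areas:
        admin1 = hierarchy.admin1_of_admin2([area])[0]
        if admin1 not in a1_tab.index or bool(a1_tab.loc[admin1, "degenerate"]):
            raise ValueError(
                f"cannot rescue area {area!r}: Admin-1 {admin1!r} direct estimate is degenerate"
            )
        p1 = float(a1_tab.loc[admin1, "p_hat"])
        obs = clusters[clusters["admin1"] == admin1]
        if len(obs) == 0:
            raise ValueError(f"no observed clusters in Admin-1 {admin1!r}")
        mean_sum_w = float(obs["sum_w"].mean())
        n = max(1, int(round(obs["n"].mean())))
        stratum = obs["stratum"].mode().iloc[0]
        existing = clusters[clusters["admin2"] == area]
        y0 = int(round(n * p1))
        if len(existing) == 0:
            targets = [min(n, y0 + 1), max(0, y0 - 1)]
        else:
            targets = [y0]
            # A single phantom whose composition matches the area's existing
            # cluster(s) still yields a zero linearised variance (all cluster
            # residual totals coincide); straddle the target by one instead.
            rates = set(np.round(existing["Y"] / existing["n"], 12))
            if rates == {round(y0 / n, 12)}:
                targets = [min(n, y0 + 1), max(0, y0 - 1)]
        for k, Y in enumerate(targets):
            cid = f"phantom::{area}::{k}"
            y = np.zeros(n, dtype=int)
            y[:Y] = 1
            new_rows.append(
                pd.DataFrame(
                    {
                        "cluster": cid,
                        "stratum": stratum,
                        "admin1": admin1,
                        "admin2": area,
                        "urban": False,
                        "y": y,
                        "weight": mean_sum_w / n,
                        "phantom": True,
                    }
                )
            )
            logger.info(
                "phantom cluster %s: n=%d Y=%d sum_w=%.3f stratum=%s", cid, n, Y, mean_sum_w, stratum
            )
    out = pd.concat([rows] + new_rows, ignore_index=True)
    return SurveyDataset(out, hierarchy)


class _FHSampler:
    """Marginal Metropolis on (σ, ϕ) + exact Gaussian conditional latent draws."""

    def __init__(self, direct: DirectEstimates, graph: Optional[AdjacencyGraph], spec: FHModelSpec):
        tab = direct.table
        self.areas = tuple(tab["area"])
        self.M = len(self.areas)
        ok = (~tab["degenerate"]) & np.isfinite(tab["theta"]) & np.isfinite(tab["V"])
        self.obs = np.flatnonzero(ok.to_numpy())
        if len(self.obs) < 2:
            raise ValueError("need non-degenerate direct estimates for at least 2 areas")
        bad = tab.loc[~tab["degenerate"]].index[
            ~np.isfinite(tab.loc[~tab["degenerate"], ["theta", "V"]]).all(axis=1)
        ]
        if len(bad):
            raise ValueError(f"non-finite inputs for areas {tab.loc[bad, 'area'].tolist()}")
        self.theta_obs = tab["theta"].to_numpy()[self.obs]
        self.V_obs = tab["V"].to_numpy()[self.obs]
        self.spec = spec

        cols, sds = [], []
        if spec.fixed_intercept is None:
            cols.append(np.ones(self.M))
            sds.append(spec.intercept_sd)
        self.offset = 0.0 if spec.fixed_intercept is None else float(spec.fixed_intercept)
        if spec.covariates is not None:
            X = np.atleast_2d(np.asarray(spec.covariates, dtype=float))
            if X.shape[0] != self.M:
                raise ValueError("covariate rows must align with areas")
            for j in range(X.shape[1]):
                cols.append(X[:, j])
                sds.append(spec.beta_sd)
        self.F = np.column_stack(cols) if cols else np.zeros((self.M, 0))
        self.delta_sd = np.array(sds)
        self.p = self.F.shape[1]

        if spec.effect == "bym2":
            if graph is None:
                raise ValueError("bym2 effect requires an adjacency graph")
            if graph.n != self.M:
                raise ValueError("graph size must match number of areas")
            self.icar = scaled_icar(graph)
            self.cov_mod = self.icar.cov.copy()
            s = self.icar.singletons
            self.cov_mod[s, s] = 1.0  # islands carry a pure unstructured effect
            self.phi_prior = pc_prior_phi(self.icar, spec.priors.phi_threshold, spec.priors.alpha_phi)
        else:
            self.icar = None
            self.cov_mod = None
            self.phi_prior = None
        self.sd_prior = pc_prior_sd(spec.priors.U_sigma, spec.priors.alpha_sigma)

    def u_cov(self, sigma: float, phi: float) -> np.ndarray:
        if self.spec.effect == "iid":
            return sigma**2 * np.eye(self.M)
        return sigma**2 * ((1.0 - phi) * np.eye(self.M) + phi * self.cov_mod)

    def marginal(self, sigma: float, phi: float):
        """Log N(θ̂_obs; offset, C) with the latent Gaussian field integrated out."""
        Su = self.u_cov(sigma, phi)
        Fo = self.F[self.obs]
        C = Su[np.ix_(self.obs, self.obs)] + np.diag(self.V_obs)
        if self.p:
            C += (Fo * self.delta_sd**2) @ Fo.T
        cf = cho_factor(C, lower=True)
        resid = self.theta_obs - self.offset
        quad = resid @ cho_solve(cf, resid)
        logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
        ll = -0.5 * (quad + logdet + len(self.obs) * np.log(2.0 * np.pi))
        return ll, cf, Su

    def log_post(self, sigma: float, phi: float):
        ll, cf, Su = self.marginal(sigma, phi)
        lp = ll
        if self.spec.fixed_sigma is None:
            lp += float(self.sd_prior.logpdf(sigma)) + np.log(sigma)  # log-scale Jacobian
        if self.spec.effect == "bym2" and self.spec.fixed_phi is None:
            lp += float(self.phi_prior.logpdf(phi)) + np.log(phi * (1.0 - phi))
        return lp, cf, Su

    def sample_u_prior(self, rng: np.random.Generator, sigma: float, phi: float) -> np.ndarray:
        if self.spec.effect == "iid":
            return sigma * rng.standard_normal(self.M)
        e_un = rng.standard_normal(self.M)
        e_st = self.icar.sample(rng, 1)[0]
        s = self.icar.singletons
        e_st[s] = rng.standard_normal(int(s.sum()))
        return sigma * (np.sqrt(1.0 - phi) * e_un + np.sqrt(phi) * e_st)

    def run(self):
        spec = self.spec
        rng = np.random.default_rng(spec.seed)
        sigma = spec.fixed_sigma if spec.fixed_sigma is not None else 0.5
        phi = 0.5
        if spec.effect == "iid":
            phi = 0.0
        elif spec.fixed_phi is not None:
            phi = spec.fixed_phi

        free = []
        if spec.fixed_sigma is None:
            free.append("sigma")
        if spec.effect == "bym2" and spec.fixed_phi is None:
            free.append("phi")
        step = {name: 0.5 for name in free}
        n_acc = {name: 0 for name in free}

        lp, cf, Su = self.log_post(sigma, phi)
        total = spec.burn + spec.draws
        S = spec.draws
        out = {
            "sigma": np.empty(S),
            "phi": np.empty(S),
            "delta": np.empty((S, self.p)),
            "u": np.empty((S, self.M)),
        }
        Fo = self.F[self.obs]
        for it in range(total):
            for name in free:
                if name == "sigma":
                    prop_sigma = sigma * np.exp(step[name] * rng.standard_normal())
                    prop_phi = phi
                else:
                    z = np.log(phi / (1 - phi)) + step[name] * rng.standard_normal()
                    prop_phi = 1.0 / (1.0 + np.exp(-z))
                    prop_sigma = sigma
                lp_prop, cf_prop, Su_prop = self.log_post(prop_sigma, prop_phi)
                accept = np.log(rng.uniform()) < lp_prop - lp
                if accept:
                    sigma, phi, lp, cf, Su = prop_sigma, prop_phi, lp_prop, cf_prop, Su_prop
                    n_acc[name] += 1
                if it < spec.burn:
                    step[name] = float(
                        np.exp(np.log(step[name]) + (int(accept) - 0.44) / (it + 1) ** 0.6)
                    )
            if it >= spec.burn:
                # exact conditional draw of (delta, u) | theta_hat, sigma, phi
                k = it - spec.burn
                delta0 = self.delta_sd * rng.standard_normal(self.p)
                u0 = self.sample_u_prior(rng, sigma, phi)
                eps0 = np.sqrt(self.V_obs) * rng.standard_normal(len(self.obs))
                y0 = (Fo @ delta0 if self.p else 0.0) + u0[self.obs] + eps0
                resid = self.theta_obs - self.offset - y0
                w = cho_solve(cf, resid)
                Kdelta = (self.delta_sd[:, None] ** 2) * Fo.T if self.p else np.zeros((0, len(self.obs)))
                Ku = Su[:, self.obs]
                out["delta"][k] = delta0 + Kdelta @ w
                out["u"][k] = u0 + Ku @ w
                out["sigma"][k] = sigma
                out["phi"][k] = phi

        diag = {name: n_acc[name] / total for name in free}
        diag["ess_sigma"] = effective_sample_size(out["sigma"]) if "sigma" in free else float(S)
        if "phi" in free:
            diag["ess_phi"] = effective_sample_size(out["phi"])
        for name, ess in (("sigma", diag.get("ess_sigma")),):
            if ess is not None and ess < 100 and "sigma" in free:
                logger.warning("low effective sample size for sigma: %.0f", ess)
        return out, diag


def fit_fay_herriot(
    direct: DirectEstimates,
    graph: Optional[AdjacencyGraph],
    spec: FHModelSpec,
) -> tuple[PosteriorFit, PosteriorField]:
    """Fit the Fay-Herriot model and return parameter draws and the prevalence field.

    Degenerate areas enter without a likelihood term and are predicted from
    the linking model; all areas appear in the returned field. Reproducible
    given ``spec.seed``.
    """
    sampler = _FHSampler(direct, graph, spec)
    out, diag = sampler.run()
    theta = np.full((spec.draws, sampler.M), sampler.offset)
    if sampler.p:
        theta += out["delta"] @ sampler.F.T
    theta += out["u"]
    field = PosteriorField(expit(theta), sampler.areas, direct.level)

    if spec.fixed_intercept is None:
        alpha = out["delta"][:, 0]
        beta = out["delta"][:, 1:] if sampler.p > 1 else None
    else:
        alpha = np.full(spec.draws, spec.fixed_intercept)
        beta = out["delta"] if sampler.p else None
    fit = PosteriorFit(
        variant="fay_herriot",
        level=direct.level,
        areas=sampler.areas,
        admin1_labels=sampler.areas,
        a_of=np.arange(sampler.M),
        alpha=alpha,
        u=out["u"],
        sigma=out["sigma"],
        beta=beta,
        phi=out["phi"] if spec.effect == "bym2" else None,
        diagnostics=diag,
    )
    logger.info("Fay-Herriot fit complete: %s", diag)
    return fit, field
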