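"""Cluster-level beta-binomial prevalence models.

The cluster counts are modelled as Y_c | p_c ~ BetaBinomial(n_c, p_c, d),
where p_c is the latent cluster prevalence and d ∈ (0,1) the intra-cluster
correlation capturing extra within-cluster variation (shape parameters
a = p(1−d)/d, b = (1−p)(1−d)/d; d → 0 recovers the binomial).

Five linear predictors link p_c to area effects (1{·} is the rural indicator):

  unstratified                   logit(p_c) = α + x_cᵀβ + u_i[c]
  nested unstratified            logit(p_c) = α_a[c] + x_cᵀβ + u_i[c]
  stratified non-nested          logit(p_c) = α + γ·1 + x_cᵀβ + u_i[c]
  stratified nested              logit(p_c) = α_a[c] + γ·1 + x_cᵀβ + u_i[c]
  stratified nested interaction  logit(p_c) = α_a[c] + γ_a[c]·1 + x_cᵀβ + u_i[c]

u is BYM2 (or IID / absent) over the areas at the model's resolution, with PC
hyperpriors. Admin-1 intercepts α_a and the interaction slopes γ_a are vague
normal fixed effects. Inference is adaptive Metropolis-within-Gibbs with the
area-wise updates vectorised (the likelihood factorises over areas, so all
u_i, α_a, γ_a proposals are accepted/rejected in parallel) and the structured
BYM2 component updated by an exact constrained GMRF Gibbs draw.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import brentq
from scipy.special import betaln, expit, gammaln, logit

from prevmap.posterior import PosteriorFit, effective_sample_size
from prevmap.spatial import AdjacencyGraph, PCPriorSpec, pc_prior_phi, pc_prior_sd, scaled_icar
from prevmap.survey_data import ClusterTable

logger = logging.getLogger(__name__)

VARIANTS = (
    "unstratified",
    "nested_unstratified",
    "stratified_nonnested",
    "stratified_nested",
    "stratified_nested_interaction",
)
_NESTED = ("nested_unstratified", "stratified_nested", "stratified_nested_interaction")
_STRATIFIED = ("stratified_nonnested", "stratified_nested", "stratified_nested_interaction")


def betabinomial_logpmf(Y, n, p, d):
    """Log-pmf of the beta-binomial with mean p and intra-cluster correlation d.

    Vectorised over all arguments; ``d = 0`` returns the binomial log-pmf.
    """
    Y = np.asarray(Y)
    n = np.asarray(n)
    p = np.asarray(p, dtype=float)
    d = np.asarray(d, dtype=float)
    if np.any(Y < 0) or np.any(Y > n):
        raise ValueError("require 0 <= Y <= n")
    if np.any(p <= 0) or np.any(p >= 1):
        raise ValueError("require p in (0, 1)")
    if np.any(d < 0) or np.any(d >= 1):
        raise ValueError("require d in [0, 1)")
    comb = gammaln(n + 1) - gammaln(Y + 1) - gammaln(n - Y + 1)
    if np.all(d == 0):
        return comb + Y * np.log(p) + (n - Y) * np.log1p(-p)
    a = p * (1.0 - d) / d
    b = (1.0 - p) * (1.0 - d) / d
    return comb + betaln(Y + a, n - Y + b) - betaln(a, b)


@dataclass(frozen=True)
class TruncatedExpPrior:
    """Exponential density truncated to (0,1), calibrated by P(d > threshold) = alpha."""

    rate: float
    threshold: float
    alpha: float

    @classmethod
    def calibrated(cls, threshold: float = 0.5, alpha: float = 0.1) -> "TruncatedExpPrior":
        def tail(lam):
            if abs(lam) < 1e-12:
                return 1.0 - threshold
            return (np.exp(-lam * threshold) - np.exp(-lam)) / (1.0 - np.exp(-lam))

        lam = brentq(lambda L: tail(L) - alpha, -500.0, 500.0)
        return cls(lam, threshold, alpha)

    def logpdf(self, d):
        d = np.asarray(d, dtype=float)
        lam = self.rate
        norm = (1.0 - np.exp(-lam)) / lam if abs(lam) > 1e-12 else 1.0
        return np.where((d > 0) & (d < 1), -lam * d - np.log(norm), -np.inf)


@dataclass
class ClusterModelSpec:
    """Configuration of a beta-binomial cluster-level fit.

    ``level`` is the resolution of the area random effect ("admin2" or
    "admin1"); nested variants require admin2. ``covariates`` is (C, k) per
    cluster or (M, k) per area depending on ``covariate_level``. ``fixed_d``
    pins the overdispersion (``0`` gives a pure binomial likelihood) and
    ``intercept_prior="uniform-prevalence"`` puts a uniform prior on expit(α)
    instead of a vague normal on α — the conjugate Beta limit for a single
    area with no random effect.
    """

    variant: str = "stratified_nested"
    level: str = "admin2"
    effect: str = "bym2"  # bym2 | iid | none
    covariates: Optional[np.ndarray] = None
    covariate_level: str = "none"  # none | area | cluster
    priors: PCPriorSpec = field(default_factory=PCPriorSpec)
    d_prior_threshold: float = 0.5
    d_prior_alpha: float = 0.1
    fixed_d: Optional[float] = None
    draws: int = 2000
    burn: int = 1000
    seed: int = 0
    fe_sd: float = 31.6
    intercept_prior: str = "normal"
    store_p: bool = True
    store_loglik: bool = True

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.variant in _NESTED and self.level != "admin2":
            raise ValueError("nested variants require level='admin2'")
        if self.effect not in ("bym2", "iid", "none"):
            raise ValueError("effect must be 'bym2', 'iid' or 'none'")
        if self.covariate_level not in ("none", "area", "cluster"):
            raise ValueError("covariate_level must be none|area|cluster")


def _cluster_design(clusters: ClusterTable, spec: ClusterModelSpec):
    """Internal index arrays: per-cluster area and admin1 ids, rural flags, X."""
    tab = clusters.table
    h = clusters.hierarchy
    if spec.level == "admin2":
        area_labels = h.admin2_labels
        area_idx = h.admin2_id(tab["admin2"].to_numpy())
        a_of = h.a_of
    else:
        area_labels = h.admin1_labels
        area_idx = h.admin1_id(tab["admin1"].to_numpy())
        a_of = np.arange(h.n_admin1)
    a_idx = h.admin1_id(tab["admin1"].to_numpy())
    rural = ~tab["urban"].to_numpy(dtype=bool)
    X = None
    if spec.covariate_level != "none":
        X = np.atleast_2d(np.asarray(spec.covariates, dtype=float))
        if spec.covariate_level == "area":
            if X.shape[0] != len(area_labels):
                raise ValueError("area-level covariates must have one row per area")
            X = X[area_idx]
        elif X.shape[0] != len(tab):
            raise ValueError("cluster-level covariates must have one row per cluster")
    return area_labels, area_idx, a_idx, a_of, rural, X


def linear_predictor(clusters: ClusterTable, spec: ClusterModelSpec, params: dict) -> np.ndarray:
    """Per-cluster latent prevalence p_c = expit(linear predictor) for ``spec.variant``.

    ``params`` holds ``alpha`` (scalar or per-Admin-1 vector), optionally
    ``gamma`` (scalar or per-Admin-1), ``beta`` and ``u`` (per area at the
    model resolution).
    """
    area_labels, area_idx, a_idx, _, rural, X = _cluster_design(clusters, spec)
    alpha = np.asarray(params["alpha"], dtype=float)
    eta = alpha[a_idx] if alpha.ndim == 1 else np.full(len(area_idx), float(alpha))
    if spec.variant in _STRATIFIED:
        gamma = np.asarray(params["gamma"], dtype=float)
        g = gamma[a_idx] if gamma.ndim == 1 else float(gamma)
        eta = eta + np.where(rural, g, 0.0)
    if X is not None:
        beta = np.asarray(params["beta"], dtype=float)
        if beta.shape[0] != X.shape[1]:
            raise ValueError("beta length must match number of covariates")
        eta = eta + X @ beta
    u = np.asarray(params.get("u", np.zeros(len(area_labels))), dtype=float)
    if u.shape[0] != len(area_labels):
        raise ValueError("u length must match number of areas at the model resolution")
    return expit(eta + u[area_idx])


class _ClusterSampler:
    def __init__(self, clusters: ClusterTable, graph: Optional[AdjacencyGraph], spec: ClusterModelSpec):
        tab = clusters.table
        if len(tab) < 2:
            raise ValueError("need at least 2 clusters")
        self.spec = spec
        self.Y = tab["Y"].to_numpy(dtype=float)
        self.n = tab["n"].to_numpy(dtype=float)
        (
            self.area_labels,
            self.area_idx,
            self.a_idx,
            self.a_of,
            self.rural,
            self.X,
        ) = _cluster_design(clusters, spec)
        self.C = len(self.Y)
        self.M = len(self.area_labels)
        self.A = clusters.hierarchy.n_admin1
        self.admin1_labels = clusters.hierarchy.admin1_labels
        if spec.variant in _STRATIFIED:
            if not self.rural.any() or self.rural.all():
                raise ValueError(
                    "urban/rural effect unidentified: all clusters share one stratum designation"
                )
        self.comb = gammaln(self.n + 1) - gammaln(self.Y + 1) - gammaln(self.n - self.Y + 1)

        if spec.effect == "bym2":
            if graph is None or graph.n != self.M:
                raise ValueError("bym2 effect requires an adjacency graph over the model areas")
            self.icar = scaled_icar(graph)
            self.singles = self.icar.singletons
            self.phi_prior = pc_prior_phi(self.icar, spec.priors.phi_threshold, spec.priors.alpha_phi)
            # eigen-structure of (scaled precision + singleton identity): the s-Gibbs
            # posterior precision is this matrix plus a multiple of I, so one
            # decomposition serves every sweep
            B = self.icar.precision + np.diag(self.singles.astype(float))
            self.B_vals, self.B_vecs = np.linalg.eigh(B)
            comps = self.icar.graph.components
            self.constraints = []
            for comp in range(self.icar.graph.n_components):
                idx = np.flatnonzero(comps == comp)
                if len(idx) > 1:
                    a = np.zeros(self.M)
                    a[idx] = 1.0
                    self.constraints.append(a)
            self.constraints = np.array(self.constraints) if self.constraints else np.zeros((0, self.M))
        else:
            self.icar = None
            self.singles = np.zeros(self.M, dtype=bool)
            self.phi_prior = None
        self.sd_prior = pc_prior_sd(spec.priors.U_sigma, spec.priors.alpha_sigma)
        self.d_prior = TruncatedExpPrior.calibrated(spec.d_prior_threshold, spec.d_prior_alpha)

    # likelihood pieces -----------------------------------------------------
    def _ll(self, eta: np.ndarray, d: float, idx=None) -> np.ndarray:
        """Per-cluster beta-binomial log-likelihood at logit-scale predictor eta."""
        if idx is None:
            Y, n, comb = self.Y, self.n, self.comb
        else:
            Y, n, comb, eta = self.Y[idx], self.n[idx], self.comb[idx], eta[idx]
        p = expit(eta)
        p = np.clip(p, 1e-12, 1.0 - 1e-12)
        if d == 0.0:
            return comb + Y * np.log(p) + (n - Y) * np.log1p(-p)
        a = p * (1.0 - d) / d
        b = (1.0 - p) * (1.0 - d) / d
        return comb + betaln(Y + a, n - Y + b) - betaln(a, b)

    def _u_prior_logpdf(self, u, s, sigma, phi):
        """log p(u_i | s_i, σ, ϕ) summed by area (singletons: s_i ~ N(0,1) too)."""
        var = sigma**2 * (1.0 - phi) if self.spec.effect == "bym2" else sigma**2
        mean = sigma * np.sqrt(phi) * s if self.spec.effect == "bym2" else 0.0
        return -0.5 * ((u - mean) ** 2) / var - 0.5 * np.log(2 * np.pi * var)

    def run(self):
        spec = self.spec
        rng = np.random.default_rng(spec.seed)
        C, M, A = self.C, self.M, self.A

        per_a_alpha = spec.variant in _NESTED
        has_gamma = spec.variant in _STRATIFIED
        per_a_gamma = spec.variant == "stratified_nested_interaction"
        k = self.X.shape[1] if self.X is not None else 0

        # initial state
        p0 = (self.Y.sum() + 0.5) / (self.n.sum() + 1.0)
        if per_a_alpha:
            alpha = np.full(A, logit(p0))
            for a in range(A):
                mask = self.a_idx == a
                if mask.any():
                    alpha[a] = logit((self.Y[mask].sum() + 0.5) / (self.n[mask].sum() + 1.0))
        else:
            alpha = float(logit(p0))
        gamma = (np.zeros(A) if per_a_gamma else 0.0) if has_gamma else None
        beta = np.zeros(k)
        u = np.zeros(M)
        s = np.zeros(M)
        sigma, phi = 0.3, 0.5
        if spec.effect != "bym2":
            phi = 0.0
        d = spec.fixed_d if spec.fixed_d is not None else 0.05
        use_u = spec.effect != "none"

        def eta_from_state():
            e = alpha[self.a_idx] if per_a_alpha else np.full(C, alpha)
            if has_gamma:
                g = gamma[self.a_idx] if per_a_gamma else gamma
                e = e + np.where(self.rural, g if per_a_gamma else float(g), 0.0)
            if k:
                e = e + self.X @ beta
            if use_u:
                e = e + u[self.area_idx]
            return e

        eta = eta_from_state()
        ll = self._ll(eta, d)

        # adaptive step sizes
        step_u = np.full(M, 0.5)
        step_alpha = np.full(A, 0.3) if per_a_alpha else 0.3
        step_gamma = (np.full(A, 0.3) if per_a_gamma else 0.3) if has_gamma else None
        step_beta = np.full(k, 0.2)
        step_d, step_sigma, step_phi, step_joint, step_jphi = 0.5, 0.5, 0.8, 0.3, 0.5

        fe_prec = 1.0 / spec.fe_sd**2
        S = spec.draws
        out = {
            "alpha": np.empty((S, A) if per_a_alpha else S),
            "gamma": np.empty((S, A) if per_a_gamma else S) if has_gamma else None,
            "beta": np.empty((S, k)) if k else None,
            "u": np.empty((S, M)),
            "sigma": np.empty(S),
            "phi": np.empty(S),
            "d": np.empty(S),
            "p": np.empty((S, C)) if spec.store_p else None,
            "loglik": np.empty((S, C)) if spec.store_loglik else None,
        }
        acc = {"d": 0, "sigma": 0, "phi": 0}
        total = spec.burn + spec.draws

        def adapt(stp, accepted, t):
            return np.exp(np.log(stp) + (accepted - 0.44) / (t + 1) ** 0.6)

        def fe_logprior(x):
            if not per_a_alpha and spec.intercept_prior == "uniform-prevalence":
                # uniform prior on expit(alpha): log Jacobian of the logistic map
                return np.log(expit(x)) + np.log(expit(-x))
            return -0.5 * fe_prec * np.asarray(x) ** 2

        for it in range(total):
            burn = it < spec.burn
            # --- u block (vectorised over areas) ---------------------------
            if use_u:
                prop = u + step_u * rng.standard_normal(M)
                eta_p = eta + (prop - u)[self.area_idx]
                ll_p = self._ll(eta_p, d)
                dll = np.bincount(self.area_idx, weights=ll_p - ll, minlength=M)
                dlp = self._u_prior_logpdf(prop, s, sigma, phi) - self._u_prior_logpdf(u, s, sigma, phi)
                a_mask = np.log(rng.uniform(size=M)) < dll + dlp
                if a_mask.any():
                    u = np.where(a_mask, prop, u)
                    keep = a_mask[self.area_idx]
                    eta = np.where(keep, eta_p, eta)
                    ll = np.where(keep, ll_p, ll)
                if burn:
                    step_u = adapt(step_u, a_mask.astype(float), it)

            # --- s Gibbs (constrained GMRF) --------------------------------
            if spec.effect == "bym2":
                c = phi / (1.0 - phi)
                bvec = np.sqrt(phi) * u / (sigma * (1.0 - phi))
                inv_vals = 1.0 / (self.B_vals + c)
                Vt_b = self.B_vecs.T @ bvec
                mean = self.B_vecs @ (inv_vals * Vt_b)
                z = rng.standard_normal(M)
                samp = mean + self.B_vecs @ (np.sqrt(inv_vals) * z)
                if len(self.constraints):
                    QiAt = self.B_vecs @ (inv_vals[:, None] * (self.B_vecs.T @ self.constraints.T))
                    W = self.constraints @ QiAt
                    corr = QiAt @ np.linalg.solve(W, self.constraints @ samp)
                    samp = samp - corr
                s = samp

            # --- alpha ------------------------------------------------------
            if per_a_alpha:
                prop = alpha + step_alpha * rng.standard_normal(A)
                eta_p = eta + (prop - alpha)[self.a_idx]
                ll_p = self._ll(eta_p, d)
                dll = np.bincount(self.a_idx, weights=ll_p - ll, minlength=A)
                dlp = fe_logprior(prop) - fe_logprior(alpha)
                a_mask = np.log(rng.uniform(size=A)) < dll + dlp
                if a_mask.any():
                    alpha = np.where(a_mask, prop, alpha)
                    keep = a_mask[self.a_idx]
                    eta = np.where(keep, eta_p, eta)
                    ll = np.where(keep, ll_p, ll)
                if burn:
                    step_alpha = adapt(step_alpha, a_mask.astype(float), it)
            else:
                prop = alpha + step_alpha * rng.standard_normal()
                eta_p = eta + (prop - alpha)
                ll_p = self._ll(eta_p, d)
                dlp = float(fe_logprior(prop) - fe_logprior(alpha))
                ok = np.log(rng.uniform()) < ll_p.sum() - ll.sum() + dlp
                if ok:
                    alpha, eta, ll = prop, eta_p, ll_p
                if burn:
                    step_alpha = float(adapt(step_alpha, float(ok), it))

            # --- gamma ------------------------------------------------------
            if has_gamma:
                if per_a_gamma:
                    prop = gamma + step_gamma * rng.standard_normal(A)
                    shift = np.where(self.rural, (prop - gamma)[self.a_idx], 0.0)
                    eta_p = eta + shift
                    ll_p = self._ll(eta_p, d)
                    dll = np.bincount(self.a_idx, weights=ll_p - ll, minlength=A)
                    dlp = -0.5 * fe_prec * (prop**2 - gamma**2)
                    a_mask = np.log(rng.uniform(size=A)) < dll + dlp
                    if a_mask.any():
                        gamma = np.where(a_mask, prop, gamma)
                        keep = a_mask[self.a_idx] & self.rural
                        eta = np.where(keep, eta_p, eta)
                        ll = np.where(keep, ll_p, ll)
                    if burn:
                        step_gamma = adapt(step_gamma, a_mask.astype(float), it)
                else:
                    prop = gamma + step_gamma * rng.standard_normal()
                    r = np.flatnonzero(self.rural)
                    eta_p = eta.copy()
                    eta_p[r] += prop - gamma
                    ll_pr = self._ll(eta_p, d, idx=r)
                    dlp = -0.5 * fe_prec * (prop**2 - gamma**2)
                    ok = np.log(rng.uniform()) < ll_pr.sum() - ll[r].sum() + dlp
                    if ok:
                        gamma = prop
                        eta = eta_p
                        ll[r] = ll_pr
                    if burn:
                        step_gamma = float(adapt(step_gamma, float(ok), it))

            # --- beta -------------------------------------------------------
            for j in range(k):
                prop_j = beta[j] + step_beta[j] * rng.standard_normal()
                eta_p = eta + self.X[:, j] * (prop_j - beta[j])
                ll_p = self._ll(eta_p, d)
                dlp = -0.5 * fe_prec * (prop_j**2 - beta[j] ** 2)
                ok = np.log(rng.uniform()) < ll_p.sum() - ll.sum() + dlp
                if ok:
                    beta[j], eta, ll = prop_j, eta_p, ll_p
                if burn:
                    step_beta[j] = float(adapt(step_beta[j], float(ok), it))

            # --- d ----------------------------------------------------------
            if spec.fixed_d is None:
                z = logit(d) + step_d * rng.standard_normal()
                prop_d = float(expit(z))
                ll_p = self._ll(eta, prop_d)
                dlp = float(self.d_prior.logpdf(prop_d) - self.d_prior.logpdf(d))
                djac = np.log(prop_d * (1 - prop_d)) - np.log(d * (1 - d))
                ok = np.log(rng.uniform()) < ll_p.sum() - ll.sum() + dlp + djac
                if ok:
                    d, ll = prop_d, ll_p
                    acc["d"] += 1
                if burn:
                    step_d = float(adapt(step_d, float(ok), it))

            # --- joint (sigma, u) rescale: u' = (sigma'/sigma) u -------------
            # non-centred move; p(u'|s,sigma') cancels the Jacobian exactly,
            # leaving the likelihood and sigma-prior ratios. Breaks the slow
            # coupling between sigma and the random-effect magnitudes.
            if use_u:
                c = np.exp(step_joint * rng.standard_normal())
                prop_u = c * u
                eta_p = eta + (prop_u - u)[self.area_idx]
                ll_p = self._ll(eta_p, d)
                dlp = (
                    ll_p.sum()
                    - ll.sum()
                    + float(self.sd_prior.logpdf(c * sigma) - self.sd_prior.logpdf(sigma))
                    + np.log(c)
                )
                ok = np.log(rng.uniform()) < dlp
                if ok:
                    sigma = c * sigma
                    u, eta, ll = prop_u, eta_p, ll_p
                if burn:
                    step_joint = float(adapt(step_joint, float(ok), it))

            # --- sigma, phi (only touch the u prior) ------------------------
            if use_u:
                prop_s = sigma * np.exp(step_sigma * rng.standard_normal())
                dlp = (
                    self._u_prior_logpdf(u, s, prop_s, phi).sum()
                    - self._u_prior_logpdf(u, s, sigma, phi).sum()
                    + float(self.sd_prior.logpdf(prop_s) - self.sd_prior.logpdf(sigma))
                    + np.log(prop_s / sigma)
                )
                ok = np.log(rng.uniform()) < dlp
                if ok:
                    sigma = prop_s
                    acc["sigma"] += 1
                if burn:
                    step_sigma = float(adapt(step_sigma, float(ok), it))
            if spec.effect == "bym2":
                z = logit(phi) + step_phi * rng.standard_normal()
                prop_p = float(expit(z))
                dlp = (
                    self._u_prior_logpdf(u, s, sigma, prop_p).sum()
                    - self._u_prior_logpdf(u, s, sigma, phi).sum()
                    + float(self.phi_prior.logpdf(prop_p) - self.phi_prior.logpdf(phi))
                    + np.log(prop_p * (1 - prop_p)) - np.log(phi * (1 - phi))
                )
                ok = np.log(rng.uniform()) < dlp
                if ok:
                    phi = prop_p
                    acc["phi"] += 1
                if burn:
                    step_phi = float(adapt(step_phi, float(ok), it))

                # --- joint (phi, u) move holding the whitened residual fixed.
                # u' = sigma*sqrt(phi')*s + sqrt((1-phi')/(1-phi))*(u - sigma*sqrt(phi)*s);
                # the Gaussian prior ratio cancels the Jacobian exactly, so only
                # the likelihood, phi prior and logit-scale Jacobian remain.
                z = logit(phi) + step_jphi * rng.standard_normal()
                prop_p = float(expit(z))
                mean_old = sigma * np.sqrt(phi) * s
                prop_u = sigma * np.sqrt(prop_p) * s + np.sqrt(
                    (1.0 - prop_p) / (1.0 - phi)
                ) * (u - mean_old)
                eta_p = eta + (prop_u - u)[self.area_idx]
                ll_p = self._ll(eta_p, d)
                dlp = (
                    ll_p.sum()
                    - ll.sum()
                    + float(self.phi_prior.logpdf(prop_p) - self.phi_prior.logpdf(phi))
                    + np.log(prop_p * (1 - prop_p)) - np.log(phi * (1 - phi))
                )
                ok = np.log(rng.uniform()) < dlp
                if ok:
                    phi = prop_p
                    u, eta, ll = prop_u, eta_p, ll_p
                if burn:
                    step_jphi = float(adapt(step_jphi, float(ok), it))

            # --- record -----------------------------------------------------
            if not burn:
                t = it - spec.burn
                out["alpha"][t] = alpha
                if has_gamma:
                    out["gamma"][t] = gamma
                if k:
                    out["beta"][t] = beta
                out["u"][t] = u
                out["sigma"][t] = sigma
                out["phi"][t] = phi
                out["d"][t] = d
                if spec.store_p:
                    out["p"][t] = expit(eta)
                if spec.store_loglik:
                    out["loglik"][t] = ll

        diag = {key: val / total for key, val in acc.items()}
        diag["ess_sigma"] = effective_sample_size(out["sigma"]) if use_u else float(S)
        if has_gamma and not per_a_gamma:
            diag["ess_gamma"] = effective_sample_size(out["gamma"])
        if diag["ess_sigma"] < 100:
            logger.warning("low effective sample size for sigma: %.0f", diag["ess_sigma"])
        return out, diag


def fit_cluster_model(
    clusters: ClusterTable,
    graph: Optional[AdjacencyGraph],
    spec: ClusterModelSpec,
) -> PosteriorFit:
    """Fit a beta-binomial cluster-level model by adaptive Metropolis-within-Gibbs.

    Returns a :class:`PosteriorFit` whose ``p_draws`` (per-draw cluster
    prevalences) and ``loglik`` (per-draw, per-cluster log-likelihoods, the
    WAIC input) follow the cluster order of ``clusters.table``. Reproducible
    given ``spec.seed``.
    """
    sampler = _ClusterSampler(clusters, graph, spec)
    out, diag = sampler.run()
    fit = PosteriorFit(
        variant=spec.variant,
        level=spec.level,
        areas=tuple(sampler.area_labels),
        admin1_labels=tuple(sampler.admin1_labels),
        a_of=sampler.a_of,
        alpha=out["alpha"],
        u=out["u"],
        sigma=out["sigma"],
        gamma=out["gamma"],
        beta=out["beta"],
        phi=out["phi"] if spec.effect == "bym2" else None,
        d=out["d"],
        p_draws=out["p"],
        loglik=out["loglik"],
        diagnostics=diag,
    )
    logger.info("cluster model fit complete (%s): %s", spec.variant, diag)
    return fit


@dataclass(frozen=True)
class WAICResult:
    waic: float
    p_waic: float
    lppd: float
    pointwise: np.ndarray  # per-cluster contributions to waic


def waic(loglik: np.ndarray) -> WAICResult:
    """Widely applicable information criterion from per-draw log-likelihoods.

    ``loglik`` is S x C. waic = −2 [ Σ_c log mean_s L_cs − Σ_c var_s log L_cs ].
    """
    loglik = np.asarray(loglik, dtype=float)
    if loglik.ndim != 2 or loglik.shape[0] < 100:
        raise ValueError("need an S x C matrix with S >= 100 draws")
    if not np.isfinite(loglik).all():
        raise ValueError("non-finite log-likelihood values")
    S = loglik.shape[0]
    lppd_c = np.logaddexp.reduce(loglik, axis=0) - np.log(S)
    p_c = loglik.var(axis=0, ddof=1)
    pointwise = -2.0 * (lppd_c - p_c)
    return WAICResult(float(pointwise.sum()), float(p_c.sum()), float(lppd_c.sum()), pointwise)
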