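"""Bayesian double-hierarchical (location-scale) mixed models.

The univariate model per behaviour is

    mean:       Y = X b + Z a + eps,          a_j  ~ N(0, s_a^2)
    dispersion: eps_i ~ N(0, sigma_i^2),      log sigma_i = Xd bd + Zd ad,
                ad_j ~ N(0, w2_ID),

so each individual carries a behavioural type (a_j, random intercept of the
mean submodel) and a residual intra-individual variability effect (ad_j,
random intercept of the log residual SD). Individual residual SDs are
therefore lognormal, and the coefficient of variation in predictability is
CVp = sqrt(exp(w2_ID) - 1). The multivariate extension stacks T (z-scored)
behaviours, gives every individual 2T random effects with a full covariance
matrix (behavioural syndromes = type-type correlations, predictability
syndromes = rIIV-rIIV correlations) and a full residual cross-trait
correlation matrix.

Sampling is Metropolis-within-Gibbs, authored here: conjugate updates for
mean fixed effects, behavioural types and the random-effect covariance
(inverse-Wishart), adaptive random-walk Metropolis for the dispersion
parameters and the residual correlation. Adaptation runs only during
burn-in. Priors: N(0, 10^2) on fixed effects, IW(K+1, 0.02 I) on the
random-effect covariance (uniform marginal correlations, scale small
enough not to prop variance components away from zero), uniform over
positive-definite matrices for the residual correlation.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import invgamma, invwishart

logger = logging.getLogger(__name__)

__all__ = [
    "DHGLMSpec",
    "MCMCSettings",
    "PriorSpec",
    "DHGLMFit",
    "CvpEstimate",
    "CorrelationReport",
    "fit_dhglm",
    "fit_mv_dhglm",
    "compute_cvp",
    "extract_correlations",
    "convergence_diagnostics",
    "raftery_lewis",
]

_REFERENCES = {"sex": "F", "breed": "HF", "weaning_stage": "not_weaning",
               "health_status": "healthy"}
_NUMERIC = {"age": "age_days", "temperature": "mean_temperature_C"}
_CATEGORICAL = {"time_unit": "unit_index", "cohort": "cohort", "sex": "sex",
                "breed": "breed", "weaning_stage": "weaning_stage",
                "health_status": "health_status"}


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------

@dataclass
class DHGLMSpec:
    """Model specification.

    ``responses`` are behaviour column names (several => multivariate, in
    which case each is z-scored with the full-sample mean/SD). Mean and
    dispersion submodels share the same fixed effects and grouping.
    ``re_structure``:

    * ``"independent"`` - every random effect has its own variance, no
      correlations;
    * ``"correlated"`` / ``"full"`` - one full covariance matrix across all
      random effects (within-trait type-rIIV correlation in the univariate
      case; the full 2T x 2T matrix in the multivariate case).
    """

    responses: tuple[str, ...]
    fixed_effects: tuple[str, ...] = ()
    cohort_unit_interaction: bool = False
    dispersion_random: bool = True
    re_structure: str = "independent"
    scale_responses: bool = False
    group_col: str = "individual_id"

    def __post_init__(self) -> None:
        if isinstance(self.responses, str):
            self.responses = (self.responses,)
        self.responses = tuple(self.responses)
        if not self.responses:
            raise ValueError("at least one response is required")
        if self.re_structure not in ("independent", "correlated", "full"):
            raise ValueError("re_structure must be independent|correlated|full")

    @property
    def n_traits(self) -> int:
        return len(self.responses)


@dataclass
class MCMCSettings:
    """Chains / iterations / burn-in / thinning for the Gibbs sampler.
    Defaults follow the univariate analysis protocol (4 chains of 10 000
    iterations, burn-in 5000, thinning 10); the multivariate protocol uses
    burn-in 6000 and thinning 4."""

    n_chains: int = 4
    n_iter: int = 10_000
    burn_in: int = 5_000
    thin: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.burn_in < self.n_iter:
            raise ValueError("burn_in must be smaller than n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.n_chains < 1:
            raise ValueError("need at least one chain")

    @classmethod
    def multivariate(cls, seed: int = 0) -> "MCMCSettings":
        return cls(n_chains=4, n_iter=10_000, burn_in=6_000, thin=4, seed=seed)

    @property
    def n_draws_per_chain(self) -> int:
        return (self.n_iter - self.burn_in) // self.thin


@dataclass
class PriorSpec:
    """Hyperparameters. ``iw_df_offset``/``iw_scale`` set the
    inverse-Wishart IW(K + iw_df_offset, iw_scale * I) prior on the
    random-effect covariance (scalar components reduce to
    IG(a, b) with a = (1 + iw_df_offset)/2, b = iw_scale/2). The default
    scale is deliberately small: an inverse-Wishart has vanishing density
    at zero, so a large scale would keep variance components away from 0
    and inflate CVp when individuals do not differ in predictability."""

    beta_sd: float = 10.0
    iw_df_offset: float = 1.0
    iw_scale: float = 0.02


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------

@dataclass
class CvpEstimate:
    cvp: float
    cri_low: float
    cri_high: float
    response: str = ""

    def __post_init__(self) -> None:
        if self.cvp < 0:
            raise ValueError("CVp must be non-negative")


@dataclass
class CorrelationReport:
    """Posterior summaries for a set of random-effect correlations."""

    rows: pd.DataFrame  # pair, kind, mean, cri_low, cri_high, decisive

    def __len__(self) -> int:
        return len(self.rows)


@dataclass
class DHGLMFit:
    draws: dict[str, np.ndarray]       # name -> (n_chains, n_draws)
    individual_effects: pd.DataFrame   # posterior means of a_j / ad_j per trait
    spec: DHGLMSpec
    settings: MCMCSettings
    response_scale: dict[str, tuple[float, float]]  # resp -> (mean, sd) used
    accept_rates: dict[str, float] = field(default_factory=dict)

    @property
    def n_draws(self) -> int:
        first = next(iter(self.draws.values()))
        return first.shape[0] * first.shape[1]

    def stacked(self, name: str) -> np.ndarray:
        return self.draws[name].reshape(-1)

    def draws_frame(self) -> pd.DataFrame:
        """Columnar table of all stored draws (chain, draw, one column per
        parameter), suitable for writing as delimited text."""
        first = next(iter(self.draws.values()))
        n_chains, n_draws = first.shape
        out = pd.DataFrame({
            "chain": np.repeat(np.arange(n_chains), n_draws),
            "draw": np.tile(np.arange(n_draws), n_chains),
        })
        for name, arr in self.draws.items():
            out[name] = arr.reshape(-1)
        return out

    def summary(self) -> pd.DataFrame:
        rows = []
        for name, arr in self.draws.items():
            flat = arr.reshape(-1)
            lo, hi = np.percentile(flat, [2.5, 97.5])
            rows.append(dict(parameter=name, mean=flat.mean(),
                             sd=flat.std(ddof=1), cri_low=lo, cri_high=hi))
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------

def build_design(table: pd.DataFrame, fixed_effects: Sequence[str],
                 interaction: bool) -> tuple[np.ndarray, list[str]]:
    """Intercept-first fixed-effect design with stated reference levels
    (first cohort / first unit / female / purebred dairy / not weaning /
    healthy); numeric covariates are mean-centred."""
    n = len(table)
    cols = [np.ones(n)]
    names = ["intercept"]
    dummies: dict[str, dict] = {}
    for f in fixed_effects:
        if f in _NUMERIC:
            v = table[_NUMERIC[f]].to_numpy(dtype=float)
            cols.append(v - v.mean())
            names.append(f)
        elif f in _CATEGORICAL:
            col = table[_CATEGORICAL[f]]
            levels = sorted(col.unique(), key=str)
            ref = _REFERENCES.get(f, levels[0])
            dummies[f] = {}
            for lev in levels:
                if lev == ref:
                    continue
                d = (col == lev).to_numpy(dtype=float)
                dummies[f][lev] = d
                cols.append(d)
                names.append(f"{f}[{lev}]")
        else:
            raise ValueError(f"unknown fixed effect {f!r}")
    if interaction and "cohort" in dummies and "time_unit" in dummies:
        for cl, cd in dummies["cohort"].items():
            for ul, ud in dummies["time_unit"].items():
                cols.append(cd * ud)
                names.append(f"cohort[{cl}]:time_unit[{ul}]")
    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        logger.warning("DHGLM fixed-effect design rank deficient "
                       "(%d columns, rank %d)", X.shape[1], rank)
    return X, names


# ---------------------------------------------------------------------------
# the sampler
# ---------------------------------------------------------------------------

class _GibbsState:
    """Mutable per-chain state plus cached residual quantities."""

    def __init__(self, Y, X, Xd, codes, J, spec, priors, rng):
        self.Y, self.X, self.Xd, self.codes = Y, X, Xd, codes
        self.N, self.T = Y.shape
        self.p, self.pd = X.shape[1], Xd.shape[1]
        self.J = J
        self.spec = spec
        self.priors = priors
        self.rng = rng
        T = self.T
        self.K = 2 * T if spec.dispersion_random else T
        self.disp_re = spec.dispersion_random
        self.full_cov = spec.re_structure in ("correlated", "full") and self.K > 1

        # --- initial values (moment-based, jittered per chain) ---
        self.beta = np.zeros((self.p, T))
        self.beta_d = np.zeros((self.pd, T))
        gmean = np.zeros((J, T))
        counts = np.bincount(codes, minlength=J).astype(float)
        for t in range(T):
            self.beta[0, t] = Y[:, t].mean()
            gmean[:, t] = (np.bincount(codes, weights=Y[:, t], minlength=J)
                           / counts) - self.beta[0, t]
        resid0 = Y - self.beta[0][None, :] - gmean[codes]
        for t in range(T):
            self.beta_d[0, t] = np.log(max(resid0[:, t].std(), 1e-3))
        self.U = np.zeros((J, self.K))
        self.U[:, :T] = gmean + 0.1 * rng.standard_normal((J, T))
        self.beta += 0.05 * rng.standard_normal(self.beta.shape)
        self.beta_d += 0.05 * rng.standard_normal(self.beta_d.shape)
        if self.disp_re:
            self.U[:, T:] = 0.05 * rng.standard_normal((J, T))
        var0 = np.maximum(gmean.var(axis=0), 1e-3)
        diag = np.concatenate([var0, np.full(T, 0.05)])[: self.K]
        self.Sigma_u = np.diag(diag)
        self.R = np.eye(T)
        self._refresh_R_caches()
        self._refresh_residuals()

        # adaptive MH step sizes (log scale)
        self.step_ad = np.full((J, T), -0.7)       # ~ exp => 0.5
        self.step_bd = np.full((self.pd, T), -1.6)
        self.n_pairs = T * (T - 1) // 2
        self.step_rho = np.full(self.n_pairs, -2.3)
        self.acc_ad = np.zeros(2)
        self.acc_bd = np.zeros(2)

    # -- caches ------------------------------------------------------------
    def _refresh_R_caches(self):
        T = self.T
        self.Q = np.linalg.inv(self.R)
        self.logdetR = float(np.linalg.slogdet(self.R)[1])
        self.w = []       # per trait: weights for conditional mean of z_t
        self.cv = []      # per trait: conditional variance of z_t
        for t in range(T):
            others = [s for s in range(T) if s != t]
            if others:
                wt = np.linalg.solve(self.R[np.ix_(others, others)],
                                     self.R[others, t])
                self.w.append((others, wt))
                self.cv.append(float(self.R[t, t] - self.R[t, others] @ wt))
            else:
                self.w.append(([], np.zeros(0)))
                self.cv.append(1.0)

    def _refresh_residuals(self):
        T = self.T
        self.mu = self.X @ self.beta + self.U[:, :T][self.codes]
        self.resid = self.Y - self.mu
        eta = self.Xd @ self.beta_d
        if self.disp_re:
            eta = eta + self.U[:, T:][self.codes]
        self.log_sigma = np.clip(eta, -30.0, 30.0)
        self.sigma = np.exp(self.log_sigma)
        self.z = self.resid / self.sigma

    def _cond_mean_var(self, k: int, j_slice=slice(None)):
        """Prior conditional N(mean, var) of RE component k given the rest."""
        if not self.full_cov:
            return (np.zeros(self.J)[j_slice],
                    float(self.Sigma_u[k, k]))
        Om = np.linalg.inv(self.Sigma_u)
        pv = 1.0 / Om[k, k]
        others = [l for l in range(self.K) if l != k]
        pm = -pv * (self.U[:, others] @ Om[others, k])
        return pm[j_slice], float(pv)

    # -- conjugate updates -------------------------------------------------
    def update_beta(self, t: int):
        others, wt = self.w[t]
        m = self.z[:, others] @ wt if others else 0.0
        cv = self.cv[t]
        r = (self.Y[:, t] - self.U[self.codes, t] - self.sigma[:, t] * m)
        Wd = 1.0 / (self.sigma[:, t] ** 2 * cv)
        Xw = self.X * Wd[:, None]
        A = self.X.T @ Xw + np.eye(self.p) / self.priors.beta_sd ** 2
        bvec = Xw.T @ r
        L = np.linalg.cholesky(A)
        mean = np.linalg.solve(A, bvec)
        self.beta[:, t] = mean + np.linalg.solve(
            L.T, self.rng.standard_normal(self.p))
        self.mu[:, t] = self.X @ self.beta[:, t] + self.U[self.codes, t]
        self.resid[:, t] = self.Y[:, t] - self.mu[:, t]
        self.z[:, t] = self.resid[:, t] / self.sigma[:, t]

    def update_alpha(self, t: int):
        others, wt = self.w[t]
        m = self.z[:, others] @ wt if others else 0.0
        cv = self.cv[t]
        r = self.Y[:, t] - self.X @ self.beta[:, t] - self.sigma[:, t] * m
        Wd = 1.0 / (self.sigma[:, t] ** 2 * cv)
        pm, pv = self._cond_mean_var(t)
        prec = np.bincount(self.codes, weights=Wd, minlength=self.J) + 1.0 / pv
        mean = (np.bincount(self.codes, weights=Wd * r, minlength=self.J)
                + pm / pv) / prec
        self.U[:, t] = mean + self.rng.standard_normal(self.J) / np.sqrt(prec)
        self.mu[:, t] = self.X @ self.beta[:, t] + self.U[self.codes, t]
        self.resid[:, t] = self.Y[:, t] - self.mu[:, t]
        self.z[:, t] = self.resid[:, t] / self.sigma[:, t]

    def update_sigma_u(self):
        pr = self.priors
        if self.full_cov:
            df = self.K + pr.iw_df_offset + self.J
            S = pr.iw_scale * np.eye(self.K) + self.U.T @ self.U
            self.Sigma_u = invwishart.rvs(df=df, scale=S,
                                          random_state=self.rng)
            self.Sigma_u = np.atleast_2d(self.Sigma_u)
        else:
            a0 = 0.5 * (1.0 + pr.iw_df_offset)
            b0 = 0.5 * pr.iw_scale
            for k in range(self.K):
                a = a0 + 0.5 * self.J
                b = b0 + 0.5 * float(self.U[:, k] @ self.U[:, k])
                self.Sigma_u[k, k] = invgamma.rvs(a, scale=b,
                                                  random_state=self.rng)

    # -- Metropolis updates ------------------------------------------------
    def _delta_loglik_scale(self, t, new_log_sigma_t):
        """Per-observation log-likelihood change when trait t's residual
        scale changes (the other traits' z held fixed)."""
        new_sig = np.exp(new_log_sigma_t)
        z_new = self.resid[:, t] / new_sig
        z_old = self.z[:, t]
        others = [s for s in range(self.T) if s != t]
        c = self.z[:, others] @ self.Q[others, t] if others else 0.0
        dquad = (self.Q[t, t] * (z_new ** 2 - z_old ** 2)
                 + 2.0 * (z_new - z_old) * c)
        return -(new_log_sigma_t - self.log_sigma[:, t]) - 0.5 * dquad, new_sig, z_new

    def update_alpha_d(self, t: int, adapt: bool, gamma: float):
        if not self.disp_re:
            return
        k = self.T + t
        cur = self.U[:, k]
        step = np.exp(self.step_ad[:, t])
        prop = cur + step * self.rng.standard_normal(self.J)
        new_ls = self.log_sigma[:, t] + (prop - cur)[self.codes]
        dll, new_sig, z_new = self._delta_loglik_scale(t, new_ls)
        dll_j = np.bincount(self.codes, weights=dll, minlength=self.J)
        pm, pv = self._cond_mean_var(k)
        dprior = ((cur - pm) ** 2 - (prop - pm) ** 2) / (2.0 * pv)
        logacc = dll_j + dprior
        accept = np.log(self.rng.random(self.J)) < logacc
        if accept.any():
            self.U[accept, k] = prop[accept]
            rows = accept[self.codes]
            self.log_sigma[rows, t] = new_ls[rows]
            self.sigma[rows, t] = new_sig[rows]
            self.z[rows, t] = z_new[rows]
        if adapt:
            self.step_ad[:, t] += gamma * (accept.astype(float) - 0.44)
        self.acc_ad += (accept.sum(), self.J)

    def update_beta_d(self, t: int, adapt: bool, gamma: float):
        for q in range(self.pd):
            step = np.exp(self.step_bd[q, t])
            delta = step * self.rng.standard_normal()
            new_ls = self.log_sigma[:, t] + self.Xd[:, q] * delta
            dll, new_sig, z_new = self._delta_loglik_scale(t, new_ls)
            old, new = self.beta_d[q, t], self.beta_d[q, t] + delta
            dprior = (old ** 2 - new ** 2) / (2.0 * self.priors.beta_sd ** 2)
            if np.log(self.rng.random()) < dll.sum() + dprior:
                self.beta_d[q, t] = new
                self.log_sigma[:, t] = new_ls
                self.sigma[:, t] = new_sig
                self.z[:, t] = z_new
                acc = 1.0
            else:
                acc = 0.0
            if adapt:
                self.step_bd[q, t] += gamma * (acc - 0.44)
            self.acc_bd += (acc, 1.0)

    def update_res_corr(self, adapt: bool, gamma: float):
        if self.T < 2:
            return
        Sz = self.z.T @ self.z
        pairs = list(itertools.combinations(range(self.T), 2))
        for idx, (a, b) in enumerate(pairs):
            Rp = self.R.copy()
            delta = np.exp(self.step_rho[idx]) * self.rng.standard_normal()
            Rp[a, b] = Rp[b, a] = self.R[a, b] + delta
            try:
                np.linalg.cholesky(Rp)
            except np.linalg.LinAlgError:
                if adapt:
                    self.step_rho[idx] += gamma * (0.0 - 0.30)
                continue
            sign, logdet_p = np.linalg.slogdet(Rp)
            Qp = np.linalg.inv(Rp)
            dll = (-0.5 * self.N * (logdet_p - self.logdetR)
                   - 0.5 * (np.sum(Qp * Sz) - np.sum(self.Q * Sz)))
            acc = np.log(self.rng.random()) < dll
            if acc:
                self.R = Rp
                self.Q = Qp
                self.logdetR = logdet_p
            if adapt:
                self.step_rho[idx] += gamma * (float(acc) - 0.30)
        self._refresh_R_caches()

    def recenter(self):
        """Joint translation moves between each intercept fixed effect and
        the mean of its random-effect vector (likelihood-invariant, exact
        conditional draw); breaks the slow beta0 <-> mean(alpha) random
        walk of the centred parameterization."""
        pr = self.priors
        if self.full_cov:
            Om = np.linalg.inv(self.Sigma_u)
        S = self.U.sum(axis=0)
        for t in range(self.T):
            pairs = [(t, self.beta, 0)]
            if self.disp_re:
                pairs.append((self.T + t, self.beta_d, 0))
            for k, beta_arr, row in pairs:
                if self.full_cov:
                    prior_prec = self.J * Om[k, k]
                    lin = float(Om[k] @ S)
                else:
                    prior_prec = self.J / self.Sigma_u[k, k]
                    lin = S[k] / self.Sigma_u[k, k]
                prec = prior_prec + 1.0 / pr.beta_sd ** 2
                mean = (lin - beta_arr[row, t] / pr.beta_sd ** 2) / prec
                delta = mean + self.rng.standard_normal() / np.sqrt(prec)
                beta_arr[row, t] += delta
                self.U[:, k] -= delta
                S[k] -= self.J * delta
        # mu and log_sigma are unchanged by construction

    # -- one sweep ---------------------------------------------------------
    def sweep(self, it: int, burn_in: int):
        adapt = it < burn_in
        gamma = min(0.25, (it + 1) ** -0.6)
        for t in range(self.T):
            self.update_beta(t)
            self.update_alpha(t)
            self.update_alpha_d(t, adapt, gamma)
            self.update_beta_d(t, adapt, gamma)
        self.update_sigma_u()
        self.recenter()
        self.update_res_corr(adapt, gamma)


def _re_labels(spec: DHGLMSpec) -> list[str]:
    labels = [f"type:{r}" for r in spec.responses]
    if spec.dispersion_random:
        labels += [f"riiv:{r}" for r in spec.responses]
    return labels


def fit_dhglm(table: pd.DataFrame, spec: DHGLMSpec,
              settings: MCMCSettings | None = None,
              priors: PriorSpec | None = None) -> DHGLMFit:
    """Fit a (possibly multivariate) double-hierarchical model by
    Metropolis-within-Gibbs MCMC. Reproducible given ``settings.seed``."""
    settings = settings or MCMCSettings()
    priors = priors or PriorSpec()
    T = spec.n_traits

    cols = list(spec.responses) + [spec.group_col]
    cols += [_NUMERIC.get(f, _CATEGORICAL.get(f)) for f in spec.fixed_effects]
    data = table[list(dict.fromkeys(cols))].dropna().copy()
    if data[spec.group_col].nunique() < 2:
        raise ValueError("need at least 2 individuals")
    if data.groupby(spec.group_col).size().min() < 2:
        raise ValueError("each individual needs at least 2 units")

    scale: dict[str, tuple[float, float]] = {}
    Y = np.empty((len(data), T))
    for t, resp in enumerate(spec.responses):
        v = data[resp].to_numpy(dtype=float)
        if not np.isfinite(v).all():
            raise ValueError(f"non-finite values in response {resp!r}")
        if spec.scale_responses:
            m, s = v.mean(), v.std(ddof=1)
            scale[resp] = (m, s)
            v = (v - m) / s
        else:
            scale[resp] = (0.0, 1.0)
        Y[:, t] = v
    X, _names = build_design(data, spec.fixed_effects,
                             spec.cohort_unit_interaction)
    Xd = X  # same fixed effects in mean and dispersion submodels
    codes, uniq = pd.factorize(data[spec.group_col])
    J = len(uniq)

    ss = np.random.SeedSequence(settings.seed)
    chain_seeds = ss.spawn(settings.n_chains)
    n_save = settings.n_draws_per_chain
    labels = _re_labels(spec)
    K = len(labels)
    store: dict[str, np.ndarray] = {}

    def slot(name):
        return store.setdefault(
            name, np.empty((settings.n_chains, n_save)))

    U_sum = np.zeros((J, K))
    acc_ad = np.zeros(2)
    acc_bd = np.zeros(2)
    for c, cseed in enumerate(chain_seeds):
        rng = np.random.default_rng(cseed)
        st = _GibbsState(Y, X, Xd, codes, J, spec, priors, rng)
        isave = 0
        for it in range(settings.n_iter):
            st.sweep(it, settings.burn_in)
            if it >= settings.burn_in and (it - settings.burn_in) % settings.thin == 0:
                if isave >= n_save:
                    break
                for t, resp in enumerate(spec.responses):
                    slot(f"b_mean[{resp},intercept]")[c, isave] = st.beta[0, t]
                    slot(f"b_disp[{resp},intercept]")[c, isave] = st.beta_d[0, t]
                    slot(f"v_ind[{resp}]")[c, isave] = st.Sigma_u[t, t]
                    if spec.dispersion_random:
                        slot(f"omega2[{resp}]")[c, isave] = st.Sigma_u[T + t, T + t]
                if spec.re_structure in ("correlated", "full") and K > 1:
                    d = np.sqrt(np.diag(st.Sigma_u))
                    C = st.Sigma_u / np.outer(d, d)
                    for a, b in itertools.combinations(range(K), 2):
                        slot(f"re_corr[{labels[a]}|{labels[b]}]")[c, isave] = C[a, b]
                if T > 1:
                    for a, b in itertools.combinations(range(T), 2):
                        slot(f"res_corr[{spec.responses[a]}|{spec.responses[b]}]")[c, isave] = st.R[a, b]
                U_sum += st.U
                isave += 1
        acc_ad += st.acc_ad
        acc_bd += st.acc_bd

    U_mean = U_sum / (settings.n_chains * n_save)
    eff_rows = []
    for t, resp in enumerate(spec.responses):
        for j, iid in enumerate(uniq):
            eff_rows.append(dict(
                individual_id=iid, response=resp,
                type_mean=U_mean[j, t],
                riiv_mean=U_mean[j, T + t] if spec.dispersion_random else np.nan))
    accept_rates = {}
    if acc_ad[1] > 0:
        accept_rates["alpha_d"] = float(acc_ad[0] / acc_ad[1])
    if acc_bd[1] > 0:
        accept_rates["beta_d"] = float(acc_bd[0] / acc_bd[1])
    fit = DHGLMFit(draws=store,
                   individual_effects=pd.DataFrame(eff_rows),
                   spec=spec, settings=settings, response_scale=scale,
                   accept_rates=accept_rates)
    return fit


def fit_mv_dhglm(table: pd.DataFrame, traits: Sequence[str],
                 settings: MCMCSettings | None = None,
                 priors: PriorSpec | None = None,
                 fixed_effects: Sequence[str] = (),
                 dispersion_random: bool = True) -> DHGLMFit:
    """Multivariate DHGLM across ``traits`` (z-scored), with a full
    correlation matrix over all individual random effects and a full
    residual cross-trait correlation matrix."""
    if len(traits) < 2:
        raise ValueError("multivariate model needs at least 2 traits")
    spec = DHGLMSpec(responses=tuple(traits),
                     fixed_effects=tuple(fixed_effects),
                     dispersion_random=dispersion_random,
                     re_structure="full", scale_responses=True)
    settings = settings or MCMCSettings.multivariate()
    return fit_dhglm(table, spec, settings, priors)


# ---------------------------------------------------------------------------
# post-processing
# ---------------------------------------------------------------------------

def compute_cvp(fit: DHGLMFit, response: str | None = None) -> CvpEstimate:
    """CVp = sqrt(exp(w2_ID) - 1) applied draw-wise to the dispersion
    random-effect variance; posterior mean with central 95% credible
    interval."""
    response = response or fit.spec.responses[0]
    key = f"omega2[{response}]"
    if key not in fit.draws:
        raise ValueError(f"no dispersion random-effect draws for {response!r}")
    cvp = np.sqrt(np.expm1(fit.stacked(key)))
    lo, hi = np.percentile(cvp, [2.5, 97.5])
    return CvpEstimate(cvp=float(cvp.mean()), cri_low=float(lo),
                       cri_high=float(hi), response=response)


_KINDS = {"type-type": ("type", "type"), "type-riiv": ("type", "riiv"),
          "riiv-riiv": ("riiv", "riiv")}


def extract_correlations(fit: DHGLMFit, kind: str = "all") -> CorrelationReport:
    """Posterior summaries of among-individual random-effect correlations.

    ``kind``: "type-type" (behavioural syndromes), "type-riiv"
    (personality-predictability; positive = higher behavioural type goes
    with larger rIIV, i.e. less predictable), "riiv-riiv" (predictability
    syndromes) or "all". The ``decisive`` flag marks 95% credible intervals
    excluding zero.
    """
    if kind not in _KINDS and kind != "all":
        raise ValueError(f"unknown correlation kind {kind!r}")
    names = [n for n in fit.draws if n.startswith("re_corr[")]
    if not names:
        raise ValueError(
            "fit has no random-effect correlations (re_structure="
            f"{fit.spec.re_structure!r}); refit with re_structure='correlated' "
            "or 'full'")
    rows = []
    for name in names:
        inner = name[len("re_corr["):-1]
        la, lb = inner.split("|")
        ka, kb = la.split(":")[0], lb.split(":")[0]
        pair_kind = f"{ka}-{kb}" if f"{ka}-{kb}" in _KINDS else f"{kb}-{ka}"
        if kind != "all" and pair_kind != kind:
            continue
        flat = fit.stacked(name)
        lo, hi = np.percentile(flat, [2.5, 97.5])
        rows.append(dict(pair=inner, kind=pair_kind, mean=float(flat.mean()),
                         cri_low=float(lo), cri_high=float(hi),
                         decisive=bool(lo > 0 or hi < 0)))
    if kind != "all" and not rows:
        raise ValueError(f"fit has no correlations of kind {kind!r}")
    return CorrelationReport(rows=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# convergence diagnostics
# ---------------------------------------------------------------------------

def raftery_lewis(chain: np.ndarray, q: float = 0.025, r: float = 0.005,
                  s: float = 0.95) -> dict:
    """Raftery-Lewis run-length diagnostic for estimating the ``q`` quantile
    to within ``r`` with probability ``s``: dichotomizes the chain at the
    quantile, thins to approximate first-order Markov behaviour, and uses
    the two-state transition estimates to give burn-in and total iteration
    requirements, plus the iid minimum N_min."""
    from scipy.stats import norm

    chain = np.asarray(chain, dtype=float).ravel()
    n = len(chain)
    zq = norm.ppf(0.5 * (1 + s))
    nmin = int(np.ceil(q * (1 - q) * (zq / r) ** 2))
    if n < max(nmin // 10, 100):
        return dict(k_thin=1, burn_in=np.nan, n_required=np.nan,
                    n_min=nmin, dependence_factor=np.nan)
    cutoff = np.quantile(chain, q)
    z = (chain <= cutoff).astype(int)

    def _bic_prefers_markov(zz):
        # second- vs first-order Markov comparison via G2/BIC
        trip = np.stack([zz[:-2], zz[1:-1], zz[2:]])
        counts = np.zeros((2, 2, 2))
        for a, b, cc in trip.T:
            counts[a, b, cc] += 1
        g2 = 0.0
        for a in range(2):
            for b in range(2):
                for cc in range(2):
                    obs = counts[a, b, cc]
                    if obs == 0:
                        continue
                    exp = (counts[a, b, :].sum() * counts[:, b, cc].sum()
                           / max(counts[:, b, :].sum(), 1e-12))
                    g2 += 2 * obs * np.log(obs / exp)
        bic = g2 - 2.0 * np.log(len(zz) - 2)
        return bic < 0

    k = 1
    while k < max(2, n // 50):
        if _bic_prefers_markov(z[::k]):
            break
        k += 1
    zt = z[::k]
    trans = np.zeros((2, 2))
    for a, b in zip(zt[:-1], zt[1:]):
        trans[a, b] += 1
    row = trans.sum(axis=1)
    alpha = trans[0, 1] / row[0] if row[0] else 0.5  # P(0 -> 1)
    beta = trans[1, 0] / row[1] if row[1] else 0.5   # P(1 -> 0)
    ab = alpha + beta
    if ab <= 0 or ab >= 2 or alpha == 0 or beta == 0:
        return dict(k_thin=k, burn_in=0, n_required=nmin, n_min=nmin,
                    dependence_factor=1.0)
    m = int(np.ceil(np.log(0.01 * ab / max(alpha, beta))
                    / np.log(abs(1 - ab)))) * k
    n_req = int(np.ceil((2 - ab) * alpha * beta / ab ** 3
                        * (zq / r) ** 2)) * k
    return dict(k_thin=k, burn_in=max(m, 0), n_required=n_req + max(m, 0),
                n_min=nmin, dependence_factor=(n_req + max(m, 0)) / nmin)


def convergence_diagnostics(fit: DHGLMFit, rhat_threshold: float = 1.05,
                            rl_params: dict | None = None) -> pd.DataFrame:
    """Split-R-hat, effective sample size and Raftery-Lewis requirements
    per stored parameter. A parameter with R-hat above the threshold is
    flagged (and a warning logged) rather than silently passed."""
    import arviz as az

    rl_params = rl_params or {}
    rows = []
    multi_chain = fit.settings.n_chains >= 2
    if not multi_chain:
        logger.warning("single chain: R-hat unavailable")
    for name, arr in fit.draws.items():
        rhat = float(az.rhat(arr)) if multi_chain else np.nan
        ess = float(az.ess(arr))
        rl = raftery_lewis(arr.reshape(-1), **rl_params)
        flagged = bool(multi_chain and np.isfinite(rhat)
                       and rhat > rhat_threshold)
        if flagged:
            logger.warning("parameter %s has R-hat %.3f > %.2f",
                           name, rhat, rhat_threshold)
        rows.append(dict(parameter=name, rhat=rhat, ess=ess,
                         rl_n_required=rl["n_required"], rl_n_min=rl["n_min"],
                         non_converged=flagged))
    return pd.DataFrame(rows)
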