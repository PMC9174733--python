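"""Adjusted repeatability from a random-intercept mixed model.

For each behaviour Y, the model

    Y_ij = beta0 + x_ij' beta + ind_j + e_ij,
    ind_j ~ N(0, V_ind),  e_ij ~ N(0, V_e),

is fitted by REML (statsmodels MixedLM); the adjusted repeatability is the
intraclass correlation R = V_ind / (V_ind + V_e), i.e. the fraction of
phenotypic variance, after fixed effects, attributable to consistent
differences between individuals. Uncertainty comes from a seeded parametric
bootstrap (simulate from the fitted model, refit, percentile interval).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.tools.sm_exceptions import ConvergenceWarning

logger = logging.getLogger(__name__)

__all__ = [
    "LMMSpec",
    "LMMFit",
    "RepeatabilityEstimate",
    "fit_lmm_reml",
    "adjusted_repeatability",
    "bootstrap_repeatability_ci",
    "anova_reml_balanced",
]

DEFAULT_FIXED_EFFECTS = ("time_unit", "cohort", "age", "temperature",
                         "breed", "sex", "weaning_stage", "health_status")

_TERMS = {
    "time_unit": "C(unit_index)",
    "cohort": "C(cohort)",
    "age": "age_days",
    "temperature": "mean_temperature_C",
    "breed": "C(breed, Treatment('HF'))",
    "sex": "C(sex, Treatment('F'))",
    "weaning_stage": "C(weaning_stage, Treatment('not_weaning'))",
    "health_status": "C(health_status, Treatment('healthy'))",
}

_COLUMNS = {
    "time_unit": "unit_index", "cohort": "cohort", "age": "age_days",
    "temperature": "mean_temperature_C", "breed": "breed", "sex": "sex",
    "weaning_stage": "weaning_stage", "health_status": "health_status",
}


@dataclass
class LMMSpec:
    """Model specification: response behaviour, fixed effects (by
    covariate name), the cohort x time-unit interaction, and the grouping
    column for the individual random intercept."""

    response: str
    fixed_effects: tuple[str, ...] = DEFAULT_FIXED_EFFECTS
    cohort_unit_interaction: bool = True
    group_col: str = "individual_id"

    def formula(self) -> str:
        terms = [_TERMS[f] for f in self.fixed_effects]
        if self.cohort_unit_interaction and {"cohort", "time_unit"} <= set(self.fixed_effects):
            terms.append("C(cohort):C(unit_index)")
        rhs = " + ".join(terms) if terms else "1"
        return f"{self.response} ~ {rhs}"

    def required_columns(self) -> list[str]:
        return ([self.response, self.group_col]
                + [_COLUMNS[f] for f in self.fixed_effects])


@dataclass
class LMMFit:
    beta: pd.Series
    v_ind: float
    v_res: float
    blups: pd.DataFrame           # individual_id, blup, blup_sd
    converged: bool
    singular: bool
    loglik: float
    n_individuals: int
    n_obs: int
    spec: LMMSpec
    data: pd.DataFrame = field(repr=False)
    result: object = field(default=None, repr=False)


@dataclass
class RepeatabilityEstimate:
    r: float
    ci_low: float = np.nan
    ci_high: float = np.nan
    n_individuals: int = 0
    n_boot: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.r <= 1:
            raise ValueError("repeatability must lie in [0, 1]")


def _fit_with_fallback(model: MixedLM):
    last = None
    result = None
    for method in ("bfgs", "lbfgs", "powell"):
        try:
            result = model.fit(reml=True, method=method, maxiter=2000)
            break
        except np.linalg.LinAlgError as exc:  # optimizer walked into a
            last = exc                        # singular profile; retry
    if result is None:
        raise RuntimeError(f"REML optimization failed: {last}")
    # polish to a tight gradient tolerance when the surface allows it
    try:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            polished = model.fit(reml=True, method="bfgs", maxiter=5000,
                                 gtol=1e-10)
        if polished.converged and not any(
                issubclass(w.category, ConvergenceWarning) for w in caught):
            return polished
    except np.linalg.LinAlgError:
        pass
    return result


def fit_lmm_reml(table: pd.DataFrame, spec: LMMSpec) -> LMMFit:
    """REML fit of the random-intercept mixed model for one behaviour.

    Rows with missing response or covariates are dropped; a rank-deficient
    fixed-effect design and singular variance estimates are reported via
    the returned flags / log, never silently hidden.
    """
    cols = [c for c in spec.required_columns() if c in table.columns]
    missing = set(spec.required_columns()) - set(cols)
    if missing:
        raise ValueError(f"behaviour table lacks columns: {sorted(missing)}")
    data = table[cols].dropna().copy()
    if data[spec.group_col].nunique() < 2:
        raise ValueError("need at least 2 individuals")
    if data.groupby(spec.group_col).size().min() < 2:
        raise ValueError("each individual needs at least 2 observational units")

    model = smf.mixedlm(spec.formula(), data, groups=data[spec.group_col])
    exog_names = list(model.exog_names)
    rank = np.linalg.matrix_rank(model.exog)
    if rank < model.exog.shape[1]:
        # aliased columns (e.g. a cohort-by-unit covariate under a
        # saturated interaction): drop them, as lme4 does, and say so
        from scipy.linalg import qr

        _, _, piv = qr(model.exog, mode="economic", pivoting=True)
        keep = np.sort(piv[:rank])
        if 0 not in keep:
            keep = np.unique(np.concatenate([[0], keep[: rank - 1]]))
        dropped = [exog_names[i] for i in range(model.exog.shape[1])
                   if i not in keep]
        logger.warning("fixed-effect design rank deficient (%d columns, "
                       "rank %d); dropping aliased columns: %s",
                       model.exog.shape[1], rank, dropped)
        model = MixedLM(model.endog, model.exog[:, keep],
                        groups=data[spec.group_col].to_numpy())
        exog_names = [exog_names[i] for i in keep]
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        result = _fit_with_fallback(model)
    converged = bool(getattr(result, "converged", True)) and not any(
        issubclass(w.category, ConvergenceWarning) for w in caught)

    v_ind = max(0.0, float(np.asarray(result.cov_re)[0, 0]))
    v_res = float(result.scale)
    singular = v_ind < 1e-8 * max(v_res, 1e-12)
    if singular:
        logger.warning("singular fit: between-individual variance ~ 0 "
                       "for %s", spec.response)

    try:
        re = result.random_effects
        re_cov = {g: result.random_effects_cov[g] for g in re}
        blups = pd.DataFrame({
            "individual_id": list(re.keys()),
            "blup": [float(v.iloc[0]) for v in re.values()],
            "blup_sd": [float(np.sqrt(max(0.0, np.asarray(re_cov[g])[0, 0])))
                        for g in re],
        })
    except (ValueError, np.linalg.LinAlgError):
        # singular random-effect covariance: no conditional modes
        blups = pd.DataFrame(columns=["individual_id", "blup", "blup_sd"])
    if not converged:
        logger.warning("REML optimizer did not converge for %s", spec.response)
    beta = pd.Series(np.asarray(result.fe_params), index=exog_names)
    return LMMFit(beta=beta, v_ind=v_ind, v_res=v_res,
                  blups=blups, converged=converged, singular=singular,
                  loglik=float(result.llf),
                  n_individuals=data[spec.group_col].nunique(),
                  n_obs=len(data), spec=spec, data=data, result=result)


def adjusted_repeatability(fit: LMMFit) -> RepeatabilityEstimate:
    """R = V_ind / (V_ind + V_e) from a fitted model (point estimate)."""
    denom = fit.v_ind + fit.v_res
    if denom <= 0:
        raise ValueError("repeatability undefined: both variance components are 0")
    return RepeatabilityEstimate(r=fit.v_ind / denom,
                                 n_individuals=fit.n_individuals)


def anova_reml_balanced(y: np.ndarray, groups: np.ndarray) -> tuple[float, float]:
    """Closed-form one-way REML variance components for a balanced layout
    (equals the ANOVA moment estimators when interior):
    V_e = MSW, V_ind = max(0, (MSB - MSW) / n_per_group)."""
    y = np.asarray(y, float)
    codes, _ = pd.factorize(groups)
    k = codes.max() + 1
    counts = np.bincount(codes)
    if not np.all(counts == counts[0]):
        raise ValueError("balanced closed form requires equal group sizes")
    n = counts[0]
    means = np.bincount(codes, weights=y) / n
    ssw = float(((y - means[codes]) ** 2).sum())
    msw = ssw / (k * (n - 1))
    msb = float(n * ((means - means.mean()) ** 2).sum() / (k - 1))
    return max(0.0, (msb - msw) / n), msw


def _refit_r(y: np.ndarray, exog: np.ndarray, groups: np.ndarray) -> float:
    model = MixedLM(y, exog, groups=groups)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = _fit_with_fallback(model)
    v_ind = max(0.0, float(np.asarray(res.cov_re)[0, 0]))
    v_res = float(res.scale)
    return v_ind / (v_ind + v_res)


def bootstrap_repeatability_ci(table: pd.DataFrame, spec: LMMSpec,
                               n_boot: int = 1000, level: float = 0.95,
                               seed: int = 0,
                               max_retries: int = 50) -> RepeatabilityEstimate:
    """Parametric-bootstrap percentile interval for adjusted repeatability.

    Responses are simulated from the fitted model (fixed-effect fit plus
    fresh random intercepts and residuals) and the model refitted on each
    replicate. For an intercept-only spec on a balanced table the refit
    uses the closed-form balanced REML estimator (property-tested equal to
    the iterative fit), which makes large bootstraps cheap.
    """
    fit = fit_lmm_reml(table, spec)
    point = adjusted_repeatability(fit)
    if n_boot <= 0:
        return point

    rng = np.random.default_rng(seed)
    data = fit.data.reset_index(drop=True)
    groups = data[spec.group_col].to_numpy()
    codes, uniq = pd.factorize(groups)
    counts = np.bincount(codes)
    balanced_simple = (not spec.fixed_effects
                       and np.all(counts == counts[0]))
    if balanced_simple:
        mu = np.full(len(data), float(fit.beta.iloc[0]))
    else:  # fixed-effect part of the fit, on the rows actually used
        mu = np.asarray(fit.result.model.exog @ np.asarray(fit.result.fe_params))

    sd_ind, sd_res = np.sqrt(fit.v_ind), np.sqrt(fit.v_res)
    rs = []
    failures = 0
    while len(rs) < n_boot:
        b = rng.normal(0.0, sd_ind, size=len(uniq))
        y = mu + b[codes] + rng.normal(0.0, sd_res, size=len(data))
        if balanced_simple:
            v_i, v_e = anova_reml_balanced(y, codes)
            rs.append(v_i / (v_i + v_e))
            continue
        try:
            rs.append(_refit_r(y, fit.result.model.exog, groups))
        except Exception:  # non-converged replicate: resample
            failures += 1
            if failures > max_retries:
                raise RuntimeError(
                    f"bootstrap exceeded {max_retries} non-converged replicates")
            logger.info("bootstrap replicate failed to converge; resampling")
    alpha = (1.0 - level) / 2.0
    lo, hi = np.percentile(rs, [100 * alpha, 100 * (1 - alpha)])
    return RepeatabilityEstimate(r=point.r, ci_low=float(lo),
                                 ci_high=float(hi),
                                 n_individuals=fit.n_individuals,
                                 n_boot=n_boot)
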