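"""Synthetic data with the statistical structure the analysis assumes.

Two tiers of generator are provided:

* :func:`simulate_metric_table` draws behaviour tables directly from the
  hierarchical location-scale model that the downstream mixed-model and
  DHGLM stages fit: individual random intercepts, individual random effects
  on the log residual SD (the source of differences in predictability), an
  arbitrary correlation matrix across all random effects and traits, and
  optional fixed-effect covariates mimicking the study design (four cohorts
  of 14-16 calves, sex/breed frequencies, age, pen temperature, weaning
  stage, health status).

* :func:`simulate_trajectories` emulates the raw 1-Hz indoor-positioning
  stream: Ornstein-Uhlenbeck wandering around an individual home centre
  inside a bounded pen, feeder visits (dwell inside the feeder polygon),
  day-level lognormal re-draws of the movement parameters (which induce
  residual intra-individual variability in unit-level metrics), isotropic
  positional noise and bursty data gaps.

* :func:`simulate_static_sensor_test` mirrors the static sensor validation
  (repeated noisy fixes at known positions) used to exercise the CEP/DIST
  estimators.

Random-number contract: every generator takes one integer seed; internally a
``numpy.random.SeedSequence`` is spawned into per-individual (and per-day)
substreams, so enlarging the population does not perturb the draws of the
individuals already present.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .geometry import PenGeometry
from .trajectory import SECONDS_PER_DAY, Trajectory

__all__ = [
    "CovariateSpec",
    "MetricSimConfig",
    "MetricSimResult",
    "simulate_metric_table",
    "LognormalDist",
    "GapSpec",
    "TrajectorySimConfig",
    "simulate_trajectories",
    "StaticTestData",
    "simulate_static_sensor_test",
    "default_covariates",
]

# Cohort composition used as covariate-generator defaults: per cohort
# (n, females, males, purebred dairy, beef-cross-1, beef-cross-2, mean age d0).
_COHORTS = [
    dict(n=14, f=12, m=2, hf=13, bb=0, aa=1, age0=38.7),
    dict(n=14, f=12, m=2, hf=10, bb=3, aa=1, age0=41.5),
    dict(n=16, f=14, m=2, hf=10, bb=3, aa=3, age0=24.1),
    dict(n=16, f=13, m=3, hf=10, bb=2, aa=4, age0=31.6),
]


# ---------------------------------------------------------------------------
# covariate generator
# ---------------------------------------------------------------------------

@dataclass
class CovariateSpec:
    """Covariate layout and (optional) fixed-effect sizes.

    Effects default to zero so that the variance-component truth of the
    generated table is exactly the configured one; set entries of
    ``effects`` (keyed by covariate name) to inject real fixed effects.
    Supported keys: age (per day), temperature (per deg C), sex_M,
    breed_beef, weaning_step_down, weaning_weaned, health_sick,
    health_convalescent, cohort_2..cohort_4, unit (per unit index).
    """

    effects: dict[str, float] = field(default_factory=dict)
    temperature_mean: float = 12.0
    temperature_sd: float = 4.0

    def effect(self, key: str) -> float:
        return float(self.effects.get(key, 0.0))


def default_covariates(n_individuals: int, n_units: int,
                       rng: np.random.Generator,
                       spec: CovariateSpec | None = None) -> pd.DataFrame:
    """Per-individual x per-unit covariate rows following the study layout."""
    spec = spec or CovariateSpec()
    rows = []
    ind = 0
    cohort_of, sex_of, breed_of, age0_of = {}, {}, {}, {}
    for c, comp in enumerate(_COHORTS, start=1):
        sexes = ["F"] * comp["f"] + ["M"] * comp["m"]
        breeds = ["HF"] * comp["hf"] + ["HFxBB"] * comp["bb"] + ["HFxAA"] * comp["aa"]
        rng.shuffle(breeds)
        for k in range(comp["n"]):
            if ind >= n_individuals:
                break
            iid = f"calf_{ind + 1:03d}"
            cohort_of[iid] = c
            sex_of[iid] = sexes[k % len(sexes)]
            breed_of[iid] = breeds[k % len(breeds)]
            age0_of[iid] = comp["age0"] + rng.normal(0, 5)
            ind += 1
    while ind < n_individuals:  # beyond the 60-calf layout: recycle cohort 4
        iid = f"calf_{ind + 1:03d}"
        cohort_of[iid] = 4
        sex_of[iid] = "F" if rng.random() < 0.85 else "M"
        breed_of[iid] = "HF"
        age0_of[iid] = 30 + rng.normal(0, 5)
        ind += 1

    unit_temp = {c: spec.temperature_mean
                 + rng.normal(0, spec.temperature_sd, size=n_units)
                 for c in range(1, 5)}
    for iid in cohort_of:
        c = cohort_of[iid]
        # weaning: step-down begins ~2/3 through, weaned for the last unit
        step_down_unit = max(1, int(n_units * 2 / 3))
        weaned_unit = max(step_down_unit + 1, n_units - 1)
        for u in range(n_units):
            stage = ("not_weaning" if u < step_down_unit else
                     "step_down" if u < weaned_unit else "weaned")
            health = "healthy"
            if rng.random() < 0.05:
                health = rng.choice(["sick", "convalescent"])
            rows.append(dict(individual_id=iid, unit_index=u, cohort=c,
                             sex=sex_of[iid], breed=breed_of[iid],
                             age_days=age0_of[iid] + 4 * (u + 1),
                             mean_temperature_C=unit_temp[c][u],
                             weaning_stage=stage, health_status=health))
    return pd.DataFrame(rows)


def _fixed_effect_contribution(cov: pd.DataFrame, spec: CovariateSpec) -> np.ndarray:
    eta = np.zeros(len(cov))
    eta += spec.effect("age") * cov["age_days"].to_numpy()
    eta += spec.effect("temperature") * cov["mean_temperature_C"].to_numpy()
    eta += spec.effect("sex_M") * (cov["sex"] == "M").to_numpy()
    eta += spec.effect("breed_beef") * cov["breed"].str.startswith("HFx").to_numpy()
    eta += spec.effect("weaning_step_down") * (cov["weaning_stage"] == "step_down").to_numpy()
    eta += spec.effect("weaning_weaned") * (cov["weaning_stage"] == "weaned").to_numpy()
    eta += spec.effect("health_sick") * (cov["health_status"] == "sick").to_numpy()
    eta += spec.effect("health_convalescent") * (cov["health_status"] == "convalescent").to_numpy()
    for c in (2, 3, 4):
        eta += spec.effect(f"cohort_{c}") * (cov["cohort"] == c).to_numpy()
    eta += spec.effect("unit") * cov["unit_index"].to_numpy()
    return eta


# ---------------------------------------------------------------------------
# metric-table generator
# ---------------------------------------------------------------------------

def _as_trait_vector(v, n_traits: int, name: str) -> np.ndarray:
    arr = np.atleast_1d(np.asarray(v, dtype=float))
    if arr.size == 1:
        arr = np.repeat(arr, n_traits)
    if arr.size != n_traits:
        raise ValueError(f"{name} must be scalar or length n_traits")
    if np.any(arr < 0):
        raise ValueError(f"{name} must be non-negative")
    return arr


@dataclass
class MetricSimConfig:
    """Configuration for the behaviour-table generator.

    v_ind, v_res and omega2_id may be scalars (shared across traits) or
    per-trait vectors. ``re_correlation`` is the correlation matrix of the
    full random-effect vector, ordered as all trait intercepts followed by
    all trait dispersion effects (2*n_traits square); identity if omitted.
    ``v_res`` is the *mean* residual variance: the baseline log residual SD
    is offset by -omega2_id so that E[sigma_j^2] equals v_res exactly.
    """

    n_individuals: int = 60
    n_units: int = 12
    v_ind: float | Sequence[float] = 0.8
    v_res: float | Sequence[float] = 0.2
    omega2_id: float | Sequence[float] = 0.0
    re_correlation: np.ndarray | None = None
    n_traits: int = 1
    trait_names: Sequence[str] | None = None
    fixed_effect_design: CovariateSpec | None = None
    beta0: float | Sequence[float] = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_units < 2:
            raise ValueError("n_units must be >= 2 (repeated measures)")
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")
        self.v_ind = _as_trait_vector(self.v_ind, self.n_traits, "v_ind")
        self.v_res = _as_trait_vector(self.v_res, self.n_traits, "v_res")
        self.omega2_id = _as_trait_vector(self.omega2_id, self.n_traits, "omega2_id")
        if np.any(self.v_res <= 0):
            raise ValueError("v_res must be positive")
        k = 2 * self.n_traits
        if self.re_correlation is None:
            self.re_correlation = np.eye(k)
        self.re_correlation = np.asarray(self.re_correlation, dtype=float)
        C = self.re_correlation
        if C.shape != (k, k):
            raise ValueError(f"re_correlation must be {k}x{k} "
                             f"(intercepts then dispersion effects)")
        if not np.allclose(C, C.T, atol=1e-10):
            raise ValueError("re_correlation must be symmetric")
        if not np.allclose(np.diag(C), 1.0, atol=1e-10):
            raise ValueError("re_correlation must have unit diagonal")
        evals = np.linalg.eigvalsh(C)
        if evals.min() <= 1e-10:
            raise ValueError(
                f"re_correlation is not positive-definite "
                f"(min eigenvalue {evals.min():.3g})")
        if self.trait_names is None:
            self.trait_names = ([f"trait_{t + 1}" for t in range(self.n_traits)]
                                if self.n_traits > 1 else ["trait"])
        self.trait_names = list(self.trait_names)
        if len(self.trait_names) != self.n_traits:
            raise ValueError("trait_names length must equal n_traits")
        self.beta0 = np.resize(np.asarray(self.beta0, dtype=float), self.n_traits)


@dataclass
class MetricSimResult:
    """Generated behaviour table plus the generator truth for recovery tests."""

    table: pd.DataFrame
    intercepts: np.ndarray       # (J, T) true individual intercept effects
    dispersion_effects: np.ndarray  # (J, T) true effects on log residual SD
    individual_sd: np.ndarray    # (J, T) true residual SD per individual
    config: MetricSimConfig


def simulate_metric_table(config: MetricSimConfig) -> MetricSimResult:
    """Draw a per-individual x per-unit behaviour table from the
    location-scale hierarchical model.

    For individual j, unit i and trait t:

        Y_ijt = beta0_t + x_ij' beta + alpha_jt + e_ijt,
        e_ijt ~ N(0, sigma_jt^2),  log sigma_jt = eta0_t + alpha_d_jt,

    with (alpha_j., alpha_d_j.) jointly multivariate normal with the
    configured scales and correlation matrix. Reproducible given the seed.
    """
    cfg = config
    J, n, T = cfg.n_individuals, cfg.n_units, cfg.n_traits
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))

    scales = np.concatenate([np.sqrt(cfg.v_ind), np.sqrt(cfg.omega2_id)])
    L = np.linalg.cholesky(cfg.re_correlation)
    u = (rng.standard_normal((J, 2 * T)) @ L.T) * scales  # (J, 2T)
    alpha = u[:, :T]
    alpha_d = u[:, T:]

    # baseline log residual SD chosen so E[sigma_j^2] = v_res
    eta0 = 0.5 * np.log(cfg.v_res) - cfg.omega2_id
    sigma_j = np.exp(eta0 + alpha_d)  # (J, T)

    ids = [f"calf_{j + 1:03d}" for j in range(J)]
    base = pd.DataFrame({
        "individual_id": np.repeat(ids, n),
        "unit_index": np.tile(np.arange(n), J),
    })
    if cfg.fixed_effect_design is not None:
        cov = default_covariates(J, n, rng, cfg.fixed_effect_design)
        base = base.merge(cov, on=["individual_id", "unit_index"], how="left")
        fx = _fixed_effect_contribution(base, cfg.fixed_effect_design)
    else:
        fx = np.zeros(len(base))

    jidx = np.repeat(np.arange(J), n)
    eps = rng.standard_normal((len(base), T)) * sigma_j[jidx]
    Y = cfg.beta0[None, :] + fx[:, None] + alpha[jidx] + eps
    for t, name in enumerate(cfg.trait_names):
        base[name] = Y[:, t]
    return MetricSimResult(table=base, intercepts=alpha,
                           dispersion_effects=alpha_d,
                           individual_sd=sigma_j, config=cfg)


# ---------------------------------------------------------------------------
# trajectory generator
# ---------------------------------------------------------------------------

@dataclass
class LognormalDist:
    """Lognormal across-individual distribution given by median and log-SD."""

    median: float
    sigma_log: float = 0.0

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return self.median * np.exp(rng.normal(0.0, self.sigma_log, size=n))


@dataclass
class GapSpec:
    """Bursty missingness: target removed fraction and mean burst length."""

    fraction: float = 0.0314
    mean_burst_s: float = 600.0

    def __post_init__(self) -> None:
        if not 0 <= self.fraction < 1:
            raise ValueError("gap fraction must be in [0, 1)")


@dataclass
class TrajectorySimConfig:
    """Configuration for the Ornstein-Uhlenbeck pen-movement generator.

    ``ou_attraction`` is the mean-reversion rate toward the individual home
    centre (1/s); ``ou_diffusion`` the diffusion scale (m/sqrt(s)); the
    stationary ranging SD of the unbounded process is
    diffusion/sqrt(2*attraction). ``day_effect_sd`` is the log-SD of the
    day-level multipliers applied to both parameters, the mechanism that
    makes some individuals' space use less predictable than others.
    """

    pen: PenGeometry = field(default_factory=PenGeometry.default)
    n_individuals: int = 4
    days: int = 8
    hz: float = 1.0
    ou_attraction: LognormalDist = field(default_factory=lambda: LognormalDist(0.01, 0.3))
    ou_diffusion: LognormalDist = field(default_factory=lambda: LognormalDist(0.15, 0.4))
    day_effect_sd: float = 0.2
    feeder_visit_rate: LognormalDist = field(default_factory=lambda: LognormalDist(8.0, 0.3))
    feeder_visit_duration_min: LognormalDist = field(default_factory=lambda: LognormalDist(6.0, 0.5))
    noise_sd: float = 0.15 / 1.1774  # isotropic SD giving a CEP of ~0.15 m
    gap_spec: GapSpec = field(default_factory=GapSpec)
    start_day: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hz <= 0:
            raise ValueError("hz must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.pen.boundary.area <= 0:  # pragma: no cover - PenGeometry enforces
            raise ValueError("degenerate pen polygon")


def _reflect(v: float, lo: float, hi: float) -> float:
    # fold into [lo, hi] (triangle-wave reflection at the walls)
    width = hi - lo
    if width <= 0:
        return lo
    z = (v - lo) % (2 * width)
    return lo + (z if z <= width else 2 * width - z)


def simulate_trajectories(config: TrajectorySimConfig) -> list[Trajectory]:
    """Simulate one bounded-OU trajectory per individual.

    Pre-noise positions are guaranteed inside the pen; the feeder polygon is
    off-limits except during feeder visits, when the animal dwells inside
    it. The returned trajectories carry the pre-noise coordinates in
    ``meta['x_true'] / meta['y_true']`` for validation.
    """
    cfg = config
    ss = np.random.SeedSequence(cfg.seed)
    ind_seeds = ss.spawn(cfg.n_individuals)
    master = np.random.default_rng(ss.spawn(1)[0])

    xmin, ymin, xmax, ymax = cfg.pen.bounds()
    fxmin, fymin, fxmax, fymax = cfg.pen.feeder_zone.bounds
    feeder_cx = 0.5 * (fxmin + fxmax)
    feeder_cy = 0.5 * (fymin + fymax)

    attraction = cfg.ou_attraction.sample(master, cfg.n_individuals)
    diffusion = cfg.ou_diffusion.sample(master, cfg.n_individuals)
    visit_rate = cfg.feeder_visit_rate.sample(master, cfg.n_individuals)

    dt = 1.0 / cfg.hz
    steps_per_day = int(round(SECONDS_PER_DAY * cfg.hz))
    out: list[Trajectory] = []
    margin = min(0.25, 0.05 * min(xmax - xmin, ymax - ymin))

    for j in range(cfg.n_individuals):
        rng = np.random.default_rng(ind_seeds[j])
        # home centre: inside the pen, outside the feeder zone
        for _ in range(1000):
            hx = rng.uniform(xmin + margin, xmax - margin)
            hy = rng.uniform(ymin + margin, ymax - margin)
            if not cfg.pen.in_feeder(np.array([hx]), np.array([hy]))[0]:
                break
        t_all, x_all, y_all = [], [], []
        px, py = hx, hy
        for day in range(cfg.days):
            day_mult_b = math.exp(rng.normal(0, cfg.day_effect_sd))
            day_mult_g = math.exp(rng.normal(0, cfg.day_effect_sd))
            b = attraction[j] * day_mult_b
            g = diffusion[j] * day_mult_g
            decay = math.exp(-b * dt)
            step_sd = g * math.sqrt((1 - decay * decay) / (2 * b)) if b > 0 else g * math.sqrt(dt)

            # feeder visits for the day
            n_visits = rng.poisson(visit_rate[j])
            visiting = np.zeros(steps_per_day, dtype=bool)
            for _ in range(n_visits):
                start = rng.integers(0, steps_per_day)
                dur = max(1, int(round(cfg.feeder_visit_duration_min.sample(rng, 1)[0]
                                       * 60 * cfg.hz)))
                visiting[start:start + dur] = True

            noise = rng.standard_normal((steps_per_day, 2)) * step_sd
            xs = np.empty(steps_per_day)
            ys = np.empty(steps_per_day)
            for k in range(steps_per_day):
                if visiting[k]:
                    # strong dwell around the feeder centre, clamped inside
                    z = noise[k] / max(step_sd, 1e-12)  # unit normals
                    nx = feeder_cx + (px - feeder_cx) * 0.5 + 0.1 * z[0]
                    ny = feeder_cy + (py - feeder_cy) * 0.5 + 0.1 * z[1]
                    nx = min(max(nx, fxmin), fxmax)
                    ny = min(max(ny, fymin), fymax)
                else:
                    nx = hx + (px - hx) * decay + noise[k, 0]
                    ny = hy + (py - hy) * decay + noise[k, 1]
                    nx = _reflect(nx, xmin, xmax)
                    ny = _reflect(ny, ymin, ymax)
                    if fxmin <= nx <= fxmax and fymin <= ny <= fymax:
                        nx, ny = px, py  # feeder occupies this corner: blocked
                xs[k] = nx
                ys[k] = ny
                px, py = nx, ny
            ts = ((cfg.start_day + day) * SECONDS_PER_DAY
                  + np.arange(steps_per_day) * dt)
            t_all.append(ts)
            x_all.append(xs)
            y_all.append(ys)

        t = np.concatenate(t_all)
        x = np.concatenate(x_all)
        y = np.concatenate(y_all)

        keep = np.ones(len(t), dtype=bool)
        if cfg.gap_spec.fraction > 0:
            target = int(cfg.gap_spec.fraction * len(t))
            removed = 0
            while removed < target:
                start = rng.integers(0, len(t))
                burst = max(1, int(rng.exponential(cfg.gap_spec.mean_burst_s) * cfg.hz))
                stop = min(len(t), start + burst)
                removed += int(keep[start:stop].sum())
                keep[start:stop] = False
        t, x, y = t[keep], x[keep], y[keep]

        x_obs = x + rng.normal(0, cfg.noise_sd, size=len(x))
        y_obs = y + rng.normal(0, cfg.noise_sd, size=len(y))
        out.append(Trajectory(f"calf_{j + 1:03d}", t, x_obs, y_obs,
                              nominal_hz=cfg.hz,
                              meta={"x_true": x, "y_true": y,
                                    "home_centre": (hx, hy)}))
    return out


# ---------------------------------------------------------------------------
# static sensor validation data
# ---------------------------------------------------------------------------

@dataclass
class StaticTestData:
    """Repeated noisy fixes at known static positions."""

    position_ids: list[str]
    truth: np.ndarray          # (P, 2) ground-truth coordinates
    fixes: list[np.ndarray]    # per position, (n, 2) observed fixes


def simulate_static_sensor_test(true_positions: Sequence[Sequence[float]],
                                noise_sd: float, n_samples: int,
                                seed: int = 0) -> StaticTestData:
    """Noisy fixes around each true position (isotropic Gaussian noise)."""
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    truth = np.asarray(true_positions, dtype=float).reshape(-1, 2)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    fixes = [p + rng.normal(0, noise_sd, size=(n_samples, 2)) for p in truth]
    ids = [f"pos_{k + 1}" for k in range(len(truth))]
    return StaticTestData(position_ids=ids, truth=truth, fixes=fixes)
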