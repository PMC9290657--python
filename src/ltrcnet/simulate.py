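"""Synthetic LTRC cohort generator and Weibull calibration utilities.

The data-generating process emulates an oncology clinico-genomic cohort in
which survival is measured from diagnosis but patients are observed only
after a later milestone (e.g. receiving a genomic test):

* correlated binary "alteration" predictors via a latent multivariate
  probit (random correlation matrix, marginal prevalences pi_k ~ U(0.2, 0.8));
* sparse weak effects: each binary coefficient is nonzero with probability
  0.5 and then uniform on (-0.25, 0.25), so hazard ratios span 0.78-1.28;
* latent survival T from a proportional-hazards Weibull with the linear
  predictor centred so mean predicted survival matches the intercept-only
  model;
* independent Weibull censoring U;
* a two-part entry time V: a point mass at zero (probability 0.2,
  patients observed from diagnosis) mixed with a lognormal whose median
  is 1 year and mean 1.6 years (delayed entry at genomic testing).

Subjects with V > Y = min(T, U) are left-truncated: they exist in the
complete cohort but would never be observed in a real study.  All times
are in years.  Every sampler takes an explicit integer seed.
"""

from __future__ import annotations

import dataclasses
import json
import math
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .coxnet import cross_validate
from .data import CompleteCohort, LTRCDataset, split_indices
from .evaluation import breslow_baseline, calibration_curve, concordance, predict_survival

# --------------------------------------------------------------------------
# Stand-in clinical covariates
# --------------------------------------------------------------------------
# Eleven synthetic clinical covariates (six standard-normal continuous, five
# Bernoulli) stand in for the licensed registry variables of the real
# cohort, preserving the mixed-type structure and total dimension
# (11 + p_binary).  Their coefficients were drawn once from U(-0.3, 0.3)
# and are shipped as constants so every run uses the same clinical signal.

STANDIN_NAMES = [
    "age", "year_dx", "lab_a", "lab_b", "lab_c", "lab_d",
    "practice_community", "male", "smoker", "prior_treatment", "stage_high",
]
STANDIN_N_CONTINUOUS = 6
STANDIN_BERNOULLI_P = np.array([0.3, 0.4, 0.5, 0.6, 0.7])
STANDIN_COEFS = np.array([
    -0.200429, 0.123914, 0.053192, -0.078535, 0.206241, -0.265934,
    -0.052993, 0.249628, 0.020175, -0.240704, 0.295763,
])


@dataclasses.dataclass
class SimConfig:
    """All data-generating-process parameters (times in years).

    Defaults encode the study conditions: median latent survival of one
    year (Weibull shape 1, intercept log log 2), median censoring of two
    years, a 20% point mass at zero entry with lognormal(0, 2 ln 1.6)
    positive entry times, and the sparse weak-effect coefficient law for
    the binary block.  Roughly half the cohort is left-truncated at these
    settings, mirroring the survivor selection of milestone-entry cohorts.
    """

    n: int = 5000
    p_binary: int = 10
    pi_range: tuple[float, float] = (0.2, 0.8)
    coef_nonzero_prob: float = 0.5
    coef_bounds: tuple[float, float] = (-0.25, 0.25)
    weibull_shape: float = 1.0
    weibull_intercept: float = math.log(math.log(2.0))
    cens_shape: float = 1.0
    cens_scale: float = math.log(2.0) / 2.0
    entry_positive_prob: float = 0.8
    entry_log_mu: float = 0.0
    entry_log_sigma: float = math.sqrt(2.0 * math.log(1.6))
    train_fraction: float = 0.75
    seed: int = 0
    include_standins: bool = True

    def __post_init__(self) -> None:
        for name in ("weibull_shape", "cens_shape", "cens_scale", "entry_log_sigma"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        for name in ("coef_nonzero_prob", "entry_positive_prob", "train_fraction"):
            val = getattr(self, name)
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.coef_bounds[0] > self.coef_bounds[1]:
            raise ValueError("coef_bounds must be ordered (low <= high)")

    def replace(self, **kw) -> "SimConfig":
        return dataclasses.replace(self, **kw)

    def to_json(self, path) -> None:
        from pathlib import Path

        Path(path).write_text(json.dumps(dataclasses.asdict(self)))

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        for key in ("pi_range", "coef_bounds"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def small_p_config(**kw) -> SimConfig:
    """10 binary predictors + 11 clinical stand-ins (p = 21)."""
    kw.setdefault("p_binary", 10)
    return SimConfig(**kw)


def large_p_config(**kw) -> SimConfig:
    """1000 binary predictors + 11 clinical stand-ins (p = 1011)."""
    kw.setdefault("p_binary", 1000)
    return SimConfig(**kw)


# --------------------------------------------------------------------------
# Samplers
# --------------------------------------------------------------------------


def make_correlation(p_binary: int, seed: int) -> np.ndarray:
    """Random correlation matrix: S = G'G with G ~ N(0,1), scaled to unit diagonal."""
    if p_binary < 1:
        raise ValueError("p_binary must be >= 1")
    rng = np.random.default_rng(seed)
    G = rng.standard_normal((p_binary, p_binary))
    S = G.T @ G
    dsqrt = np.sqrt(np.diag(S))
    return S / np.outer(dsqrt, dsqrt)


def _safe_cholesky(corr: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.cholesky(corr)
    except np.linalg.LinAlgError:
        warnings.warn("correlation matrix numerically indefinite; clipping eigenvalues")
        vals, vecs = np.linalg.eigh(corr)
        vals = np.clip(vals, 1e-10, None)
        fixed = (vecs * vals) @ vecs.T
        d = np.sqrt(np.diag(fixed))
        fixed = fixed / np.outer(d, d)
        return np.linalg.cholesky(fixed + 1e-12 * np.eye(len(corr)))


def sample_binary_design(
    n: int, corr: np.ndarray, pi_range: tuple[float, float], seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Correlated binaries via a latent multivariate probit.

    Marginal prevalences pi_k ~ U(pi_range); thresholds mu_k =
    Phi^{-1}(pi_k); latent rows ~ N(mu, corr); x_ik = 1 iff latent > 0.
    Returns (X binary matrix, pi vector).
    """
    rng = np.random.default_rng(seed)
    p = corr.shape[0]
    pi = rng.uniform(pi_range[0], pi_range[1], size=p)
    mu = stats.norm.ppf(pi)
    L = _safe_cholesky(np.asarray(corr, dtype=float))
    latent = mu + rng.standard_normal((n, p)) @ L.T
    return (latent > 0).astype(float), pi


def sample_coefficients(
    p_binary: int, coef_nonzero_prob: float, coef_bounds: tuple[float, float], seed: int
) -> np.ndarray:
    """Sparse uniform coefficient law for the binary block.

    Each coefficient is 0 with probability 1 - coef_nonzero_prob, else
    U(coef_bounds); at the defaults the implied hazard-ratio range is
    exp(-0.25)..exp(0.25), i.e. 0.78..1.28.
    """
    rng = np.random.default_rng(seed)
    nonzero = rng.random(p_binary) < coef_nonzero_prob
    vals = rng.uniform(coef_bounds[0], coef_bounds[1], size=p_binary)
    return np.where(nonzero, vals, 0.0)


def hazard_ratio_bounds(coef_bounds: tuple[float, float] = (-0.25, 0.25)) -> tuple[float, float]:
    """Extreme hazard ratios implied by the coefficient support."""
    return math.exp(coef_bounds[0]), math.exp(coef_bounds[1])


def sample_survival(
    X: np.ndarray, beta: np.ndarray, weibull_shape: float, weibull_intercept: float, seed: int
) -> np.ndarray:
    """Latent survival from the proportional-hazards Weibull.

    The density is f(t) = a m t^{a-1} exp(-m t^a) with log m_i =
    intercept + x_i'b - mean(x'b); the centring makes the average log
    scale equal the intercept, so population-average survival matches the
    intercept-only model.  Sampling is by inversion:
    T = (-log U / m)^{1/a}.
    """
    if weibull_shape <= 0:
        raise ValueError("weibull_shape must be > 0")
    rng = np.random.default_rng(seed)
    eta = np.asarray(X, dtype=float) @ np.asarray(beta, dtype=float)
    log_m = weibull_intercept + eta - eta.mean()
    u = rng.random(len(log_m))
    return (-np.log(u) / np.exp(log_m)) ** (1.0 / weibull_shape)


def sample_censoring(n: int, cens_shape: float, cens_scale: float, seed: int) -> np.ndarray:
    """Independent Weibull censoring times (same parameterization), by inversion."""
    if cens_shape <= 0 or cens_scale <= 0:
        raise ValueError("censoring parameters must be strictly positive")
    rng = np.random.default_rng(seed)
    u = rng.random(n)
    return (-np.log(u) / cens_scale) ** (1.0 / cens_shape)


def sample_entry(
    n: int, entry_positive_prob: float, entry_log_mu: float, entry_log_sigma: float, seed: int
) -> np.ndarray:
    """Two-part entry times: zero w.p. 1 - p, else lognormal(mu, sigma^2)."""
    if not 0.0 <= entry_positive_prob <= 1.0:
        raise ValueError("entry_positive_prob must be in [0, 1]")
    if entry_log_sigma <= 0:
        raise ValueError("entry_log_sigma must be > 0")
    rng = np.random.default_rng(seed)
    positive = rng.random(n) < entry_positive_prob
    v = np.zeros(n)
    v[positive] = rng.lognormal(entry_log_mu, entry_log_sigma, size=int(positive.sum()))
    return v


def assemble_cohort(T, U, V, X, beta, predictor_names: Sequence[str] | None = None) -> CompleteCohort:
    """Combine latent draws into a complete cohort.

    Y = min(T, U); event = 1[T <= U]; truncated = 1[V > Y].  The
    non-truncated subset with entry := V is a valid LTRC dataset.
    """
    T = np.asarray(T, dtype=float)
    U = np.asarray(U, dtype=float)
    V = np.asarray(V, dtype=float)
    X = np.asarray(X, dtype=float)
    Y = np.minimum(T, U)
    if predictor_names is None:
        predictor_names = [f"x{j+1}" for j in range(X.shape[1])]
    return CompleteCohort(
        latent_T=T,
        latent_U=U,
        latent_V=V,
        observed_Y=Y,
        event=(T <= U).astype(int),
        truncated=(V > Y).astype(int),
        predictors=X,
        true_beta=np.asarray(beta, dtype=float),
        predictor_names=predictor_names,
    )


def _child_seeds(seed: int, k: int) -> list[int]:
    state = np.random.SeedSequence(seed).generate_state(k, dtype=np.uint64)
    return [int(s % (2**31)) for s in state]


def _sample_standins(n: int, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    Xc = rng.standard_normal((n, STANDIN_N_CONTINUOUS))
    Xb = (rng.random((n, len(STANDIN_BERNOULLI_P))) < STANDIN_BERNOULLI_P).astype(float)
    return np.hstack([Xc, Xb])


def generate_cohort(config: SimConfig) -> CompleteCohort:
    """Draw a full cohort (design, coefficients, T, U, V) from the DGP."""
    s_corr, s_bin, s_coef, s_surv, s_cens, s_entry, s_stand = _child_seeds(config.seed, 7)
    corr = make_correlation(config.p_binary, s_corr)
    Xb, _ = sample_binary_design(config.n, corr, config.pi_range, s_bin)
    beta_b = sample_coefficients(
        config.p_binary, config.coef_nonzero_prob, config.coef_bounds, s_coef
    )
    names = [f"alt_{j+1}" for j in range(config.p_binary)]
    if config.include_standins:
        X = np.hstack([_sample_standins(config.n, s_stand), Xb])
        beta = np.concatenate([STANDIN_COEFS, beta_b])
        names = STANDIN_NAMES + names
    else:
        X, beta = Xb, beta_b
    T = sample_survival(X, beta, config.weibull_shape, config.weibull_intercept, s_surv)
    U = sample_censoring(config.n, config.cens_shape, config.cens_scale, s_cens)
    V = sample_entry(
        config.n, config.entry_positive_prob, config.entry_log_mu, config.entry_log_sigma, s_entry
    )
    return assemble_cohort(T, U, V, X, beta, names)


# --------------------------------------------------------------------------
# Weibull LTRC maximum likelihood
# --------------------------------------------------------------------------


@dataclasses.dataclass
class WeibullFit:
    """Intercept-only Weibull MLE under left truncation.

    ``shape`` is a, ``log_scale`` is log m in the proportional-hazards
    parameterization f(t) = a m t^{a-1} exp(-m t^a).
    """

    shape: float
    log_scale: float
    loglik: float
    converged: bool


def fit_weibull_ltrc(dataset: LTRCDataset, reverse_indicator: bool = False) -> WeibullFit:
    """Maximize the truncation-conditional Weibull log-likelihood.

    Each subject contributes e*log f(y) + (1-e)*log S(y) - log S(v), i.e.
    the usual right-censored terms conditioned on survival to entry.  With
    ``reverse_indicator`` the event/censoring roles are swapped, which
    fits the censoring-time distribution instead (censoring is then
    "the event" and death censors it).
    """
    y = dataset.time
    v = dataset.entry
    e = (1 - dataset.event if reverse_indicator else dataset.event).astype(float)
    if e.sum() < 2:
        raise ValueError("need at least 2 events (after optional indicator reversal)")
    log_y = np.log(y)
    vpos = v > 0
    log_v = np.zeros_like(v)
    log_v[vpos] = np.log(v[vpos])
    n_events = e.sum()

    def negloglik_and_grad(params):
        la, lm = params
        a, m = math.exp(la), math.exp(lm)
        ya = y**a
        va = np.where(vpos, v**a, 0.0)
        ll = np.sum(e * (la + lm + (a - 1.0) * log_y)) - m * ya.sum() + m * va.sum()
        d_la = a * (np.sum(e * (1.0 / a + log_y)) - m * np.sum(ya * log_y) + m * np.sum(va * log_v))
        d_lm = n_events - m * (ya.sum() - va.sum())
        return -ll, np.array([-d_la, -d_lm])

    # moment-style init: exponential rate on at-risk time
    rate0 = max(n_events / np.sum(y - v), 1e-8)
    res = optimize.minimize(
        negloglik_and_grad,
        x0=np.array([0.0, math.log(rate0)]),
        jac=True,
        method="BFGS",
        options={"gtol": 1e-6, "maxiter": 500},
    )
    # the log-likelihood scales with n; judge convergence by the gradient
    # norm rather than the optimizer's line-search status
    grad_small = bool(np.max(np.abs(res.jac)) < 1e-3 * max(1.0, n_events / 100.0))
    return WeibullFit(
        shape=float(math.exp(res.x[0])),
        log_scale=float(res.x[1]),
        loglik=float(-res.fun),
        converged=bool(res.success or grad_small),
    )


# --------------------------------------------------------------------------
# Replicate engine
# --------------------------------------------------------------------------

#: Default calibration evaluation grid (years).
DEFAULT_EVAL_TIMES = (0.5, 1.0, 2.0)


@dataclasses.dataclass
class ReplicateResult:
    """One simulation replicate: fits with/without adjustment, evaluated twice.

    ``c_index`` maps (model, sample) with model in {"adjusted",
    "unadjusted"} and sample in {"observed", "complete"}; ``calibration``
    maps the same keys to decile tables.
    """

    c_index: dict
    calibration: dict
    lambda_min: dict
    n_total: int
    n_truncated: int
    n_train_observed: int
    n_test_observed: int

    def c_index_frame(self) -> pd.DataFrame:
        rows = [
            {"adjusted": model == "adjusted", "sample": sample, "c_index": val}
            for (model, sample), val in self.c_index.items()
        ]
        return pd.DataFrame(rows)


def run_replicate(
    config: SimConfig,
    scenario: str | None = None,
    eval_times: Sequence[float] = DEFAULT_EVAL_TIMES,
    n_folds: int = 10,
    n_bins: int = 10,
) -> ReplicateResult:
    """Full protocol for one replicate of the simulation study.

    Generates a cohort, splits 75/25, fits lasso Cox models with and
    without the left-truncation adjustment on the observed training
    subjects (lambda by ``n_folds``-fold CV deviance minimization), and
    evaluates Harrell's C and decile calibration on the test set twice:
    on the observed (non-truncated) subset and on the complete sample.
    """
    if scenario is not None:
        p_map = {"small_p": 10, "large_p": 1000}
        if scenario not in p_map:
            raise ValueError(f"scenario must be one of {sorted(p_map)}, got {scenario!r}")
        config = config.replace(p_binary=p_map[scenario])
    s_split, s_cv_adj, s_cv_unadj = _child_seeds(config.seed ^ 0x5F5E100, 3)
    cohort = generate_cohort(config)
    train_idx, test_idx = split_indices(cohort.n, config.train_fraction, s_split)

    train_obs = cohort.observed(rows=train_idx)
    test_obs = cohort.observed(rows=test_idx)
    X_test_complete = cohort.predictors[test_idx]
    y_test_complete = cohort.observed_Y[test_idx]
    e_test_complete = cohort.event[test_idx]

    c_index: dict = {}
    calibration: dict = {}
    lambda_min: dict = {}
    for model, adjust, cv_seed in (
        ("adjusted", True, s_cv_adj),
        ("unadjusted", False, s_cv_unadj),
    ):
        cv = cross_validate(train_obs, alpha_mix=1.0, n_folds=n_folds, adjust=adjust, seed=cv_seed)
        beta = cv.coef_min
        lambda_min[model] = cv.lambda_min
        baseline = breslow_baseline(train_obs, beta, adjust=adjust)

        risk_obs = test_obs.predictors @ beta
        c_index[(model, "observed")] = concordance(test_obs.time, test_obs.event, risk_obs)
        risk_complete = X_test_complete @ beta
        c_index[(model, "complete")] = concordance(
            y_test_complete, e_test_complete, risk_complete
        )

        pred_obs = predict_survival(baseline, beta, test_obs.predictors, eval_times)
        calibration[(model, "observed")] = calibration_curve(
            pred_obs, test_obs.time, test_obs.event, eval_times,
            n_bins=n_bins, entries=test_obs.entry,
        )
        pred_complete = predict_survival(baseline, beta, X_test_complete, eval_times)
        calibration[(model, "complete")] = calibration_curve(
            pred_complete, y_test_complete, e_test_complete, eval_times, n_bins=n_bins,
        )

    return ReplicateResult(
        c_index=c_index,
        calibration=calibration,
        lambda_min=lambda_min,
        n_total=cohort.n,
        n_truncated=int(cohort.truncated.sum()),
        n_train_observed=train_obs.n,
        n_test_observed=test_obs.n,
    )
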