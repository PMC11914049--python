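"""Hierarchical Bayesian effect-size models for cover and colony counts.

Two model families are supported, mirroring the survey designs:

* **alr cover, normal/identity** — the alr-transformed cover of a taxon (or
  of total cover) regressed on a binary substrate/processing indicator, water
  depth, and survey year, with their interactions; the harbor-wide model adds
  survey-site and survey-method random intercepts (11 and 5 levels).
* **colony counts, gamma/log** — colony density regressed on the same block
  design, with the gamma parameterized by mean ``mu`` and variance ``eps^2``
  (shape ``mu^2/eps^2``, rate ``mu/eps^2``).

Covariates (including binary indicators, by default) are standardized to
mean 0 / SD 0.5 by subtracting the mean and dividing by twice the sample SD,
so coefficients are comparable effect sizes.  Priors are deliberately those
of the original survey protocol: Uniform(-10, 10) on cover coefficients,
Uniform(-20, 20) on colony coefficients, and Half-Cauchy(scale 1e-2) on all
scale parameters.  Sampling is gradient-based no-U-turn MCMC: five
independent runs of 1000 discarded tuning steps + 2000 retained draws,
pooled into 10,000 draws; convergence is assessed with the classical
Gelman-Rubin statistic across the five runs.

An effect is classified *credible* when its 80% highest-density interval
excludes zero (an endpoint exactly at zero counts as overlapping).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import digamma, expit, gammaln

from ._nuts import nuts_sample

__all__ = [
    "ModelSpec",
    "ScalingRecord",
    "PosteriorSummary",
    "standardize_design",
    "fit_hbm",
    "hdi",
    "classify_trend",
    "gelman_rubin",
    "bayes_r2",
    "screen_collinearity",
]


# ---------------------------------------------------------------------------
# design standardization

@dataclass(frozen=True)
class ScalingRecord:
    """Means and SDs used for 2SD standardization, kept for back-transforms."""

    means: "pd.Series[float]"
    sds: "pd.Series[float]"


def standardize_design(
    columns: pd.DataFrame, *, which: Sequence[str] | None = None
) -> tuple[pd.DataFrame, ScalingRecord]:
    """Standardize covariates to (x - mean) / (2 * SD), sample SD (ddof=1).

    The resulting columns have mean 0 and SD 0.5, putting continuous slopes
    on the same scale as binary contrasts.  Raises on constant columns.
    """
    cols = list(which) if which is not None else list(columns.columns)
    out = columns.copy()
    means = {}
    sds = {}
    for col in cols:
        x = columns[col].astype(float)
        sd = float(x.std(ddof=1))
        if sd == 0.0 or not np.isfinite(sd):
            raise ValueError(f"column {col!r} is constant; cannot standardize")
        means[col] = float(x.mean())
        sds[col] = sd
        out[col] = (x - means[col]) / (2.0 * sd)
    return out, ScalingRecord(means=pd.Series(means), sds=pd.Series(sds))


# ---------------------------------------------------------------------------
# model specification

_EQUATIONS = {
    # equation: (response family, binary term, continuous terms, random?, bound)
    "eq1_cover": ("normal", "substrate", ("depth", "year"), True, 10.0),
    "eq2_block_cover": ("normal", "surface_processing", ("depth", "years"), False, 10.0),
    "eq3_colony": ("gamma", "surface_processing", ("depth", "years"), False, 20.0),
}


@dataclass
class ModelSpec:
    """Configuration of one hierarchical model fit."""

    equation: str
    family: str = field(init=False)
    binary_term: str = field(init=False)
    continuous_terms: tuple[str, str] = field(init=False)
    has_random_effects: bool = field(init=False)
    prior_bound: float = field(init=False)
    halfcauchy_scale: float = 1e-2
    standardize_binary: bool = True
    tune: int = 1000
    draws: int = 2000
    repetitions: int = 5
    target_accept: float = 0.8
    max_treedepth: int = 10
    divergence_warn_fraction: float = 0.05

    def __post_init__(self) -> None:
        if self.equation not in _EQUATIONS:
            raise ValueError(f"unknown equation {self.equation!r}")
        family, binary, continuous, random_fx, bound = _EQUATIONS[self.equation]
        self.family = family
        self.binary_term = binary
        self.continuous_terms = continuous
        self.has_random_effects = random_fx
        self.prior_bound = bound
        if self.tune <= 0 or self.draws <= 0 or self.repetitions <= 0:
            raise ValueError("tune, draws and repetitions must be positive")

    @property
    def term_names(self) -> list[str]:
        b, (c1, c2) = self.binary_term, self.continuous_terms
        return ["intercept", b, c1, c2, f"{b}:{c1}", f"{b}:{c2}"]


# ---------------------------------------------------------------------------
# log posteriors (unconstrained space, analytic gradients)

_LOG_2_PI = np.log(2.0 * np.pi)


def _bounded(z: np.ndarray, bound: float) -> tuple[np.ndarray, np.ndarray, float]:
    """Map real z to (-bound, bound); return value, dvalue/dz, log-Jacobian."""
    s = expit(z)
    value = bound * (2.0 * s - 1.0)
    dval = 2.0 * bound * s * (1.0 - s)
    with np.errstate(divide="ignore"):
        log_jac = float(np.sum(np.log(dval)))
    return value, dval, log_jac


def _half_cauchy(sigma: float, scale: float) -> tuple[float, float]:
    """Half-Cauchy log density and d/dsigma."""
    lp = np.log(2.0 / np.pi) + np.log(scale) - np.log(scale**2 + sigma**2)
    return lp, -2.0 * sigma / (scale**2 + sigma**2)


class _NormalModel:
    """y ~ Normal(X beta [+ site/method random intercepts], eps^2)."""

    def __init__(self, X, y, bound, hc_scale, site_idx=None, method_idx=None):
        self.X = X
        self.y = y
        self.bound = bound
        self.hc = hc_scale
        self.site_idx = site_idx
        self.method_idx = method_idx
        self.p = X.shape[1]
        self.n_site = 0 if site_idx is None else int(site_idx.max()) + 1
        self.n_method = 0 if method_idx is None else int(method_idx.max()) + 1
        self.dim = self.p + 1 + (2 + self.n_site + self.n_method if site_idx is not None else 0)

    def unpack(self, z):
        p = self.p
        beta, dbeta, jac = _bounded(z[:p], self.bound)
        eps = np.exp(z[p])
        parts = {"beta": beta, "eps": eps}
        if self.site_idx is not None:
            s_site = np.exp(z[p + 1])
            s_method = np.exp(z[p + 2])
            u_site = z[p + 3 : p + 3 + self.n_site]
            u_method = z[p + 3 + self.n_site :]
            parts.update(
                s_site=s_site, s_method=s_method, u_site=u_site, u_method=u_method
            )
        return parts, dbeta, jac

    def mu(self, parts):
        mu = self.X @ parts["beta"]
        if self.site_idx is not None:
            mu = mu + parts["s_site"] * parts["u_site"][self.site_idx]
            mu = mu + parts["s_method"] * parts["u_method"][self.method_idx]
        return mu

    def logp_and_grad(self, z):
        # scale parameters live on the log scale; reject the far tails before
        # exp() can overflow into NaN gradients
        n_scales = 3 if self.site_idx is not None else 1
        if np.max(np.abs(z[self.p : self.p + n_scales])) > 200.0:
            return -np.inf, np.zeros_like(z)
        parts, dbeta, jac = self.unpack(z)
        eps = parts["eps"]
        mu = self.mu(parts)
        res = self.y - mu
        n = self.y.size
        ss = float(res @ res)
        logp = -0.5 * n * _LOG_2_PI - n * np.log(eps) - 0.5 * ss / eps**2
        grad = np.zeros_like(z)
        dmu = res / eps**2                       # d loglik / d mu_i
        grad[: self.p] = (self.X.T @ dmu) * dbeta + (1.0 - 2.0 * expit(z[: self.p]))
        logp += jac
        # eps: likelihood + half-Cauchy prior + log-Jacobian of exp
        lp_hc, dlp_hc = _half_cauchy(eps, self.hc)
        logp += lp_hc + z[self.p]
        grad[self.p] = (-n / eps + ss / eps**3 + dlp_hc) * eps + 1.0
        if self.site_idx is not None:
            p = self.p
            for name, idx, zslot in (
                ("site", self.site_idx, p + 1),
                ("method", self.method_idx, p + 2),
            ):
                s = parts[f"s_{name}"]
                u = parts[f"u_{name}"]
                n_lev = u.size
                acc = np.bincount(idx, weights=dmu, minlength=n_lev)
                # non-centered: effect = s * u, u ~ N(0, 1)
                logp += -0.5 * n_lev * _LOG_2_PI - 0.5 * float(u @ u)
                lp_s, dlp_s = _half_cauchy(s, self.hc)
                logp += lp_s + z[zslot]
                grad[zslot] = (float(acc @ u) + dlp_s) * s + 1.0
                off = p + 3 if name == "site" else p + 3 + self.n_site
                grad[off : off + n_lev] = s * acc - u
        if not np.isfinite(logp):
            return -np.inf, np.zeros_like(z)
        return logp, grad


class _GammaModel:
    """y ~ Gamma(mean mu = exp(X beta), variance eps^2), log link."""

    def __init__(self, X, y, bound, hc_scale):
        if np.any(y <= 0):
            raise ValueError(
                "gamma colony model requires strictly positive counts; "
                "zero densities are outside its support"
            )
        self.X = X
        self.y = y
        self.logy = np.log(y)
        self.bound = bound
        self.hc = hc_scale
        self.p = X.shape[1]
        self.dim = self.p + 1

    def unpack(self, z):
        beta, dbeta, jac = _bounded(z[: self.p], self.bound)
        return beta, np.exp(z[self.p]), dbeta, jac

    def logp_and_grad(self, z):
        beta, eps, dbeta, jac = self.unpack(z)
        eta = self.X @ beta
        if np.max(np.abs(eta)) > 250.0 or eps > 1e8 or eps < 1e-8:
            return -np.inf, np.zeros_like(z)
        mu = np.exp(eta)
        v = eps**2
        k = mu**2 / v                 # shape
        lam = mu / v                  # rate
        logp = float(
            np.sum(k * np.log(lam) - gammaln(k) + (k - 1.0) * self.logy - lam * self.y)
        )
        dl_dk = np.log(lam) - digamma(k) + self.logy
        dl_dlam = k / lam - self.y
        dl_dmu = dl_dk * (2.0 * mu / v) + dl_dlam / v
        dl_deta = dl_dmu * mu
        grad = np.zeros_like(z)
        grad[: self.p] = (self.X.T @ dl_deta) * dbeta + (1.0 - 2.0 * expit(z[: self.p]))
        logp += jac
        dl_dv = float(np.sum(dl_dk * (-(mu**2) / v**2) + dl_dlam * (-mu / v**2)))
        lp_hc, dlp_hc = _half_cauchy(eps, self.hc)
        logp += lp_hc + z[self.p]
        grad[self.p] = (dl_dv * 2.0 * eps + dlp_hc) * eps + 1.0
        if not np.isfinite(logp):
            return -np.inf, np.zeros_like(z)
        return logp, grad


# ---------------------------------------------------------------------------
# posterior summaries

@dataclass
class PosteriorSummary:
    """Pooled posterior draws and per-parameter summaries for one fit."""

    equation: str
    table: pd.DataFrame            # median, HDIs, rhat, credibility per parameter
    draws: dict[str, np.ndarray]   # name -> (repetitions, draws)
    bayes_r2: dict[str, float]     # median and 95% HDI of the R^2 distribution
    scaling: ScalingRecord
    n_obs: int
    seeds: list[int]
    n_divergent: int
    divergence_warning: bool

    @property
    def coefficients(self) -> pd.DataFrame:
        mask = ~self.table.index.str.startswith(("eps", "s_site", "s_method"))
        return self.table[mask]

    def pooled(self, name: str) -> np.ndarray:
        return self.draws[name].reshape(-1)


def hdi(draws: np.ndarray, mass: float) -> tuple[float, float]:
    """Shortest contiguous interval containing ``mass`` of the draws."""
    if not 0.0 < mass < 1.0:
        raise ValueError("mass must be in (0, 1)")
    x = np.sort(np.asarray(draws, dtype=float).ravel())
    n = x.size
    if n < 100:
        raise ValueError("need at least 100 draws for an HDI")
    m = int(np.ceil(mass * n))
    widths = x[m - 1 :] - x[: n - m + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + m - 1])


def classify_trend(interval: tuple[float, float]) -> str:
    """Credibility of an effect from its 80% HDI (strictly excludes zero)."""
    low, high = interval
    if high < 0.0:
        return "credible_negative"
    if low > 0.0:
        return "credible_positive"
    return "not_credible"


def gelman_rubin(chains: np.ndarray) -> float:
    """Classical potential scale reduction factor across independent runs.

    ``chains`` is (k, n) with k >= 2.  Identical chains give ~1.0; a zero
    within-chain variance with nonzero spread between chains flags the
    parameter with ``inf``.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2:
        raise ValueError("need a (k >= 2, n) array of chains")
    k, n = chains.shape
    within = float(np.mean(np.var(chains, axis=1, ddof=1)))
    b_over_n = float(np.var(np.mean(chains, axis=1), ddof=1))
    if within == 0.0:
        return 1.0 if b_over_n == 0.0 else np.inf
    var_plus = (n - 1) / n * within + b_over_n
    return float(np.sqrt(var_plus / within))


def bayes_r2(mu_draws: np.ndarray, sigma2_draws: np.ndarray) -> dict[str, float]:
    """Bayesian R^2: per-draw var(predicted) / (var(predicted) + var(residual)).

    ``mu_draws`` is (draws, n_obs); ``sigma2_draws`` the model residual
    variance per draw.
    """
    var_pred = np.var(mu_draws, axis=1, ddof=1)
    r2 = var_pred / (var_pred + np.asarray(sigma2_draws))
    low, high = hdi(r2, 0.95)
    return {"median": float(np.median(r2)), "hdi95_low": low, "hdi95_high": high}


def screen_collinearity(columns: pd.DataFrame) -> dict[str, pd.DataFrame | pd.Series]:
    """Variance inflation factors and the pairwise Pearson correlation matrix.

    This is a report, not a gate: the survey protocol only documents that
    VIFs and correlations are small before fitting.
    """
    X = columns.astype(float)
    if X.shape[1] < 2:
        raise ValueError("need at least two covariates to screen")
    vifs = {}
    for col in X.columns:
        others = X.drop(columns=col).to_numpy()
        design = np.column_stack([np.ones(len(X)), others])
        y = X[col].to_numpy()
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        resid = y - design @ coef
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 - float(resid @ resid) / ss_tot if ss_tot > 0 else 1.0
        vifs[col] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return {"vif": pd.Series(vifs), "correlation": X.corr()}


# ---------------------------------------------------------------------------
# fitting

def build_design(
    spec: ModelSpec, data: pd.DataFrame
) -> tuple[np.ndarray, list[str], ScalingRecord, np.ndarray | None, np.ndarray | None]:
    """Standardize covariates and assemble the fixed-effects design matrix.

    Interactions are products of the *standardized* main effects.
    """
    b, (c1, c2) = spec.binary_term, spec.continuous_terms
    cols = [b, c1, c2]
    missing = [c for c in cols if c not in data.columns]
    if missing:
        raise ValueError(f"data lacks required columns {missing}")
    which = cols if spec.standardize_binary else [c1, c2]
    std, scaling = standardize_design(data[cols], which=which)
    X = np.column_stack(
        [
            np.ones(len(data)),
            std[b],
            std[c1],
            std[c2],
            std[b] * std[c1],
            std[b] * std[c2],
        ]
    )
    site_idx = method_idx = None
    if spec.has_random_effects:
        for col in ("site_id", "method"):
            if col not in data.columns:
                raise ValueError(f"equation {spec.equation} needs column {col!r}")
        site_idx = pd.Categorical(data["site_id"]).codes.astype(int)
        method_idx = pd.Categorical(data["method"]).codes.astype(int)
    return X, spec.term_names, scaling, site_idx, method_idx


def fit_hbm(
    spec: ModelSpec, data: pd.DataFrame, response: str, seed: int
) -> PosteriorSummary:
    """Fit one hierarchical model under the five-run NUTS protocol.

    ``data`` is a resolved table with the covariate columns the equation
    needs plus the ``response`` column (alr cover, or strictly positive
    colony density for the gamma model).  All randomness flows from ``seed``,
    which is expanded deterministically into one sub-seed per run.
    """
    y = data[response].to_numpy(dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError(f"response {response!r} contains non-finite values")
    X, names, scaling, site_idx, method_idx = build_design(spec, data)

    if spec.family == "normal":
        model = _NormalModel(
            X, y, spec.prior_bound, spec.halfcauchy_scale, site_idx, method_idx
        )
    else:
        model = _GammaModel(X, y, spec.prior_bound, spec.halfcauchy_scale)

    seed_seq = np.random.SeedSequence(seed)
    run_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in seed_seq.spawn(spec.repetitions)]
    p = model.p
    all_draws = np.empty((spec.repetitions, spec.draws, model.dim))
    n_divergent = 0
    scale_init = np.log(max(float(np.std(y)), 0.1))
    for r, run_seed in enumerate(run_seeds):
        rng = np.random.default_rng(run_seed)
        z0 = np.zeros(model.dim)
        z0[p] = scale_init
        if spec.family == "normal" and spec.has_random_effects:
            z0[p + 1] = z0[p + 2] = np.log(0.1)
        z0 = z0 + rng.uniform(-0.1, 0.1, model.dim)
        result = nuts_sample(
            model.logp_and_grad,
            z0,
            spec.tune,
            spec.draws,
            rng,
            target_accept=spec.target_accept,
            max_treedepth=spec.max_treedepth,
        )
        all_draws[r] = result.draws
        n_divergent += result.n_divergent

    # transform to the constrained scale, named per parameter
    draws: dict[str, np.ndarray] = {}
    beta_draws = spec.prior_bound * (2.0 * expit(all_draws[..., :p]) - 1.0)
    for j, name in enumerate(names):
        draws[name] = beta_draws[..., j]
    eps_label = {"eq1_cover": "eps", "eq2_block_cover": "eps2", "eq3_colony": "eps3"}[
        spec.equation
    ]
    draws[eps_label] = np.exp(all_draws[..., p])
    if spec.has_random_effects:
        draws["s_site"] = np.exp(all_draws[..., p + 1])
        draws["s_method"] = np.exp(all_draws[..., p + 2])

    rows = []
    for name, d in draws.items():
        pooled = d.reshape(-1)
        h80 = hdi(pooled, 0.80)
        h95 = hdi(pooled, 0.95)
        rows.append(
            {
                "parameter": name,
                "median": float(np.median(pooled)),
                "hdi80_low": h80[0],
                "hdi80_high": h80[1],
                "hdi95_low": h95[0],
                "hdi95_high": h95[1],
                "rhat": gelman_rubin(d) if spec.repetitions >= 2 else np.nan,
                "credible": classify_trend(h80) if name in names else "",
            }
        )
    table = pd.DataFrame(rows).set_index("parameter")

    # Bayesian R^2 on the pooled linear predictor
    flat = all_draws.reshape(-1, model.dim)
    beta_flat = beta_draws.reshape(-1, p)
    if spec.family == "normal":
        mu = beta_flat @ X.T
        if spec.has_random_effects:
            s_site = draws["s_site"].reshape(-1, 1)
            s_method = draws["s_method"].reshape(-1, 1)
            u_site = flat[:, p + 3 : p + 3 + model.n_site]
            u_method = flat[:, p + 3 + model.n_site :]
            mu = mu + s_site * u_site[:, site_idx] + s_method * u_method[:, method_idx]
        sigma2 = draws[eps_label].reshape(-1) ** 2
    else:
        mu = np.exp(np.clip(beta_flat @ X.T, -250, 250))
        sigma2 = draws[eps_label].reshape(-1) ** 2
    r2 = bayes_r2(mu, sigma2)

    total_draws = spec.repetitions * spec.draws
    return PosteriorSummary(
        equation=spec.equation,
        table=table,
        draws=draws,
        bayes_r2=r2,
        scaling=scaling,
        n_obs=len(y),
        seeds=run_seeds,
        n_divergent=n_divergent,
        divergence_warning=n_divergent > spec.divergence_warn_fraction * total_draws,
    )
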