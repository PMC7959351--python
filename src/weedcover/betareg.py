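"""Beta regression of green proportion on days after treatment.

Mean model (logit link):
    h(mu) = alpha0 + alpha1*P0 + alpha2*P1 + (beta0 + beta1*P0 + beta2*P1) * D
where D is continuous days after treatment and P0, P1 are dummies for the
nongray and gray zones of a treated pot (control C is the reference).
Precision model (log link): log(phi) = gamma0 + gamma1 * D. Outcomes follow
Beta(mu*phi, (1-mu)*phi).

Two fits are provided, mirroring the two analyses the method calls for:
an unconstrained maximum-likelihood fit (betareg-style), and a Bayesian fit
whose parameter space is restricted to growth that cannot be negative —
beta0 > 0, beta0 + beta1 > 0, beta0 + beta2 > 0 — sampled by adaptive
random-walk Metropolis with a hard admissibility indicator.

Group labels: the canonical three-group analysis uses C / P0 / P1. For the
pre-segmentation analysis the whole treated pot enters as a single group
labelled "T", which occupies the first dummy slot (alpha1, beta1); the unused
second slot is NaN so accidental use of an absent group fails loudly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, gammaln

__all__ = [
    "BetaRegParams",
    "PriorSpec",
    "PosteriorDraws",
    "FitReport",
    "BoundaryDataError",
    "validate_observations",
    "nudge_boundary",
    "linear_predictor",
    "mean_mu",
    "precision_phi",
    "log_likelihood",
    "fit_ml",
    "sample_posterior",
]

OBS_COLUMNS = ("pot_id", "group", "day", "proportion")

# dummy slot occupied by each non-reference group label
_SLOT = {"P0": 0, "P1": 1, "T": 0}

MEAN_COEF = ("alpha0", "alpha1", "alpha2", "beta0", "beta1", "beta2")
PREC_COEF = ("gamma0", "gamma1")
ALL_COEF = MEAN_COEF + PREC_COEF


class BoundaryDataError(ValueError):
    """Outcome exactly 0 or 1; apply nudge_boundary before fitting."""


@dataclass(frozen=True)
class BetaRegParams:
    """The 8 regression coefficients (mean model + precision model)."""

    alpha0: float
    alpha1: float = 0.0
    alpha2: float = 0.0
    beta0: float = 0.0
    beta1: float = 0.0
    beta2: float = 0.0
    gamma0: float = 0.0
    gamma1: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, k) for k in ALL_COEF], dtype=float)

    def is_admissible(self) -> bool:
        """Growth-monotonicity constraints: every group's slope positive."""
        return bool(
            self.beta0 > 0
            and self.beta0 + self.beta1 > 0
            and self.beta0 + self.beta2 > 0
        )


def _dummies(group: str | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    g = np.asarray(group, dtype=object)
    known = {"C"} | set(_SLOT)
    bad = {x for x in np.atleast_1d(g) if x not in known}
    if bad:
        raise ValueError(f"unknown group label(s) {sorted(bad)}; expected C/P0/P1/T")
    p0 = np.where((g == "P0") | (g == "T"), 1.0, 0.0)
    p1 = np.where(g == "P1", 1.0, 0.0)
    return p0, p1


def linear_predictor(
    params: BetaRegParams, day: float | np.ndarray, group: str | np.ndarray
) -> float | np.ndarray:
    """eta = alpha0 + alpha1*P0 + alpha2*P1 + (beta0 + beta1*P0 + beta2*P1)*D.

    A zero dummy contributes exactly zero even when the other group's
    coefficient is NaN (absent from a two-group fit); a nonzero dummy with a
    NaN coefficient propagates NaN, which downstream consumers reject.
    """
    p0, p1 = _dummies(group)
    d = np.asarray(day, dtype=float)

    def term(coef: float, dummy: np.ndarray) -> np.ndarray:
        return np.where(dummy == 0.0, 0.0, coef * dummy)

    eta = (
        params.alpha0 + term(params.alpha1, p0) + term(params.alpha2, p1)
        + (params.beta0 + term(params.beta1, p0) + term(params.beta2, p1)) * d
    )
    return float(eta) if eta.ndim == 0 else eta


def mean_mu(
    params: BetaRegParams, day: float | np.ndarray, group: str | np.ndarray
) -> float | np.ndarray:
    """mu = logit^-1(eta), overflow-safe (saturates strictly inside (0,1))."""
    eta = linear_predictor(params, day, group)
    mu = expit(eta)
    return float(mu) if np.ndim(mu) == 0 else mu


def precision_phi(params: BetaRegParams, day: float | np.ndarray) -> float | np.ndarray:
    """phi = exp(gamma0 + gamma1 * D)."""
    phi = np.exp(params.gamma0 + params.gamma1 * np.asarray(day, dtype=float))
    return float(phi) if phi.ndim == 0 else phi


def validate_observations(obs: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in OBS_COLUMNS if c not in obs.columns]
    if missing:
        raise ValueError(f"observation table missing columns {missing}")
    y = obs["proportion"].to_numpy(dtype=float)
    if np.any((y <= 0.0) | (y >= 1.0)):
        raise BoundaryDataError(
            "proportions must lie strictly in (0, 1); apply nudge_boundary() "
            "to boundary outcomes first"
        )
    if np.any(obs["day"].to_numpy(dtype=float) < 0):
        raise ValueError("days must be nonnegative")
    _dummies(obs["group"].to_numpy())
    return obs


def nudge_boundary(y: np.ndarray | pd.Series, n: int | None = None) -> np.ndarray:
    """Standard compression (y*(n-1) + 0.5)/n pulling exact 0/1 outcomes into
    the open interval; n defaults to the sample size."""
    arr = np.asarray(y, dtype=float)
    if n is None:
        n = arr.size
    return (arr * (n - 1) + 0.5) / n


# ---------------------------------------------------------------------------
# likelihood


def _design(obs: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(X_mean, X_prec, y): columns [1, P0, P1, D, D*P0, D*P1] and [1, D]."""
    p0, p1 = _dummies(obs["group"].to_numpy())
    d = obs["day"].to_numpy(dtype=float)
    y = obs["proportion"].to_numpy(dtype=float)
    ones = np.ones_like(d)
    x_mean = np.column_stack([ones, p0, p1, d, d * p0, d * p1])
    x_prec = np.column_stack([ones, d])
    return x_mean, x_prec, y


def _loglik_vec(theta: np.ndarray, x_mean: np.ndarray, x_prec: np.ndarray, y: np.ndarray) -> float:
    """Beta log-likelihood at one 8-vector (mean coefs then gamma0, gamma1)."""
    eta = x_mean @ theta[:6]
    mu = expit(eta)
    phi = np.exp(x_prec @ theta[6:])
    a = mu * phi
    b = (1.0 - mu) * phi
    if np.any(a <= 0) or np.any(b <= 0) or not np.all(np.isfinite(a + b)):
        return -np.inf
    ll = (
        gammaln(phi) - gammaln(a) - gammaln(b)
        + (a - 1.0) * np.log(y) + (b - 1.0) * np.log1p(-y)
    )
    return float(ll.sum())


def log_likelihood(params: BetaRegParams, obs: pd.DataFrame) -> float:
    """Sum of Beta(mu_i*phi_i, (1-mu_i)*phi_i) log densities over the table."""
    validate_observations(obs)
    x_mean, x_prec, y = _design(obs)
    return _loglik_vec(params.as_array(), x_mean, x_prec, y)


# ---------------------------------------------------------------------------
# maximum likelihood


@dataclass(frozen=True)
class FitReport:
    converged: bool
    loglik: float
    grad_norm: float
    n_obs: int
    groups: tuple[str, ...]
    std_errors: dict[str, float]
    message: str = ""
    cov: np.ndarray | None = None  # parameter covariance, fit's column order


def _start_values(obs: pd.DataFrame) -> np.ndarray:
    """Logit of group-day cell means for the mean model; log of a
    method-of-moments precision for gamma0; 0 for gamma1."""
    df = obs.copy()
    cell = df.groupby(["group", "day"])["proportion"].mean()
    eps = 1e-4
    logit_cell = np.log(np.clip(cell, eps, 1 - eps) / np.clip(1 - cell, eps, 1 - eps))
    # least squares of logit cell means on the mean design
    tab = logit_cell.reset_index()
    p0, p1 = _dummies(tab["group"].to_numpy())
    d = tab["day"].to_numpy(dtype=float)
    x = np.column_stack([np.ones_like(d), p0, p1, d, d * p0, d * p1])
    keep = _identifiable_columns(obs)
    coef = np.zeros(6)
    sol, *_ = np.linalg.lstsq(x[:, keep], logit_cell.to_numpy(), rcond=None)
    coef[keep] = sol
    ybar = df["proportion"].mean()
    s2 = max(df["proportion"].var(), 1e-6)
    phi0 = max(ybar * (1 - ybar) / s2 - 1.0, 1.1)
    return np.concatenate([coef, [np.log(phi0), 0.0]])


def _identifiable_columns(obs: pd.DataFrame) -> list[int]:
    """Mean-design columns identifiable from the groups present in the data."""
    groups = set(obs["group"].unique())
    keep = {0, 3}  # intercept, D
    if groups & {"P0", "T"}:
        keep |= {1, 4}
    if "P1" in groups:
        keep |= {2, 5}
    return sorted(keep)


def fit_ml(
    obs: pd.DataFrame, start: BetaRegParams | None = None
) -> tuple[BetaRegParams, FitReport]:
    """Unconstrained maximum-likelihood fit of the variable-precision beta
    regression (the betareg-style analysis).

    Requires at least 10 observations spanning at least 2 distinct days.
    Coefficients of groups absent from the data are NaN in the returned
    params. Standard errors come from the observed information.
    """
    validate_observations(obs)
    if len(obs) < 10:
        raise ValueError("need at least 10 observations")
    if obs["day"].nunique() < 2:
        raise ValueError("need observations on at least 2 distinct days")
    y = obs["proportion"].to_numpy(dtype=float)
    if y.std() < 1e-6:
        warnings.warn("outcome nearly constant; fit may be degenerate", stacklevel=2)

    from statsmodels.genmod.families.links import Log
    from statsmodels.othermod.betareg import BetaModel

    x_mean, x_prec, _ = _design(obs)
    keep = _identifiable_columns(obs)
    names = [MEAN_COEF[i] for i in keep] + list(PREC_COEF)
    x = x_mean[:, keep]

    if start is not None:
        sv = np.concatenate([start.as_array()[keep], start.as_array()[6:]])
    else:
        full = _start_values(obs)
        sv = np.concatenate([full[keep], full[6:]])

    model = BetaModel(y, x, exog_precision=x_prec, link_precision=Log())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(start_params=sv, method="bfgs", maxiter=500, disp=False)
        if not res.mle_retvals.get("converged", False):
            res = model.fit(start_params=res.params, method="nm", maxiter=5000, disp=False)
            res = model.fit(start_params=res.params, method="bfgs", maxiter=500, disp=False)

    grad = model.score(res.params)
    grad_norm = float(np.linalg.norm(grad))
    converged = bool(res.mle_retvals.get("converged", False)) or grad_norm < 1e-3
    if not converged:
        raise RuntimeError(
            f"beta regression did not converge (|grad|={grad_norm:.3g}); "
            f"trace: {res.mle_retvals}"
        )

    est = dict(zip(names, res.params))
    se = dict(zip(names, res.bse))
    full_est = {k: est.get(k, np.nan) for k in ALL_COEF}
    # groups absent from the data keep NaN coefficients; present ones are real
    params = BetaRegParams(**full_est)
    report = FitReport(
        converged=converged,
        loglik=float(res.llf),
        grad_norm=grad_norm,
        n_obs=len(obs),
        groups=tuple(sorted(obs["group"].unique())),
        std_errors=se,
        message=str(res.mle_retvals.get("warnflag", "")),
        cov=np.asarray(res.cov_params()),
    )
    return params, report


# ---------------------------------------------------------------------------
# constrained Bayesian fit


@dataclass(frozen=True)
class PriorSpec:
    """Independent normal priors: N(0, mean_scale) on the six mean-model
    coefficients, N(0, precision_scale) on gamma0 and gamma1 — weakly
    informative defaults in the spirit of regularized-regression software —
    plus a hard indicator enforcing the admissible slope region."""

    mean_loc: float = 0.0
    mean_scale: float = 2.5
    precision_loc: float = 0.0
    precision_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.mean_scale <= 0 or self.precision_scale <= 0:
            raise ValueError("prior scales must be positive")

    def log_prior(self, theta: np.ndarray, keep: Sequence[int]) -> float:
        m = theta[: len(keep)]
        g = theta[len(keep):]
        lp = -0.5 * np.sum(((m - self.mean_loc) / self.mean_scale) ** 2)
        lp += -0.5 * np.sum(((g - self.precision_loc) / self.precision_scale) ** 2)
        return float(lp)


@dataclass
class PosteriorDraws:
    """Constrained posterior sample with convergence metadata.

    ``draws`` has shape (n_chains, n_draws, ndim) in ``names`` order; every
    stored draw satisfies the admissibility constraints.
    """

    draws: np.ndarray
    names: tuple[str, ...]
    groups: tuple[str, ...]
    n_chains: int
    n_warmup: int
    seed: int
    rhat: dict[str, float] = field(default_factory=dict)
    ess: dict[str, float] = field(default_factory=dict)
    accept_rate: float = float("nan")
    warnings_: list[str] = field(default_factory=list)

    @property
    def n_draws(self) -> int:
        return self.draws.shape[0] * self.draws.shape[1]

    def flat(self) -> np.ndarray:
        return self.draws.reshape(-1, self.draws.shape[2])

    def to_params(self) -> list[BetaRegParams]:
        out = []
        for row in self.flat():
            d = {k: np.nan for k in ALL_COEF}
            d.update(dict(zip(self.names, row)))
            out.append(BetaRegParams(**d))
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.flat(), columns=list(self.names))

    def param_arrays(self) -> dict[str, np.ndarray]:
        flat = self.flat()
        d = {k: np.full(flat.shape[0], np.nan) for k in ALL_COEF}
        for j, name in enumerate(self.names):
            d[name] = flat[:, j]
        return d


def _admissible_vec(theta: np.ndarray, names: Sequence[str]) -> bool:
    d = dict(zip(names, theta))
    b0 = d.get("beta0", np.nan)
    if not b0 > 0:
        return False
    if "beta1" in d and not b0 + d["beta1"] > 0:
        return False
    if "beta2" in d and not b0 + d["beta2"] > 0:
        return False
    return True


def _project_admissible(theta: np.ndarray, names: Sequence[str], margin: float = 0.05) -> np.ndarray:
    out = theta.copy()
    idx = {n: i for i, n in enumerate(names)}
    b0 = max(out[idx["beta0"]], margin)
    out[idx["beta0"]] = b0
    for slope in ("beta1", "beta2"):
        if slope in idx and b0 + out[idx[slope]] <= 0:
            out[idx[slope]] = -b0 + margin
    return out


def sample_posterior(
    obs: pd.DataFrame,
    priors: PriorSpec | None = None,
    n_chains: int = 4,
    n_iter: int = 2000,
    n_warmup: int = 1000,
    seed: int = 0,
) -> PosteriorDraws:
    """Sample the constrained posterior by adaptive random-walk Metropolis.

    Posterior ∝ likelihood × normal priors × 1{beta0>0, beta0+beta1>0,
    beta0+beta2>0}. Chains are independent (per-chain substreams of ``seed``),
    initialized by jittering the ML fit projected into the admissible region.
    Warmup uses Haario-style covariance adaptation with an acceptance-rate
    controlled global scale; the proposal is frozen afterwards. Split-R̂ and
    bulk ESS are computed per coefficient; R̂ > 1.05 attaches a warning
    rather than failing, so short exploratory runs remain inspectable.
    """
    if priors is None:
        priors = PriorSpec()
    if n_iter < 1 or n_warmup < 1 or n_chains < 2:
        raise ValueError("need n_iter >= 1, n_warmup >= 1, n_chains >= 2")
    validate_observations(obs)

    x_mean_full, x_prec, y = _design(obs)
    keep = _identifiable_columns(obs)
    names = tuple([MEAN_COEF[i] for i in keep] + list(PREC_COEF))
    x_mean = x_mean_full[:, keep]
    ndim = len(names)

    def log_post(theta: np.ndarray) -> float:
        if not _admissible_vec(theta, names):
            return -np.inf
        eta = x_mean @ theta[: len(keep)]
        mu = expit(eta)
        phi = np.exp(x_prec @ theta[len(keep):])
        a = mu * phi
        b = (1.0 - mu) * phi
        if np.any(a <= 0) or np.any(b <= 0) or not np.all(np.isfinite(a + b)):
            return -np.inf
        ll = (
            gammaln(phi) - gammaln(a) - gammaln(b)
            + (a - 1.0) * np.log(y) + (b - 1.0) * np.log1p(-y)
        )
        return float(ll.sum()) + priors.log_prior(theta, keep)

    # initialize at the (projected) ML solution; seed the proposal with the
    # ML parameter covariance so chains mix despite coefficient correlations
    ml_cov = None
    try:
        ml, report = fit_ml(obs)
        center_full = ml.as_array()
        scale_full = np.array(
            [report.std_errors.get(k, 0.1) for k in ALL_COEF], dtype=float
        )
        if report.cov is not None and report.cov.shape == (ndim, ndim):
            ml_cov = report.cov
    except Exception:  # ML failure should not block the Bayesian fit
        center_full = _start_values(obs)
        scale_full = np.full(8, 0.1)
    sel = keep + [6, 7]
    center = _project_admissible(
        np.nan_to_num(center_full[sel], nan=0.0), names
    )
    scale = np.clip(np.nan_to_num(scale_full[sel], nan=0.1), 1e-3, 1.0)

    seeds = np.random.SeedSequence(seed).spawn(n_chains)
    chains = np.empty((n_chains, n_iter, ndim))
    accepts = 0
    total = 0

    for ci in range(n_chains):
        rng = np.random.default_rng(seeds[ci])
        cur = center + 0.1 * scale * rng.standard_normal(ndim)
        cur = _project_admissible(cur, names)
        for _ in range(100):
            if np.isfinite(log_post(cur)):
                break
            cur = _project_admissible(
                center + 0.1 * scale * rng.standard_normal(ndim), names
            )
        lp_cur = log_post(cur)
        if not np.isfinite(lp_cur):
            raise RuntimeError("could not find an admissible starting point")

        if ml_cov is not None:
            cov = (2.38**2 / ndim) * ml_cov + 1e-10 * np.eye(ndim)
        else:
            cov = np.diag(scale**2)
        log_scale = 0.0
        hist = np.empty((n_warmup, ndim))
        try:
            chol = np.linalg.cholesky(cov)
        except np.linalg.LinAlgError:
            chol = np.diag(np.sqrt(np.clip(np.diag(cov), 1e-8, None)))
        acc_window = 0
        for t in range(n_warmup + n_iter):
            step = np.exp(log_scale) * (chol @ rng.standard_normal(ndim))
            prop = cur + step
            lp_prop = log_post(prop)
            if np.log(rng.random()) < lp_prop - lp_cur:
                cur, lp_cur = prop, lp_prop
                acc_window += 1
                if t >= n_warmup:
                    accepts += 1
            if t >= n_warmup:
                total += 1
                chains[ci, t - n_warmup] = cur
            else:
                hist[t] = cur
                # adapt every 50 warmup iterations
                if (t + 1) % 50 == 0:
                    rate = acc_window / 50.0
                    log_scale += 0.5 * (rate - 0.3)
                    acc_window = 0
                    if t + 1 >= 200:
                        emp = np.cov(hist[: t + 1].T) + 1e-8 * np.eye(ndim)
                        chol = np.linalg.cholesky(
                            (2.38**2 / ndim) * emp
                        )

    # all stored draws are admissible by construction of log_post
    assert all(
        _admissible_vec(row, names) for row in chains.reshape(-1, ndim)[:: max(1, n_iter // 10)]
    )

    import arviz as az

    idata = az.from_dict({n: chains[..., j] for j, n in enumerate(names)})
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rhat_ds = az.rhat(idata)
        ess_ds = az.ess(idata)
    rhat = {n: float(rhat_ds[n].values) for n in names}
    ess = {n: float(ess_ds[n].values) for n in names}

    warn_list = []
    bad = {n: v for n, v in rhat.items() if v > 1.05}
    if bad:
        warn_list.append(f"split-Rhat above 1.05 for {sorted(bad)}: {bad}")
        warnings.warn(warn_list[-1], stacklevel=2)

    return PosteriorDraws(
        draws=chains,
        names=names,
        groups=tuple(sorted(obs["group"].unique())),
        n_chains=n_chains,
        n_warmup=n_warmup,
        seed=seed,
        rhat=rhat,
        ess=ess,
        accept_rate=accepts / max(total, 1),
        warnings_=warn_list,
    )
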