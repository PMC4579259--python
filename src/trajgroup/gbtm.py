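"""Finite-mixture trajectory likelihood and its maximization.

The model: each subject i belongs to one of k latent groups.  Group j has a
polynomial trajectory over the swallow-trial index t,

    eta_j(t) = beta_j0 + beta_j1 t + beta_j2 t^2 + beta_j3 t^3,

linked to the observed score by either a Bernoulli-logit (dichotomized
three-point outcomes; P(impaired) = expit(eta)) or a censored normal
(piecemeal deglutition on 0-4; latent N(eta, sigma) with point masses at the
scale bounds).  Group membership follows a multinomial logit on subject
covariates (typically etiology), with the first group as reference.  Trials
within a subject are conditionally independent given the group, so the
marginal likelihood of subject i is

    P(Y_i) = sum_j pi_j(x_i) * prod_{t observed} P(y_it | group j),

and the total log-likelihood is maximized directly by quasi-Newton with an
analytic gradient (no EM), which makes standard errors a single
observed-information evaluation at the optimum.

Numerical notes: polynomials are evaluated internally on a centered/scaled
time axis u = (t - mid)/half in [-1, 1] for conditioning, and coefficients
are converted back to the raw trial-index scale for reporting; sigma is
optimized as log(sigma); the mixture sum uses log-sum-exp throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from numpy.polynomial import Polynomial
from scipy.optimize import minimize
from scipy.special import expit, logsumexp
from scipy.stats import norm
from statsmodels.tools.numdiff import approx_hess

from trajgroup.data_model import ETIOLOGIES, REFERENCE_ETIOLOGY

MAX_POLY_ORDER = 3
MAX_GROUPS = 5


# ---------------------------------------------------------------------------
# specs and containers


@dataclass(frozen=True)
class TrajectoryModelSpec:
    """Configuration of one candidate trajectory model.

    Parameters
    ----------
    k
        Number of latent groups (1..5).
    poly_orders
        Per-group polynomial order, 0 (intercept-only) to 3 (cubic); an int
        broadcasts to all groups.
    link
        ``"logit"`` or ``"cnorm"`` (censored normal).
    bounds
        (scale_min, scale_max) censoring bounds; censored-normal only.
    membership_covariates
        Categorical covariate names entering the membership logit; only
        ``"etiology"`` is supported.  Empty tuple = intercepts only.
    reference_etiology
        Reference level for etiology dummies.
    n_starts
        Number of perturbed initializations for the multi-start search.
    seed
        RNG seed for start perturbations (deterministic fits).
    bic_n
        ``"subjects"`` (default) or ``"observations"``: the n in the BIC
        penalty p*log(n).
    """

    k: int
    poly_orders: tuple[int, ...] | int = MAX_POLY_ORDER
    link: str = "logit"
    bounds: tuple[float, float] = (0.0, 1.0)
    membership_covariates: tuple[str, ...] = ()
    reference_etiology: str = REFERENCE_ETIOLOGY
    n_starts: int = 3
    seed: int = 0
    max_iter: int = 1000
    gtol: float = 1e-6
    ftol: float = 1e-11
    bic_n: str = "subjects"

    def __post_init__(self):
        if not 1 <= self.k <= MAX_GROUPS:
            raise ValueError(f"k must be in 1..{MAX_GROUPS}, got {self.k}")
        orders = self.poly_orders
        if isinstance(orders, int):
            orders = (orders,) * self.k
        orders = tuple(int(o) for o in orders)
        if len(orders) != self.k:
            raise ValueError("poly_orders length must equal k")
        if any(o < 0 or o > MAX_POLY_ORDER for o in orders):
            raise ValueError(f"polynomial orders must be 0..{MAX_POLY_ORDER}")
        object.__setattr__(self, "poly_orders", orders)
        if self.link not in ("logit", "cnorm"):
            raise ValueError(f"unknown link '{self.link}'")
        if self.bounds[0] >= self.bounds[1]:
            raise ValueError("bounds must satisfy min < max")
        for cov in self.membership_covariates:
            if cov != "etiology":
                raise ValueError(f"unsupported membership covariate '{cov}'")


@dataclass
class FittedModel:
    """Maximum-likelihood fit of a :class:`TrajectoryModelSpec`.

    Groups are numbered in ascending impairment (mean fitted linear
    predictor over the observed trials), matching the convention
    "1 = low impairment ... k = high impairment".  The first group is the
    membership-logit reference, so ``theta[0] == 0``.

    Attributes
    ----------
    beta
        Per-group trajectory coefficients on the raw trial-index scale
        (length order_j + 1 each).
    beta_internal
        Same coefficients on the internal centered/scaled time axis; the
        parametrization in which ``vcov`` lives.
    sigma
        Shared residual SD (censored-normal link; None for logit).
    theta
        (k, m) membership-logit coefficients; row 0 identically zero.
    vcov
        Observed-information covariance of the packed internal parameter
        vector (see ``param_names``); None if the information matrix was
        singular.
    """

    spec: TrajectoryModelSpec
    beta: list[np.ndarray]
    beta_internal: list[np.ndarray]
    sigma: float | None
    theta: np.ndarray
    covariate_names: list[str]
    loglik: float
    n_params: int
    bic: float
    bic_nobs: float
    n_subjects: int
    n_obs: int
    vcov: np.ndarray | None
    param_names: list[str]
    converged: bool
    time_center: float
    time_half: float
    start_log: list[dict] = field(default_factory=list)

    # -- parameter bookkeeping ------------------------------------------------
    def param_slices(self) -> dict[str, slice]:
        """Slices of the packed internal parameter vector per block."""
        sl: dict[str, slice] = {}
        pos = 0
        for j, o in enumerate(self.spec.poly_orders):
            sl[f"beta[{j}]"] = slice(pos, pos + o + 1)
            pos += o + 1
        if self.spec.link == "cnorm":
            sl["log_sigma"] = slice(pos, pos + 1)
            pos += 1
        m = len(self.covariate_names)
        for j in range(1, self.spec.k):
            sl[f"theta[{j}]"] = slice(pos, pos + m)
            pos += m
        return sl

    def packed_params(self) -> np.ndarray:
        parts = [b for b in self.beta_internal]
        if self.spec.link == "cnorm":
            parts.append(np.array([np.log(self.sigma)]))
        for j in range(1, self.spec.k):
            parts.append(self.theta[j])
        return np.concatenate(parts) if parts else np.array([])

    def group_curve(self, group: int, trials: Sequence[int]) -> np.ndarray:
        """Fitted curve for one group over raw trial indices.

        Logit link: probability of the impaired category.  Censored normal:
        expected observed score (censoring-adjusted mean), which always lies
        within the scale bounds.
        """
        eta = trajectory_mean(self.beta[group], np.asarray(trials, dtype=float))
        if self.spec.link == "logit":
            return expit(eta)
        return censored_mean(eta, self.sigma, self.spec.bounds)

    def summary_table(self) -> pd.DataFrame:
        rows = []
        for j, b in enumerate(self.beta):
            for p, coef in enumerate(b):
                rows.append({"group": j + 1, "term": f"t^{p}", "estimate": coef})
        if self.sigma is not None:
            rows.append({"group": 0, "term": "sigma", "estimate": self.sigma})
        for j in range(1, self.spec.k):
            for name, coef in zip(self.covariate_names, self.theta[j]):
                rows.append({"group": j + 1, "term": f"membership:{name}", "estimate": coef})
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class GbtmParams:
    """A fixed parameter set on the raw time scale, for direct likelihood evaluation."""

    beta: tuple[np.ndarray, ...]
    theta: np.ndarray  # (k, m); row 0 zero
    sigma: float | None = None

    def __post_init__(self):
        object.__setattr__(self, "beta", tuple(np.asarray(b, float) for b in self.beta))
        object.__setattr__(self, "theta", np.atleast_2d(np.asarray(self.theta, float)))
        if np.any(self.theta[0] != 0.0):
            raise ValueError("reference group theta must be identically zero")


# ---------------------------------------------------------------------------
# elementary likelihood pieces (raw scale; used directly by tests and oracles)


def trajectory_mean(beta_j: np.ndarray, trial) -> np.ndarray | float:
    """Polynomial linear predictor beta_0 + beta_1 t + beta_2 t^2 + beta_3 t^3."""
    beta_j = np.asarray(beta_j, dtype=float)
    if beta_j.size > MAX_POLY_ORDER + 1:
        raise ValueError("coefficient vector longer than cubic")
    t = np.asarray(trial, dtype=float)
    out = np.polynomial.polynomial.polyval(t, beta_j)
    return float(out) if np.isscalar(trial) else out


def censored_normal_loglik(score, mu, sigma, bounds) -> np.ndarray | float:
    """Log-likelihood of a censored-normal observation.

    Interior scores contribute the N(mu, sigma) log-density; scores at the
    scale minimum contribute log Phi((min - mu)/sigma); scores at the
    maximum contribute log(1 - Phi((max - mu)/sigma)).
    """
    lo, hi = bounds
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    score = np.asarray(score, dtype=float)
    if np.any(score < lo) or np.any(score > hi):
        raise ValueError(f"score outside censoring bounds [{lo}, {hi}]")
    mu = np.broadcast_to(np.asarray(mu, dtype=float), score.shape)
    out = norm.logpdf(score, mu, sigma)
    at_lo = score == lo
    at_hi = score == hi
    out = np.where(at_lo, norm.logcdf((lo - mu) / sigma), out)
    out = np.where(at_hi, norm.logsf((hi - mu) / sigma), out)
    return float(out) if out.ndim == 0 else out


def bernoulli_logit_loglik(score, eta) -> np.ndarray:
    """Stable log P(y | expit(eta)) for y in {0, 1}."""
    score = np.asarray(score, dtype=float)
    eta = np.broadcast_to(np.asarray(eta, dtype=float), score.shape)
    sign = 2.0 * score - 1.0
    return -np.logaddexp(0.0, -sign * eta)


def subject_group_loglik(
    trials, scores, beta_j, link: str, sigma: float | None = None, bounds=(0.0, 1.0)
) -> float:
    """Log-probability of one subject's observed trials under one group.

    Missing trials are simply absent and contribute nothing (missing at
    random given the group).
    """
    trials = np.asarray(trials, dtype=float)
    scores = np.asarray(scores, dtype=float)
    if trials.size == 0:
        raise ValueError("subject has no observed trials")
    eta = trajectory_mean(beta_j, trials)
    if link == "logit":
        return float(np.sum(bernoulli_logit_loglik(scores, eta)))
    return float(np.sum(censored_normal_loglik(scores, eta, sigma, bounds)))


def membership_probs(theta: np.ndarray, x: np.ndarray | None = None) -> np.ndarray:
    """Multinomial-logit group probabilities pi_j(x) = softmax_j(theta_j' x).

    ``theta`` is (k, m) with the reference row identically zero; ``x`` is a
    covariate vector of length m (defaults to intercept-only [1]).
    """
    theta = np.atleast_2d(np.asarray(theta, dtype=float))
    if np.any(theta[0] != 0.0):
        raise ValueError("reference group theta must be identically zero")
    if x is None:
        x = np.ones(theta.shape[1])
    x = np.asarray(x, dtype=float)
    if x.shape[-1] != theta.shape[1]:
        raise ValueError("covariate dimension mismatch")
    logits = x @ theta.T
    logits = logits - logsumexp(logits, axis=-1, keepdims=True)
    return np.exp(logits)


def censored_mean(mu, sigma, bounds) -> np.ndarray:
    """E[Y] when Y = clamp(N(mu, sigma), lo, hi)."""
    lo, hi = bounds
    mu = np.asarray(mu, dtype=float)
    a = (lo - mu) / sigma
    b = (hi - mu) / sigma
    return (
        lo * norm.cdf(a)
        + hi * norm.sf(b)
        + mu * (norm.cdf(b) - norm.cdf(a))
        - sigma * (norm.pdf(b) - norm.pdf(a))
    )


# ---------------------------------------------------------------------------
# panel -> arrays


class PanelArrays:
    """Flat array view of a single-variable long panel.

    Rows are sorted by subject; ``sidx`` maps each observation to its
    subject index.  ``W`` is the membership design matrix (intercept plus
    etiology dummies when requested).
    """

    def __init__(self, panel: pd.DataFrame, spec: TrajectoryModelSpec):
        variables = panel["variable"].unique()
        if len(variables) != 1:
            raise ValueError(f"fit expects a single-variable panel, got {sorted(variables)}")
        if spec.link == "logit":
            vals = set(np.unique(panel["score"].to_numpy(dtype=float)))
            if not vals <= {0.0, 1.0}:
                raise ValueError(
                    "logit link requires dichotomized 0/1 scores; run dichotomize() first"
                )
        counts = panel.groupby("patient_id", sort=True)["trial"].count()
        if (counts < 1).any():
            raise ValueError("every subject must have at least one observed trial")
        panel = panel.sort_values(["patient_id", "trial"], kind="mergesort")
        self.subject_ids = counts.index.to_numpy()
        self.n_subjects = len(self.subject_ids)
        code = pd.Categorical(panel["patient_id"], categories=self.subject_ids)
        self.sidx = code.codes.astype(np.int64)
        self.y = panel["score"].to_numpy(dtype=float)
        self.t = panel["trial"].to_numpy(dtype=float)
        self.n_obs = len(self.y)

        tmin, tmax = self.t.min(), self.t.max()
        self.time_center = (tmin + tmax) / 2.0
        self.time_half = max((tmax - tmin) / 2.0, 1.0)
        u = (self.t - self.time_center) / self.time_half
        self.X = np.vander(u, MAX_POLY_ORDER + 1, increasing=True)

        # membership design (one row per subject)
        first = panel.drop_duplicates("patient_id").set_index("patient_id").loc[self.subject_ids]
        cols = [np.ones(self.n_subjects)]
        names = ["(intercept)"]
        if "etiology" in spec.membership_covariates:
            et = first["etiology"].to_numpy()
            present = [e for e in ETIOLOGIES if e in set(et)]
            if spec.reference_etiology not in present:
                raise ValueError(
                    f"reference etiology '{spec.reference_etiology}' absent from panel"
                )
            for e in present:
                if e == spec.reference_etiology:
                    continue
                cols.append((et == e).astype(float))
                names.append(f"etiology[{e}]")
            self.etiology = et
        else:
            self.etiology = first["etiology"].to_numpy() if "etiology" in first else None
        self.W = np.column_stack(cols)
        self.covariate_names = names
        self.trials_grid = np.unique(self.t)


# ---------------------------------------------------------------------------
# packed-parameter objective with analytic gradient


class _Objective:
    def __init__(self, arrays: PanelArrays, spec: TrajectoryModelSpec):
        self.a = arrays
        self.spec = spec
        self.k = spec.k
        self.orders = spec.poly_orders
        self.m = arrays.W.shape[1]
        self.has_sigma = spec.link == "cnorm"
        self.n_beta = sum(o + 1 for o in self.orders)
        self.n_theta = (self.k - 1) * self.m
        self.n_params = self.n_beta + int(self.has_sigma) + self.n_theta
        lo, hi = spec.bounds
        if self.has_sigma:
            self.at_lo = arrays.y == lo
            self.at_hi = arrays.y == hi
            self.interior = ~(self.at_lo | self.at_hi)

    def unpack(self, params: np.ndarray):
        betas, pos = [], 0
        for o in self.orders:
            betas.append(params[pos : pos + o + 1])
            pos += o + 1
        log_sigma = None
        if self.has_sigma:
            log_sigma = params[pos]
            pos += 1
        theta = np.zeros((self.k, self.m))
        for j in range(1, self.k):
            theta[j] = params[pos : pos + self.m]
            pos += self.m
        return betas, log_sigma, theta

    def _per_obs(self, betas, log_sigma):
        """Per-observation loglik and d/d(eta), d/d(log sigma) for each group."""
        a = self.a
        n, k = a.n_obs, self.k
        ll = np.empty((n, k))
        dl_deta = np.empty((n, k))
        dl_dls = np.empty((n, k)) if self.has_sigma else None
        lo, hi = self.spec.bounds
        for j, b in enumerate(betas):
            eta = a.X[:, : b.size] @ b
            if self.spec.link == "logit":
                ll[:, j] = bernoulli_logit_loglik(a.y, eta)
                dl_deta[:, j] = a.y - expit(eta)
            else:
                sigma = np.exp(log_sigma)
                z_lo = (lo - eta) / sigma
                z_hi = (eta - hi) / sigma
                resid = (a.y - eta) / sigma
                llj = norm.logpdf(a.y, eta, sigma)
                deta = resid / sigma
                dls = resid**2 - 1.0
                # lower censoring: log Phi(z_lo)
                r_lo = np.exp(norm.logpdf(z_lo) - norm.logcdf(z_lo))
                llj = np.where(self.at_lo, norm.logcdf(z_lo), llj)
                deta = np.where(self.at_lo, -r_lo / sigma, deta)
                dls = np.where(self.at_lo, -z_lo * r_lo, dls)
                # upper censoring: log Phi(z_hi)
                r_hi = np.exp(norm.logpdf(z_hi) - norm.logcdf(z_hi))
                llj = np.where(self.at_hi, norm.logcdf(z_hi), llj)
                deta = np.where(self.at_hi, r_hi / sigma, deta)
                dls = np.where(self.at_hi, -z_hi * r_hi, dls)
                ll[:, j] = llj
                dl_deta[:, j] = deta
                dl_dls[:, j] = dls
        return ll, dl_deta, dl_dls

    def loglik_parts(self, params: np.ndarray):
        betas, log_sigma, theta = self.unpack(params)
        a = self.a
        ll_obs, dl_deta, dl_dls = self._per_obs(betas, log_sigma)
        # subject x group conditional loglik
        L = np.zeros((a.n_subjects, self.k))
        for j in range(self.k):
            L[:, j] = np.bincount(a.sidx, weights=ll_obs[:, j], minlength=a.n_subjects)
        logits = a.W @ theta.T
        log_pi = logits - logsumexp(logits, axis=1, keepdims=True)
        A = log_pi + L
        li = logsumexp(A, axis=1)
        post = np.exp(A - li[:, None])
        return li.sum(), post, np.exp(log_pi), dl_deta, dl_dls

    def value_and_grad(self, params: np.ndarray):
        total, post, pi, dl_deta, dl_dls = self.loglik_parts(params)
        a = self.a
        grad = np.empty(self.n_params)
        pos = 0
        w_obs = post[a.sidx]  # (n_obs, k)
        for j, o in enumerate(self.orders):
            wd = w_obs[:, j] * dl_deta[:, j]
            grad[pos : pos + o + 1] = a.X[:, : o + 1].T @ wd
            pos += o + 1
        if self.has_sigma:
            grad[pos] = float(np.sum(w_obs * dl_dls))
            pos += 1
        if self.k > 1:
            gtheta = a.W.T @ (post - pi)  # (m, k)
            for j in range(1, self.k):
                grad[pos : pos + self.m] = gtheta[:, j]
                pos += self.m
        return total, grad

    def neg(self, params: np.ndarray):
        with np.errstate(over="ignore", invalid="ignore"):
            v, g = self.value_and_grad(params)
        if not np.isfinite(v):
            return 1e12, np.zeros_like(params)
        return -v, -g

    def neg_value(self, params: np.ndarray) -> float:
        with np.errstate(over="ignore", invalid="ignore"):
            v = self.loglik_parts(params)[0]
        return -v if np.isfinite(v) else 1e12


# ---------------------------------------------------------------------------
# public likelihood on fixed raw-scale parameters (oracle-facing)


def mixture_loglik(panel: pd.DataFrame, params: GbtmParams, spec: TrajectoryModelSpec) -> float:
    """Total mixture log-likelihood sum_i log sum_j pi_j(x_i) P(Y_i | j).

    ``params.beta`` are on the raw trial-index scale.  Computed with
    log-sum-exp stabilization; usable with arbitrary fixed parameters (no
    fitting), e.g. for brute-force cross-checks.
    """
    li = _subject_log_mixture(panel, params, spec)[0]
    return float(li.sum())


def _subject_log_mixture(panel: pd.DataFrame, params: GbtmParams, spec: TrajectoryModelSpec):
    """Per-subject log mixture likelihood and the (subject x group) joint log terms."""
    if len(params.beta) != spec.k:
        raise ValueError("params.beta length must equal spec.k")
    arrays = PanelArrays(panel, spec)
    n, k = arrays.n_subjects, spec.k
    L = np.zeros((n, k))
    for j, b in enumerate(params.beta):
        eta = np.polynomial.polynomial.polyval(arrays.t, np.asarray(b, float))
        if spec.link == "logit":
            ll = bernoulli_logit_loglik(arrays.y, eta)
        else:
            ll = censored_normal_loglik(arrays.y, eta, params.sigma, spec.bounds)
        L[:, j] = np.bincount(arrays.sidx, weights=ll, minlength=n)
    if params.theta.shape != (k, arrays.W.shape[1]):
        raise ValueError(
            f"theta must be (k, m) = ({k}, {arrays.W.shape[1]}), got {params.theta.shape}"
        )
    logits = arrays.W @ params.theta.T
    log_pi = logits - logsumexp(logits, axis=1, keepdims=True)
    A = log_pi + L
    return logsumexp(A, axis=1), A, arrays


# ---------------------------------------------------------------------------
# initialization, fitting, canonicalization


def _initial_params(obj: _Objective) -> np.ndarray:
    """Data-driven start: subjects pre-clustered by mean response into k bins,
    per-bin polynomial fits on the working scale, membership from bin shares."""
    a, spec = obj.a, obj.spec
    k = spec.k
    means = np.bincount(a.sidx, weights=a.y) / np.bincount(a.sidx)
    order = np.argsort(means, kind="mergesort")
    bins = np.array_split(order, k)
    lo, hi = spec.bounds
    parts = []
    resid_var = []
    for j, members in enumerate(bins):
        o = spec.poly_orders[j]
        mask = np.isin(a.sidx, members)
        u = (a.t[mask] - a.time_center) / a.time_half
        y = a.y[mask]
        if spec.link == "logit":
            # empirical logit of the per-trial impairment frequency
            df = pd.DataFrame({"u": u, "y": y}).groupby("u")["y"].mean()
            p = np.clip(df.to_numpy(), 0.05, 0.95)
            work = np.log(p / (1 - p))
            uu = df.index.to_numpy()
        else:
            work, uu = y, u
        deg = min(int(o), max(len(np.unique(uu)) - 1, 0))
        coef = np.zeros(o + 1)
        if deg == 0:
            coef[0] = float(np.mean(work))
        else:
            fitted = np.polynomial.polynomial.polyfit(uu, work, deg)
            coef[: deg + 1] = fitted
        parts.append(coef)
        if spec.link == "cnorm":
            pred = np.polynomial.polynomial.polyval(u, coef)
            resid_var.append(np.mean((y - pred) ** 2))
    params = list(np.concatenate(parts))
    if obj.has_sigma:
        params.append(0.5 * np.log(max(float(np.mean(resid_var)), 1e-2)))
    shares = np.maximum(np.array([len(b) for b in bins], dtype=float), 1.0)
    shares /= shares.sum()
    for j in range(1, k):
        theta_j = np.zeros(obj.m)
        theta_j[0] = np.log(shares[j] / shares[0])
        params.extend(theta_j)
    return np.asarray(params)


def _raw_coeffs(beta_internal: np.ndarray, center: float, half: float) -> np.ndarray:
    """Convert coefficients on u = (t - center)/half back to the raw t scale."""
    sub = Polynomial([-center / half, 1.0 / half])
    raw = Polynomial(np.asarray(beta_internal, float))(sub).coef
    out = np.zeros(len(beta_internal))
    out[: len(raw)] = raw
    return out


def fit(panel: pd.DataFrame, spec: TrajectoryModelSpec) -> FittedModel:
    """Maximum-likelihood fit of the group-based trajectory model.

    Multi-start quasi-Newton (L-BFGS-B with analytic gradient) from a
    data-driven initialization perturbed by a seeded RNG; the best local
    optimum wins, with ties broken toward the lowest start index.  The
    variance-covariance matrix comes from the numerically differentiated
    observed information at the optimum.  Groups in the returned model are
    relabeled in ascending impairment and the membership logit is
    re-referenced to the new first group.

    The panel must be restricted to a single outcome variable and, for the
    logit link, already dichotomized to 0/1.
    """
    arrays = PanelArrays(panel, spec)
    obj = _Objective(arrays, spec)
    rng = np.random.default_rng(spec.seed)
    base = _initial_params(obj)

    best = None
    start_log = []
    for s in range(max(spec.n_starts, 1)):
        x0 = base.copy()
        if s > 0:
            x0 = x0 + rng.normal(scale=0.5, size=x0.size)
        res = minimize(
            obj.neg,
            x0,
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": spec.max_iter, "gtol": spec.gtol, "ftol": spec.ftol},
        )
        ll = -res.fun
        start_log.append({"start": s, "loglik": float(ll), "converged": bool(res.success)})
        if best is None or ll > best[0] + 1e-9:
            best = (ll, res, s)
    ll_hat, res, _ = best
    if not res.success:
        warnings.warn("no start converged cleanly; returning the best local optimum found")

    params = res.x
    betas, log_sigma, theta = obj.unpack(params)

    # canonical ordering: ascending mean linear predictor over the trial grid
    u_grid = (arrays.trials_grid - arrays.time_center) / arrays.time_half
    mean_eta = np.array(
        [np.mean(np.polynomial.polynomial.polyval(u_grid, b)) for b in betas]
    )
    perm = np.argsort(mean_eta, kind="mergesort")
    betas = [betas[j] for j in perm]
    theta = theta[perm] - theta[perm[0]]
    canon_spec = replace(spec, poly_orders=tuple(spec.poly_orders[j] for j in perm))
    canon_obj = _Objective(arrays, canon_spec)
    packed = list(betas)
    if obj.has_sigma:
        packed.append(np.array([log_sigma]))
    packed.extend(theta[1:])
    packed = np.concatenate(packed) if packed else np.array([])

    vcov = None
    if packed.size:
        try:
            H = approx_hess(packed, canon_obj.neg_value)
            vcov = np.linalg.inv(H)
            if not np.all(np.isfinite(vcov)) or np.any(np.diag(vcov) <= 0):
                vcov = None
        except np.linalg.LinAlgError:
            vcov = None

    n_params = canon_obj.n_params
    bic = -2.0 * ll_hat + n_params * np.log(arrays.n_subjects)
    bic_nobs = -2.0 * ll_hat + n_params * np.log(arrays.n_obs)
    sigma = float(np.exp(log_sigma)) if obj.has_sigma else None
    beta_raw = [_raw_coeffs(b, arrays.time_center, arrays.time_half) for b in betas]

    grad_norm = float(np.max(np.abs(res.jac))) if res.jac is not None else np.inf
    return FittedModel(
        spec=canon_spec,
        beta=beta_raw,
        beta_internal=[np.asarray(b) for b in betas],
        sigma=sigma,
        theta=theta,
        covariate_names=arrays.covariate_names,
        loglik=float(ll_hat),
        n_params=n_params,
        bic=float(bic if spec.bic_n == "subjects" else bic_nobs),
        bic_nobs=float(bic_nobs),
        n_subjects=arrays.n_subjects,
        n_obs=arrays.n_obs,
        vcov=vcov,
        param_names=_param_names(canon_spec, arrays.covariate_names),
        converged=bool(res.success or grad_norm < 1e-3),
        time_center=arrays.time_center,
        time_half=arrays.time_half,
        start_log=start_log,
    )


def _param_names(spec: TrajectoryModelSpec, covariate_names: list[str]) -> list[str]:
    names = []
    for j, o in enumerate(spec.poly_orders):
        names.extend(f"beta[{j + 1}]:u^{p}" for p in range(o + 1))
    if spec.link == "cnorm":
        names.append("log_sigma")
    for j in range(1, spec.k):
        names.extend(f"theta[{j + 1}]:{c}" for c in covariate_names)
    return names
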