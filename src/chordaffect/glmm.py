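"""Mixed-effects logistic regression of trial accuracy on stimulus type
and a standardised neural predictor, with crossed random effects.

Fixed effects: stimulus type (consonant reference), the predictor, and
type x predictor interactions.  Random effects: per-subject intercept,
uncorrelated per-subject slopes for the two type dummies, and a
per-item intercept.  Estimation maximises the Laplace approximation of
the marginal likelihood; the random-effect mode is found by an inner
Newton iteration that exploits the sparse crossed structure of Z'WZ.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve
from scipy.special import expit

__all__ = [
    "GLMMSpec",
    "GLMMFit",
    "fit_mixed_logit",
    "likelihood_ratio_test",
    "odds_ratio_table",
]

FIXED_NAMES = (
    "(Intercept)",
    "dissonant",
    "neutral",
    "x",
    "dissonant:x",
    "neutral:x",
)


@dataclass(frozen=True)
class GLMMSpec:
    """Model structure for :func:`fit_mixed_logit`."""

    predictor: str = "neural"
    reference_level: str = "consonant"
    standardize_predictor: bool = True
    include_predictor: bool = True
    include_interactions: bool = True
    subject_intercept: bool = True
    subject_slopes: bool = True
    item_intercept: bool = True

    def fixed_terms(self) -> tuple[str, ...]:
        terms = ["(Intercept)", "dissonant", "neutral"]
        if self.include_predictor:
            terms.append("x")
        if self.include_predictor and self.include_interactions:
            terms += ["dissonant:x", "neutral:x"]
        return tuple(terms)

    def variance_blocks(self) -> tuple[str, ...]:
        blocks = []
        if self.subject_intercept:
            blocks.append("subject")
        if self.subject_slopes:
            blocks += ["subject_dissonant", "subject_neutral"]
        if self.item_intercept:
            blocks.append("item")
        return tuple(blocks)


@dataclass
class GLMMFit:
    names: tuple[str, ...]
    beta: np.ndarray
    se: np.ndarray
    loglik: float
    variance_components: dict
    converged: bool
    n_obs: int
    n_params: int
    spec: GLMMSpec
    predictor_mean: float = 0.0
    predictor_sd: float = 1.0
    message: str = ""
    separation_suspected: bool = False

    @property
    def z(self) -> np.ndarray:
        return self.beta / self.se

    @property
    def p_values(self) -> np.ndarray:
        return 2.0 * stats.norm.sf(np.abs(self.z))

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "beta": self.beta,
                "se": self.se,
                "z": self.z,
                "p": self.p_values,
            },
            index=list(self.names),
        )


class _Design:
    """Dense fixed design plus index-coded crossed random structure."""

    def __init__(self, trials: pd.DataFrame, spec: GLMMSpec, neural=None):
        if spec.reference_level != "consonant":
            raise ValueError("only the consonant reference level is supported")
        self.y = trials["accuracy"].to_numpy(dtype=float)
        if len(np.unique(self.y)) < 2:
            raise ValueError("outcome is degenerate: all trials share one accuracy value")
        stype = trials["stimulus_type"].to_numpy()
        unknown = set(stype) - {"consonant", "dissonant", "neutral"}
        if unknown:
            raise ValueError(f"unknown stimulus types {sorted(unknown)}")
        self.diss = (stype == "dissonant").astype(float)
        self.neut = (stype == "neutral").astype(float)

        if neural is None:
            x = trials[spec.predictor].to_numpy(dtype=float)
        elif isinstance(neural, dict):
            x = trials["subject"].map(neural).to_numpy(dtype=float)
        else:
            x = np.asarray(neural, dtype=float)
        self.x_mean, self.x_sd = 0.0, 1.0
        if spec.standardize_predictor:
            self.x_mean = float(x.mean())
            sd = float(x.std())
            self.x_sd = sd if sd > 0 else 1.0
            x = (x - self.x_mean) / self.x_sd
        self.x = x

        cols = {"(Intercept)": np.ones(len(self.y)), "dissonant": self.diss,
                "neutral": self.neut, "x": x, "dissonant:x": self.diss * x,
                "neutral:x": self.neut * x}
        self.fixed_names = spec.fixed_terms()
        self.X = np.column_stack([cols[t] for t in self.fixed_names])

        subjects = sorted(trials["subject"].unique())
        items = sorted(trials["item"].unique())
        if len(subjects) < 2 or len(items) < 2:
            raise ValueError("need at least 2 subjects and 2 items")
        self.subj = trials["subject"].map({s: i for i, s in enumerate(subjects)}).to_numpy()
        self.item = trials["item"].map({s: i for i, s in enumerate(items)}).to_numpy()
        self.n_subj, self.n_item = len(subjects), len(items)

        # random-effect layout: concatenated blocks, each a vector of
        # per-group coefficients; loadings are 0/1 indicators
        self.blocks = spec.variance_blocks()
        self.block_sizes = []
        self.block_group = []   # group index per observation, per block
        self.block_load = []    # observation loading per block
        for b in self.blocks:
            if b == "subject":
                self.block_sizes.append(self.n_subj)
                self.block_group.append(self.subj)
                self.block_load.append(np.ones(len(self.y)))
            elif b == "subject_dissonant":
                self.block_sizes.append(self.n_subj)
                self.block_group.append(self.subj)
                self.block_load.append(self.diss)
            elif b == "subject_neutral":
                self.block_sizes.append(self.n_subj)
                self.block_group.append(self.subj)
                self.block_load.append(self.neut)
            else:  # item
                self.block_sizes.append(self.n_item)
                self.block_group.append(self.item)
                self.block_load.append(np.ones(len(self.y)))
        self.q = int(sum(self.block_sizes))
        self.offsets = np.concatenate([[0], np.cumsum(self.block_sizes)])[:-1]

    def eta_random(self, u: np.ndarray) -> np.ndarray:
        eta = np.zeros(len(self.y))
        for k in range(len(self.blocks)):
            o = self.offsets[k]
            eta += self.block_load[k] * u[o + self.block_group[k]]
        return eta

    def zt_dot(self, v: np.ndarray) -> np.ndarray:
        """Z' v accumulated per block."""
        out = np.empty(self.q)
        for k, size in enumerate(self.block_sizes):
            o = self.offsets[k]
            out[o : o + size] = np.bincount(
                self.block_group[k], weights=self.block_load[k] * v, minlength=size
            )
        return out

    def ztwz(self, w: np.ndarray) -> np.ndarray:
        """Dense Z' diag(w) Z using per-block and pairwise aggregation."""
        h = np.zeros((self.q, self.q))
        nb = len(self.blocks)
        for a in range(nb):
            oa, ga, la, sa = (
                self.offsets[a], self.block_group[a], self.block_load[a],
                self.block_sizes[a],
            )
            for b in range(a, nb):
                ob, gb, lb, sb = (
                    self.offsets[b], self.block_group[b], self.block_load[b],
                    self.block_sizes[b],
                )
                wab = w * la * lb
                if ga is gb:
                    d = np.bincount(ga, weights=wab, minlength=sa)
                    blk = np.zeros((sa, sb))
                    np.fill_diagonal(blk, d)
                else:
                    flat = np.bincount(ga * sb + gb, weights=wab, minlength=sa * sb)
                    blk = flat.reshape(sa, sb)
                h[oa : oa + sa, ob : ob + sb] = blk
                if a != b:
                    h[ob : ob + sb, oa : oa + sa] = blk.T
        return h

    def ztwx(self, w: np.ndarray) -> np.ndarray:
        """Z' diag(w) X, shape (q, p)."""
        p = self.X.shape[1]
        out = np.empty((self.q, p))
        for j in range(p):
            out[:, j] = self.zt_dot(w * self.X[:, j])
        return out


def _laplace_loglik(
    design: _Design,
    beta: np.ndarray,
    sigmas: np.ndarray,
    u0: np.ndarray,
    tol: float = 1e-9,
    max_newton: int = 50,
) -> tuple[float, np.ndarray]:
    """Laplace marginal log-likelihood and the random-effect mode."""
    y, X = design.y, design.X
    eta_fixed = X @ beta
    inv_var = np.repeat(
        1.0 / np.maximum(sigmas, 1e-10) ** 2, design.block_sizes
    )
    u = u0.copy()
    for _ in range(max_newton):
        eta = eta_fixed + design.eta_random(u)
        p = expit(eta)
        grad = design.zt_dot(y - p) - inv_var * u
        gnorm = float(np.max(np.abs(grad)))
        if gnorm < tol:
            break
        w = np.maximum(p * (1.0 - p), 1e-10)
        h = design.ztwz(w)
        h[np.diag_indices_from(h)] += inv_var
        try:
            c = cho_factor(h, lower=True, check_finite=False)
        except np.linalg.LinAlgError:
            h[np.diag_indices_from(h)] += 1e-6
            c = cho_factor(h, lower=True, check_finite=False)
        step = cho_solve(c, grad, check_finite=False)
        # backtracking on the penalised conditional objective
        g_now = float(np.sum(y * eta - np.logaddexp(0.0, eta)) - 0.5 * np.sum(inv_var * u**2))
        alpha = 1.0
        for _ls in range(30):
            u_new = u + alpha * step
            eta_n = eta_fixed + design.eta_random(u_new)
            g_new = float(
                np.sum(y * eta_n - np.logaddexp(0.0, eta_n))
                - 0.5 * np.sum(inv_var * u_new**2)
            )
            if g_new >= g_now - 1e-12:
                break
            alpha *= 0.5
        u = u_new

    eta = eta_fixed + design.eta_random(u)
    p = expit(eta)
    w = np.maximum(p * (1.0 - p), 1e-10)
    h = design.ztwz(w)
    h[np.diag_indices_from(h)] += inv_var
    sign, logdet_h = np.linalg.slogdet(h)
    if sign <= 0:
        return -np.inf, u
    log_prior_norm = float(
        np.sum(np.asarray(design.block_sizes) * np.log(np.maximum(sigmas, 1e-10)))
    )
    ll = (
        float(np.sum(y * eta - np.logaddexp(0.0, eta)))
        - 0.5 * float(np.sum(inv_var * u**2))
        - log_prior_norm
        - 0.5 * logdet_h
    )
    return ll, u


def _plain_logistic_loglik(design: _Design, beta: np.ndarray) -> float:
    eta = design.X @ beta
    return float(np.sum(design.y * eta - np.logaddexp(0.0, eta)))


def fit_mixed_logit(
    trials: pd.DataFrame,
    neural=None,
    spec: GLMMSpec | None = None,
    maxiter: int = 200,
) -> GLMMFit:
    """Fit the accuracy GLMM by maximising the Laplace marginal likelihood.

    ``trials`` needs columns subject, item, stimulus_type, accuracy, and
    the predictor column unless ``neural`` supplies per-subject (dict) or
    per-trial (array) values.  Optimisation starts from zero coefficients
    and random-effect variance 0.1, so fits are deterministic.
    """
    spec = spec or GLMMSpec()
    design = _Design(trials, spec, neural=neural)
    p = design.X.shape[1]
    nb = len(design.blocks)
    u_state = {"u": np.zeros(design.q)}

    if nb == 0:
        def nll(beta):
            return -_plain_logistic_loglik(design, beta)

        res = optimize.minimize(
            nll, np.zeros(p), method="BFGS",
            options={"maxiter": maxiter, "gtol": 1e-8},
        )
        beta = res.x
        eta = design.X @ beta
        w = expit(eta) * (1 - expit(eta))
        info = design.X.T @ (design.X * w[:, None])
        cov = np.linalg.inv(info)
        return GLMMFit(
            names=design.fixed_names,
            beta=beta,
            se=np.sqrt(np.diag(cov)),
            loglik=float(-res.fun),
            variance_components={},
            converged=bool(res.success),
            n_obs=len(design.y),
            n_params=p,
            spec=spec,
            predictor_mean=design.x_mean,
            predictor_sd=design.x_sd,
            message=str(res.message),
            separation_suspected=bool(np.max(np.abs(beta)) > 15),
        )

    def nll(params):
        beta = params[:p]
        sigmas = np.exp(params[p:])
        ll, u = _laplace_loglik(design, beta, sigmas, u_state["u"])
        u_state["u"] = u
        return -ll

    start = np.concatenate(
        [np.zeros(p), np.full(nb, 0.5 * np.log(0.1))]  # variances start at 0.1
    )
    bounds = [(-30.0, 30.0)] * p + [(-6.0, 3.0)] * nb
    res = optimize.minimize(
        nll, start, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": maxiter, "ftol": 1e-11, "gtol": 1e-7},
    )
    beta = res.x[:p]
    sigmas = np.exp(res.x[p:])
    ll, u = _laplace_loglik(design, beta, sigmas, u_state["u"])

    # conditional Fisher information for the fixed effects (lme4-style):
    # I_beta = X'WX - X'WZ (Z'WZ + D^-1)^-1 Z'WX at the converged mode
    eta = design.X @ beta + design.eta_random(u)
    mu = expit(eta)
    w = np.maximum(mu * (1 - mu), 1e-10)
    xtwx = design.X.T @ (design.X * w[:, None])
    ztwx = design.ztwx(w)
    h = design.ztwz(w)
    h[np.diag_indices_from(h)] += np.repeat(
        1.0 / np.maximum(sigmas, 1e-10) ** 2, design.block_sizes
    )
    c = cho_factor(h, lower=True, check_finite=False)
    info = xtwx - ztwx.T @ cho_solve(c, ztwx, check_finite=False)
    cov = np.linalg.inv(info)
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))

    return GLMMFit(
        names=design.fixed_names,
        beta=beta,
        se=se,
        loglik=float(ll),
        variance_components={
            b: float(s**2) for b, s in zip(design.blocks, sigmas)
        },
        converged=bool(res.success),
        n_obs=len(design.y),
        n_params=p + nb,
        spec=spec,
        predictor_mean=design.x_mean,
        predictor_sd=design.x_sd,
        message=str(res.message),
        separation_suspected=bool(np.max(np.abs(beta)) > 15),
    )


def likelihood_ratio_test(full: GLMMFit, reduced: GLMMFit) -> tuple[float, int, float]:
    """Chi-square LRT between nested fits."""
    if not set(reduced.names) <= set(full.names):
        raise ValueError("reduced model fixed effects are not nested in the full model")
    if set(reduced.variance_components) - set(full.variance_components):
        raise ValueError("reduced model random structure is not nested in the full model")
    df = full.n_params - reduced.n_params
    if df < 0:
        raise ValueError("full model must have at least as many parameters as the reduced model")
    chi2 = max(0.0, 2.0 * (full.loglik - reduced.loglik))
    if df == 0:
        # identical specifications: no test to perform
        return 0.0, 0, 1.0
    p = float(stats.chi2.sf(chi2, df)) if chi2 > 0 else 1.0
    return chi2, df, p


def odds_ratio_table(
    fit: GLMMFit, level: float = 0.95, extreme_width_ratio: float = 1e3
) -> pd.DataFrame:
    """Odds ratios with Wald confidence intervals per fixed effect."""
    zc = stats.norm.ppf(0.5 + level / 2.0)
    or_ = np.exp(fit.beta)
    lo = np.exp(fit.beta - zc * fit.se)
    hi = np.exp(fit.beta + zc * fit.se)
    with np.errstate(divide="ignore", invalid="ignore"):
        width = np.where(lo > 0, hi / lo, np.inf)
    return pd.DataFrame(
        {
            "OR": or_,
            "ci_low": lo,
            "ci_high": hi,
            "extreme": width > extreme_width_ratio,
        },
        index=list(fit.names),
    )
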