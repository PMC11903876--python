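"""Logistic classification models for dichotomized urine markers.

Two model classes in the statsmodels idiom:

* :class:`LogitModel` (LR) — an ordinary logit-link GLM fitted by
  iteratively reweighted least squares (statsmodels underneath).
* :class:`RandomInterceptLogitModel` (LRRE) — a logistic regression with
  a per-patient random intercept b_i ~ N(0, sigma_b^2).  The marginal
  likelihood integrates the Bernoulli likelihood over each patient's
  intercept; the integral is evaluated by adaptive Gauss-Hermite
  quadrature (per-patient mode and curvature rescaling, 15 nodes by
  default; 1 node is the Laplace approximation) and maximised by
  quasi-Newton optimisation.

Both ``fit()`` methods return Results objects exposing ``params``,
``bse``, ``llf``, ``aic``, ``converged``, ``predict`` and ``summary()``.
AIC counts the random-intercept variance as one parameter.

:func:`best_subset` exhaustively scores every candidate-wavelength
subset by AIC and returns the minimiser with a deterministic tie-break.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize
from scipy.special import expit, logsumexp
from statsmodels.tools.numdiff import approx_hess
from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

from .exceptions import (DegenerateOutcomeError, SchemaError,
                         SelectionFailureError)

_SIGMA_FLOOR = 1e-6  # below this the random intercept is treated as absent


def _as_design(X, add_intercept: bool = True):
    """Coerce a DataFrame/array into (matrix incl. intercept, names)."""
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        mat = X.to_numpy(dtype=float)
    else:
        mat = np.asarray(X, dtype=float)
        if mat.ndim == 1:
            mat = mat.reshape(-1, 1)  # one feature column
        names = [f"x{i + 1}" for i in range(mat.shape[1])]
    if len(set(names)) != len(names):
        raise SchemaError("design matrix: duplicate column names")
    if add_intercept:
        mat = np.column_stack([np.ones(mat.shape[0]), mat])
        names = ["const"] + names
    return mat, names


def _check_outcome(y) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    classes = np.unique(y)
    if not np.all(np.isin(classes, [0.0, 1.0])):
        raise ValueError("labels must be binary 0/1")
    if classes.size < 2:
        raise DegenerateOutcomeError("outcome has a single class")
    return y


def _bernoulli_loglik(y: np.ndarray, eta: np.ndarray) -> np.ndarray:
    # y*eta - log(1 + exp(eta)), numerically stable
    return y * eta - np.logaddexp(0.0, eta)


class _ResultsBase:
    """Shared surface of LR/LRRE results."""

    kind: str
    feature_names: list[str]
    params: np.ndarray
    bse: np.ndarray
    llf: float
    n_params: int
    converged: bool
    nobs: int

    @property
    def aic(self) -> float:
        return -2.0 * self.llf + 2.0 * self.n_params

    def _check_X(self, X):
        mat, names = _as_design(X, add_intercept=True)
        expected = ["const"] + self.feature_names
        if isinstance(X, pd.DataFrame):
            if names != expected:
                raise SchemaError(f"feature mismatch: model has {expected}, "
                                  f"got {names}")
        elif mat.shape[1] != len(expected):
            raise SchemaError(f"feature mismatch: model has {len(expected) - 1} "
                              f"features, got {mat.shape[1] - 1}")
        return mat

    def summary(self) -> str:
        rows = pd.DataFrame({"coef": self.params,
                             "std err": self.bse[:self.params.size]},
                            index=["const"] + self.feature_names)
        head = (f"{self.kind} results | nobs={self.nobs} "
                f"| loglik={self.llf:.4f} | AIC={self.aic:.4f} "
                f"| converged={self.converged}")
        extra = ""
        if self.kind == "LRRE":
            extra = (f"\nsigma_b (random-intercept sd): {self.sigma_b:.4f} "
                     f"(std err {self.bse[-1]:.4f})")
        return head + extra + "\n" + rows.to_string(float_format="%.4f")


@dataclass
class LogitResults(_ResultsBase):
    feature_names: list[str]
    params: np.ndarray
    bse: np.ndarray
    llf: float
    converged: bool
    nobs: int
    separation_flag: bool = False
    kind: str = "LR"

    @property
    def n_params(self) -> int:
        return self.params.size

    def predict(self, X, groups=None, mode: str = "marginal") -> np.ndarray:
        mat = self._check_X(X)
        return expit(mat @ self.params)


class LogitModel:
    """Ordinary logistic regression (logit-link GLM, IRLS).

    Parameters
    ----------
    endog : binary labels (1 = pathological)
    exog : DataFrame or array of features; an intercept is prepended.
    """

    def __init__(self, endog, exog, add_intercept: bool = True):
        self.endog = _check_outcome(endog)
        self.exog, names = _as_design(exog, add_intercept=add_intercept)
        if not add_intercept:
            names = ["const"] + names[1:] if names[0] == "const" else names
        self.feature_names = [n for n in names if n != "const"]
        if self.exog.shape[0] != self.endog.size:
            raise ValueError("endog and exog length mismatch")

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, outcome: str,
                       features: list[str]) -> "LogitModel":
        return cls(data[outcome].to_numpy(), data[list(features)])

    def fit(self, maxiter: int = 100) -> LogitResults:
        separation = False
        with warnings.catch_warnings(record=True) as caught, \
                np.errstate(all="ignore"):
            warnings.simplefilter("always")
            glm = sm.GLM(self.endog, self.exog, family=sm.families.Binomial())
            res = glm.fit(maxiter=maxiter)
            llf = float(res.llf)  # lazy in statsmodels: evaluate while suppressed
            bse = np.asarray(res.bse, float)
            for w in caught:
                if issubclass(w.category, PerfectSeparationWarning):
                    separation = True
        # separation shows as diverging coefficients / non-finite likelihood;
        # merely steep (but finite) fits are legitimate
        if not np.isfinite(llf) or np.any(np.abs(res.params) > 500.0):
            separation = True
        converged = bool(getattr(res, "converged", True)) and not separation
        return LogitResults(feature_names=self.feature_names,
                            params=np.asarray(res.params, float),
                            bse=bse, llf=llf, converged=converged,
                            nobs=self.endog.size, separation_flag=separation)


# ---------------------------------------------------------------------------
# random-intercept logit

@dataclass
class RandomInterceptLogitResults(_ResultsBase):
    feature_names: list[str]
    params: np.ndarray        # fixed effects (incl. intercept)
    sigma_b: float            # random-intercept sd
    bse: np.ndarray           # se of fixed effects + sigma_b (last entry)
    llf: float                # marginal log-likelihood
    converged: bool
    nobs: int
    n_groups: int
    random_effects: dict      # patient id -> posterior-mode intercept (BLUP)
    boundary_flag: bool = False  # sigma_b hit the zero boundary
    kind: str = "LRRE"

    @property
    def n_params(self) -> int:
        return self.params.size + 1  # variance component counts as one

    def predict(self, X, groups=None, mode: str = "conditional") -> np.ndarray:
        """Conditional uses each patient's BLUP (0 for unseen patients)."""
        mat = self._check_X(X)
        eta = mat @ self.params
        if mode == "conditional":
            if groups is None:
                raise SchemaError("conditional prediction needs group ids")
            b = np.array([self.random_effects.get(g, 0.0) for g in np.asarray(groups)])
            eta = eta + b
        elif mode != "marginal":
            raise ValueError("mode must be 'conditional' or 'marginal'")
        return expit(eta)


class RandomInterceptLogitModel:
    """Logistic regression with a per-patient random intercept.

    Marginal likelihood over b_i ~ N(0, sigma_b^2) is computed by adaptive
    Gauss-Hermite quadrature and maximised over (beta, sigma_b) with
    L-BFGS-B (sigma_b bounded at 0).
    """

    def __init__(self, endog, exog, groups, n_quadrature: int = 15,
                 add_intercept: bool = True):
        self.endog = _check_outcome(endog)
        self.exog, names = _as_design(exog, add_intercept=add_intercept)
        self.feature_names = [n for n in names if n != "const"]
        groups = np.asarray(groups)
        if groups.size != self.endog.size:
            raise ValueError("groups length mismatch")
        self.group_labels, self.group_idx = np.unique(groups, return_inverse=True)
        if self.group_labels.size < 2:
            raise ValueError("need >= 2 groups for a random intercept")
        if n_quadrature < 1:
            raise ValueError("n_quadrature must be >= 1")
        self.n_quadrature = int(n_quadrature)
        self._gh_x, self._gh_w = np.polynomial.hermite.hermgauss(self.n_quadrature)

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, outcome: str,
                       features: list[str], group_col: str = "patient_id",
                       **kw) -> "RandomInterceptLogitModel":
        return cls(data[outcome].to_numpy(), data[list(features)],
                   data[group_col].to_numpy(), **kw)

    # -- likelihood machinery ------------------------------------------------

    def _posterior_modes(self, eta: np.ndarray, sigma: float,
                         b0: np.ndarray | None = None,
                         tol: float = 1e-10, maxiter: int = 100):
        """Per-group mode and curvature of log p(y|b) + log phi(b; 0, sigma^2)."""
        g = self.group_idx
        y = self.endog
        G = self.group_labels.size
        b = np.zeros(G) if b0 is None else b0.copy()
        inv_var = 1.0 / (sigma * sigma)
        for _ in range(maxiter):
            p = expit(eta + b[g])
            grad = np.bincount(g, weights=y - p, minlength=G) - b * inv_var
            curv = -np.bincount(g, weights=p * (1 - p), minlength=G) - inv_var
            step = grad / curv
            np.clip(step, -5.0, 5.0, out=step)
            b -= step
            if np.max(np.abs(step)) < tol:
                break
        p = expit(eta + b[g])
        curv = -np.bincount(g, weights=p * (1 - p), minlength=G) - 1.0 / (sigma * sigma)
        return b, curv

    def loglik(self, params: np.ndarray) -> float:
        """Marginal log-likelihood at (beta, sigma_b)."""
        beta, sigma = params[:-1], params[-1]
        eta = self.exog @ beta
        if sigma < _SIGMA_FLOOR:
            return float(_bernoulli_loglik(self.endog, eta).sum())
        g = self.group_idx
        G = self.group_labels.size
        b_hat, curv = self._posterior_modes(eta, sigma)
        tau = 1.0 / np.sqrt(-curv)                       # (G,)
        # adaptive nodes: b_gk = b_hat_g + sqrt(2) tau_g x_k
        b_nodes = b_hat[None, :] + np.sqrt(2.0) * tau[None, :] * self._gh_x[:, None]
        log_terms = np.empty((self.n_quadrature, G))
        log_norm = -0.5 * np.log(2 * np.pi * sigma * sigma)
        for k in range(self.n_quadrature):
            bk = b_nodes[k]
            ll = _bernoulli_loglik(self.endog, eta + bk[g])
            per_group = np.bincount(g, weights=ll, minlength=G)
            log_prior = log_norm - 0.5 * (bk / sigma) ** 2
            log_terms[k] = per_group + log_prior
        log_w = np.log(self._gh_w)[:, None] + (self._gh_x ** 2)[:, None]
        group_logint = (np.log(np.sqrt(2.0) * tau)
                        + logsumexp(log_terms + log_w, axis=0))
        return float(group_logint.sum())

    # -- fitting -------------------------------------------------------------

    def fit(self, start_params=None, maxiter: int = 200,
            compute_bse: bool = True) -> RandomInterceptLogitResults:
        p = self.exog.shape[1]
        if start_params is None:
            try:
                lr = LogitModel(self.endog, self.exog[:, 1:]
                                if p > 1 else np.empty((self.endog.size, 0)),
                                add_intercept=True).fit()
                beta0 = lr.params
            except Exception:
                beta0 = np.zeros(p)
            start = np.append(beta0, 1.0)
        else:
            start = np.asarray(start_params, dtype=float)

        def neg(params):
            return -self.loglik(params)

        bounds = [(None, None)] * p + [(0.0, None)]
        res = optimize.minimize(neg, start, method="L-BFGS-B", bounds=bounds,
                                options={"maxiter": maxiter, "ftol": 1e-12,
                                         "gtol": 1e-8})
        params = res.x
        beta, sigma = params[:-1], params[-1]
        boundary = sigma < 1e-4
        llf = -res.fun

        bse = np.full(p + 1, np.nan)
        if compute_bse:
            try:
                with np.errstate(all="ignore"):
                    H = approx_hess(params, neg)
                    cov = np.linalg.inv(H)
                    d = np.diag(cov)
                    bse = np.where(d > 0, np.sqrt(np.abs(d)), np.nan)
            except np.linalg.LinAlgError:
                pass

        eta = self.exog @ beta
        if sigma >= _SIGMA_FLOOR:
            b_hat, _ = self._posterior_modes(eta, sigma)
        else:
            b_hat = np.zeros(self.group_labels.size)
        blups = {lbl: float(bv) for lbl, bv in zip(self.group_labels, b_hat)}
        return RandomInterceptLogitResults(
            feature_names=self.feature_names, params=beta, sigma_b=float(sigma),
            bse=bse, llf=float(llf), converged=bool(res.success),
            nobs=self.endog.size, n_groups=self.group_labels.size,
            random_effects=blups, boundary_flag=bool(boundary))


# ---------------------------------------------------------------------------
# best-subset selection

@dataclass
class SubsetTrial:
    features: tuple[str, ...]
    aic: float
    converged: bool
    results: _ResultsBase


@dataclass
class BestSubsetResults:
    """Outcome of exhaustive AIC minimisation over candidate subsets."""

    best: _ResultsBase
    selected_features: tuple[str, ...]
    trials: list[SubsetTrial] = field(default_factory=list)

    @property
    def n_fits(self) -> int:
        return len(self.trials)


def _fit_one(X: pd.DataFrame, y, groups, kind: str, features: tuple[str, ...],
             n_quadrature: int):
    Xsub = X[list(features)] if features else pd.DataFrame(index=X.index)
    if kind == "lr":
        model = LogitModel(y, Xsub)
        return model.fit()
    model = RandomInterceptLogitModel(y, Xsub, groups, n_quadrature=n_quadrature)
    return model.fit(compute_bse=False)


def best_subset(X_candidates: pd.DataFrame, y, groups=None, kind: str = "lr",
                max_size: int | None = None, hard_cap: int = 12,
                n_quadrature: int = 15,
                include_baseline: bool = True) -> BestSubsetResults:
    """Exhaustive AIC best-subset selection over candidate features.

    Fits every non-empty subset of up to ``max_size`` candidates plus the
    intercept-only baseline and returns the minimum-AIC converged model.
    Ties break toward fewer features, then lexicographic feature names.
    ``include_baseline=False`` restricts the choice to feature-bearing
    models (the baseline is still fitted for reference).
    """
    kind = kind.lower()
    if kind not in ("lr", "lrre"):
        raise ValueError("kind must be 'lr' or 'lrre'")
    if kind == "lrre" and groups is None:
        raise ValueError("kind='lrre' requires groups")
    names = list(X_candidates.columns)
    if len(names) > hard_cap:
        raise ValueError(f"{len(names)} candidates exceed the hard cap {hard_cap}")
    max_size = len(names) if max_size is None else min(max_size, len(names))

    trials: list[SubsetTrial] = []
    subsets: list[tuple[str, ...]] = [()]
    for size in range(1, max_size + 1):
        subsets.extend(itertools.combinations(names, size))
    for feats in subsets:
        try:
            res = _fit_one(X_candidates, y, groups, kind, feats, n_quadrature)
            trials.append(SubsetTrial(feats, res.aic, res.converged, res))
        except DegenerateOutcomeError:
            raise
        except Exception:
            continue
    ok = [t for t in trials if t.converged
          and (include_baseline or t.features)]
    if not ok:
        raise SelectionFailureError("no candidate subset produced a converged model")
    winner = min(ok, key=lambda t: (t.aic, len(t.features), t.features))
    # refit winner with standard errors for reporting (cheap: one model)
    if kind == "lrre":
        final = RandomInterceptLogitModel(
            y, X_candidates[list(winner.features)], groups,
            n_quadrature=n_quadrature).fit(compute_bse=True)
    else:
        final = winner.results
    return BestSubsetResults(best=final, selected_features=winner.features,
                             trials=trials)
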