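"""Exact conditional logistic regression for small matched strata.

Fits the stratified logistic model whose likelihood conditions, within each
stratum (family), on the observed number of cases.  With ``k`` cases among
``m`` members carrying linear predictors ``eta_i = x_i' beta`` the stratum
contributes

    L_s(beta) = exp(sum_{i in cases} eta_i) / sum_{|S|=k} exp(sum_{i in S} eta_i)

where the denominator runs over all size-``k`` subsets of the stratum.  Any
stratum-level confounding (shared family environment, relatedness) cancels in
the ratio, which is why the model is the standard choice for family-based
case/control designs.  Strata without outcome diversity carry no information
and are removed before fitting; covariates that are constant within every
stratum are unidentifiable and reported as NaN.

The denominator is enumerated exactly, which is fast for the family-sized
strata (2-6 members) this package targets, and the likelihood is maximised by
Newton-Raphson with step halving.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import norm

__all__ = ["ConditionalLogit", "ConditionalLogitResults"]

_MAX_SUBSETS = 50_000


def _informative_strata(endog, groups):
    """Group labels -> indices, keeping strata with >=2 members and both outcomes."""
    order = np.argsort(groups, kind="stable")
    kept, dropped = [], 0
    g_sorted = np.asarray(groups)[order]
    bounds = np.flatnonzero(np.r_[True, g_sorted[1:] != g_sorted[:-1], True])
    for a, b in zip(bounds[:-1], bounds[1:]):
        idx = order[a:b]
        y = endog[idx]
        if len(idx) >= 2 and y.min() == 0 and y.max() == 1:
            kept.append(idx)
        else:
            dropped += 1
    return kept, dropped


@dataclass
class _ShapeClass:
    # strata sharing the same (size m, n cases k); arrays stacked over strata
    X: np.ndarray          # (G, m, p)
    y: np.ndarray          # (G, m)
    A: np.ndarray          # (C, m) subset indicator matrix

    def loglike(self, beta):
        eta = self.X @ beta                      # (G, m)
        u = eta @ self.A.T                       # (G, C)
        obs = (eta * self.y).sum(axis=1)
        return float((obs - logsumexp(u, axis=1)).sum())

    def score_hessian(self, beta):
        eta = self.X @ beta
        u = eta @ self.A.T
        u -= u.max(axis=1, keepdims=True)
        w = np.exp(u)
        p = w / w.sum(axis=1, keepdims=True)     # (G, C)
        B = np.einsum("cm,gmp->gcp", self.A, self.X)   # subset covariate sums
        E = np.einsum("gc,gcp->gp", p, B)
        obs = np.einsum("gm,gmp->gp", self.y, self.X)
        score = (obs - E).sum(axis=0)
        hess = -(np.einsum("gc,gcp,gcq->pq", p, B, B) - np.einsum("gp,gq->pq", E, E))
        return score, hess


class ConditionalLogit:
    """Conditional (fixed-strata) logistic regression via exact enumeration.

    Parameters
    ----------
    endog : array-like of {0, 1}
        Case status per individual.
    exog : 2-d array-like or DataFrame
        Covariates; no intercept (it is absorbed by the strata).
    groups : array-like
        Stratum (family) label per individual.
    exog_names : sequence of str, optional
        Column names when ``exog`` is a bare array.
    """

    def __init__(self, endog, exog, groups, exog_names=None):
        if isinstance(exog, pd.DataFrame):
            exog_names = list(exog.columns)
            exog = exog.to_numpy(dtype=float)
        else:
            exog = np.asarray(exog, dtype=float)
            if exog.ndim == 1:
                exog = exog[:, None]
        endog = np.asarray(endog, dtype=int)
        groups = np.asarray(groups)
        if not np.isin(endog, (0, 1)).all():
            raise ValueError("endog must be binary 0/1")
        if not (len(endog) == len(exog) == len(groups)):
            raise ValueError("endog, exog and groups must have equal length")
        self.exog_names = list(exog_names) if exog_names is not None else [
            f"x{j}" for j in range(exog.shape[1])
        ]
        self.k_params = exog.shape[1]

        strata, self.n_strata_dropped = _informative_strata(endog, groups)
        self.n_strata = len(strata)
        if self.n_strata == 0:
            raise ValueError("no informative strata (need >=2 members and both outcomes)")

        # columns constant within every informative stratum are unidentifiable
        within_var = np.zeros(self.k_params, dtype=bool)
        for idx in strata:
            within_var |= np.ptp(exog[idx], axis=0) > 0
        self.estimable = within_var
        self.dropped_columns = [n for n, ok in zip(self.exog_names, within_var) if not ok]
        use = np.flatnonzero(within_var)
        if use.size == 0:
            raise ValueError("no covariate varies within any informative stratum")
        self._use = use

        shapes: dict[tuple[int, int], list] = {}
        for idx in strata:
            y = endog[idx]
            shapes.setdefault((len(idx), int(y.sum())), []).append((exog[np.ix_(idx, use)], y))
        self._classes: list[_ShapeClass] = []
        for (m, k), rows in shapes.items():
            from math import comb

            if comb(m, k) > _MAX_SUBSETS:
                raise ValueError(f"stratum of size {m} with {k} cases is too large to enumerate")
            A = np.zeros((comb(m, k), m))
            for c, combo in enumerate(itertools.combinations(range(m), k)):
                A[c, list(combo)] = 1.0
            self._classes.append(
                _ShapeClass(
                    X=np.stack([x for x, _ in rows]),
                    y=np.stack([y for _, y in rows]).astype(float),
                    A=A,
                )
            )

    # -- likelihood machinery -------------------------------------------------
    def loglike(self, params):
        beta = np.asarray(params, dtype=float)
        if beta.shape[0] == self.k_params:
            beta = beta[self._use]
        return sum(cl.loglike(beta) for cl in self._classes)

    def _score_hessian(self, beta):
        p = self._use.size
        score, hess = np.zeros(p), np.zeros((p, p))
        for cl in self._classes:
            s, h = cl.score_hessian(beta)
            score += s
            hess += h
        return score, hess

    def fit(self, start_params=None, maxiter=100, gtol=1e-8, lltol=1e-8,
            divergence_bound=15.0):
        """Maximise the conditional likelihood by Newton-Raphson.

        ``divergence_bound`` flags (quasi-)complete separation: if any
        coefficient wanders beyond it the estimate is reported with
        ``diverged=True`` rather than silently capped.
        """
        p = self._use.size
        beta = np.zeros(p) if start_params is None else np.asarray(start_params, float)[self._use]
        ll = self.loglike_reduced(beta)
        converged = diverged = False
        for _ in range(maxiter):
            score, hess = self._score_hessian(beta)
            if np.max(np.abs(score)) < gtol:
                converged = True
                break
            try:
                step = np.linalg.solve(hess, -score)
            except np.linalg.LinAlgError:
                step = -np.linalg.pinv(hess) @ (-score)
            # step halving
            new_ll, t = -np.inf, 1.0
            for _ in range(30):
                cand = beta + t * step
                new_ll = self.loglike_reduced(cand)
                if new_ll >= ll - 1e-12:
                    break
                t /= 2
            beta, prev_ll, ll = cand, ll, new_ll
            if np.max(np.abs(beta)) > divergence_bound:
                diverged = True
                break
            if abs(ll - prev_ll) < lltol * (abs(prev_ll) + 1e-12) and np.max(np.abs(score)) < 1e-4:
                converged = True
                break
        _, hess = self._score_hessian(beta)
        try:
            cov = np.linalg.inv(-hess)
            bse_r = np.sqrt(np.clip(np.diag(cov), 0, None))
        except np.linalg.LinAlgError:
            bse_r = np.full(p, np.nan)

        params = np.full(self.k_params, np.nan)
        bse = np.full(self.k_params, np.nan)
        params[self._use] = beta
        bse[self._use] = bse_r
        return ConditionalLogitResults(
            model=self, params=params, bse=bse, llf=ll,
            converged=converged and not diverged, diverged=diverged,
        )

    def loglike_reduced(self, beta):
        return sum(cl.loglike(beta) for cl in self._classes)


@dataclass
class ConditionalLogitResults:
    """Estimates, Wald inference and fit diagnostics for :class:`ConditionalLogit`."""

    model: ConditionalLogit
    params: np.ndarray
    bse: np.ndarray
    llf: float
    converged: bool
    diverged: bool
    zvalues: np.ndarray = field(init=False)
    pvalues: np.ndarray = field(init=False)

    def __post_init__(self):
        with np.errstate(invalid="ignore", divide="ignore"):
            self.zvalues = self.params / self.bse
            self.pvalues = 2 * norm.sf(np.abs(self.zvalues))

    @property
    def n_strata(self):
        return self.model.n_strata

    @property
    def n_strata_dropped(self):
        return self.model.n_strata_dropped

    def conf_int(self, alpha=0.05):
        q = norm.ppf(1 - alpha / 2)
        return np.column_stack([self.params - q * self.bse, self.params + q * self.bse])

    def to_frame(self):
        ci = self.conf_int()
        return pd.DataFrame(
            {
                "coef": self.params,
                "se": self.bse,
                "z": self.zvalues,
                "p": self.pvalues,
                "ci_low": ci[:, 0],
                "ci_high": ci[:, 1],
            },
            index=self.model.exog_names,
        )

    def summary(self):
        head = (
            f"Conditional logistic regression (exact strata enumeration)\n"
            f"informative strata: {self.n_strata}   dropped strata: {self.n_strata_dropped}\n"
            f"log-likelihood: {self.llf:.4f}   converged: {self.converged}"
            f"{'   DIVERGED (separation suspected)' if self.diverged else ''}\n"
        )
        if self.model.dropped_columns:
            head += f"unidentifiable (constant within strata): {', '.join(self.model.dropped_columns)}\n"
        return head + self.to_frame().to_string(float_format=lambda v: f"{v:10.4f}")
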