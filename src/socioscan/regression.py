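"""Permutation-based linear regression of road presence on life-history and
network predictors.

The response is each individual's percentage of behavioural records along
the road; predictors are binary age (adult/nonadult, subadults coded adult),
binary sex, own eigenvector and betweenness centrality, and the top
associate's eigenvector and betweenness centrality, all taken from the
comprehensive forest proximity network.

Inference permutes the response while holding the design fixed: for each
term the two-tailed p-value is the proportion of permutations whose
coefficient magnitude meets or exceeds the observed one.  A sequential
stopping rule ends a term's permutations once its p estimate is stable
(clearly null terms stop after few iterations; significant terms run to the
iteration cap), mirroring the behaviour of permutation-regression software
that reports a per-term iteration count.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .association import AssociationMatrix, top_associate
from .metrics import MetricTable
from .scan_data import Roster

PREDICTORS = (
    "age",
    "sex",
    "eigenvector",
    "betweenness",
    "assoc_eigenvector",
    "assoc_betweenness",
)


def build_design(
    roster: Roster,
    metrics: MetricTable,
    assoc: AssociationMatrix,
    proportions: pd.Series,
    interactions: list[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Assemble the regression design, one row per analysis individual.

    Coding: age 1 = adult (subadults count as adults), 0 = nonadult; sex
    1 = male, 0 = female — so the intercept represents nonadult females.
    Associate covariates are the centrality values of each individual's top
    associate in the forest proximity network.  ``interactions`` optionally
    adds product terms (excluded by default).
    """
    ids = [i for i in roster.ids if i in proportions.index]
    missing = [i for i in ids if i not in metrics.table.index]
    if missing:
        raise ValueError(f"individuals missing from metric table: {missing}")
    failures = []
    assoc_ids = {}
    for i in ids:
        try:
            assoc_ids[i] = top_associate(assoc, i)
        except ValueError:
            failures.append(i)
    if failures:
        raise ValueError(f"top associate unresolvable (no nonzero associations) for: {failures}")

    rows = {}
    for i in ids:
        ind = roster[i]
        partner = assoc_ids[i]
        rows[i] = {
            "road_pct": float(proportions[i]),
            "age": 1.0 if ind.age_class in ("adult", "subadult") else 0.0,
            "sex": 1.0 if ind.sex == "male" else 0.0,
            "eigenvector": float(metrics.table.loc[i, "eigenvector"]),
            "betweenness": float(metrics.table.loc[i, "betweenness"]),
            "assoc_eigenvector": float(metrics.table.loc[partner, "eigenvector"]),
            "assoc_betweenness": float(metrics.table.loc[partner, "betweenness"]),
            "top_associate": partner,
        }
    design = pd.DataFrame.from_dict(rows, orient="index")
    for a, b in interactions or []:
        design[f"{a}:{b}"] = design[a] * design[b]
    if design.drop(columns="top_associate").isna().any().any():
        raise ValueError("design contains missing values")
    return design


@dataclass
class PermutationOLSResults:
    """Fit results: coefficients with permutation p-values and iteration counts."""

    model: "PermutationOLS"
    params: pd.Series
    iterations: pd.Series
    pvalues: pd.Series
    rsquared: float
    rsquared_adj: float
    omnibus_pvalue: float
    exact: bool = False

    @property
    def terms(self) -> list[str]:
        return list(self.params.index)

    def summary(self) -> str:
        lines = [
            "Permutation-based linear regression",
            f"n = {self.model.nobs}, response = {self.model.response_name}",
            "",
            f"{'Variable':<28}{'Coefficient':>12}{'Iterations':>12}{'p-value':>10}",
            "-" * 62,
        ]
        for term in self.terms:
            star = " *" if self.pvalues[term] <= 0.05 and term != "Intercept" else ""
            lines.append(
                f"{term:<28}{self.params[term]:>12.3f}{int(self.iterations[term]):>12}"
                f"{self.pvalues[term]:>10.3f}{star}"
            )
        lines += [
            "-" * 62,
            f"Adjusted R^2 = {self.rsquared_adj:.3f}, omnibus p = {self.omnibus_pvalue:.4g}",
        ]
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coefficient": self.params,
                "iterations": self.iterations.astype(int),
                "p_value": self.pvalues,
            }
        )

    def write_csv(self, path) -> None:
        df = self.to_frame().reset_index(names="variable")
        footer = pd.DataFrame(
            [{"variable": "adjusted_R2", "coefficient": self.rsquared_adj, "iterations": "", "p_value": self.omnibus_pvalue}]
        )
        pd.concat([df, footer], ignore_index=True).to_csv(path, index=False)


class PermutationOLS:
    """OLS point estimates with response-permutation inference.

    Parameters
    ----------
    endog : array-like
        Response vector (road percentage per individual).
    exog : DataFrame
        Predictor columns; an intercept is added automatically.
    """

    def __init__(self, endog, exog: pd.DataFrame, response_name: str = "y"):
        self.exog_names = ["Intercept", *exog.columns]
        X = np.column_stack([np.ones(len(exog)), exog.to_numpy(float)])
        y = np.asarray(endog, dtype=float)
        if y.ndim != 1 or len(y) != X.shape[0]:
            raise ValueError("endog/exog length mismatch")
        n, k = X.shape
        if n <= k:
            raise ValueError(f"need n > number of parameters ({k}), got n = {n}")
        rank = np.linalg.matrix_rank(X)
        if rank < k:
            raise ValueError(self._collinearity_message(X))
        self.X = X
        self.y = y
        self.nobs = n
        self.df_model = k - 1
        self.response_name = response_name
        self._pinv = np.linalg.pinv(X)

    def _collinearity_message(self, X: np.ndarray) -> str:
        culprits = []
        for j in range(1, X.shape[1]):
            others = np.delete(X, j, axis=1)
            resid = X[:, j] - others @ np.linalg.lstsq(others, X[:, j], rcond=None)[0]
            if np.linalg.norm(resid) < 1e-10 * max(1.0, np.linalg.norm(X[:, j])):
                culprits.append(self.exog_names[j])
        return f"design is rank deficient; collinear column(s): {culprits or 'intercept-related'}"

    @classmethod
    def from_dataframe(
        cls, data: pd.DataFrame, response: str = "road_pct", predictors=PREDICTORS
    ) -> "PermutationOLS":
        cols = [c for c in predictors if c in data.columns]
        return cls(data[response], data[cols], response_name=response)

    # -- point estimates ---------------------------------------------------

    def _ols(self, y: np.ndarray) -> tuple[np.ndarray, float]:
        beta = self._pinv @ y
        fitted = self.X @ beta
        ss_res = float(((y - fitted) ** 2).sum())
        ss_tot = float(((y - y.mean()) ** 2).sum())
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
        return beta, r2

    def fit_ols(self) -> tuple[pd.Series, float]:
        """Plain least-squares coefficients and adjusted R² (no permutations)."""
        beta, r2 = self._ols(self.y)
        n, k = self.nobs, self.df_model
        adj = 1.0 - (1.0 - r2) * (n - 1) / (n - k - 1)
        return pd.Series(beta, index=self.exog_names), adj

    # -- permutation inference --------------------------------------------

    def fit(
        self,
        max_iter: int = 5000,
        seed: int | None = None,
        stop_rule: str = "sequential",
        min_iter: int = 50,
        rel_se: float = 0.1,
        chunk: int = 50,
    ) -> PermutationOLSResults:
        """Permute the response until each term's p-value converges.

        A term stops once its iteration count reaches ``min_iter`` and the
        binomial standard error of its estimated p falls below ``rel_se``
        times the estimate, or at ``max_iter``.  ``stop_rule='none'`` runs
        every term to ``max_iter``.  Two-tailed p-values carry an add-one
        correction: p = (1 + #{|b*| ≥ |b_obs|}) / (1 + iterations).
        """
        if max_iter < min_iter:
            raise ValueError(f"max_iter must be at least min_iter ({min_iter})")
        rng = np.random.default_rng(seed)
        beta_obs, r2_obs = self._ols(self.y)
        k = len(beta_obs)
        tol = 1e-12 * np.maximum(1.0, np.abs(beta_obs))

        counts = np.zeros(k)
        iters = np.zeros(k, dtype=int)
        active = np.ones(k, dtype=bool)
        omni_count = 0
        omni_iters = 0
        done = 0
        while done < max_iter and active.any():
            b = min(chunk, max_iter - done)
            perms = np.empty((self.nobs, b))
            for c in range(b):
                perms[:, c] = rng.permutation(self.y)
            betas = self._pinv @ perms  # (k, b)
            exceed = np.abs(betas) >= (np.abs(beta_obs) - tol)[:, None]
            counts[active] += exceed[active].sum(axis=1)
            iters[active] += b
            # omnibus: R^2 of each permuted response (same SST as y)
            fitted = self.X @ betas
            ss_tot = float(((self.y - self.y.mean()) ** 2).sum())
            if ss_tot > 0:
                r2_perm = 1.0 - ((perms - fitted) ** 2).sum(axis=0) / ss_tot
            else:
                r2_perm = np.zeros(b)
            omni_count += int(np.sum(r2_perm >= r2_obs - 1e-12))
            omni_iters += b
            done += b
            if stop_rule == "sequential":
                p_hat = (1 + counts) / (1 + iters)
                se = np.sqrt(p_hat * (1 - p_hat) / np.maximum(iters, 1))
                converged = (iters >= min_iter) & (se < rel_se * p_hat)
                active &= ~converged
            elif stop_rule != "none":
                raise ValueError(f"unknown stop_rule {stop_rule!r}")

        pvals = (1 + counts) / (1 + iters)
        n, kk = self.nobs, self.df_model
        adj = 1.0 - (1.0 - r2_obs) * (n - 1) / (n - kk - 1)
        omni_p = (1 + omni_count) / (1 + omni_iters)
        return PermutationOLSResults(
            model=self,
            params=pd.Series(beta_obs, index=self.exog_names),
            iterations=pd.Series(iters, index=self.exog_names),
            pvalues=pd.Series(pvals, index=self.exog_names),
            rsquared=r2_obs,
            rsquared_adj=adj,
            omnibus_pvalue=omni_p,
        )

    def fit_exhaustive(self) -> PermutationOLSResults:
        """Enumerate all n! response permutations (n ≤ 8): exact p-values.

        Exact p = #{|b*| ≥ |b_obs|} / n! with the identity permutation
        included, so p > 0 without an add-one correction.
        """
        n = self.nobs
        if n > 8:
            raise ValueError("exhaustive enumeration limited to n <= 8")
        beta_obs, r2_obs = self._ols(self.y)
        tol = 1e-12 * np.maximum(1.0, np.abs(beta_obs))
        perms = np.array(list(itertools.permutations(self.y)))  # (n!, n)
        betas = self._pinv @ perms.T  # (k, n!)
        counts = (np.abs(betas) >= (np.abs(beta_obs) - tol)[:, None]).sum(axis=1)
        fitted = self.X @ betas
        ss_tot = float(((self.y - self.y.mean()) ** 2).sum())
        if ss_tot > 0:
            r2_perm = 1.0 - ((perms.T - fitted) ** 2).sum(axis=0) / ss_tot
        else:
            r2_perm = np.zeros(perms.shape[0])
        omni_p = float(np.mean(r2_perm >= r2_obs - 1e-12))
        total = perms.shape[0]
        kk = self.df_model
        adj = 1.0 - (1.0 - r2_obs) * (n - 1) / (n - kk - 1)
        return PermutationOLSResults(
            model=self,
            params=pd.Series(beta_obs, index=self.exog_names),
            iterations=pd.Series(total, index=self.exog_names),
            pvalues=pd.Series(counts / total, index=self.exog_names),
            rsquared=r2_obs,
            rsquared_adj=adj,
            omnibus_pvalue=omni_p,
            exact=True,
        )


# -- functional wrappers (module-level convenience API) ---------------------


def ols_fit(design: pd.DataFrame, response: str = "road_pct", predictors=PREDICTORS):
    """Least-squares coefficients and adjusted R² for the road-presence design."""
    return PermutationOLS.from_dataframe(design, response, predictors).fit_ols()


def perm_lm(
    design: pd.DataFrame,
    max_iter: int = 5000,
    seed: int | None = None,
    stop_rule: str = "sequential",
    response: str = "road_pct",
    predictors=PREDICTORS,
    **kwargs,
) -> PermutationOLSResults:
    """Permutation regression of ``response`` on ``predictors``."""
    model = PermutationOLS.from_dataframe(design, response, predictors)
    return model.fit(max_iter=max_iter, seed=seed, stop_rule=stop_rule, **kwargs)


def exact_perm_lm(design: pd.DataFrame, response: str = "road_pct", predictors=PREDICTORS) -> PermutationOLSResults:
    """Exhaustive-permutation regression for tiny designs (n ≤ 8).

    Implemented as an explicit loop over permutations with an independent
    per-permutation least-squares solve; serves as the oracle for the
    vectorised Monte-Carlo path.
    """
    cols = [c for c in predictors if c in design.columns]
    y = design[response].to_numpy(float)
    X = np.column_stack([np.ones(len(design)), design[cols].to_numpy(float)])
    n, k = X.shape
    if n > 8:
        raise ValueError("exhaustive enumeration limited to n <= 8")
    if n <= k or np.linalg.matrix_rank(X) < k:
        raise ValueError("design must be full rank with n > number of parameters")
    beta_obs = np.linalg.lstsq(X, y, rcond=None)[0]
    tol = 1e-12 * np.maximum(1.0, np.abs(beta_obs))
    counts = np.zeros(k)
    r2_count = 0
    fitted = X @ beta_obs
    ss_tot = float(((y - y.mean()) ** 2).sum())

    def _r2(resp, fit):
        return 1.0 - float(((resp - fit) ** 2).sum()) / ss_tot if ss_tot > 0 else 0.0

    r2_obs = _r2(y, fitted)
    total = 0
    for perm in itertools.permutations(y):
        yp = np.asarray(perm)
        b = np.linalg.lstsq(X, yp, rcond=None)[0]
        counts += np.abs(b) >= np.abs(beta_obs) - tol
        if _r2(yp, X @ b) >= r2_obs - 1e-12:
            r2_count += 1
        total += 1
    names = ["Intercept", *cols]
    adj = 1.0 - (1.0 - r2_obs) * (n - 1) / (n - k)
    model = PermutationOLS(design[response], design[cols], response_name=response)
    return PermutationOLSResults(
        model=model,
        params=pd.Series(beta_obs, index=names),
        iterations=pd.Series(total, index=names),
        pvalues=pd.Series(counts / total, index=names),
        rsquared=r2_obs,
        rsquared_adj=adj,
        omnibus_pvalue=r2_count / total,
        exact=True,
    )
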