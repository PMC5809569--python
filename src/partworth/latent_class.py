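"""Latent-class conditional logit estimation by multi-start EM.

Respondents are modelled as a finite mixture of C preference classes.
Class c has effects-coded part-worth vector ``beta_c`` (length P) and
share ``pi_c``; within a task, the probability of an alternative is the
softmax of its utility ``x @ beta_c``; a respondent belongs to one class
for all of their tasks, so the marginal likelihood of respondent i is

    L_i = sum_c pi_c * prod_t P(chosen_it | beta_c).

Estimation maximizes ``sum_i log L_i`` by EM with per-respondent
posteriors: the E-step computes membership probabilities ``h_ic``, the
M-step updates shares to the mean posterior and each ``beta_c`` by a
posterior-weighted Newton step on the conditional-logit likelihood (with
step-halving, so the EM objective never decreases).  Multiple random
starts guard against local optima; the best final log-likelihood wins.

Standard errors come from the inverse observed information of the
mixture log-likelihood at convergence (central finite differences of the
analytic score, shares parameterized as multinomial logits).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import chi2

from .data import ChoiceDataset, effects_columns
from .design import AttributeSpec

__all__ = [
    "LatentClassSolution",
    "FitIndexRow",
    "LrtResult",
    "choice_probabilities",
    "log_likelihood",
    "fit_latent_class",
    "posterior_assign",
    "compute_fit_indices",
    "entropy_r2",
    "select_classes",
    "bootstrap_lrt",
    "wald_tests",
]


def choice_probabilities(beta: np.ndarray, rows: np.ndarray) -> np.ndarray:
    """Conditional-logit probabilities for one task's effects-coded rows."""
    u = np.asarray(rows) @ np.asarray(beta)
    u = u - u.max()
    e = np.exp(u)
    return e / e.sum()


# ---------------------------------------------------------------------------
# internal dense representation

@dataclass
class _Arrays:
    X: np.ndarray        # (T, A, P)
    chosen: np.ndarray   # (T,) 0-based
    resp: np.ndarray     # (T,) respondent index
    ids: list[str]

    @property
    def n_resp(self) -> int:
        return len(self.ids)

    @property
    def n_params(self) -> int:
        return self.X.shape[2]


def _as_arrays(dataset: ChoiceDataset | _Arrays) -> _Arrays:
    if isinstance(dataset, _Arrays):
        return dataset
    X, chosen, resp, ids = dataset.to_arrays()
    return _Arrays(X, chosen, resp, ids)


def _class_logprobs(arr: _Arrays, beta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-task log probability of the chosen alternative and full (T, A) probs."""
    u = arr.X @ beta                       # (T, A)
    u = u - u.max(axis=1, keepdims=True)
    e = np.exp(u)
    denom = e.sum(axis=1)
    t_idx = np.arange(len(u))
    logp_chosen = u[t_idx, arr.chosen] - np.log(denom)
    return logp_chosen, e / denom[:, None]


def _resp_loglik(arr: _Arrays, betas: np.ndarray) -> np.ndarray:
    """(N, C) matrix of per-respondent conditional log-likelihoods."""
    C = betas.shape[0]
    L = np.empty((arr.n_resp, C))
    for c in range(C):
        logp, _ = _class_logprobs(arr, betas[c])
        L[:, c] = np.bincount(arr.resp, weights=logp, minlength=arr.n_resp)
    return L


def log_likelihood(
    dataset: ChoiceDataset | _Arrays, shares: np.ndarray, betas: np.ndarray
) -> float:
    """Mixture log-likelihood with respondent-level class membership."""
    arr = _as_arrays(dataset)
    betas = np.atleast_2d(np.asarray(betas, dtype=float))
    shares = np.asarray(shares, dtype=float)
    L = _resp_loglik(arr, betas)
    with np.errstate(divide="ignore"):
        return float(logsumexp(np.log(shares)[None, :] + L, axis=1).sum())


# ---------------------------------------------------------------------------
# weighted conditional-logit Newton (the M-step work-horse)

def _weighted_cl_objective(arr: _Arrays, beta: np.ndarray, w: np.ndarray, ridge: float) -> float:
    logp, _ = _class_logprobs(arr, beta)
    return float(w @ logp) - ridge * float(beta @ beta)


def _weighted_cl_newton(
    arr: _Arrays,
    beta0: np.ndarray,
    w: np.ndarray,
    ridge: float = 0.0,
    max_inner: int = 3,
    gtol: float = 1e-10,
) -> tuple[np.ndarray, float]:
    """Maximize the w-weighted conditional-logit log-likelihood by Newton steps.

    Step-halving guarantees the objective never decreases, which keeps the
    enclosing EM monotone.  Returns (beta, objective).
    """
    X, chosen = arr.X, arr.chosen
    t_idx = np.arange(X.shape[0])
    x_chosen = X[t_idx, chosen, :]
    beta = beta0.copy()
    obj = _weighted_cl_objective(arr, beta, w, ridge)
    eye = np.eye(arr.n_params)
    for _ in range(max_inner):
        _, P = _class_logprobs(arr, beta)
        xbar = np.einsum("ta,tap->tp", P, X)
        grad = w @ (x_chosen - xbar) - 2.0 * ridge * beta
        gnorm = np.abs(grad).max()
        if gnorm < gtol:
            break
        sw = np.sqrt(np.maximum(w, 0.0))
        Y = (np.sqrt(P) * sw[:, None])[:, :, None] * X
        Yf = Y.reshape(-1, arr.n_params)
        Z = sw[:, None] * xbar
        H = Yf.T @ Yf - Z.T @ Z + 2.0 * ridge * eye
        try:
            step = np.linalg.solve(H + 1e-10 * eye, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        scale = 1.0
        for _half in range(40):
            cand = beta + scale * step
            cand_obj = _weighted_cl_objective(arr, cand, w, ridge)
            if cand_obj >= obj - 1e-12:
                break
            scale *= 0.5
        else:
            break  # no improving step; keep current beta
        improved = cand_obj - obj
        beta, obj = cand, cand_obj
        if improved < 1e-12 * (abs(obj) + 1.0):
            break
    return beta, obj


# ---------------------------------------------------------------------------
# solution container

@dataclass
class LatentClassSolution:
    """A fitted C-class conditional-logit mixture.

    Classes are reported in decreasing share order.  ``coefficients`` are
    on the effects-coded scale (C x P); expanded zero-centered level
    utilities are available through :mod:`partworth.postestimation`.
    """

    n_classes: int
    shares: np.ndarray
    coefficients: np.ndarray
    loglik: float
    posterior: np.ndarray
    respondent_ids: list[str]
    attributes: list[AttributeSpec]
    column_map: list[tuple[int, int]]
    se: np.ndarray | None = None
    z: np.ndarray | None = None
    covariance: np.ndarray | None = field(default=None, repr=False)
    ll_trace: list[float] = field(default_factory=list, repr=False)
    n_starts: int = 1
    best_start: int = 0
    n_iter: int = 0
    converged: bool = True

    @property
    def n_respondents(self) -> int:
        return len(self.respondent_ids)

    def save(self, path: str | Path) -> None:
        payload = {
            "n_classes": self.n_classes,
            "shares": self.shares.tolist(),
            "coefficients": self.coefficients.tolist(),
            "se": None if self.se is None else self.se.tolist(),
            "z": None if self.z is None else self.z.tolist(),
            "loglik": self.loglik,
            "posterior": self.posterior.tolist(),
            "respondent_ids": list(self.respondent_ids),
            "column_map": [list(c) for c in self.column_map],
            "attributes": [
                {"id": a.attribute_id, "name": a.name, "levels": list(a.levels)}
                for a in self.attributes
            ],
            "n_starts": self.n_starts,
            "best_start": self.best_start,
            "n_iter": self.n_iter,
            "converged": self.converged,
        }
        Path(path).write_text(json.dumps(payload, indent=1) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "LatentClassSolution":
        d = json.loads(Path(path).read_text())
        return cls(
            n_classes=d["n_classes"],
            shares=np.asarray(d["shares"], dtype=float),
            coefficients=np.asarray(d["coefficients"], dtype=float),
            loglik=float(d["loglik"]),
            posterior=np.asarray(d["posterior"], dtype=float),
            respondent_ids=list(d["respondent_ids"]),
            attributes=[
                AttributeSpec(a["id"], a["name"], tuple(a["levels"]))
                for a in d["attributes"]
            ],
            column_map=[tuple(c) for c in d["column_map"]],
            se=None if d["se"] is None else np.asarray(d["se"], dtype=float),
            z=None if d["z"] is None else np.asarray(d["z"], dtype=float),
            n_starts=d.get("n_starts", 1),
            best_start=d.get("best_start", 0),
            n_iter=d.get("n_iter", 0),
            converged=d.get("converged", True),
        )


# ---------------------------------------------------------------------------
# EM driver

def _em_single_start(
    arr: _Arrays,
    n_classes: int,
    rng: np.random.Generator,
    tol: float,
    max_iter: int,
    ridge: float,
    max_inner: int,
) -> tuple[float, np.ndarray, np.ndarray, np.ndarray, list[float], bool, int]:
    N, C, P = arr.n_resp, n_classes, arr.n_params
    if C == 1:
        h = np.ones((N, 1))
    else:
        h = rng.dirichlet(np.ones(C), size=N)
    betas = np.zeros((C, P))
    pi = np.full(C, 1.0 / C)
    trace: list[float] = []
    converged = False
    w_task = np.empty(arr.X.shape[0])
    inner = 50 if C == 1 else max_inner
    prev_ll = -np.inf
    for it in range(1, max_iter + 1):
        # M-step against the current posterior
        pi = np.clip(h.mean(axis=0), 1e-12, None)
        pi = pi / pi.sum()
        for c in range(C):
            w_task[:] = h[arr.resp, c]
            betas[c], _ = _weighted_cl_newton(
                arr, betas[c], w_task, ridge=ridge, max_inner=inner
            )
        # E-step: posteriors and mixture log-likelihood
        L = _resp_loglik(arr, betas)
        M = np.log(pi)[None, :] + L
        lse = logsumexp(M, axis=1)
        ll = float(lse.sum())
        h = np.exp(M - lse[:, None])
        trace.append(ll)
        if it > 1 and abs(ll - prev_ll) < tol * (abs(ll) + 1.0):
            converged = True
            break
        prev_ll = ll
    return trace[-1], pi, betas, h, trace, converged, len(trace)


def fit_latent_class(
    dataset: ChoiceDataset | _Arrays,
    n_classes: int,
    n_starts: int = 10,
    seed: int = 0,
    tol: float = 1e-8,
    max_iter: int = 2000,
    ridge: float = 0.0,
    max_inner: int = 3,
    compute_se: bool = True,
    attributes: list[AttributeSpec] | None = None,
) -> LatentClassSolution:
    """Fit a C-class conditional-logit mixture.

    Parameters
    ----------
    dataset
        Estimation data (holdout tasks should already be removed).
    n_classes
        Number of latent classes C >= 1.
    n_starts
        Independent random initializations of the posterior matrix; the
        start with the best final log-likelihood is returned (ties go to
        the lower start index).  A single start is used when C == 1 (the
        likelihood is concave).
    ridge
        Optional quadratic stabilizing penalty on the coefficients during
        the M-step (default 0 = pure maximum likelihood).
    """
    if n_classes < 1:
        raise ValueError("n_classes must be >= 1")
    arr = _as_arrays(dataset)
    if n_classes > arr.n_resp:
        raise ValueError("more classes than respondents")
    if attributes is None:
        if not isinstance(dataset, ChoiceDataset):
            raise ValueError("attributes required when fitting from raw arrays")
        attributes = dataset.attributes
    if n_classes == 1:
        n_starts = 1
    best = None
    for s in range(n_starts):
        rng = np.random.default_rng([seed, s])
        result = _em_single_start(
            arr, n_classes, rng, tol, max_iter, ridge, max_inner
        )
        if best is None or result[0] > best[1][0]:
            best = (s, result)
    best_start, (ll, pi, betas, h, trace, converged, n_iter) = best

    order = np.argsort(-pi, kind="stable")  # canonical: decreasing share
    pi, betas, h = pi[order], betas[order], h[:, order]

    solution = LatentClassSolution(
        n_classes=n_classes,
        shares=pi,
        coefficients=betas,
        loglik=ll,
        posterior=h,
        respondent_ids=arr.ids,
        attributes=list(attributes),
        column_map=effects_columns(attributes),
        ll_trace=trace,
        n_starts=n_starts,
        best_start=best_start,
        n_iter=n_iter,
        converged=converged,
    )
    if compute_se:
        _attach_standard_errors(solution, arr)
    return solution


# ---------------------------------------------------------------------------
# observed information / standard errors

def _mixture_score(arr: _Arrays, pi: np.ndarray, betas: np.ndarray) -> np.ndarray:
    """Analytic score of the mixture LL in (beta_1..C, alpha_1..C-1) order."""
    C, P = betas.shape
    L = _resp_loglik(arr, betas)
    M = np.log(pi)[None, :] + L
    h = np.exp(M - logsumexp(M, axis=1)[:, None])
    t_idx = np.arange(arr.X.shape[0])
    x_chosen = arr.X[t_idx, arr.chosen, :]
    parts = []
    for c in range(C):
        _, Pm = _class_logprobs(arr, betas[c])
        xbar = np.einsum("ta,tap->tp", Pm, arr.X)
        parts.append(h[arr.resp, c] @ (x_chosen - xbar))
    score = np.concatenate(parts)
    if C > 1:
        score = np.concatenate([score, (h - pi[None, :]).sum(axis=0)[: C - 1]])
    return score


def _theta_to_params(theta: np.ndarray, C: int, P: int) -> tuple[np.ndarray, np.ndarray]:
    betas = theta[: C * P].reshape(C, P)
    if C == 1:
        return np.ones(1), betas
    alpha = np.concatenate([theta[C * P :], [0.0]])
    e = np.exp(alpha - alpha.max())
    return e / e.sum(), betas


def observed_information(arr: _Arrays, pi: np.ndarray, betas: np.ndarray) -> np.ndarray:
    """Observed information of the mixture LL (central FD of the analytic score)."""
    C, P = betas.shape
    if C == 1:
        alpha = np.empty(0)
    else:
        alpha = np.log(np.clip(pi[:-1], 1e-300, None) / pi[-1])
    theta = np.concatenate([betas.ravel(), alpha])
    dim = len(theta)
    info = np.empty((dim, dim))
    for j in range(dim):
        eps = 1e-5 * (1.0 + abs(theta[j]))
        tp, tm = theta.copy(), theta.copy()
        tp[j] += eps
        tm[j] -= eps
        sp = _mixture_score(arr, *_theta_to_params(tp, C, P))
        sm = _mixture_score(arr, *_theta_to_params(tm, C, P))
        info[:, j] = (sm - sp) / (2.0 * eps)
    return 0.5 * (info + info.T)


def _attach_standard_errors(solution: LatentClassSolution, arr: _Arrays) -> None:
    C, P = solution.coefficients.shape
    info = observed_information(arr, solution.shares, solution.coefficients)
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(info)
    solution.covariance = cov
    var = np.clip(np.diag(cov)[: C * P].reshape(C, P), 0.0, None)
    solution.se = np.sqrt(var)
    with np.errstate(divide="ignore", invalid="ignore"):
        solution.z = np.where(solution.se > 0, solution.coefficients / solution.se, np.nan)


# ---------------------------------------------------------------------------
# post-fit summaries

def posterior_assign(solution: LatentClassSolution) -> np.ndarray:
    """1-based modal class per respondent; ties go to the lower class index."""
    return np.argmax(solution.posterior, axis=1) + 1


def entropy_r2(posterior: np.ndarray) -> float:
    """1 - (total posterior entropy) / (N ln C); 1.0 for C == 1.

    0 means class assignment is uninformative (uniform posteriors),
    1 means perfect separation (degenerate posteriors).
    """
    h = np.asarray(posterior, dtype=float)
    n, c = h.shape
    if c == 1:
        return 1.0
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(h > 0, -h * np.log(h), 0.0)
    return float(1.0 - terms.sum() / (n * np.log(c)))


@dataclass(frozen=True)
class FitIndexRow:
    """Parameter accounting and information criteria for one class count."""

    n_classes: int
    n_params: int
    df: int
    loglik: float
    aic: float
    aic3: float
    bic: float
    caic: float
    entropy_r2: float | None = None

    def as_dict(self) -> dict:
        return {
            "classes": self.n_classes,
            "parameters": self.n_params,
            "df": self.df,
            "loglik": self.loglik,
            "AIC": self.aic,
            "AIC3": self.aic3,
            "BIC": self.bic,
            "CAIC": self.caic,
            "entropy_r2": self.entropy_r2,
        }


def compute_fit_indices(
    loglik: float,
    n_classes: int,
    n_coefficients: int,
    n_respondents: int,
    entropy: float | None = None,
) -> FitIndexRow:
    """Information criteria for a C-class solution.

    ``p = C * P + (C - 1)`` free parameters (per-class coefficients plus
    shares); sample size for BIC/CAIC/df is the number of respondents.
    AIC = -2LL + 2p, AIC3 = -2LL + 3p, BIC = -2LL + p ln N,
    CAIC = -2LL + p (ln N + 1).
    """
    p = n_classes * n_coefficients + (n_classes - 1)
    n = n_respondents
    m2ll = -2.0 * loglik
    return FitIndexRow(
        n_classes=n_classes,
        n_params=p,
        df=n - p,
        loglik=loglik,
        aic=m2ll + 2.0 * p,
        aic3=m2ll + 3.0 * p,
        bic=m2ll + p * np.log(n) if p else m2ll,
        caic=m2ll + p * (np.log(n) + 1.0) if p else m2ll,
        entropy_r2=entropy,
    )


def select_classes(
    dataset: ChoiceDataset,
    class_counts: list[int] | range = range(1, 6),
    **fit_kwargs,
) -> tuple[pd.DataFrame, dict[int, LatentClassSolution]]:
    """Fit each candidate class count and tabulate fit indices."""
    rows, solutions = [], {}
    fit_kwargs.setdefault("compute_se", False)
    for c in class_counts:
        sol = fit_latent_class(dataset, c, **fit_kwargs)
        solutions[c] = sol
        rows.append(
            compute_fit_indices(
                sol.loglik,
                c,
                sol.coefficients.shape[1],
                sol.n_respondents,
                entropy=entropy_r2(sol.posterior),
            ).as_dict()
        )
    return pd.DataFrame(rows).set_index("classes"), solutions


# ---------------------------------------------------------------------------
# bootstrap likelihood-difference test

@dataclass(frozen=True)
class LrtResult:
    """-2 log-likelihood difference with a parametric-bootstrap p-value."""

    statistic: float
    n_bootstrap: int
    p_value: float
    bootstrap_statistics: tuple[float, ...] = ()


def _simulate_from_solution(
    dataset: ChoiceDataset, solution: LatentClassSolution, rng: np.random.Generator
) -> ChoiceDataset:
    """Parametric-bootstrap dataset: same respondents and tasks, choices
    redrawn from the fitted mixture (class from shares, then conditional
    logit)."""
    from .data import ChoiceObservation

    arr = _as_arrays(dataset)
    C = solution.n_classes
    probs = np.stack(
        [_class_logprobs(arr, solution.coefficients[c])[1] for c in range(C)]
    )  # (C, T, A)
    z = rng.choice(C, size=arr.n_resp, p=solution.shares)
    p_task = probs[z[arr.resp], np.arange(arr.X.shape[0])]  # (T, A)
    u = rng.random(arr.X.shape[0])
    draws = (p_task.cumsum(axis=1) < u[:, None]).sum(axis=1)
    observations = [
        ChoiceObservation(o.respondent_id, o.version, o.position, int(d) + 1)
        for o, d in zip(dataset.observations, draws)
    ]
    return ChoiceDataset(dataset.attributes, dataset.tasks, observations)


def bootstrap_lrt(
    dataset: ChoiceDataset,
    c0: int,
    c1: int,
    n_bootstrap: int = 100,
    seed: int = 0,
    n_starts: int = 3,
    sol0: LatentClassSolution | None = None,
    sol1: LatentClassSolution | None = None,
    **fit_kwargs,
) -> LrtResult:
    """Parametric-bootstrap -2LL difference test of c0 vs c1 classes.

    The null distribution comes from datasets simulated under the fitted
    c0 model, each refit at both class counts (with ``n_starts`` random
    starts — fewer than a headline fit, for tractability); the p-value is
    the proportion of bootstrap statistics at or above the observed one.
    """
    if c1 <= c0:
        raise ValueError("c1 must exceed c0")
    if n_bootstrap < 1:
        raise ValueError("n_bootstrap must be >= 1")
    fit_kwargs.setdefault("compute_se", False)
    fit_kwargs.setdefault("max_inner", 3)
    if sol0 is None:
        sol0 = fit_latent_class(dataset, c0, n_starts=n_starts, seed=seed, **fit_kwargs)
    if sol1 is None:
        sol1 = fit_latent_class(dataset, c1, n_starts=n_starts, seed=seed, **fit_kwargs)
    observed = -2.0 * (sol0.loglik - sol1.loglik)
    stats = []
    for b in range(n_bootstrap):
        rng = np.random.default_rng([seed, 7_777, b])
        boot = _simulate_from_solution(dataset, sol0, rng)
        b0 = fit_latent_class(boot, c0, n_starts=n_starts, seed=seed + b + 1, **fit_kwargs)
        b1 = fit_latent_class(boot, c1, n_starts=n_starts, seed=seed + b + 1, **fit_kwargs)
        stats.append(-2.0 * (b0.loglik - b1.loglik))
    stats_arr = np.asarray(stats)
    return LrtResult(
        statistic=float(observed),
        n_bootstrap=n_bootstrap,
        p_value=float(np.mean(stats_arr >= observed)),
        bootstrap_statistics=tuple(float(s) for s in stats_arr),
    )


# ---------------------------------------------------------------------------
# Wald tests

def wald_tests(solution: LatentClassSolution) -> pd.DataFrame:
    """Per-attribute Wald tests from the fitted covariance.

    For every attribute: a joint-zero test of its K-1 coefficients within
    each class (df = K-1), and a cross-class equality test of its
    coefficients (df = (C-1)(K-1); NaN when C == 1).  Attributes whose
    covariance block is singular are reported as NaN.
    """
    if solution.covariance is None:
        raise ValueError("solution has no covariance; refit with compute_se=True")
    C, P = solution.coefficients.shape
    cov = solution.covariance
    offsets: dict[int, list[int]] = {}
    for j, (aid, _level) in enumerate(solution.column_map):
        offsets.setdefault(aid, []).append(j)
    rows = []
    for attr in solution.attributes:
        idx = np.asarray(offsets[attr.attribute_id])
        k1 = len(idx)
        row: dict[str, object] = {"attribute": attr.name}
        for c in range(C):
            b = solution.coefficients[c, idx]
            block = cov[np.ix_(c * P + idx, c * P + idx)]
            try:
                w = float(b @ np.linalg.solve(block, b))
                pval = float(chi2.sf(w, df=k1))
            except np.linalg.LinAlgError:
                w, pval = np.nan, np.nan
            row[f"wald_zero_class{c + 1}"] = w
            row[f"p_zero_class{c + 1}"] = pval
        if C > 1:
            d = np.concatenate(
                [solution.coefficients[c, idx] - solution.coefficients[0, idx]
                 for c in range(1, C)]
            )
            sel = np.concatenate([c * P + idx for c in range(C)])
            sub = cov[np.ix_(sel, sel)]
            L = np.zeros(((C - 1) * k1, C * k1))
            for c in range(1, C):
                L[(c - 1) * k1 : c * k1, 0:k1] = -np.eye(k1)
                L[(c - 1) * k1 : c * k1, c * k1 : (c + 1) * k1] = np.eye(k1)
            v = L @ sub @ L.T
            try:
                w = float(d @ np.linalg.solve(v, d))
                pval = float(chi2.sf(w, df=(C - 1) * k1))
            except np.linalg.LinAlgError:
                w, pval = np.nan, np.nan
            row["wald_equal"] = w
            row["p_equal"] = pval
            row["df_equal"] = (C - 1) * k1
        else:
            row["wald_equal"] = np.nan
            row["p_equal"] = np.nan
            row["df_equal"] = 0
        row["df_zero"] = k1
        rows.append(row)
    return pd.DataFrame(rows).set_index("attribute")
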