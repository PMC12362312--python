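"""Traditional missing-data treatments: PM, TW, EM, and MI baselines.

* Person-mean (PM): an NA cell takes the examinee's rounded observed mean.
* Two-way (TW): PM_i + IM_j - GM (person, item, grand observed means),
  clipped to [0, 1] and rounded.
* EM: single imputation under a multivariate-normal working model on the
  item columns; conditional expectations fill NA cells, the mean and
  (ridge-regularised) covariance are re-estimated until convergence, and
  the final expectations are clipped and rounded.
* MI: multiple imputation by chained logistic regressions, m completed
  datasets with Bayesian-bootstrap parameter draws and Bernoulli cell
  draws; downstream metrics are pooled by averaging across the m datasets.

All rounding is half-up (an expectation of exactly 0.5 becomes 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import LogisticRegression

from .dina_core import ResponseMatrix

logger = logging.getLogger(__name__)


def _round_half_up(v: np.ndarray) -> np.ndarray:
    return np.floor(v + 0.5)


def _check_rows_items(x: ResponseMatrix, need_items: bool = False) -> None:
    nan = np.isnan(x.values)
    if nan.all(axis=1).any():
        raise ValueError("an examinee has no observed responses")
    if need_items and nan.all(axis=0).any():
        raise ValueError("an item has no observed responses")


@dataclass
class MiResult:
    """m completed datasets from multiple imputation."""

    datasets: list[ResponseMatrix]

    @property
    def m(self) -> int:
        return len(self.datasets)


def impute_pm(x: ResponseMatrix) -> ResponseMatrix:
    """Person-mean imputation."""
    _check_rows_items(x)
    values = x.values
    pm = np.nanmean(values, axis=1)
    out = values.copy()
    nan_r, nan_c = np.nonzero(np.isnan(values))
    out[nan_r, nan_c] = _round_half_up(pm[nan_r])
    return ResponseMatrix(out)


def impute_tw(x: ResponseMatrix) -> ResponseMatrix:
    """Two-way imputation: person mean + item mean - grand mean."""
    _check_rows_items(x, need_items=True)
    values = x.values
    pm = np.nanmean(values, axis=1)
    im = np.nanmean(values, axis=0)
    gm = np.nanmean(values)
    out = values.copy()
    nan_r, nan_c = np.nonzero(np.isnan(values))
    tw = np.clip(pm[nan_r] + im[nan_c] - gm, 0.0, 1.0)
    out[nan_r, nan_c] = _round_half_up(tw)
    return ResponseMatrix(out)


def _mvn_em(
    values: np.ndarray, tol: float, max_iter: int, ridge: float
) -> tuple[np.ndarray, np.ndarray]:
    """EM for a multivariate normal with missing cells.

    Returns the matrix of conditional expectations for the missing cells
    (observed cells untouched) and the observed-data log-likelihood trace.
    Rows are grouped by missingness pattern so the per-pattern linear
    solves are shared.
    """
    n, j = values.shape
    nan = np.isnan(values)
    filled = np.where(nan, np.nanmean(values, axis=0), values)
    mu = filled.mean(axis=0)
    sigma = np.cov(filled, rowvar=False, bias=True) + ridge * np.eye(j)

    patterns, inverse = np.unique(nan, axis=0, return_inverse=True)
    trace: list[float] = []
    expect = filled.copy()
    for _ in range(max_iter):
        s1 = np.zeros(j)
        s2 = np.zeros((j, j))
        loglik = 0.0
        for pidx, pattern in enumerate(patterns):
            rows = np.flatnonzero(inverse == pidx)
            o = ~pattern
            m = pattern
            xo = values[np.ix_(rows, np.flatnonzero(o))]
            so_oo = sigma[np.ix_(np.flatnonzero(o), np.flatnonzero(o))]
            # observed-block likelihood contribution
            chol = np.linalg.cholesky(so_oo)
            dev = xo - mu[o]
            sol = np.linalg.solve(so_oo, dev.T)
            logdet = 2.0 * np.log(np.diag(chol)).sum()
            loglik += float(
                -0.5 * (dev.T * sol).sum()
                - 0.5 * len(rows) * (logdet + o.sum() * np.log(2 * np.pi))
            )
            if m.any():
                so_mo = sigma[np.ix_(np.flatnonzero(m), np.flatnonzero(o))]
                cond_mean = mu[m] + (so_mo @ sol).T
                so_mm = sigma[np.ix_(np.flatnonzero(m), np.flatnonzero(m))]
                cond_cov = so_mm - so_mo @ np.linalg.solve(so_oo, so_mo.T)
                expect[np.ix_(rows, np.flatnonzero(m))] = cond_mean
                s2[np.ix_(np.flatnonzero(m), np.flatnonzero(m))] += len(rows) * cond_cov
            s1 += expect[rows].sum(axis=0)
            s2 += expect[rows].T @ expect[rows]
        trace.append(loglik)
        mu_new = s1 / n
        sigma_new = s2 / n - np.outer(mu_new, mu_new) + ridge * np.eye(j)
        change = max(np.abs(mu_new - mu).max(), np.abs(sigma_new - sigma).max())
        mu, sigma = mu_new, sigma_new
        if change < tol:
            break
    return expect, np.asarray(trace)


def impute_em(
    x: ResponseMatrix,
    tol: float = 1e-5,
    max_iter: int = 500,
    ridge: float = 1e-4,
) -> ResponseMatrix:
    """EM-based single imputation (normal working model, then dichotomise)."""
    _check_rows_items(x, need_items=True)
    values = x.values
    if not np.isnan(values).any():
        return x.copy()
    try:
        expect, _ = _mvn_em(values, tol, max_iter, ridge)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - ridge guards this
        raise np.linalg.LinAlgError(f"singular working covariance: {exc}") from exc
    out = values.copy()
    nan = np.isnan(values)
    out[nan] = _round_half_up(np.clip(expect[nan], 0.0, 1.0))
    return ResponseMatrix(out)


def em_working_loglik_trace(
    x: ResponseMatrix, tol: float = 1e-5, max_iter: int = 500, ridge: float = 1e-4
) -> np.ndarray:
    """Observed-data log-likelihood trace of the EM working model."""
    return _mvn_em(x.values, tol, max_iter, ridge)[1]


def impute_mi(
    x: ResponseMatrix,
    m: int = 20,
    seed: int | None = None,
    burn_in: int = 10,
) -> MiResult:
    """Multiple imputation by chained logistic regressions.

    Each of the ``m`` chains starts from Bernoulli(item mean) fills, then
    cycles ``burn_in`` times over the items in ascending-missingness order.
    Per item and cycle a ridge-penalised logistic regression is fit on the
    originally-observed rows with Dirichlet(1, ..., 1) observation weights
    (a Bayesian-bootstrap draw of the coefficients); missing cells are
    redrawn as Bernoulli from the predicted probabilities.
    """
    _check_rows_items(x, need_items=True)
    values = x.values
    nan = np.isnan(values)
    if not nan.any():
        return MiResult([x.copy() for _ in range(m)])
    item_means = np.nanmean(values, axis=0)
    counts = nan.sum(axis=0)
    items = np.flatnonzero(counts > 0)
    order = items[np.argsort(counts[items], kind="stable")]
    chains = np.random.SeedSequence(seed).spawn(m)
    datasets = []
    for chain_ss in chains:
        rng = np.random.default_rng(chain_ss)
        work = values.copy()
        work[nan] = (rng.random(int(nan.sum())) < item_means[np.nonzero(nan)[1]]).astype(float)
        for _ in range(burn_in):
            for jj in order:
                obs_rows = ~nan[:, jj]
                mis_rows = nan[:, jj]
                other = np.ones(values.shape[1], dtype=bool)
                other[jj] = False
                y = values[obs_rows, jj].astype(int)
                if np.unique(y).size == 1:
                    work[mis_rows, jj] = float(y[0])
                    continue
                w = rng.dirichlet(np.ones(int(obs_rows.sum()))) * obs_rows.sum()
                # liblinear: fastest exact solver at these problem sizes
                clf = LogisticRegression(C=1.0, max_iter=200, solver="liblinear")
                clf.fit(work[obs_rows][:, other], y, sample_weight=w)
                p1 = clf.predict_proba(work[mis_rows][:, other])[
                    :, list(clf.classes_).index(1)
                ]
                work[mis_rows, jj] = (rng.random(p1.shape[0]) < p1).astype(float)
        datasets.append(ResponseMatrix(work))
    return MiResult(datasets)
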