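"""DINA model machinery: data generation, EM estimation, MAP classification.

The DINA (deterministic inputs, noisy "and" gate) model is a conjunctive
cognitive diagnosis model. An examinee with attribute profile
``alpha in {0,1}^K`` produces the ideal response ``eta_ij = prod_k
alpha_ik^{q_jk}`` on item j, and the observed response is a noisy version
of it:

    P(X_ij = 1 | alpha_i) = (1 - s_j)^{eta_ij} * g_j^{1 - eta_ij}

with slipping parameter ``s_j`` and guessing parameter ``g_j``. Estimation
is marginal-maximum-likelihood EM over all 2^K latent classes with an
unstructured class prior; missing cells contribute nothing to the
likelihood (the per-person likelihood is a product over observed items
only). Examinees are classified by the maximum a posteriori (MAP) profile.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import logsumexp

logger = logging.getLogger(__name__)

_CLAMP = 1e-4  # estimation clamp for s, g and prior components


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class QMatrix:
    """Binary item x attribute incidence matrix (q_jk = 1 iff item j requires k)."""

    entries: np.ndarray

    def __post_init__(self) -> None:
        q = np.asarray(self.entries, dtype=int)
        if q.ndim != 2:
            raise ValueError("Q matrix must be 2-dimensional")
        if not np.isin(q, (0, 1)).all():
            raise ValueError("Q matrix entries must be 0/1")
        if (q.sum(axis=1) == 0).any():
            raise ValueError("Q matrix has an all-zero row (item measures no attribute)")
        if (q.sum(axis=0) == 0).any():
            raise ValueError("Q matrix has an all-zero column (attribute never measured)")
        object.__setattr__(self, "entries", q)

    @property
    def n_items(self) -> int:
        return self.entries.shape[0]

    @property
    def n_attributes(self) -> int:
        return self.entries.shape[1]

    @classmethod
    def from_csv(cls, path: str | Path) -> "QMatrix":
        return cls(pd.read_csv(path, header=None).to_numpy())

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.entries).to_csv(path, header=False, index=False)


@dataclass(frozen=True)
class AttributeProfileSet:
    """N x K binary mastery profiles plus the population spec they came from."""

    profiles: np.ndarray
    rho: float = 0.5
    cut_point: float = 0.0

    def __post_init__(self) -> None:
        p = np.asarray(self.profiles, dtype=int)
        if p.ndim != 2 or not np.isin(p, (0, 1)).all():
            raise ValueError("profiles must be an N x K binary matrix")
        object.__setattr__(self, "profiles", p)

    @property
    def n_examinees(self) -> int:
        return self.profiles.shape[0]

    @property
    def n_attributes(self) -> int:
        return self.profiles.shape[1]


@dataclass(frozen=True)
class ItemParams:
    """Per-item slipping (s) and guessing (g) probabilities."""

    s: np.ndarray
    g: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.s, dtype=float)
        g = np.asarray(self.g, dtype=float)
        if s.shape != g.shape or s.ndim != 1:
            raise ValueError("s and g must be 1-d vectors of equal length")
        if ((s <= 0) | (s >= 1) | (g <= 0) | (g >= 1)).any():
            raise ValueError("s and g must lie strictly inside (0, 1)")
        object.__setattr__(self, "s", s)
        object.__setattr__(self, "g", g)

    @property
    def n_items(self) -> int:
        return self.s.shape[0]


@dataclass
class ResponseMatrix:
    """Dichotomous N x J response matrix; missing cells are stored as NaN.

    ``values`` is a float array over {0.0, 1.0, NaN}; ``mask`` is the
    derived binary missingness indicator (1 exactly where NaN).
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("response matrix must be 2-dimensional")
        observed = v[~np.isnan(v)]
        if not np.isin(observed, (0.0, 1.0)).all():
            raise ValueError("non-missing responses must be 0/1")
        self.values = v

    @property
    def mask(self) -> np.ndarray:
        """Binary missingness indicator (1 = missing)."""
        return np.isnan(self.values).astype(int)

    @property
    def n_examinees(self) -> int:
        return self.values.shape[0]

    @property
    def n_items(self) -> int:
        return self.values.shape[1]

    @property
    def missing_rate(self) -> float:
        return float(np.isnan(self.values).mean())

    def copy(self) -> "ResponseMatrix":
        return ResponseMatrix(self.values.copy())

    @classmethod
    def from_csv(cls, path: str | Path, na_token: str = "NA") -> "ResponseMatrix":
        df = pd.read_csv(path, na_values=[na_token], keep_default_na=False)
        return cls(df.to_numpy(dtype=float))

    def to_csv(self, path: str | Path, na_token: str = "NA") -> None:
        df = pd.DataFrame(
            self.values, columns=[f"item{j + 1}" for j in range(self.n_items)]
        )
        df.to_csv(path, index=False, na_rep=na_token, float_format="%.0f")


@dataclass
class DinaFit:
    """Result of the DINA EM fit."""

    item_params: ItemParams
    prior: np.ndarray  # over all 2^K profiles, lexicographic order
    posterior: np.ndarray  # N x 2^K
    map_profiles: np.ndarray  # N x K binary
    loglik_trace: np.ndarray
    converged: bool
    n_iter: int

    @property
    def loglik(self) -> float:
        return float(self.loglik_trace[-1])

    def to_json(self, path: str | Path) -> None:
        payload = {
            "s": self.item_params.s.tolist(),
            "g": self.item_params.g.tolist(),
            "prior": self.prior.tolist(),
            "converged": self.converged,
            "n_iter": self.n_iter,
            "loglik": self.loglik,
        }
        Path(path).write_text(json.dumps(payload, indent=1))


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


def enumerate_profiles(k: int) -> np.ndarray:
    """All 2^k binary profiles in lexicographic order ((0,...,0) first)."""
    return np.array(list(itertools.product((0, 1), repeat=k)), dtype=int)


def ideal_responses(profiles: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Conjunctive ideal response matrix eta: rows profiles, columns items."""
    profiles = np.atleast_2d(np.asarray(profiles, dtype=int))
    q = np.asarray(q, dtype=int)
    # eta = 1 iff the profile masters every required attribute
    return (profiles[:, None, :] >= q[None, :, :]).all(axis=2).astype(int)


def irf(profile: np.ndarray, q_row: np.ndarray, s_j: float, g_j: float) -> float:
    """DINA item response probability for one profile on one item."""
    profile = np.asarray(profile, dtype=int)
    q_row = np.asarray(q_row, dtype=int)
    if profile.shape != q_row.shape:
        raise ValueError("profile and q_row must have the same length")
    eta = int((profile >= q_row).all())
    return (1.0 - s_j) if eta else g_j


def response_probabilities(
    profiles: np.ndarray, q: QMatrix, params: ItemParams
) -> np.ndarray:
    """Correct-response probability matrix P (rows profiles, columns items)."""
    eta = ideal_responses(profiles, q.entries)
    return np.where(eta == 1, 1.0 - params.s, params.g)


def simulate_profiles(
    n: int, k: int, rho: float = 0.5, seed: int | None = None
) -> AttributeProfileSet:
    """Draw attribute profiles from a dichotomized multivariate normal.

    Latent vectors are K-variate standard normal with exchangeable
    correlation ``rho``; a profile entry is 1 iff the latent value is >= 0
    (cut point at the mean, so each attribute is mastered by half the
    population marginally).
    """
    if n < 1 or k < 1:
        raise ValueError("n and k must be positive")
    if k > 1 and not (-1.0 / (k - 1) < rho < 1.0):
        raise ValueError(f"rho={rho} gives a non-positive-definite covariance for k={k}")
    rng = np.random.default_rng(seed)
    cov = np.full((k, k), rho)
    np.fill_diagonal(cov, 1.0)
    latent = rng.multivariate_normal(np.zeros(k), cov, size=n, method="cholesky")
    return AttributeProfileSet((latent >= 0.0).astype(int), rho=rho)


def generate_q_matrix(j: int, k: int, seed: int | None = None) -> QMatrix:
    """Random Q matrix: i.i.d. Bernoulli(0.5) entries (U(0,1) cut at 0.5).

    Rows that come out all-zero are redrawn (an item must measure at least
    one attribute); if any attribute ends up measured by no item the whole
    matrix is redrawn.
    """
    if not j >= k >= 1:
        raise ValueError("need j >= k >= 1")
    rng = np.random.default_rng(seed)
    for _ in range(1000):
        q = (rng.random((j, k)) < 0.5).astype(int)
        for row in range(j):
            tries = 0
            while q[row].sum() == 0:
                q[row] = (rng.random(k) < 0.5).astype(int)
                tries += 1
                if tries > 1000:  # pragma: no cover - p = 2^-1000k
                    raise RuntimeError("row redraw limit exceeded")
        if (q.sum(axis=0) > 0).all():
            return QMatrix(q)
    raise RuntimeError("Q matrix redraw limit exceeded")  # pragma: no cover


def simulate_item_params(
    j: int, low: float = 0.05, high: float = 0.25, seed: int | None = None
) -> ItemParams:
    """Slipping and guessing drawn i.i.d. from U(low, high) per item."""
    rng = np.random.default_rng(seed)
    return ItemParams(s=rng.uniform(low, high, j), g=rng.uniform(low, high, j))


def simulate_responses(
    profiles: AttributeProfileSet,
    q: QMatrix,
    params: ItemParams,
    seed: int | None = None,
) -> ResponseMatrix:
    """Complete dichotomous responses: X_ij = 1 iff u_ij <= P_j(alpha_i)."""
    if profiles.n_attributes != q.n_attributes:
        raise ValueError("profiles and Q matrix disagree on K")
    if params.n_items != q.n_items:
        raise ValueError("item parameters and Q matrix disagree on J")
    rng = np.random.default_rng(seed)
    p = response_probabilities(profiles.profiles, q, params)
    u = rng.random(p.shape)
    return ResponseMatrix((u <= p).astype(float))


# ---------------------------------------------------------------------------
# estimation
# ---------------------------------------------------------------------------


def fit_dina_em(
    data: ResponseMatrix,
    q: QMatrix,
    tol: float = 1e-4,
    max_iter: int = 1000,
) -> DinaFit:
    """Marginal-maximum-likelihood EM for the DINA model.

    Missing cells are skipped in the per-person likelihood (ignorable by
    construction). The latent-class prior is an unstructured mixing
    proportion vector over all 2^K profiles. Convergence is declared when
    the largest absolute change over (s, g, prior) drops below ``tol``.
    """
    values = data.values
    observed = ~np.isnan(values)
    if (observed.sum(axis=0) == 0).any():
        raise ValueError("an item has no observed responses")

    n, j = values.shape
    k = q.n_attributes
    profiles = enumerate_profiles(k)
    eta = ideal_responses(profiles, q.entries)  # C x J

    y = np.nan_to_num(values, nan=0.0) * observed  # 0-filled, masked
    obs = observed.astype(float)

    constant_items = [
        jj
        for jj in range(j)
        if np.unique(values[observed[:, jj], jj]).size == 1
    ]
    if constant_items:
        logger.warning(
            "items %s have all-identical observed responses; estimates will clamp",
            constant_items,
        )

    s = np.full(j, 0.2)
    g = np.full(j, 0.2)
    prior = np.full(eta.shape[0], 1.0 / eta.shape[0])
    trace: list[float] = []
    converged = False
    it = 0

    for it in range(1, max_iter + 1):
        p = np.where(eta == 1, 1.0 - s, g)  # C x J
        logp = np.log(p)
        log1mp = np.log1p(-p)
        # per-person, per-class log-likelihood over observed cells only
        ll = y @ logp.T + (obs - y) @ log1mp.T  # N x C
        logpost = ll + np.log(prior)
        norm = logsumexp(logpost, axis=1)
        trace.append(float(norm.sum()))
        post = np.exp(logpost - norm[:, None])

        n_jc = obs.T @ post  # J x C expected observed counts
        r_jc = y.T @ post  # expected observed correct counts
        with np.errstate(invalid="ignore", divide="ignore"):
            g_new = ((1 - eta.T) * r_jc).sum(axis=1) / np.maximum(
                ((1 - eta.T) * n_jc).sum(axis=1), 1e-300
            )
            one_minus_s = (eta.T * r_jc).sum(axis=1) / np.maximum(
                (eta.T * n_jc).sum(axis=1), 1e-300
            )
        g_new = np.clip(g_new, _CLAMP, 1.0 - _CLAMP)
        s_new = np.clip(1.0 - one_minus_s, _CLAMP, 1.0 - _CLAMP)
        prior_new = np.clip(post.mean(axis=0), _CLAMP, 1.0 - _CLAMP)
        prior_new /= prior_new.sum()

        change = max(
            np.abs(s_new - s).max(),
            np.abs(g_new - g).max(),
            np.abs(prior_new - prior).max(),
        )
        s, g, prior = s_new, g_new, prior_new
        if change < tol:
            converged = True
            break

    if ((1.0 - s) <= g).any():
        logger.info(
            "monotonicity 1-s > g violated for items %s (not enforced)",
            np.flatnonzero((1.0 - s) <= g).tolist(),
        )

    # final E-step with converged parameters
    p = np.where(eta == 1, 1.0 - s, g)
    ll = y @ np.log(p).T + (obs - y) @ np.log1p(-p).T
    logpost = ll + np.log(prior)
    norm = logsumexp(logpost, axis=1)
    trace.append(float(norm.sum()))
    post = np.exp(logpost - norm[:, None])

    map_idx = post.argmax(axis=1)  # first max = lexicographically smallest
    fit = DinaFit(
        item_params=ItemParams(s=s, g=g),
        prior=prior,
        posterior=post,
        map_profiles=profiles[map_idx],
        loglik_trace=np.array(trace),
        converged=converged,
        n_iter=it,
    )
    return fit


def estimate_profiles_map(data: ResponseMatrix, fit: DinaFit, q: QMatrix) -> np.ndarray:
    """MAP attribute profiles from a fitted DINA model.

    Recomputes the posterior for ``data`` under the fit's parameters, so a
    fit obtained on one matrix can classify another of the same width.
    Ties pick the lexicographically smallest profile.
    """
    values = data.values
    observed = ~np.isnan(values)
    profiles = enumerate_profiles(q.n_attributes)
    eta = ideal_responses(profiles, q.entries)
    p = np.where(eta == 1, 1.0 - fit.item_params.s, fit.item_params.g)
    y = np.nan_to_num(values, nan=0.0) * observed
    obs = observed.astype(float)
    ll = y @ np.log(p).T + (obs - y) @ np.log1p(-p).T
    logpost = ll + np.log(fit.prior)
    return profiles[logpost.argmax(axis=1)]


def export_fit(fit: DinaFit, json_path: str | Path, profiles_csv: str | Path) -> None:
    """Write item parameters/prior as JSON and MAP profiles as CSV."""
    fit.to_json(json_path)
    pd.DataFrame(
        fit.map_profiles,
        columns=[f"attr{k + 1}" for k in range(fit.map_profiles.shape[1])],
    ).to_csv(profiles_csv, index=False)

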