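"""Random-forest threshold imputation (RFTI / RFDTI) for dichotomous tests.

Both methods iterate missForest-style chained random-forest passes over the
items with missing cells, but instead of hard-classifying every predicted
probability they only impute cells predicted with enough certainty:

    Y_ij = 1           if p_ij >= tau_u
    Y_ij = NA          if tau_l < p_ij < tau_u
    Y_ij = 0           if p_ij <= tau_l

RFTI fixes the lower threshold at 0.5 (tau_l = 0.5) and searches tau_u;
RFDTI searches both thresholds. The iteration stops the first time the
change statistic

    Delta = #(imputed-cell states differing between successive passes) / #NA

increases, returning the previous pass's output. Candidate thresholds are
scored by refitting a DINA model to each thresholded matrix (remaining NA
ignored) and computing the mean adapted response-conformity person-fit
index RCI_C-bar; the pair minimising it wins — a balance between imputing
many cells (which shrinks each person's index when the imputations match
the model's ideal responses) and imputing uncertain cells (which inflates
it when they do not).

Internally the working predictor matrix carries the 0.5-rounded
probability for every originally-missing cell, which makes the probability
trace identical for every threshold pair; ``select_thresholds`` exploits
this by computing the trace once and replaying the stopping rule per pair.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterator

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .dina_core import (
    DinaFit,
    QMatrix,
    ResponseMatrix,
    fit_dina_em,
    ideal_responses,
)

logger = logging.getLogger(__name__)

_P_CLAMP = 1e-6  # clamp for the RCI logs


# ---------------------------------------------------------------------------
# configuration types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RFConfig:
    """Random-forest settings for the imputation passes.

    ``max_features=None`` means floor(sqrt(J - 1)), the missForest
    default for classification. ``max_iter`` caps the number of passes; the
    Delta rule alone does not guarantee termination.
    """

    n_trees: int = 100
    max_features: int | None = None
    max_iter: int = 10
    n_jobs: int = 1

    def resolved_max_features(self, n_predictors: int) -> int:
        if self.max_features is not None:
            return self.max_features
        return max(1, int(np.floor(np.sqrt(n_predictors))))


@dataclass(frozen=True)
class ThresholdPair:
    """Lower/upper dichotomisation thresholds; RFTI is exactly tau_l = 0.5."""

    tau_l: float
    tau_u: float

    def __post_init__(self) -> None:
        if not 0.0 < self.tau_l <= 0.5:
            raise ValueError("tau_l must lie in (0, 0.5]")
        if not 0.5 <= self.tau_u < 1.0:
            raise ValueError("tau_u must lie in [0.5, 1)")


@dataclass(frozen=True)
class ThresholdGrid:
    """Candidate (tau_l, tau_u) combinations on an evenly spaced grid."""

    step: float = 0.05
    mode: str = "RFDTI"

    def __post_init__(self) -> None:
        if self.mode not in ("RFTI", "RFDTI"):
            raise ValueError("mode must be RFTI or RFDTI")
        if not 0.0 < self.step <= 0.5:
            raise ValueError("step must be in (0, 0.5]")

    @property
    def tau_l_values(self) -> np.ndarray:
        if self.mode == "RFTI":
            return np.array([0.5])
        v = np.round(np.arange(self.step, 0.5, self.step), 10)
        return v[v < 0.5]

    @property
    def tau_u_values(self) -> np.ndarray:
        v = np.round(np.arange(0.5, 1.0, self.step), 10)
        return v[v < 1.0]

    @property
    def pairs(self) -> list[ThresholdPair]:
        return [
            ThresholdPair(float(tl), float(tu))
            for tl in self.tau_l_values
            for tu in self.tau_u_values
        ]


@dataclass
class FitIndexReport:
    """Per-person adapted RCI values and their mean."""

    rci_per_person: np.ndarray  # NaN where the person had no scored items
    m_i: np.ndarray

    @property
    def rci_mean(self) -> float:
        included = self.rci_per_person[~np.isnan(self.rci_per_person)]
        if included.size == 0:
            raise ValueError("no person has a nonmissing item")
        return float(included.mean())


@dataclass
class ImputationResult:
    """Winning imputation plus the full grid-search record."""

    imputed: ResponseMatrix
    thresholds: ThresholdPair
    rci_mean: float
    remaining_missing_rate: float
    grid_table: pd.DataFrame
    fit: DinaFit


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------


def initial_impute(x: ResponseMatrix) -> np.ndarray:
    """Item-mean start: NA cells take the rounded observed item mean."""
    values = x.values
    if np.isnan(values).all(axis=0).any():
        raise ValueError("an item has no observed responses")
    with np.errstate(invalid="ignore"):
        means = np.nanmean(values, axis=0)
    fill = (means >= 0.5).astype(float)
    out = values.copy()
    nan_r, nan_c = np.nonzero(np.isnan(values))
    out[nan_r, nan_c] = fill[nan_c]
    return out


def order_variables(x: ResponseMatrix) -> np.ndarray:
    """Items with missing cells, by ascending NA count (ties: column index)."""
    counts = np.isnan(x.values).sum(axis=0)
    items = np.flatnonzero(counts > 0)
    return items[np.argsort(counts[items], kind="stable")]


def threshold_map(p: np.ndarray | float, thresholds: ThresholdPair) -> np.ndarray | float:
    """Dichotomise probabilities: 1 above tau_u, 0 below tau_l, NA between."""
    p_arr = np.asarray(p, dtype=float)
    out = np.full(p_arr.shape, np.nan)
    out[p_arr >= thresholds.tau_u] = 1.0
    out[p_arr <= thresholds.tau_l] = 0.0
    return float(out) if np.ndim(p) == 0 else out


def delta(new: np.ndarray, old: np.ndarray, mask: np.ndarray) -> float:
    """Fraction of originally-missing cells whose {0,1,NA} state changed."""
    mask = np.asarray(mask, dtype=bool)
    n_na = int(mask.sum())
    if n_na == 0:
        raise ValueError("nothing to impute (no originally-missing cells)")
    a = np.asarray(new, dtype=float)[mask]
    b = np.asarray(old, dtype=float)[mask]
    an, bn = np.isnan(a), np.isnan(b)
    changed = (an != bn) | (~an & ~bn & (a != b))
    return float(changed.sum()) / n_na


def rf_pass(
    working: np.ndarray,
    observed_values: np.ndarray,
    order: np.ndarray,
    mask: np.ndarray,
    rf_config: RFConfig,
    seed: int,
) -> np.ndarray:
    """One chained random-forest pass over the items in ``order``.

    For each item the forest is trained on the originally-observed rows
    (response = the item's observed values, predictors = the other columns
    of the current working matrix) and predicts the class-1 probability for
    the originally-missing rows. The working column is updated in place
    with the 0.5-rounded prediction before the next item is visited.
    Returns an N x J matrix of probabilities (NaN outside missing cells).
    """
    n, j = working.shape
    probs = np.full((n, j), np.nan)
    ss = np.random.SeedSequence(seed)
    item_seeds = ss.generate_state(j)
    other = np.ones(j, dtype=bool)
    for s in order:
        obs_rows = ~mask[:, s].astype(bool)
        mis_rows = ~obs_rows
        y = observed_values[obs_rows, s].astype(int)
        other[:] = True
        other[s] = False
        classes = np.unique(y)
        if classes.size == 1:
            p1 = np.full(int(mis_rows.sum()), float(classes[0]))
        else:
            rf = RandomForestClassifier(
                n_estimators=rf_config.n_trees,
                max_features=rf_config.resolved_max_features(j - 1),
                random_state=int(item_seeds[s]) % (2**32 - 1),
                n_jobs=rf_config.n_jobs,
            )
            rf.fit(working[obs_rows][:, other], y)
            proba = rf.predict_proba(working[mis_rows][:, other])
            p1 = proba[:, list(rf.classes_).index(1)]
        probs[mis_rows, s] = p1
        working[mis_rows, s] = (p1 >= 0.5).astype(float)
    return probs


def _trace_passes(
    x: ResponseMatrix, rf_config: RFConfig, seed: int
) -> Iterator[np.ndarray]:
    """Yield the per-pass probability matrices of the iterative scheme.

    The working matrix starts from the item-mean imputation and is updated
    with rounded probabilities each pass, so the trace does not depend on
    any threshold pair.
    """
    mask = x.mask
    working = initial_impute(x)
    order = order_variables(x)
    pass_seeds = np.random.SeedSequence(seed).generate_state(rf_config.max_iter)
    for t in range(rf_config.max_iter):
        yield rf_pass(working, x.values, order, mask, rf_config, int(pass_seeds[t]))


class _StoppingReplay:
    """Replays the Delta stopping rule for one threshold pair along a trace."""

    def __init__(self, x: ResponseMatrix, thresholds: ThresholdPair):
        self.thresholds = thresholds
        self.mask = x.mask.astype(bool)
        self.observed = x.values
        self.prev = initial_impute(x)
        self.prev_delta: float | None = None
        self.result: np.ndarray | None = None
        self.delta_trace: list[float] = []

    def feed(self, probs: np.ndarray) -> bool:
        """Consume one pass's probabilities; True once stopped."""
        if self.result is not None:
            return True
        cand = self.observed.copy()
        cand[self.mask] = threshold_map(probs[self.mask], self.thresholds)
        d = delta(cand, self.prev, self.mask)
        self.delta_trace.append(d)
        if d == 0.0:
            self.result = cand
        elif self.prev_delta is not None and d > self.prev_delta:
            self.result = self.prev  # revert to the previous pass's output
        else:
            self.prev = cand
            self.prev_delta = d
            return False
        return True

    def finalize(self) -> np.ndarray:
        """Last candidate if the iteration cap was hit before stopping."""
        return self.result if self.result is not None else self.prev


def iterate_impute(
    x: ResponseMatrix,
    thresholds: ThresholdPair,
    rf_config: RFConfig | None = None,
    seed: int = 0,
) -> ResponseMatrix:
    """Run the iterative RF imputation for a single threshold pair."""
    rf_config = rf_config or RFConfig()
    if int(x.mask.sum()) == 0:
        raise ValueError("response matrix has no missing cells")
    replay = _StoppingReplay(x, thresholds)
    for probs in _trace_passes(x, rf_config, seed):
        if replay.feed(probs):
            break
    return ResponseMatrix(replay.finalize())


# ---------------------------------------------------------------------------
# person-fit index
# ---------------------------------------------------------------------------


def rci_c_person(
    y_row: np.ndarray,
    profile_hat: np.ndarray,
    q: QMatrix,
    s: np.ndarray,
    g: np.ndarray,
) -> float:
    """Adapted response-conformity index for one examinee.

    Over the person's nonmissing items, responses that match the ideal
    response of the estimated profile contribute 0; a 1 where the ideal
    response is 0 contributes |ln((1-P)/P)|; a 0 where it is 1 contributes
    |ln(P/(1-P))|; the sum is divided by the number of scored items m_i.
    """
    y_row = np.asarray(y_row, dtype=float)
    scored = ~np.isnan(y_row)
    m_i = int(scored.sum())
    if m_i == 0:
        raise ValueError("examinee has no nonmissing items")
    eta = ideal_responses(profile_hat, q.entries)[0]
    p = np.clip(np.where(eta == 1, 1.0 - s, g), _P_CLAMP, 1.0 - _P_CLAMP)
    y, i_j, pj = y_row[scored], eta[scored], p[scored]
    # matching responses contribute 0; either mismatch contributes |logit(P)|
    contrib = np.where(y == i_j, 0.0, np.abs(np.log(pj / (1.0 - pj))))
    return float(contrib.sum() / m_i)


def rci_c_report(
    values: np.ndarray,
    map_profiles: np.ndarray,
    q: QMatrix,
    s: np.ndarray,
    g: np.ndarray,
) -> FitIndexReport:
    """Vectorised RCI_C for a whole matrix (NaN for all-missing persons)."""
    values = np.asarray(values, dtype=float)
    scored = ~np.isnan(values)
    m_i = scored.sum(axis=1)
    eta_ij = ideal_responses(map_profiles, q.entries)  # N x J
    p = np.clip(np.where(eta_ij == 1, 1.0 - s, g), _P_CLAMP, 1.0 - _P_CLAMP)
    logit = np.abs(np.log(p / (1.0 - p)))
    mismatch = scored & (np.nan_to_num(values, nan=-1.0) != eta_ij)
    total = (mismatch * logit).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        rci = np.where(m_i > 0, total / np.maximum(m_i, 1), np.nan)
    if (m_i == 0).any():
        logger.warning("%d examinee(s) with no nonmissing items excluded", (m_i == 0).sum())
    return FitIndexReport(rci_per_person=rci, m_i=m_i)


def rci_c_mean(rci_values: np.ndarray) -> float:
    """Arithmetic mean of the included per-person indices."""
    rci_values = np.asarray(rci_values, dtype=float)
    included = rci_values[~np.isnan(rci_values)]
    if included.size == 0:
        raise ValueError("no examinees to average over")
    return float(included.mean())


# ---------------------------------------------------------------------------
# threshold selection
# ---------------------------------------------------------------------------


def _score_candidate(
    imputed: np.ndarray, q: QMatrix, dina_tol: float, dina_max_iter: int
) -> tuple[float, float, DinaFit]:
    rm = ResponseMatrix(imputed)
    fit = fit_dina_em(rm, q, tol=dina_tol, max_iter=dina_max_iter)
    report = rci_c_report(
        rm.values, fit.map_profiles, q, fit.item_params.s, fit.item_params.g
    )
    remaining = float(np.isnan(rm.values).mean())
    return report.rci_mean, remaining, fit


def select_thresholds_multi(
    x: ResponseMatrix,
    q: QMatrix,
    grids: dict[str, ThresholdGrid],
    rf_config: RFConfig | None = None,
    seed: int = 0,
    dina_tol: float = 1e-4,
    dina_max_iter: int = 1000,
) -> dict[str, ImputationResult]:
    """Evaluate several threshold grids against one shared probability trace.

    Because the trace is threshold independent, evaluating the RFDTI and
    RFTI grids on the same dataset costs one set of forest passes plus the
    per-pair DINA refits; each grid's result is identical to running
    ``select_thresholds`` with the same seed.
    """
    rf_config = rf_config or RFConfig()
    if int(x.mask.sum()) == 0:
        raise ValueError("response matrix has no missing cells")
    replays = {name: [_StoppingReplay(x, p) for p in grid.pairs] for name, grid in grids.items()}
    flat = [r for rs in replays.values() for r in rs]
    for probs in _trace_passes(x, rf_config, seed):
        done = [r.feed(probs) for r in flat]  # feed every replay
        if all(done):
            break

    results: dict[str, ImputationResult] = {}
    for name, grid_replays in replays.items():
        rows = []
        best = None
        for replay in grid_replays:
            pair = replay.thresholds
            try:
                rci, remaining, fit = _score_candidate(
                    replay.finalize(), q, dina_tol, dina_max_iter
                )
            except Exception as exc:  # noqa: BLE001 - grid cell failure is data
                logger.warning(
                    "grid cell (%.2f, %.2f) failed: %s", pair.tau_l, pair.tau_u, exc
                )
                rows.append((pair.tau_l, pair.tau_u, np.nan, np.nan, False))
                continue
            rows.append((pair.tau_l, pair.tau_u, rci, remaining, True))
            key = (rci, remaining, -pair.tau_l, pair.tau_u)
            if best is None or key < best[0]:
                best = (key, replay, rci, remaining, fit)
        if best is None:
            raise RuntimeError("every grid cell failed")
        table = pd.DataFrame(
            rows, columns=["tau_l", "tau_u", "rci_mean", "remaining_missing_rate", "ok"]
        )
        _, replay, rci, remaining, fit = best
        results[name] = ImputationResult(
            imputed=ResponseMatrix(replay.finalize()),
            thresholds=replay.thresholds,
            rci_mean=rci,
            remaining_missing_rate=remaining,
            grid_table=table,
            fit=fit,
        )
    return results


def select_thresholds(
    x: ResponseMatrix,
    q: QMatrix,
    grid: ThresholdGrid,
    rf_config: RFConfig | None = None,
    seed: int = 0,
    dina_tol: float = 1e-4,
    dina_max_iter: int = 1000,
) -> ImputationResult:
    """Grid-search (tau_l, tau_u) by minimising the mean adapted RCI.

    The RF probability trace is shared across grid cells (it is threshold
    independent by construction), so each pair only replays the stopping
    rule and refits the DINA model on its own thresholded matrix. Ties on
    RCI_C-bar prefer the smaller remaining missing rate, then the larger
    tau_l, then the smaller tau_u.
    """
    return select_thresholds_multi(
        x, q, {"grid": grid}, rf_config, seed, dina_tol, dina_max_iter
    )["grid"]


def rfdti(
    x: ResponseMatrix,
    q: QMatrix,
    stepV: float = 0.05,
    rf_config: RFConfig | None = None,
    seed: int = 0,
    **kwargs,
) -> ImputationResult:
    """Dynamic lower and upper thresholds (the full grid)."""
    return select_thresholds(
        x, q, ThresholdGrid(step=stepV, mode="RFDTI"), rf_config, seed, **kwargs
    )


def rfti(
    x: ResponseMatrix,
    q: QMatrix,
    stepV: float = 0.05,
    rf_config: RFConfig | None = None,
    seed: int = 0,
    **kwargs,
) -> ImputationResult:
    """Fixed lower threshold 0.5, dynamic upper threshold."""
    return select_thresholds(
        x, q, ThresholdGrid(step=stepV, mode="RFTI"), rf_config, seed, **kwargs
    )
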