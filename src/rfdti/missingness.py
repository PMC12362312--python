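"""MCAR / MAR / MNAR / MIXED missingness generators for response matrices.

Missingness is imposed on a random 80% subsample of examinees (the
complement stays fully observed, which helps train the forests downstream):

* MCAR deletes each subsampled cell independently with probability ``mr``.
* MAR deletes with a rate that depends on an observable ability proxy: for
  each target item the examinee's rest score (number correct on all other
  items) is z-normalised and split into seven fractiles at the 5/15/30/70/
  85/95th percentiles; the fractile deletion rates are mr x (1.50, 1.35,
  1.15, 1.00, 0.85, 0.65, 0.50) from lowest to highest fractile, whose
  fractile-width-weighted mean is exactly mr.
* MNAR deletes a fixed per-examinee count (round(mr x J)) of responses,
  preferentially on items the examinee would likely get wrong: a response
  is removed when a fresh uniform draw exceeds p + epsilon, with p the true
  correct-response probability and epsilon adjusted up/down in 0.01 steps
  until the count is hit exactly.
* MIXED computes per-examinee counts from the MAR fractile rates (proxy =
  total score) and selects which items to omit by the MNAR procedure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .dina_core import ResponseMatrix

logger = logging.getLogger(__name__)

MECHANISMS = ("MCAR", "MAR", "MNAR", "MIXED")


def _round_half_up(x: np.ndarray | float) -> np.ndarray | int:
    """Round halves away from zero (0.5 -> 1), unlike banker's rounding."""
    r = np.floor(np.asarray(x, dtype=float) + 0.5).astype(int)
    return int(r) if np.isscalar(x) or np.ndim(x) == 0 else r


@dataclass(frozen=True)
class MarScheme:
    """Seven-fractile MAR deletion-rate scheme.

    ``multipliers`` scale the target rate MR per fractile; the fractile
    widths implied by ``percentile_breaks`` dot the multipliers to exactly
    1, so the average deletion rate equals MR.
    """

    percentile_breaks: tuple = (5.0, 15.0, 30.0, 70.0, 85.0, 95.0)
    multipliers: tuple = (1.50, 1.35, 1.15, 1.00, 0.85, 0.65, 0.50)

    def __post_init__(self) -> None:
        if len(self.multipliers) != len(self.percentile_breaks) + 1:
            raise ValueError("need one multiplier per fractile")
        if abs(np.dot(self.fractile_weights, self.multipliers) - 1.0) > 1e-12:
            raise ValueError("fractile weights dotted with multipliers must equal 1")

    @property
    def fractile_weights(self) -> np.ndarray:
        edges = np.concatenate(([0.0], self.percentile_breaks, [100.0]))
        return np.diff(edges) / 100.0

    def assign_fractiles(self, scores: np.ndarray) -> np.ndarray:
        """Fractile index per score; boundary cases go to the higher fractile."""
        z = _normalize(scores)
        breaks = np.percentile(z, self.percentile_breaks)
        return np.searchsorted(breaks, z, side="right")


@dataclass(frozen=True)
class MissingnessSpec:
    """Run-config block describing one missingness condition."""

    mechanism: str
    mr: float
    subsample_fraction: float = 0.8
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.mechanism not in MECHANISMS:
            raise ValueError(f"mechanism must be one of {MECHANISMS}")
        if not 0.0 < self.mr < 1.0:
            raise ValueError("mr must be in (0, 1)")


def _normalize(scores: np.ndarray) -> np.ndarray:
    sd = scores.std()
    if sd == 0.0:
        logger.warning("degenerate ability proxy (all scores equal)")
        return np.zeros_like(scores, dtype=float)
    return (scores - scores.mean()) / sd


def _check_complete(x: ResponseMatrix) -> None:
    if np.isnan(x.values).any():
        raise ValueError("input response matrix must be complete")


def select_subsample(n: int, fraction: float = 0.8, seed: int | None = None) -> np.ndarray:
    """floor(fraction * n) distinct examinee indices, uniform without replacement."""
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)
    size = int(np.floor(fraction * n))
    return np.sort(rng.choice(n, size=size, replace=False))


def apply_mcar(
    x: ResponseMatrix, mr: float, subsample: np.ndarray, seed: int | None = None
) -> ResponseMatrix:
    """Delete each subsampled cell independently with probability mr."""
    _check_complete(x)
    if not 0.0 < mr < 1.0:
        raise ValueError("mr must be in (0, 1)")
    rng = np.random.default_rng(seed)
    out = x.values.copy()
    u = rng.random((len(subsample), x.n_items))
    rows = out[subsample]
    rows[u < mr] = np.nan
    out[subsample] = rows
    return ResponseMatrix(out)


def apply_mar(
    x: ResponseMatrix,
    mr: float,
    subsample: np.ndarray,
    scheme: MarScheme | None = None,
    seed: int | None = None,
) -> ResponseMatrix:
    """Fractile-rate deletion driven by the per-item rest score."""
    _check_complete(x)
    scheme = scheme or MarScheme()
    rng = np.random.default_rng(seed)
    out = x.values.copy()
    total = x.values.sum(axis=1)
    for j in range(x.n_items):
        rest = total - x.values[:, j]  # number correct on all but item j
        frac = scheme.assign_fractiles(rest[subsample])
        rates = mr * np.asarray(scheme.multipliers)[frac]
        u = rng.random(len(subsample))
        out[subsample[u < rates], j] = np.nan
    return ResponseMatrix(out)


def _mnar_row(
    p_row: np.ndarray,
    target: int,
    rng: np.random.Generator,
    step: float = 0.01,
    max_rounds: int = 10_000,
) -> np.ndarray:
    """Indices to delete for one examinee via the epsilon-adjustment loop."""
    if target <= 0:
        return np.empty(0, dtype=int)
    j = p_row.shape[0]
    if target > j:
        raise ValueError("target omission count exceeds test length")
    eps = 0.0
    for _ in range(max_rounds):
        u = rng.random(j)
        deleted = np.flatnonzero(u > p_row + eps)
        if deleted.size == target:
            return deleted
        # too many omissions -> raise the bar p + eps; too few -> lower it
        eps += step if deleted.size > target else -step
    raise RuntimeError("MNAR epsilon adjustment did not converge")


def apply_mnar(
    x: ResponseMatrix,
    mr: float,
    subsample: np.ndarray,
    p_true: np.ndarray,
    seed: int | None = None,
    step: float = 0.01,
) -> ResponseMatrix:
    """Per-examinee exact-count deletion tied to the (unobserved) success probability.

    ``p_true`` is the N x J matrix of correct-response probabilities under
    the generating model; cells with low p are deleted more often.
    """
    _check_complete(x)
    if p_true.shape != x.values.shape:
        raise ValueError("p_true must match the response matrix shape")
    rng = np.random.default_rng(seed)
    out = x.values.copy()
    target = _round_half_up(mr * x.n_items)
    for i in subsample:
        out[i, _mnar_row(p_true[i], target, rng, step=step)] = np.nan
    return ResponseMatrix(out)


def apply_mixed(
    x: ResponseMatrix,
    mr: float,
    subsample: np.ndarray,
    p_true: np.ndarray,
    scheme: MarScheme | None = None,
    seed: int | None = None,
    step: float = 0.01,
) -> ResponseMatrix:
    """MAR-style per-examinee counts, MNAR-style item selection."""
    _check_complete(x)
    scheme = scheme or MarScheme()
    rng = np.random.default_rng(seed)
    out = x.values.copy()
    total = x.values.sum(axis=1)  # proxy: total number-correct score
    frac = scheme.assign_fractiles(total[subsample])
    counts = _round_half_up(mr * np.asarray(scheme.multipliers)[frac] * x.n_items)
    for i, target in zip(subsample, counts):
        out[i, _mnar_row(p_true[i], int(target), rng, step=step)] = np.nan
    return ResponseMatrix(out)


def impose_missingness(
    x: ResponseMatrix,
    spec: MissingnessSpec,
    p_true: np.ndarray | None = None,
    scheme: MarScheme | None = None,
) -> ResponseMatrix:
    """Dispatch on the mechanism named in ``spec``; seeds split internally."""
    seeds = np.random.SeedSequence(spec.seed).generate_state(2)
    subsample = select_subsample(x.n_examinees, spec.subsample_fraction, int(seeds[0]))
    seed = int(seeds[1])
    if spec.mechanism == "MCAR":
        return apply_mcar(x, spec.mr, subsample, seed)
    if spec.mechanism == "MAR":
        return apply_mar(x, spec.mr, subsample, scheme, seed)
    if p_true is None:
        raise ValueError(f"{spec.mechanism} requires p_true")
    if spec.mechanism == "MNAR":
        return apply_mnar(x, spec.mr, subsample, p_true, seed)
    return apply_mixed(x, spec.mr, subsample, p_true, scheme, seed)
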