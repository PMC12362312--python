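"""Classification-accuracy metrics for estimated attribute profiles.

PCA (pattern-wise classification accuracy) is the fraction of examinees
whose whole estimated K-vector equals the truth; ACA (attribute-wise) is
the fraction of matching person-attribute cells. Pooling over replications
(or over multiple-imputation datasets) is by arithmetic mean, so PCA <=
ACA always holds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dina_core import ResponseMatrix


def _check_shapes(estimated: np.ndarray, truth: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    estimated = np.asarray(estimated, dtype=int)
    truth = np.asarray(truth, dtype=int)
    if estimated.shape != truth.shape:
        raise ValueError("estimated and true profile matrices must share a shape")
    return estimated, truth


def pca(estimated: np.ndarray, truth: np.ndarray) -> float:
    """Fraction of examinees with a fully correct attribute pattern."""
    estimated, truth = _check_shapes(estimated, truth)
    return float((estimated == truth).all(axis=1).mean())


def aca(estimated: np.ndarray, truth: np.ndarray) -> float:
    """Fraction of correctly classified person-attribute cells."""
    estimated, truth = _check_shapes(estimated, truth)
    return float((estimated == truth).mean())


def remaining_missing_rate(imputed: ResponseMatrix) -> float:
    """Proportion of all N x J cells still missing after imputation."""
    return float(np.isnan(imputed.values).mean())


@dataclass
class EvaluationReport:
    """Metrics for one condition x method (possibly pooled over replications)."""

    pca: float
    aca: float
    remaining_missing_rate: float
    r_converged: int
    condition: dict

    def __post_init__(self) -> None:
        if not 0.0 <= self.pca <= self.aca <= 1.0:
            raise ValueError("requires 0 <= PCA <= ACA <= 1")
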