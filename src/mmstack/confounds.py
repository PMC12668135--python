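"""In-fold confound regression.

Coefficients are estimated on training subjects only and applied unchanged
to test subjects, the standard leakage-safe deconfounding protocol.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np


@dataclass
class ConfoundCoefficients:
    coef: np.ndarray       # (n_confounds,) or (n_confounds, n_outputs)
    intercept: np.ndarray  # scalar or (n_outputs,)
    rank: int


def confound_fit(confounds: np.ndarray, data: np.ndarray
                 ) -> ConfoundCoefficients:
    """OLS (with intercept) of data on confounds, training rows only.

    Collinear confound columns are tolerated via the minimum-norm
    least-squares solution, with a warning.
    """
    x = np.asarray(confounds, dtype=float)
    y = np.asarray(data, dtype=float)
    if x.shape[0] < 10:
        raise ValueError(f"need >= 10 training rows, got {x.shape[0]}")
    design = np.column_stack([np.ones(x.shape[0]), x])
    beta, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < design.shape[1]:
        warnings.warn(
            f"confound design rank {rank} < {design.shape[1]}: collinear "
            "columns effectively dropped (minimum-norm solve)",
            RuntimeWarning, stacklevel=2)
    return ConfoundCoefficients(coef=beta[1:], intercept=beta[0], rank=rank)


def confound_apply(confounds: np.ndarray, data: np.ndarray,
                   coefs: ConfoundCoefficients) -> np.ndarray:
    """Residualise data against confounds using training coefficients."""
    x = np.asarray(confounds, dtype=float)
    y = np.asarray(data, dtype=float)
    return y - (x @ coefs.coef + coefs.intercept)
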