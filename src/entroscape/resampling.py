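"""Delete-one jackknife standard errors for scalar estimators.

The estimator is re-run n times, each time with one observation unit removed;
the standard error is ``sqrt((n-1)/n * sum((theta_i - theta_bar)^2))`` where
``theta_bar`` is the mean of the leave-one-out estimates. Deletion order never
affects the result.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .exceptions import InputError

__all__ = ["JackknifeResult", "jackknife", "jackknife_se_from_loo"]


@dataclass(frozen=True)
class JackknifeResult:
    """Full-sample estimate plus leave-one-out diagnostics.

    ``estimate_full`` is the estimator on all n units (the value to report);
    ``estimate_mean`` is the mean of the leave-one-out estimates (kept for
    diagnostics, not bias correction).
    """

    estimate_full: float
    estimate_mean: float
    leave_one_out: np.ndarray
    se: float
    n: int


def jackknife_se_from_loo(leave_one_out: np.ndarray) -> float:
    """Standard error from precomputed leave-one-out estimates."""
    loo = np.asarray(leave_one_out, dtype=float)
    n = loo.size
    if n < 2:
        raise InputError("jackknife needs at least 2 observation units")
    mean = loo.mean()
    return float(np.sqrt((n - 1) / n * np.sum((loo - mean) ** 2)))


def jackknife(
    samples: Sequence | np.ndarray,
    estimator: Callable[[Sequence | np.ndarray], float],
) -> JackknifeResult:
    """Jackknife a scalar ``estimator`` over a sequence of observation units.

    ``samples`` may be a list or an array; for arrays the first axis indexes
    units, so a (cells x genes) matrix is jackknifed over cells. An estimator
    failure on a subset is re-raised naming the deleted index.
    """
    is_array = isinstance(samples, np.ndarray)
    if not is_array:
        samples = list(samples)
    n = len(samples)
    if n < 2:
        raise InputError(f"jackknife needs at least 2 observation units, got {n}")

    full = float(estimator(samples))
    loo = np.empty(n, dtype=float)
    for i in range(n):
        if is_array:
            subset = np.delete(samples, i, axis=0)
        else:
            subset = samples[:i] + samples[i + 1 :]
        try:
            loo[i] = float(estimator(subset))
        except Exception as exc:
            raise InputError(
                f"estimator failed on the subset with unit {i} deleted: {exc}"
            ) from exc
    mean = float(loo.mean())
    se = jackknife_se_from_loo(loo)
    return JackknifeResult(
        estimate_full=full, estimate_mean=mean, leave_one_out=loo, se=se, n=n
    )
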