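"""Binary and pairwise-joint Shannon entropy in bits, plus count-based estimators.

All entropies use the base-2 logarithm, so a single on/off variable is
bounded by 1 bit and a gene pair by 2 bits. The plug-in (maximum-likelihood)
estimator is the default; the Miller--Madow bias correction and the
James--Stein-type shrinkage estimator (uniform target, closed-form optimal
intensity) are provided for robustness comparisons. Estimator functions
accept a single count vector or an array of count vectors stacked along the
last axis and broadcast accordingly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .exceptions import InputError

__all__ = [
    "BinaryDistribution",
    "JointBinaryDistribution",
    "EntropyEstimate",
    "fit_binary_distribution",
    "fit_joint_distribution",
    "binary_entropy",
    "joint_entropy",
    "normalize_entropy",
    "mutual_information",
    "bernoulli_variance",
    "entropy_ml",
    "entropy_miller_madow",
    "entropy_james_stein",
    "ESTIMATORS",
]

_LN2 = float(np.log(2.0))
_PROB_TOL = 1e-12


@dataclass(frozen=True)
class BinaryDistribution:
    """On/off probabilities of a single gene.

    ``p0`` is the probability of "off" (no measurable expression), ``p1`` of
    "on"; ``n`` is the number of cells the probabilities were estimated from
    (0 for analytically specified distributions).
    """

    p0: float
    p1: float
    n: int = 0

    def __post_init__(self) -> None:
        for name in ("p0", "p1"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < -_PROB_TOL or v > 1 + _PROB_TOL:
                raise InputError(f"{name}={v!r} is not a probability")
        if abs(self.p0 + self.p1 - 1.0) > _PROB_TOL:
            raise InputError(
                f"probabilities must sum to 1, got p0+p1={self.p0 + self.p1!r}"
            )
        if self.n < 0:
            raise InputError(f"sample count n={self.n} must be >= 0")


@dataclass(frozen=True)
class JointBinaryDistribution:
    """Joint on/off probabilities of an ordered gene pair.

    State order is (gene A bit, gene B bit) lexicographically:
    ``p00, p01, p10, p11``.
    """

    p00: float
    p01: float
    p10: float
    p11: float
    n: int = 0

    def __post_init__(self) -> None:
        for name in ("p00", "p01", "p10", "p11"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < -_PROB_TOL or v > 1 + _PROB_TOL:
                raise InputError(f"{name}={v!r} is not a probability")
        total = self.p00 + self.p01 + self.p10 + self.p11
        if abs(total - 1.0) > _PROB_TOL:
            raise InputError(f"joint probabilities must sum to 1, got {total!r}")
        if self.n < 0:
            raise InputError(f"sample count n={self.n} must be >= 0")

    def as_array(self) -> np.ndarray:
        return np.array([self.p00, self.p01, self.p10, self.p11], dtype=float)

    def marginals(self) -> tuple[BinaryDistribution, BinaryDistribution]:
        """Marginal distributions of gene A and gene B."""
        a1 = min(1.0, self.p10 + self.p11)
        b1 = min(1.0, self.p01 + self.p11)
        return (
            BinaryDistribution(p0=1.0 - a1, p1=a1, n=self.n),
            BinaryDistribution(p0=1.0 - b1, p1=b1, n=self.n),
        )


@dataclass(frozen=True)
class EntropyEstimate:
    """An entropy value in bits with its provenance.

    ``se`` is a jackknife standard error when available. ``normalized``
    records whether the value has been divided by the log number of states.
    """

    value: float
    estimator: str = "ml"
    se: Optional[float] = None
    normalized: bool = False
    n: int = field(default=0, compare=False)


def _plugin_entropy(p: np.ndarray) -> np.ndarray:
    """-sum p log2 p over the last axis, with 0 log 0 := 0."""
    p = np.asarray(p, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log2(np.where(p > 0, p, 1.0)), 0.0)
    return -terms.sum(axis=-1)


def _check_counts(counts: np.ndarray, min_total: int) -> tuple[np.ndarray, np.ndarray]:
    counts = np.asarray(counts, dtype=float)
    if counts.ndim == 0 or counts.shape[-1] < 2:
        raise InputError("counts must have at least two states on the last axis")
    if np.any(counts < 0) or not np.all(np.isfinite(counts)):
        raise InputError("counts must be finite and non-negative")
    n = counts.sum(axis=-1)
    if np.any(n < min_total):
        raise InputError(f"total count must be >= {min_total}")
    return counts, n


def fit_binary_distribution(calls) -> BinaryDistribution:
    """Maximum-likelihood Bernoulli fit to a vector of {0,1} calls."""
    calls = np.asarray(calls)
    if calls.size == 0:
        raise InputError("cannot fit a distribution to an empty sample")
    if not np.isin(calls, (0, 1)).all():
        raise InputError("calls must all be 0 or 1")
    n = int(calls.size)
    p1 = float(np.count_nonzero(calls)) / n
    return BinaryDistribution(p0=1.0 - p1, p1=p1, n=n)


def fit_joint_distribution(calls_a, calls_b) -> JointBinaryDistribution:
    """Maximum-likelihood fit of the joint on/off distribution of two genes."""
    a = np.asarray(calls_a)
    b = np.asarray(calls_b)
    if a.size == 0 or a.shape != b.shape:
        raise InputError("call vectors must be non-empty and equal-length")
    if not (np.isin(a, (0, 1)).all() and np.isin(b, (0, 1)).all()):
        raise InputError("calls must all be 0 or 1")
    n = int(a.size)
    state = 2 * a.astype(int) + b.astype(int)
    counts = np.bincount(state, minlength=4)
    p = counts / n
    return JointBinaryDistribution(p00=p[0], p01=p[1], p10=p[2], p11=p[3], n=n)


def binary_entropy(d: BinaryDistribution) -> float:
    """Shannon entropy of a single on/off variable, in bits (range [0, 1])."""
    return float(_plugin_entropy(np.array([d.p0, d.p1])))


def joint_entropy(j: JointBinaryDistribution) -> float:
    """Shannon entropy of a gene pair's joint on/off states, in bits ([0, 2])."""
    return float(_plugin_entropy(j.as_array()))


def normalize_entropy(h: float, n_states: int, *, allow_excess: bool = False) -> float:
    """Divide an entropy by log2(n_states) so the result lies in [0, 1].

    ``allow_excess`` admits values above the ceiling (the Miller--Madow
    correction can push small-sample entropies past it); they are returned
    unclipped so the excess stays visible.
    """
    if not np.isfinite(h) or h < 0:
        raise InputError(f"entropy must be finite and >= 0, got {h!r}")
    if n_states < 2:
        raise InputError("n_states must be >= 2")
    hmax = float(np.log2(n_states))
    if h > hmax + 1e-9 and not allow_excess:
        raise InputError(f"entropy {h!r} exceeds log2({n_states}) = {hmax!r}")
    return h / hmax


def mutual_information(j: JointBinaryDistribution) -> float:
    """I = H(A) + H(B) - H(A,B) in bits; non-negative up to rounding."""
    a, b = j.marginals()
    value = binary_entropy(a) + binary_entropy(b) - joint_entropy(j)
    # exact-arithmetic I >= 0; clip float dust only
    return 0.0 if -1e-12 < value < 0.0 else value


def bernoulli_variance(d: BinaryDistribution) -> float:
    """Variance p0 (1 - p0) of the on/off indicator; same zero set as entropy."""
    return float(d.p0 * (1.0 - d.p0))


def entropy_ml(counts) -> float | np.ndarray:
    """Plug-in (maximum-likelihood) entropy of per-state counts, in bits."""
    counts, n = _check_counts(counts, min_total=1)
    h = _plugin_entropy(counts / n[..., None])
    return float(h) if h.ndim == 0 else h


def entropy_miller_madow(counts) -> float | np.ndarray:
    """Plug-in entropy plus the (m-1)/(2n) bias correction, converted to bits.

    ``m`` counts occupied (non-zero) states. The correction can raise a
    two-state entropy above 1 bit; callers must tolerate that.
    """
    counts, n = _check_counts(counts, min_total=1)
    m = np.count_nonzero(counts, axis=-1)
    h = _plugin_entropy(counts / n[..., None]) + (m - 1) / (2.0 * n * _LN2)
    return float(h) if h.ndim == 0 else h


def entropy_james_stein(counts) -> float | np.ndarray:
    """Shrinkage entropy: plug-in entropy of frequencies shrunk toward uniform.

    The shrinkage intensity is the closed-form optimum
    ``lambda = (1 - sum th^2) / ((n - 1) sum (t - th)^2)`` with uniform
    target ``t = 1/S``, clipped to [0, 1]; a zero denominator (frequencies
    already uniform) yields lambda = 1.
    """
    counts, n = _check_counts(counts, min_total=2)
    S = counts.shape[-1]
    t = 1.0 / S
    theta = counts / n[..., None]
    num = 1.0 - (theta**2).sum(axis=-1)
    den = (n - 1) * ((t - theta) ** 2).sum(axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        lam = np.where(den > 0, num / np.where(den > 0, den, 1.0), 1.0)
    lam = np.clip(lam, 0.0, 1.0)
    shrunk = lam[..., None] * t + (1.0 - lam[..., None]) * theta
    h = _plugin_entropy(shrunk)
    return float(h) if h.ndim == 0 else h


ESTIMATORS = {
    "ml": entropy_ml,
    "miller_madow": entropy_miller_madow,
    "james_stein": entropy_james_stein,
}
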