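"""Two-stage USP <905> uniformity-of-dosage-units decision procedure.

Implements the content-uniformity branch of the harmonized test
(USP <905> / Ph. Eur. 2.9.40 / JP 6.02) as applied to sachets of
mini-tablets: an acceptance value

    AV = |M - x_bar| + k * s

is computed from the sample mean ``x_bar`` and sample standard deviation
``s`` (n-1 denominator) of per-unit assays expressed in percent of label
claim (%LC).  ``M`` is the reference value: the sample mean clamped to the
98.5-101.5 %LC band (the T <= 101.5 case; batch means are centred at 100%
of target throughout this package).  Stage 1 tests 10 units with k = 2.4;
if AV exceeds L1 = 15, a further 20 units are pooled to n = 30 and retested
with k = 2.0, with the added requirement that every individual unit lie
within (1 +/- L2/100) * M, L2 = 25.

Boundary convention: a batch passes a stage iff AV <= L1, and an individual
unit passes iff it lies inside the closed interval [lower, upper].  Both
choices are measure-zero under continuous assay noise; they matter only for
the exact zero-variability arithmetic (e.g. a 3-of-4 fill at exactly
75.0 %LC passes the individual criterion when M = 100 but fails it when
M < 98.6).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from numpy.typing import ArrayLike, NDArray

__all__ = [
    "AcceptanceParams",
    "AssaySet",
    "AVResult",
    "Outcome",
    "BatchJudgment",
    "reference_value",
    "acceptance_value",
    "individual_limits",
    "judge_batch",
    "judge_matrix",
]


@dataclass(frozen=True)
class AcceptanceParams:
    """Constants of the harmonized USP <905> content-uniformity test.

    All limits are in percent; ``ref_low``/``ref_high``/``target`` are in
    %LC.  The defaults are the compendial values for the T <= 101.5 case.
    """

    L1: float = 15.0
    L2: float = 25.0
    k_stage1: float = 2.4
    k_stage2: float = 2.0
    ref_low: float = 98.5
    ref_high: float = 101.5
    target: float = 100.0
    n_stage1: int = 10
    n_total: int = 30

    def __post_init__(self) -> None:
        for name in ("L1", "L2", "k_stage1", "k_stage2", "ref_low",
                     "ref_high", "target", "n_stage1", "n_total"):
            if not getattr(self, name) > 0:
                raise ValueError(f"AcceptanceParams.{name} must be strictly positive")
        if self.ref_low > self.ref_high:
            raise ValueError("ref_low must not exceed ref_high")
        if self.n_stage1 >= self.n_total:
            raise ValueError("n_stage1 must be smaller than n_total")


@dataclass(frozen=True)
class AssaySet:
    """Ordered per-sachet assay values (%LC) for one tested set.

    The first ``n_stage1`` entries are the stage-1 sample.  Length must be
    ``n_total`` for a full judgment or ``n_stage1`` for a stage-1-only one.
    """

    values: NDArray[np.float64]

    def __init__(self, values: ArrayLike):
        arr = np.asarray(values, dtype=float).ravel()
        if arr.size == 0:
            raise ValueError("AssaySet requires at least one value")
        if not np.all(np.isfinite(arr)):
            raise ValueError("assay values must be finite")
        if np.any(arr < 0):
            raise ValueError("assay values must be non-negative")
        object.__setattr__(self, "values", arr)

    def __len__(self) -> int:
        return int(self.values.size)

    def stage1(self, params: AcceptanceParams = AcceptanceParams()) -> NDArray[np.float64]:
        return self.values[: params.n_stage1]


@dataclass(frozen=True)
class AVResult:
    """Acceptance-value computation: av = |M - mean| + k * sd."""

    mean: float
    sd: float
    M: float
    k: float
    av: float


class Outcome(str, enum.Enum):
    PASS_STAGE1 = "PASS_STAGE1"
    PASS_STAGE2 = "PASS_STAGE2"
    FAIL = "FAIL"
    #: stage-1-only judgment whose AV exceeds L1; no batch verdict possible.
    STAGE2_REQUIRED = "STAGE2_REQUIRED"


@dataclass(frozen=True)
class BatchJudgment:
    outcome: Outcome
    stage1: AVResult
    stage2: Optional[AVResult] = None
    n_individual_violations: int = 0
    violation_indices: tuple[int, ...] = field(default_factory=tuple)
    stage1_triggered_stage2: bool = False


def reference_value(mean: float, params: AcceptanceParams = AcceptanceParams()) -> float:
    """Clamp a sample mean (%LC) to the compendial reference band.

    Returns ``mean`` unchanged inside [ref_low, ref_high] and the nearer
    band edge outside it.
    """
    mean = float(mean)
    if not math.isfinite(mean):
        raise ValueError("mean must be finite")
    if mean < 0:
        raise ValueError("mean must be non-negative")
    return min(max(mean, params.ref_low), params.ref_high)


def acceptance_value(
    values: ArrayLike,
    k: float,
    params: AcceptanceParams = AcceptanceParams(),
) -> AVResult:
    """Compute the acceptance value |M - mean| + k*sd of a sample of assays.

    ``sd`` is the sample standard deviation (n-1 denominator).  Requires at
    least two finite values.
    """
    arr = np.asarray(values, dtype=float).ravel()
    if arr.size < 2:
        raise ValueError("acceptance_value requires at least 2 values")
    if not np.all(np.isfinite(arr)):
        raise ValueError("assay values must be finite")
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1))
    M = reference_value(mean, params)
    av = abs(M - mean) + float(k) * sd
    return AVResult(mean=mean, sd=sd, M=M, k=float(k), av=av)


def individual_limits(
    M: float, params: AcceptanceParams = AcceptanceParams()
) -> tuple[float, float]:
    """Stage-2 individual-unit limits (1 -/+ L2/100) * M in %LC.

    For the default parameters these span 73.875-123.125 at M = 98.5 and
    76.125-126.875 at M = 101.5.
    """
    M = float(M)
    if not math.isfinite(M) or M < 0:
        raise ValueError("M must be finite and non-negative")
    half = params.L2 / 100.0
    return (1.0 - half) * M, (1.0 + half) * M


def judge_batch(
    assays: AssaySet | ArrayLike,
    params: AcceptanceParams = AcceptanceParams(),
) -> BatchJudgment:
    """Apply the two-stage USP <905> decision procedure to one set.

    Stage 1 is computed on the first ``n_stage1`` values with ``k_stage1``;
    if its AV is within L1 the batch passes outright and no stage-2
    quantity is computed.  Otherwise stage 2 pools all ``n_total`` values
    (k = ``k_stage2``) and additionally requires every individual value to
    lie within ``individual_limits`` evaluated at the stage-2 reference
    value.  A 10-value input performs a stage-1-only judgment.
    """
    if not isinstance(assays, AssaySet):
        assays = AssaySet(assays)
    values = assays.values
    stage1_only = values.size == params.n_stage1
    if not stage1_only and values.size != params.n_total:
        raise ValueError(
            f"expected {params.n_total} values (or {params.n_stage1} for a "
            f"stage-1-only judgment), got {values.size}"
        )

    av1 = acceptance_value(values[: params.n_stage1], params.k_stage1, params)
    if av1.av <= params.L1:
        return BatchJudgment(outcome=Outcome.PASS_STAGE1, stage1=av1)
    if stage1_only:
        return BatchJudgment(
            outcome=Outcome.STAGE2_REQUIRED, stage1=av1, stage1_triggered_stage2=True
        )

    av2 = acceptance_value(values, params.k_stage2, params)
    lower, upper = individual_limits(av2.M, params)
    outside = np.flatnonzero((values < lower) | (values > upper))
    failed = av2.av > params.L1 or outside.size > 0
    return BatchJudgment(
        outcome=Outcome.FAIL if failed else Outcome.PASS_STAGE2,
        stage1=av1,
        stage2=av2,
        n_individual_violations=int(outside.size),
        violation_indices=tuple(int(i) for i in outside),
        stage1_triggered_stage2=True,
    )


def judge_matrix(
    assays: NDArray[np.float64],
    params: AcceptanceParams = AcceptanceParams(),
) -> dict[str, NDArray]:
    """Vectorized judgment of many sets at once.

    Parameters
    ----------
    assays
        Array of shape (n_sets, n_total) of %LC values; columns
        0..n_stage1-1 are the stage-1 sample of each set.

    Returns
    -------
    dict with per-set arrays: ``av1``, ``av2``, ``M2``, ``stage1_fail``
    (AV1 > L1, i.e. stage 2 triggered), ``any_violation`` and ``fail``
    (batch-release failure).  Unlike :func:`judge_batch`, stage-2
    quantities are evaluated for every set so that unconditional mean
    acceptance values can be reported; the decision logic is identical.
    """
    a = np.asarray(assays, dtype=float)
    if a.ndim != 2 or a.shape[1] != params.n_total:
        raise ValueError(f"assays must have shape (n_sets, {params.n_total})")
    n1 = params.n_stage1
    s1 = a[:, :n1]
    mean1 = s1.mean(axis=1)
    sd1 = s1.std(axis=1, ddof=1)
    M1 = np.clip(mean1, params.ref_low, params.ref_high)
    av1 = np.abs(M1 - mean1) + params.k_stage1 * sd1

    mean2 = a.mean(axis=1)
    sd2 = a.std(axis=1, ddof=1)
    M2 = np.clip(mean2, params.ref_low, params.ref_high)
    av2 = np.abs(M2 - mean2) + params.k_stage2 * sd2
    half = params.L2 / 100.0
    lower = (1.0 - half) * M2
    upper = (1.0 + half) * M2
    any_violation = ((a < lower[:, None]) | (a > upper[:, None])).any(axis=1)

    stage1_fail = av1 > params.L1
    fail = stage1_fail & ((av2 > params.L1) | any_violation)
    return {
        "av1": av1,
        "av2": av2,
        "M2": M2,
        "stage1_fail": stage1_fail,
        "any_violation": any_violation,
        "fail": fail,
    }
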