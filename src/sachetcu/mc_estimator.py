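"""Monte Carlo estimation of USP <905> failure probabilities.

A scenario couples a tablet-variability model and a fill model; the
estimator simulates many independent sets of 30 sachets, judges each with
the two-stage procedure and reports

* ``p_stage1_fail`` -- the fraction of sets whose stage-1 acceptance value
  exceeds L1 (stage 2 triggered), and
* ``p_stage2_fail`` -- the fraction of sets failing batch release
  (stage 2 AV over L1 or an individual unit outside its limits),

with Wilson 95% score intervals, which remain informative near zero.
Estimates with no observed failures are flagged as below the reporting
floor (the convention "< 1/n_sets", e.g. <0.0001% at one million sets).

Degenerate regimes admit independent oracles used by the test-suite:
a closed form for the no-miscount stage-1 rate and a count-only evaluation
when tablet variability is zero.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats

from ._rng import substream
from .sachet_sim import FillModel, SachetAssayBlock, TabletModel, simulate_assay_sets
from .usp905 import AcceptanceParams, judge_matrix

__all__ = [
    "ScenarioConfig",
    "FailureEstimate",
    "composite_rsd",
    "estimate_failure",
    "stage1_fail_closed_form",
    "zero_rsd_oracle",
]

#: probabilities smaller than this cannot be resolved at the default set count
REPORTING_FLOOR = 1e-6

_CHUNK_SETS = 250_000


def composite_rsd(weight_rsd: float, potency_rsd: float) -> float:
    """Root sum of squares of weight and potency RSDs (same units in/out).

    Collapses the two bulk variability axes into the single composite-RSD
    axis used by the contour grids: sqrt(w**2 + p**2).
    """
    if weight_rsd < 0 or potency_rsd < 0:
        raise ValueError("RSDs must be non-negative")
    return float(np.hypot(weight_rsd, potency_rsd))


@dataclass(frozen=True)
class ScenarioConfig:
    """Full stochastic specification of one simulated scenario."""

    tablets: TabletModel
    fill: FillModel
    n_sets: int = 1_000_000
    seed: int = 0
    params: AcceptanceParams = field(default_factory=AcceptanceParams)
    method: str = "auto"

    def __post_init__(self) -> None:
        if self.n_sets < 1:
            raise ValueError("n_sets must be >= 1")


@dataclass(frozen=True)
class FailureEstimate:
    """Estimated stage-1/stage-2 failure probabilities for one scenario."""

    p_stage1_fail: float
    p_stage2_fail: float
    ci95_stage1: tuple[float, float]
    ci95_stage2: tuple[float, float]
    mean_av1: float
    mean_av2_all: float
    mean_av2_conditional: float
    n_sets: int
    n_fail_stage1: int
    n_fail_stage2: int
    below_floor_stage1: bool
    below_floor_stage2: bool

    def to_dict(self) -> dict:
        d = {
            "p_stage1_fail": self.p_stage1_fail,
            "p_stage2_fail": self.p_stage2_fail,
            "ci95_stage1_low": self.ci95_stage1[0],
            "ci95_stage1_high": self.ci95_stage1[1],
            "ci95_stage2_low": self.ci95_stage2[0],
            "ci95_stage2_high": self.ci95_stage2[1],
            "mean_av1": self.mean_av1,
            "mean_av2_all": self.mean_av2_all,
            "mean_av2_conditional": self.mean_av2_conditional,
            "n_sets": self.n_sets,
            "n_fail_stage1": self.n_fail_stage1,
            "n_fail_stage2": self.n_fail_stage2,
            "below_floor_stage1": self.below_floor_stage1,
            "below_floor_stage2": self.below_floor_stage2,
        }
        return d


def _wilson(k: int, n: int) -> tuple[float, float]:
    ci = stats.binomtest(k, n).proportion_ci(confidence_level=0.95, method="wilson")
    return (float(ci.low), float(ci.high))


def estimate_failure(
    config: ScenarioConfig,
    *,
    rng: Optional[np.random.Generator] = None,
) -> FailureEstimate:
    """Simulate the scenario and estimate its failure probabilities.

    Sets are generated in chunks through
    :func:`sachetcu.sachet_sim.simulate_assay_sets` and judged with the
    vectorized decision rule; ``mean_av2_all`` averages the stage-2
    acceptance value over every set (whether or not stage 2 was entered)
    while ``mean_av2_conditional`` averages only sets that triggered
    stage 2 (NaN when none did).
    """
    if rng is None:
        rng = substream(config.seed, "estimate_failure")
    n_total = config.params.n_total
    remaining = config.n_sets
    n_fail1 = n_fail2 = 0
    sum_av1 = sum_av2 = sum_av2_cond = 0.0

    while remaining > 0:
        chunk = min(remaining, _CHUNK_SETS)
        block = simulate_assay_sets(
            chunk, config.tablets, config.fill, rng,
            set_size=n_total, method=config.method,
        )
        verdict = judge_matrix(block.assays, config.params)
        n_fail1 += int(verdict["stage1_fail"].sum())
        n_fail2 += int(verdict["fail"].sum())
        sum_av1 += float(verdict["av1"].sum())
        sum_av2 += float(verdict["av2"].sum())
        sum_av2_cond += float(verdict["av2"][verdict["stage1_fail"]].sum())
        remaining -= chunk

    n = config.n_sets
    return FailureEstimate(
        p_stage1_fail=n_fail1 / n,
        p_stage2_fail=n_fail2 / n,
        ci95_stage1=_wilson(n_fail1, n),
        ci95_stage2=_wilson(n_fail2, n),
        mean_av1=sum_av1 / n,
        mean_av2_all=sum_av2 / n,
        mean_av2_conditional=(sum_av2_cond / n_fail1) if n_fail1 else float("nan"),
        n_sets=n,
        n_fail_stage1=n_fail1,
        n_fail_stage2=n_fail2,
        below_floor_stage1=n_fail1 == 0,
        below_floor_stage2=n_fail2 == 0,
    )


def stage1_fail_closed_form(
    sigma_c: float,
    n: int,
    params: AcceptanceParams = AcceptanceParams(),
    *,
    include_mean_term: bool = True,
) -> float:
    """Probability that the stage-1 AV exceeds L1 with no miscounts.

    With error-free fills and composite-mode contents, each sachet assay is
    Normal(100, sigma_s) with sigma_s = 100 * sigma_c / sqrt(n) %LC, so the
    stage-1 sample SD satisfies (n1-1) s^2 / sigma_s^2 ~ chi-square(n1-1)
    independently of the sample mean.  With ``include_mean_term`` the clamp
    contribution |M - mean| = max(distance of the mean outside the
    reference band, 0) is integrated over the Normal(100, sigma_s/sqrt(n1))
    law of the mean (numerical quadrature; exact for this model).  Without
    it the pure chi-square tail P(chi2_{n1-1} > (n1-1) (L1/k1)^2 /
    sigma_s^2) is returned, which is accurate only when the mean rarely
    leaves the reference band.
    """
    if sigma_c < 0:
        raise ValueError("sigma_c must be non-negative")
    if sigma_c == 0:
        return 0.0
    n1 = params.n_stage1
    df = n1 - 1
    sigma_s = 100.0 * sigma_c / np.sqrt(n)
    k1 = params.k_stage1

    if not include_mean_term:
        return float(stats.chi2.sf(df * (params.L1 / k1) ** 2 / sigma_s**2, df))

    sigma_mean = sigma_s / np.sqrt(n1)
    z = np.linspace(-8.0, 8.0, 8001)
    mean = params.target + sigma_mean * z
    outside = np.maximum(np.maximum(params.ref_low - mean, mean - params.ref_high), 0.0)
    thresh = (params.L1 - outside) / k1
    p_fail = np.where(
        thresh <= 0, 1.0, stats.chi2.sf(df * np.maximum(thresh, 1e-300) ** 2 / sigma_s**2, df)
    )
    weights = stats.norm.pdf(z)
    return float(np.trapezoid(p_fail * weights, z))


def _naive_judge_set(assays: list[float], params: AcceptanceParams) -> tuple[bool, bool]:
    """Straightforward scalar re-coding of the two-stage rule (oracle use).

    Deliberately shares no helper code with :mod:`sachetcu.usp905`: plain
    ``statistics`` functions and explicit branching.  Returns
    (stage1_failed, batch_failed).
    """
    first = assays[: params.n_stage1]
    m1 = statistics.fmean(first)
    s1 = statistics.stdev(first)
    if m1 < params.ref_low:
        ref1 = params.ref_low
    elif m1 > params.ref_high:
        ref1 = params.ref_high
    else:
        ref1 = m1
    av1 = abs(ref1 - m1) + params.k_stage1 * s1
    if av1 <= params.L1:
        return False, False
    m2 = statistics.fmean(assays)
    s2 = statistics.stdev(assays)
    if m2 < params.ref_low:
        ref2 = params.ref_low
    elif m2 > params.ref_high:
        ref2 = params.ref_high
    else:
        ref2 = m2
    av2 = abs(ref2 - m2) + params.k_stage2 * s2
    lo = ref2 * (1 - params.L2 / 100.0)
    hi = ref2 * (1 + params.L2 / 100.0)
    bad = any(x < lo or x > hi for x in assays)
    return True, (av2 > params.L1) or bad


def zero_rsd_oracle(
    fill: FillModel,
    params: AcceptanceParams,
    n_sets: int,
    rng: np.random.Generator,
) -> tuple[float, float]:
    """Failure probabilities when tablet variability is exactly zero.

    Every assay is then 100 * c / n for realized count c, so the judgment
    depends only on the 30 counts.  Counts are drawn with the shared fill
    model but the decision rule is an independent scalar re-coding,
    providing a cross-check of :func:`estimate_failure` in the sigma = 0
    regime.  Returns (stage-1, stage-2) failure frequencies.
    """
    from .sachet_sim import draw_fill_counts

    n = fill.target_count
    counts = draw_fill_counts(n_sets * params.n_total, fill, rng)
    assays = (100.0 * counts / n).reshape(n_sets, params.n_total)
    f1 = f2 = 0
    for row in assays:
        a, b = _naive_judge_set(list(row), params)
        f1 += a
        f2 += b
    return f1 / n_sets, f2 / n_sets
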