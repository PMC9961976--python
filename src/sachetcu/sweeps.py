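"""Parameter sweeps and inverse-design solvers.

``run_grid`` evaluates the failure estimator over a lattice of
(fill count x composite RSD x fill-error probability) cells, one named
random substream per cell, and returns a long-format table.  The solvers
answer the two design questions practitioners ask of such a grid:

* which fill counts keep the batch-failure probability below a limit
  (:func:`solve_fill_counts`), and
* how large a per-tablet fill-error probability a process can tolerate at
  a given count (:func:`solve_max_error_prob`).

Both certify against the upper end of the Wilson 95% interval rather than
the point estimate: a noisy estimate below the limit is not evidence of
compliance.  The error-probability solver evaluates its whole lattice
under common random numbers (shared uniforms mapped through the inverse
binomial CDF, shared content normals), so the estimates are paired and
non-decreasing in p up to the coupling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ._rng import substream
from .mc_estimator import FailureEstimate, ScenarioConfig, estimate_failure, _wilson
from .sachet_sim import FillModel, TabletModel, simulate_assay_sets
from .usp905 import AcceptanceParams, judge_matrix

__all__ = [
    "GridSpec",
    "GridResult",
    "run_grid",
    "SolveCountsResult",
    "solve_fill_counts",
    "SolveErrorProbResult",
    "solve_max_error_prob",
]

logger = logging.getLogger(__name__)

_DEFAULT_COUNTS = tuple(range(1, 11))
_DEFAULT_RSDS = tuple(round(0.01 * i, 4) for i in range(16))  # 0..15% by 1 pp
_DEFAULT_ERROR_PROBS = (0.0, 1e-6, 1e-5, 1e-4, 1e-3, 1e-2, 1e-1)


@dataclass(frozen=True)
class GridSpec:
    """Lattice over the modeled ranges (counts 1-10, composite RSD 0-15%,
    per-tablet error probability 0-10%), overridable cell by cell."""

    fill_counts: Sequence[int] = _DEFAULT_COUNTS
    composite_rsds: Sequence[float] = _DEFAULT_RSDS
    error_probs: Sequence[float] = _DEFAULT_ERROR_PROBS
    n_sets: int = 100_000
    seed: int = 0
    overfill_fraction: float = 0.5
    params: AcceptanceParams = field(default_factory=AcceptanceParams)
    method: str = "auto"

    def __post_init__(self) -> None:
        if not (len(self.fill_counts) and len(self.composite_rsds) and len(self.error_probs)):
            raise ValueError("GridSpec lattices must be non-empty")
        if self.n_sets < 1:
            raise ValueError("n_sets must be >= 1")


@dataclass(frozen=True)
class GridResult:
    """Long-format sweep output: one row per lattice cell."""

    table: pd.DataFrame
    spec: GridSpec

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def to_json(self, path) -> None:
        self.table.to_json(path, orient="records", indent=1)

    def max_failure(self, stage: str = "stage2") -> float:
        col = "p_stage1_fail" if stage == "stage1" else "p_stage2_fail"
        return float(self.table[col].max())


def _cell_label(n: int, rsd: float, p: float) -> tuple:
    return ("grid-cell", int(n), float(rsd), float(p))


def run_grid(spec: GridSpec) -> GridResult:
    """Evaluate the failure estimator on every cell of the lattice.

    Each cell runs on an independent substream named by its coordinates,
    so results are reproducible cell-by-cell and independent of evaluation
    order.  A cell that raises is recorded (``error`` column) rather than
    aborting the sweep.
    """
    rows = []
    n_cells = len(spec.fill_counts) * len(spec.composite_rsds) * len(spec.error_probs)
    done = 0
    for n in spec.fill_counts:
        for rsd in spec.composite_rsds:
            for p in spec.error_probs:
                label = _cell_label(n, rsd, p)
                row = {
                    "fill_count": int(n),
                    "composite_rsd": float(rsd),
                    "error_prob": float(p),
                    "substream": repr(label),
                    "error": None,
                }
                try:
                    config = ScenarioConfig(
                        tablets=TabletModel.composite(rsd),
                        fill=FillModel(
                            target_count=int(n),
                            error_prob=float(p),
                            overfill_fraction=spec.overfill_fraction,
                        ),
                        n_sets=spec.n_sets,
                        seed=spec.seed,
                        params=spec.params,
                        method=spec.method,
                    )
                    est = estimate_failure(
                        config, rng=substream(spec.seed, label)
                    )
                    row.update(est.to_dict())
                except Exception as exc:  # pragma: no cover - defensive
                    row["error"] = f"{type(exc).__name__}: {exc}"
                    logger.warning("grid cell %s failed: %s", label, row["error"])
                rows.append(row)
                done += 1
                logger.info(
                    "grid cell %d/%d n=%d rsd=%.4f p=%.2e p2=%s",
                    done, n_cells, n, rsd, p, row.get("p_stage2_fail"),
                )
    return GridResult(table=pd.DataFrame(rows), spec=spec)


@dataclass(frozen=True)
class SolveCountsResult:
    passing: tuple[int, ...]
    estimates: dict[int, FailureEstimate]
    max_fail: float


def solve_fill_counts(
    max_fail: float,
    sigma_c: float,
    p: float,
    counts: Sequence[int] = _DEFAULT_COUNTS,
    n_sets: int = 100_000,
    seed: int = 0,
    params: AcceptanceParams = AcceptanceParams(),
    overfill_fraction: float = 0.5,
) -> SolveCountsResult:
    """Fill counts whose stage-2 failure probability is certified < max_fail.

    A count passes when the upper end of its Wilson 95% interval lies
    below ``max_fail``; with ``max_fail = 0`` no Monte Carlo estimate can
    certify compliance and the result is empty.
    """
    if not len(counts):
        raise ValueError("candidate counts must be non-empty")
    estimates: dict[int, FailureEstimate] = {}
    passing = []
    for n in counts:
        config = ScenarioConfig(
            tablets=TabletModel.composite(sigma_c),
            fill=FillModel(int(n), p, overfill_fraction),
            n_sets=n_sets,
            seed=seed,
            params=params,
        )
        est = estimate_failure(config, rng=substream(seed, ("solve-counts", int(n))))
        estimates[int(n)] = est
        if est.ci95_stage2[1] < max_fail:
            passing.append(int(n))
        logger.info(
            "solve_fill_counts n=%d p2=%.3e ci_high=%.3e pass=%s",
            n, est.p_stage2_fail, est.ci95_stage2[1], est.ci95_stage2[1] < max_fail,
        )
    return SolveCountsResult(tuple(passing), estimates, max_fail)


@dataclass(frozen=True)
class SolveErrorProbResult:
    feasible: bool
    p_max: Optional[float]
    bracket: tuple[Optional[float], Optional[float]]
    p_grid: tuple[float, ...]
    p_stage2_fail: tuple[float, ...]
    ci95_high: tuple[float, ...]


def solve_max_error_prob(
    max_fail: float,
    sigma_c: float,
    n: int,
    p_grid: Sequence[float] = (0.0, 1e-6, 1e-5, 1e-4, 1e-3, 1e-2, 1e-1),
    n_sets: int = 100_000,
    seed: int = 0,
    params: AcceptanceParams = AcceptanceParams(),
    overfill_fraction: float = 0.5,
) -> SolveErrorProbResult:
    """Largest lattice error probability certified to keep failure < max_fail.

    All lattice points are evaluated under common random numbers: one
    shared set of per-sachet uniforms drives the miscount draws through
    the inverse binomial CDF (monotone in p) and one shared set of
    standard normals drives the content noise, so comparisons along the
    lattice are paired.  Certification again uses the Wilson upper bound.
    If even the smallest lattice point cannot be certified the result is
    flagged infeasible.
    """
    p_grid = tuple(sorted(float(p) for p in p_grid))
    if not p_grid:
        raise ValueError("p_grid must be non-empty")
    tablets = TabletModel.composite(sigma_c)
    n_fail = np.zeros(len(p_grid), dtype=np.int64)
    rng = substream(seed, ("solve-error-prob", int(n)))
    n_total = params.n_total

    chunk = 100_000
    remaining = int(n_sets)
    while remaining > 0:
        c_sets = min(remaining, chunk)
        m = c_sets * n_total
        u_err = rng.random(m)
        u_dir = rng.random(m)
        z = rng.standard_normal(m)
        for i, p in enumerate(p_grid):
            fill = FillModel(int(n), p, overfill_fraction)
            # re-plays the shared draws through a dummy generator-free path
            block = _collapsed_with_crn(c_sets, tablets, fill, u_err, u_dir, z, n_total)
            verdict = judge_matrix(block, params)
            n_fail[i] += int(verdict["fail"].sum())
        remaining -= c_sets

    p2 = n_fail / n_sets
    ci_high = np.array([_wilson(int(k), int(n_sets))[1] for k in n_fail])
    ok = ci_high < max_fail
    for i, p in enumerate(p_grid):
        logger.info("solve_max_error_prob p=%.2e p2=%.3e ci_high=%.3e ok=%s",
                    p, p2[i], ci_high[i], bool(ok[i]))
    if not ok[0]:
        return SolveErrorProbResult(False, None, (None, p_grid[0]),
                                    p_grid, tuple(p2), tuple(ci_high))
    idx = int(np.max(np.flatnonzero(ok)))
    # largest certified point and the first uncertified one above it
    upper = p_grid[idx + 1] if idx + 1 < len(p_grid) else None
    return SolveErrorProbResult(True, p_grid[idx], (p_grid[idx], upper),
                                p_grid, tuple(p2), tuple(ci_high))


def _collapsed_with_crn(
    n_sets: int,
    tablets: TabletModel,
    fill: FillModel,
    u_err: np.ndarray,
    u_dir: np.ndarray,
    z: np.ndarray,
    set_size: int,
) -> np.ndarray:
    """Composite-mode assay matrix driven entirely by shared draws."""
    from .sachet_sim import draw_fill_counts

    counts = draw_fill_counts(
        n_sets * set_size, fill, rng=None, u_error=u_err, u_direction=u_dir
    )
    sigma = tablets.composite_rsd_value
    sums = counts + np.sqrt(counts) * sigma * z
    np.maximum(sums, 0.0, out=sums)
    assays = 100.0 * sums / fill.target_count
    return assays.reshape(n_sets, set_size)
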