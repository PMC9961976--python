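"""Stochastic model of sachet filling: tablet variability and miscounts.

Each sachet targets ``n`` mini-tablets.  Every intended tablet carries an
independent Bernoulli(p) miscount opportunity; a realized error adds or
removes one tablet (overfill with probability ``overfill_fraction``, else
underfill), so a single sachet can accumulate several +/-1 miscounts.  The
drug content of each tablet is drawn either as the product of independent
weight and potency factors Normal(1, sigma_w) * Normal(1, sigma_p)
("separate" mode) or as a single Normal(1, sigma_c) ("composite" mode);
the batch is centred at 100% of target in both.  The sachet assay in
percent of label claim is

    assay = 100 * (sum of the realized tablets' contents) / n.

Negative draws are floored at zero (a >= 6.7 sigma event at the modeled
RSDs); realized counts cannot fall below zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np
from numpy.typing import NDArray
from scipy import stats

__all__ = [
    "TabletModel",
    "FillModel",
    "SachetAssayBlock",
    "content_rsd",
    "draw_fill_counts",
    "draw_tablet_contents",
    "simulate_assay_sets",
]

_CHUNK_TABLETS = 20_000_000  # per-tablet sampling works in chunks of this many draws


@dataclass(frozen=True)
class TabletModel:
    """Bulk mini-tablet variability (all RSDs as fractions, e.g. 0.05).

    ``separate`` mode draws weight and potency-per-weight factors
    independently; ``composite`` mode draws a single content factor whose
    RSD is typically the root sum of squares of the two (Eq. bridge in
    :func:`sachetcu.mc_estimator.composite_rsd`).
    """

    mode: Literal["separate", "composite"]
    weight_rsd: Optional[float] = None
    potency_rsd: Optional[float] = None
    composite_rsd_value: Optional[float] = None

    def __post_init__(self) -> None:
        if self.mode == "separate":
            if self.weight_rsd is None or self.potency_rsd is None:
                raise ValueError("separate mode requires weight_rsd and potency_rsd")
            if self.composite_rsd_value is not None:
                raise ValueError("separate mode must leave composite_rsd_value unset")
            if self.weight_rsd < 0 or self.potency_rsd < 0:
                raise ValueError("RSDs must be non-negative")
        elif self.mode == "composite":
            if self.composite_rsd_value is None:
                raise ValueError("composite mode requires composite_rsd_value")
            if self.weight_rsd is not None or self.potency_rsd is not None:
                raise ValueError("composite mode must leave weight/potency RSDs unset")
            if self.composite_rsd_value < 0:
                raise ValueError("RSDs must be non-negative")
        else:
            raise ValueError(f"unknown mode {self.mode!r}")

    @classmethod
    def separate(cls, weight_rsd: float, potency_rsd: float) -> "TabletModel":
        return cls(mode="separate", weight_rsd=weight_rsd, potency_rsd=potency_rsd)

    @classmethod
    def composite(cls, rsd: float) -> "TabletModel":
        return cls(mode="composite", composite_rsd_value=rsd)


@dataclass(frozen=True)
class FillModel:
    """Sachet filling process: target count and per-tablet miscount law."""

    target_count: int
    error_prob: float = 0.0
    overfill_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.target_count < 1:
            raise ValueError("target_count must be >= 1")
        if not 0.0 <= self.error_prob <= 1.0:
            raise ValueError("error_prob must lie in [0, 1]")
        if not 0.0 <= self.overfill_fraction <= 1.0:
            raise ValueError("overfill_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class SachetAssayBlock:
    """Simulated assays (%LC) and realized fill counts, shape (n_sets, set_size)."""

    assays: NDArray[np.float64]
    counts: NDArray[np.int64]


def content_rsd(tablets: TabletModel) -> float:
    """Exact RSD of a single tablet's content under the model.

    For independent weight and potency factors the variance of the product
    is sigma_w**2 + sigma_p**2 + sigma_w**2 * sigma_p**2.
    """
    if tablets.mode == "composite":
        return float(tablets.composite_rsd_value)
    w, p = float(tablets.weight_rsd), float(tablets.potency_rsd)
    return float(np.sqrt(w * w + p * p + w * w * p * p))


def _quantile_binomial(u: NDArray, n: int, p: float) -> NDArray[np.int64]:
    """Inverse-CDF Binomial(n, p) draw from shared uniforms (CRN coupling)."""
    cdf = stats.binom.cdf(np.arange(n + 1), n, p)
    return np.searchsorted(cdf, u, side="left").astype(np.int64)


def draw_fill_counts(
    n_sachets: int,
    fill: FillModel,
    rng: np.random.Generator,
    *,
    u_error: Optional[NDArray] = None,
    u_direction: Optional[NDArray] = None,
) -> NDArray[np.int64]:
    """Realized per-sachet fill counts n + sum_i E_i * D_i, clamped at >= 0.

    ``E_i ~ Bernoulli(error_prob)`` independently for each of the ``n``
    intended tablets and ``D_i = +1`` with probability
    ``overfill_fraction`` else ``-1``.  Equivalently the number of errors
    is Binomial(n, p) and the overfills among them Binomial(e, f).

    ``u_error``/``u_direction`` optionally supply per-sachet uniforms used
    through the inverse CDF instead of fresh draws; sharing them across
    scenarios yields common-random-number coupling that is monotone in
    ``error_prob``.
    """
    if n_sachets < 1:
        raise ValueError("n_sachets must be >= 1")
    n, p, f = fill.target_count, fill.error_prob, fill.overfill_fraction
    if p == 0.0 and u_error is None:
        return np.full(n_sachets, n, dtype=np.int64)

    if u_error is None:
        e = rng.binomial(n, p, size=n_sachets).astype(np.int64)
    else:
        e = _quantile_binomial(np.asarray(u_error), n, p)

    o = np.zeros_like(e)
    hit = e > 0
    if hit.any():
        if u_direction is None:
            o[hit] = rng.binomial(e[hit], f)
        else:
            u_dir = np.asarray(u_direction)
            for k in np.unique(e[hit]):
                sel = e == k
                o[sel] = _quantile_binomial(u_dir[sel], int(k), f)

    c = n + 2 * o - e
    return np.maximum(c, 0)


def draw_tablet_contents(
    n_tablets: int,
    tablets: TabletModel,
    rng: np.random.Generator,
) -> NDArray[np.float64]:
    """Relative drug contents (target = 1) of ``n_tablets`` mini-tablets."""
    if n_tablets < 0:
        raise ValueError("n_tablets must be >= 0")
    if tablets.mode == "composite":
        contents = rng.normal(1.0, tablets.composite_rsd_value, size=n_tablets)
    else:
        w = rng.normal(1.0, tablets.weight_rsd, size=n_tablets)
        p = rng.normal(1.0, tablets.potency_rsd, size=n_tablets)
        _floor_negative(w)
        _floor_negative(p)
        contents = w * p
    _floor_negative(contents)
    return contents


def _floor_negative(arr: NDArray[np.float64]) -> None:
    neg = arr < 0
    n_neg = int(np.count_nonzero(neg))
    if n_neg:
        warnings.warn(
            f"floored {n_neg} negative content draw(s) at zero", RuntimeWarning,
            stacklevel=3,
        )
        arr[neg] = 0.0


def simulate_assay_sets(
    n_sets: int,
    tablets: TabletModel,
    fill: FillModel,
    rng: np.random.Generator,
    *,
    set_size: int = 30,
    method: Literal["auto", "tablet", "collapsed"] = "auto",
    u_error: Optional[NDArray] = None,
    u_direction: Optional[NDArray] = None,
) -> SachetAssayBlock:
    """Simulate ``n_sets`` sets of ``set_size`` sachet assays (%LC).

    ``method="tablet"`` draws every realized tablet's content explicitly.
    ``method="collapsed"`` (composite mode only) uses the fact that the sum
    of c iid Normal(1, sigma_c) contents is exactly Normal(c, sqrt(c) *
    sigma_c) and draws one normal per sachet; the two methods sample the
    same distribution up to the negligible non-negativity floor.
    ``"auto"`` picks collapsed in composite mode, tablet otherwise.
    """
    if n_sets < 1:
        raise ValueError("n_sets must be >= 1")
    if method == "auto":
        method = "collapsed" if tablets.mode == "composite" else "tablet"
    if method == "collapsed" and tablets.mode != "composite":
        raise ValueError("collapsed sampling requires composite mode")

    m = n_sets * set_size
    counts = draw_fill_counts(m, fill, rng, u_error=u_error, u_direction=u_direction)
    n = fill.target_count

    if method == "collapsed":
        sigma = tablets.composite_rsd_value
        sums = rng.normal(counts.astype(float), np.sqrt(counts, dtype=float) * sigma)
        np.maximum(sums, 0.0, out=sums)
    else:
        sums = np.empty(m, dtype=float)
        chunk = max(1, _CHUNK_TABLETS // max(n, 1))
        for lo in range(0, m, chunk):
            hi = min(lo + chunk, m)
            sums[lo:hi] = _tablet_sums(counts[lo:hi], n, tablets, rng)

    assays = 100.0 * sums / n
    return SachetAssayBlock(
        assays=assays.reshape(n_sets, set_size),
        counts=counts.reshape(n_sets, set_size),
    )


def _tablet_sums(
    counts: NDArray[np.int64], n: int, tablets: TabletModel, rng: np.random.Generator
) -> NDArray[np.float64]:
    """Sum of ``counts[j]`` iid tablet contents for each sachet j.

    Draws an (m, n) base block, keeps the first min(c, n) tablets of each
    row via a cumulative sum, and draws the c - n extras of overfilled
    sachets separately; exact because tablets are iid.
    """
    m = counts.size
    base = draw_tablet_contents(m * n, tablets, rng).reshape(m, n)
    cum = np.cumsum(base, axis=1)
    kept = np.minimum(counts, n)
    sums = np.where(kept > 0, cum[np.arange(m), np.maximum(kept, 1) - 1], 0.0)

    extra = counts - n
    over = np.flatnonzero(extra > 0)
    if over.size:
        n_extra = extra[over]
        draws = draw_tablet_contents(int(n_extra.sum()), tablets, rng)
        offsets = np.concatenate(([0], np.cumsum(n_extra)[:-1]))
        sums[over] += np.add.reduceat(draws, offsets)
    return sums
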