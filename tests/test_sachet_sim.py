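"""Tests for the sachet filling / tablet content generator."""

import numpy as np
import pytest
from scipy import stats

from sachetcu._rng import substream
from sachetcu.sachet_sim import (
    FillModel,
    TabletModel,
    content_rsd,
    draw_fill_counts,
    draw_tablet_contents,
    simulate_assay_sets,
)


def exact_count_pmf(n, p, f):
    """Distribution of the realized count by direct enumeration.

    Errors e ~ Binomial(n, p), overfills o ~ Binomial(e, f),
    c = max(n + 2o - e, 0); summing the joint pmf over (e, o) enumerates
    every error/direction outcome exactly.
    """
    pmf = {}
    for e in range(n + 1):
        pe = stats.binom.pmf(e, n, p)
        for o in range(e + 1):
            c = max(n + 2 * o - e, 0)
            pmf[c] = pmf.get(c, 0.0) + pe * stats.binom.pmf(o, e, f)
    return pmf


class TestDrawFillCounts:
    def test_error_free_counts_are_exact(self, rng):
        counts = draw_fill_counts(1000, FillModel(4, 0.0), rng)
        assert np.all(counts == 4)

    def test_forced_overfill(self, rng):
        counts = draw_fill_counts(500, FillModel(3, 1.0, overfill_fraction=1.0), rng)
        assert np.all(counts == 6)

    def test_forced_underfill_clamps_at_zero(self, rng):
        counts = draw_fill_counts(500, FillModel(1, 1.0, overfill_fraction=0.0), rng)
        assert np.all(counts == 0)

    @pytest.mark.parametrize("n,p,f", [(4, 0.1, 0.5), (6, 0.03, 0.2), (2, 0.4, 0.7)])
    def test_matches_enumeration_oracle(self, n, p, f, rng):
        m = 400_000
        counts = draw_fill_counts(m, FillModel(n, p, f), rng)
        pmf = exact_count_pmf(n, p, f)
        for c, prob in pmf.items():
            freq = np.mean(counts == c)
            se = np.sqrt(prob * (1 - prob) / m)
            assert abs(freq - prob) < 4 * se + 1e-9, (c, freq, prob)
        # total-variation against the full enumeration
        support = sorted(pmf)
        tv = 0.5 * sum(abs(np.mean(counts == c) - pmf[c]) for c in support)
        assert tv < 0.002

    def test_quantile_coupling_is_monotone_in_p(self, rng):
        u_err = rng.random(50_000)
        u_dir = rng.random(50_000)
        lo = draw_fill_counts(
            50_000, FillModel(5, 0.001), rng, u_error=u_err, u_direction=u_dir
        )
        hi = draw_fill_counts(
            50_000, FillModel(5, 0.05), rng, u_error=u_err, u_direction=u_dir
        )
        # under shared uniforms the error count per sachet is monotone in p,
        # so every sachet miscounted at the low rate saw errors at the high
        # rate too, and the miscount frequency can only grow
        assert np.mean(hi != 5) > np.mean(lo != 5)
        assert set(np.flatnonzero(lo != 5)) <= set(np.flatnonzero(u_err > (1 - 0.05) ** 5))


class TestDrawTabletContents:
    def test_degenerate_model_is_exact(self, rng):
        contents = draw_tablet_contents(100, TabletModel.separate(0.0, 0.0), rng)
        assert np.all(contents == 1.0)

    def test_composite_moments(self, rng):
        sigma = 0.05
        x = draw_tablet_contents(1_000_000, TabletModel.composite(sigma), rng)
        se_mean = sigma / 1000.0
        assert abs(x.mean() - 1.0) < 3 * se_mean
        assert abs(x.std(ddof=1) - sigma) < 3 * sigma / np.sqrt(2e6)

    def test_separate_mode_product_rsd(self, rng):
        model = TabletModel.separate(0.05, 0.05)
        x = draw_tablet_contents(1_000_000, model, rng)
        expected = content_rsd(model)
        assert expected == pytest.approx(np.sqrt(0.05**2 + 0.05**2 + 0.05**4), rel=1e-12)
        assert abs(x.std(ddof=1) - expected) < 4 * expected / np.sqrt(2e6)

    def test_mode_validation(self):
        with pytest.raises(ValueError):
            TabletModel(mode="composite", weight_rsd=0.05, composite_rsd_value=0.05)
        with pytest.raises(ValueError):
            TabletModel(mode="separate", weight_rsd=0.05)


class TestSimulateAssaySets:
    def test_error_free_zero_rsd_assays_are_100(self, rng):
        block = simulate_assay_sets(
            5, TabletModel.separate(0.0, 0.0), FillModel(4, 0.0), rng
        )
        assert block.assays.shape == (5, 30)
        assert np.all(block.assays == 100.0)
        assert np.all(block.counts == 4)

    @pytest.mark.parametrize("n,expected", [(4, 75.0), (5, 80.0)])
    def test_single_underfill_dose_error(self, n, expected, rng):
        # with zero tablet variability a miscount is an exact 100/n percent
        # dose step: a single underfill gives 75 %LC at n=4 and 80 at n=5
        block = simulate_assay_sets(
            200,
            TabletModel.separate(0.0, 0.0),
            FillModel(n, 0.05, overfill_fraction=0.0),
            rng,
            method="tablet",
        )
        assert np.array_equal(block.assays, 100.0 * block.counts / n)
        single = block.counts == n - 1
        assert single.any()
        assert np.all(block.assays[single] == expected)

    def test_mean_assay_centred_when_directions_balanced(self, rng):
        block = simulate_assay_sets(
            4000, TabletModel.composite(0.05), FillModel(4, 0.01), rng
        )
        se = block.assays.std() / np.sqrt(block.assays.size)
        assert abs(block.assays.mean() - 100.0) < 4 * se

    @pytest.mark.parametrize("n", [1, 4, 9])
    def test_composite_per_sachet_sd_scales_with_root_count(self, n, rng):
        sigma = 0.06
        block = simulate_assay_sets(
            4000, TabletModel.composite(sigma), FillModel(n, 0.0), rng
        )
        expected = 100.0 * sigma / np.sqrt(n)
        observed = block.assays.std(ddof=1)
        se = expected / np.sqrt(2 * block.assays.size)
        assert abs(observed - expected) < 4 * se

    def test_bit_identical_reproducibility(self):
        for method in ("tablet", "collapsed"):
            blocks = [
                simulate_assay_sets(
                    50,
                    TabletModel.composite(0.05),
                    FillModel(3, 0.01),
                    substream(123, "repro"),
                    method=method,
                )
                for _ in range(2)
            ]
            assert np.array_equal(blocks[0].assays, blocks[1].assays)
            assert np.array_equal(blocks[0].counts, blocks[1].counts)

    def test_tablet_and_collapsed_methods_sample_same_law(self, rng):
        """Summing c iid normals equals one Normal(c, sqrt(c) sigma) draw."""
        tablets = TabletModel.composite(0.08)
        fill = FillModel(4, 0.02)
        a = simulate_assay_sets(4000, tablets, fill, rng, method="tablet")
        b = simulate_assay_sets(4000, tablets, fill, rng, method="collapsed")
        ks = stats.ks_2samp(a.assays.ravel(), b.assays.ravel())
        assert ks.pvalue > 1e-3
        assert a.assays.mean() == pytest.approx(b.assays.mean(), abs=0.15)
        assert a.assays.std() == pytest.approx(b.assays.std(), rel=0.03)

    def test_collapsed_requires_composite_mode(self, rng):
        with pytest.raises(ValueError):
            simulate_assay_sets(
                1, TabletModel.separate(0.05, 0.05), FillModel(4, 0.0), rng,
                method="collapsed",
            )
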