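"""Gate hierarchy: thresholds, bands, boxes, contours and tails."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from segnoise import flow
from segnoise import synthetic as syn


def events_from(**cols):
    n = len(next(iter(cols.values())))
    base = {"FSC": np.full(n, 5e4), "SSC": np.full(n, 2.5e4),
            "PW": np.full(n, 2000.0), "FSC_W": np.full(n, 1100.0)}
    base.update(cols)
    return pd.DataFrame(base)


class TestTriggerThreshold:
    def test_boundary_is_inclusive_at_the_threshold(self):
        ev = events_from(FSC=np.array([2569.0, 2570.0, 2571.0]))
        rep = flow.apply_trigger_threshold(ev)
        assert rep.mask.tolist() == [False, True, True]

    def test_empty_table(self):
        rep = flow.apply_trigger_threshold(events_from(FSC=np.array([])))
        assert rep.n_in == 0 and rep.n_out == 0

    def test_counts_by_construction(self):
        rng = np.random.default_rng(0)
        fsc = np.concatenate([rng.uniform(3000, 9000, 63),
                              rng.uniform(100, 2500, 37)])
        rep = flow.apply_trigger_threshold(events_from(FSC=fsc))
        assert rep.n_out == 63

    def test_missing_column_is_schema_error(self):
        with pytest.raises(KeyError, match="FSC"):
            flow.apply_trigger_threshold(pd.DataFrame({"SSC": [1.0]}))


class TestConstantBand:
    def test_constant_y_fully_retained(self):
        rng = np.random.default_rng(1)
        ev = events_from(FSC=rng.uniform(1e3, 1e5, 800),
                         PW=np.full(800, 1500.0))
        rep = flow.gate_constant_band(ev, "PW")
        assert rep.n_out == 800

    def test_injected_outliers_removed_exactly(self):
        rng = np.random.default_rng(2)
        n = 6400
        x = rng.uniform(1e3, 1e5, n)
        y = 2.0 + 1e-7 * x + rng.uniform(-0.01, 0.01, n)  # bounded noise
        outliers = rng.choice(n, size=n // 20, replace=False)
        y[outliers] += 0.5  # ~100 bin-MADs: far outside the band
        ev = events_from(FSC=x, PW=y)
        rep = flow.gate_constant_band(ev, "PW", n_bins=32, k=3.0)
        removed = set(np.flatnonzero(~rep.mask))
        assert removed == set(outliers)
        # independent oracle: recompute the per-bin median +- k MAD band
        edges = np.quantile(x, np.linspace(0, 1, 33))
        bins = np.clip(np.searchsorted(edges, x, side="right") - 1, 0, 31)
        oracle = np.zeros(n, dtype=bool)
        for b in range(32):
            sel = bins == b
            med = np.median(y[sel])
            mad = np.median(np.abs(y[sel] - med))
            oracle[sel] = np.abs(y[sel] - med) <= 3.0 * mad
        assert np.array_equal(rep.mask, oracle)

    def test_infinite_k_retains_everything(self):
        rng = np.random.default_rng(3)
        ev = events_from(FSC=rng.uniform(1e3, 1e5, 500),
                         PW=rng.normal(0, 100, 500))
        rep = flow.gate_constant_band(ev, "PW", k=np.inf)
        assert rep.n_out == 500

    def test_fewer_events_than_bins_falls_back_to_one_bin(self):
        ev = events_from(FSC=np.arange(5.0), PW=np.arange(5.0))
        with pytest.warns(UserWarning, match="one bin"):
            rep = flow.gate_constant_band(ev, "PW", n_bins=32)
        assert rep.params["n_bins"] == 1


class TestPercentileBox:
    def test_independent_uniforms_retain_product_of_margins(self):
        rng = np.random.default_rng(4)
        n = 20_000
        ev = events_from(FSC=rng.random(n), SSC=rng.random(n))
        rep = flow.gate_percentile_box(ev)
        assert abs(rep.n_out / n - 0.90 ** 2) < 0.015

    def test_full_range_retains_all(self):
        rng = np.random.default_rng(5)
        ev = events_from(FSC=rng.random(100), SSC=rng.random(100))
        rep = flow.gate_percentile_box(ev, lo=0, hi=100)
        assert rep.n_out == 100

    def test_perfectly_correlated_channels_retain_single_margin(self):
        x = np.linspace(1, 2, 2000)
        ev = events_from(FSC=x, SSC=x ** 2)  # monotone, perfectly dependent
        rep = flow.gate_percentile_box(ev)
        assert abs(rep.n_out / 2000 - 0.90) < 0.005

    def test_inverted_bounds_rejected(self):
        ev = events_from(FSC=np.arange(10.0))
        with pytest.raises(ValueError, match="lo"):
            flow.gate_percentile_box(ev, lo=95, hi=5)


class TestDensityContour:
    def test_full_keep_frac_retains_all(self):
        rng = np.random.default_rng(6)
        ev = events_from(FSC=rng.random(300), SSC=rng.random(300))
        rep = flow.gate_density_contour(ev, keep_frac=1.0)
        assert rep.n_out == 300

    def test_exact_retained_count(self):
        rng = np.random.default_rng(7)
        ev = events_from(FSC=rng.random(1000), SSC=rng.random(1000))
        rep = flow.gate_density_contour(ev, keep_frac=0.60)
        assert rep.n_out == 600

    def test_gaussian_contour_matches_analytic_ellipse(self):
        # highest-density 60% of a standard bivariate normal is the disc
        # of Mahalanobis radius sqrt(chi2.ppf(0.6, df=2))
        rng = np.random.default_rng(8)
        n = 100_000
        x, y = rng.standard_normal((2, n))
        ev = events_from(FSC=x, SSC=y)
        rep = flow.gate_density_contour(ev, keep_frac=0.60)
        radius = np.sqrt(x ** 2 + y ** 2)
        analytic = np.sqrt(stats.chi2.ppf(0.60, df=2))
        # grid quantization blurs the boundary by a bin width or two
        assert abs(np.quantile(radius[rep.mask], 0.99) - analytic) < 0.15

    def test_bad_keep_frac_rejected(self):
        ev = events_from(FSC=np.arange(10.0))
        with pytest.raises(ValueError, match="keep_frac"):
            flow.gate_density_contour(ev, keep_frac=0.0)


class TestSelectTail:
    def test_top_tail_count_and_ordering(self):
        rng = np.random.default_rng(9)
        v = rng.permutation(10_000).astype(float)
        ev = events_from(GFP=v)
        rep = flow.select_tail(ev, "GFP", side="top", frac=0.05)
        assert rep.n_out == 500
        assert v[rep.mask].min() >= v[~rep.mask].max()

    def test_top_and_bottom_are_disjoint(self):
        rng = np.random.default_rng(10)
        ev = events_from(GFP=rng.permutation(1000).astype(float))
        top = flow.select_tail(ev, "GFP", side="top", frac=0.1)
        bottom = flow.select_tail(ev, "GFP", side="bottom", frac=0.1)
        assert not (top.mask & bottom.mask).any()

    def test_uniform_top_tail_starts_near_95th_percentile(self):
        rng = np.random.default_rng(11)
        v = rng.random(50_000)
        rep = flow.select_tail(events_from(GFP=v), "GFP", "top", 0.05)
        assert abs(v[rep.mask].min() - 0.95) < 0.01

    def test_bad_fraction_rejected(self):
        ev = events_from(GFP=np.arange(10.0))
        with pytest.raises(ValueError, match="frac"):
            flow.select_tail(ev, "GFP", frac=1.5)


class TestHierarchy:
    def test_gates_compose_monotonically(self, contaminated_events):
        gated, reports = flow.apply_gate_hierarchy(contaminated_events)
        masks = [r.mask for r in reports]
        for prev, nxt in zip(masks, masks[1:]):
            assert not (nxt & ~prev).any()  # each stage subsets the previous
        assert len(gated) == reports[-1].n_out

    def test_contour_stage_keeps_sixty_percent_of_second_gate(self,
                                                              clean_events):
        gated, reports = flow.apply_gate_hierarchy(clean_events)
        n_second = reports[2].n_out
        assert reports[3].n_out == int(np.rint(0.60 * n_second))
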