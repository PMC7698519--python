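"""Exposure-slope fitting, the R²/detectability filter, and fold-change calls."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from kinarray.signal_processing import (
    call_differential,
    compute_fold_change,
    filter_peptides,
    fit_exposure_slope,
    fit_run,
    preprocess_run,
)
from kinarray.synthetic_data import simulate_run

from conftest import make_truth

EXPOSURES = [10.0, 20.0, 50.0, 100.0, 200.0]


class TestSlopeFit:
    def test_exact_line(self):
        fit = fit_exposure_slope(EXPOSURES, [20, 40, 100, 200, 400])
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(0.0, abs=1e-9)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.detectable

    def test_constant_signal_flat_and_undetectable(self):
        fit = fit_exposure_slope(EXPOSURES, [5, 5, 5, 5, 5])
        assert fit.slope == pytest.approx(0.0)
        assert not fit.detectable

    def test_matches_closed_form_normal_equations(self):
        # frozen from the closed-form normal equations on these 5 points
        fit = fit_exposure_slope(EXPOSURES, [12, 19, 55, 98, 205])
        assert fit.slope == pytest.approx(1.0151741293532337, rel=1e-12)
        assert fit.intercept == pytest.approx(0.6467661691542332, rel=1e-9)
        assert fit.r_squared == pytest.approx(0.9985038534691293, rel=1e-12)

    @given(
        slope=st.floats(-5, 5, allow_nan=False).filter(lambda s: abs(s) >= 1e-3),
        intercept=st.floats(-50, 50, allow_nan=False),
    )
    @settings(max_examples=50, deadline=None)
    def test_recovers_any_affine_series(self, slope, intercept):
        t = np.array(EXPOSURES)
        fit = fit_exposure_slope(t, slope * t + intercept)
        assert fit.slope == pytest.approx(slope, abs=1e-8)
        assert fit.r_squared == pytest.approx(1.0)

    def test_agrees_with_scipy_linregress(self):
        rng = np.random.default_rng(3)
        t = np.array(EXPOSURES)
        for _ in range(10):
            y = rng.normal(size=5) * 10 + 2 * t
            fit = fit_exposure_slope(t, y)
            lr = stats.linregress(t, y)
            assert fit.slope == pytest.approx(lr.slope)
            assert fit.intercept == pytest.approx(lr.intercept)
            assert fit.r_squared == pytest.approx(lr.rvalue**2)

    def test_rejects_degenerate_series(self):
        with pytest.raises(ValueError):
            fit_exposure_slope([10], [1])
        with pytest.raises(ValueError):
            fit_exposure_slope([10, 10], [1, 2])
        with pytest.raises(ValueError):
            fit_exposure_slope([10, 20], [np.nan, 1.0])

    def test_vectorized_fit_matches_single_series(self, catalog, kmap):
        run = simulate_run(catalog, kmap, make_truth([], noise_sd=8.0), n_replicates=1)
        fits = fit_run(run.frame).set_index(["peptide_id", "sample_id"])
        sub = run.frame[run.frame["sample_id"] == "case_1"]
        for pep in catalog.peptide_ids[:10]:
            series = sub[sub["peptide_id"] == pep]
            single = fit_exposure_slope(series["exposure_ms"], series["intensity"])
            row = fits.loc[(pep, "case_1")]
            assert row["slope"] == pytest.approx(single.slope)
            assert row["r_squared"] == pytest.approx(single.r_squared)


def _fits_frame(rows):
    return pd.DataFrame(
        rows, columns=["peptide_id", "sample_id", "condition", "replicate", "slope", "r_squared", "detectable"]
    )


class TestFilter:
    def test_single_low_r2_sample_excludes_peptide(self):
        fits = _fits_frame(
            [
                ("p1", "case_1", "case", 1, 1.0, 0.89, True),
                ("p1", "control_1", "control", 1, 1.0, 0.99, True),
                ("p2", "case_1", "case", 1, 1.0, 0.95, True),
                ("p2", "control_1", "control", 1, 1.0, 0.95, True),
            ]
        )
        assert filter_peptides(fits) == {"p2"}

    def test_r2_boundary_inclusive(self):
        fits = _fits_frame(
            [
                ("exact", "s", "case", 1, 1.0, 0.90, True),
                ("below", "s", "case", 1, 1.0, 0.8999, True),
            ]
        )
        assert filter_peptides(fits) == {"exact"}

    def test_controls_never_retained(self):
        fits = _fits_frame([("ctrl", "s", "case", 1, 1.0, 1.0, True)])
        assert filter_peptides(fits, control_ids={"ctrl"}) == set()

    def test_empty_input(self):
        assert filter_peptides(_fits_frame([])) == set()

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=8))
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_r2_threshold(self, r2s):
        fits = _fits_frame(
            [(f"p{i}", "s", "case", 1, 1.0, r2, True) for i, r2 in enumerate(r2s)]
        )
        lo = filter_peptides(fits, r2_min=0.5)
        hi = filter_peptides(fits, r2_min=0.9)
        assert hi <= lo


class TestFoldChange:
    @staticmethod
    def _paired_fits(case_slopes, ctrl_slopes):
        rows = []
        for i, s in enumerate(case_slopes, start=1):
            rows.append(("p", f"case_{i}", "case", i, s, 1.0, True))
        for i, s in enumerate(ctrl_slopes, start=1):
            rows.append(("p", f"control_{i}", "control", i, s, 1.0, True))
        return _fits_frame(rows)

    def test_ratio_mean_across_replicates(self):
        fits = self._paired_fits([1.2, 1.3, 1.4], [1.0, 1.0, 1.0])
        table, excluded = compute_fold_change(fits, {"p"})
        assert not excluded
        assert table.loc[0, "fc"] == pytest.approx(1.3)
        assert table.loc[0, "n_replicates"] == 3

    def test_identity_when_case_equals_control(self):
        fits = self._paired_fits([0.7, 2.0], [0.7, 2.0])
        table, _ = compute_fold_change(fits, {"p"})
        assert table.loc[0, "fc"] == pytest.approx(1.0)
        assert table.loc[0, "log2fc"] == pytest.approx(0.0)

    def test_nonpositive_control_slope_routed_to_exclusion(self):
        fits = self._paired_fits([1.0], [-0.5])
        table, excluded = compute_fold_change(fits, {"p"})
        assert excluded == {"p"} and table.empty

    def test_geometric_option(self):
        fits = self._paired_fits([2.0, 8.0], [1.0, 1.0])
        arith, _ = compute_fold_change(fits, {"p"}, ratio_mean="arithmetic")
        geom, _ = compute_fold_change(fits, {"p"}, ratio_mean="geometric")
        assert arith.loc[0, "fc"] == pytest.approx(5.0)
        assert geom.loc[0, "fc"] == pytest.approx(4.0)

    @given(st.lists(st.floats(0.1, 10), min_size=1, max_size=5))
    @settings(max_examples=50, deadline=None)
    def test_reciprocal_symmetry_per_replicate(self, slopes):
        # fc(case, control) * fc(control, case) == 1 for each replicate ratio
        case = np.array(slopes)
        ctrl = np.ones_like(case)
        forward = case / ctrl
        backward = ctrl / case
        assert np.allclose(forward * backward, 1.0)

    def test_noise_free_spiked_fc_is_exact_power_of_effect(self, catalog, kmap, spiked_family):
        _, members = spiked_family
        run = simulate_run(catalog, kmap, make_truth(members, effect=1.0, noise_sd=0.0))
        pre = preprocess_run(run.frame, control_ids=catalog.control_ids)
        fc = dict(zip(pre.fold_changes["peptide_id"], pre.fold_changes["fc"]))
        for pep in run.spiked_peptides:
            assert fc[pep] == pytest.approx(2.0, rel=1e-9)


class TestDifferentialCall:
    @pytest.mark.parametrize(
        "fc,expected",
        [(1.30, True), (0.70, True), (1.29, False), (0.71, False), (1.00, False), (2.5, True), (0.1, True)],
    )
    def test_inclusive_thresholds(self, fc, expected):
        assert call_differential(fc) is expected

    def test_invalid_threshold_order(self):
        with pytest.raises(ValueError):
            call_differential(1.0, up=0.5, down=0.7)

    def test_noise_free_differential_set_equals_spiked_truth(self, catalog, kmap, spiked_family):
        _, members = spiked_family
        run = simulate_run(catalog, kmap, make_truth(members, effect=1.5, noise_sd=0.0))
        pre = preprocess_run(run.frame, control_ids=catalog.control_ids)
        assert pre.differential == run.spiked_peptides
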