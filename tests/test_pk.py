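import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ivpharm import (
    CalibrationCurve,
    cell_concentrations,
    fit_calibration,
    fit_uptake_kinetics,
    fluorescence_to_concentration,
    label_regions,
    nuclear_fraction,
    one_compartment_concentration,
    subtherapeutic_fraction,
    vessel_curve,
)
from ivpharm.errors import CalibrationError, StructuralError

from conftest import regions_from_truth


class TestCalibration:
    def test_noiseless_line_recovered_exactly(self):
        table = [(0.2, 0.1), (0.4, 0.2), (0.6, 0.3)]  # conc = 2 * fluor
        curve = fit_calibration(table)
        assert curve.slope == pytest.approx(2.0)
        assert curve.intercept == pytest.approx(0.0, abs=1e-12)
        assert curve.r_squared == pytest.approx(1.0)
        assert curve.valid_range == pytest.approx((0.1, 0.3))

    def test_matches_normal_equations(self):
        fluor = np.array([0.1, 0.25, 0.6])
        conc = np.array([0.5, 1.9, 4.1])
        sxx = ((fluor - fluor.mean()) ** 2).sum()
        sxy = ((fluor - fluor.mean()) * (conc - conc.mean())).sum()
        slope = sxy / sxx
        intercept = conc.mean() - slope * fluor.mean()
        curve = fit_calibration(list(zip(conc, fluor)))
        assert curve.slope == pytest.approx(slope)
        assert curve.intercept == pytest.approx(intercept)

    def test_degenerate_designs_rejected(self):
        with pytest.raises(CalibrationError):
            fit_calibration([(1.0, 0.1), (2.0, 0.2)])  # too few points
        with pytest.raises(CalibrationError):
            fit_calibration([(1.0, 0.1), (1.0, 0.2), (1.0, 0.3)])  # one concentration
        with pytest.raises(CalibrationError):
            fit_calibration([(1.0, 0.2), (2.0, 0.2), (3.0, 0.2)])  # flat fluorescence

    def test_conversion_and_extrapolation_flag(self):
        curve = CalibrationCurve(slope=2.0, intercept=0.0, r_squared=1.0, valid_range=(0.1, 0.3))
        value, extrapolated = fluorescence_to_concentration(curve, 0.2)
        assert value == pytest.approx(0.4) and not extrapolated
        assert fluorescence_to_concentration(curve, 0.0)[0] == pytest.approx(0.0)
        assert fluorescence_to_concentration(curve, 0.5)[1] is True

    def test_affine_identity(self):
        curve = CalibrationCurve(slope=3.0, intercept=-0.7, r_squared=1.0, valid_range=(0, 1))
        a, b = 0.31, 0.57
        assert curve.convert(a) + curve.convert(b) == pytest.approx(
            curve.convert(a + b) + curve.convert(0.0)
        )


class TestCellConcentrations:
    def _curve(self):
        return CalibrationCurve(slope=2.0, intercept=0.0, r_squared=1.0, valid_range=(0, 1))

    def test_uniform_drug_frame(self):
        mask = np.zeros((16, 16), bool)
        mask[2:6, 2:6] = True
        mask[10:14, 10:14] = True
        lab = label_regions(mask)
        drug = np.full((1, 16, 16), 0.25)
        series = cell_concentrations([lab], drug, self._curve())
        assert series.cells["conc_uM"].to_numpy() == pytest.approx([0.5, 0.5])
        assert series.frames.loc[0, "sd_uM"] == pytest.approx(0.0)

    def test_frame_without_cells_is_nan_not_crash(self):
        lab = label_regions(np.zeros((8, 8), bool))
        series = cell_concentrations([lab], np.zeros((1, 8, 8)), self._curve())
        assert series.frames.loc[0, "n_cells"] == 0
        assert math.isnan(series.frames.loc[0, "mean_uM"])
        assert series.cells.empty

    def test_estimates_within_noise_propagation_bound(self, pk_movie):
        spec, stack, truth = pk_movie
        regs = [regions_from_truth(lm) for lm in truth.label_maps]
        series = cell_concentrations(regs, stack.channels["drug"], spec.calibration(),
                                     spec.frame_interval_s)
        err, tol = [], []
        for r in series.cells.itertuples():
            lab = regs[int(r.frame)]
            area = {rg.id: rg.area_px for rg in lab.regions}[int(r.cell_id)]
            err.append(abs(r.conc_uM - truth.conc_uM[int(r.frame), int(r.cell_id) - 1]))
            tol.append(3 * spec.calibration_slope * spec.noise_sigma / math.sqrt(area))
        frac = (np.asarray(err) <= np.asarray(tol)).mean()
        assert frac >= 0.99


class TestVesselCurve:
    def _curve(self):
        return CalibrationCurve(slope=4.0, intercept=0.0, r_squared=1.0, valid_range=(0, 1))

    def test_uniform_frames_constant_series(self):
        frames = np.full((3, 8, 8), 0.5)
        out = vessel_curve(frames, (1, 4, 1, 4), self._curve())
        assert out["vessel_uM"].to_numpy() == pytest.approx([2.0] * 3)

    def test_single_pixel_roi(self):
        frames = np.random.default_rng(0).random((4, 8, 8))
        out = vessel_curve(frames, (2, 3, 5, 6), self._curve())
        assert out["vessel_uM"].to_numpy() == pytest.approx(4.0 * frames[:, 2, 5])

    def test_roi_out_of_bounds_rejected(self):
        with pytest.raises(StructuralError):
            vessel_curve(np.zeros((2, 8, 8)), (0, 9, 0, 4), self._curve())

    def test_recovers_synthetic_vessel_kinetics(self, pk_movie):
        spec, stack, truth = pk_movie
        out = vessel_curve(stack.channels["drug"], truth.vessel_roi, spec.calibration(),
                           spec.frame_interval_s)
        err = np.abs(out["vessel_uM"].to_numpy() - truth.vessel_uM)
        assert err.max() < 5 * spec.calibration_slope * spec.noise_sigma


class TestSubtherapeuticFraction:
    def test_examples(self):
        assert subtherapeutic_fraction([2.0, 3.0, 1.5]) == 0.0  # boundary counts as therapeutic
        assert subtherapeutic_fraction([0.5, 1.0, 2.0, 3.0]) == 0.5
        assert subtherapeutic_fraction([0.5, 1.0], threshold_uM=0.0) == 0.0

    def test_empty_is_undefined(self):
        assert math.isnan(subtherapeutic_fraction([]))

    @settings(max_examples=25, derandomize=True)
    @given(st.lists(st.floats(0, 10), min_size=1, max_size=20), st.floats(0, 3))
    def test_nonincreasing_under_uniform_dose_increase(self, concs, boost):
        before = subtherapeutic_fraction(concs)
        after = subtherapeutic_fraction([c + boost for c in concs])
        assert after <= before


class TestNuclearFraction:
    def test_all_signal_inside_nuclei(self):
        mask = np.zeros((20, 20), bool)
        mask[8:12, 8:12] = True
        lab = label_regions(mask)
        drug = np.where(mask, 0.8, 0.0)
        assert nuclear_fraction(lab, drug, ring_radius=3) == pytest.approx(1.0)

    def test_uniform_drug_equals_area_ratio(self):
        from ivpharm.segmentation import disk_element
        from scipy import ndimage as ndi

        mask = np.zeros((30, 30), bool)
        mask[12:18, 12:18] = True
        lab = label_regions(mask)
        drug = np.full((30, 30), 0.6)
        ring = ndi.binary_dilation(mask, structure=disk_element(4)) & ~mask
        expected = mask.sum() / (mask.sum() + ring.sum())
        assert nuclear_fraction(lab, drug, ring_radius=4) == pytest.approx(expected)

    def test_zero_signal_is_undefined(self):
        mask = np.zeros((10, 10), bool)
        mask[4:6, 4:6] = True
        assert math.isnan(nuclear_fraction(label_regions(mask), np.zeros((10, 10))))


class TestUptakeKinetics:
    def test_zero_efflux_matches_integrated_vessel_input(self):
        # k_out = 0: C(t) = k_in * peak * (1 - exp(-k_decay t)) / k_decay
        t = np.linspace(0, 7200, 97)
        peak, kd, k_in = 6.0, 4e-4, 5e-4
        got = one_compartment_concentration(t, peak, kd, k_in, 0.0)
        expected = k_in * peak * (1 - np.exp(-kd * t)) / kd
        np.testing.assert_allclose(got, expected, rtol=1e-12)

    def test_closed_form_satisfies_ode(self):
        t = np.linspace(0, 7200, 200)
        peak, kd, k_in, k_out = 6.0, 4e-4, 5e-4, 1e-4
        c = one_compartment_concentration(t, peak, kd, k_in, k_out)
        cv = peak * np.exp(-kd * t)
        dcdt = k_in * peak * (-kd * np.exp(-kd * t) + k_out * np.exp(-k_out * t)) / (k_out - kd)
        residual = np.abs(dcdt - (k_in * cv - k_out * c))
        assert residual.max() < 1e-8

    def test_refit_recovers_true_rates_within_10_percent(self, pk_movie):
        spec, stack, truth = pk_movie
        regs = [regions_from_truth(lm) for lm in truth.label_maps]
        series = cell_concentrations(regs, stack.channels["drug"], spec.calibration(),
                                     spec.frame_interval_s)
        fit = fit_uptake_kinetics(series.frames["time_s"], series.frames["mean_uM"],
                                  spec.kinetics.vessel_peak_uM, spec.kinetics.k_decay)
        true_k_in = np.mean([c["k_in"] for c in truth.cells])
        assert abs(fit["k_in"] - true_k_in) / true_k_in < 0.10
        assert abs(fit["k_out"] - spec.kinetics.k_out) / spec.kinetics.k_out < 0.10

    def test_measured_subtherapeutic_fraction_matches_truth(self, pk_movie):
        spec, stack, truth = pk_movie
        regs = [regions_from_truth(lm) for lm in truth.label_maps]
        series = cell_concentrations(regs, stack.channels["drug"], spec.calibration(),
                                     spec.frame_interval_s)
        last = spec.n_frames - 1
        measured = subtherapeutic_fraction(
            series.cells[series.cells["frame"] == last]["conc_uM"].to_numpy()
        )
        assert measured == pytest.approx((truth.conc_uM[last] < 1.5).mean())
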