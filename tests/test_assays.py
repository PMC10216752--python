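import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from flimflux.assays import (
    adenylate_energy_charge,
    atp_adp_ratio,
    block_levels,
    calibrate,
    integrate_peaks,
    mtt_normalize,
    nucleotide_panel,
    rate_robust,
    respiration_metrics,
    respiration_metrics_table,
)
from flimflux.synthetic import (
    FLUX_BLOCKS,
    FluxDesign,
    WellSpec,
    generate_chromatogram,
    generate_flux_traces,
)
from flimflux.stats import welch_ttest


def make_well(name="A1", group="control", rep=1,
              ocr=(100.0, 100.0, 40.0, 160.0, 10.0), ecar=(5.0, 20.0, 22.0, 22.0, 3.0),
              excluded=False):
    return WellSpec(
        well=name, group=group, replicate=rep, excluded=excluded,
        ocr_by_block=dict(zip(FLUX_BLOCKS, ocr)),
        ecar_by_block=dict(zip(FLUX_BLOCKS, ecar)),
    )


class TestIntegratePeaks:
    def test_gaussian_peak_recovered(self):
        chrom = generate_chromatogram({"ATP": 3.0}, {"ATP": 2.0}, noise_sd=0.0)
        # endpoint-baseline subtraction itself removes ~0.11% of a pure
        # Gaussian at +/-4 sigma (tail mass + baseline trapezoid)
        areas = integrate_peaks(chrom.trace, {"ATP": (5.0 - 4 * 0.08, 5.0 + 4 * 0.08)})
        assert areas["ATP"] == pytest.approx(6.0, rel=2e-3)
        wide = integrate_peaks(chrom.trace, {"ATP": (5.0 - 6 * 0.08, 5.0 + 6 * 0.08)})
        assert wide["ATP"] == pytest.approx(6.0, rel=1e-4)

    def test_flat_trace_zero_area(self):
        trace = pd.DataFrame({"time_min": np.linspace(0, 10, 500), "signal": 0.0})
        assert integrate_peaks(trace, {"x": (2.0, 4.0)})["x"] == 0.0

    def test_disjoint_peaks_independent(self):
        win = {"ADP": (3.1, 3.9), "ATP": (4.6, 5.4)}
        a = integrate_peaks(
            generate_chromatogram({"ADP": 1.0, "ATP": 1.0}, {"ADP": 1.0, "ATP": 1.0}).trace, win
        )
        b = integrate_peaks(
            generate_chromatogram({"ADP": 5.0, "ATP": 1.0}, {"ADP": 1.0, "ATP": 1.0}).trace, win
        )
        assert a["ATP"] == pytest.approx(b["ATP"], rel=1e-6)

    def test_baseline_subtraction(self):
        chrom = generate_chromatogram({"ATP": 3.0}, {"ATP": 2.0}, baseline=7.5)
        areas = integrate_peaks(chrom.trace, {"ATP": (4.68, 5.32)})
        assert areas["ATP"] == pytest.approx(6.0, rel=2e-3)

    def test_window_outside_trace_rejected(self):
        trace = pd.DataFrame({"time_min": [0.0, 1.0], "signal": [0.0, 0.0]})
        with pytest.raises(ValueError):
            integrate_peaks(trace, {"x": (0.5, 2.0)})

    def test_overlapping_windows_rejected(self):
        trace = pd.DataFrame({"time_min": np.linspace(0, 10, 100), "signal": 0.0})
        with pytest.raises(ValueError, match="overlap"):
            integrate_peaks(trace, {"a": (1.0, 3.0), "b": (2.0, 4.0)})


class TestCalibrate:
    def test_equal_area_gives_standard_amount(self):
        out = calibrate({"ATP": 8.0}, {"ATP": [8.0]}, {"ATP": [2.5]})
        assert out["ATP"] == pytest.approx(2.5)

    def test_linearity(self):
        c1 = calibrate({"ATP": 4.0}, {"ATP": [8.0]}, {"ATP": [2.0]})
        c2 = calibrate({"ATP": 8.0}, {"ATP": [8.0]}, {"ATP": [2.0]})
        assert c2["ATP"] == pytest.approx(2 * c1["ATP"])

    def test_multipoint_noisy_standards(self):
        rng = np.random.default_rng(0)
        amounts = np.array([1.0, 2.0, 4.0])
        true_factor = 3.0
        areas = true_factor * amounts * (1 + rng.normal(0, 0.01, 3))
        out = calibrate({"ATP": 6.0}, {"ATP": areas}, {"ATP": amounts})
        assert out["ATP"] == pytest.approx(6.0 / true_factor, rel=0.02)

    def test_zero_standard_area_rejected(self):
        with pytest.raises(ValueError):
            calibrate({"ATP": 1.0}, {"ATP": [0.0]}, {"ATP": [1.0]})


class TestAdenylateEnergyCharge:
    def test_all_atp(self):
        assert adenylate_energy_charge(5.0, 0.0, 0.0) == 1.0

    def test_all_adp(self):
        assert adenylate_energy_charge(0.0, 2.0, 0.0) == 0.5

    def test_worked_panel(self):
        assert adenylate_energy_charge(16.25, 1.0, 0.25) == pytest.approx(0.9571, abs=5e-5)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            adenylate_energy_charge(0.0, 0.0, 0.0)

    @given(st.floats(0, 100), st.floats(0, 100), st.floats(0, 100))
    def test_bounded_unit_interval(self, atp, adp, amp):
        if atp + adp + amp == 0:
            return
        aec = adenylate_energy_charge(atp, adp, amp)
        assert 0.0 <= aec <= 1.0

    @given(st.floats(0.1, 50), st.floats(0.1, 50), st.floats(0, 10))
    def test_monotone_in_atp_at_fixed_pool(self, atp, rest, delta):
        # move delta from the ADP+AMP pool into ATP: AEC must not decrease
        lo = adenylate_energy_charge(atp, rest, 0.0)
        d = min(delta, rest)
        hi = adenylate_energy_charge(atp + d, rest - d, 0.0)
        assert hi >= lo - 1e-12


class TestAtpAdpRatio:
    def test_worked(self):
        assert atp_adp_ratio(16.25, 1.0) == pytest.approx(16.25)

    def test_unity_and_zero(self):
        assert atp_adp_ratio(3.0, 3.0) == 1.0
        assert atp_adp_ratio(0.0, 3.0) == 0.0

    def test_zero_adp_flagged(self):
        with pytest.warns(UserWarning):
            assert np.isnan(atp_adp_ratio(1.0, 0.0))


class TestChromatogramRoundTrip:
    def test_aec_recovered(self):
        # generator amounts (ATP, ADP, AMP) = (16.25, 1.0, 1.0): the formula
        # gives (16.25 + 0.5)/18.25 = 0.917808...
        amounts = {"ATP": 16.25, "ADP": 1.0, "AMP": 1.0}
        factors = {"ATP": 2.0, "ADP": 3.0, "AMP": 1.5}
        chrom = generate_chromatogram(amounts, factors, noise_sd=0.0)
        windows = {a: (rt - 0.4, rt + 0.4) for a, rt in chrom.retention_times.items()}
        areas = integrate_peaks(chrom.trace, windows)
        conc = calibrate(
            areas,
            {a: [amounts[a] * factors[a]] for a in amounts},
            {a: [amounts[a]] for a in amounts},
        )
        panel = nucleotide_panel(conc["ATP"], conc["ADP"], conc["AMP"])
        truth_aec = (16.25 + 0.5) / 18.25
        assert panel.aec == pytest.approx(truth_aec, rel=0.005)
        assert panel.atp_adp_ratio == pytest.approx(16.25, rel=0.01)


class TestRateRobust:
    def test_exact_line(self):
        t = np.arange(7.0)
        assert rate_robust(t, 3 * t + 1) == pytest.approx(3.0)

    def test_constant_trace(self):
        assert rate_robust(np.arange(5.0), np.full(5, 2.0)) == 0.0

    def test_outlier_breakdown(self):
        t = np.arange(7.0)
        y = 2 * t + 1
        y[3] += 500.0  # gross outlier
        assert rate_robust(t, y) == pytest.approx(2.0, abs=1e-9)

    def test_matches_ols_on_collinear_data(self):
        t = np.linspace(0, 5, 9)
        y = -4.2 * t + 0.3
        ols = np.polyfit(t, y, 1)[0]
        assert rate_robust(t, y) == pytest.approx(ols, rel=1e-12)

    def test_huber_option(self):
        t = np.arange(10.0)
        assert rate_robust(t, 1.5 * t, method="huber") == pytest.approx(1.5, rel=1e-6)

    def test_duplicate_timestamps_rejected(self):
        with pytest.raises(ValueError):
            rate_robust([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestBlockLevels:
    def test_noiseless_levels_recovered(self):
        plate = generate_flux_traces(FluxDesign(wells=[make_well()]), seed=0)
        per_well, per_rep = block_levels(plate)
        got = dict(zip(per_well["block"], per_well["ocr"]))
        assert got["baseline"] == pytest.approx(100.0)
        assert got["oligomycin"] == pytest.approx(40.0)
        assert got["rotenone_antimycin"] == pytest.approx(10.0)

    def test_excluded_well_absent(self):
        wells = [make_well("A1"), make_well("A2", excluded=True)]
        plate = generate_flux_traces(FluxDesign(wells=wells), seed=0)
        per_well, _ = block_levels(plate)
        assert set(per_well["well"]) == {"A1"}

    def test_unbalanced_pooling_weights_wells_equally(self):
        wells = [
            make_well("A1", rep=1, ocr=(100,) * 5),
            make_well("A2", rep=1, ocr=(200,) * 5),
            make_well("B1", rep=2, ocr=(50,) * 5),
        ]
        plate = generate_flux_traces(FluxDesign(wells=wells), seed=0)
        _, per_rep = block_levels(plate)
        rep1 = per_rep[(per_rep.replicate == 1) & (per_rep.block == "baseline")]
        assert rep1["ocr"].iloc[0] == pytest.approx(150.0)

    def test_all_excluded_warns(self):
        plate = generate_flux_traces(FluxDesign(wells=[make_well(excluded=True)]), seed=0)
        with pytest.warns(UserWarning, match="all wells excluded"):
            per_well, per_rep = block_levels(plate)
        assert per_well.empty and per_rep.empty


class TestRespirationMetrics:
    LEVELS = dict(zip(FLUX_BLOCKS, (100.0, 100.0, 40.0, 160.0, 10.0)))
    ECAR = dict(zip(FLUX_BLOCKS, (5.0, 20.0, 22.0, 22.0, 3.0)))

    def test_worked_arithmetic(self):
        m = respiration_metrics(self.LEVELS, self.ECAR)
        assert m.proton_leak_ocr == pytest.approx(30.0)
        assert m.atp_linked_ocr == pytest.approx(60.0)
        assert m.basal_ocr == pytest.approx(90.0)
        assert m.max_capacity_ocr == pytest.approx(150.0)
        assert m.non_mito_ocr == pytest.approx(10.0)
        assert m.glycolytic_increase_ecar == pytest.approx(15.0)
        assert m.non_glycolytic_ecar == pytest.approx(3.0)

    def test_basal_identity(self):
        m = respiration_metrics(self.LEVELS, self.ECAR)
        assert m.basal_ocr == m.atp_linked_ocr + m.proton_leak_ocr

    def test_zero_leak(self):
        levels = dict(self.LEVELS, oligomycin=10.0)
        assert respiration_metrics(levels, self.ECAR).proton_leak_ocr == 0.0

    def test_negative_leak_flagged(self):
        levels = dict(self.LEVELS, oligomycin=5.0)
        with pytest.warns(UserWarning, match="negative proton leak"):
            m = respiration_metrics(levels, self.ECAR)
        assert m.leak_flagged

    def test_missing_block_rejected(self):
        with pytest.raises(ValueError, match="missing blocks"):
            respiration_metrics({"baseline": 1.0}, self.ECAR)

    def test_group_leak_difference_detected(self):
        # mutant plates generated with +15 leak units; Welch test finds it
        wells = []
        rng_leak = {"control": 30.0, "mutant": 45.0}
        for group in ("control", "mutant"):
            for rep in range(1, 9):
                leak = rng_leak[group]
                ocr = (100.0, 100.0, 10.0 + leak, 160.0, 10.0)
                wells.append(make_well(f"{group[0]}{rep}", group=group, rep=rep, ocr=ocr))
        design = FluxDesign(wells=wells, noise_sd_ocr=2.0)
        plate = generate_flux_traces(design, seed=7)
        _, per_rep = block_levels(plate)
        metrics = respiration_metrics_table(per_rep)
        ctrl = metrics.loc[metrics.group == "control", "proton_leak_ocr"]
        mut = metrics.loc[metrics.group == "mutant", "proton_leak_ocr"]
        t, df, p, diff = welch_ttest(mut, ctrl)
        assert diff == pytest.approx(15.0, abs=3.0)
        assert p < 0.05


class TestMttNormalize:
    def make_plate(self):
        return pd.DataFrame(
            {
                "line": ["wt"] * 4 + ["mut"] * 4,
                "treatment": ["mock", "mock", "cccp", "cccp"] * 2,
                "absorbance": [1.0, 1.2, 0.55, 0.55, 2.0, 2.0, 1.0, 1.0],
            }
        )

    def test_mock_wells_average_one(self):
        out = mtt_normalize(self.make_plate())
        mock = out[out.treatment == "mock"]
        for _, sub in mock.groupby("line"):
            assert sub["viability_norm"].mean() == pytest.approx(1.0)

    def test_half_signal_half_viability(self):
        out = mtt_normalize(self.make_plate())
        assert out.loc[(out.line == "mut") & (out.treatment == "cccp"), "viability_norm"].iloc[0] == pytest.approx(0.5)

    def test_per_line_independence(self):
        plate = self.make_plate()
        out_a = mtt_normalize(plate)
        plate2 = plate.copy()
        plate2.loc[plate2.line == "mut", "absorbance"] *= 10
        out_b = mtt_normalize(plate2)
        wt_a = out_a[out_a.line == "wt"]["viability_norm"].to_numpy()
        wt_b = out_b[out_b.line == "wt"]["viability_norm"].to_numpy()
        np.testing.assert_allclose(wt_a, wt_b)

    def test_missing_mock_rejected(self):
        plate = self.make_plate()
        plate = plate[~((plate.line == "mut") & (plate.treatment == "mock"))]
        with pytest.raises(ValueError, match="mock"):
            mtt_normalize(plate)
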