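"""Peak measurement, doublet pairing, populations, CSP, exchange bounds."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from docklink.grids import SpectrumGrid
from docklink.nmr import (
    Peak,
    PeakDoublet,
    PeakNotFoundError,
    ShiftPerturbation,
    combined_csp,
    estimate_populations,
    exchange_timescale_bound,
    measure_peak_intensity,
    pair_doublets,
    read_sparky_list,
    write_sparky_list,
)
from docklink.synthetic import (
    EnsembleGroundTruth,
    default_grid,
    default_probes,
    generate_spectrum_pair,
)
from conftest import quantify_pair


def _lorentz_grid(center_h, center_c, fwhm_h_ppm=0.02, fwhm_c_ppm=0.08, amp=1.0):
    c_axis, h_axis = default_grid()
    h = h_axis.ppm_scale()
    c = c_axis.ppm_scale()
    lh = 1.0 / (1.0 + (2.0 * (h - center_h) / fwhm_h_ppm) ** 2)
    lc = 1.0 / (1.0 + (2.0 * (c - center_c) / fwhm_c_ppm) ** 2)
    return SpectrumGrid(amp * lc[:, None] * lh[None, :], c_axis, h_axis)


class TestPeakMeasurement:
    def test_on_node_maximum_measured_exactly(self):
        c_axis, h_axis = default_grid()
        center_h = h_axis.index_to_ppm(250)
        center_c = c_axis.index_to_ppm(120)
        spec = _lorentz_grid(center_h, center_c)
        peak = measure_peak_intensity(spec, (center_h, center_c))
        assert peak.height == pytest.approx(1.0, abs=1e-12)
        assert peak.delta_h == pytest.approx(center_h, abs=1e-9)
        assert peak.delta_c == pytest.approx(center_c, abs=1e-9)

    def test_between_node_maximum_within_one_percent(self):
        """Parabolic interpolation of an off-node Lorentzian maximum recovers
        unit height to <1% at ~10 points per linewidth."""
        c_axis, h_axis = default_grid()
        center_h = h_axis.index_to_ppm(250) + 0.45 * h_axis.step_ppm
        center_c = c_axis.index_to_ppm(120) + 0.45 * c_axis.step_ppm
        spec = _lorentz_grid(center_h, center_c)
        peak = measure_peak_intensity(spec, (center_h, center_c))
        assert peak.height == pytest.approx(1.0, rel=0.01)
        assert peak.delta_h == pytest.approx(center_h, abs=h_axis.step_ppm / 4)

    def test_height_ratio_is_linear_in_amplitude(self):
        c_axis, h_axis = default_grid()
        pos_a = (h_axis.index_to_ppm(150), c_axis.index_to_ppm(60))
        pos_b = (h_axis.index_to_ppm(350), c_axis.index_to_ppm(180))
        spec_a = _lorentz_grid(*pos_a, amp=2.0)
        spec_b = _lorentz_grid(*pos_b, amp=1.0)
        both = SpectrumGrid(spec_a.data + spec_b.data, c_axis, h_axis)
        pa = measure_peak_intensity(both, pos_a)
        pb = measure_peak_intensity(both, pos_b)
        assert pa.height / pb.height == pytest.approx(2.0, rel=1e-3)

    def test_no_local_maximum_raises_named_error(self):
        spec = _lorentz_grid(0.7, 13.5)
        with pytest.raises(PeakNotFoundError, match="lonely"):
            # far tail: gradient points back toward the real peak
            measure_peak_intensity(spec, (0.95, 14.2), assignment="lonely")

    def test_maximum_on_grid_edge_flagged_without_interpolation(self):
        c_axis, h_axis = default_grid()
        data = np.zeros((c_axis.npoints, h_axis.npoints))
        data[0, 100] = 5.0  # maximum on the first 13C row
        spec = SpectrumGrid(data, c_axis, h_axis)
        peak = measure_peak_intensity(
            spec, (h_axis.index_to_ppm(100), c_axis.index_to_ppm(0))
        )
        assert peak.on_edge
        assert peak.height == 5.0


class TestDoubletPairing:
    def test_identical_spectra_pair_as_singlets(self):
        """Reference == full length: every probe is U-only, no doublets
        (the fully undocked, ADP-bound situation)."""
        peaks = [
            Peak("I145", 0.75, 13.9, 1.0),
            Peak("I371", 0.55, 13.1, 0.9),
        ]
        result = pair_doublets(peaks, peaks)
        assert len(result.doublets) == 0
        assert len(result.singlets) == 2
        assert all(s.is_singlet for s in result.singlets)

    def test_three_synthetic_doublets_recover_generator_offsets(self):
        truth = EnsembleGroundTruth(
            docked_fraction=0.53, probes=default_probes(), noise_sigma=0.0
        )
        _, pairing = quantify_pair(truth)
        assert len(pairing.doublets) == 3
        assert pairing.overlapped == []
        by_probe = {d.probe: d for d in pairing.doublets}
        for p in truth.probes:
            d = by_probe[p.label]
            csp = combined_csp(d.d_peak, d.u_peak)
            assert csp.delta_h == pytest.approx(p.offset_h, abs=2e-4)
            assert csp.delta_c == pytest.approx(p.offset_c, abs=2e-3)

    def test_ambiguous_docked_candidates_flagged_overlapped(self):
        ref = [Peak("P1", 0.75, 13.9, 1.0)]
        fl = [
            Peak("a", 0.75, 13.9, 0.5),
            Peak("b", 0.78, 14.2, 0.5),
            Peak("c", 0.72, 13.6, 0.5),
        ]
        with pytest.warns(RuntimeWarning, match="overlapped"):
            result = pair_doublets(fl, ref)
        assert result.overlapped == ["P1"]
        assert result.doublets == []

    def test_contested_full_length_peak_goes_to_closer_reference(self):
        ref = [Peak("near", 0.750, 13.90, 1.0), Peak("far", 0.755, 13.92, 1.0)]
        fl = [Peak("x", 0.7501, 13.901, 1.0)]
        result = pair_doublets(fl, ref)
        assert [s.probe for s in result.singlets] == ["near"]
        assert result.unmatched_reference == ["far"]


class TestPopulations:
    def test_equal_intensities_give_fifty_percent_no_scatter(self):
        doublets = [
            PeakDoublet(f"P{i}", Peak("u", 0.7, 13, 5.0), Peak("d", 0.73, 13.4, 5.0))
            for i in range(3)
        ]
        est = estimate_populations(doublets)
        assert est.p_d == 50.0
        assert est.sd_across_doublets == 0.0

    def test_three_doublet_hand_arithmetic(self):
        """Intensities (53,47), (50,50), (56,44) -> p_D = 53.0%, SD = 3.0%."""
        pairs = [(53.0, 47.0), (50.0, 50.0), (56.0, 44.0)]
        doublets = [
            PeakDoublet(f"P{i}", Peak("u", 0.7, 13, iu), Peak("d", 0.73, 13.4, idd))
            for i, (idd, iu) in enumerate(pairs)
        ]
        est = estimate_populations(doublets)
        assert est.p_d == pytest.approx(53.0, abs=1e-12)
        assert est.sd_across_doublets == pytest.approx(3.0, abs=1e-12)

    def test_no_doublets_is_an_error(self):
        singlet = PeakDoublet("P1", Peak("u", 0.7, 13, 1.0), None)
        with pytest.raises(ValueError, match="no doublets"):
            estimate_populations([singlet])

    def test_negative_docked_intensity_clamped_with_warning(self):
        with pytest.warns(RuntimeWarning, match="clamped"):
            d = PeakDoublet("P1", Peak("u", 0.7, 13, 1.0), Peak("d", 0.73, 13.4, -0.1))
        assert d.i_d == 0.0

    @given(
        intensities=st.lists(
            st.tuples(
                st.floats(0.01, 100.0, allow_nan=False),
                st.floats(0.01, 100.0, allow_nan=False),
            ),
            min_size=1,
            max_size=6,
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_label_swap_symmetry_and_complement(self, intensities):
        """Swapping D/U maps p_D -> 100 - p_D; p_D + p_U = 100 exactly."""
        fwd = [
            PeakDoublet(f"P{i}", Peak("u", 0.7, 13, iu), Peak("d", 0.73, 13.4, idd))
            for i, (idd, iu) in enumerate(intensities)
        ]
        rev = [
            PeakDoublet(f"P{i}", Peak("u", 0.73, 13.4, idd), Peak("d", 0.7, 13, iu))
            for i, (idd, iu) in enumerate(intensities)
        ]
        ef, er = estimate_populations(fwd), estimate_populations(rev)
        assert ef.p_d + ef.p_u == 100.0
        assert ef.p_d == pytest.approx(100.0 - er.p_d, abs=1e-9)
        assert ef.sd_across_doublets == pytest.approx(er.sd_across_doublets, abs=1e-9)

    def test_error_does_not_grow_with_more_doublets(self):
        """Under i.i.d. per-doublet scatter the reported error is, on average,
        no larger for a 6-doublet probe set than for a 3-doublet one."""
        rng = np.random.default_rng(42)

        def mean_error(n_doublets, n_trials=200):
            errors = []
            for _ in range(n_trials):
                p = 53.0 + rng.normal(0, 3.0, n_doublets)
                doublets = [
                    PeakDoublet(
                        f"P{i}",
                        Peak("u", 0.7, 13, 100 - pi),
                        Peak("d", 0.73, 13.4, pi),
                    )
                    for i, pi in enumerate(p)
                ]
                errors.append(estimate_populations(doublets).error)
            return np.mean(errors)

        assert mean_error(6) <= mean_error(3) * 1.05

    def test_noiseless_pipeline_recovers_truth(self, three_probe_truth):
        est, _ = quantify_pair(three_probe_truth)
        assert abs(est.p_d - 53.0) < 0.1  # percentage points


class TestShiftPerturbation:
    def test_identical_positions_give_zero(self):
        a = Peak("x", 0.7, 13.0, 1.0)
        assert combined_csp(a, a).combined == 0.0

    def test_canonical_methyl_splitting(self):
        """0.03 ppm 1H with 0.4 ppm 13C at w = 0.25 combines to ~0.1044 ppm."""
        s = ShiftPerturbation(delta_h=0.03, delta_c=0.4)
        assert s.combined == pytest.approx(np.sqrt(0.0009 + 0.01), abs=1e-12)

    def test_single_axis_case(self):
        assert ShiftPerturbation(0.03, 0.0).combined == pytest.approx(0.03)


class TestExchangeBound:
    def test_proton_splitting_sets_tens_of_ms_bound(self):
        """0.03 ppm at 750 MHz -> 22.5 Hz -> tau = 1/dnu ~ 44 ms."""
        bound = exchange_timescale_bound([ShiftPerturbation(0.03, 0.0)])
        assert bound.delta_nu_min_hz == pytest.approx(22.5)
        assert bound.tau_s == pytest.approx(1 / 22.5)
        assert 0.010 < bound.tau_s < 0.100

    def test_reciprocal_scaling(self):
        b1 = exchange_timescale_bound([ShiftPerturbation(0.03, 0.0)])
        b2 = exchange_timescale_bound([ShiftPerturbation(0.06, 0.0)])
        assert b2.tau_s == pytest.approx(b1.tau_s / 2)

    def test_minimum_over_axes_is_proton_here(self):
        """0.4 ppm 13C at 188.6 MHz is 75.4 Hz: the 1H 22.5 Hz still rules."""
        bound = exchange_timescale_bound(
            [ShiftPerturbation(0.03, 0.4)], frequencies_mhz=(750.0, 188.6)
        )
        assert bound.delta_nu_min_hz == pytest.approx(22.5)

    def test_zero_offsets_indeterminate(self):
        with pytest.raises(ValueError, match="indeterminate"):
            exchange_timescale_bound([ShiftPerturbation(0.0, 0.0)])


class TestSparkyIO:
    def test_round_trip(self, tmp_path):
        peaks = [
            Peak("I145-CD1", 0.7512, 13.9041, 123456.0),
            Peak("I371-CD1", 0.5501, 13.1002, 98765.4),
        ]
        path = write_sparky_list(peaks, tmp_path / "peaks.list")
        back = read_sparky_list(path)
        assert [p.assignment for p in back] == ["I145-CD1", "I371-CD1"]
        for orig, rt in zip(peaks, back):
            assert rt.height == orig.height
            assert rt.delta_h == pytest.approx(orig.delta_h, abs=1e-4)
            assert rt.delta_c == pytest.approx(orig.delta_c, abs=1e-4)

    def test_comments_and_header_rows_skipped(self, tmp_path):
        text = (
            "# comment line\n"
            "      Assignment        w1        w2   Data Height\n"
            "  I145-CD1   13.9000    0.7500   1000.0\n"
        )
        path = tmp_path / "peaks.list"
        path.write_text(text)
        peaks = read_sparky_list(path)
        assert len(peaks) == 1
        assert peaks[0].delta_c == pytest.approx(13.9)
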