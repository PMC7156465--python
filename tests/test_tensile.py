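"""Tensile-curve analysis: CSA, preprocessing, linear fit, peaks."""

import warnings

import numpy as np
import pytest

from iomorph import (
    PipelineConfig,
    TensileCurve,
    analyze_curve,
    detect_linear_region,
    detect_peaks,
    nominal_stress,
    preprocess_curve,
    stiffness,
    trapezoid_csa,
    trim_preconditioning,
)
from iomorph.errors import (
    InsufficientDataError,
    InsufficientLoadError,
    ValidationError,
)
from iomorph.phantom import TensileTruth, make_tensile_curve, sample_tensile_truths
from iomorph.reference import (
    DOB_CSA_PUBLISHED,
    DOB_THICKNESS_CCD,
    DOB_WIDTH_RADIAL_EXVIVO,
    DOB_WIDTH_ULNAR_EXVIVO,
)


def line_curve(slope, n=60, step=0.05, offset=0.0, gauge=30.0):
    d = np.arange(n) * step
    return TensileCurve(d, offset + slope * d, gauge_length=gauge)


class TestTrapezoidCSA:
    def test_rectangle(self):
        assert trapezoid_csa(10, 10, 2) == pytest.approx(20.0)

    def test_dob_cross_table_consistency(self):
        """Optically measured DOB widths and CCD thickness reproduce the
        published DOB CSA within 0.5 %."""
        csa = trapezoid_csa(
            DOB_WIDTH_RADIAL_EXVIVO, DOB_WIDTH_ULNAR_EXVIVO, DOB_THICKNESS_CCD
        )
        assert csa == pytest.approx(50.4525)
        assert abs(csa - DOB_CSA_PUBLISHED) / DOB_CSA_PUBLISHED < 0.005

    def test_thin_limit(self):
        assert trapezoid_csa(10, 10, 1e-9) == pytest.approx(0.0, abs=1e-7)

    def test_domain_errors(self):
        with pytest.raises(ValidationError):
            trapezoid_csa(0, 10, 2)
        with pytest.raises(ValidationError):
            trapezoid_csa(10, 10, -1)


class TestNominalStress:
    def test_examples(self):
        assert nominal_stress(100.0, 50.0) == pytest.approx(2.0)
        assert nominal_stress(0.0, 50.0) == 0.0
        # published forearm-1 CB ultimate over its CSA
        assert nominal_stress(198.77, 130.00) == pytest.approx(1.529, abs=5e-4)

    def test_domain_error(self):
        with pytest.raises(ValidationError):
            nominal_stress(10.0, 0.0)


class TestPreprocess:
    def test_curve_starting_at_preload_keeps_origin(self):
        c = line_curve(40.0, offset=0.5)
        pre = preprocess_curve(c)
        assert pre.displacement[0] == 0.0
        assert pre.force[0] == 0.5
        assert len(pre.force) == len(c.force)

    def test_all_zero_force_rejected(self):
        c = TensileCurve(np.linspace(0, 1, 30), np.zeros(30), gauge_length=30)
        with pytest.raises(InsufficientLoadError):
            preprocess_curve(c)

    def test_truncation_at_stop_criterion(self):
        """The cut must land within one sample of the analytic 95 %
        crossing of the generator's terminal decay."""
        tt = TensileTruth(43.53, 127.8, 187.93, 4.4)
        step = 0.005
        c = make_tensile_curve(tt, sample_step_mm=step)
        pre = preprocess_curve(c)
        du = tt.gauge_length * tt.ultimate_strain_true / 100.0
        d_end = du + max(5 * step, 0.05 * du)
        # tail decays linearly from (du, fu) to (d_end, 0.35 fu)
        d_cross = du + (1.0 - 0.95) / (1.0 - 0.35) * (d_end - du)
        assert pre.displacement[-1] == pytest.approx(d_cross, abs=step)
        assert pre.force[-1] >= 0.95 * pre.force.max() - 1e-9

    def test_trim_preconditioning(self):
        up = np.linspace(0, 1, 20)
        cycles = np.concatenate([up, up[::-1], up, up[::-1], np.linspace(0, 5, 50)])
        force = np.linspace(0, 10, len(cycles))
        d2, f2 = trim_preconditioning(cycles, force)
        assert np.all(np.diff(d2) >= 0)
        # the ramp plus the valley sample where the last reversal ended
        assert len(d2) == 51
        assert len(f2) == len(d2)


class TestLinearRegion:
    def test_exact_line_full_window(self):
        c = line_curve(40.0, n=120, offset=1.0)
        region = detect_linear_region(c)
        assert region.slope == pytest.approx(40.0, rel=1e-9)
        assert region.r2 == pytest.approx(1.0, abs=1e-12)
        assert region.index_lo == 0
        assert region.index_hi == len(c.force) - 1

    def test_stiffness_printed_value(self):
        assert stiffness(line_curve(27.71, n=80)) == pytest.approx(27.71, rel=1e-9)

    def test_force_scaling_scales_stiffness(self):
        c = line_curve(30.0, n=80)
        doubled = c.replace(force=2 * c.force)
        assert stiffness(doubled) == pytest.approx(2 * stiffness(c), rel=1e-9)

    def test_force_offset_invariance(self):
        c = line_curve(30.0, n=80)
        shifted = c.replace(force=c.force + 7.5)
        assert stiffness(shifted) == pytest.approx(stiffness(c), rel=1e-9)

    def test_too_few_samples_rejected(self):
        with pytest.raises(InsufficientDataError):
            detect_linear_region(line_curve(40.0, n=12))

    def test_poor_linearity_warns_but_returns(self, rng):
        d = np.arange(400) * 0.005
        f = 1.0 + 0.02 * d + rng.normal(0, 0.5, size=d.size)
        f[-1] = f.max() + 1.0  # put the global maximum at the end
        c = TensileCurve(d, f, gauge_length=30)
        with pytest.warns(UserWarning, match="poorly linear"):
            region = detect_linear_region(c)
        assert region.r2 < 0.9

    def test_window_placed_in_declared_strain_range(self):
        """CB-like synthetic curve with the linear region at 1-3 % strain
        is recovered within [0.8, 3.2] %."""
        tt = TensileTruth(43.53, 300.0, 330.0, 5.0, toe_span=2.5, linear_span=5.0,
                          gauge_length=250.0)
        pre = preprocess_curve(make_tensile_curve(tt))
        region = detect_linear_region(pre)
        assert 0.8 <= region.strain_lo <= 1.2
        assert 2.8 <= region.strain_hi <= 3.2
        assert region.slope == pytest.approx(43.53, rel=0.005)


class TestPeaks:
    def test_monotone_then_drop_is_monophasic(self):
        d = np.arange(40) * 0.05
        f = np.concatenate([np.linspace(0, 100, 30), np.linspace(95, 40, 10)])
        fp, fu, es = detect_peaks(TensileCurve(d, f, gauge_length=30))
        assert fp == fu == 100.0

    def test_ultimate_strain_arithmetic(self):
        """Ultimate at 1.008 mm displacement with a 30 mm gauge is 3.36 %."""
        d = np.arange(217) * 0.006  # sample 168 sits at 1.008 mm
        f = np.interp(d, [0.0, 1.008, 1.296], [0.0, 100.0, 50.0])
        fp, fu, es = detect_peaks(TensileCurve(d, f, gauge_length=30))
        assert fu == pytest.approx(100.0)
        assert es == pytest.approx(3.36, abs=1e-6)

    def test_biphasic_recovery(self):
        tt = TensileTruth(43.53, 68.81, 198.77, 3.36)
        fp, fu, es = detect_peaks(preprocess_curve(make_tensile_curve(tt)))
        assert fp == pytest.approx(68.81, abs=1e-9)
        assert fu == pytest.approx(198.77, abs=1e-9)

    def test_too_few_samples_rejected(self):
        with pytest.raises(InsufficientDataError):
            detect_peaks(TensileCurve([0, 1, 2], [0, 1, 2], gauge_length=30))


class TestScaleEquivariance:
    def test_force_and_displacement_scaling(self):
        tt = TensileTruth(43.53, 127.8, 187.93, 4.4)
        pre = preprocess_curve(make_tensile_curve(tt))
        base = analyze_curve(pre.replace(), csa=100.0)
        k = 2.0
        force_scaled = analyze_curve(pre.replace(force=k * pre.force), csa=100.0)
        assert force_scaled.stiffness == pytest.approx(k * base.stiffness, rel=1e-6)
        assert force_scaled.first_peak_force == pytest.approx(k * base.first_peak_force)
        assert force_scaled.ultimate_force == pytest.approx(k * base.ultimate_force)
        disp_scaled = analyze_curve(
            pre.replace(displacement=k * pre.displacement), csa=100.0
        )
        assert disp_scaled.stiffness == pytest.approx(base.stiffness / k, rel=1e-6)
        assert disp_scaled.ultimate_strain == pytest.approx(
            k * base.ultimate_strain, rel=1e-6
        )


class TestGeneratorRecovery:
    def test_noise_free_recovery_sample(self):
        for tt in sample_tensile_truths(12, seed=21):
            c = make_tensile_curve(tt)
            step = float(c.displacement[1] - c.displacement[0])
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                pre = preprocess_curve(c)
                region = detect_linear_region(pre)
                fp, fu, es = detect_peaks(pre)
            assert region.slope == pytest.approx(tt.stiffness_true, rel=0.005)
            assert fp == pytest.approx(tt.first_peak_force_true, abs=1e-8)
            assert fu == pytest.approx(tt.ultimate_force_true, abs=1e-8)
            assert abs(es - tt.ultimate_strain_true) <= 100.0 * step / tt.gauge_length
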