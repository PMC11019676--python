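"""Forward optical model: coefficients, signals, frames, designs."""

import dataclasses
import math

import numpy as np
import pytest

import eemquant as eq
from eemquant.forward import reflected_excitation
from eemquant.instrument import OpticalMedium


@pytest.fixture
def medium():
    return OpticalMedium()


class TestOpticalCoefficients:
    def test_reference_scattering_value(self, medium):
        assert eq.reduced_scattering(medium, 470.0) == pytest.approx(8.3)

    def test_zero_scatter_power_is_flat(self):
        med = OpticalMedium(scatter_power=0.0)
        for wl in (300.0, 470.0, 680.0):
            assert eq.reduced_scattering(med, wl) == pytest.approx(8.3)

    def test_power_law_at_doubled_wavelength(self):
        med = OpticalMedium(ref_wavelength=350.0, scatter_power=2.4)
        assert eq.reduced_scattering(med, 700.0) == pytest.approx(8.3 * 2 ** -2.4)

    def test_reference_absorption_value(self, medium):
        assert eq.absorption_coefficient(medium, 470.0, absorber_fraction=0.5) \
            == pytest.approx(0.32)

    def test_absorption_linear_in_ink_fraction(self, medium):
        assert eq.absorption_coefficient(medium, 470.0, absorber_fraction=0.0) == 0.0
        assert eq.absorption_coefficient(medium, 470.0, absorber_fraction=4.0) \
            == pytest.approx(8 * 0.32)

    @pytest.mark.parametrize("wl", [200.0, 900.0])
    def test_wavelength_range_enforced(self, medium, wl):
        with pytest.raises(ValueError, match="range"):
            eq.reduced_scattering(medium, wl)
        with pytest.raises(ValueError, match="range"):
            eq.absorption_coefficient(medium, wl)

    def test_effective_attenuation(self):
        assert eq.effective_attenuation(0.0, 8.3) == 0.0
        assert eq.effective_attenuation(0.32, 8.3) == pytest.approx(
            math.sqrt(3 * 0.32 * (0.32 + 8.3)))
        mues = [eq.effective_attenuation(mua, 8.3) for mua in (0.1, 0.3, 1.0, 3.0)]
        assert all(b > a for a, b in zip(mues, mues[1:]))
        with pytest.raises(ValueError):
            eq.effective_attenuation(-0.1, 8.3)


class TestDiffuseReflectance:
    def test_no_absorber_gives_full_signal(self, instrument):
        sample = eq.PhantomSample("s", {}, absorber_fraction=0.0)
        got = eq.diffuse_reflectance(sample, instrument, 470)
        i = instrument.source_index(470)
        expected = instrument.source_powers[i] * instrument.pd_gain * math.exp(
            -eq.effective_attenuation(0.0, eq.reduced_scattering(instrument.medium, 470))
            * instrument.sd_separation_drs)
        assert got == pytest.approx(expected)

    def test_linearity_in_source_power(self, instrument):
        sample = eq.standard_sample()
        doubled = dataclasses.replace(
            instrument, source_powers=tuple(2 * p for p in instrument.source_powers))
        for wl in instrument.source_wavelengths:
            assert eq.diffuse_reflectance(sample, doubled, wl) == pytest.approx(
                2 * eq.diffuse_reflectance(sample, instrument, wl))

    def test_absorber_strictly_attenuates_every_wavelength(self, instrument):
        lo = eq.PhantomSample("lo", {}, absorber_fraction=0.5)
        hi = eq.PhantomSample("hi", {}, absorber_fraction=4.0)
        for wl in instrument.source_wavelengths:
            assert eq.diffuse_reflectance(hi, instrument, wl) \
                < eq.diffuse_reflectance(lo, instrument, wl)

    def test_unknown_source_rejected(self, instrument):
        with pytest.raises(KeyError):
            eq.diffuse_reflectance(eq.standard_sample(), instrument, 555)


class TestFluorescenceSignal:
    def test_zero_concentration_zero_signal(self, instrument):
        assert eq.fluorescence_signal(eq.standard_sample(), instrument, 340, 470) == 0.0

    def test_linear_in_each_concentration(self, instrument):
        base = eq.PhantomSample("a", {"NADH": 25.0, "FAD": 5.0, "PpIX": 5.0})
        twice = eq.PhantomSample("b", {"NADH": 50.0, "FAD": 5.0, "PpIX": 5.0})
        only = eq.PhantomSample("c", {"NADH": 25.0})
        rest = eq.PhantomSample("d", {"FAD": 5.0, "PpIX": 5.0})
        v_base = eq.fluorescence_signal(base, instrument, 340, 470)
        v_twice = eq.fluorescence_signal(twice, instrument, 340, 470)
        v_only = eq.fluorescence_signal(only, instrument, 340, 470)
        v_rest = eq.fluorescence_signal(rest, instrument, 340, 470)
        assert v_twice - v_base == pytest.approx(v_only, rel=1e-12)
        assert v_base == pytest.approx(v_only + v_rest, rel=1e-12)

    def test_matched_pair_dominates_off_diagonal(self, instrument):
        nadh_only = eq.PhantomSample("n", {"NADH": 50.0})
        matched = eq.fluorescence_signal(nadh_only, instrument, 340, 470)
        off = eq.fluorescence_signal(nadh_only, instrument, 590, 680)
        assert matched > 1e6 * off

    def test_exact_linearity_over_concentration_ladder(self, noiseless_instrument):
        """Noiseless response over 5 levels is an exact line (zero residual)."""
        levels = np.array([0.0, 12.5, 25.0, 50.0, 100.0])
        vals = np.array([eq.fluorescence_signal(
            eq.PhantomSample("s", {"NADH": c}), noiseless_instrument, 340, 470)
            for c in levels])
        slope, intercept = np.polyfit(levels, vals, 1)
        resid = vals - (slope * levels + intercept)
        assert np.max(np.abs(resid)) < 1e-12 * np.max(vals)
        assert intercept == pytest.approx(0.0, abs=1e-14)


class TestSimulateFrame:
    def test_structure(self, instrument, factorial):
        frame = eq.simulate_frame(factorial[0], instrument, 7)
        assert len(frame.states) == 9
        assert frame.states[0].label == "dark"
        assert [s.label for s in frame.states[1:]] == \
            [str(w) for w in instrument.source_wavelengths]

    def test_noiseless_zero_fluorophore_is_pure_leakage(self, noiseless_instrument):
        ins = noiseless_instrument.without_saturation()
        sample = eq.standard_sample()
        frame = eq.simulate_frame(sample, ins, 0)
        for s_idx, src in enumerate(ins.source_wavelengths):
            refl = reflected_excitation(sample, ins, src)
            expect = np.asarray(ins.crosstalk)[:, s_idx] * refl * ins.gain
            np.testing.assert_allclose(frame.state(src).sipmt, expect, rtol=1e-12)

    def test_saturation_clip_never_exceeded(self, instrument):
        huge = eq.PhantomSample("huge", {"NADH": 1e6, "FAD": 1e6, "PpIX": 1e6})
        frame = eq.simulate_frame(huge, instrument, 3)
        for state in frame.states:
            assert np.all(state.sipmt <= instrument.v_max)
        assert frame.state(340).sipmt[instrument.channel_index(470)] \
            == instrument.v_max

    def test_seeded_reproducibility(self, instrument, factorial):
        a = eq.simulate_frame(factorial[5], instrument, 11)
        b = eq.simulate_frame(factorial[5], instrument, 11)
        c = eq.simulate_frame(factorial[5], instrument, 12)
        for sa, sb in zip(a.states, b.states):
            assert sa.pd_drs == sb.pd_drs
            assert np.array_equal(sa.sipmt, sb.sipmt)
        assert any(not np.array_equal(sa.sipmt, sc.sipmt)
                   for sa, sc in zip(a.states, c.states))

    def test_extending_design_preserves_earlier_draws(self, instrument, factorial):
        short = eq.simulate_frames(factorial[:3], instrument, 5)
        longer = eq.simulate_frames(factorial[:6], instrument, 5)
        for fa, fb in zip(short, longer):
            for sa, sb in zip(fa.states, fb.states):
                assert np.array_equal(sa.sipmt, sb.sipmt)

    def test_flash_coupling_scales_whole_state(self, noiseless_instrument):
        """Scaling one source's power scales that state's photodiode and all
        its (unsaturated) SiPMT values by the same factor."""
        ins = noiseless_instrument.without_saturation()
        sample = eq.PhantomSample("s", {"NADH": 25.0, "FAD": 2.5, "PpIX": 2.5})
        powers = list(ins.source_powers)
        i = ins.source_index(390)
        powers[i] *= 3.0
        scaled = dataclasses.replace(ins, source_powers=tuple(powers))
        f0 = eq.simulate_frame(sample, ins, 0)
        f1 = eq.simulate_frame(sample, scaled, 0)
        assert f1.state(390).pd_drs == pytest.approx(3 * f0.state(390).pd_drs)
        np.testing.assert_allclose(f1.state(390).sipmt, 3 * f0.state(390).sipmt,
                                   rtol=1e-12)
        np.testing.assert_allclose(f1.state(470).sipmt, f0.state(470).sipmt,
                                   rtol=1e-12)


class TestDesigns:
    def test_fluorophore_factorial_structure(self, factorial):
        assert len(factorial) == 125
        nadh = {s.concentrations["NADH"] for s in factorial}
        assert nadh == {100.0, 50.0, 25.0, 12.5, 0.0}
        blanks = [s for s in factorial if all(v == 0 for v in s.concentrations.values())]
        assert len(blanks) == 1
        assert all(s.absorber_fraction == 0.5 and s.scatterer_fraction == 4.0
                   for s in factorial)

    def test_absorber_series_structure(self):
        design = eq.absorber_series()
        assert len(design) == 20
        fad = sorted({s.concentrations["FAD"] for s in design})
        assert fad[0] == 0.0 and fad[-1] == 10.0 and len(fad) == 5
        for level in fad:
            fracs = {s.absorber_fraction for s in design
                     if s.concentrations["FAD"] == level}
            assert len(fracs) == 4
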