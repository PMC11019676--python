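"""Forward model: from phantom composition to raw acquisition frames.

Light transport through the turbid phantom is closed with a modified
Beer-Lambert attenuation exp(-mu_eff * rho) using the diffusion-theory
effective attenuation coefficient mu_eff = sqrt(3 mu_a (mu_a + mu_s')) and a
fixed effective path rho per collection geometry.  Fluorescence is strictly
linear in each fluorophore concentration; the nonlinearities of the recorded
frame come from the detector (saturation clip at v_max) and the noise model
(per-flash source fluctuation shared by all detectors of a state, additive
detector noise, constant ambient background).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .instrument import WAVELENGTH_RANGE, FluorophoreSpec, InstrumentSpec, OpticalMedium
from .phantoms import PhantomSample

_FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


@dataclass
class IlluminationState:
    """One of the nine acquisition states: ``label`` is 'dark' or the source
    wavelength in nm; ``pd_drs`` the photodiode reading; ``sipmt`` the eight
    channel voltages."""

    label: str
    pd_drs: float
    sipmt: np.ndarray


@dataclass
class AcquisitionFrame:
    sample_id: str
    states: list[IlluminationState]
    seed: int | None = None

    def __post_init__(self) -> None:
        if len(self.states) != 9:
            raise ValueError("a frame has exactly 9 states (dark + 8 sources)")
        if sum(s.label == "dark" for s in self.states) != 1:
            raise ValueError("a frame has exactly one dark state")

    @property
    def dark(self) -> IlluminationState:
        return next(s for s in self.states if s.label == "dark")

    def state(self, wavelength: int) -> IlluminationState:
        for s in self.states:
            if s.label == str(int(wavelength)):
                return s
        raise KeyError(f"no state for source {wavelength} nm")


# -- optical properties ----------------------------------------------------

def _check_wavelength(wavelength: float) -> None:
    lo, hi = WAVELENGTH_RANGE
    if not lo <= wavelength <= hi:
        raise ValueError(f"wavelength {wavelength} nm outside supported "
                         f"range [{lo}, {hi}]")


def reduced_scattering(medium: OpticalMedium, wavelength: float,
                       scatterer_fraction: float | None = None) -> float:
    """mu_s'(lambda) in cm^-1, power-law in wavelength, linear in the
    intralipid fraction relative to the reference fraction."""
    _check_wavelength(wavelength)
    frac = medium.scatterer_fraction_ref if scatterer_fraction is None else scatterer_fraction
    scale = frac / medium.scatterer_fraction_ref
    return medium.musp_ref * (wavelength / medium.ref_wavelength) ** (-medium.scatter_power) * scale


def absorption_coefficient(medium: OpticalMedium, wavelength: float,
                           absorber_fraction: float | None = None) -> float:
    """mu_a(lambda) in cm^-1, linear in the ink fraction relative to the
    reference fraction (0.5 %)."""
    _check_wavelength(wavelength)
    frac = medium.absorber_fraction_ref if absorber_fraction is None else absorber_fraction
    scale = frac / medium.absorber_fraction_ref
    return medium.mua_ref * medium.absorber_shape_at(wavelength) * scale


def effective_attenuation(mua: float, musp: float) -> float:
    """Diffusion-theory mu_eff = sqrt(3 mu_a (mu_a + mu_s')) in cm^-1."""
    if mua < 0 or musp <= 0:
        raise ValueError("require mua >= 0 and musp > 0")
    return math.sqrt(3.0 * mua * (mua + musp))


def _mueff(sample: PhantomSample, medium: OpticalMedium, wavelength: float) -> float:
    mua = absorption_coefficient(medium, wavelength, sample.absorber_fraction)
    musp = reduced_scattering(medium, wavelength, sample.scatterer_fraction)
    return effective_attenuation(mua, musp)


# -- spectral shapes -------------------------------------------------------

def excitation_efficiency(fluor: FluorophoreSpec, wavelength: float) -> float:
    """Peak-normalised Gaussian excitation shape at ``wavelength``."""
    sigma = fluor.ex_fwhm * _FWHM_TO_SIGMA
    return math.exp(-0.5 * ((wavelength - fluor.ex_peak) / sigma) ** 2)


def emission_fraction(fluor: FluorophoreSpec, channel_center: float,
                      channel_fwhm: float) -> float:
    """Fraction of the emission band captured by a channel passband
    (Gaussian emission integrated over a square passband of width fwhm)."""
    sigma = fluor.em_fwhm * _FWHM_TO_SIGMA
    lo = (channel_center - channel_fwhm / 2 - fluor.em_peak) / (sigma * math.sqrt(2))
    hi = (channel_center + channel_fwhm / 2 - fluor.em_peak) / (sigma * math.sqrt(2))
    return 0.5 * (math.erf(hi) - math.erf(lo))


# -- noiseless signals -----------------------------------------------------

def diffuse_reflectance(sample: PhantomSample, instrument: InstrumentSpec,
                        source_wavelength: float) -> float:
    """Noiseless photodiode DRS signal for one source (arbitrary units)."""
    i = instrument.source_index(source_wavelength)
    power = instrument.source_powers[i]
    mueff = _mueff(sample, instrument.medium, source_wavelength)
    return power * instrument.pd_gain * math.exp(-mueff * instrument.sd_separation_drs)


def fluorescence_signal(sample: PhantomSample, instrument: InstrumentSpec,
                        source_wavelength: float, channel_center: float) -> float:
    """Noiseless, pre-clip SiPMT fluorescence voltage for one (source,
    channel) pair; strictly linear in every concentration."""
    i = instrument.source_index(source_wavelength)
    instrument.channel_index(channel_center)
    power = instrument.source_powers[i]
    med = instrument.medium
    mueff_x = _mueff(sample, med, source_wavelength)
    mueff_m = _mueff(sample, med, channel_center)
    atten = math.exp(-mueff_x * instrument.sd_separation_fluor
                     - mueff_m * instrument.sd_separation_fluor)
    total = 0.0
    for fluor in instrument.fluorophores:
        c = sample.concentrations.get(fluor.name, 0.0)
        if c == 0.0:
            continue
        total += (power * c * fluor.molar_response
                  * excitation_efficiency(fluor, source_wavelength)
                  * fluor.quantum_yield
                  * emission_fraction(fluor, channel_center, instrument.channel_fwhm))
    return total * atten * instrument.gain


def reflected_excitation(sample: PhantomSample, instrument: InstrumentSpec,
                         source_wavelength: float) -> float:
    """Reflected (elastic) excitation power reaching the SiPMT prism, nW.

    This is the strong component that saturates the matched channel and,
    through the leakage matrix, contaminates the fluorescence channels."""
    i = instrument.source_index(source_wavelength)
    power = instrument.source_powers[i]
    mueff = _mueff(sample, instrument.medium, source_wavelength)
    return (power * instrument.refl_excitation_gain
            * math.exp(-2.0 * mueff * instrument.sd_separation_fluor))


# -- frame simulation ------------------------------------------------------

def _resolve_rng(rng_seed) -> tuple[np.random.Generator, int | None]:
    if isinstance(rng_seed, np.random.Generator):
        return rng_seed, None
    if isinstance(rng_seed, np.random.SeedSequence):
        return np.random.default_rng(rng_seed), None
    return np.random.default_rng(rng_seed), int(rng_seed)


def simulate_frame(sample: PhantomSample, instrument: InstrumentSpec,
                   rng_seed) -> AcquisitionFrame:
    """Simulate one 9-state acquisition (dark first, then the 8 sources).

    Per illuminated state, one lognormal flash factor (CV =
    ``noise_source_cv``) scales every light-driven signal of that state --
    the photodiode DRS and all eight SiPMT voltages -- modelling shared
    source fluctuation.  SiPMT voltages are clipped at ``v_max`` only at the
    top; detector-noise negatives are retained.
    """
    rng, seed = _resolve_rng(rng_seed)
    n_ch = len(instrument.channel_centers)
    sd = instrument.noise_detector_sd

    def det_noise(n: int) -> np.ndarray:
        if sd == 0:
            return np.zeros(n)
        return rng.normal(0.0, sd, size=n)

    states: list[IlluminationState] = []

    noise = det_noise(n_ch + 1)
    dark_sipmt = np.minimum(instrument.ambient_level + noise[:n_ch], instrument.v_max)
    states.append(IlluminationState("dark", instrument.ambient_level + noise[-1],
                                    dark_sipmt))

    cv = instrument.noise_source_cv
    log_sigma = math.sqrt(math.log(1.0 + cv * cv)) if cv > 0 else 0.0

    for src in instrument.source_wavelengths:
        s_idx = instrument.source_index(src)
        if log_sigma > 0:
            flash = float(rng.lognormal(mean=-0.5 * log_sigma ** 2, sigma=log_sigma))
        else:
            flash = 1.0
        drs = diffuse_reflectance(sample, instrument, src)
        refl_nw = reflected_excitation(sample, instrument, src)
        noise = det_noise(n_ch + 1)
        pd = min(drs * flash + instrument.ambient_level + noise[-1], instrument.pd_max)
        sipmt = np.empty(n_ch)
        for c_idx, ch in enumerate(instrument.channel_centers):
            fl = fluorescence_signal(sample, instrument, src, ch)
            leak = instrument.crosstalk[c_idx, s_idx] * refl_nw * instrument.gain
            sipmt[c_idx] = (fl + leak) * flash + instrument.ambient_level + noise[c_idx]
        np.minimum(sipmt, instrument.v_max, out=sipmt)
        states.append(IlluminationState(str(int(src)), pd, sipmt))

    return AcquisitionFrame(sample_id=sample.sample_id, states=states, seed=seed)


def simulate_frames(samples: list[PhantomSample], instrument: InstrumentSpec,
                    seed: int) -> list[AcquisitionFrame]:
    """Simulate a whole design with one splittable per-sample stream: child
    stream i depends only on (seed, i), so extending the design never
    perturbs earlier samples' draws."""
    children = np.random.SeedSequence(seed).spawn(len(samples))
    frames = []
    for i, (sample, child) in enumerate(zip(samples, children)):
        frame = simulate_frame(sample, instrument, child)
        frame.seed = seed
        frames.append(frame)
    return frames
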