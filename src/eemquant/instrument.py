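"""Instrument and medium configuration.

The probe interrogates a turbid liquid phantom with eight pulsed sources
(300-680 nm) and collects light on two arms: a photodiode measuring diffuse
reflectance (DRS) 1 mm from the illumination fibre, and an eight-channel
SiPMT array behind a multi-dichroic prism measuring the much weaker
fluorescence. :class:`InstrumentSpec` holds every constant of that chain --
wavelengths, per-source powers, channel passbands, the illumination-leakage
(crosstalk) matrix, the detector's linear range and ca. 5 V saturation
ceiling, and the noise model -- together with the reference optical medium
and the fluorophore library, so that a single YAML file fully determines a
simulation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import yaml

WAVELENGTH_RANGE = (250.0, 800.0)

#: The eight source wavelengths of the default instrument (nm); the
#: detection-channel centers coincide with them by design of the dichroic
#: stack (each element's cut-off matches a source).
DEFAULT_WAVELENGTHS = (300, 340, 390, 440, 470, 515, 590, 680)


@dataclass(frozen=True)
class FluorophoreSpec:
    """Spectral model of one fluorophore.

    Excitation and emission are peak-normalised Gaussians.  ``molar_response``
    sets the emitted power (nW) per µg/ml at peak excitation under unit
    source power, before quantum yield and collection factors.
    ``matched_pair`` is the (source nm, channel nm) combination the
    instrument designates for this fluorophore.
    """

    name: str
    ex_peak: float
    ex_fwhm: float
    em_peak: float
    em_fwhm: float
    quantum_yield: float
    molar_response: float
    matched_pair: tuple[int, int]

    def __post_init__(self) -> None:
        if not self.em_peak > self.ex_peak:
            raise ValueError(f"{self.name}: emission peak must lie redward of "
                             f"excitation (Stokes shift)")
        if self.ex_fwhm <= 0 or self.em_fwhm <= 0:
            raise ValueError(f"{self.name}: fwhm must be positive")
        if not 0 < self.quantum_yield <= 1:
            raise ValueError(f"{self.name}: quantum yield must be in (0, 1]")


@dataclass(frozen=True)
class OpticalMedium:
    """Reference optical properties of the intralipid/ink phantom base.

    ``mua_ref`` and ``musp_ref`` are the absorption and reduced-scattering
    coefficients (cm^-1) at ``ref_wavelength`` for the reference absorber and
    scatterer volume fractions.  Scattering follows a power law
    mu_s'(lambda) = musp_ref * (lambda/ref)^-b; the ink absorber is
    spectrally flat by default (``absorber_shape`` maps nm -> relative
    absorption).
    """

    mua_ref: float = 0.32
    musp_ref: float = 8.3
    ref_wavelength: float = 470.0
    scatter_power: float = 2.4
    absorber_fraction_ref: float = 0.5   # % volume of ink stock
    scatterer_fraction_ref: float = 4.0  # % volume of intralipid stock
    absorber_shape: dict[float, float] | None = None  # None -> flat

    def __post_init__(self) -> None:
        if self.mua_ref < 0:
            raise ValueError("mua_ref must be >= 0")
        if self.musp_ref <= 0:
            raise ValueError("musp_ref must be > 0")

    def absorber_shape_at(self, wavelength: float) -> float:
        if self.absorber_shape is None:
            return 1.0
        wl = np.array(sorted(self.absorber_shape), dtype=float)
        vals = np.array([self.absorber_shape[w] for w in sorted(self.absorber_shape)])
        return float(np.interp(wavelength, wl, vals))


def _default_crosstalk(wavelengths: Sequence[int]) -> np.ndarray:
    """Illumination-leakage matrix L[channel, source].

    The matched channel (same wavelength as the source) receives the full
    reflected excitation (L = 1, the 100 % reference).  Leakage into
    longer-wavelength channels falls off with spectral distance and is
    pinned at the three characterised pairs: 1e-5 at (source 340, channel
    470), 2.5e-4 at (440, 590) and 2e-5 at (340, 680).  Channels blueward
    of the source see the much larger short-pass leak of the dichroic
    stack; those cells are masked out of the feature matrix anyway.
    """
    wl = np.asarray(wavelengths, dtype=float)
    n = len(wl)
    L = np.zeros((n, n))
    for c in range(n):
        for s in range(n):
            if c == s:
                L[c, s] = 1.0
            elif wl[c] > wl[s]:
                L[c, s] = 5e-5 * np.exp(-(wl[c] - wl[s]) / 250.0)
            else:
                L[c, s] = 0.15 * np.exp(-(wl[s] - wl[c]) / 400.0)
    pinned = {(470, 340): 1e-5, (590, 440): 2.5e-4, (680, 340): 2e-5}
    idx = {int(w): i for i, w in enumerate(wavelengths)}
    for (ch, src), val in pinned.items():
        if ch in idx and src in idx:
            L[idx[ch], idx[src]] = val
    return L


def default_fluorophores() -> tuple[FluorophoreSpec, ...]:
    """NADH, FAD and PpIX with literature-typical Gaussian spectra.

    Matched pairs follow the instrument's channel assignment -- NADH
    (340, 470), FAD (440, 590), PpIX (340, 680) -- not the spectral peaks.
    Molar responses are calibrated so matched-pair signals at the top of the
    phantom concentration ranges sit in the low-volt range of the SiPMT.
    """
    return (
        FluorophoreSpec("NADH", ex_peak=340, ex_fwhm=60, em_peak=460, em_fwhm=80,
                        quantum_yield=0.02, molar_response=40.0,
                        matched_pair=(340, 470)),
        FluorophoreSpec("FAD", ex_peak=450, ex_fwhm=60, em_peak=525, em_fwhm=80,
                        quantum_yield=0.03, molar_response=900.0,
                        matched_pair=(440, 590)),
        FluorophoreSpec("PpIX", ex_peak=405, ex_fwhm=60, em_peak=635, em_fwhm=80,
                        quantum_yield=0.011, molar_response=1300.0,
                        matched_pair=(340, 680)),
    )


@dataclass(frozen=True)
class InstrumentSpec:
    source_wavelengths: tuple[int, ...] = DEFAULT_WAVELENGTHS
    # the three LED sources (300, 340, 590 nm) are weaker than the lasers
    source_powers: tuple[float, ...] = (0.3, 0.6, 1.0, 1.0, 1.0, 1.0, 0.6, 1.0)
    channel_centers: tuple[int, ...] = DEFAULT_WAVELENGTHS
    channel_fwhm: float = 40.0
    crosstalk: np.ndarray = field(default_factory=lambda: _default_crosstalk(DEFAULT_WAVELENGTHS))
    v_max: float = 5.0                       # SiPMT saturation ceiling, volts
    linear_range: tuple[float, float] = (0.03, 37.0)  # nW
    pd_max: float = 22.0                     # photodiode ceiling (mW scale)
    gain: float = 5.0 / 37.0                 # V per nW: maps linear range onto ~0-5 V
    pd_gain: float = 1.0                     # DRS arbitrary-unit gain
    refl_excitation_gain: float = 50.0       # nW of reflected excitation at the SiPMT per unit source power
    noise_source_cv: float = 0.02            # per-flash source fluctuation (relative)
    noise_detector_sd: float = 1e-4          # additive detector noise, volts
    ambient_level: float = 0.05              # ambient background, volts
    sd_separation_fluor: float = 0.05        # effective excitation/emission path, cm
    sd_separation_drs: float = 0.15          # effective DRS path, cm
    medium: OpticalMedium = field(default_factory=OpticalMedium)
    fluorophores: tuple[FluorophoreSpec, ...] = field(default_factory=default_fluorophores)

    def __post_init__(self) -> None:
        ct = np.asarray(self.crosstalk, dtype=float)
        object.__setattr__(self, "crosstalk", ct)
        ns, nc = len(self.source_wavelengths), len(self.channel_centers)
        if ct.shape != (nc, ns):
            raise ValueError(f"crosstalk must be [channel x source] = ({nc}, {ns})")
        if np.any(ct < 0) or np.any(ct > 1):
            raise ValueError("crosstalk entries must lie in [0, 1]")
        if self.v_max <= 0:
            raise ValueError("v_max must be positive")
        for name, seq in (("source_wavelengths", self.source_wavelengths),
                          ("channel_centers", self.channel_centers)):
            if any(b <= a for a, b in zip(seq, seq[1:])):
                raise ValueError(f"{name} must be strictly increasing")
        if len(self.source_powers) != ns:
            raise ValueError("need one power per source")

    # -- convenience -------------------------------------------------------

    def source_index(self, wavelength: float) -> int:
        try:
            return self.source_wavelengths.index(int(wavelength))
        except ValueError:
            raise KeyError(f"no source at {wavelength} nm") from None

    def channel_index(self, wavelength: float) -> int:
        try:
            return self.channel_centers.index(int(wavelength))
        except ValueError:
            raise KeyError(f"no channel at {wavelength} nm") from None

    def noiseless(self) -> "InstrumentSpec":
        """Copy with source fluctuation, detector noise and ambient zeroed."""
        return dataclasses.replace(self, noise_source_cv=0.0,
                                   noise_detector_sd=0.0, ambient_level=0.0)

    def without_saturation(self) -> "InstrumentSpec":
        """Copy with the saturation ceiling lifted far above any signal."""
        return dataclasses.replace(self, v_max=1e9)


def default_instrument() -> InstrumentSpec:
    return InstrumentSpec()


# -- YAML round-trip -------------------------------------------------------

def instrument_to_dict(spec: InstrumentSpec) -> dict:
    d = {
        "source_wavelengths": list(spec.source_wavelengths),
        "source_powers": list(spec.source_powers),
        "channel_centers": list(spec.channel_centers),
        "channel_fwhm": spec.channel_fwhm,
        "crosstalk": np.asarray(spec.crosstalk).tolist(),
        "v_max": spec.v_max,
        "linear_range": list(spec.linear_range),
        "pd_max": spec.pd_max,
        "gain": spec.gain,
        "pd_gain": spec.pd_gain,
        "refl_excitation_gain": spec.refl_excitation_gain,
        "noise_source_cv": spec.noise_source_cv,
        "noise_detector_sd": spec.noise_detector_sd,
        "ambient_level": spec.ambient_level,
        "sd_separation_fluor": spec.sd_separation_fluor,
        "sd_separation_drs": spec.sd_separation_drs,
        "medium": dataclasses.asdict(spec.medium),
        "fluorophores": [
            {**dataclasses.asdict(f), "matched_pair": list(f.matched_pair)}
            for f in spec.fluorophores
        ],
    }
    return d


def instrument_from_dict(d: dict) -> InstrumentSpec:
    d = dict(d)
    medium = OpticalMedium(**d.pop("medium"))
    fluors = tuple(
        FluorophoreSpec(**{**f, "matched_pair": tuple(f["matched_pair"])})
        for f in d.pop("fluorophores")
    )
    return InstrumentSpec(
        source_wavelengths=tuple(d["source_wavelengths"]),
        source_powers=tuple(d["source_powers"]),
        channel_centers=tuple(d["channel_centers"]),
        channel_fwhm=d["channel_fwhm"],
        crosstalk=np.asarray(d["crosstalk"], dtype=float),
        v_max=d["v_max"],
        linear_range=tuple(d["linear_range"]),
        pd_max=d["pd_max"],
        gain=d["gain"],
        pd_gain=d["pd_gain"],
        refl_excitation_gain=d["refl_excitation_gain"],
        noise_source_cv=d["noise_source_cv"],
        noise_detector_sd=d["noise_detector_sd"],
        ambient_level=d["ambient_level"],
        sd_separation_fluor=d["sd_separation_fluor"],
        sd_separation_drs=d["sd_separation_drs"],
        medium=medium,
        fluorophores=fluors,
    )


def save_instrument(spec: InstrumentSpec, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(instrument_to_dict(spec), fh, sort_keys=False)


def load_instrument(path) -> InstrumentSpec:
    with open(path, encoding="utf-8") as fh:
        return instrument_from_dict(yaml.safe_load(fh))
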