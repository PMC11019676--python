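"""From raw frames to the masked, DRS-normalised feature matrix.

The chain is: subtract the dark (ambient) state per detector, drop channel/
source pairs whose detection band lies blueward of the excitation source
(they carry no fluorescence), and normalise each remaining fluorescence
voltage by the product of the DRS readings at the excitation and emission
wavelengths, nFL = FL / (Ex * Em).  The DRS factors compensate phantom
attenuation of illumination and of emitted light, and cancel one power of
the shared per-flash source fluctuation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .forward import AcquisitionFrame
from .instrument import InstrumentSpec


@dataclass
class CorrectedFrame:
    """Background-subtracted frame: 8 illuminated states, dark removed.

    ``sipmt[i, c]`` is the voltage of channel c under source i minus that
    channel's dark value; ``saturated[i, c]`` flags values that sat at the
    clip ceiling in the raw frame.  Values may be slightly negative after
    subtraction (detector noise); they are kept as-is.
    """

    sample_id: str
    source_wavelengths: tuple[int, ...]
    pd_drs: np.ndarray          # (8,)
    sipmt: np.ndarray           # (8, n_channels)
    saturated: np.ndarray = field(default=None)  # bool, same shape as sipmt

    def __post_init__(self) -> None:
        if self.saturated is None:
            self.saturated = np.zeros_like(self.sipmt, dtype=bool)


def subtract_background(frame: AcquisitionFrame,
                        v_max: float | None = None) -> CorrectedFrame:
    """Subtract the dark state per detector and drop it.

    If ``v_max`` is given, raw SiPMT values at or above it are flagged as
    saturated (they are carried through, never imputed).
    """
    dark = frame.dark
    lit = [s for s in frame.states if s.label != "dark"]
    if len(lit) != 8:
        raise ValueError("expected 8 illuminated states")
    wavelengths = tuple(int(s.label) for s in lit)
    pd_drs = np.array([s.pd_drs - dark.pd_drs for s in lit])
    raw = np.vstack([s.sipmt for s in lit])
    sipmt = raw - dark.sipmt[None, :]
    sat = (raw >= v_max - 1e-12) if v_max is not None else np.zeros_like(raw, dtype=bool)
    return CorrectedFrame(frame.sample_id, wavelengths, pd_drs, sipmt, sat)


def mask_pairs(source_wavelengths, channel_centers) -> list[tuple[int, int]]:
    """(source, channel) pairs with channel >= source, source-major order.

    Channels blueward of the excitation cannot carry Stokes-shifted
    fluorescence and are omitted; for k shared wavelengths this keeps
    k(k+1)/2 pairs (36 for the 8-wavelength instrument).
    """
    for name, seq in (("source_wavelengths", source_wavelengths),
                      ("channel_centers", channel_centers)):
        if any(b <= a for a, b in zip(seq, seq[1:])):
            raise ValueError(f"{name} must be strictly increasing")
    return [(int(s), int(c)) for s in source_wavelengths
            for c in channel_centers if c >= s]


def normalize_drs(fl, ex, em):
    """nFL = FL / (Ex * Em); Ex and Em must be positive DRS readings."""
    ex = np.asarray(ex, dtype=float)
    em = np.asarray(em, dtype=float)
    if np.any(ex <= 0) or np.any(em <= 0):
        raise ValueError("Ex and Em must be positive")
    return np.asarray(fl, dtype=float) / (ex * em)


@dataclass
class FeatureMatrix:
    """n samples x p masked (source, channel) features.

    ``values`` is a DataFrame indexed by sample id with ``src<λ>_ch<λ>``
    columns; ``pairs`` gives the (source, channel) wavelengths per column in
    the same deterministic source-major order.
    """

    values: pd.DataFrame
    pairs: list[tuple[int, int]]
    normalization: str = "drs"
    saturated: pd.DataFrame | None = None
    excluded: list[str] = field(default_factory=list)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]


def pair_label(source: int, channel: int) -> str:
    return f"src{source}_ch{channel}"


def assemble_feature_matrix(frames: list[CorrectedFrame],
                            instrument: InstrumentSpec,
                            normalization: str = "drs") -> FeatureMatrix:
    """Build the masked feature matrix from corrected frames.

    With ``normalization='drs'`` each feature is FL/(Ex*Em) where Ex is the
    background-subtracted DRS under the pair's source and Em the DRS under
    the source whose wavelength equals the channel centre (source and
    channel wavelengths coincide by instrument design).  Samples with a
    non-positive Ex or Em are excluded with a warning.
    """
    if normalization not in ("drs", "none"):
        raise ValueError("normalization must be 'drs' or 'none'")
    pairs = mask_pairs(instrument.source_wavelengths, instrument.channel_centers)
    if normalization == "drs":
        src_set = set(instrument.source_wavelengths)
        missing = {c for _, c in pairs} - src_set
        if missing:
            raise ValueError(f"drs normalization needs a source at every "
                             f"channel wavelength; missing {sorted(missing)}")
    labels = [pair_label(s, c) for s, c in pairs]
    src_pos = {int(w): i for i, w in enumerate(instrument.source_wavelengths)}
    ch_pos = {int(w): i for i, w in enumerate(instrument.channel_centers)}

    rows, sat_rows, ids, excluded = [], [], [], []
    for frame in frames:
        if tuple(frame.source_wavelengths) != tuple(instrument.source_wavelengths):
            raise ValueError(f"{frame.sample_id}: frame wavelengths do not "
                             f"match the instrument")
        row = np.empty(len(pairs))
        sat = np.empty(len(pairs), dtype=bool)
        valid = True
        for j, (s, c) in enumerate(pairs):
            fl = frame.sipmt[src_pos[s], ch_pos[c]]
            sat[j] = bool(frame.saturated[src_pos[s], ch_pos[c]])
            if normalization == "drs":
                ex = frame.pd_drs[src_pos[s]]
                em = frame.pd_drs[src_pos[c]]
                if ex <= 0 or em <= 0:
                    valid = False
                    break
                row[j] = fl / (ex * em)
            else:
                row[j] = fl
        if not valid:
            excluded.append(frame.sample_id)
            warnings.warn(f"sample {frame.sample_id} excluded: non-positive "
                          f"DRS reading invalidates normalization")
            continue
        rows.append(row)
        sat_rows.append(sat)
        ids.append(frame.sample_id)

    values = pd.DataFrame(np.array(rows).reshape(len(rows), len(pairs)),
                          index=pd.Index(ids, name="sample_id"), columns=labels)
    sat_df = pd.DataFrame(np.array(sat_rows).reshape(len(sat_rows), len(pairs)),
                          index=values.index, columns=labels)
    return FeatureMatrix(values=values, pairs=pairs, normalization=normalization,
                         saturated=sat_df, excluded=excluded)
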