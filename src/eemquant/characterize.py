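"""Instrument and analysis diagnostics.

Four characterisations mirror the bench measurements used to qualify the
device and its analysis: the illumination-leakage (crosstalk) matrix from a
fluorophore-free standard, concentration-response slopes per excitation/
detection pair (excitation specificity), cross-fluorophore independence of
the recovered concentrations, and the linear input-power range of the
detector chain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .forward import AcquisitionFrame
from .instrument import InstrumentSpec
from .pipeline import CorrectedFrame, subtract_background
from .pls import CVResult


@dataclass
class CrosstalkReport:
    """Percentage leakage per (source, channel), relative to each source's
    matched channel (the channel at the source wavelength, defined as
    100 %).  ``undefined`` flags sources whose matched-channel value was
    non-positive."""

    matrix: pd.DataFrame            # index: source nm, columns: channel nm, in %
    reference_channel: dict[int, int]
    undefined: list[int]


def crosstalk_matrix(frames: list[AcquisitionFrame] | list[CorrectedFrame],
                     instrument: InstrumentSpec) -> CrosstalkReport:
    """Crosstalk percentages from frames of a zero-fluorescence standard.

    Background-subtracted channel values under each source are expressed as
    100 * value / matched-channel value; frames are averaged first.
    """
    corrected = [f if isinstance(f, CorrectedFrame)
                 else subtract_background(f, v_max=instrument.v_max)
                 for f in frames]
    mean = np.mean([f.sipmt for f in corrected], axis=0)  # (source, channel)
    sources = list(instrument.source_wavelengths)
    channels = list(instrument.channel_centers)
    ref_channel = {}
    undefined = []
    rows = np.full((len(sources), len(channels)), np.nan)
    for i, src in enumerate(sources):
        j = instrument.channel_index(src)
        ref_channel[src] = channels[j]
        ref = mean[i, j]
        if ref <= 0:
            undefined.append(src)
            continue
        rows[i] = 100.0 * mean[i] / ref
    matrix = pd.DataFrame(rows, index=pd.Index(sources, name="source_nm"),
                          columns=pd.Index(channels, name="channel_nm"))
    return CrosstalkReport(matrix=matrix, reference_channel=ref_channel,
                           undefined=undefined)


def specificity_slopes(series: dict[str, tuple[np.ndarray, pd.DataFrame]],
                       flag_se: float = 3.0) -> pd.DataFrame:
    """Concentration-response slope per (fluorophore, feature pair).

    ``series`` maps a fluorophore name to (concentrations, intensities)
    where intensities is an n x p table (one column per (source, channel)
    pair, replicate means allowed).  Returns a tidy table of least-squares
    slope, intercept and slope standard error, flagging pairs whose slope
    differs from zero by more than ``flag_se`` standard errors.
    """
    records = []
    for name, (conc, intensities) in series.items():
        conc = np.asarray(conc, dtype=float)
        if len(np.unique(conc)) < 2:
            raise ValueError(f"{name}: need >= 2 distinct concentration levels")
        for col in intensities.columns:
            y = np.asarray(intensities[col], dtype=float)
            res = stats.linregress(conc, y)
            se = res.stderr if np.isfinite(res.stderr) else 0.0
            flagged = bool(se > 0 and abs(res.slope) > flag_se * se) or \
                bool(se == 0 and res.slope != 0)
            records.append({"fluorophore": name, "pair": col,
                            "slope": res.slope, "intercept": res.intercept,
                            "stderr": se, "responsive": flagged})
    return pd.DataFrame.from_records(records)


def independence_check(cv: CVResult, truth: pd.DataFrame,
                       k: int | None = None) -> pd.DataFrame:
    """Slope of LOOCV-predicted concentration of one fluorophore against
    the true concentration of another, over a factorial design.

    On a balanced factorial any prediction that depends only on its own
    true concentration gives exactly zero cross-slopes.  Self-pairs
    (predicted vs its own truth) are included; their slope is ~1 on good
    recovery.
    """
    preds = cv.predictions_at(k) if k is not None else cv.predictions
    names = list(truth.columns)
    pred_df = pd.DataFrame(preds, columns=names, index=truth.index)
    records = []
    for f1 in names:
        for f2 in names:
            res = stats.linregress(truth[f2].to_numpy(dtype=float),
                                   pred_df[f1].to_numpy(dtype=float))
            records.append({"predicted": f1, "against": f2,
                            "slope": res.slope, "stderr": res.stderr,
                            "self": f1 == f2})
    return pd.DataFrame.from_records(records)


def linearity_range(power_nw: np.ndarray, output: np.ndarray,
                    deviation: float = 0.05) -> tuple[float, float]:
    """Largest contiguous input range with output within ``deviation`` of
    the least-squares line fitted to the central decade of the sweep.

    The reference line is fitted to the points within half a decade of the
    sweep's log-midpoint, away from both the noise floor and saturation.
    """
    power = np.asarray(power_nw, dtype=float)
    output = np.asarray(output, dtype=float)
    if power.size < 4:
        raise ValueError("need at least 4 sweep points")
    if np.any(power <= 0) or np.any(np.diff(power) <= 0):
        raise ValueError("power sweep must be positive and strictly increasing")
    logp = np.log10(power)
    mid = 0.5 * (logp[0] + logp[-1])
    ref = np.abs(logp - mid) <= 0.5
    if ref.sum() < 2:
        ref = np.zeros_like(ref)
        ref[len(ref) // 2 - 1: len(ref) // 2 + 1] = True
    slope, intercept = np.polyfit(power[ref], output[ref], 1)
    fitted = slope * power + intercept
    ok = np.abs(output - fitted) <= deviation * np.abs(fitted)
    # longest contiguous True run
    best_len, best = 0, (0, 0)
    start = None
    for i, flag in enumerate(np.append(ok, False)):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            if i - start > best_len:
                best_len, best = i - start, (start, i - 1)
            start = None
    if best_len == 0:
        raise ValueError("no linear region found")
    return float(power[best[0]]), float(power[best[1]])
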