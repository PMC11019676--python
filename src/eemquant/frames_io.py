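"""Long-format CSV serialisation of acquisition frames and feature tables.

Frame files carry one row per (sample, state, detector) with columns
``sample_id, state, detector, value, seed``; ``state`` is ``dark`` or the
source wavelength in nm, ``detector`` is ``pd`` or ``ch<λ>``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .forward import AcquisitionFrame, IlluminationState
from .pipeline import FeatureMatrix

FRAME_COLUMNS = ["sample_id", "state", "detector", "value", "seed"]


class FrameFormatError(ValueError):
    pass


def frames_to_table(frames: list[AcquisitionFrame],
                    channel_centers) -> pd.DataFrame:
    rows = []
    for frame in frames:
        for state in frame.states:
            rows.append((frame.sample_id, state.label, "pd", state.pd_drs,
                         frame.seed))
            for ch, v in zip(channel_centers, state.sipmt):
                rows.append((frame.sample_id, state.label, f"ch{int(ch)}", v,
                             frame.seed))
    return pd.DataFrame(rows, columns=FRAME_COLUMNS)


def write_frames(frames: list[AcquisitionFrame], path, channel_centers) -> None:
    # %.17g guarantees bit-exact float round trips through the CSV
    frames_to_table(frames, channel_centers).to_csv(path, index=False,
                                                    float_format="%.17g")


def read_frames(path) -> list[AcquisitionFrame]:
    """Parse a long-format frame CSV; frames keep input sample order, states
    are ordered dark-first then ascending wavelength, independent of row
    order in the file."""
    df = pd.read_csv(path, dtype={"sample_id": str, "state": str,
                                  "detector": str},
                     float_precision="round_trip")
    missing = set(FRAME_COLUMNS[:4]) - set(df.columns)
    if missing:
        raise FrameFormatError(f"missing columns: {sorted(missing)}")
    bad = df[pd.to_numeric(df["value"], errors="coerce").isna()]
    if len(bad):
        raise FrameFormatError(f"non-numeric value at file row "
                               f"{int(bad.index[0]) + 2}")
    frames = []
    for sample_id in df["sample_id"].drop_duplicates():
        sub = df[df["sample_id"] == sample_id]
        states = []
        labels = sub["state"].drop_duplicates().tolist()
        if "dark" not in labels:
            raise FrameFormatError(f"sample {sample_id}: missing dark state")
        wavelengths = sorted(int(s) for s in labels if s != "dark")
        for label in ["dark"] + [str(w) for w in wavelengths]:
            grp = sub[sub["state"] == label]
            pd_rows = grp[grp["detector"] == "pd"]
            if len(pd_rows) != 1:
                raise FrameFormatError(
                    f"sample {sample_id}, state {label}: expected one 'pd' "
                    f"row, found {len(pd_rows)}")
            ch_rows = grp[grp["detector"] != "pd"]
            chans = []
            for det in ch_rows["detector"]:
                if not det.startswith("ch"):
                    row = int(ch_rows[ch_rows["detector"] == det].index[0]) + 2
                    raise FrameFormatError(
                        f"unknown detector label {det!r} at file row {row}")
                chans.append(int(det[2:]))
            order = np.argsort(chans)
            sipmt = ch_rows["value"].to_numpy(dtype=float)[order]
            states.append(IlluminationState(label, float(pd_rows["value"].iloc[0]),
                                            sipmt))
        seed = None
        if "seed" in sub.columns and pd.notna(sub["seed"].iloc[0]):
            seed = int(sub["seed"].iloc[0])
        frames.append(AcquisitionFrame(sample_id=str(sample_id), states=states,
                                       seed=seed))
    return frames


def write_features(fm: FeatureMatrix, path) -> None:
    fm.values.to_csv(path)


def read_features(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="sample_id",
                       float_precision="round_trip")
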