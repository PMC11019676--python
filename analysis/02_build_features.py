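"""Turn raw frames into masked, DRS-normalised feature matrices.

Reads the frames written by 01_simulate_phantoms.py, subtracts the ambient
(dark) state, drops anti-Stokes (channel < source) pairs and applies the
Ex*Em normalisation, writing one n x 36 feature CSV per study.
"""

from pathlib import Path

import eemquant as eq
from eemquant import frames_io
from eemquant.workflow import build_features

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    instrument = eq.load_instrument(OUT / "instrument.yaml")
    for name in ("factorial", "absorber"):
        frames = frames_io.read_frames(OUT / f"frames_{name}.csv")
        fm = build_features(frames, instrument)
        frames_io.write_features(fm, OUT / f"features_{name}.csv")
        n_sat = int(fm.saturated.to_numpy().sum())
        print(f"{name}: {fm.n} x {fm.p} feature matrix "
              f"({n_sat} saturated cells carried through, "
              f"{len(fm.excluded)} samples excluded)")


if __name__ == "__main__":
    main()
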