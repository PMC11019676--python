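"""Liquid tissue-phantom designs.

Two factorial designs mirror the validation experiments: a 125-sample
three-fluorophore factorial at fixed optical properties, and a 20-sample
FAD-by-absorber grid used to probe the residual absorber dependence of the
normalised fluorescence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import pandas as pd

NADH_LEVELS = (100.0, 50.0, 25.0, 12.5, 0.0)   # µg/ml
FAD_LEVELS = (10.0, 5.0, 2.5, 1.25, 0.0)       # µg/ml
PPIX_LEVELS = (10.0, 5.0, 2.5, 1.25, 0.0)      # µg/ml

#: ink-stock volume fractions (%) of the absorber series, 0.5 % to 4 %
ABSORBER_LEVELS = (0.5, 1.0, 2.0, 4.0)

INK_FRACTION_DEFAULT = 0.5        # % volume of ink stock
INTRALIPID_FRACTION_DEFAULT = 4.0  # % volume of 20 % intralipid stock


@dataclass(frozen=True)
class PhantomSample:
    """One liquid phantom: fluorophore concentrations plus base composition."""

    sample_id: str
    concentrations: dict[str, float] = field(default_factory=dict)
    absorber_fraction: float = INK_FRACTION_DEFAULT
    scatterer_fraction: float = INTRALIPID_FRACTION_DEFAULT

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.concentrations.values()):
            raise ValueError(f"{self.sample_id}: concentrations must be >= 0")
        if self.absorber_fraction < 0 or self.scatterer_fraction < 0:
            raise ValueError(f"{self.sample_id}: fractions must be >= 0")


def fluorophore_factorial(absorber_fraction: float = INK_FRACTION_DEFAULT,
                  scatterer_fraction: float = INTRALIPID_FRACTION_DEFAULT,
                  ) -> list[PhantomSample]:
    """Full 5x5x5 factorial over the NADH/FAD/PpIX concentration ladders.

    All 125 samples share the fixed 0.5 % ink / 4 % intralipid base.
    """
    samples = []
    for i, (n, f, p) in enumerate(product(NADH_LEVELS, FAD_LEVELS, PPIX_LEVELS)):
        samples.append(PhantomSample(
            sample_id=f"t1_{i:03d}",
            concentrations={"NADH": n, "FAD": f, "PpIX": p},
            absorber_fraction=absorber_fraction,
            scatterer_fraction=scatterer_fraction,
        ))
    return samples


def absorber_series(scatterer_fraction: float = INTRALIPID_FRACTION_DEFAULT,
                ) -> list[PhantomSample]:
    """5 FAD levels x 4 absorber fractions (n = 20), scatterer fixed."""
    samples = []
    for i, (f, a) in enumerate(product(FAD_LEVELS, ABSORBER_LEVELS)):
        samples.append(PhantomSample(
            sample_id=f"s1_{i:03d}",
            concentrations={"NADH": 0.0, "FAD": f, "PpIX": 0.0},
            absorber_fraction=a,
            scatterer_fraction=scatterer_fraction,
        ))
    return samples


def standard_sample() -> PhantomSample:
    """Fluorophore-free solid-standard analogue used for crosstalk runs."""
    return PhantomSample(sample_id="standard",
                         concentrations={"NADH": 0.0, "FAD": 0.0, "PpIX": 0.0})


def design_to_frame(samples: list[PhantomSample]) -> pd.DataFrame:
    rows = []
    for s in samples:
        row = {"sample_id": s.sample_id, **s.concentrations,
               "absorber_fraction": s.absorber_fraction,
               "scatterer_fraction": s.scatterer_fraction}
        rows.append(row)
    return pd.DataFrame(rows)


def design_from_frame(df: pd.DataFrame) -> list[PhantomSample]:
    meta = {"sample_id", "absorber_fraction", "scatterer_fraction"}
    fluors = [c for c in df.columns if c not in meta]
    samples = []
    for _, row in df.iterrows():
        samples.append(PhantomSample(
            sample_id=str(row["sample_id"]),
            concentrations={f: float(row[f]) for f in fluors},
            absorber_fraction=float(row["absorber_fraction"]),
            scatterer_fraction=float(row["scatterer_fraction"]),
        ))
    return samples
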