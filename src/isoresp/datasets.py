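"""Synthetic study-shaped example datasets.

These constructors build *synthetic stand-ins* for the per-fraction isotope
tables of a two-species coculture incubation experiment: the fraction
counts, collection spans, carbon masses and isotope trajectories follow the
qualitative shape reported for such experiments (a dozen fractions over
~5 days, progressive ¹³C enrichment, a lost fraction in one run), but every
number here is invented for testing and demonstration.  None of these values
are measured data; do not use them to draw scientific conclusions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .isotopes import CO2Fraction, IsotopeMeasurement
from .mixing import Endmember, EndmemberSet

__all__ = [
    "synthetic_endmembers",
    "synthetic_study_fractions",
]


def synthetic_endmembers() -> EndmemberSet:
    """Plausible (synthetic) three-pool endmember signatures.

    Phytoplankton-derived carbon: modern, relatively ¹³C-enriched;
    acetate/fermentation products: ¹³C-depleted, moderately aged;
    pre-aged organic carbon: strongly ¹⁴C-depleted.  The 1σ values are
    placeholder assumed uncertainties; real analyses must substitute their
    own endmember characterization.
    """
    return EndmemberSet(
        [
            Endmember(
                "phytoplankton",
                IsotopeMeasurement(-20.0, 50.0, sigma_delta13C=1.0, sigma_Delta14C=50.0),
            ),
            Endmember(
                "acetate_ferm",
                IsotopeMeasurement(-38.0, -250.0, sigma_delta13C=1.0, sigma_Delta14C=50.0),
            ),
            Endmember(
                "pre_aged",
                IsotopeMeasurement(-27.0, -900.0, sigma_delta13C=1.0, sigma_Delta14C=50.0),
            ),
        ]
    )


# (t_start_h, t_end_h, mass_ugC, delta13C, Delta14C); None marks the lost fraction
_HYDROTHERMAL_ROWS = [
    (0.0, 8.0, 800.0, -37.0, -218.0),
    (8.0, 14.0, 1500.0, -35.8, -227.0),
    (14.0, 20.0, 1900.0, -34.6, -236.0),
    (20.0, 26.0, 1900.0, -33.5, -246.0),
    (26.0, 32.0, 1700.0, -32.3, -255.0),
    (32.0, 40.0, 1500.0, -31.1, -264.0),
    (40.0, 48.0, 1300.0, -29.9, -274.0),
    (48.0, 58.0, 1100.0, -28.7, -283.0),
    (58.0, 70.0, 900.0, -27.5, -292.0),
    (70.0, 84.0, 800.0, -26.4, -302.0),
    (84.0, 100.0, 900.0, -25.2, -311.0),
    (100.0, 120.0, 800.0, -24.0, -321.0),
]

_UNIMPACTED_ROWS = [
    (0.0, 10.0, 700.0, -31.0, -111.0),
    (10.0, 22.0, 1400.0, -29.0, -98.0),
    (22.0, 34.0, 1500.0, -27.0, -94.0),
    (34.0, 39.0, 300.0, None, None),  # lost fraction: collected, never measured
    (39.0, 55.0, 1200.0, -24.0, -100.0),
    (55.0, 67.0, 800.0, -22.0, -108.0),
    (67.0, 79.0, 600.0, -19.0, -115.0),
    (79.0, 91.0, 400.0, -17.0, -123.0),
]


def synthetic_study_fractions(kind: str = "unimpacted") -> list[CO2Fraction]:
    """Synthetic trap-fraction table shaped like a sediment coculture run.

    ``kind='hydrothermal'``: 12 fractions over 5 days, ~15.1 mg total respired
    carbon, δ¹³C climbing from −37 to −24‰ while Δ¹⁴C falls from −218 to
    −321‰ (increasing use of aged carbon).  ``kind='unimpacted'``: 8 fractions
    over 91 h, ~6.9 mg, δ¹³C from −31 to −17‰, Δ¹⁴C hooking positive over the
    first day before declining; the fourth fraction has no isotope values
    (sample lost before measurement).  All values are synthetic.
    """
    rows = {"hydrothermal": _HYDROTHERMAL_ROWS, "unimpacted": _UNIMPACTED_ROWS}.get(kind)
    if rows is None:
        raise ValueError(f"unknown dataset kind {kind!r}")
    out = []
    for i, (t0, t1, mass, d13, d14) in enumerate(rows, start=1):
        iso = (
            None
            if d13 is None
            else IsotopeMeasurement(d13, d14, sigma_delta13C=2.0, sigma_Delta14C=50.0)
        )
        out.append(CO2Fraction(index=i, t_start=t0, t_end=t1, mass_ugC=mass, isotopes=iso))
    return out
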