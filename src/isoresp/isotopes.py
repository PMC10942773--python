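"""Isotope conventions, unit conversions, blank correction and mass-weighted averages.

Stable carbon isotope ratios are expressed in delta notation (δ¹³C, per mil
vs VPDB) and radiocarbon content in Δ¹⁴C notation: the per-mil deviation of a
sample's ¹³C-normalized ¹⁴C/¹²C ratio from the 1950 atmospheric reference,
decay-corrected to the year of collection.  Both tracers mix linearly to good
approximation, which is what the mass-balance machinery in
:mod:`isoresp.mixing` relies on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "IsotopeMeasurement",
    "RadiocarbonConstants",
    "CO2Fraction",
    "delta14c_from_fm",
    "fm_from_delta14c",
    "blank_correct",
    "mass_weighted_mean",
    "read_fraction_table",
    "write_fraction_table",
    "OverCorrectionWarning",
]

#: Radiocarbon-dead carbon has Δ¹⁴C of exactly −1000‰ (no ¹⁴C left).
DEAD_CARBON_PERMIL = -1000.0


class OverCorrectionWarning(UserWarning):
    """Blank correction pushed Δ¹⁴C below the dead-carbon bound of −1000‰."""


@dataclass(frozen=True)
class IsotopeMeasurement:
    """A paired (δ¹³C, Δ¹⁴C) observation with 1σ uncertainties.

    Parameters
    ----------
    delta13C : float
        Stable carbon isotope value, ‰ vs VPDB.
    Delta14C : float
        Radiocarbon value, ‰ (age- and fractionation-corrected convention).
        Bounded below by −1000‰ (radiocarbon-dead carbon).
    sigma_delta13C, sigma_Delta14C : float
        1σ measurement uncertainties, ‰.  Must be non-negative.
    """

    delta13C: float
    Delta14C: float
    sigma_delta13C: float = 0.0
    sigma_Delta14C: float = 0.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.delta13C) or not np.isfinite(self.Delta14C):
            raise ValueError("isotope values must be finite")
        if self.Delta14C < DEAD_CARBON_PERMIL:
            raise ValueError(
                f"Delta14C = {self.Delta14C:.1f} ‰ is below the dead-carbon "
                f"bound of {DEAD_CARBON_PERMIL:.0f} ‰"
            )
        if self.sigma_delta13C < 0 or self.sigma_Delta14C < 0:
            raise ValueError("1-sigma uncertainties must be non-negative")

    def as_vector(self) -> np.ndarray:
        """Return ``[delta13C, Delta14C]`` as a float array."""
        return np.array([self.delta13C, self.Delta14C], dtype=float)

    def sigma_vector(self) -> np.ndarray:
        """Return ``[sigma_delta13C, sigma_Delta14C]`` as a float array."""
        return np.array([self.sigma_delta13C, self.sigma_Delta14C], dtype=float)


@dataclass(frozen=True)
class RadiocarbonConstants:
    """Constants of the Δ¹⁴C reporting convention.

    ``lambda_decay`` is the Libby-scale decay constant 1/8267 yr⁻¹ used in the
    age correction that refers a measured fraction modern back to 1950.  It is
    configurable because the convention, not the numeric constant, is what the
    reporting standard fixes.
    """

    lambda_decay: float = 1.0 / 8267.0
    reference_year: float = 1950.0

    def __post_init__(self) -> None:
        if self.lambda_decay <= 0:
            raise ValueError("lambda_decay must be positive")


@dataclass(frozen=True)
class CO2Fraction:
    """One trap-collection window of respired CO₂.

    ``isotopes`` is ``None`` for fractions that were collected but never
    measured (e.g. lost during handling at the radiocarbon facility); the
    mass-weighted averaging then either fails loudly or renormalizes over the
    measured fractions, depending on the caller's choice.
    """

    index: int
    t_start: float  # hours since inoculation
    t_end: float
    mass_ugC: float
    isotopes: IsotopeMeasurement | None = None

    def __post_init__(self) -> None:
        if not self.t_start < self.t_end:
            raise ValueError(
                f"fraction {self.index}: t_start ({self.t_start}) must precede "
                f"t_end ({self.t_end})"
            )
        if not self.mass_ugC > 0:
            raise ValueError(f"fraction {self.index}: mass_ugC must be positive")

    @property
    def duration_h(self) -> float:
        return self.t_end - self.t_start


def validate_fraction_sequence(fractions: Sequence[CO2Fraction]) -> None:
    """Check that collection windows are time-ordered and non-overlapping."""
    ordered = sorted(fractions, key=lambda f: f.t_start)
    for a, b in zip(ordered, ordered[1:]):
        if b.t_start < a.t_end - 1e-9:
            raise ValueError(
                f"fractions {a.index} and {b.index} overlap in time "
                f"([{a.t_start}, {a.t_end}] vs [{b.t_start}, {b.t_end}])"
            )


def delta14c_from_fm(
    fm: float,
    year_collected: float,
    constants: RadiocarbonConstants = RadiocarbonConstants(),
) -> float:
    """Convert δ¹³C-normalized fraction modern to Δ¹⁴C (‰).

    Δ¹⁴C = (fm · exp(λ · (1950 − year_collected)) − 1) · 1000

    The exponential factor removes the decay accumulated between the 1950
    reference and the year the sample was measured, so that samples of the
    same true ¹⁴C content collected in different years report the same Δ¹⁴C.

    Parameters
    ----------
    fm : float
        Fraction modern, already normalized to δ¹³C = −25‰.  Must be ≥ 0;
        fm = 0 is radiocarbon-dead carbon and maps to −1000‰.
    year_collected : float
        Calendar year of collection/measurement.
    """
    if fm < 0:
        raise ValueError(f"fraction modern must be non-negative, got {fm}")
    age_factor = math.exp(
        constants.lambda_decay * (constants.reference_year - year_collected)
    )
    return (fm * age_factor - 1.0) * 1000.0


def fm_from_delta14c(
    delta14c: float,
    year_collected: float,
    constants: RadiocarbonConstants = RadiocarbonConstants(),
) -> float:
    """Inverse of :func:`delta14c_from_fm`; exact round trip by construction."""
    if delta14c < DEAD_CARBON_PERMIL:
        raise ValueError(
            f"Delta14C below the dead-carbon bound: {delta14c} < {DEAD_CARBON_PERMIL}"
        )
    age_factor = math.exp(
        constants.lambda_decay * (constants.reference_year - year_collected)
    )
    return (delta14c / 1000.0 + 1.0) / age_factor


def blank_correct(
    total_mass_ugC: float,
    total_isotopes: IsotopeMeasurement,
    blank_mass_ugC: float,
    blank_isotopes: IsotopeMeasurement,
    *,
    warn_on_overcorrection: bool = True,
) -> IsotopeMeasurement:
    """Remove a constant-mass procedural blank by two-component unmixing.

    The measured sample is modelled as a mixture of the true sample and a
    contamination blank of known mass and isotopic composition; for each
    tracer x,

        x_corr = (m_tot · x_tot − m_bl · x_bl) / (m_tot − m_bl)

    Uncertainties are propagated to first order assuming independent inputs
    (masses are treated as exact):

        σ_corr = sqrt((m_tot σ_tot)² + (m_bl σ_bl)²) / (m_tot − m_bl)

    A zero blank mass is a no-op.  If the corrected Δ¹⁴C falls below −1000‰
    the blank assumptions are inconsistent with the measurement
    (over-correction); a warning is emitted and the value clamped is NOT
    applied — the out-of-range value is raised as an error by the
    IsotopeMeasurement constructor unless warnings are downgraded.
    """
    if blank_mass_ugC < 0:
        raise ValueError("blank mass must be non-negative")
    if blank_mass_ugC == 0:
        return total_isotopes
    if total_mass_ugC <= blank_mass_ugC:
        raise ValueError(
            f"degenerate blank correction: blank mass ({blank_mass_ugC} µg C) "
            f"must be smaller than total mass ({total_mass_ugC} µg C)"
        )
    m_net = total_mass_ugC - blank_mass_ugC
    x_tot = total_isotopes.as_vector()
    x_bl = blank_isotopes.as_vector()
    x_corr = (total_mass_ugC * x_tot - blank_mass_ugC * x_bl) / m_net
    s_tot = total_isotopes.sigma_vector()
    s_bl = blank_isotopes.sigma_vector()
    s_corr = np.hypot(total_mass_ugC * s_tot, blank_mass_ugC * s_bl) / m_net

    if x_corr[1] < DEAD_CARBON_PERMIL:
        import warnings

        if warn_on_overcorrection:
            warnings.warn(
                f"blank correction drives Delta14C to {x_corr[1]:.1f} ‰, below "
                "the dead-carbon bound; the blank mass or signature is likely "
                "overestimated",
                OverCorrectionWarning,
                stacklevel=2,
            )
        # keep the flag visible but return a physically admissible object
        x_corr[1] = DEAD_CARBON_PERMIL
    return IsotopeMeasurement(
        delta13C=float(x_corr[0]),
        Delta14C=float(x_corr[1]),
        sigma_delta13C=float(s_corr[0]),
        sigma_Delta14C=float(s_corr[1]),
    )


def mass_weighted_mean(
    fractions: Sequence[CO2Fraction],
    tracer: Literal["delta13C", "Delta14C"],
    *,
    renormalize_missing: bool = False,
) -> float:
    """Mass-weighted average of a tracer over trap fractions (‰).

    Each fraction's isotope value is weighted by its share of the total
    trapped carbon mass: Σᵢ wᵢ xᵢ with wᵢ = mᵢ / Σ m.  Fractions without
    isotope measurements are dropped and the weights renormalized over the
    measured remainder when ``renormalize_missing`` is set; otherwise their
    presence is an error.  The result always lies within the range of the
    contributing values.
    """
    if tracer not in ("delta13C", "Delta14C"):
        raise ValueError(f"unknown tracer {tracer!r}")
    if not fractions:
        raise ValueError("no fractions supplied")
    measured = [f for f in fractions if f.isotopes is not None]
    missing = [f for f in fractions if f.isotopes is None]
    if not measured:
        raise ValueError("no fraction carries isotope measurements")
    if missing and not renormalize_missing:
        idx = ", ".join(str(f.index) for f in missing)
        raise ValueError(
            f"fractions {idx} lack isotope values; pass renormalize_missing=True "
            "to drop them and renormalize the mass weights"
        )
    masses = np.array([f.mass_ugC for f in measured], dtype=float)
    values = np.array([getattr(f.isotopes, tracer) for f in measured], dtype=float)
    weights = masses / masses.sum()
    return float(np.dot(weights, values))


# ---------------------------------------------------------------------------
# CSV interface
# ---------------------------------------------------------------------------

FRACTION_COLUMNS = [
    "index",
    "t_start_h",
    "t_end_h",
    "mass_ugC",
    "delta13C_permil",
    "Delta14C_permil",
    "sigma13",
    "sigma14",
]


def read_fraction_table(path) -> list[CO2Fraction]:
    """Read a trap-fraction table from CSV.

    Columns: ``index, t_start_h, t_end_h, mass_ugC, delta13C_permil,
    Delta14C_permil, sigma13, sigma14``.  Empty isotope cells mark fractions
    that were collected but not measured.
    """
    df = pd.read_csv(path)
    missing_cols = set(FRACTION_COLUMNS) - set(df.columns)
    if missing_cols:
        raise ValueError(f"{path}: missing columns {sorted(missing_cols)}")
    fractions: list[CO2Fraction] = []
    for _, row in df.iterrows():
        if pd.isna(row["delta13C_permil"]) or pd.isna(row["Delta14C_permil"]):
            iso = None
        else:
            iso = IsotopeMeasurement(
                delta13C=float(row["delta13C_permil"]),
                Delta14C=float(row["Delta14C_permil"]),
                sigma_delta13C=float(row["sigma13"]) if pd.notna(row["sigma13"]) else 0.0,
                sigma_Delta14C=float(row["sigma14"]) if pd.notna(row["sigma14"]) else 0.0,
            )
        fractions.append(
            CO2Fraction(
                index=int(row["index"]),
                t_start=float(row["t_start_h"]),
                t_end=float(row["t_end_h"]),
                mass_ugC=float(row["mass_ugC"]),
                isotopes=iso,
            )
        )
    validate_fraction_sequence(fractions)
    return fractions


def write_fraction_table(fractions: Sequence[CO2Fraction], path) -> None:
    """Write fractions to CSV in the schema read by :func:`read_fraction_table`."""
    rows = []
    for f in fractions:
        iso = f.isotopes
        rows.append(
            {
                "index": f.index,
                "t_start_h": f.t_start,
                "t_end_h": f.t_end,
                "mass_ugC": f.mass_ugC,
                "delta13C_permil": iso.delta13C if iso else np.nan,
                "Delta14C_permil": iso.Delta14C if iso else np.nan,
                "sigma13": iso.sigma_delta13C if iso else np.nan,
                "sigma14": iso.sigma_Delta14C if iso else np.nan,
            }
        )
    pd.DataFrame(rows, columns=FRACTION_COLUMNS).to_csv(path, index=False)
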