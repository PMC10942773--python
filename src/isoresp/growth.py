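"""dPCR growth curves: dilution scaling, replicate summaries, dominance ratios.

Digital PCR reports absolute genome copies per microliter of reaction; each
subsample is diluted before quantification, so copies are rescaled by the
dilution factor, and replicate DNA extractions at a time point give a mean
and a standard error (sd/√n) for the growth curve.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DpcrObservation",
    "scale_by_dilution",
    "replicate_summary",
    "growth_series",
    "dominance_ratio",
    "read_dpcr_csv",
]


@dataclass(frozen=True)
class DpcrObservation:
    """Replicate dPCR counts for one species at one sampling time."""

    time: float  # hours since inoculation
    species: str
    replicate_values: tuple[float, ...]  # genome copies per uL of reaction
    dilution_factor: float = 1.0

    def __post_init__(self) -> None:
        vals = tuple(float(v) for v in self.replicate_values)
        object.__setattr__(self, "replicate_values", vals)
        if not vals:
            raise ValueError("at least one replicate value is required")
        if any(v < 0 for v in vals):
            raise ValueError("genome copies cannot be negative")
        if self.dilution_factor < 1:
            raise ValueError(
                f"dilution factor must be ≥ 1, got {self.dilution_factor}"
            )


def scale_by_dilution(obs: DpcrObservation) -> DpcrObservation:
    """Rescale replicate counts to the undiluted subsample (× dilution factor)."""
    scaled = tuple(v * obs.dilution_factor for v in obs.replicate_values)
    return DpcrObservation(
        time=obs.time,
        species=obs.species,
        replicate_values=scaled,
        dilution_factor=1.0,
    )


def replicate_summary(values: Sequence[float]) -> tuple[float, float]:
    """Mean and standard error (sample sd / √n) of replicate measurements.

    With a single replicate the standard error is undefined and returned as
    NaN rather than zero — one measurement says nothing about scatter.
    """
    vals = np.asarray(values, dtype=float)
    if vals.size == 0:
        raise ValueError("empty replicate list")
    mean = float(vals.mean())
    if vals.size == 1:
        return mean, float("nan")
    se = float(vals.std(ddof=1) / math.sqrt(vals.size))
    return mean, se


def growth_series(observations: Sequence[DpcrObservation]) -> pd.DataFrame:
    """Reduce observations to a growth-curve table.

    Returns a DataFrame with columns ``time_h, species, mean, se`` where the
    mean is dilution-scaled genome copies per μL of original subsample and
    ``se`` the standard error between replicate subsamples; rows sorted by
    species then time.
    """
    if not observations:
        raise ValueError("no observations supplied")
    rows = []
    for obs in observations:
        scaled = scale_by_dilution(obs)
        mean, se = replicate_summary(scaled.replicate_values)
        rows.append(
            {"time_h": obs.time, "species": obs.species, "mean": mean, "se": se}
        )
    return (
        pd.DataFrame(rows)
        .sort_values(["species", "time_h"], kind="stable")
        .reset_index(drop=True)
    )


def dominance_ratio(
    series: pd.DataFrame, species_a: str, species_b: str
) -> pd.DataFrame:
    """Per-time ratio of mean abundances a/b at shared time points.

    Times where species b has zero mean are reported with a NaN ratio rather
    than dropped.  Raises if the species share no time points.
    """
    a = series[series["species"] == species_a].set_index("time_h")["mean"]
    b = series[series["species"] == species_b].set_index("time_h")["mean"]
    common = a.index.intersection(b.index)
    if common.empty:
        raise ValueError(
            f"species {species_a!r} and {species_b!r} share no time points"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(b.loc[common] != 0, a.loc[common] / b.loc[common], np.nan)
    return pd.DataFrame({"time_h": common.to_numpy(float), "ratio": ratio})


def read_dpcr_csv(path) -> list[DpcrObservation]:
    """Read a dPCR CSV: ``time_h, species, replicate_id, copies_per_ul, dilution_factor``.

    Rows sharing (time_h, species) are grouped into one observation; their
    dilution factors must agree.
    """
    df = pd.read_csv(path)
    required = {"time_h", "species", "replicate_id", "copies_per_ul", "dilution_factor"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    observations = []
    for (time_h, species), group in df.groupby(["time_h", "species"], sort=True):
        factors = group["dilution_factor"].unique()
        if len(factors) != 1:
            raise ValueError(
                f"{path}: inconsistent dilution factors for species {species} "
                f"at t={time_h} h: {sorted(factors)}"
            )
        observations.append(
            DpcrObservation(
                time=float(time_h),
                species=str(species),
                replicate_values=tuple(group["copies_per_ul"].astype(float)),
                dilution_factor=float(factors[0]),
            )
        )
    return observations
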