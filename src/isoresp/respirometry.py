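"""Respirometer signal processing: from a CO₂ detector log to a production rate.

A flow-through respirometer sparges the culture vessel with CO₂-free carrier
gas; respired CO₂ accumulates in the headspace, is flushed to an infrared
detector (mole fraction, ppm), and is then trapped for manometric and
isotopic analysis.  Recovering the microbial CO₂ production rate per liter of
medium requires four corrections, applied in order:

1. baseline drift removal (linear between pre- and post-run anchor windows),
2. the ideal-gas unit bridge from ppm × flow to a carbon mass flux,
3. rescaling each trap window so its integral matches the high-precision
   manometric carbon yield of that trap,
4. deconvolution of the well-mixed headspace: the detector sees the flushed
   signal F(t) = (Q/V_h)·X(t) where headspace CO₂ mass X obeys
   dX/dt = S(t) − (Q/V_h)·X; the source term is recovered as
   S(t) = F(t) + (V_h/Q)·dF/dt, with the derivative estimated by a local
   polynomial (Savitzky–Golay) filter, and divided by the (shrinking) medium
   volume.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

__all__ = [
    "DetectorTimeSeries",
    "FluxSeries",
    "TrapWindow",
    "VesselGeometry",
    "RateSeries",
    "baseline_correct",
    "ppm_to_carbon_flux",
    "carbon_flux_to_ppm",
    "rescale_to_manometric",
    "deconvolve_headspace",
    "simulate_headspace",
    "integrate_window",
    "read_detector_csv",
    "read_trap_csv",
]

R_GAS = 8.31446261815324  # J mol^-1 K^-1
M_CARBON = 12.011  # g mol^-1
MAX_TRAP_MASS_UGC = 2000.0  # traps are sized so no fraction exceeds 2 mg C


def _check_time(time: np.ndarray) -> None:
    if time.ndim != 1 or time.size < 2:
        raise ValueError("time axis must be 1-D with at least two samples")
    if not np.all(np.diff(time) > 0):
        raise ValueError("time must be strictly increasing")


@dataclass(frozen=True)
class DetectorTimeSeries:
    """Raw detector log: CO₂ mole fraction vs time under constant carrier flow.

    time is minutes since the carrier-gas flow was set; flow in mL min⁻¹
    (100 by default), temperature/pressure are the detector-side gas
    conditions for the ideal-gas conversion.
    """

    time: np.ndarray  # minutes
    co2_ppm: np.ndarray
    flow: float = 100.0  # mL min^-1
    temperature: float = 298.15  # K
    pressure: float = 101.325  # kPa

    def __post_init__(self) -> None:
        object.__setattr__(self, "time", np.asarray(self.time, dtype=float))
        object.__setattr__(self, "co2_ppm", np.asarray(self.co2_ppm, dtype=float))
        _check_time(self.time)
        if self.co2_ppm.shape != self.time.shape:
            raise ValueError("co2_ppm and time must have the same shape")
        if not np.all(np.isfinite(self.co2_ppm)):
            raise ValueError("co2_ppm contains non-finite values")
        if self.flow <= 0:
            raise ValueError("carrier flow must be positive")
        if self.temperature <= 0 or self.pressure <= 0:
            raise ValueError("temperature and pressure must be positive")


@dataclass(frozen=True)
class FluxSeries:
    """Carbon mass flux past the detector, μg C min⁻¹ vs minutes."""

    time: np.ndarray
    flux: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "time", np.asarray(self.time, dtype=float))
        object.__setattr__(self, "flux", np.asarray(self.flux, dtype=float))
        _check_time(self.time)
        if self.flux.shape != self.time.shape:
            raise ValueError("flux and time must have the same shape")


@dataclass(frozen=True)
class RateSeries:
    """Microbial CO₂ production rate per liter of medium, μg C L⁻¹ min⁻¹.

    Negative excursions are measurement/deconvolution noise; they are
    retained (clipping would break mass closure with the manometric totals)
    and flagged via :attr:`has_negative_rates`.
    """

    time: np.ndarray  # minutes
    rate: np.ndarray  # ug C L^-1 min^-1

    def __post_init__(self) -> None:
        object.__setattr__(self, "time", np.asarray(self.time, dtype=float))
        object.__setattr__(self, "rate", np.asarray(self.rate, dtype=float))
        _check_time(self.time)
        if self.rate.shape != self.time.shape:
            raise ValueError("rate and time must have the same shape")
        if not np.all(np.isfinite(self.rate)):
            raise ValueError("rate contains non-finite values")

    @property
    def has_negative_rates(self) -> bool:
        return bool(np.any(self.rate < 0))

    @property
    def peak_time(self) -> float:
        return float(self.time[np.argmax(self.rate)])

    @property
    def peak_rate(self) -> float:
        return float(self.rate.max())


@dataclass(frozen=True)
class TrapWindow:
    """One molecular-sieve trap collection window with its manometric yield."""

    t_start: float  # minutes
    t_end: float
    manometric_mass_ugC: float

    def __post_init__(self) -> None:
        if not self.t_start < self.t_end:
            raise ValueError("trap window start must precede end")
        if not self.manometric_mass_ugC > 0:
            raise ValueError("manometric mass must be positive")
        if self.manometric_mass_ugC > MAX_TRAP_MASS_UGC:
            raise ValueError(
                f"manometric mass {self.manometric_mass_ugC:.0f} µg C exceeds the "
                f"{MAX_TRAP_MASS_UGC:.0f} µg trap capacity"
            )


def validate_trap_sequence(traps: Sequence[TrapWindow]) -> None:
    ordered = sorted(traps, key=lambda t: t.t_start)
    for a, b in zip(ordered, ordered[1:]):
        if b.t_start < a.t_end - 1e-9:
            raise ValueError(
                f"trap windows overlap: [{a.t_start}, {a.t_end}] and "
                f"[{b.t_start}, {b.t_end}]"
            )


@dataclass(frozen=True)
class VesselGeometry:
    """Culture vessel geometry for the headspace correction.

    The medium volume is piecewise constant and non-increasing (subsampling
    removes medium over the run); the headspace is the vessel volume minus
    the current medium volume unless an explicit ``headspace_volume`` is
    given.  ``flow`` is the carrier flow through the headspace, mL min⁻¹.
    """

    vessel_volume: float = 3.0  # L
    medium_volume_schedule: tuple[tuple[float, float], ...] = ((0.0, 2.0),)
    flow: float = 100.0  # mL min^-1
    headspace_volume: float | None = None  # L; default: vessel - medium

    def __post_init__(self) -> None:
        sched = tuple((float(t), float(v)) for t, v in self.medium_volume_schedule)
        object.__setattr__(self, "medium_volume_schedule", sched)
        if not sched:
            raise ValueError("medium volume schedule must be non-empty")
        times = [t for t, _ in sched]
        vols = [v for _, v in sched]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("schedule times must be strictly increasing")
        if any(b > a for a, b in zip(vols, vols[1:])):
            raise ValueError("medium volume must be non-increasing (sampling removes medium)")
        if min(vols) <= 0:
            raise ValueError("medium volume must stay positive over the run")
        if self.flow <= 0:
            raise ValueError("flow must be positive")
        if self.headspace_volume is None:
            if max(vols) >= self.vessel_volume:
                raise ValueError("medium volume cannot fill or exceed the vessel")
        elif self.headspace_volume <= 0:
            raise ValueError("headspace volume must be positive")

    def medium_volume(self, time_min: np.ndarray | float) -> np.ndarray:
        """Medium volume (L) at the given times (piecewise constant)."""
        t = np.asarray(time_min, dtype=float)
        times = np.array([s[0] for s in self.medium_volume_schedule])
        vols = np.array([s[1] for s in self.medium_volume_schedule])
        idx = np.clip(np.searchsorted(times, t, side="right") - 1, 0, len(vols) - 1)
        return vols[idx]

    def headspace(self, time_min: np.ndarray | float) -> np.ndarray:
        """Headspace gas volume (L) at the given times."""
        if self.headspace_volume is not None:
            return np.broadcast_to(
                np.float64(self.headspace_volume), np.shape(np.asarray(time_min))
            ).copy() if np.ndim(time_min) else np.asarray(self.headspace_volume, dtype=float)
        return self.vessel_volume - self.medium_volume(time_min)


# ---------------------------------------------------------------------------
# Corrections
# ---------------------------------------------------------------------------


def _window_slice(time: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    lo, hi = window
    mask = (time >= lo) & (time <= hi)
    if mask.sum() < 3:
        raise ValueError(
            f"baseline window [{lo}, {hi}] contains {int(mask.sum())} samples; "
            "at least 3 are required"
        )
    return mask


def baseline_correct(
    series: DetectorTimeSeries,
    pre_window: tuple[float, float],
    post_window: tuple[float, float],
) -> DetectorTimeSeries:
    """Subtract a linear baseline anchored on pre- and post-run windows.

    The baseline is interpolated between the mean ppm of the pre-injection
    window and the mean of the end-of-run window, anchored at the window
    centers, and extrapolated outside.  If an anchor window appears to sit on
    the respiration pulse — its local slope departs from the cross-window
    baseline slope by more than 3× the detrended within-window scatter over
    the window span — a warning is emitted; the correction still proceeds.
    """
    t = series.time
    pre_mask = _window_slice(t, pre_window)
    post_mask = _window_slice(t, post_window)
    pre_mean = float(series.co2_ppm[pre_mask].mean())
    post_mean = float(series.co2_ppm[post_mask].mean())
    t_pre = float(t[pre_mask].mean())
    t_post = float(t[post_mask].mean())
    global_slope = (
        (post_mean - pre_mean) / (t_post - t_pre) if t_post != t_pre else 0.0
    )
    # floor keeps the check from firing on sub-resolution tail effects when
    # the anchor windows are essentially noiseless
    floor = 1e-3 * float(np.ptp(series.co2_ppm)) + 1e-9
    for mask, label in ((pre_mask, "pre"), (post_mask, "post")):
        tw, yw = t[mask], series.co2_ppm[mask]
        local_slope, intercept = np.polyfit(tw, yw, 1)
        resid_sd = float(np.std(yw - (local_slope * tw + intercept), ddof=1))
        span = float(tw[-1] - tw[0])
        if abs(local_slope - global_slope) * span > 3.0 * resid_sd + floor:
            warnings.warn(
                f"{label} baseline anchor window has a local slope inconsistent "
                "with the cross-window drift; it may overlap the respiration pulse",
                UserWarning,
                stacklevel=2,
            )
    if t_post == t_pre:
        baseline = np.full_like(t, pre_mean)
    else:
        slope = (post_mean - pre_mean) / (t_post - t_pre)
        baseline = pre_mean + slope * (t - t_pre)
    return replace(series, co2_ppm=series.co2_ppm - baseline)


def ppm_to_carbon_flux(series: DetectorTimeSeries) -> FluxSeries:
    """Ideal-gas bridge from CO₂ mole fraction to carbon mass flux.

    flux [µg C min⁻¹] = ppm·10⁻⁶ · Q[L min⁻¹] · P/(R·T) [mol L⁻¹]
                        · 12.011 [g mol⁻¹] · 10⁶ [µg g⁻¹]
    """
    molar_density = (series.pressure * 1000.0) / (R_GAS * series.temperature)  # mol m^-3
    molar_density_per_L = molar_density / 1000.0  # mol L^-1
    flow_L = series.flow / 1000.0  # L min^-1
    flux = series.co2_ppm * 1e-6 * flow_L * molar_density_per_L * M_CARBON * 1e6
    return FluxSeries(time=series.time, flux=flux)


def carbon_flux_to_ppm(
    flux: FluxSeries,
    flow: float = 100.0,
    temperature: float = 298.15,
    pressure: float = 101.325,
) -> DetectorTimeSeries:
    """Inverse of :func:`ppm_to_carbon_flux` (used by the forward simulator)."""
    molar_density_per_L = (pressure * 1000.0) / (R_GAS * temperature) / 1000.0
    flow_L = flow / 1000.0
    ppm = flux.flux / (1e-6 * flow_L * molar_density_per_L * M_CARBON * 1e6)
    return DetectorTimeSeries(
        time=flux.time, co2_ppm=ppm, flow=flow, temperature=temperature, pressure=pressure
    )


def integrate_window(
    series: FluxSeries | RateSeries, t_start: float, t_end: float
) -> float:
    """Trapezoidal integral of a flux/rate series over [t_start, t_end].

    Edge values are linearly interpolated so the integral is exactly additive
    over adjacent windows.  Units: flux in μg C min⁻¹ integrates to μg C.
    """
    if not t_start < t_end:
        raise ValueError("empty or inverted integration window")
    t = series.time
    y = series.flux if isinstance(series, FluxSeries) else series.rate
    if t_start < t[0] - 1e-9 or t_end > t[-1] + 1e-9:
        raise ValueError(
            f"window [{t_start}, {t_end}] extends beyond the series span "
            f"[{t[0]}, {t[-1]}]"
        )
    inner = (t > t_start) & (t < t_end)
    tt = np.concatenate([[t_start], t[inner], [t_end]])
    yy = np.concatenate(
        [[np.interp(t_start, t, y)], y[inner], [np.interp(t_end, t, y)]]
    )
    return float(np.trapezoid(yy, tt))


def rescale_to_manometric(
    flux: FluxSeries, traps: Sequence[TrapWindow]
) -> tuple[FluxSeries, pd.DataFrame]:
    """Rescale the detector flux so each trap window integrates to its manometric yield.

    The manometric carbon mass of each trapped fraction is far more precise
    than the detector calibration, so within each trap window the flux is
    multiplied by (manometric mass) / (window integral).  Returns the rescaled
    series and a per-window QC table (integral before, scale factor).
    Samples outside every window keep their original values.

    When two windows share a boundary (continuous trapping) the boundary
    sample belongs to the later window, and the scale factors are solved by
    backward substitution so that *every* window's trapezoidal integral
    equals its manometric mass to machine precision — a naive per-window
    multiply leaves a one-trapezoid error at each shared boundary.
    """
    traps = sorted(traps, key=lambda w: w.t_start)
    validate_trap_sequence(traps)
    t = flux.time
    y = flux.flux
    n = len(traps)
    # sample ownership: [t_start, t_end), boundary sample goes to the later
    # window; a window's end sample is its own when no successor starts there
    owner = np.full(t.size, -1, dtype=int)
    for i, trap in enumerate(traps):
        mask = (t >= trap.t_start) & (t < trap.t_end)
        owner[mask] = i
        has_successor = i + 1 < n and abs(traps[i + 1].t_start - trap.t_end) < 1e-9
        if not has_successor:
            owner[np.isclose(t, trap.t_end)] = i

    scaled = y.copy()
    factors = np.empty(n)
    integrals = np.empty(n)
    for i in reversed(range(n)):
        trap = traps[i]
        own = owner == i
        base = FluxSeries(t, np.where(own, y, 0.0))
        other = FluxSeries(t, np.where(own, 0.0, scaled))
        p = integrate_window(base, trap.t_start, trap.t_end)
        integrals[i] = integrate_window(flux, trap.t_start, trap.t_end)
        if p <= 0 or integrals[i] <= 0:
            raise ValueError(
                f"trap window [{trap.t_start}, {trap.t_end}] has non-positive "
                f"flux integral ({integrals[i]:.3g} µg C); cannot rescale"
            )
        q = integrate_window(other, trap.t_start, trap.t_end)
        factors[i] = (trap.manometric_mass_ugC - q) / p
        scaled[own] = y[own] * factors[i]

    qc = pd.DataFrame(
        {
            "window": np.arange(n),
            "t_start_min": [w.t_start for w in traps],
            "t_end_min": [w.t_end for w in traps],
            "integral_ugC": integrals,
            "manometric_ugC": [w.manometric_mass_ugC for w in traps],
            "scale_factor": factors,
        }
    )
    return FluxSeries(time=t, flux=scaled), qc


def deconvolve_headspace(
    flux: FluxSeries,
    geometry: VesselGeometry,
    *,
    smooth_window: int = 31,
    polyorder: int = 2,
) -> RateSeries:
    """Invert the well-mixed headspace compartment to recover the source rate.

    The headspace CO₂ mass X(t) obeys dX/dt = S(t) − (Q/V_h)·X with the
    detector seeing F(t) = (Q/V_h)·X(t); hence

        S(t) = F(t) + (V_h / Q) · dF/dt.

    dF/dt is estimated with a Savitzky–Golay local polynomial of
    ``smooth_window`` samples (odd, ≥ 3) and order ``polyorder``; larger
    windows suppress detector noise at the cost of smearing fast transients.
    The per-liter rate is S(t) divided by the medium volume at t.

    Requires (approximately) uniform sampling; the nominal step is the median
    time difference.
    """
    if smooth_window < 3:
        raise ValueError("derivative window must span at least 3 samples")
    if smooth_window % 2 == 0:
        smooth_window += 1
    if smooth_window > flux.time.size:
        raise ValueError("derivative window exceeds the series length")
    dt = float(np.median(np.diff(flux.time)))
    dFdt = savgol_filter(
        flux.flux, window_length=smooth_window, polyorder=polyorder, deriv=1, delta=dt
    )
    v_h = geometry.headspace(flux.time)
    q_L = geometry.flow / 1000.0  # L min^-1
    source = flux.flux + (v_h / q_L) * dFdt
    v_med = geometry.medium_volume(flux.time)
    if np.any(v_med <= 0):
        raise ValueError("medium volume reaches zero within the series span")
    return RateSeries(time=flux.time, rate=source / v_med)


def simulate_headspace(
    time: np.ndarray, source: np.ndarray, geometry: VesselGeometry
) -> FluxSeries:
    """Forward headspace model: convolve a source term into the detector flux.

    Integrates dX/dt = S(t) − (Q/V_h)·X with X(0) = 0 using an exact
    exponential step for piecewise-constant S over each interval (midpoint
    value), and returns F = (Q/V_h)·X.  This is the forward counterpart of
    :func:`deconvolve_headspace` and the reference model for round-trip
    validation.
    """
    time = np.asarray(time, dtype=float)
    source = np.asarray(source, dtype=float)
    _check_time(time)
    q_L = geometry.flow / 1000.0
    v_h = geometry.headspace(time)
    a = q_L / v_h  # flushing rate, min^-1
    x = np.zeros_like(time)
    for i in range(1, time.size):
        dt = time[i] - time[i - 1]
        s_mid = 0.5 * (source[i] + source[i - 1])
        ai = a[i]
        decay = np.exp(-ai * dt)
        x[i] = x[i - 1] * decay + (s_mid / ai) * (1.0 - decay)
    return FluxSeries(time=time, flux=a * x)


# ---------------------------------------------------------------------------
# CSV interface
# ---------------------------------------------------------------------------


def read_detector_csv(
    path,
    flow: float = 100.0,
    temperature: float = 298.15,
    pressure: float = 101.325,
) -> DetectorTimeSeries:
    """Read a detector log CSV with columns ``time_min, co2_ppm``."""
    df = pd.read_csv(path)
    for col in ("time_min", "co2_ppm"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    return DetectorTimeSeries(
        time=df["time_min"].to_numpy(float),
        co2_ppm=df["co2_ppm"].to_numpy(float),
        flow=flow,
        temperature=temperature,
        pressure=pressure,
    )


def read_trap_csv(path) -> list[TrapWindow]:
    """Read a trap table CSV with columns ``t_start_min, t_end_min, mass_ugC``."""
    df = pd.read_csv(path)
    for col in ("t_start_min", "t_end_min", "mass_ugC"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    traps = [
        TrapWindow(
            t_start=float(r["t_start_min"]),
            t_end=float(r["t_end_min"]),
            manometric_mass_ugC=float(r["mass_ugC"]),
        )
        for _, r in df.iterrows()
    ]
    validate_trap_sequence(traps)
    return traps
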