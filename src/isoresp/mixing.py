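"""Three-endmember dual-tracer (δ¹³C, Δ¹⁴C) isotope mass balance.

A measured CO₂ isotope pair is modelled as a linear mixture of three carbon
pools with assumed isotopic signatures (endmembers):

    δ¹³C_CO₂ = f₁ δ¹³C₁ + f₂ δ¹³C₂ + f₃ δ¹³C₃
    Δ¹⁴C_CO₂ = f₁ Δ¹⁴C₁ + f₂ Δ¹⁴C₂ + f₃ Δ¹⁴C₃
           1 = f₁ + f₂ + f₃

Two tracers plus the closure constraint exactly determine the three
fractions, so the system is solved directly (no fitting is involved for a
single noiseless measurement).  Uncertainty in both the measurement and the
endmember signatures is propagated by Monte Carlo resampling: each draw
perturbs every isotope value with normally distributed noise, re-solves the
linear system, and the fractions are summarized as means and standard
deviations over draws.

The user-facing entry point is :class:`CarbonSourceMixingModel`, which wraps
a set of trap fractions and an endmember set and whose :meth:`fit` returns a
:class:`MixingResults` object with per-fraction apportionments, aggregate
pool contributions, and a ``summary()`` table.  The lower-level functions
(:func:`solve_exact`, :func:`monte_carlo_apportion`,
:func:`total_contributions`) are the building blocks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .isotopes import CO2Fraction, IsotopeMeasurement, validate_fraction_sequence

__all__ = [
    "Endmember",
    "EndmemberSet",
    "MixingSolution",
    "NoiseModel",
    "FractionApportionment",
    "ContributionSummary",
    "MixingGeometryError",
    "solve_exact",
    "monte_carlo_apportion",
    "total_contributions",
    "CarbonSourceMixingModel",
    "MixingResults",
    "read_endmember_table",
    "write_endmember_table",
]


class MixingGeometryError(ValueError):
    """The endmember signatures are (near-)collinear in the (δ¹³C, Δ¹⁴C) plane."""


@dataclass(frozen=True)
class Endmember:
    """One assumed carbon pool: a name and its isotopic signature.

    The signature's sigmas are the 1σ uncertainties on the assumed endmember
    values, resampled in the Monte Carlo procedure.
    """

    name: str
    signature: IsotopeMeasurement

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("endmember name must be non-empty")


class EndmemberSet:
    """Exactly three endmembers spanning a non-degenerate mixing triangle.

    The 3×3 mixing matrix (rows: δ¹³C signatures, Δ¹⁴C signatures, ones) must
    be well conditioned; three (near-)collinear signatures leave the fractions
    unidentifiable and raise :class:`MixingGeometryError` at construction.
    """

    def __init__(
        self, endmembers: Sequence[Endmember], *, cond_threshold: float = 1e8
    ) -> None:
        if len(endmembers) != 3:
            raise ValueError(f"exactly three endmembers required, got {len(endmembers)}")
        names = [e.name for e in endmembers]
        if len(set(names)) != 3:
            raise ValueError(f"endmember names must be unique, got {names}")
        self.endmembers = tuple(endmembers)
        self.cond_threshold = cond_threshold
        cond = np.linalg.cond(self.matrix)
        if not np.isfinite(cond) or cond > cond_threshold:
            raise MixingGeometryError(
                f"endmembers {names} are collinear or nearly so in the "
                f"(delta13C, Delta14C) plane (condition number {cond:.3g} > "
                f"{cond_threshold:.3g}); the mixing fractions are not identifiable"
            )

    @property
    def names(self) -> list[str]:
        return [e.name for e in self.endmembers]

    @property
    def matrix(self) -> np.ndarray:
        """3×3 mixing matrix: rows δ¹³C, Δ¹⁴C, closure (ones)."""
        d13 = [e.signature.delta13C for e in self.endmembers]
        d14 = [e.signature.Delta14C for e in self.endmembers]
        return np.array([d13, d14, [1.0, 1.0, 1.0]], dtype=float)

    @property
    def signatures(self) -> np.ndarray:
        """2×3 array of signatures: row 0 δ¹³C, row 1 Δ¹⁴C."""
        return self.matrix[:2]

    @property
    def sigmas(self) -> np.ndarray:
        """2×3 array of signature 1σ uncertainties (same layout as signatures)."""
        s13 = [e.signature.sigma_delta13C for e in self.endmembers]
        s14 = [e.signature.sigma_Delta14C for e in self.endmembers]
        return np.array([s13, s14], dtype=float)

    def __iter__(self):
        return iter(self.endmembers)

    def __repr__(self) -> str:
        return f"EndmemberSet({', '.join(self.names)})"


@dataclass(frozen=True)
class MixingSolution:
    """Exact solution of the mixing system for one measurement.

    Fractions are returned unclipped: a measurement outside the mixing
    triangle yields components outside [0, 1] (``in_simplex`` is False), which
    is diagnostic information, not an error.
    """

    f: np.ndarray  # shape (3,), sums to 1
    names: tuple[str, str, str]

    @property
    def in_simplex(self) -> bool:
        return bool(np.all(self.f >= 0.0) and np.all(self.f <= 1.0))

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, map(float, self.f)))


@dataclass(frozen=True)
class NoiseModel:
    """Monte Carlo noise configuration.

    Defaults are the per-tracer 1σ analytical reproducibilities used for
    respired-CO₂ fractions in this kind of experiment: δ¹³C ± 2‰ and
    Δ¹⁴C ± 50‰, interpreted as standard deviations of normal noise.

    ``use_measured_sigmas`` replaces these defaults with each measurement's
    own reported 1σ where available (non-zero).  ``perturb_endmembers``
    controls whether endmember signatures are resampled with their own
    uncertainties (on by default, as in the standard procedure).
    """

    sigma_delta13C: float = 2.0
    sigma_Delta14C: float = 50.0
    perturb_endmembers: bool = True
    use_measured_sigmas: bool = False

    def __post_init__(self) -> None:
        if self.sigma_delta13C < 0 or self.sigma_Delta14C < 0:
            raise ValueError("noise sigmas must be non-negative")

    def measurement_sigmas(self, measurement: IsotopeMeasurement) -> np.ndarray:
        """Effective (σ_δ13C, σ_Δ14C) for a given measurement."""
        sig = np.array([self.sigma_delta13C, self.sigma_Delta14C], dtype=float)
        if self.use_measured_sigmas:
            own = measurement.sigma_vector()
            sig = np.where(own > 0, own, sig)
        return sig


@dataclass(frozen=True)
class FractionApportionment:
    """Monte Carlo summary of endmember fractions for one measurement."""

    names: tuple[str, str, str]
    mean: np.ndarray  # per-endmember mean fraction
    sd: np.ndarray  # per-endmember standard deviation
    n_draws: int
    simplex_share: float  # proportion of draws with all f in [0, 1]
    seed: int | None
    n_rejected: int = 0  # draws discarded for near-singular perturbed geometry

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, map(float, self.mean)))


@dataclass(frozen=True)
class ContributionSummary:
    """Aggregate pool contributions to total respired CO₂ over all fractions."""

    names: tuple[str, str, str]
    total_mass_ugC: np.ndarray  # mean per-endmember carbon mass
    percent: np.ndarray  # mean percent of total respired carbon
    percent_sd: np.ndarray
    n_replicates: int
    seed: int | None
    negative_mass_share: float = 0.0  # share of replicate×endmember masses < 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "endmember": self.names,
                "total_mass_ugC": self.total_mass_ugC,
                "percent": self.percent,
                "percent_sd": self.percent_sd,
            }
        )


# ---------------------------------------------------------------------------
# Core solvers
# ---------------------------------------------------------------------------

# Relative determinant threshold below which a perturbed 2x2 reduced system is
# treated as singular and the draw resampled.
_SINGULAR_RTOL = 1e-10


def _solve_reduced(signatures: np.ndarray, measurement: np.ndarray) -> np.ndarray:
    """Solve the mixing system with the closure row eliminated.

    ``signatures`` is 2×3 (rows δ¹³C, Δ¹⁴C), ``measurement`` length-2.
    Substituting f₃ = 1 − f₁ − f₂ turns the 3×3 system into a 2×2 one; f₃ is
    then computed from the closure identity so every returned triple sums to
    exactly 1 in floating point.
    """
    m = signatures[:, :2] - signatures[:, 2:3]
    b = measurement - signatures[:, 2]
    det = m[0, 0] * m[1, 1] - m[0, 1] * m[1, 0]
    scale = np.hypot(m[0, 0], m[0, 1]) * np.hypot(m[1, 0], m[1, 1])
    if abs(det) <= _SINGULAR_RTOL * scale:
        raise MixingGeometryError("degenerate mixing geometry (zero determinant)")
    f1 = (m[1, 1] * b[0] - m[0, 1] * b[1]) / det
    f2 = (m[0, 0] * b[1] - m[1, 0] * b[0]) / det
    f12 = f1 + f2
    return np.array([f1, f2, 1.0 - f12])


def solve_exact(
    measurement: IsotopeMeasurement, endmembers: EndmemberSet
) -> MixingSolution:
    """Solve the three-endmember mixing system exactly for one measurement.

    The solution is unique because two tracers plus the closure constraint
    give three equations for three unknowns.  Fractions are not clipped to
    [0, 1]; inspect ``in_simplex`` on the returned solution.
    """
    f = _solve_reduced(endmembers.signatures, measurement.as_vector())
    return MixingSolution(f=f, names=tuple(endmembers.names))


def _mc_draws(
    measurement: IsotopeMeasurement,
    endmembers: EndmemberSet,
    n_draws: int,
    noise: NoiseModel,
    rng: np.random.Generator,
) -> tuple[np.ndarray, int]:
    """Vectorized Monte Carlo draws of mixing fractions.

    Returns (draws, n_rejected) where draws has shape (n_draws, 3) and each
    row sums to exactly 1.  Draws whose perturbed endmember triangle is
    numerically degenerate are rejected and resampled; more than 50%
    rejections overall aborts with a geometry error.
    """
    meas = measurement.as_vector()
    meas_sigma = noise.measurement_sigmas(measurement)
    sig = endmembers.signatures  # (2, 3)
    em_sigma = endmembers.sigmas if noise.perturb_endmembers else np.zeros((2, 3))

    out = np.empty((n_draws, 3), dtype=float)
    filled = 0
    n_rejected = 0
    n_proposed = 0
    while filled < n_draws:
        k = n_draws - filled
        pert_meas = meas + rng.standard_normal((k, 2)) * meas_sigma
        pert_sig = sig + rng.standard_normal((k, 2, 3)) * em_sigma
        n_proposed += k

        m = pert_sig[:, :, :2] - pert_sig[:, :, 2:3]  # (k, 2, 2)
        b = pert_meas - pert_sig[:, :, 2]  # (k, 2)
        det = m[:, 0, 0] * m[:, 1, 1] - m[:, 0, 1] * m[:, 1, 0]
        scale = np.hypot(m[:, 0, 0], m[:, 0, 1]) * np.hypot(m[:, 1, 0], m[:, 1, 1])
        ok = np.abs(det) > _SINGULAR_RTOL * scale
        n_rejected += int(k - ok.sum())
        if n_proposed >= 1000 and n_rejected > 0.5 * n_proposed:
            raise MixingGeometryError(
                f"{n_rejected}/{n_proposed} Monte Carlo draws produced a "
                "degenerate endmember geometry; endmember uncertainties are too "
                "large relative to the separation of the signatures"
            )
        if not ok.any():
            continue
        mo, bo, do = m[ok], b[ok], det[ok]
        f1 = (mo[:, 1, 1] * bo[:, 0] - mo[:, 0, 1] * bo[:, 1]) / do
        f2 = (mo[:, 0, 0] * bo[:, 1] - mo[:, 1, 0] * bo[:, 0]) / do
        f12 = f1 + f2
        n_ok = f1.size
        out[filled : filled + n_ok, 0] = f1
        out[filled : filled + n_ok, 1] = f2
        out[filled : filled + n_ok, 2] = 1.0 - f12
        filled += n_ok
    return out, n_rejected


def monte_carlo_apportion(
    measurement: IsotopeMeasurement,
    endmembers: EndmemberSet,
    n_draws: int = 10_000,
    noise: NoiseModel = NoiseModel(),
    seed: int | np.random.Generator | None = None,
    *,
    simplex_only: bool = False,
) -> FractionApportionment:
    """Monte Carlo uncertainty propagation for one measurement.

    Each of ``n_draws`` draws adds normal noise to the measurement (per-tracer
    1σ from ``noise``) and, independently, to every endmember signature (its
    own 1σ), then solves the mixing system exactly.  The apportionment is the
    mean and standard deviation of the draws; ``simplex_share`` reports the
    proportion of draws that landed inside the physical simplex.

    Out-of-simplex draws are retained by default — clipping or discarding
    them biases the means.  ``simplex_only=True`` restricts the summary to
    in-simplex draws (sensitivity mode).

    A fixed integer ``seed`` makes the summary bit-reproducible.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be at least 1")
    seed_out = seed if isinstance(seed, (int, np.integer)) else None
    rng = np.random.default_rng(seed)
    draws, n_rejected = _mc_draws(measurement, endmembers, n_draws, noise, rng)
    in_simplex = np.all((draws >= 0.0) & (draws <= 1.0), axis=1)
    simplex_share = float(in_simplex.mean())
    kept = draws[in_simplex] if simplex_only else draws
    if kept.shape[0] == 0:
        raise MixingGeometryError(
            "simplex_only requested but no draw fell inside the simplex"
        )
    mean = kept.mean(axis=0)
    sd = kept.std(axis=0, ddof=1) if kept.shape[0] > 1 else np.zeros(3)
    return FractionApportionment(
        names=tuple(endmembers.names),
        mean=mean,
        sd=sd,
        n_draws=n_draws,
        simplex_share=simplex_share,
        seed=seed_out,
        n_rejected=n_rejected,
    )


def total_contributions(
    fractions: Sequence[CO2Fraction],
    endmembers: EndmemberSet,
    n_replicates: int = 10_000,
    noise: NoiseModel = NoiseModel(),
    seed: int | np.random.Generator | None = None,
    *,
    shared_endmember_draws: bool = True,
) -> ContributionSummary:
    """Apportion the total respired carbon mass over the endmember pools.

    Per Monte Carlo replicate, the endmember signatures are perturbed once and
    shared across all fractions (endmember uncertainty is a systematic error:
    the same assumed values underlie every fraction), while measurement noise
    is drawn independently per fraction.  Each fraction's mixing system is
    solved, the per-endmember carbon mass is Σᵢ mᵢ f_{e,i}, and its percent of
    the total trapped mass is summarized as mean ± sd over replicates.

    ``shared_endmember_draws=False`` switches to fully independent endmember
    perturbations per fraction, for comparing propagation schemes.

    Percents sum to 100 per replicate by construction; out-of-simplex
    solutions can make an individual pool's mass negative in some replicates
    (reported via ``negative_mass_share``, never silently clipped).
    """
    fractions = [f for f in fractions]
    if not fractions:
        raise ValueError("empty fraction list")
    missing = [f.index for f in fractions if f.isotopes is None]
    if missing:
        raise ValueError(
            f"fractions {missing} lack isotope measurements; drop them before "
            "apportioning totals"
        )
    if n_replicates < 1:
        raise ValueError("n_replicates must be at least 1")
    seed_out = seed if isinstance(seed, (int, np.integer)) else None
    rng = np.random.default_rng(seed)

    masses = np.array([f.mass_ugC for f in fractions], dtype=float)
    n_frac = len(fractions)
    meas = np.array([f.isotopes.as_vector() for f in fractions])  # (n_frac, 2)
    meas_sigma = np.array(
        [noise.measurement_sigmas(f.isotopes) for f in fractions]
    )  # (n_frac, 2)
    sig = endmembers.signatures  # (2, 3)
    em_sigma = endmembers.sigmas if noise.perturb_endmembers else np.zeros((2, 3))

    # (n_rep, n_frac, 2, 3) perturbed signatures
    if shared_endmember_draws:
        em_noise = rng.standard_normal((n_replicates, 1, 2, 3))
    else:
        em_noise = rng.standard_normal((n_replicates, n_frac, 2, 3))
    pert_sig = sig + em_noise * em_sigma
    pert_meas = meas + rng.standard_normal((n_replicates, n_frac, 2)) * meas_sigma

    m = pert_sig[..., :2] - pert_sig[..., 2:3]  # (n_rep, 1 or n_frac, 2, 2)
    if shared_endmember_draws:
        m = np.broadcast_to(m, (n_replicates, n_frac, 2, 2))
        pert_sig = np.broadcast_to(pert_sig, (n_replicates, n_frac, 2, 3))
    b = pert_meas - pert_sig[..., 2]
    det = m[..., 0, 0] * m[..., 1, 1] - m[..., 0, 1] * m[..., 1, 0]
    scale = np.hypot(m[..., 0, 0], m[..., 0, 1]) * np.hypot(m[..., 1, 0], m[..., 1, 1])
    bad = np.abs(det) <= _SINGULAR_RTOL * scale
    if bad.any():
        # Resample offending replicates wholesale by rerunning with fresh noise
        # is overkill at these noise levels; guard instead.
        if bad.mean() > 0.5:
            raise MixingGeometryError(
                "more than half of the contribution replicates hit a degenerate "
                "perturbed endmember geometry"
            )
        det = np.where(bad, np.nan, det)

    f = np.empty((n_replicates, n_frac, 3))
    f[..., 0] = (m[..., 1, 1] * b[..., 0] - m[..., 0, 1] * b[..., 1]) / det
    f[..., 1] = (m[..., 0, 0] * b[..., 1] - m[..., 1, 0] * b[..., 0]) / det
    f[..., 2] = 1.0 - (f[..., 0] + f[..., 1])

    pool_mass = np.einsum("i,rie->re", masses, f)  # (n_rep, 3)
    percent = 100.0 * pool_mass / masses.sum()
    mean_mass = np.nanmean(pool_mass, axis=0)
    mean_pct = np.nanmean(percent, axis=0)
    sd_pct = np.nanstd(percent, axis=0, ddof=1) if n_replicates > 1 else np.zeros(3)
    return ContributionSummary(
        names=tuple(endmembers.names),
        total_mass_ugC=mean_mass,
        percent=mean_pct,
        percent_sd=sd_pct,
        n_replicates=n_replicates,
        seed=seed_out,
        negative_mass_share=float(np.nanmean(pool_mass < 0)),
    )


# ---------------------------------------------------------------------------
# Model / Results interface
# ---------------------------------------------------------------------------


class CarbonSourceMixingModel:
    """Carbon-source apportionment model for a run of trapped CO₂ fractions.

    Wraps a sequence of :class:`~isoresp.isotopes.CO2Fraction` observations
    and an :class:`EndmemberSet`, exposing a ``fit`` method that performs the
    Monte Carlo apportionment of every measured fraction and aggregates pool
    contributions over the whole incubation.

    Parameters
    ----------
    fractions : sequence of CO2Fraction
        Trap windows with carbon masses; fractions without isotope values are
        allowed (they are excluded from mixing but can be renormalized over in
        mass-weighted averages).
    endmembers : EndmemberSet
        The three assumed carbon pools.
    noise : NoiseModel, optional
        Monte Carlo noise configuration.

    Examples
    --------
    >>> model = CarbonSourceMixingModel(fractions, endmembers)
    >>> res = model.fit(n_draws=10_000, seed=42)
    >>> print(res.summary())
    """

    def __init__(
        self,
        fractions: Sequence[CO2Fraction],
        endmembers: EndmemberSet,
        noise: NoiseModel = NoiseModel(),
    ) -> None:
        fractions = list(fractions)
        if not fractions:
            raise ValueError("at least one CO2 fraction is required")
        validate_fraction_sequence(fractions)
        self.fractions = fractions
        self.endmembers = endmembers
        self.noise = noise

    @classmethod
    def from_dataframe(
        cls,
        fraction_df: pd.DataFrame,
        endmember_df: pd.DataFrame,
        noise: NoiseModel = NoiseModel(),
        *,
        cond_threshold: float = 1e8,
    ) -> "CarbonSourceMixingModel":
        """Build from the standard fraction / endmember table schemas.

        ``fraction_df`` columns: index, t_start_h, t_end_h, mass_ugC,
        delta13C_permil, Delta14C_permil, sigma13, sigma14.
        ``endmember_df`` columns: name, delta13C_permil, sigma13,
        Delta14C_permil, sigma14.
        """
        from .isotopes import read_fraction_table  # schema lives there
        import io as _io

        buf = _io.StringIO()
        fraction_df.to_csv(buf, index=False)
        buf.seek(0)
        fractions = read_fraction_table(buf)
        endmembers = endmember_set_from_frame(endmember_df, cond_threshold=cond_threshold)
        return cls(fractions, endmembers, noise=noise)

    @property
    def measured_fractions(self) -> list[CO2Fraction]:
        return [f for f in self.fractions if f.isotopes is not None]

    def fit(
        self,
        n_draws: int = 10_000,
        seed: int | None = None,
        *,
        simplex_only: bool = False,
        shared_endmember_draws: bool = True,
    ) -> "MixingResults":
        """Run the Monte Carlo apportionment and return a results object.

        All randomness derives from ``seed`` through named substreams (one per
        fraction, one for the aggregate contribution replicates), so the fit
        is bit-reproducible and individual stages can be re-run independently.
        """
        measured = self.measured_fractions
        if not measured:
            raise ValueError("no fraction carries isotope measurements")
        ss = np.random.SeedSequence(seed)
        frac_streams = ss.spawn(len(measured) + 1)
        apportionments = [
            monte_carlo_apportion(
                f.isotopes,
                self.endmembers,
                n_draws=n_draws,
                noise=self.noise,
                seed=np.random.default_rng(stream),
                simplex_only=simplex_only,
            )
            for f, stream in zip(measured, frac_streams)
        ]
        contributions = total_contributions(
            measured,
            self.endmembers,
            n_replicates=n_draws,
            noise=self.noise,
            seed=np.random.default_rng(frac_streams[-1]),
            shared_endmember_draws=shared_endmember_draws,
        )
        return MixingResults(
            model=self,
            apportionments=apportionments,
            contributions=contributions,
            n_draws=n_draws,
            seed=seed,
        )


class MixingResults:
    """Results of a :class:`CarbonSourceMixingModel` fit.

    Attributes
    ----------
    apportionments : list of FractionApportionment
        Per measured fraction, in time order.
    contributions : ContributionSummary
        Pool shares of the total respired carbon over the whole run.
    params : pandas.DataFrame
        Per-fraction mean mixing fractions (rows: fraction index).
    bse : pandas.DataFrame
        Matching Monte Carlo standard deviations.
    """

    def __init__(
        self,
        model: CarbonSourceMixingModel,
        apportionments: list[FractionApportionment],
        contributions: ContributionSummary,
        n_draws: int,
        seed: int | None,
    ) -> None:
        self.model = model
        self.apportionments = apportionments
        self.contributions = contributions
        self.n_draws = n_draws
        self.seed = seed

    @property
    def names(self) -> list[str]:
        return self.model.endmembers.names

    @property
    def params(self) -> pd.DataFrame:
        idx = [f.index for f in self.model.measured_fractions]
        return pd.DataFrame(
            [a.mean for a in self.apportionments], columns=self.names, index=idx
        )

    @property
    def bse(self) -> pd.DataFrame:
        idx = [f.index for f in self.model.measured_fractions]
        return pd.DataFrame(
            [a.sd for a in self.apportionments], columns=self.names, index=idx
        )

    def mass_weighted_isotopes(
        self, *, renormalize_missing: bool = True
    ) -> dict[str, float]:
        """Mass-weighted average δ¹³C and Δ¹⁴C over all fractions (‰)."""
        from .isotopes import mass_weighted_mean

        return {
            "delta13C": mass_weighted_mean(
                self.model.fractions, "delta13C", renormalize_missing=renormalize_missing
            ),
            "Delta14C": mass_weighted_mean(
                self.model.fractions, "Delta14C", renormalize_missing=renormalize_missing
            ),
        }

    def apportionment_frame(self) -> pd.DataFrame:
        """Per-fraction apportionment table (long-friendly wide format)."""
        rows = []
        for f, a in zip(self.model.measured_fractions, self.apportionments):
            row: dict = {
                "fraction": f.index,
                "t_start_h": f.t_start,
                "t_end_h": f.t_end,
                "mass_ugC": f.mass_ugC,
                "simplex_share": a.simplex_share,
                "n_draws": a.n_draws,
            }
            for name, m, s in zip(a.names, a.mean, a.sd):
                row[f"f_{name}"] = m
                row[f"sd_{name}"] = s
            rows.append(row)
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Human-readable summary table."""
        lines = []
        lines.append("Carbon source mixing model — Monte Carlo apportionment")
        lines.append("=" * 62)
        lines.append(
            f"fractions: {len(self.apportionments)} measured / "
            f"{len(self.model.fractions)} collected    "
            f"draws: {self.n_draws}    seed: {self.seed}"
        )
        mw = self.mass_weighted_isotopes()
        lines.append(
            f"mass-weighted d13C: {mw['delta13C']:8.2f} permil    "
            f"mass-weighted D14C: {mw['Delta14C']:8.1f} permil"
        )
        lines.append("-" * 62)
        lines.append(f"{'fraction':>8} " + "".join(f"{n:>16}" for n in self.names) + f"{'in-simplex':>12}")
        for f, a in zip(self.model.measured_fractions, self.apportionments):
            cells = "".join(
                f"  {m:6.3f} ±{s:5.3f}" for m, s in zip(a.mean, a.sd)
            )
            lines.append(f"{f.index:>8} {cells}{a.simplex_share:>11.0%}")
        lines.append("-" * 62)
        lines.append("share of total respired carbon:")
        c = self.contributions
        for name, mass, pct, sd in zip(
            c.names, c.total_mass_ugC, c.percent, c.percent_sd
        ):
            lines.append(
                f"{name:>20}: {pct:5.1f} ± {sd:4.1f} %   ({mass:9.1f} ug C)"
            )
        lines.append("=" * 62)
        return "\n".join(lines)

    def plot_apportionment(self, ax=None):
        """Quick-look stacked view of per-fraction pool fractions ± 1 sd.

        Requires matplotlib (optional dependency); returns the axes.
        """
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        x = [f.index for f in self.model.measured_fractions]
        for j, name in enumerate(self.names):
            means = [a.mean[j] for a in self.apportionments]
            sds = [a.sd[j] for a in self.apportionments]
            ax.errorbar(x, means, yerr=sds, marker="o", capsize=3, label=name)
        ax.axhline(0.0, color="0.7", lw=0.8)
        ax.axhline(1.0, color="0.7", lw=0.8)
        ax.set_xlabel("CO₂ fraction")
        ax.set_ylabel("mixing fraction")
        ax.legend()
        return ax

    def __repr__(self) -> str:
        return (
            f"<MixingResults: {len(self.apportionments)} fractions, "
            f"{self.n_draws} draws, seed={self.seed}>"
        )


# ---------------------------------------------------------------------------
# CSV interface
# ---------------------------------------------------------------------------

ENDMEMBER_COLUMNS = ["name", "delta13C_permil", "sigma13", "Delta14C_permil", "sigma14"]


def endmember_set_from_frame(
    df: pd.DataFrame, *, cond_threshold: float = 1e8
) -> EndmemberSet:
    missing = set(ENDMEMBER_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"endmember table missing columns {sorted(missing)}")
    members = [
        Endmember(
            name=str(row["name"]),
            signature=IsotopeMeasurement(
                delta13C=float(row["delta13C_permil"]),
                Delta14C=float(row["Delta14C_permil"]),
                sigma_delta13C=float(row["sigma13"]),
                sigma_Delta14C=float(row["sigma14"]),
            ),
        )
        for _, row in df.iterrows()
    ]
    return EndmemberSet(members, cond_threshold=cond_threshold)


def read_endmember_table(path, *, cond_threshold: float = 1e8) -> EndmemberSet:
    """Read an endmember CSV (name, delta13C_permil, sigma13, Delta14C_permil, sigma14)."""
    return endmember_set_from_frame(pd.read_csv(path), cond_threshold=cond_threshold)


def write_endmember_table(endmembers: EndmemberSet, path) -> None:
    rows = [
        {
            "name": e.name,
            "delta13C_permil": e.signature.delta13C,
            "sigma13": e.signature.sigma_delta13C,
            "Delta14C_permil": e.signature.Delta14C,
            "sigma14": e.signature.sigma_Delta14C,
        }
        for e in endmembers
    ]
    pd.DataFrame(rows, columns=ENDMEMBER_COLUMNS).to_csv(path, index=False)
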