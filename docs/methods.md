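# Methods

This note documents the models, conventions, numerical choices and known
limitations behind `isoresp`, in the order data flows through the package.

## Isotope conventions (`isoresp.isotopes`)

Stable carbon isotope values are per-mil deviations from VPDB and are treated
as mixing linearly across carbon sources — exact for ¹³C/¹²C *ratios* and an
excellent approximation in delta notation at natural abundances. Radiocarbon
is handled in Δ¹⁴C notation: the per-mil deviation of the δ¹³C-normalized
¹⁴C content from the 1950 atmospheric reference,

    Δ¹⁴C = (fm · e^{λ(1950 − y_c)} − 1) · 1000,

where `fm` is the fraction modern reported by an AMS facility, `y_c` the
collection year, and λ the Libby-scale decay constant 1/8267 yr⁻¹. The
constant is configurable (`RadiocarbonConstants`) because the convention,
not the numeral, is standardized; −1000‰ (fm = 0) is radiocarbon-dead
carbon and a hard lower bound enforced throughout. δ¹³C normalization of raw
machine ratios is out of scope: inputs are assumed already normalized.

**Blank correction** removes a constant-mass procedural contamination by
two-component unmixing, `x_corr = (m_tot·x_tot − m_bl·x_bl)/(m_tot − m_bl)`,
with first-order error propagation treating masses as exact. The blank's
mass and signature are config inputs with placeholder defaults (blank mass
0 → no-op) because blank characterization is laboratory-specific. If the
correction would push Δ¹⁴C below −1000‰ the inputs are inconsistent; the
package warns (`OverCorrectionWarning`) and clamps to the bound rather than
emitting an unphysical value.

**Mass-weighted averages** over trap fractions use weights mᵢ/Σm. Fractions
collected but never measured (sample loss) either abort the average or, with
`renormalize_missing`, are dropped with weights renormalized over the
measured remainder. The flag is explicit rather than silent because the
treatment of a lost fraction is an analysis decision, not a default.

## The mixing model (`isoresp.mixing`)

Each measured CO₂ fraction is assumed to be a conservative mixture of three
endmember pools with fixed isotopic signatures; two tracers plus the closure
constraint Σf = 1 give a determined 3×3 linear system, so the fractions are
*solved*, not estimated. Numerically the closure row is eliminated first
(substituting f₃ = 1 − f₁ − f₂ into a 2×2 system) so every solution —
including every Monte Carlo draw — sums to exactly 1 in floating point.
Solutions are returned unclipped: a measurement outside the endmember
triangle legitimately produces components outside [0, 1], and `in_simplex` /
`simplex_share` make that visible. Endmember sets whose triangle is
degenerate (condition number of the mixing matrix above 10⁸ by default) are
rejected at construction with the offending names.

**Uncertainty propagation** is Monte Carlo: per draw, normal noise is added
to the measurement (1σ defaults δ¹³C 2‰, Δ¹⁴C 50‰, interpreted as standard
deviations; per-measurement reported σ can override via
`NoiseModel(use_measured_sigmas=True)`) and independently to every endmember
signature (its own 1σ); the system is re-solved and the draws summarized as
means and standard deviations. 10 000 draws is the default. Because the
measurement→fraction map is affine, the estimator is unbiased under
symmetric noise (verified empirically in the tests). Out-of-simplex draws
are *retained* in the summary — clipping or discarding them biases the
means toward the triangle's interior; a `simplex_only` sensitivity mode
discards them for comparison. Draws whose perturbed triangle is numerically
singular (relative determinant below 10⁻¹⁰) are rejected and resampled, with
the count reported; more than 50% rejections aborts with a geometry error.

**Aggregate contributions** multiply each fraction's solved fractions by its
manometric carbon mass and sum per pool, reported as percent of total
trapped carbon, mean ± sd over replicates. Within a replicate the endmember
perturbation is *shared* across fractions (endmember signatures are a
systematic assumption common to the whole run) while measurement noise is
independent per fraction; `shared_endmember_draws=False` switches to fully
independent perturbations for comparing propagation schemes, since either
convention is defensible. Percents sum to 100 per replicate by construction;
individual pool masses can go negative in out-of-simplex replicates and are
flagged (`negative_mass_share`), never clipped.

The user-facing wrapper is `CarbonSourceMixingModel` → `fit()` →
`MixingResults` (per-fraction `params`/`bse`, aggregate `contributions`,
`summary()`), in the style of statsmodels. All randomness inside a fit flows
from one seed through spawned substreams (one per fraction, one for the
aggregate), so the fit is bit-reproducible and stages can be re-run
independently.

## Respirometry (`isoresp.respirometry`)

The chain from detector log to production rate applies, in order:

1. **Baseline correction** — a straight line anchored at the mean ppm of a
   pre-injection window and an end-of-run window (centers as abscissae).
   Linear is the least-structured drift model; anything more belongs in
   instrument-specific preprocessing. A heuristic warns when an anchor
   window's local slope is inconsistent with the cross-window drift slope
   (more than 3× the detrended within-window scatter over the window span),
   which catches windows accidentally placed on the respiration pulse
   without firing on honest linear drift.
2. **Unit bridge** — flux [µg C min⁻¹] = ppm·10⁻⁶ · Q · P/(RT) · 12.011·10⁶,
   ideal gas at the detector-side conditions (defaults 298.15 K,
   101.325 kPa, configurable).
3. **Manometric rescaling** — within each trap window the flux is scaled so
   its trapezoidal integral equals the manometric carbon yield of that trap,
   the far more precise measurement. When adjacent windows share a boundary
   sample, a naive per-window multiply leaves a one-trapezoid error at each
   seam; the scale factors are instead solved by backward substitution
   (boundary samples belong to the later window), which restores *every*
   window integral to machine precision.
4. **Headspace deconvolution** — the headspace is modelled as one
   well-mixed compartment of volume V_h flushed at flow Q: detector flux
   F = (Q/V_h)·X with dX/dt = S − (Q/V_h)·X, inverted as
   S = F + (V_h/Q)·dF/dt. The derivative is a Savitzky–Golay local
   polynomial (default 31 samples, order 2, at the 1-min cadence); wider
   windows trade noise suppression against smearing of fast transients.
   The per-liter rate divides S by the medium volume, a piecewise-constant
   non-increasing schedule (subsampling removes medium); the headspace
   volume defaults to vessel volume minus current medium volume. This
   single-compartment first-order model is the minimal description of
   headspace mixing; it is a reconstruction chosen for parsimony, not a
   claim about any particular instrument's internal correction, and it
   ignores dissolved-CO₂/carbonate-system equilibration (out of scope).

Negative post-correction rates are retained and flagged: clipping them would
break consistency between rate integrals and manometric masses. Window
integrals interpolate edge values so integration is exactly additive over
adjacent windows.

## Growth curves (`isoresp.growth`)

dPCR concentrations (genome copies per µL of reaction) are taken as
exported by the instrument — partition-level Poisson statistics are not
recomputed. Replicate DNA extractions at a time point are summarized as
mean and standard error sd/√n; a single replicate reports a missing (NaN)
standard error rather than zero. Dilution scaling multiplies by the
subsample's dilution factor and commutes with the summary. Conversion to
cells per mL of slurry requires extraction volumes that are
protocol-specific and is left to an optional user-supplied factor.

## The forward simulator (`isoresp.simulate`)

The simulator exists so every pipeline stage can be validated by parameter
recovery; its contract is statistical structure, not biological fidelity.
Kinetics are deliberately minimal: pool p is consumed at
`k_sp · M_p · B_s/B_s0` by species s (first-order in remaining pool mass,
scaled by relative biomass), a fixed `respired_fraction` of consumed carbon
becomes CO₂ and the rest grows biomass at a fixed yield, with a per-species
lag. The `respired_fraction` field (default 0.5, a typical heterotrophic
growth efficiency regime) exists because without an explicit
respiration/assimilation split the carbon budget cannot close; the
invariant respired + assimilated + residual = initial holds to floating
point because the bookkeeping accumulates the same Euler increments that
advance the state. Integration is fixed-step explicit Euler at 1-min
resolution — matching the detector cadence and trivially auditable — with
within-step consumption capped so pools cannot go negative.

The default configuration emulates a sediment-slurry coculture: three
isotopically distinct pools (phytoplankton-derived: −20‰/+50‰;
acetate/fermentation products: −38‰/−250‰; pre-aged OC: −27‰/−900‰ — all
synthetic placeholder signatures), two competing species (a labile-substrate
specialist and a slower, broader macromolecule degrader), a 3 L vessel with
2 L of medium under 100 mL min⁻¹ carrier flow, 12 trap windows of 6–24 h
sized so no fraction exceeds the 2 mg trap capacity, and dPCR subsampling
every 12 h with 2 replicates. The rate constants were chosen so the
respiration pulse peaks near 15 h and decays to ≪5% of peak within 5 days —
the single-peak shape such incubations exhibit. Observation noise is applied
last: δ¹³C σ = 2‰ and Δ¹⁴C σ = 50‰ on fraction isotopes, 0.5% relative
error on manometric masses, 0.3 ppm detector noise plus a linear baseline
drift (5 ppm + 0.002 ppm min⁻¹), and lognormal dPCR noise with 20% CV.

Simulated trap masses are defined as integrals of the *true source flux*
over each window; the carbon physically reaching a trap is the (delayed)
detector flux, but the two differ only by edge effects of order the
headspace flushing time (V_h/Q = 10 min), far below the 6–24 h window
lengths, and referencing masses to the source keeps trap masses, fraction
isotope mixtures and ground-truth pool fractions mutually consistent.
Windows that trap no carbon (e.g. zero uptake) produce no fraction objects
rather than zero-mass ones.

What the simulator does *not* emulate: enzyme kinetics, cross-feeding,
priming, temperature or pH effects, detector drift nonlinearity, or
correlated isotope errors. Passing recovery tests therefore demonstrates
that the *analysis chain* is correct and well-calibrated under its own
stated noise model — not that any particular biological inference from real
data is right.

## Synthetic study-shaped tables (`isoresp.datasets`)

`synthetic_study_fractions` provides two fixed fraction tables shaped like
real sediment-incubation runs — 12 fractions/5 days/~15.1 mg with δ¹³C
climbing −37→−24‰ and Δ¹⁴C falling −218→−321‰, and 8 fractions/91 h/~6.9 mg
with δ¹³C −31→−17‰, an early positive Δ¹⁴C excursion and a lost fourth
fraction. They exist so the full pipeline can be demonstrated and
benchmarked at realistic size without measured data; every value is
synthetic, as their docstrings state. Reproducing a published experiment's
apportionment requires its measured per-fraction and endmember tables in
the same CSV schemas.

## Problem sizes and determinism

Default problem sizes — 10 000 Monte Carlo draws per fraction, 1-min
detector sampling over 5 days (7201 samples), 50 incubations in the
recovery benchmark — were chosen as the scale at which the Monte Carlo
summaries are stable to well under their reported standard deviations; the
whole test suite and the acceptance script each run in tens of seconds on
one CPU. Every stochastic computation takes an explicit seed
(numpy `default_rng` / `SeedSequence` substreams) and records it in its
output; identical seeds give bit-identical results.

## Known limitations

- Exactly three endmembers and two tracers (the determined case). More
  sources or tracers require a different (over/under-determined) estimator,
  e.g. Bayesian mixing models, deliberately out of scope.
- No source-concentration dependence or concentration-weighted mixing;
  δ¹³C is mixed linearly in delta space.
- The headspace inversion assumes (near-)uniform sampling and a single
  well-mixed gas compartment.
- The baseline model is linear between two anchor windows; strong nonlinear
  drift must be handled upstream.
- dPCR inputs are instrument-exported concentrations; no partition-level
  error model.
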