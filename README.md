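# isoresp

Carbon-source apportionment for flow-through respirometry incubations.

When heterotrophic microbes remineralize natural organic matter, the CO₂ they
respire inherits the stable-carbon (δ¹³C, ‰ vs VPDB) and radiocarbon (Δ¹⁴C,
‰ vs the 1950 atmospheric reference) signatures of the carbon pools being
consumed. Experiments that sparge a sealed culture vessel with CO₂-free
carrier gas, log the effluent CO₂ concentration continuously, and trap the
respired CO₂ as successive fractions for manometric and isotopic analysis can
therefore resolve *which* carbon pools were respired, *when*, and *how fast*.
`isoresp` implements the full analysis chain for such experiments, for
microbial ecologists and isotope biogeochemists:

- **respirometry** — detector trace (ppm) → microbial CO₂ production rate
  (µg C L⁻¹ min⁻¹): linear baseline removal, ideal-gas unit bridge, rescaling
  of each trap window to its high-precision manometric carbon yield, and
  deconvolution of the well-mixed headspace compartment
  (S(t) = F(t) + (V_h/Q)·dF/dt, with a Savitzky–Golay derivative).
- **mixing** — the core model: each trapped CO₂ fraction's isotope pair is a
  linear mixture of three assumed endmember pools,

  ```
  δ¹³C_CO₂ = f₁·δ¹³C₁ + f₂·δ¹³C₂ + f₃·δ¹³C₃
  Δ¹⁴C_CO₂ = f₁·Δ¹⁴C₁ + f₂·Δ¹⁴C₂ + f₃·Δ¹⁴C₃
         1 = f₁ + f₂ + f₃
  ```

  a determined 3×3 linear system solved exactly per fraction, with
  uncertainties propagated by Monte Carlo resampling (default 10 000 draws;
  normal noise, 1σ defaults δ¹³C ± 2‰ and Δ¹⁴C ± 50‰ on measurements, each
  endmember's own 1σ on its signature). Pool shares of the total respired
  carbon are mass-weighted aggregates over all fractions.
- **isotopes** — Δ¹⁴C ↔ fraction-modern conversions (λ = 1/8267 yr⁻¹ decay
  correction to 1950), procedural blank correction by two-component
  unmixing, and mass-weighted isotope averages.
- **growth** — duplex dPCR genome-copy tables → per-species growth curves
  with replicate standard errors and dominance ratios.
- **simulate** — a forward simulator of a two-species, three-pool coculture
  incubation with ground truth retained at every level, so each stage is
  validated by parameter recovery rather than against opaque expectations.

## Worked example

Fit the mixing model to the bundled *synthetic* study-shaped fraction table
(8 trap fractions over 91 h, one lost before isotopic measurement, ~6.9 mg
respired carbon; all numbers invented for demonstration):

```python
from isoresp.datasets import synthetic_study_fractions, synthetic_endmembers
from isoresp.mixing import CarbonSourceMixingModel

fractions = [f for f in synthetic_study_fractions("unimpacted")
             if f.isotopes is not None]
model = CarbonSourceMixingModel(fractions, synthetic_endmembers())
res = model.fit(n_draws=10_000, seed=1)
print(res.summary())
```

```
Carbon source mixing model — Monte Carlo apportionment
==============================================================
fractions: 7 measured / 7 collected    draws: 10000    seed: 1
mass-weighted d13C:   -25.36 permil    mass-weighted D14C:   -103.1 permil
--------------------------------------------------------------
fraction    phytoplankton    acetate_ferm        pre_aged  in-simplex
       1    0.406 ±0.104   0.625 ±0.140  -0.031 ±0.088        37%
       2    0.503 ±0.104   0.501 ±0.139  -0.004 ±0.087        49%
       3    0.593 ±0.104   0.375 ±0.140   0.032 ±0.087        64%
       5    0.718 ±0.105   0.184 ±0.141   0.098 ±0.088        77%
       6    0.801 ±0.107   0.052 ±0.142   0.148 ±0.090        60%
       7    0.926 ±0.111  -0.145 ±0.146   0.219 ±0.096        15%
       8    1.006 ±0.114  -0.275 ±0.150   0.269 ±0.100         3%
--------------------------------------------------------------
share of total respired carbon:
       phytoplankton:  65.6 ±  5.6 %   (   4332.6 ug C)
        acetate_ferm:  26.7 ±  7.2 %   (   1763.5 ug C)
            pre_aged:   7.6 ±  5.5 %   (    503.9 ug C)
==============================================================
```

Reading the table: each row is one trapped CO₂ fraction; `f_pool ± sd` are
the Monte Carlo mean and standard deviation of that pool's mixing fraction
(unclipped — values outside [0, 1] indicate the measurement sits outside the
endmember triangle for part of the noise cloud, and `in-simplex` reports how
often a draw was physically admissible). The early fractions are dominated by
labile acetate/fermentation products; phytoplankton-derived carbon takes over
as the incubation proceeds. The bottom block mass-weights those per-fraction
solutions into each pool's share of *all* respired carbon — here
phytoplankton-derived material accounts for 65.6 ± 5.6 % of the 6.6 mg of
measured respired CO₂. The per-fraction means in each row sum to exactly 1
(the closure equation is solved, not fitted).

The same object exposes `res.params` / `res.bse` (per-fraction DataFrames),
`res.contributions.to_frame()`, and `res.mass_weighted_isotopes()`.

## Command line

```bash
isoresp simulate --seed 2 --out sim/          # forward model → CSV bundle
isoresp all --config examples/run_config.yaml --out results/
```

Subcommands `rates`, `apportion`, `summarize`, `growth` run individual
stages; every output directory gets a `manifest.json` with the seed and a
hash of the resolved configuration. The endmember CSV in `examples/` holds
clearly-labelled synthetic placeholders — substitute your experiment's
assumed endmember signatures before interpreting results.

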