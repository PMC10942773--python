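"""End-to-end orchestration: config, logging, and the derived-table pipeline.

One structured YAML config drives the whole analysis (rate reconstruction,
per-fraction apportionment, mass-weighted isotope averages, total pool
contributions, growth curves).  All randomness flows from a single seed via
named substreams, and every output directory carries a machine-readable run
manifest with the seed and a hash of the resolved configuration, so any
stage can be reproduced independently.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .growth import growth_series, read_dpcr_csv
from .isotopes import (
    IsotopeMeasurement,
    blank_correct,
    mass_weighted_mean,
    read_fraction_table,
)
from .mixing import CarbonSourceMixingModel, NoiseModel, read_endmember_table
from .respirometry import (
    VesselGeometry,
    baseline_correct,
    deconvolve_headspace,
    ppm_to_carbon_flux,
    read_detector_csv,
    read_trap_csv,
    rescale_to_manometric,
)

logger = logging.getLogger("isoresp")

__all__ = ["RunConfig", "run_pipeline", "load_config"]


@dataclass
class RunConfig:
    """Resolved pipeline configuration.

    Paths may be None when the corresponding stage is skipped (e.g. no dPCR
    table → no growth curve output).  Physical constants and flags mirror the
    module-level defaults; see docs/methods.md for units and rationale.
    """

    # input tables
    detector_csv: str | None = None
    trap_csv: str | None = None
    fraction_csv: str | None = None
    endmember_csv: str | None = None
    dpcr_csv: str | None = None
    # vessel geometry / detector conditions
    vessel_volume_L: float = 3.0
    medium_volume_schedule: list = field(default_factory=lambda: [[0.0, 2.0]])
    flow_ml_min: float = 100.0
    temperature_K: float = 298.15
    pressure_kPa: float = 101.325
    headspace_volume_L: float | None = None
    # baseline windows (minutes)
    baseline_pre_window: list = field(default_factory=lambda: [0.0, 30.0])
    baseline_post_window: list | None = None  # default: last 60 min
    derivative_window_samples: int = 31
    # system blank (no-op at zero mass; values are placeholders to be filled
    # from the lab's own blank characterization)
    blank_mass_ugC: float = 0.0
    blank_delta13C: float = -25.0
    blank_Delta14C: float = -1000.0
    blank_sigma13: float = 0.0
    blank_sigma14: float = 0.0
    # Monte Carlo settings
    n_draws: int = 10_000
    seed: int | None = 0
    sigma_delta13C: float = 2.0
    sigma_Delta14C: float = 50.0
    use_measured_sigmas: bool = False
    perturb_endmembers: bool = True
    # behaviour flags
    renormalize_missing: bool = False
    simplex_only: bool = False
    shared_endmember_draws: bool = True

    def __post_init__(self) -> None:
        if self.n_draws < 1:
            raise ValueError("n_draws must be at least 1")

    def geometry(self) -> VesselGeometry:
        return VesselGeometry(
            vessel_volume=self.vessel_volume_L,
            medium_volume_schedule=tuple(
                (float(t), float(v)) for t, v in self.medium_volume_schedule
            ),
            flow=self.flow_ml_min,
            headspace_volume=self.headspace_volume_L,
        )

    def noise(self) -> NoiseModel:
        return NoiseModel(
            sigma_delta13C=self.sigma_delta13C,
            sigma_Delta14C=self.sigma_Delta14C,
            perturb_endmembers=self.perturb_endmembers,
            use_measured_sigmas=self.use_measured_sigmas,
        )

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path) -> RunConfig:
    """Load a YAML config file into a validated :class:`RunConfig`."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    return RunConfig(**raw)


def compute_rates(config: RunConfig):
    """Detector log → per-liter production rate + per-window QC table."""
    if config.detector_csv is None:
        raise ValueError("config.detector_csv is required for the rates stage")
    series = read_detector_csv(
        config.detector_csv,
        flow=config.flow_ml_min,
        temperature=config.temperature_K,
        pressure=config.pressure_kPa,
    )
    post = config.baseline_post_window or [series.time[-1] - 60.0, series.time[-1]]
    corrected = baseline_correct(
        series, tuple(config.baseline_pre_window), tuple(post)
    )
    flux = ppm_to_carbon_flux(corrected)
    qc = None
    if config.trap_csv is not None:
        traps = read_trap_csv(config.trap_csv)
        flux, qc = rescale_to_manometric(flux, traps)
    rate = deconvolve_headspace(
        flux, config.geometry(), smooth_window=config.derivative_window_samples
    )
    return rate, qc


def run_pipeline(config: RunConfig, outdir) -> dict[str, Path]:
    """Run every stage the config provides inputs for; write the result bundle.

    Outputs (CSV unless noted): ``rate.csv`` (time_min, rate), ``trap_qc.csv``
    (scale factors, integrals), ``apportionment.csv`` (per-fraction mixing
    means/sds), ``summary.csv`` (per-endmember total mass and percent),
    ``mass_weighted.csv`` (mass-weighted average isotope values),
    ``growth.csv`` (per-species growth curves), and ``manifest.json`` (seed,
    config hash, package version, stages run).

    Deterministic: the same config and seed produce byte-identical outputs.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    stages: list[str] = []

    if config.detector_csv is not None:
        logger.info("rates: reconstructing production rate from %s", config.detector_csv)
        rate, qc = compute_rates(config)
        rate_df = pd.DataFrame({"time_min": rate.time, "rate_ugC_L_min": rate.rate})
        written["rate"] = outdir / "rate.csv"
        rate_df.to_csv(written["rate"], index=False)
        if qc is not None:
            written["trap_qc"] = outdir / "trap_qc.csv"
            qc.to_csv(written["trap_qc"], index=False)
        stages.append("rates")

    if config.fraction_csv is not None and config.endmember_csv is not None:
        logger.info("apportion: mixing model on %s", config.fraction_csv)
        fractions = read_fraction_table(config.fraction_csv)
        endmembers = read_endmember_table(config.endmember_csv)
        if config.blank_mass_ugC > 0:
            blank = IsotopeMeasurement(
                delta13C=config.blank_delta13C,
                Delta14C=config.blank_Delta14C,
                sigma_delta13C=config.blank_sigma13,
                sigma_Delta14C=config.blank_sigma14,
            )
            fractions = [
                dataclasses.replace(
                    f,
                    isotopes=blank_correct(
                        f.mass_ugC, f.isotopes, config.blank_mass_ugC, blank
                    ),
                )
                if f.isotopes is not None
                else f
                for f in fractions
            ]
        missing = [f.index for f in fractions if f.isotopes is None]
        if missing and not config.renormalize_missing:
            raise ValueError(
                f"fractions {missing} lack isotope values; set "
                "renormalize_missing to drop them from mass-weighted averages"
            )
        model = CarbonSourceMixingModel(fractions, endmembers, noise=config.noise())
        res = model.fit(
            n_draws=config.n_draws,
            seed=config.seed,
            simplex_only=config.simplex_only,
            shared_endmember_draws=config.shared_endmember_draws,
        )
        app = res.apportionment_frame()
        app["seed"] = config.seed
        written["apportionment"] = outdir / "apportionment.csv"
        app.to_csv(written["apportionment"], index=False)
        summary = res.contributions.to_frame()
        summary["n_replicates"] = res.contributions.n_replicates
        summary["seed"] = config.seed
        written["summary"] = outdir / "summary.csv"
        summary.to_csv(written["summary"], index=False)
        mw = res.mass_weighted_isotopes(renormalize_missing=True)
        written["mass_weighted"] = outdir / "mass_weighted.csv"
        pd.DataFrame([mw]).to_csv(written["mass_weighted"], index=False)
        stages.append("apportion")

    if config.dpcr_csv is not None:
        logger.info("growth: reducing dPCR table %s", config.dpcr_csv)
        obs = read_dpcr_csv(config.dpcr_csv)
        written["growth"] = outdir / "growth.csv"
        growth_series(obs).to_csv(written["growth"], index=False)
        stages.append("growth")

    manifest = {
        "package": "isoresp",
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "stages": stages,
        "outputs": {k: str(v.name) for k, v in written.items()},
    }
    written["manifest"] = outdir / "manifest.json"
    with open(written["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return written


def write_synthetic_bundle(dataset, outdir) -> dict[str, Path]:
    """Write a simulated incubation as the standard CSV input bundle.

    Emits detector, trap, fraction, endmember and dPCR CSVs plus a
    ground-truth sidecar (true rate, true per-fraction pool fractions,
    carbon budget) so the pipeline can be run end-to-end against files.
    """
    from .isotopes import write_fraction_table
    from .mixing import write_endmember_table

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["detector"] = outdir / "detector.csv"
    pd.DataFrame(
        {"time_min": dataset.detector.time, "co2_ppm": dataset.detector.co2_ppm}
    ).to_csv(paths["detector"], index=False)

    paths["traps"] = outdir / "traps.csv"
    pd.DataFrame(
        [
            {
                "t_start_min": t.t_start,
                "t_end_min": t.t_end,
                "mass_ugC": t.manometric_mass_ugC,
            }
            for t in dataset.traps
        ]
    ).to_csv(paths["traps"], index=False)

    paths["fractions"] = outdir / "fractions.csv"
    write_fraction_table(dataset.fractions, paths["fractions"])

    paths["endmembers"] = outdir / "endmembers.csv"
    write_endmember_table(dataset.endmember_table(), paths["endmembers"])

    paths["dpcr"] = outdir / "dpcr.csv"
    pd.DataFrame(
        [
            {
                "time_h": o.time,
                "species": o.species,
                "replicate_id": i + 1,
                "copies_per_ul": v,
                "dilution_factor": o.dilution_factor,
            }
            for o in dataset.dpcr
            for i, v in enumerate(o.replicate_values)
        ]
    ).to_csv(paths["dpcr"], index=False)

    paths["ground_truth"] = outdir / "ground_truth.json"
    truth = {
        "seed": dataset.seed,
        "true_peak_time_min": dataset.true_rate.peak_time,
        "true_peak_rate_ugC_L_min": dataset.true_rate.peak_rate,
        "true_trap_masses_ugC": dataset.true_trap_masses.tolist(),
        "true_fraction_pool_fractions": dataset.true_fraction_pool_fractions.to_dict(
            orient="records"
        ),
        "carbon_budget": dataset.carbon_budget.to_dict(orient="records"),
    }
    with open(paths["ground_truth"], "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)

    paths["true_rate"] = outdir / "true_rate.csv"
    pd.DataFrame(
        {"time_min": dataset.true_rate.time, "rate_ugC_L_min": dataset.true_rate.rate}
    ).to_csv(paths["true_rate"], index=False)
    return paths
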