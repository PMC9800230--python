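"""End-to-end pipeline: generate or load claims, validate, classify,
aggregate, and write the report bundle.

A run is fully described by a :class:`PipelineConfig` (YAML-serialisable);
rerunning with the same config and seed produces a byte-identical bundle.
The bundle mirrors the study's result tables: one yearly-summary row per
study year, the dispensation mix, prescriber attribution, the per-patient
chronic-status and episode tables, and the coverage-threshold sensitivity
counts, plus a manifest echoing the config, seed, package versions and row
counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml
from pydantic import BaseModel, Field, model_validator

from . import __version__, claims_io, metrics
from .claims_io import ClaimsDataset, apply_exclusions, read_dataset
from .exposure import (classify_statuses, segment_all_episodes,
                       threshold_sensitivity)
from .synthetic_claims import GeneratorConfig, write_synthetic_dataset

__all__ = ["PipelineConfig", "ReportBundle", "render_tables", "run_pipeline"]

log = logging.getLogger("ppicohort")


class PipelineConfig(BaseModel):
    """Configuration of a full analysis run.

    Either ``input_dir`` points at an existing claims dataset, or the
    bundled generator runs with ``generator`` (and ``seed`` overriding its
    seed).  ``years`` are the January 1 anchors to classify, contiguous and
    ascending; thresholds are coverage fractions in (0, 1].
    """

    input_dir: Path | None = None
    generator: GeneratorConfig = Field(default_factory=GeneratorConfig)
    years: list[int] | None = None
    thresholds: list[float] = Field(default_factory=lambda: [0.75, 0.80, 0.85])
    primary_threshold: float = 0.80
    gap_days: int = Field(default=61, gt=0)
    rate_decimals: int = 1
    mix_decimals: int = 2
    output_dir: Path = Path("ppicohort_out")
    seed: int | None = None
    log_level: str = "INFO"

    @model_validator(mode="after")
    def _check(self):
        for t in [*self.thresholds, self.primary_threshold]:
            if not 0 < t <= 1:
                raise ValueError(f"threshold {t} outside (0, 1]")
        if self.years is not None:
            if sorted(self.years) != self.years or not self.years:
                raise ValueError("years must be non-empty and ascending")
            if any(b - a != 1 for a, b in zip(self.years, self.years[1:])):
                raise ValueError("years must be contiguous")
        return self

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.model_validate(yaml.safe_load(fh) or {})


@dataclass
class ReportBundle:
    """In-memory result of a pipeline run (the written CSVs, as frames)."""

    statuses: pd.DataFrame
    episodes: pd.DataFrame
    yearly_summary: pd.DataFrame
    mix: pd.DataFrame
    prescribers: pd.DataFrame
    sensitivity: pd.DataFrame
    manifest: dict


def _resolve_years(config: PipelineConfig, dataset: ClaimsDataset) -> list[int]:
    if config.years is not None:
        return config.years
    years = sorted(dataset.denominators["year"])
    # first anchor needs the full trailing quarter inside the data
    return years[1:] if len(years) > 1 else years


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Run generate/load -> validate -> exclude -> classify -> aggregate
    -> report and write the bundle under ``config.output_dir``."""
    logging.basicConfig(level=config.log_level)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.input_dir is not None:
        log.info("stage load: reading dataset from %s", config.input_dir)
        dataset, n_out_of_region = read_dataset(config.input_dir)
    else:
        gen = config.generator
        if config.seed is not None:
            gen = gen.model_copy(update={"seed": config.seed})
        log.info("stage simulate: generating %d patients (seed %d)",
                 gen.n_patients, gen.seed)
        dataset, _ = write_synthetic_dataset(gen, out / "synthetic_input")
        n_out_of_region = 0

    years = _resolve_years(config, dataset)
    log.info("stage exclude: anchor year %d", years[0])
    patients, dispensings, excl = apply_exclusions(
        dataset.patients, dataset.dispensings, years[0])
    log.info("exclusions: %s (out-of-region dropped at read: %d)",
             excl.as_dict(), n_out_of_region)
    dataset = ClaimsDataset(patients, dispensings, dataset.drug_reference,
                            dataset.denominators)

    log.info("stage classify: years %s, threshold %.2f",
             years, config.primary_threshold)
    statuses = classify_statuses(dispensings, patients, years,
                                 threshold=config.primary_threshold)
    episodes = segment_all_episodes(dispensings, gap_days=config.gap_days)

    log.info("stage metrics: %d chronic patient-years", len(statuses))
    summaries = [metrics.build_yearly_summary(
        dataset, y, statuses, config.rate_decimals, config.mix_decimals)
        for y in years]
    yearly = pd.DataFrame([s.as_row() for s in summaries])

    mix_rows = []
    for s in summaries:
        for product, pct in s.drug_mix.items():
            mix_rows.append({"year": s.year, "product": product, "pct": pct})
    mix = pd.DataFrame(mix_rows, columns=["year", "product", "pct"])
    prescribers = metrics.prescriber_attribution(dataset, config.rate_decimals)

    sens_rows = []
    for year in years:
        counts = threshold_sensitivity(dispensings, patients, year,
                                       config.thresholds)
        for t in config.thresholds:
            sens_rows.append({"year": year, "threshold": t,
                              "chronic_count": counts[t]})
    sensitivity = pd.DataFrame(sens_rows,
                               columns=["year", "threshold", "chronic_count"])

    manifest = {
        "config": yaml.safe_load(config.model_dump_json()),
        "package_version": __version__,
        "years": years,
        "row_counts": {
            "patients": len(patients),
            "dispensings": len(dispensings),
            "chronic_patient_years": int(len(statuses)),
            "episodes": int(len(episodes)),
        },
        "exclusions": {**excl.as_dict(), "out_of_region": n_out_of_region},
    }

    _write_bundle(out, statuses, episodes, yearly, mix, prescribers,
                  sensitivity, manifest)
    log.info("stage report: bundle written to %s", out)
    return ReportBundle(statuses, episodes, yearly, mix, prescribers,
                        sensitivity, manifest)


def _write_bundle(out: Path, statuses, episodes, yearly, mix, prescribers,
                  sensitivity, manifest) -> None:
    statuses.to_csv(out / "chronic_status.csv", index=False)
    eps = episodes.copy()
    if not eps.empty:
        eps["start_date"] = eps["start_date"].map(lambda d: d.isoformat())
        eps["end_date"] = eps["end_date"].map(lambda d: d.isoformat())
    eps.to_csv(out / "episodes.csv", index=False)
    yearly.to_csv(out / "yearly_summary.csv", index=False)
    mix.to_csv(out / "mix.csv", index=False)
    prescribers.to_csv(out / "prescribers.csv", index=False)
    sensitivity.to_csv(out / "sensitivity.csv", index=False)
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)


def render_tables(yearly: pd.DataFrame) -> str:
    """Plain-text analogs of the study's four result tables.

    Discontinuation counts carry the death tally in the published
    "count (deaths +)" footnote style.
    """
    if yearly.empty:
        raise ValueError("no yearly summaries to render")
    years = [int(y) for y in yearly["year"]]
    lines = []

    def table(title: str, rows: list[tuple[str, list]]) -> None:
        lines.append(title)
        header = "".join(f"{y:>14}" for y in years)
        lines.append(f"{'':34}{header}")
        for label, values in rows:
            cells = "".join(f"{v:>14}" for v in values)
            lines.append(f"{label:<34}{cells}")
        lines.append("")

    table("Incident chronic consumer population", [
        ("Incident count", [f"{v:,}" for v in yearly["incident_count"]]),
        ("Age mean; sd", [f"{m}; {s}" for m, s in
                          zip(yearly["incident_age_mean"], yearly["incident_age_sd"])]),
        ("Male n (%)", [f"{n:,} ({p}%)" for n, p in
                        zip(yearly["incident_male_count"], yearly["incident_male_pct"])]),
        ("General population", [f"{v:,}" for v in yearly["general_population"]]),
        ("Incidence rate", [f"{v}%" for v in yearly["incidence_rate_pct"]]),
    ])
    table("Prevalent chronic patient population", [
        ("Prevalent count", [f"{v:,}" for v in yearly["prevalent_count"]]),
        ("Age mean; sd", [f"{m}; {s}" for m, s in
                          zip(yearly["prevalent_age_mean"], yearly["prevalent_age_sd"])]),
        ("Male n (%)", [f"{n:,} ({p}%)" for n, p in
                        zip(yearly["prevalent_male_count"], yearly["prevalent_male_pct"])]),
        ("General population", [f"{v:,}" for v in yearly["general_population"]]),
        ("Prevalence rate", [f"{v}%" for v in yearly["prevalence_rate_pct"]]),
    ])
    table("Evolution of chronic PPI consumption", [
        ("Chronic patients Jan 1", [f"{v:,}" for v in yearly["prevalent_count"]]),
        ("No refill Nov 1 - Dec 31", [
            f"{c:,} ({d} +)" for c, d in
            zip(yearly["discontinuation_count"], yearly["deaths_before_cutoff"])]),
        ("Discontinuation", [f"{v}%" for v in yearly["discontinuation_pct"]]),
    ])
    table("DDD accounting", [
        ("Median DDD per patient", [f"{v:.0f}" for v in
                                    yearly["median_ddd_per_patient"]]),
    ])
    return "\n".join(lines)
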