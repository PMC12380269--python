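"""End-to-end orchestration: registry → matching → balance → outcomes.

A run is fully described by a :class:`RunConfig` (loadable from YAML) and a
single RNG seed; the seed fans out deterministically to per-stage child
seeds, so two runs with identical config and seed produce byte-identical
output files.  Every output is a plain CSV/JSON file; the run manifest
records versions, the seed, per-stage counts and a SHA-256 checksum of each
output.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .balance import balance_grid, balance_table
from .covariates import default_matching_spec
from .exceptions import ConfigurationError
from .matching import CentroidMatcher, MatchedCohort
from .propensity import PropensityMatcher
from .registry import (
    COHORT_CONTROL,
    COHORT_TREATED,
    read_registry,
    treatment_indicator,
    write_registry,
)
from .survival import (
    FIVE_YEARS_MONTHS,
    cox_fit,
    etiology_table,
    graft_survival_km,
    logrank,
    patient_survival_km,
    stratified_survival_table,
)
from .synthetic import GeneratorConfig, default_config, generate_registry, prematch_config, save_registry

logger = logging.getLogger(__name__)

METHODS = (
    "cluster_manhattan",
    "cluster_cosine",
    "psm_with_replacement",
    "psm_without_replacement",
)

COX_COVARIATES = ("age", "bmi", "cold_ischemia", "hla_mismatch", "ethnicity", "sex")


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    methods: tuple[str, ...] = ("cluster_manhattan",)
    k: int = 5
    min_size: int = 5
    synthetic: GeneratorConfig | None = None
    input_csv: str | None = None
    column_map: Mapping[str, str] | None = None
    run_balance: bool = True
    run_outcomes: bool = True
    out_dir: str = "graftmatch_run"
    rng_seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        if not self.methods:
            raise ConfigurationError("methods: at least one matching method is required")
        unknown = set(self.methods) - set(METHODS)
        if unknown:
            raise ConfigurationError(f"methods: unknown methods {sorted(unknown)}")
        if any(m.startswith("cluster") for m in self.methods) and self.k > self.min_size:
            raise ConfigurationError("k: must not exceed min_size for clustering methods")
        if (self.synthetic is None) == (self.input_csv is None):
            raise ConfigurationError(
                "input: exactly one of a synthetic config or an input CSV is required"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: Mapping) -> "RunConfig":
        raw = dict(raw)
        syn = raw.pop("synthetic", None)
        if syn is not None:
            syn = dict(syn)
            preset = syn.pop("preset", None)
            if preset is not None:
                maker = {"default": default_config, "prematch": prematch_config}.get(preset)
                if maker is None:
                    raise ConfigurationError(f"synthetic.preset: unknown preset {preset!r}")
                syn = maker(**syn)
            else:
                syn = GeneratorConfig.from_dict(syn)
        if "methods" in raw:
            raw["methods"] = tuple(raw["methods"])
        return cls(synthetic=syn, **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.synthetic is not None:
            d["synthetic"] = self.synthetic.to_dict()
        return d


def _child_seed(root: int, label: str) -> int:
    """Deterministic per-stage child seed below 2^31."""
    h = hashlib.sha256(f"{root}:{label}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _fit_method(method: str, records: pd.DataFrame, config: RunConfig) -> MatchedCohort:
    X = records
    y = treatment_indicator(records)
    if method.startswith("cluster_"):
        est = CentroidMatcher(metric=method.removeprefix("cluster_"), k=config.k, min_size=config.min_size)
    else:
        est = PropensityMatcher(
            k=config.k,
            with_replacement=(method == "psm_with_replacement"),
            random_state=_child_seed(config.rng_seed, method),
        )
    return est.fit(X, y).matched_cohort_


def _matched_records(records: pd.DataFrame, cohort: MatchedCohort) -> pd.DataFrame:
    """Records of matched subjects, with multiplicity for reused controls."""
    return records.loc[cohort.subject_ids]


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=str) + "\n")


def run(config: RunConfig) -> dict:
    """Execute all configured stages; returns the run manifest.

    Any stage failure aborts the run with a stage-tagged error and removes
    the partial outputs already written.
    """
    config.validate()
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    stage = "setup"

    def emit(path: Path) -> Path:
        written.append(path)
        return path

    try:
        stage = "registry"
        if config.synthetic is not None:
            syn = dataclasses.replace(
                config.synthetic, rng_seed=_child_seed(config.rng_seed, "registry")
            )
            records = generate_registry(syn)
            save_registry(records, syn, emit(out / "registry.csv"))
            emit(out / "registry.csv.provenance.json")
        else:
            records = read_registry(config.input_csv, config.column_map)
        logger.info("registry: %d records", len(records))

        stage = "matching"
        cohorts: dict[str, MatchedCohort] = {}
        for method in config.methods:
            cohort = _fit_method(method, records, config)
            cohorts[method] = cohort
            cohort.write_csv(emit(out / f"matched_{method}.csv"))

        manifest: dict = {
            "graftmatch_version": __version__,
            "rng_seed": config.rng_seed,
            "config": config.to_dict(),
            "n_records": len(records),
            "methods": {m: c.manifest() for m, c in cohorts.items()},
        }

        if config.run_balance:
            stage = "balance"
            spec = default_matching_spec()
            bal_summary = {}
            for method, cohort in cohorts.items():
                before, after = balance_table(records, cohort, spec)
                pd.concat([before.table, after.table]).to_csv(
                    emit(out / f"balance_{method}.csv"), index=False
                )
                bal_summary[method] = {"before": before.summary(), "after": after.summary()}
            balance_grid(records, cohorts, spec).to_csv(emit(out / "balance_grid.csv"))
            manifest["balance"] = bal_summary

        if config.run_outcomes:
            stage = "outcomes"
            primary = cohorts[config.methods[0]]
            matched = _matched_records(records, primary)
            outcome_summary: dict = {"method": config.methods[0]}
            for label, cohort_name in (("treated", COHORT_TREATED), ("control", COHORT_CONTROL)):
                sub = matched[matched["cohort"] == cohort_name]
                graft_survival_km(sub).to_frame().to_csv(
                    emit(out / f"km_graft_{label}.csv"), index=False
                )
                patient_survival_km(sub).to_frame().to_csv(
                    emit(out / f"km_patient_{label}.csv"), index=False
                )
                outcome_summary[f"graft_survival_60m_{label}"] = graft_survival_km(sub).survival_at(
                    FIVE_YEARS_MONTHS
                )
                outcome_summary[f"patient_survival_60m_{label}"] = patient_survival_km(
                    sub
                ).survival_at(FIVE_YEARS_MONTHS)
            t = matched[matched["cohort"] == COHORT_TREATED]
            c = matched[matched["cohort"] == COHORT_CONTROL]
            _, outcome_summary["graft_logrank_p"] = logrank(
                t["followup_months"], t["graft_failure_event"],
                c["followup_months"], c["graft_failure_event"],
            )
            _, outcome_summary["patient_logrank_p"] = logrank(
                t["followup_months"], t["death_event"],
                c["followup_months"], c["death_event"],
            )
            stratified_survival_table(matched).to_csv(
                emit(out / "survival_by_stratum.csv"), index=False
            )
            etiology_table(matched).to_csv(emit(out / "etiology.csv"), index=False)
            try:
                cox = cox_fit(matched, COX_COVARIATES)
                cox.summary.to_csv(emit(out / "cox.csv"))
                outcome_summary["cox_converged"] = cox.converged
            except Exception as exc:
                logger.warning("cox fit skipped: %s", exc)
                outcome_summary["cox_converged"] = False
            _write_json(outcome_summary, emit(out / "outcomes_summary.json"))
            manifest["outcomes"] = outcome_summary

        stage = "manifest"
        manifest["checksums"] = {p.name: _sha256(p) for p in sorted(written)}
        _write_json(manifest, out / "manifest.json")
        return manifest
    except Exception as exc:
        for p in written:
            p.unlink(missing_ok=True)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
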