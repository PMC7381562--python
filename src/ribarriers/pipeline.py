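"""End-to-end orchestration: inputs -> per-barrier RI -> cascade reports.

``run_pipeline`` reads the four input datasets (suitability rasters +
occurrences, flowering survey, visitation table, hand-cross records), runs
each barrier module, assembles a barrier table per ecotype direction, and
combines strengths into total isolation with per-barrier contributions —
with and without the ecogeographic barrier ("sympatry", i.e. isolation at a
contact zone).  Stages whose inputs are missing are skipped and marked
unavailable rather than imputed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import crossing as crossing_mod
from . import ecogeography as eco
from . import phenology as phen
from . import pollinators as poll
from . import ri_core

logger = logging.getLogger("ribarriers")

__all__ = ["RunConfig", "ValidationReport", "run_pipeline", "validate_inputs"]


@dataclass
class RunConfig:
    """Paths, labels and options for a full pipeline run.

    Any input path may be None; the corresponding barriers are then reported
    as unavailable.
    """

    focal: str
    other: str
    output_dir: str
    suitability_focal: str | None = None
    suitability_other: str | None = None
    occurrences: str | None = None
    survey: str | None = None
    visitation: str | None = None
    crosses: str | None = None
    dispersal_radius_m: float = 500.0
    dispersal_structure: str = "square"
    aggregation_period: str = "month"
    baseline_gene_flow: float = 0.5
    n_background: int = 10_000
    seed: int = 0
    round_to: int | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


@dataclass
class ValidationReport:
    errors: list = field(default_factory=list)
    checked: list = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


def _check(report: ValidationReport, label: str, fn) -> None:
    try:
        fn()
        report.checked.append(label)
    except Exception as exc:  # collected, not raised: report everything at once
        report.errors.append(f"{label}: {exc}")


def validate_inputs(config: RunConfig) -> ValidationReport:
    """Schema- and sanity-check every configured input file."""
    report = ValidationReport()
    for name in ("suitability_focal", "suitability_other"):
        path = getattr(config, name)
        if path:
            _check(report, name, lambda p=path: eco.read_ascii_grid(p))
    if config.occurrences:
        _check(
            report,
            "occurrences",
            lambda: eco.OccurrenceSet(pd.read_csv(config.occurrences)),
        )
    if config.survey:
        _check(report, "survey", lambda: phen.read_survey(config.survey))
    if config.visitation:
        _check(report, "visitation", lambda: poll.read_visitation(config.visitation))
    if config.crosses:
        def _load_crosses():
            records = crossing_mod.read_crosses(config.crosses)
            crossing_mod.validate_records(records)
        _check(report, "crosses", _load_crosses)
    return report


def _ecogeography_stage(config: RunConfig, intermediates: dict) -> dict[str, float]:
    grids = {
        config.focal: eco.read_ascii_grid(config.suitability_focal),
        config.other: eco.read_ascii_grid(config.suitability_other),
    }
    occurrences = eco.OccurrenceSet(pd.read_csv(config.occurrences))
    rng = np.random.default_rng(config.seed)
    maps = {}
    for label, grid in grids.items():
        presence = grid.scores_at(occurrences.for_ecotype(label))
        finite = grid.values[np.isfinite(grid.values)].ravel()
        background = rng.choice(finite, size=config.n_background, replace=True)
        threshold = eco.etss_threshold(presence, background)
        maps[label] = eco.binarize(grid, threshold, label)
    classification = eco.classify_overlap(
        maps[config.focal], maps[config.other], config.dispersal_radius_m, config.dispersal_structure
    )
    values = {
        config.focal: eco.ri_ecogeographic(classification),
        config.other: eco.ri_ecogeographic(classification.swapped()),
    }
    intermediates["ecogeography"] = {
        "thresholds": {label: m.threshold for label, m in maps.items()},
        "pixel_counts": dataclasses.asdict(classification),
        "ri": values,
    }
    return values


def _phenology_stage(config: RunConfig, intermediates: dict) -> dict[str, float]:
    survey = phen.read_survey(config.survey)
    values = phen.ri_phenology(survey, period=config.aggregation_period)
    series = phen.aggregate_survey(survey, focal=config.focal, period=config.aggregation_period)
    intermediates["phenology"] = {
        "period": config.aggregation_period,
        "series": phen.series_to_frame(series, config.focal, config.other).to_dict("records"),
        "ri": values,
    }
    return values


def _pollinator_stage(config: RunConfig, intermediates: dict) -> dict[str, float]:
    table = poll.read_visitation(config.visitation)
    a, b = table.ecotypes
    d = poll.bray_curtis(table.column(a), table.column(b))
    ri = poll.ri_pollinator(table)
    test = poll.visitation_rank_test(table)
    intermediates["pollinators"] = {
        "bray_curtis": d,
        "rank_test": test.as_dict(),
        "ri": {a: ri, b: ri},
    }
    return {a: ri, b: ri}


def _crossing_stage(config: RunConfig, intermediates: dict) -> tuple[str, dict[str, float]]:
    records = crossing_mod.read_crosses(config.crosses)
    crossing_mod.validate_records(records)
    maternal = {r.maternal_ecotype for r in records if r.treatment is not None}
    if len(maternal) != 1:
        raise ValueError(f"expected one maternal ecotype, found {sorted(maternal)}")
    direction = maternal.pop()
    stage_to_barrier = {
        "adhesion": "pollen_adhesion",
        "germination": "pollen_germination",
        "seed_set": "seed_development",
    }
    values, inter = {}, {}
    for stage, barrier in stage_to_barrier.items():
        summary = crossing_mod.analyze_stage(records, stage)
        values[barrier] = summary.ri
        inter[stage] = {
            "parental_metric": summary.parental_metric,
            "hybrid_metric": summary.hybrid_metric,
            "parental_se": summary.parental_se,
            "hybrid_se": summary.hybrid_se,
            "n_parental": summary.n_parental,
            "n_hybrid": summary.n_hybrid,
            "test": summary.test.as_dict(),
            "ri": summary.ri,
        }
    intermediates["crossing"] = {"direction": direction, "stages": inter}
    return direction, values


def run_pipeline(config: RunConfig) -> dict:
    """Run every configured stage and write the report bundle.

    Writes barrier_table.csv, cascade.json, intermediates.json and
    manifest.json to the output directory and returns the cascade payload.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    intermediates: dict = {}
    barrier_values: dict[str, dict[str, float]] = {config.focal: {}, config.other: {}}

    have_eco = all((config.suitability_focal, config.suitability_other, config.occurrences))
    if have_eco:
        for label, v in _ecogeography_stage(config, intermediates).items():
            barrier_values[label]["ecogeography"] = v
    else:
        logger.info("ecogeography skipped: missing raster or occurrence inputs")
    if config.survey:
        for label, v in _phenology_stage(config, intermediates).items():
            barrier_values[label]["phenology"] = v
    else:
        logger.info("phenology skipped: no survey input")
    if config.visitation:
        for label, v in _pollinator_stage(config, intermediates).items():
            barrier_values[label]["pollinator_assemblage"] = v
    else:
        logger.info("pollinators skipped: no visitation input")
    if config.crosses:
        direction, values = _crossing_stage(config, intermediates)
        if direction not in barrier_values:
            raise ValueError(
                f"maternal ecotype {direction!r} does not match configured labels "
                f"{sorted(barrier_values)}"
            )
        barrier_values[direction].update(values)
    else:
        logger.info("crossing skipped: no hand-cross input")

    methods = {
        "ecogeography": "RI4C",
        "phenology": "RI4S2",
        "pollinator_assemblage": "RI4C",
        "pollen_adhesion": "RI4A",
        "pollen_germination": "RI4A",
        "seed_development": "RI4A",
    }
    barriers: list[ri_core.BarrierStrength] = []
    for focal in (config.focal, config.other):
        for name in ri_core.BARRIER_ORDER:
            if name in barrier_values[focal]:
                barriers.append(
                    ri_core.barrier_for(name, focal, barrier_values[focal][name], methods[name])
                )
            else:
                barriers.append(
                    ri_core.barrier_for(name, focal, math.nan, methods[name], available=False)
                )
    ri_core.write_barrier_table(barriers, out / "barrier_table.csv")

    cascade_payload: dict = {}
    for focal in (config.focal, config.other):
        own = tuple(b for b in barriers if b.focal == focal)
        if not any(b.available for b in own):
            cascade_payload[focal] = None
            continue
        cascade = ri_core.BarrierCascade(own, baseline_gene_flow=config.baseline_gene_flow)
        result = ri_core.cascade_total(cascade)
        entry = {
            "total": result.total,
            "contributions": result.as_frame().to_dict("records"),
        }
        non_eco = tuple(b for b in own if b.available and b.barrier_name != "ecogeography")
        if non_eco:
            sympatry = ri_core.cascade_total(
                ri_core.BarrierCascade(
                    own, include_ecogeography=False, baseline_gene_flow=config.baseline_gene_flow
                )
            )
            entry["sympatry_total"] = sympatry.total
            entry["sympatry_contributions"] = sympatry.as_frame().to_dict("records")
        if any(b.available and b.barrier_name == "ecogeography" for b in own):
            entry["ri_4e_total"] = ri_core.ri_4e_from_barriers(cascade)
        cascade_payload[focal] = entry

    if config.round_to is not None:
        cascade_payload = _round_nested(cascade_payload, config.round_to)
        intermediates = _round_nested(intermediates, config.round_to)

    (out / "cascade.json").write_text(json.dumps(cascade_payload, indent=2, default=_json_default) + "\n")
    (out / "intermediates.json").write_text(
        json.dumps(intermediates, indent=2, default=_json_default) + "\n"
    )
    _write_manifest(config, out)
    return cascade_payload


def _round_nested(obj, ndigits: int):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_nested(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, list):
        return [_round_nested(v, ndigits) for v in obj]
    return obj


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _write_manifest(config: RunConfig, out: Path) -> None:
    from . import __version__

    inputs = {}
    for name in ("suitability_focal", "suitability_other", "occurrences", "survey", "visitation", "crosses"):
        path = getattr(config, name)
        if path and Path(path).exists():
            digest = hashlib.sha256(Path(path).read_bytes()).hexdigest()
            inputs[name] = {"path": str(path), "sha256": digest}
    manifest = {
        "package_version": __version__,
        "config": dataclasses.asdict(config),
        "inputs": inputs,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
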